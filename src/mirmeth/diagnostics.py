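"""Per-miR diagnostic threshold analysis against hypermethylator status.

Low expression is the hypothesized predictor of the hypermethylator
phenotype, so a sample is predicted positive when its expression is <= the
threshold; the optimizer never searches the reverse direction. Thresholds
are chosen to maximize correct assignments (CA, accuracy) over candidate
cutpoints placed at midpoints between consecutive distinct observed values
plus one candidate below the minimum and one above the maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig, Subtype
from .errors import AnalysisError, ValidationError
from .quant import ExpressionMatrix


def round_percent(fraction: float, rounding: str = "half_up") -> int:
    """Round 100*fraction to an integer percent.

    half_up rounds .5 away from zero (the convention that reproduces
    10/16 -> 63 and 11/16 -> 69); banker delegates to Python's round.
    """
    pct = 100.0 * fraction
    if rounding == "half_up":
        return int(math.floor(pct + 0.5))
    if rounding == "banker":
        return round(pct)
    raise ValueError(f"unknown rounding rule {rounding!r}")


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 table; positive = hypermethylator, predicted by low expression."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Integer-percent diagnostic metrics plus the unrounded fractions.

    A metric whose denominator is zero is None (reported as NA).
    """

    sensitivity: int | None
    specificity: int | None
    ppv: int | None
    npv: int | None
    ca: int | None
    fractions: dict[str, float | None]


@dataclass(frozen=True)
class ThresholdResult:
    assay_id: str
    threshold: float
    metrics: DiagnosticMetrics
    confusion: ConfusionTable
    tie_set_size: int
    n: int


def confusion_from_calls(predicted_positive: pd.Series,
                         truth: pd.Series) -> ConfusionTable:
    """Exact 2x2 counts from aligned boolean series."""
    if set(predicted_positive.index) != set(truth.index):
        raise ValidationError(
            "prediction and truth cover different sample sets"
        )
    pred = predicted_positive.reindex(truth.index).astype(bool)
    t = truth.astype(bool)
    return ConfusionTable(
        tp=int((pred & t).sum()),
        fp=int((pred & ~t).sum()),
        tn=int((~pred & ~t).sum()),
        fn=int((~pred & t).sum()),
    )


def _safe_frac(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metrics_from_confusion(c: ConfusionTable,
                           rounding: str = "half_up") -> DiagnosticMetrics:
    fractions = {
        "sensitivity": _safe_frac(c.tp, c.tp + c.fn),
        "specificity": _safe_frac(c.tn, c.tn + c.fp),
        "ppv": _safe_frac(c.tp, c.tp + c.fp),
        "npv": _safe_frac(c.tn, c.tn + c.fn),
        "ca": _safe_frac(c.tp + c.tn, c.n),
    }
    rounded = {
        k: None if v is None else round_percent(v, rounding)
        for k, v in fractions.items()
    }
    return DiagnosticMetrics(fractions=fractions, **rounded)


def candidate_thresholds(values: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct values, plus one candidate
    below the minimum and one above the maximum."""
    distinct = np.unique(values)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    # adjacent floats can round the midpoint onto the upper value, which
    # would silently merge two prediction sets; fall back to the lower value
    mids = np.where(mids >= distinct[1:], distinct[:-1], mids)
    below = distinct[0] - max(1.0, abs(distinct[0]))
    above = distinct[-1] + max(1.0, abs(distinct[-1]))
    return np.concatenate(([below], mids, [above]))


def optimize_threshold(expression: pd.Series, truth: pd.Series,
                       rounding: str = "half_up",
                       assay_id: str = "?") -> ThresholdResult:
    """CA-maximizing threshold for one miR (positive iff expression <= t).

    CA is maximized on unrounded fractions. Ties are broken by highest
    sensitivity, then by the largest threshold (most inclusive for
    positives); the number of CA-maximizing candidates is reported as
    ``tie_set_size``.
    """
    joined = pd.DataFrame({"x": expression, "y": truth}).dropna(subset=["x"])
    if len(joined) < 2:
        raise AnalysisError(f"{assay_id}: need >=2 samples with expression")
    y = joined["y"].astype(bool)
    if y.all() or (~y).all():
        raise AnalysisError(
            f"{assay_id}: both truth classes required to optimize a threshold"
        )
    x = joined["x"].to_numpy(dtype=float)

    # CA and sensitivity compared as integer counts (tp+tn and tp): the
    # denominators are fixed, so ties are exact rather than fp-tolerant
    best: tuple[int, int, float] | None = None  # (tp+tn, tp, threshold)
    best_conf: ConfusionTable | None = None
    tie_set = 0
    for t in candidate_thresholds(x):
        conf = confusion_from_calls(
            pd.Series(x <= t, index=joined.index), y
        )
        correct = conf.tp + conf.tn
        if best is None or correct > best[0]:
            best, best_conf, tie_set = (correct, conf.tp, t), conf, 1
        elif correct == best[0]:
            tie_set += 1
            if (conf.tp, t) > (best[1], best[2]):
                best, best_conf = (correct, conf.tp, t), conf
    assert best is not None and best_conf is not None

    return ThresholdResult(
        assay_id=assay_id,
        threshold=float(best[2]),
        metrics=metrics_from_confusion(best_conf, rounding),
        confusion=best_conf,
        tie_set_size=tie_set,
        n=len(joined),
    )


def evaluate_panel(
    matrix: ExpressionMatrix,
    scores: pd.DataFrame,
    config: RunConfig,
    subset: list[str] | None = None,
) -> list[ThresholdResult]:
    """One ThresholdResult per panel miR over the evaluation subset.

    The default subset is the basal-like tumors, the group in which low miR
    expression is evaluated as a predictor of the hypermethylator phenotype.
    """
    if subset is None:
        subset = list(
            scores.index[scores["subtype"] == Subtype.BASAL_LIKE.value]
        )
    subset = [s for s in subset if s in scores.index]
    if not subset:
        raise AnalysisError("evaluation subset is empty")
    truth = scores.loc[subset, "hypermethylator"].astype(bool)
    if truth.all() or (~truth).all():
        raise AnalysisError(
            "evaluation subset must contain both hypermethylator and "
            "non-hypermethylator samples"
        )
    results = []
    for assay_id in config.mir_panel:
        expr = matrix.values.loc[matrix.values.index.isin(subset), assay_id]
        expr = expr.reindex(subset)
        results.append(
            optimize_threshold(expr, truth, config.rounding, assay_id)
        )
    return results
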