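"""Group summaries, unpaired t-tests and Pearson correlations.

No multiple-testing correction is applied anywhere; the pairwise
correlation output records how many tests were performed so readers can
judge significance accordingly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import metadata_frame
from .config import Role, SampleMeta, Subtype, TUMOR_SUBTYPES
from .errors import AnalysisError
from .quant import ExpressionMatrix


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float
    sem: float


@dataclass(frozen=True)
class TTestResult:
    mean_a: float
    mean_b: float
    t: float
    p: float
    df: float
    variant: str


@dataclass(frozen=True)
class CorrelationResult:
    x_name: str
    y_name: str
    n: int
    r: float
    p: float


def _sem(values: np.ndarray) -> float:
    n = values.size
    if n == 1:
        return 0.0
    return float(values.std(ddof=1) / math.sqrt(n))


def subtype_summaries(
    matrix: ExpressionMatrix,
    meta: list[SampleMeta],
    panel: tuple[str, ...],
) -> list[GroupSummary]:
    """Mean +/- SEM of relative expression per tumor subtype per assay.

    Normal (calibrator) samples are excluded. Returned labels are
    "<subtype>/<assay>"; empty subtypes are omitted.
    """
    meta_df = metadata_frame(meta)
    out: list[GroupSummary] = []
    for subtype in TUMOR_SUBTYPES:
        ids = meta_df.index[
            (meta_df["subtype"] == subtype.value)
            & (meta_df["role"] == Role.TUMOR.value)
        ]
        sub = matrix.values.loc[matrix.values.index.isin(set(ids))]
        if sub.empty:
            continue
        for assay in panel:
            vals = sub[assay].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            out.append(
                GroupSummary(
                    group=f"{subtype.value}/{assay}",
                    n=int(vals.size),
                    mean=float(vals.mean()),
                    sem=_sem(vals),
                )
            )
    return out


def unpaired_t(group_a, group_b, variant: str = "student") -> TTestResult:
    """Two-tailed unpaired t-test (Student pooled-variance or Welch)."""
    a = np.asarray(pd.Series(group_a, dtype=float).dropna(), dtype=float)
    b = np.asarray(pd.Series(group_b, dtype=float).dropna(), dtype=float)
    if a.size < 2 or b.size < 2:
        raise AnalysisError("each group needs n >= 2 for an unpaired t-test")
    equal_var = variant == "student"
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = float(a.size + b.size - 2)
    else:
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        df = float(
            (va + vb) ** 2
            / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        )
    # identical groups give t = 0/0 in scipy (nan); define t=0, p=1
    if math.isnan(t):
        t, p = 0.0, 1.0
    return TTestResult(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t=float(t),
        p=float(p),
        df=df,
        variant=variant,
    )


def pearson_with_p(x, y, x_name: str = "x", y_name: str = "y") -> CorrelationResult:
    """Pearson r with two-sided p from the t transform with n-2 df."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    keep = ~(np.isnan(xv) | np.isnan(yv))
    xv, yv = xv[keep], yv[keep]
    if xv.size < 3:
        raise AnalysisError(
            f"correlation of {x_name} vs {y_name} needs n >= 3 complete pairs"
        )
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise AnalysisError(
            f"correlation of {x_name} vs {y_name} undefined: zero variance"
        )
    res = stats.pearsonr(xv, yv)
    return CorrelationResult(
        x_name=x_name,
        y_name=y_name,
        n=int(xv.size),
        r=float(res.statistic),
        p=float(res.pvalue),
    )


def score_correlation(scores: pd.DataFrame,
                      subset: list[str] | None = None) -> CorrelationResult:
    """Pearson correlation between miR score and gene-expression score.

    Defaults to basal-like tumors, the group in which the score
    relationship is evaluated.
    """
    if subset is None:
        subset = list(
            scores.index[scores["subtype"] == Subtype.BASAL_LIKE.value]
        )
    sub = scores.loc[scores.index.isin(set(subset))]
    return pearson_with_p(
        sub["mir_score"], sub["gene_score"],
        x_name="mir_score", y_name="gene_score",
    )


def pairwise_mir_correlations(
    matrix: ExpressionMatrix,
    mir_panel: tuple[str, ...],
    subset: list[str] | None = None,
) -> list[CorrelationResult]:
    """Pearson r for every unordered miR pair, pairwise-complete.

    Defaults to all samples in the matrix (tumors if the matrix was built
    on tumors). n is reported per pair as actually used.
    """
    vals = matrix.values
    if subset is not None:
        vals = vals.loc[vals.index.isin(set(subset))]
    out = []
    for a, b in itertools.combinations(mir_panel, 2):
        out.append(pearson_with_p(vals[a], vals[b], x_name=a, y_name=b))
    return out
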