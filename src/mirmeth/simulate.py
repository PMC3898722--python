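"""Synthetic cohort generator with known ground truth.

Cohorts mirror the study design (70 tumors across four subtypes plus 18
normal calibrators) and the structure the analysis assumes: a latent
hypermethylator state, drawn per subtype prevalence, jointly suppresses the
nine methylation-sensitive genes and the regulatory miRs (except miR-29c,
which is suppressed in all basal-like tumors regardless of latent state;
miR-203 carries a luminal-A effect instead). Biological variation is
log-normal on the fold scale; fold changes are inverted to triplicate Ct
values so the full quantification path can be exercised end to end.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CtTable
from .config import RunConfig, Role, SampleMeta, Subtype
from .errors import ConfigError

# fixed per-assay offset between target and reference Ct; arbitrary but
# recorded so zero-noise round trips are bit-exact
BASELINE_DELTA_CT = 4.0


@dataclass
class CohortSimParams:
    """Generative parameters; defaults qualitatively reproduce the study's
    subtype patterns and are parameters, not claims."""

    n_luminal_a: int = 36
    n_luminal_b: int = 13
    n_her2: int = 5
    n_basal: int = 16
    n_normal: int = 18
    p_hyper_basal: float = 9 / 16
    p_hyper_nonbasal: float = 0.08
    gene_suppression_log2: float = -3.0
    mir_suppression_log2: float = -1.5
    mir29c_basal_log2: float = -1.5
    mir203_luminalA_log2: float = -1.5
    # shared latent factor on miR-26a/miR-26b encoding their co-regulation
    mir26_shared_sd_log2: float = 0.8
    biological_sd_log2: float = 0.8
    ct_replicate_sd: float = 0.15
    reference_ct_mean: float = 24.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_luminal_a", "n_luminal_b", "n_her2", "n_basal",
                     "n_normal", "n_replicates"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.n_normal < 1:
            raise ConfigError("need at least one normal calibrator sample")
        for name in ("p_hyper_basal", "p_hyper_nonbasal"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        for name in ("biological_sd_log2", "ct_replicate_sd",
                     "mir26_shared_sd_log2"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")

    @classmethod
    def from_dict(cls, raw: dict) -> "CohortSimParams":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown simulation keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class GroundTruth:
    """Latent state and true mean log2 fold per sample."""

    hypermethylator: dict[str, bool]
    true_log2_fold: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        return cls(**raw)


def expression_to_ct(
    true_fold: float,
    reference_ct: float,
    replicate_sd: float,
    n_replicates: int,
    rng: np.random.Generator,
    baseline_delta: float = BASELINE_DELTA_CT,
) -> tuple[np.ndarray, float]:
    """Invert a fold change to noisy target Ct replicates.

    Target replicates ~ Normal(reference_ct + baseline_delta - log2(fold),
    replicate_sd); quantification recovers the fold up to replicate noise.
    Returns (replicates, noiseless mean).
    """
    if not true_fold > 0:
        raise ConfigError(f"fold change must be positive, got {true_fold}")
    center = reference_ct + baseline_delta - float(np.log2(true_fold))
    if replicate_sd == 0:
        return np.full(n_replicates, center), center
    return center + rng.normal(0.0, replicate_sd, size=n_replicates), center


def _sample_plan(params: CohortSimParams) -> list[SampleMeta]:
    plan = [
        (Subtype.LUMINAL_A, "LA", params.n_luminal_a),
        (Subtype.LUMINAL_B, "LB", params.n_luminal_b),
        (Subtype.HER2_ENRICHED, "H", params.n_her2),
        (Subtype.BASAL_LIKE, "B", params.n_basal),
        (Subtype.NORMAL, "N", params.n_normal),
    ]
    samples = []
    for subtype, prefix, n in plan:
        role = Role.CALIBRATOR if subtype is Subtype.NORMAL else Role.TUMOR
        for i in range(1, n + 1):
            samples.append(
                SampleMeta(f"{prefix}{i:02d}", subtype, role)
            )
    return samples


def _true_log2_fold(
    sample: SampleMeta,
    assay_id: str,
    hyper: bool,
    config: RunConfig,
    params: CohortSimParams,
) -> float:
    """Deterministic part of the per-assay log2 fold for one sample."""
    if sample.subtype is Subtype.NORMAL:
        return 0.0
    effect = 0.0
    if assay_id in config.gene_panel and hyper:
        effect += params.gene_suppression_log2
    if assay_id in config.mir_panel:
        if assay_id == "miR-29c":
            if sample.subtype is Subtype.BASAL_LIKE:
                effect += params.mir29c_basal_log2
        elif hyper:
            effect += params.mir_suppression_log2
        if assay_id == "miR-203" and sample.subtype is Subtype.LUMINAL_A:
            effect += params.mir203_luminalA_log2
    return effect


def simulate_cohort(
    params: CohortSimParams,
    config: RunConfig | None = None,
) -> tuple[CtTable, list[SampleMeta], GroundTruth]:
    """Draw one cohort: Ct records, metadata and ground truth.

    Fully reproducible from ``params.seed``.
    """
    if config is None:
        config = RunConfig()
    rng = np.random.default_rng(params.seed)
    samples = _sample_plan(params)

    hyper: dict[str, bool] = {}
    for s in samples:
        if s.subtype is Subtype.NORMAL:
            hyper[s.sample_id] = False
        elif s.subtype is Subtype.BASAL_LIKE:
            hyper[s.sample_id] = bool(rng.random() < params.p_hyper_basal)
        else:
            hyper[s.sample_id] = bool(rng.random() < params.p_hyper_nonbasal)

    truth = GroundTruth(hypermethylator=hyper)
    records: list[dict] = []

    def emit(sample_id: str, assay_id: str, assay_class: str,
             reps: np.ndarray) -> None:
        for i, ct in enumerate(reps, start=1):
            records.append(
                {
                    "sample_id": sample_id,
                    "assay_id": assay_id,
                    "assay_class": assay_class,
                    "replicate": i,
                    "ct": float(ct),
                }
            )

    for s in samples:
        truth.true_log2_fold[s.sample_id] = {}
        shared26 = 0.0
        if s.role is Role.TUMOR and params.mir26_shared_sd_log2 > 0:
            shared26 = rng.normal(0.0, params.mir26_shared_sd_log2)
        for ref in (config.mir_reference, config.gene_reference):
            if params.ct_replicate_sd == 0:
                reps = np.full(params.n_replicates, params.reference_ct_mean)
            else:
                reps = params.reference_ct_mean + rng.normal(
                    0.0, params.ct_replicate_sd, size=params.n_replicates
                )
            emit(s.sample_id, ref, config.assay_class(ref).value, reps)
        for assay_id in config.panel_assays:
            mu = _true_log2_fold(s, assay_id, hyper[s.sample_id], config, params)
            if assay_id in ("miR-26a", "miR-26b"):
                mu += shared26
            if params.biological_sd_log2 > 0:
                mu = mu + rng.normal(0.0, params.biological_sd_log2)
            truth.true_log2_fold[s.sample_id][assay_id] = float(mu)
            reps, _ = expression_to_ct(
                2.0**mu,
                params.reference_ct_mean,
                params.ct_replicate_sd,
                params.n_replicates,
                rng,
            )
            emit(s.sample_id, assay_id, config.assay_class(assay_id).value, reps)

    df = pd.DataFrame.from_records(
        records,
        columns=["sample_id", "assay_id", "assay_class", "replicate", "ct"],
    )
    return CtTable(df=df), samples, truth
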