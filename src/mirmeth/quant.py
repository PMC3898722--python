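"""Comparative-Ct (2^-ddCt) relative quantification.

Triplicate Cts are collapsed to a mean per sample x assay, normalized to the
matching reference assay (dCt), then to the mean dCt of the calibrator
(normal) group, and expressed as fold change 2^-(dCt - calibrator dCt).
Amplification efficiency is fixed at 2; there is no efficiency correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CtTable, metadata_frame
from .config import AssayClass, Role, RunConfig, SampleMeta
from .errors import AnalysisError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean Ct over usable replicates of one sample x assay."""

    mean: float
    sem: float
    n: int


@dataclass(frozen=True)
class DeltaCt:
    sample_id: str
    assay_id: str
    delta_ct: float
    replicate_n: int
    replicate_sem: float


@dataclass
class ExpressionMatrix:
    """Samples x assays relative expression, fold change vs calibrator mean.

    ``values``: DataFrame indexed by sample_id, one column per panel assay;
    NaN marks a sample x assay with no usable measurement.
    ``calibrator_delta_ct``: per-assay mean dCt over calibrator samples,
    kept for audit.
    """

    values: pd.DataFrame
    calibrator_delta_ct: pd.Series

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def assay_ids(self) -> list[str]:
        return list(self.values.columns)


def collapse_replicates(cts: "pd.Series | np.ndarray | list") -> ReplicateSummary | None:
    """Mean/SEM/n over non-missing replicates; None when none are usable.

    SEM is the sample standard deviation (ddof=1) over sqrt(n); 0 for n=1.
    """
    arr = np.asarray(pd.Series(cts, dtype=float).dropna(), dtype=float)
    n = arr.size
    if n == 0:
        return None
    mean = float(arr.mean())
    sem = 0.0 if n == 1 else float(arr.std(ddof=1) / math.sqrt(n))
    return ReplicateSummary(mean=mean, sem=sem, n=n)


def delta_ct(target: ReplicateSummary, reference: ReplicateSummary,
             sample_id: str, assay_id: str) -> DeltaCt:
    """dCt = mean target Ct - mean reference Ct for the same sample."""
    return DeltaCt(
        sample_id=sample_id,
        assay_id=assay_id,
        delta_ct=target.mean - reference.mean,
        replicate_n=target.n,
        replicate_sem=target.sem,
    )


def relative_expression(sample_delta_ct: float, calibrator_delta_ct: float) -> float:
    """Fold change 2^-(dCt_sample - dCt_calibrator)."""
    return float(2.0 ** -(sample_delta_ct - calibrator_delta_ct))


def _reference_for(assay_class: AssayClass, config: RunConfig) -> str:
    if assay_class is AssayClass.MIR:
        return config.mir_reference
    return config.gene_reference


def build_expression_matrix(
    ct_table: CtTable,
    meta: list[SampleMeta],
    config: RunConfig,
) -> ExpressionMatrix:
    """Assemble the full relative-expression matrix for both panels.

    miR assays normalize to ``config.mir_reference``, gene assays to
    ``config.gene_reference``; both calibrate against the mean dCt of the
    calibrator group. An assay with no calibrator data at all is an error;
    a sample missing its reference assay loses that panel's cells only.
    """
    meta_df = metadata_frame(meta)
    calibrator_ids = set(meta_df.index[meta_df["role"] == Role.CALIBRATOR.value])
    if not calibrator_ids:
        raise AnalysisError("no calibrator samples available for quantification")

    df = ct_table.df
    df = df[df["sample_id"].isin(meta_df.index)]

    # mean Ct per sample x assay (None when all replicates undetermined)
    mean_ct: dict[tuple[str, str], ReplicateSummary] = {}
    for (sample_id, assay_id), grp in df.groupby(["sample_id", "assay_id"]):
        summary = collapse_replicates(grp["ct"])
        if summary is not None:
            mean_ct[(sample_id, assay_id)] = summary

    sample_ids = list(meta_df.index)
    panel = [a for a in config.panel_assays if (df["assay_id"] == a).any()]

    dct = pd.DataFrame(np.nan, index=pd.Index(sample_ids, name="sample_id"),
                       columns=panel)
    for assay_id in panel:
        ref_assay = _reference_for(config.assay_class(assay_id), config)
        for sample_id in sample_ids:
            target = mean_ct.get((sample_id, assay_id))
            if target is None:
                continue
            reference = mean_ct.get((sample_id, ref_assay))
            if reference is None:
                logger.warning(
                    "sample %s lacks reference assay %s; %s left missing",
                    sample_id, ref_assay, assay_id,
                )
                continue
            d = delta_ct(target, reference, sample_id, assay_id)
            dct.loc[sample_id, assay_id] = d.delta_ct

    calib = dct.loc[dct.index.isin(calibrator_ids)]
    calibrator_delta_ct = calib.mean(axis=0, skipna=True)
    missing_calib = [a for a in panel if math.isnan(calibrator_delta_ct[a])]
    if missing_calib:
        raise AnalysisError(
            "no calibrator measurements for assays: "
            f"{missing_calib}; cannot compute relative expression"
        )

    values = 2.0 ** -(dct.sub(calibrator_delta_ct, axis=1))
    return ExpressionMatrix(values=values, calibrator_delta_ct=calibrator_delta_ct)
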