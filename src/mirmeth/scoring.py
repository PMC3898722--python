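"""Median binarization, panel scores and hypermethylator classification.

A panel measurement is called ``low`` when it falls strictly below the
per-assay median of the configured population (ties at the median are
``normal``). The gene-expression score counts low calls over the 9-gene
panel; a tumor is a hypermethylator when that score reaches the configured
cutoff (default >=7 of 9). The miR score counts low calls over the 9-miR
panel and partitions tumors into low (score >= cutoff, default 6) and high
expression groups.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cohort import metadata_frame
from .config import Role, RunConfig, SampleMeta
from .errors import AnalysisError
from .quant import ExpressionMatrix

logger = logging.getLogger(__name__)

LOW = "low"
NORMAL = "normal"
MISSING = "missing"


def compute_medians(matrix: ExpressionMatrix, population: list[str]) -> pd.Series:
    """Per-assay median over the given sample subset, missing cells excluded.

    Standard median: midpoint of the two central order statistics for even n.
    """
    sub = matrix.values.loc[matrix.values.index.isin(set(population))]
    if sub.empty:
        raise AnalysisError("median population is empty")
    medians = sub.median(axis=0, skipna=True)
    dead = [a for a in medians.index if np.isnan(medians[a])]
    if dead:
        raise AnalysisError(
            f"assays with no values in the median population: {dead}"
        )
    return medians


def binarize(matrix: ExpressionMatrix, medians: pd.Series) -> pd.DataFrame:
    """Call each cell low/normal/missing against its assay median."""
    uncovered = [a for a in matrix.assay_ids if a not in medians.index]
    if uncovered:
        raise AnalysisError(f"medians missing for assays: {uncovered}")
    vals = matrix.values
    calls = pd.DataFrame(MISSING, index=vals.index, columns=vals.columns)
    present = vals.notna()
    low = vals.lt(medians, axis=1) & present
    calls = calls.mask(present & ~low, NORMAL).mask(low, LOW)
    return calls


def _count_low(row: pd.Series, panel: tuple[str, ...], sample_id: str) -> int:
    n_missing = int((row[list(panel)] == MISSING).sum())
    if n_missing:
        # missing counts as normal: conservative, but make it visible
        logger.warning("sample %s: %d missing panel calls counted as normal",
                       sample_id, n_missing)
    return int((row[list(panel)] == LOW).sum())


def gene_expression_score(row: pd.Series, gene_panel: tuple[str, ...],
                          sample_id: str = "?") -> int:
    """Number of panel genes called low; missing counts as normal."""
    return _count_low(row, gene_panel, sample_id)


def call_hypermethylator(gene_score: int, cutoff: int = 7) -> bool:
    """Hypermethylator phenotype when the gene score reaches the cutoff."""
    return gene_score >= cutoff


def mir_score_and_group(row: pd.Series, mir_panel: tuple[str, ...],
                        cutoff: int = 6, sample_id: str = "?") -> tuple[int, str]:
    """(miR score, expression group): low when score >= cutoff, else high."""
    score = _count_low(row, mir_panel, sample_id)
    return score, (LOW if score >= cutoff else "high")


def score_cohort(
    matrix: ExpressionMatrix,
    meta: list[SampleMeta],
    config: RunConfig,
) -> pd.DataFrame:
    """Per-tumor score table.

    Columns: subtype, gene_score, mir_score, hypermethylator, mir_group,
    plus one call column per panel assay. Medians are computed over the
    population selected by ``config.median_population`` but scores are
    reported for tumor samples only.
    """
    meta_df = metadata_frame(meta)
    tumors = list(meta_df.index[meta_df["role"] == Role.TUMOR.value])
    if config.median_population == "tumors_only":
        population = tumors
    else:
        population = list(meta_df.index)

    medians = compute_medians(matrix, population)
    calls = binarize(matrix, medians)

    rows = []
    for sample_id in tumors:
        if sample_id not in calls.index:
            continue
        row = calls.loc[sample_id]
        gene_score = gene_expression_score(row, config.gene_panel, sample_id)
        mir_score, mir_group = mir_score_and_group(
            row, config.mir_panel, config.mir_low_group_cutoff, sample_id
        )
        rows.append(
            {
                "sample_id": sample_id,
                "subtype": meta_df.loc[sample_id, "subtype"],
                "gene_score": gene_score,
                "mir_score": mir_score,
                "hypermethylator": call_hypermethylator(
                    gene_score, config.hypermethylator_gene_cutoff
                ),
                "mir_group": mir_group,
                **{a: row[a] for a in config.panel_assays if a in row.index},
            }
        )
    scores = pd.DataFrame(rows).set_index("sample_id")
    scores.attrs["medians"] = medians.to_dict()
    scores.attrs["median_population"] = config.median_population
    return scores
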