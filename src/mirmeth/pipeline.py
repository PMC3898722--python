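"""End-to-end orchestration: quantify -> score -> diagnose -> associate."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .association import (
    pairwise_mir_correlations,
    score_correlation,
    subtype_summaries,
    unpaired_t,
)
from .cohort import CtTable, metadata_frame
from .config import Role, RunConfig, SampleMeta, Subtype
from .errors import AnalysisError
from .quant import ExpressionMatrix, build_expression_matrix
from .scoring import score_cohort


@dataclass
class PipelineResult:
    matrix: ExpressionMatrix
    scores: pd.DataFrame
    diagnostics: list
    associations: dict


def run_pipeline(
    ct_table: CtTable,
    meta: list[SampleMeta],
    config: RunConfig,
) -> PipelineResult:
    """Run the full analysis on one cohort.

    Associations comprise per-subtype miR summaries, hypermethylator-vs-not
    t-tests per miR among basal-like tumors, the miR-score/gene-score
    correlation, and all pairwise miR correlations over tumors.
    """
    from .diagnostics import evaluate_panel  # local to keep imports acyclic

    matrix = build_expression_matrix(ct_table, meta, config)
    scores = score_cohort(matrix, meta, config)

    meta_df = metadata_frame(meta)
    tumors = list(meta_df.index[meta_df["role"] == Role.TUMOR.value])
    basal = list(scores.index[scores["subtype"] == Subtype.BASAL_LIKE.value])

    try:
        diagnostics = evaluate_panel(matrix, scores, config)
    except AnalysisError:
        diagnostics = []

    group_tests = {}
    truth = scores.loc[basal, "hypermethylator"].astype(bool)
    if 2 <= truth.sum() and 2 <= (~truth).sum():
        hyper_ids = list(truth.index[truth])
        nonhyper_ids = list(truth.index[~truth])
        for assay in config.mir_panel:
            a = matrix.values.loc[hyper_ids, assay].dropna()
            b = matrix.values.loc[nonhyper_ids, assay].dropna()
            if len(a) >= 2 and len(b) >= 2:
                group_tests[assay] = unpaired_t(a, b, config.t_test_variant)

    associations = {
        "subtype_summaries": subtype_summaries(matrix, meta, config.mir_panel),
        "group_tests": group_tests,
        "correlations": {
            "n_pairwise_tests": len(config.mir_panel)
            * (len(config.mir_panel) - 1)
            // 2,
            "pairwise_mir": pairwise_mir_correlations(
                matrix, config.mir_panel, subset=tumors
            ),
        },
    }
    try:
        associations["correlations"]["score_vs_score"] = score_correlation(scores)
    except AnalysisError:
        associations["correlations"]["score_vs_score"] = None

    return PipelineResult(
        matrix=matrix,
        scores=scores,
        diagnostics=diagnostics,
        associations=associations,
    )
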