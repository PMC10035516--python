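"""End-to-end convenience: anchor -> SAM signature -> subgroups -> immune profile."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .clustering import (
    LinkageRecord,
    SubgroupAssignment,
    assign_subgroups,
    hierarchical_cluster,
    score_samples,
)
from .expression_io import ExpressionMatrix
from .immune import DEFAULT_MARKER_PANEL, CorrelationReport, correlate_score_with_markers
from .signature import (
    DEFAULT_FDR_THRESHOLD,
    DEFAULT_N_PERMUTATIONS,
    EMT_TF_CANDIDATES,
    AnchorReport,
    QuantileGroups,
    SamResult,
    Signature,
    build_signature,
    rank_anchor_variance,
    sam_two_class,
    select_quantile_groups,
)

__all__ = ["DiscoveryResult", "run_discovery"]


@dataclass
class DiscoveryResult:
    """Everything the discovery workflow produces on one cohort."""

    anchor_report: AnchorReport
    groups: QuantileGroups
    sam: SamResult
    signature: Signature
    scores: pd.Series
    linkage: LinkageRecord
    assignment: SubgroupAssignment
    correlations: CorrelationReport


def run_discovery(
    matrix: ExpressionMatrix,
    candidates: Sequence[str] = EMT_TF_CANDIDATES,
    fraction: float = 0.25,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    markers: Sequence[str] = DEFAULT_MARKER_PANEL,
    min_subgroup_size: int = 4,
) -> DiscoveryResult:
    """Run the full discovery workflow on one cohort.

    Selects the anchor by variance, forms the unique-patient quantile
    contrast groups, runs SAM, keeps genes at the FDR threshold, scores and
    clusters the samples on the signature genes, calls the four-level
    subgroup structure, and profiles score-marker correlations.
    """
    anchor_report = rank_anchor_variance(matrix, candidates)
    anchor = anchor_report.selected_anchor
    groups = select_quantile_groups(matrix, anchor, fraction)
    sam = sam_two_class(matrix, groups, n_permutations=n_permutations, seed=seed)
    signature = build_signature(sam, fdr_threshold=fdr_threshold, anchor=anchor)
    scores = score_samples(matrix, signature)
    linkage = hierarchical_cluster(matrix, signature.genes)
    assignment = assign_subgroups(
        linkage, scores, min_subgroup_size=min_subgroup_size,
        patient_ids=matrix.patient_ids,
    )
    correlations = correlate_score_with_markers(scores, matrix, markers)
    return DiscoveryResult(
        anchor_report=anchor_report,
        groups=groups,
        sam=sam,
        signature=signature,
        scores=scores,
        linkage=linkage,
        assignment=assignment,
        correlations=correlations,
    )
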