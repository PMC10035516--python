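"""Transferring a signature to an independent cohort.

The signature's genes are intersected with the cohort's symbols
(case-sensitive exact match), the cohort is re-clustered on the matched
signature genes only, the binary Cluster 1/2 partition and its Cluster-1
proportion are reported, and score-marker correlations are recomputed on
the matched up-gene subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .clustering import BinaryPartition, binary_partition, hierarchical_cluster, score_samples
from .expression_io import ExpressionMatrix
from .immune import DEFAULT_MARKER_PANEL, CorrelationReport, correlate_score_with_markers
from .signature import Signature

logger = logging.getLogger(__name__)

__all__ = ["MatchResult", "TransferReport", "intersect_signature_with_cohort", "validate_on_cohort"]

#: Below this many matched genes the signature is declared non-transferable.
MIN_MATCHED_GENES = 10


@dataclass
class MatchResult:
    """Signature genes found / not found in a cohort."""

    matched: list[str]
    missing: list[str]

    @property
    def n_matched(self) -> int:
        return len(self.matched)


def intersect_signature_with_cohort(
    signature: Signature, cohort: ExpressionMatrix
) -> MatchResult:
    """Case-sensitive exact intersection of signature genes with the cohort."""
    present = set(cohort.values.index)
    matched = [g for g in signature.genes if g in present]
    missing = [g for g in signature.genes if g not in present]
    logger.info(
        "signature transfer: %d of %d genes present in cohort",
        len(matched), len(signature),
    )
    if len(matched) < MIN_MATCHED_GENES:
        raise ValueError(
            f"only {len(matched)} signature genes present in cohort "
            f"(< {MIN_MATCHED_GENES}): signature not transferable"
        )
    return MatchResult(matched=matched, missing=missing)


@dataclass
class TransferReport:
    """Result of transferring a signature to an external cohort.

    Score-marker correlations are computed on the matched *up-gene* subset
    only, never the full signature.
    """

    cohort_name: str
    genes_in_signature: int
    genes_matched: int
    cluster1_proportion: float
    partition: BinaryPartition
    scores: pd.Series
    correlations: CorrelationReport
    matched_genes: list[str] = field(default_factory=list)


def validate_on_cohort(
    signature: Signature,
    cohort: ExpressionMatrix,
    markers: Sequence[str] = DEFAULT_MARKER_PANEL,
    cohort_name: str = "external",
) -> TransferReport:
    """Re-cluster an external cohort on the matched signature genes.

    Composes gene intersection, UPGMA clustering on matched genes, the
    binary Cluster 1/2 partition (Cluster 1 = higher mean score), signature
    scoring on matched up-genes, and score-marker correlation.
    """
    match = intersect_signature_with_cohort(signature, cohort)
    matched_up = Signature(
        anchor=signature.anchor,
        up_genes=signature.up_genes[signature.up_genes.index.isin(match.matched)],
        down_genes=signature.down_genes[signature.down_genes.index.isin(match.matched)],
        fdr_threshold=signature.fdr_threshold,
    )
    scores = score_samples(cohort, matched_up)
    record = hierarchical_cluster(cohort, match.matched)
    partition = binary_partition(record, scores)
    correlations = correlate_score_with_markers(scores, cohort, markers)
    return TransferReport(
        cohort_name=cohort_name,
        genes_in_signature=len(signature),
        genes_matched=match.n_matched,
        cluster1_proportion=partition.proportion_cluster1,
        partition=partition,
        scores=scores,
        correlations=correlations,
        matched_genes=match.matched,
    )
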