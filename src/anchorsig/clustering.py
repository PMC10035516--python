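"""Signature scoring, UPGMA clustering and subgroup calling.

A per-sample signature score is the unweighted mean of the log2 expression
of the signature's upregulated genes. Samples are clustered on the raw
(unscaled) log2 values of the signature genes with average linkage and
Euclidean distance; the two major dendrogram subbranches define the binary
cluster split, and the two principal subbranches of each major cluster give
four provisional subgroups, oriented by descending mean score (high, int1,
int2, low). Provisional subgroups smaller than a minimum size are dissolved
and their samples merged into the subgroup whose score range contains them
(else nearest mean), with every merge recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .expression_io import ExpressionMatrix
from .signature import Signature

logger = logging.getLogger(__name__)

__all__ = [
    "SUBGROUP_LABELS",
    "LinkageRecord",
    "SubgroupAssignment",
    "BinaryPartition",
    "score_samples",
    "hierarchical_cluster",
    "assign_subgroups",
    "binary_partition",
    "write_scores_and_subgroups",
    "write_linkage_table",
    "plot_signature_heatmap",
]

#: Subgroup names in descending-score order.
SUBGROUP_LABELS: tuple[str, ...] = ("high", "int1", "int2", "low")

#: Subbranches at or below this size are treated as outliers and dissolved.
DEFAULT_MIN_SUBGROUP_SIZE = 4


def score_samples(matrix: ExpressionMatrix, signature: Signature) -> pd.Series:
    """Mean log2 expression of the signature's upregulated genes, per sample.

    Up-genes absent from the matrix are skipped with a logged count; with
    none present this raises.
    """
    up = [g for g in signature.up_genes.index if g in matrix.values.index]
    missing = len(signature.up_genes) - len(up)
    if not up:
        raise ValueError("no signature up-gene present in matrix")
    if missing:
        logger.info("scoring without %d up-genes absent from matrix", missing)
    scores = matrix.values.loc[up].mean(axis=0)
    scores.name = "signature_score"
    return scores


@dataclass
class LinkageRecord:
    """UPGMA merge history over samples plus the sample order it refers to."""

    Z: np.ndarray  # scipy linkage matrix (n-1 x 4)
    sample_ids: list[str]
    genes_used: list[str]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def hierarchical_cluster(
    matrix: ExpressionMatrix, genes: Sequence[str]
) -> LinkageRecord:
    """Average-linkage (UPGMA) clustering of samples on Euclidean distance.

    Distances are computed over the listed genes' unscaled log2 values;
    genes absent from the matrix are dropped (logged). Duplicate sample
    profiles are legal (distance 0, merged first). Merge heights are
    non-decreasing (UPGMA is monotone).
    """
    present = [g for g in genes if g in matrix.values.index]
    if not present:
        raise ValueError("none of the requested genes is present in the matrix")
    if len(present) < len(genes):
        logger.info("clustering on %d of %d requested genes", len(present), len(genes))
    if matrix.n_samples < 2:
        raise ValueError("need >= 2 samples to cluster")
    data = matrix.values.loc[present].to_numpy(dtype=float).T  # samples x genes
    Z = hierarchy.linkage(pdist(data, metric="euclidean"), method="average")
    return LinkageRecord(Z=Z, sample_ids=matrix.sample_ids, genes_used=present)


def _two_cluster_cut(record: LinkageRecord) -> tuple[list[int], list[int]]:
    """Leaf index sets of the two children of the root merge."""
    root = hierarchy.to_tree(record.Z)
    return sorted(root.left.pre_order()), sorted(root.right.pre_order())


@dataclass
class BinaryPartition:
    """Two-cluster cut with Cluster 1 = higher mean signature score."""

    labels: pd.Series  # sample -> 1 or 2
    cluster_sizes: dict[int, int]
    proportion_cluster1: float
    degenerate: bool = False


def binary_partition(record: LinkageRecord, scores: pd.Series) -> BinaryPartition:
    """Cut the dendrogram at its last merge into Clusters 1 and 2.

    Cluster 1 is the side with the higher mean signature score. A cut at
    height zero (all samples identical) is flagged as degenerate.
    """
    left, right = _two_cluster_cut(record)
    ids = record.sample_ids
    mean_left = scores[[ids[i] for i in left]].mean()
    mean_right = scores[[ids[i] for i in right]].mean()
    c1, c2 = (left, right) if mean_left >= mean_right else (right, left)
    labels = pd.Series(2, index=pd.Index(ids, name="sample_id"), name="major_cluster")
    labels.iloc[c1] = 1
    degenerate = bool(record.Z[-1, 2] == 0.0)
    if degenerate:
        logger.warning("degenerate binary cut: all samples identical")
    part = BinaryPartition(
        labels=labels,
        cluster_sizes={1: len(c1), 2: len(c2)},
        proportion_cluster1=len(c1) / len(ids),
        degenerate=degenerate,
    )
    logger.info(
        "binary partition: cluster 1 n=%d (%.0f%%), cluster 2 n=%d",
        len(c1), 100 * part.proportion_cluster1, len(c2),
    )
    return part


@dataclass
class SubgroupAssignment:
    """Two-level subgroup labels with the outlier-merge audit trail.

    ``major_cluster`` is the tree-level binary cut (before any outlier
    merging); ``subgroup`` holds the oriented four-level labels after
    merging. ``merged_outliers`` records, per relabeled sample, its score
    and the target subgroup's score range. ``split_patients`` lists patients
    whose multi-lesion samples landed in different major clusters — checked
    and reported, never enforced.
    """

    linkage_record: LinkageRecord
    major_cluster: pd.Series
    subgroup: pd.Series
    merged_outliers: list[dict] = field(default_factory=list)
    split_patients: list[str] = field(default_factory=list)

    def members(self, label: str) -> list[str]:
        return list(self.subgroup.index[self.subgroup == label])


def assign_subgroups(
    record: LinkageRecord,
    scores: pd.Series,
    min_subgroup_size: int = DEFAULT_MIN_SUBGROUP_SIZE,
    patient_ids: pd.Series | None = None,
) -> SubgroupAssignment:
    """Call the four-level subgroup structure from the dendrogram.

    The two children of the root merge give the major clusters; the two
    children of each major cluster's root give up to four provisional
    subgroups. Any provisional subgroup smaller than ``min_subgroup_size``
    (when at least one larger subgroup exists) is dissolved: each of its
    samples joins the surviving subgroup whose score min-max range contains
    the sample's score, else the one with the nearest mean; every merge is
    recorded. Surviving subgroups are then labeled by descending mean
    score, the top one "high" and the bottom one "low" (int1/int2 between),
    so outlier dissolution never leaves the cohort without a high or low
    subgroup.
    """
    ids = record.sample_ids
    if len(ids) < 4:
        raise ValueError("need >= 4 samples to call subgroups")
    scores = scores[ids]

    root = hierarchy.to_tree(record.Z)
    majors = [root.left, root.right]
    mean_major = [scores.iloc[m.pre_order()].mean() for m in majors]
    if mean_major[1] > mean_major[0]:
        majors = majors[::-1]
    major_cluster = pd.Series(0, index=pd.Index(ids, name="sample_id"), name="major_cluster")
    provisional: list[list[str]] = []
    for k, node in enumerate(majors, start=1):
        leaf_ids = [ids[i] for i in node.pre_order()]
        major_cluster[leaf_ids] = k
        if node.is_leaf():
            provisional.append(leaf_ids)
        else:
            for child in (node.left, node.right):
                provisional.append([ids[i] for i in child.pre_order()])

    # provisional orientation by descending mean score (audit names)
    means = [scores[g].mean() for g in provisional]
    order = np.argsort([-m for m in means], kind="stable")
    prov_labels = list(SUBGROUP_LABELS[: len(provisional)])
    groups = {prov_labels[r]: provisional[order[r]] for r in range(len(provisional))}

    # dissolve undersized subgroups into surviving ones
    merged: list[dict] = []
    small = [lab for lab in prov_labels if len(groups[lab]) < min_subgroup_size]
    survivors = [lab for lab in prov_labels if lab not in small]
    if small and survivors:
        ranges = {
            lab: (scores[groups[lab]].min(), scores[groups[lab]].max())
            for lab in survivors
        }
        means_surv = {lab: scores[groups[lab]].mean() for lab in survivors}
        for lab in small:
            for s in groups[lab]:
                x = scores[s]
                inside = [t for t in survivors if ranges[t][0] <= x <= ranges[t][1]]
                if inside:
                    target = min(inside, key=lambda t: abs(means_surv[t] - x))
                    rule = "score in range"
                else:
                    target = min(survivors, key=lambda t: abs(means_surv[t] - x))
                    rule = "nearest mean"
                groups[target] = groups[target] + [s]
                merged.append(
                    {
                        "sample_id": s,
                        "from_subbranch": lab,
                        "to": target,
                        "score": float(x),
                        "target_range": (
                            float(ranges[target][0]),
                            float(ranges[target][1]),
                        ),
                        "rule": rule,
                    }
                )
            del groups[lab]
        if merged:
            logger.info(
                "dissolved %d undersized subgroup(s); %d sample(s) relabeled",
                len(small), len(merged),
            )
    elif small:
        logger.warning("all provisional subgroups undersized; no merging applied")

    # final orientation: surviving subgroups renamed by descending mean score
    # so the top group is always "high" and the bottom always "low"
    final_order = sorted(groups, key=lambda lab: -scores[groups[lab]].mean())
    if len(final_order) == len(SUBGROUP_LABELS):
        final_names = list(SUBGROUP_LABELS)
    else:
        middles = [f"int{i + 1}" for i in range(max(len(final_order) - 2, 0))]
        final_names = (["high"] + middles + ["low"])[: len(final_order)]
    rename = dict(zip(final_order, final_names))
    subgroup = pd.Series("", index=pd.Index(ids, name="sample_id"), name="subgroup")
    for lab, members in groups.items():
        subgroup[members] = rename[lab]
    for entry in merged:
        entry["to"] = rename[entry["to"]]

    split: list[str] = []
    if patient_ids is not None:
        for patient, grp in major_cluster.groupby(patient_ids[ids].to_numpy()):
            if grp.nunique() > 1:
                split.append(str(patient))
        if split:
            logger.warning("multi-lesion patients split across major clusters: %s", split)

    return SubgroupAssignment(
        linkage_record=record,
        major_cluster=major_cluster,
        subgroup=subgroup,
        merged_outliers=merged,
        split_patients=split,
    )


def write_scores_and_subgroups(
    assignment: SubgroupAssignment, scores: pd.Series, path
) -> None:
    """Per-sample CSV: signature score, major cluster and subgroup label."""
    frame = pd.DataFrame(
        {
            "signature_score": scores[assignment.subgroup.index],
            "major_cluster": assignment.major_cluster,
            "subgroup": assignment.subgroup,
        }
    )
    frame.to_csv(path, index_label="sample_id")


def write_linkage_table(record: LinkageRecord, path) -> None:
    """Merge history as a tab-delimited table (child ids, height, size)."""
    frame = pd.DataFrame(
        record.Z, columns=["child_a", "child_b", "height", "n_members"]
    )
    frame[["child_a", "child_b", "n_members"]] = frame[
        ["child_a", "child_b", "n_members"]
    ].astype(int)
    frame.to_csv(path, sep="\t", index_label="merge")


def plot_signature_heatmap(
    matrix: ExpressionMatrix,
    assignment: SubgroupAssignment,
    scores: pd.Series,
    path,
) -> None:
    """Heatmap of the clustered signature genes with two annotation rows
    (major cluster and subgroup), samples in dendrogram leaf order."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    record = assignment.linkage_record
    order = hierarchy.leaves_list(record.Z)
    ids = [record.sample_ids[i] for i in order]
    data = matrix.values.loc[record.genes_used, ids]

    fig, axes = plt.subplots(
        3, 1, figsize=(8, 6), height_ratios=[0.4, 0.4, 10], sharex=True
    )
    cluster_colors = {1: "tab:red", 2: "tab:blue"}
    sub_colors = {"high": "darkred", "int1": "orangered",
                  "int2": "lightblue", "low": "darkblue"}
    for ax, labels, colors in (
        (axes[0], assignment.major_cluster, cluster_colors),
        (axes[1], assignment.subgroup, sub_colors),
    ):
        for x, s in enumerate(ids):
            ax.bar(x, 1, width=1.0, color=colors.get(labels[s], "grey"))
        ax.set_ylim(0, 1)
        ax.axis("off")
    im = axes[2].imshow(data.to_numpy(), aspect="auto", cmap="RdBu_r",
                        interpolation="nearest")
    axes[2].set_xlabel("samples (dendrogram order)")
    axes[2].set_ylabel(f"{len(record.genes_used)} signature genes")
    axes[2].set_yticks([])
    fig.colorbar(im, ax=axes[2], label="log2 expression", shrink=0.6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
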