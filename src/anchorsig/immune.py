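"""Immune-marker correlation, subgroup comparisons and gene-set analyses.

Correlates per-sample signature scores with immune-checkpoint and
macrophage-marker expression (Pearson, raw p-values with a
Benjamini-Hochberg column alongside), compares expression or clinical
features across subgroups (one-way ANOVA / unpaired two-tailed t-test /
Fisher's exact), and runs Fisher-exact over-representation and exact Venn
region tabulation over gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .clustering import SUBGROUP_LABELS, SubgroupAssignment
from .expression_io import ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_MARKER_PANEL",
    "CorrelationReport",
    "GroupComparison",
    "signature_overlap",
    "OverlapReport",
    "correlate_score_with_markers",
    "compare_groups",
    "fisher_enrichment",
]

#: Immune checkpoint / macrophage markers profiled against the score.
DEFAULT_MARKER_PANEL: tuple[str, ...] = (
    "HAVCR2", "VISTA", "CTLA4", "TIGIT", "CD276", "CD163", "NOS2",
)


# ---------------------------------------------------------------------------
# Score-marker correlation
# ---------------------------------------------------------------------------


@dataclass
class CorrelationReport:
    """Pearson correlations of the score with each marker.

    ``table`` has one row per computable marker (r, p_value, q_bh, n),
    sorted by descending r; ``missing`` lists (marker, reason) pairs for
    markers that were absent or had zero variance.
    """

    table: pd.DataFrame
    missing: list[tuple[str, str]] = field(default_factory=list)

    def r(self, marker: str) -> float:
        return float(self.table.loc[marker, "r"])


def correlate_score_with_markers(
    scores: pd.Series,
    matrix: ExpressionMatrix,
    markers: Sequence[str] = DEFAULT_MARKER_PANEL,
) -> CorrelationReport:
    """Pearson r (with two-sided p, t transform on n-2 df) per marker.

    Raw p-values are reported as in the underlying statistical convention;
    a Benjamini-Hochberg adjusted column (``q_bh``) is added alongside,
    clearly labeled, since several markers are tested.
    """
    shared = [s for s in scores.index if s in matrix.values.columns]
    if len(shared) < 3:
        raise ValueError("need >= 3 samples shared between scores and matrix")
    x = scores[shared].to_numpy(dtype=float)

    rows = []
    missing: list[tuple[str, str]] = []
    for marker in markers:
        if marker not in matrix.values.index:
            missing.append((marker, "absent from matrix"))
            continue
        y = matrix.values.loc[marker, shared].to_numpy(dtype=float)
        if np.std(y) == 0 or np.std(x) == 0:
            missing.append((marker, "zero variance"))
            continue
        res = stats.pearsonr(x, y)
        rows.append({"marker": marker, "r": res.statistic,
                     "p_value": res.pvalue, "n": len(shared)})
    if missing:
        logger.info("markers not correlated: %s", missing)
    if not rows:
        return CorrelationReport(table=pd.DataFrame(
            columns=["r", "p_value", "q_bh", "n"]), missing=missing)
    table = pd.DataFrame(rows).set_index("marker")
    table["q_bh"] = multipletests(table["p_value"], method="fdr_bh")[1]
    table = table.sort_values("r", ascending=False)[["r", "p_value", "q_bh", "n"]]
    return CorrelationReport(table=table, missing=missing)


# ---------------------------------------------------------------------------
# Subgroup comparisons
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    """One feature compared across subgroups with the matching test."""

    feature: str
    test: str  # "anova" | "t_test" | "fisher_exact"
    statistic: float
    p_value: float
    group_summaries: pd.DataFrame
    excluded_groups: list[str] = field(default_factory=list)
    method_detail: str = ""


def _feature_values(
    data: ExpressionMatrix | pd.DataFrame, feature: str, samples: Sequence[str]
) -> pd.Series:
    if isinstance(data, ExpressionMatrix):
        if feature not in data.values.index:
            raise KeyError(f"gene {feature!r} not in matrix")
        return data.values.loc[feature, samples]
    if feature not in data.columns:
        raise KeyError(f"metadata key {feature!r} not found")
    return data.loc[samples, feature]


def _simulated_fisher_2xk(
    table: np.ndarray, n_tables: int = 100_000, seed: int = 0
) -> float:
    """Monte Carlo Fisher p for a 2 x k table under fixed margins.

    Draws the first row from the multivariate hypergeometric distribution
    given the column totals; p = (#{prob <= observed} + 1) / (B + 1).
    """
    col_totals = table.sum(axis=0)
    n1 = int(table[0].sum())
    rng = np.random.default_rng(seed)
    draws = stats.multivariate_hypergeom.rvs(
        col_totals, n1, size=n_tables, random_state=rng
    ).reshape(n_tables, -1)
    logp = stats.multivariate_hypergeom.logpmf(draws, col_totals, n1)
    logp_obs = stats.multivariate_hypergeom.logpmf(table[0], col_totals, n1)
    hits = int(np.sum(logp <= logp_obs + 1e-9))
    return (hits + 1) / (n_tables + 1)


def compare_groups(
    assignment: SubgroupAssignment,
    data: ExpressionMatrix | pd.DataFrame,
    feature: str,
    reference: str = "high",
    test: str | None = None,
    seed: int = 0,
) -> GroupComparison:
    """Compare one feature across subgroups.

    Continuous features: ``test="anova"`` runs a one-way ANOVA across all
    subgroups (groups with fewer than 2 samples are excluded with a
    warning); ``test="t_test"`` runs an unpaired two-tailed Welch t-test of
    the reference subgroup against the rest. Categorical features use
    Fisher's exact on the reference-vs-rest by category table (exact for
    2 x 2; seeded Monte Carlo over fixed-margin tables for k > 2).
    """
    subgroup = assignment.subgroup
    samples = list(subgroup.index)
    values = _feature_values(data, feature, samples)
    continuous = pd.api.types.is_numeric_dtype(values)
    if test is None:
        test = "anova" if continuous else "fisher_exact"

    if test in ("anova", "t_test"):
        if not continuous:
            raise ValueError(f"{test} requires a continuous feature")
        by_group = {
            lab: values[subgroup == lab].astype(float)
            for lab in SUBGROUP_LABELS
            if (subgroup == lab).any()
        }
        summaries = pd.DataFrame(
            {
                lab: {"n": len(v), "mean": v.mean(), "sd": v.std(ddof=1)}
                for lab, v in by_group.items()
            }
        ).T
        if test == "anova":
            excluded = [lab for lab, v in by_group.items() if len(v) < 2]
            kept = [v.to_numpy() for lab, v in by_group.items() if len(v) >= 2]
            if excluded:
                logger.warning("ANOVA excluding groups with < 2 samples: %s", excluded)
            if len(kept) < 2:
                raise ValueError("need >= 2 groups with >= 2 samples")
            stat, p = stats.f_oneway(*kept)
            return GroupComparison(feature, "anova", float(stat), float(p),
                                   summaries, excluded)
        ref = values[subgroup == reference].astype(float)
        rest = values[subgroup != reference].astype(float)
        if len(ref) < 2 or len(rest) < 2:
            raise ValueError("t-test needs >= 2 samples per side")
        stat, p = stats.ttest_ind(ref, rest, equal_var=False)
        return GroupComparison(feature, "t_test", float(stat), float(p), summaries,
                               method_detail=f"{reference} vs rest (Welch)")

    if test == "fisher_exact":
        is_ref = (subgroup == reference).to_numpy()
        table = pd.crosstab(
            pd.Series(np.where(is_ref, reference, "rest"), index=values.index),
            values,
        )
        table = table.reindex([reference, "rest"]).fillna(0).astype(int)
        counts = table.to_numpy()
        if counts.shape[1] < 2:
            raise ValueError(f"feature {feature!r} has a single category")
        if counts.shape[1] == 2:
            stat, p = stats.fisher_exact(counts, alternative="two-sided")
            detail = "exact 2x2"
        else:
            stat, p = np.nan, _simulated_fisher_2xk(counts, seed=seed)
            detail = "simulated (1e5 fixed-margin tables)"
        return GroupComparison(feature, "fisher_exact", float(stat), float(p),
                               table, method_detail=detail)
    raise ValueError(f"unknown test {test!r}")


# ---------------------------------------------------------------------------
# Gene-set over-representation and overlap
# ---------------------------------------------------------------------------


def fisher_enrichment(
    query: GeneSet,
    sets: Sequence[GeneSet],
    universe: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher over-representation of ``query`` in each set.

    Genes outside the universe are dropped (logged). Returns one row per
    set (overlap, set_size, universe_size, query_size, p_value,
    significant at ``alpha``), sorted by p.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = query.genes & uni
    dropped = len(query.genes) - len(q)
    if not q:
        raise ValueError("query has no genes in the universe")
    if dropped:
        logger.info("dropped %d query genes outside the universe", dropped)

    rows = []
    M, N = len(uni), len(q)
    for gs in sets:
        members = gs.genes & uni
        k = len(q & members)
        K = len(members)
        # P(X >= k) for X ~ Hypergeom(M, K, N)
        p = float(stats.hypergeom.sf(k - 1, M, K, N))
        rows.append(
            {"set_name": gs.name, "overlap": k, "set_size": K,
             "universe_size": M, "query_size": N,
             "p_value": min(p, 1.0), "significant": p <= alpha}
        )
    return pd.DataFrame(rows).sort_values("p_value", kind="stable").reset_index(drop=True)


@dataclass
class OverlapReport:
    """Exact Venn region cardinalities for 2-6 gene sets.

    ``region_counts`` maps each non-empty combination (tuple of set names,
    in input order) to the number of genes belonging to exactly those sets;
    ``core_genes`` lists the all-sets intersection.
    """

    set_names: list[str]
    region_counts: dict[tuple[str, ...], int]
    core_genes: list[str]

    def count(self, *names: str) -> int:
        """Genes in exactly the given sets (and no others)."""
        key = tuple(n for n in self.set_names if n in names)
        return self.region_counts.get(key, 0)

    def intersection_size(self, *names: str) -> int:
        """Genes in at least the given sets (any others allowed)."""
        want = set(names)
        return sum(
            c for combo, c in self.region_counts.items() if want <= set(combo)
        )

    def to_json_dict(self) -> dict:
        return {
            "set_names": self.set_names,
            "regions": {"&".join(k): v for k, v in self.region_counts.items()},
            "core_genes": self.core_genes,
        }


def signature_overlap(sets: Sequence[GeneSet]) -> OverlapReport:
    """Tabulate exact membership regions over 2-6 gene sets."""
    if not 2 <= len(sets) <= 6:
        raise ValueError("signature_overlap takes 2-6 gene sets")
    names = [gs.name for gs in sets]
    if len(set(names)) != len(names):
        raise ValueError("gene set names must be unique")
    union: set[str] = set().union(*(gs.genes for gs in sets))
    regions: dict[tuple[str, ...], int] = {}
    for gene in union:
        combo = tuple(gs.name for gs in sets if gene in gs.genes)
        regions[combo] = regions.get(combo, 0) + 1
    core = sorted(set.intersection(*(set(gs.genes) for gs in sets)))
    return OverlapReport(set_names=names, region_counts=regions, core_genes=core)
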