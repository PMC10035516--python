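"""Anchor selection and SAM-based signature construction.

The workflow mirrors intrinsic-signature building in bulk tumor cohorts:

1. among a small panel of candidate EMT transcription factors, pick the one
   with the highest expression variance across the cohort (the *anchor*);
2. rank samples by anchor expression and form top/bottom quantile contrast
   groups restricted to unique patients;
3. run a two-class SAM (significance analysis of microarrays) test between
   the groups — regularized relative difference d = (mean_hi - mean_lo) /
   (s + s0) with a permutation-based median FDR estimate;
4. keep genes at FDR <= 0.001 as the signature, split by fold-change
   direction.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "EMT_TF_CANDIDATES",
    "AnchorReport",
    "QuantileGroups",
    "SamResult",
    "Signature",
    "rank_anchor_variance",
    "select_quantile_groups",
    "estimate_s0",
    "sam_two_class",
    "build_signature",
    "write_signature",
]

#: Candidate EMT transcription factors screened for the anchor.
EMT_TF_CANDIDATES: tuple[str, ...] = (
    "ZEB1", "ZEB2", "SNAI1", "SNAI2", "TWIST1", "TWIST2", "PRRX1",
)

#: Default FDR cut for signature membership.
DEFAULT_FDR_THRESHOLD = 0.001

#: Default number of label permutations for the SAM null.
DEFAULT_N_PERMUTATIONS = 1000


# ---------------------------------------------------------------------------
# Anchor selection
# ---------------------------------------------------------------------------


@dataclass
class AnchorReport:
    """Variance ranking of candidate anchors (descending; ddof=1)."""

    variances: pd.Series  # candidate -> variance, sorted descending
    selected_anchor: str
    missing: list[str] = field(default_factory=list)

    @property
    def candidate_genes(self) -> list[str]:
        return list(self.variances.index)


def rank_anchor_variance(
    matrix: ExpressionMatrix, candidates: Sequence[str] = EMT_TF_CANDIDATES
) -> AnchorReport:
    """Rank candidate genes by cross-sample variance and select the arg-max.

    Sample variance uses denominator n-1. Candidates absent from the matrix
    are reported in ``missing`` rather than silently dropped.
    """
    present = [g for g in candidates if g in matrix.values.index]
    missing = [g for g in candidates if g not in matrix.values.index]
    if not present:
        raise ValueError(f"no candidate gene present in matrix; missing: {missing}")
    if missing:
        logger.warning("candidates absent from matrix: %s", missing)
    variances = matrix.values.loc[present].var(axis=1, ddof=1)
    variances = variances.sort_values(ascending=False, kind="stable")
    return AnchorReport(
        variances=variances, selected_anchor=str(variances.index[0]), missing=missing
    )


# ---------------------------------------------------------------------------
# Quantile contrast groups
# ---------------------------------------------------------------------------


@dataclass
class QuantileGroups:
    """Top/bottom anchor-expression groups restricted to unique patients."""

    fraction: float
    low_group: list[str]
    high_group: list[str]
    excluded_duplicates: list[str] = field(default_factory=list)


def _walk_unique_patients(
    ordered_samples: Sequence[str], patients: pd.Series, target: int
) -> tuple[list[str], list[str]]:
    """Walk from the extreme inward keeping one sample per patient."""
    kept: list[str] = []
    skipped: list[str] = []
    seen: set[str] = set()
    for s in ordered_samples:
        if len(kept) == target:
            break
        p = patients[s]
        if p in seen:
            skipped.append(s)
        else:
            seen.add(p)
            kept.append(s)
    return kept, skipped


def select_quantile_groups(
    matrix: ExpressionMatrix, anchor: str, fraction: float = 0.25
) -> QuantileGroups:
    """Form the bottom/top ``fraction`` anchor-expression groups (Q1/Q4).

    Samples are ranked by anchor expression; walking from each tail inward,
    the first (most extreme) sample per patient is kept and later samples of
    an already-represented patient are recorded in ``excluded_duplicates``.
    The per-group size is ``round(fraction * n_samples)`` (half away from
    zero), counted over all samples before de-duplication — e.g. 38 samples
    at fraction 0.25 give groups of 10.
    """
    if anchor not in matrix.values.index:
        raise ValueError(f"anchor {anchor!r} not in matrix")
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    n = matrix.n_samples
    target = int(math.floor(fraction * n + 0.5))
    expr = matrix.values.loc[anchor]
    # deterministic ranking: break expression ties by sample id
    ranked = sorted(matrix.sample_ids, key=lambda s: (expr[s], s))
    low, low_skip = _walk_unique_patients(ranked, matrix.patient_ids, target)
    high, high_skip = _walk_unique_patients(ranked[::-1], matrix.patient_ids, target)
    if len(low) < 2 or len(high) < 2:
        raise ValueError(
            f"quantile groups too small (low={len(low)}, high={len(high)}); "
            "need >= 2 unique patients per group"
        )
    if set(low) & set(high):
        raise ValueError("quantile groups overlap; fraction too large for cohort")
    return QuantileGroups(
        fraction=fraction,
        low_group=low,
        high_group=high,
        excluded_duplicates=low_skip + high_skip,
    )


# ---------------------------------------------------------------------------
# SAM two-class test
# ---------------------------------------------------------------------------


def estimate_s0(
    d_numerators: np.ndarray, pooled_se: np.ndarray, n_windows: int = 10
) -> float:
    """Choose the SAM fudge factor s0 over a percentile grid of pooled SEs.

    Candidates are the 0th-100th percentiles of ``pooled_se`` in 5% steps.
    For each candidate, genes are split into ``n_windows`` equal-occupancy
    windows by pooled SE and the coefficient of variation of the per-window
    median |d| is computed; the smallest candidate minimizing the CV wins.
    With fewer than 10 genes the median pooled SE is returned (logged).
    """
    num = np.asarray(d_numerators, dtype=float)
    se = np.asarray(pooled_se, dtype=float)
    if (se < 0).any():
        raise ValueError("pooled standard errors must be >= 0")
    if not (se > 0).any():
        raise ValueError("pooled standard errors are all zero")
    if num.size < 10:
        s0 = float(np.median(se))
        logger.warning("fewer than 10 genes: falling back to s0 = median(se) = %g", s0)
        return s0

    grid = np.percentile(se, np.arange(0, 101, 5))
    order = np.argsort(se, kind="stable")
    windows = np.array_split(order, n_windows)

    best_s0, best_cv = None, np.inf
    for s0 in grid:
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.abs(num / (se + s0))
        med = np.array([np.median(d[w]) for w in windows])
        if not np.isfinite(med).all() or med.mean() == 0:
            continue
        cv = med.std(ddof=1) / med.mean()
        if cv < best_cv - 1e-12:  # strict improvement; ties keep smallest s0
            best_cv, best_s0 = cv, float(s0)
    if best_s0 is None:
        raise ValueError("could not estimate s0 (degenerate input)")
    return best_s0


@dataclass
class SamResult:
    """Per-gene SAM statistics plus the run record.

    ``table`` is indexed by gene with columns ``d`` (relative difference),
    ``fold_change`` (linear high/low ratio) and ``q_value``.
    """

    table: pd.DataFrame
    s0: float
    n_permutations: int
    permutation_seed: int | None
    exhaustive: bool
    warnings: list[str] = field(default_factory=list)


def _group_stats(X: np.ndarray, H: np.ndarray, n1: int, n2: int):
    """Mean difference and pooled SE for each labeling column of H.

    X is genes x samples; H is samples x B with exactly n1 ones per column
    marking the "high" group. Returns (num, se): genes x B arrays. Uses the
    identity ss_high + ss_low = sum(x^2) - sum_h^2/n1 - sum_l^2/n2 so only
    one matrix product per labeling batch is needed, and works in-place to
    keep memory traffic low for large permutation batches.
    """
    dtype = H.dtype
    X = np.ascontiguousarray(X, dtype=dtype)
    total = X.sum(axis=1, keepdims=True)
    total_sq = np.square(X).sum(axis=1, keepdims=True)
    sum_h = X @ H

    num = sum_h * (1.0 / n1 + 1.0 / n2)
    num -= total / n2  # = mean_h - mean_l

    sum_l = total - sum_h
    np.square(sum_h, out=sum_h)
    sum_h *= 1.0 / n1
    np.square(sum_l, out=sum_l)
    sum_l *= 1.0 / n2
    ss = total_sq - sum_h  # pooled within-group sum of squares
    ss -= sum_l
    np.clip(ss, 0.0, None, out=ss)  # guard fp negatives
    ss *= (1.0 / n1 + 1.0 / n2) / (n1 + n2 - 2)
    se = np.sqrt(ss, out=ss)
    return num, se


def _permutation_labelings(
    n: int, n1: int, n_permutations: int, seed: int | None
) -> tuple[np.ndarray, bool]:
    """High-group indicator matrix (n x B); exhaustive when feasible."""
    n_distinct = math.comb(n, n1)
    if n_distinct <= n_permutations:
        H = np.zeros((n, n_distinct))
        for b, combo in enumerate(itertools.combinations(range(n), n1)):
            H[list(combo), b] = 1.0
        return H, True
    rng = np.random.default_rng(seed)
    H = np.zeros((n, n_permutations))
    for b in range(n_permutations):
        H[rng.choice(n, size=n1, replace=False), b] = 1.0
    return H, False


def _median_fdr(
    abs_d: np.ndarray, abs_d_perm: np.ndarray
) -> np.ndarray:
    """SAM median-based FDR per gene, monotonized in |d|.

    For the threshold set at each observed |d|: estimated FDR = median over
    permutations of #{|d*| >= t} divided by #{|d| >= t}. The per-gene
    q-value is the minimum FDR over all thresholds t <= |d_gene| (hence
    non-increasing in |d|), clipped to [0, 1].
    """
    m = abs_d.size
    order = np.argsort(abs_d, kind="stable")  # ascending thresholds
    thresholds = abs_d[order]
    sorted_obs = thresholds
    obs_counts = m - np.searchsorted(sorted_obs, thresholds, side="left")

    B = abs_d_perm.shape[1]
    perm_counts = np.empty((B, m))
    perm_sorted = np.sort(abs_d_perm, axis=0)
    for b in range(B):
        perm_counts[b] = abs_d_perm.shape[0] - np.searchsorted(
            perm_sorted[:, b], thresholds, side="left"
        )
    med_counts = np.median(perm_counts, axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = med_counts / obs_counts
    # ties: identical thresholds must share an FDR (they do: same counts)
    q_sorted = np.minimum.accumulate(fdr)  # min over all smaller thresholds
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def sam_two_class(
    matrix: ExpressionMatrix,
    groups: QuantileGroups,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int | None = 0,
    s0: float | None = None,
) -> SamResult:
    """Two-class SAM between the high and low quantile groups.

    Per gene, ``d = (mean_high - mean_low) / (s + s0)`` with ``s`` the
    two-sample pooled standard error, and ``fold_change = 2**(mean_high -
    mean_low)`` (log2 data). q-values come from the permutation null of
    group labelings: when the number of distinct labelings is at most
    ``n_permutations`` all of them are enumerated (exact null), otherwise
    ``n_permutations`` random labelings are drawn with ``seed``.
    """
    high, low = groups.high_group, groups.low_group
    n1, n2 = len(high), len(low)
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need >= 2 samples")
    X = matrix.values[high + low].to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 genes")

    obs_H = np.zeros((n1 + n2, 1))
    obs_H[:n1, 0] = 1.0
    num, se = _group_stats(X, obs_H, n1, n2)
    num, se = num[:, 0], se[:, 0]
    if s0 is None:
        s0 = estimate_s0(num, se)
    d = num / (se + s0)
    fold_change = np.exp2(num)

    H, exhaustive = _permutation_labelings(n1 + n2, n1, n_permutations, seed)
    warnings: list[str] = []
    if H.shape[1] < 10:
        msg = f"only {H.shape[1]} distinct labelings; FDR estimates are coarse"
        warnings.append(msg)
        logger.warning(msg)
    # float32 is ample for large permutation batches (only exceedance counts
    # are used) and halves the memory traffic of the genes x B work arrays;
    # small/exhaustive batches stay float64 so tiny nulls are exact
    perm_dtype = np.float32 if H.shape[1] > 200 else np.float64
    num_p, se_p = _group_stats(X, H.astype(perm_dtype), n1, n2)
    se_p += perm_dtype(s0)
    d_perm = np.divide(num_p, se_p, out=num_p)
    np.abs(d_perm, out=d_perm)
    q = _median_fdr(np.abs(d), d_perm)

    table = pd.DataFrame(
        {"d": d, "fold_change": fold_change, "q_value": q},
        index=pd.Index(matrix.gene_symbols, name="gene"),
    )
    return SamResult(
        table=table,
        s0=float(s0),
        n_permutations=H.shape[1],
        permutation_seed=seed,
        exhaustive=exhaustive,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# Signature assembly
# ---------------------------------------------------------------------------


@dataclass
class Signature:
    """Up/down gene lists (with linear fold changes) around an anchor gene."""

    anchor: str
    up_genes: pd.Series  # gene -> fold change (> 1)
    down_genes: pd.Series  # gene -> fold change (< 1)
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD

    @property
    def genes(self) -> list[str]:
        return list(self.up_genes.index) + list(self.down_genes.index)

    def __len__(self) -> int:
        return len(self.up_genes) + len(self.down_genes)


def build_signature(
    sam: SamResult,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    anchor: str = "",
) -> Signature:
    """Partition genes passing the FDR threshold by fold-change direction."""
    t = sam.table
    if t.empty:
        raise ValueError("empty SAM result")
    passing = t[t["q_value"] <= fdr_threshold]
    up = passing.loc[passing["fold_change"] > 1, "fold_change"]
    down = passing.loc[passing["fold_change"] < 1, "fold_change"]
    if up.empty and down.empty:
        raise ValueError(
            f"no gene passes FDR <= {fdr_threshold}; consider relaxing the threshold"
        )
    logger.info(
        "signature at FDR <= %g: %d up, %d down", fdr_threshold, len(up), len(down)
    )
    return Signature(
        anchor=anchor, up_genes=up, down_genes=down, fdr_threshold=fdr_threshold
    )


def write_sam_table(sam: SamResult, path: str | Path) -> None:
    """Write the per-gene SAM statistics as a tab-delimited table."""
    sam.table.to_csv(path, sep="\t", index_label="gene")


def write_signature(signature: Signature, sam: SamResult, stem: str | Path) -> None:
    """Write the signature as GMT lines plus a JSON sidecar with run info."""
    stem = Path(stem)
    with open(stem.with_suffix(".gmt"), "w") as fh:
        up = "\t".join(signature.up_genes.index)
        down = "\t".join(signature.down_genes.index)
        fh.write(f"{signature.anchor}_signature_up\tanchorsig\t{up}\n")
        if len(signature.down_genes):
            fh.write(f"{signature.anchor}_signature_down\tanchorsig\t{down}\n")
    sidecar = {
        "anchor": signature.anchor,
        "fdr_threshold": signature.fdr_threshold,
        "s0": sam.s0,
        "n_permutations": sam.n_permutations,
        "permutation_seed": sam.permutation_seed,
        "n_up": len(signature.up_genes),
        "n_down": len(signature.down_genes),
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
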