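"""Anchor ranking, quantile groups, s0 estimation and the SAM test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from anchorsig import (
    EMT_TF_CANDIDATES,
    ExpressionMatrix,
    QuantileGroups,
    SyntheticCohortConfig,
    build_signature,
    estimate_s0,
    generate_cohort,
    rank_anchor_variance,
    sam_two_class,
    select_quantile_groups,
)


def _matrix(values: dict, samples, patients=None) -> ExpressionMatrix:
    frame = pd.DataFrame(values, index=samples).T
    pid = None
    if patients is not None:
        pid = pd.Series(patients, index=samples)
    return ExpressionMatrix(values=frame, patient_ids=pid)


class TestAnchorVariance:
    def test_hand_computed_variances_and_argmax(self):
        samples = [f"S{i}" for i in range(5)]
        mat = _matrix(
            {"A": [1, 2, 3, 4, 5], "B": [3, 3, 3, 3, 3], "C": [0, 0, 0, 0, 10]},
            samples,
        )
        report = rank_anchor_variance(mat, ["A", "B", "C"])
        # hand: var(A) = 2.5, var(B) = 0, var(C) = 20 (ddof=1)
        assert report.variances["A"] == pytest.approx(2.5)
        assert report.variances["B"] == pytest.approx(0.0)
        assert report.variances["C"] == pytest.approx(20.0)
        # exhaustive arg-max
        assert report.selected_anchor == max(
            ["A", "B", "C"], key=lambda g: mat.values.loc[g].var(ddof=1)
        )

    def test_constant_candidate_never_beats_varying(self):
        samples = [f"S{i}" for i in range(4)]
        mat = _matrix({"FLAT": [5, 5, 5, 5], "VAR": [1, 2, 3, 4]}, samples)
        assert rank_anchor_variance(mat, ["FLAT", "VAR"]).selected_anchor == "VAR"

    def test_missing_candidates_reported_and_all_missing_errors(self):
        samples = ["S0", "S1"]
        mat = _matrix({"ZEB1": [1, 2]}, samples)
        report = rank_anchor_variance(mat)
        assert "PRRX1" in report.missing and "ZEB1" not in report.missing
        with pytest.raises(ValueError, match="SNAI1"):
            rank_anchor_variance(mat, ["SNAI1", "SNAI2"])

    def test_default_candidate_panel(self):
        assert EMT_TF_CANDIDATES == (
            "ZEB1", "ZEB2", "SNAI1", "SNAI2", "TWIST1", "TWIST2", "PRRX1",
        )


class TestQuantileGroups:
    def test_unique_patients_extremes(self):
        samples = [f"S{i}" for i in range(8)]
        mat = _matrix({"ANCHOR": [1, 2, 3, 4, 5, 6, 7, 8]}, samples)
        g = select_quantile_groups(mat, "ANCHOR", 0.25)
        assert set(g.low_group) == {"S0", "S1"}
        assert set(g.high_group) == {"S6", "S7"}
        assert g.excluded_duplicates == []

    def test_duplicate_patient_excluded_matches_brute_force(self):
        # top two samples share a patient: rank-2 must be excluded and the
        # next unique patient promoted
        samples = [f"S{i}" for i in range(8)]
        patients = ["p0", "p1", "p2", "p3", "p4", "p5", "pX", "pX"]
        expr = [1, 2, 3, 4, 5, 6, 7, 8]
        mat = _matrix({"A": expr}, samples, patients)
        g = select_quantile_groups(mat, "A", 0.25)
        assert set(g.high_group) == {"S7", "S5"}
        assert "S6" in g.excluded_duplicates
        # brute-force oracle: among all unique-patient pairs, the kept pair
        # maximizes total anchor expression
        e = dict(zip(samples, expr))
        p = dict(zip(samples, patients))
        best = max(
            (c for c in itertools.combinations(samples, 2) if p[c[0]] != p[c[1]]),
            key=lambda c: e[c[0]] + e[c[1]],
        )
        assert set(g.high_group) == set(best)

    def test_cohort_of_38_gives_10_per_group(self, default_cohort):
        mat, _ = default_cohort
        g = select_quantile_groups(mat, "PRRX1", 0.25)
        assert len(g.high_group) == 10
        assert len(g.low_group) == 10
        # patient uniqueness within each group
        for grp in (g.low_group, g.high_group):
            pats = mat.patient_ids[grp]
            assert pats.nunique() == len(grp)

    def test_too_small_group_errors(self):
        samples = ["S0", "S1", "S2"]
        mat = _matrix({"A": [1, 2, 3]}, samples)
        with pytest.raises(ValueError, match="too small"):
            select_quantile_groups(mat, "A", 0.25)


class TestEstimateS0:
    def test_equal_ses_return_smallest_grid_value(self):
        rng = np.random.default_rng(0)
        num = rng.normal(size=100)
        se = np.full(100, 0.5)
        # all grid percentiles equal 0.5; CV identical everywhere -> tie
        assert estimate_s0(num, se) == pytest.approx(0.5)

    def test_returned_s0_minimizes_cv_over_grid(self):
        rng = np.random.default_rng(3)
        se = rng.uniform(0.1, 2.0, 500)
        num = rng.normal(0, se + 0.3)
        s0 = estimate_s0(num, se)
        grid = np.percentile(se, np.arange(0, 101, 5))

        def cv(cand):  # independent re-derivation of the objective
            d = np.abs(num / (se + cand))
            windows = np.array_split(np.argsort(se, kind="stable"), 10)
            med = np.array([np.median(d[w]) for w in windows])
            return med.std(ddof=1) / med.mean()

        assert all(cv(s0) <= cv(c) + 1e-12 for c in grid)

    def test_fallback_below_ten_genes(self):
        se = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        num = np.ones(5)
        assert estimate_s0(num, se) == pytest.approx(0.3)


def _sam_oracle_exhaustive(X: np.ndarray, n1: int, s0: float):
    """Independent SAM oracle: plain loops over all labelings.

    Returns (d, q) with q-values from the exhaustive permutation null:
    FDR(t) = median_b #{|d*_b| >= t} / #{|d| >= t}, q_i = min over
    thresholds t <= |d_i|.
    """
    n = X.shape[1]
    n2 = n - n1

    def d_for(idx_high):
        idx_low = [j for j in range(n) if j not in idx_high]
        a, b = X[:, list(idx_high)], X[:, idx_low]
        num = a.mean(axis=1) - b.mean(axis=1)
        ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
            (b - b.mean(axis=1, keepdims=True)) ** 2
        ).sum(axis=1)
        se = np.sqrt((1 / n1 + 1 / n2) * ss / (n - 2))
        return num / (se + s0)

    d = d_for(tuple(range(n1)))
    perms = [d_for(c) for c in itertools.combinations(range(n), n1)]
    abs_perm = np.abs(np.array(perms))
    abs_d = np.abs(d)
    q = np.empty_like(d)
    for i in range(len(d)):
        fdrs = []
        for t in abs_d[abs_d <= abs_d[i]]:
            obs = (abs_d >= t).sum()
            med = np.median((abs_perm >= t).sum(axis=1))
            fdrs.append(med / obs)
        q[i] = min(1.0, min(fdrs))
    return d, q


class TestSamTwoClass:
    def test_zero_difference_gene_gets_q_one(self):
        rng = np.random.default_rng(1)
        samples = [f"S{i}" for i in range(8)]
        vals = rng.normal(8, 1, (20, 8))
        vals[0, :4] = vals[0, 4:] = 5.0  # identical group means and values
        mat = ExpressionMatrix(
            values=pd.DataFrame(vals, index=[f"G{i}" for i in range(20)], columns=samples)
        )
        groups = QuantileGroups(0.5, low_group=samples[4:], high_group=samples[:4])
        res = sam_two_class(mat, groups, seed=0, s0=0.1)
        assert res.table.loc["G0", "d"] == 0.0
        assert res.table.loc["G0", "q_value"] == 1.0

    def test_exhaustive_4v4_matches_independent_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(8, 1, (30, 8))
        X[:6, :4] += 2.0  # a few shifted genes
        samples = [f"S{i}" for i in range(8)]
        mat = ExpressionMatrix(
            values=pd.DataFrame(X, index=[f"G{i}" for i in range(30)], columns=samples)
        )
        groups = QuantileGroups(0.5, low_group=samples[4:], high_group=samples[:4])
        res = sam_two_class(mat, groups, n_permutations=100, seed=0, s0=0.2)
        assert res.exhaustive and res.n_permutations == math.comb(8, 4) == 70
        d_o, q_o = _sam_oracle_exhaustive(X, 4, s0=0.2)
        np.testing.assert_allclose(res.table["d"].to_numpy(), d_o, rtol=1e-10)
        np.testing.assert_allclose(res.table["q_value"].to_numpy(), q_o, rtol=1e-10)

    def test_label_swap_antisymmetry(self, small_matrix):
        samples = small_matrix.sample_ids
        g1 = QuantileGroups(0.5, low_group=samples[4:], high_group=samples[:4])
        g2 = QuantileGroups(0.5, low_group=samples[:4], high_group=samples[4:])
        r1 = sam_two_class(small_matrix, g1, seed=0, s0=0.1)
        r2 = sam_two_class(small_matrix, g2, seed=0, s0=0.1)
        np.testing.assert_allclose(r1.table["d"], -r2.table["d"])
        np.testing.assert_allclose(
            r1.table["fold_change"], 1.0 / r2.table["fold_change"]
        )

    def test_reproducible_given_seed_and_gene_order_invariant(self, fast_config):
        mat, _ = generate_cohort(fast_config)
        g = select_quantile_groups(mat, "PRRX1", 0.25)
        r1 = sam_two_class(mat, g, n_permutations=300, seed=5)
        r2 = sam_two_class(mat, g, n_permutations=300, seed=5)
        pd.testing.assert_frame_equal(r1.table, r2.table)
        shuffled = ExpressionMatrix(
            values=mat.values.sample(frac=1, random_state=0),
            patient_ids=mat.patient_ids,
        )
        r3 = sam_two_class(shuffled, g, n_permutations=300, seed=5)
        pd.testing.assert_frame_equal(
            r1.table.sort_index(), r3.table.sort_index()
        )

    def test_tiny_design_warns_but_computes_exact_null(self):
        rng = np.random.default_rng(4)
        samples = [f"S{i}" for i in range(4)]
        mat = ExpressionMatrix(
            values=pd.DataFrame(rng.normal(8, 1, (15, 4)),
                                index=[f"G{i}" for i in range(15)], columns=samples)
        )
        groups = QuantileGroups(0.5, low_group=samples[2:], high_group=samples[:2])
        res = sam_two_class(mat, groups, seed=0, s0=0.1)
        assert res.n_permutations == 6 and res.exhaustive
        assert res.warnings

    def test_null_fdr_estimate_consistent_with_global_null(self):
        # under a global null every discovery is false: the estimated FDR at
        # a mid-tail threshold should be near 1 (within a factor of two)
        rng = np.random.default_rng(6)
        qs = []
        for rep in range(5):
            samples = [f"S{i}" for i in range(16)]
            mat = ExpressionMatrix(
                values=pd.DataFrame(
                    rng.normal(8, 1, (500, 16)),
                    index=[f"G{i}" for i in range(500)], columns=samples,
                )
            )
            groups = QuantileGroups(0.5, low_group=samples[8:], high_group=samples[:8])
            res = sam_two_class(mat, groups, n_permutations=300, seed=rep)
            t = res.table
            gene80 = t.d.abs().quantile(0.8, interpolation="lower")
            qs.append(t.loc[t.d.abs() == gene80, "q_value"].iloc[0])
        assert 0.5 <= float(np.median(qs)) <= 1.0


class TestBuildSignature:
    def _sam_from(self, d, fc, q):
        import anchorsig.signature as sig

        table = pd.DataFrame(
            {"d": d, "fold_change": fc, "q_value": q},
            index=[f"G{i}" for i in range(len(d))],
        )
        return sig.SamResult(table=table, s0=0.1, n_permutations=10,
                             permutation_seed=0, exhaustive=True)

    def test_partition_matches_brute_force_filter(self):
        sam = self._sam_from(
            d=[3, 2, -2, 0.1, 2.5],
            fc=[4.0, 2.0, 0.5, 1.1, 2.0],
            q=[0.0005, 0.002, 0.0009, 0.5, 0.001],
        )
        s = build_signature(sam, fdr_threshold=0.001, anchor="G0")
        expected_up = {g for g in sam.table.index
                       if sam.table.loc[g, "q_value"] <= 0.001
                       and sam.table.loc[g, "fold_change"] > 1}
        expected_down = {g for g in sam.table.index
                         if sam.table.loc[g, "q_value"] <= 0.001
                         and sam.table.loc[g, "fold_change"] < 1}
        assert set(s.up_genes.index) == expected_up == {"G0", "G4"}
        assert set(s.down_genes.index) == expected_down == {"G2"}

    def test_threshold_one_includes_everything(self):
        sam = self._sam_from(d=[1, -1], fc=[2.0, 0.5], q=[0.9, 1.0])
        s = build_signature(sam, fdr_threshold=1.0)
        assert len(s) == 2

    def test_no_passing_genes_errors(self):
        sam = self._sam_from(d=[1.0], fc=[2.0], q=[0.5])
        with pytest.raises(ValueError, match="relaxing"):
            build_signature(sam, fdr_threshold=0.001)

    def test_default_threshold(self):
        from anchorsig.signature import DEFAULT_FDR_THRESHOLD

        assert DEFAULT_FDR_THRESHOLD == 0.001


def test_sam_and_signature_writers(tmp_path, fast_config):
    from anchorsig import (
        build_signature, generate_cohort, sam_two_class,
        select_quantile_groups, write_sam_table, write_signature,
    )
    import json

    mat, _ = generate_cohort(fast_config)
    groups = select_quantile_groups(mat, "PRRX1", 0.25)
    sam = sam_two_class(mat, groups, n_permutations=200, seed=1)
    write_sam_table(sam, tmp_path / "sam.tsv")
    back = pd.read_csv(tmp_path / "sam.tsv", sep="\t").set_index("gene")
    pd.testing.assert_frame_equal(back, sam.table, check_names=False)
    sig = build_signature(sam, fdr_threshold=0.05, anchor="PRRX1")
    write_signature(sig, sam, tmp_path / "sig")
    sidecar = json.loads((tmp_path / "sig.json").read_text())
    assert sidecar["anchor"] == "PRRX1" and sidecar["n_up"] == len(sig.up_genes)
    gmt_first = (tmp_path / "sig.gmt").read_text().splitlines()[0].split("\t")
    assert set(gmt_first[2:]) == set(sig.up_genes.index)
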