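"""Cohort statistics against independent naive oracles and known examples."""

import numpy as np
import pandas as pd
import pytest

from smmipseq import cohort as ch
from _oracles import (
    bh_stepup,
    fisher_enum_p,
    km_empirical,
    linkage_to_merges,
    logrank_oracle,
    mann_whitney_enum_p,
    spearman_oracle,
    upgma_oracle,
)


def frame(data, samples=None):
    df = pd.DataFrame(data)
    if samples is not None:
        df.index = pd.Index(samples, name="sample_id")
    return df


class TestPreprocess:
    def test_zero_fpm_maps_to_minus_two_before_zscore(self):
        expr = frame({"T1": [0.0, 0.99, 9.99]}, ["a", "b", "c"])
        logged = np.log10(expr + 0.01)
        assert logged.loc["a", "T1"] == pytest.approx(-2.0)
        tm = ch.preprocess_matrix(expr)
        # z-scoring preserves the order and standardises
        assert tm.values["T1"].mean() == pytest.approx(0.0, abs=1e-12)
        assert tm.values["T1"].std(ddof=1) == pytest.approx(1.0)

    def test_simple_zscore_values(self):
        expr = frame({"T1": [10**1 - 0.01, 10**2 - 0.01, 10**3 - 0.01]}, list("abc"))
        tm = ch.preprocess_matrix(expr)
        assert tm.values["T1"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_transcript_flagged_and_zeroed(self):
        expr = frame({"T1": [5.0, 5.0, 5.0], "T2": [1.0, 2.0, 3.0]}, list("abc"))
        tm = ch.preprocess_matrix(expr)
        assert tm.constant_transcripts == ["T1"]
        assert (tm.values["T1"] == 0).all()

    def test_negative_input_rejected(self):
        with pytest.raises(ch.CohortError):
            ch.preprocess_matrix(frame({"T1": [-1.0, 2.0]}, list("ab")))


class TestUpgma:
    def test_two_profile_manhattan_distance(self):
        expr = frame({"T1": [0.0, 1.0], "T2": [0.0, 3.0]}, ["s1", "s2"])
        res = ch.upgma_cluster(expr, k=2)
        assert res.linkage[0, 2] == pytest.approx(4.0)

    def test_identical_samples_merge_first_at_zero(self):
        expr = frame(
            {"T1": [1.0, 1.0, 9.0], "T2": [2.0, 2.0, 9.0]}, ["s1", "s2", "s3"]
        )
        res = ch.upgma_cluster(expr, k=2)
        assert res.linkage[0, 2] == pytest.approx(0.0)
        assert set(res.linkage[0, :2].astype(int)) == {0, 1}
        assert res.labels["s1"] == res.labels["s2"] != res.labels["s3"]

    def test_k_larger_than_n_rejected(self):
        expr = frame({"T1": [1.0, 2.0]}, ["s1", "s2"])
        with pytest.raises(ch.CohortError):
            ch.upgma_cluster(expr, k=5)

    @pytest.mark.parametrize("seed", range(20))
    def test_merge_tree_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        X = rng.normal(size=(n, 4))
        expr = frame(
            {f"T{j}": X[:, j] for j in range(4)}, [f"s{i}" for i in range(n)]
        )
        res = ch.upgma_cluster(expr, k=2)
        ours = linkage_to_merges(res.linkage, n)
        oracle = upgma_oracle(X)
        assert len(ours) == len(oracle) == n - 1
        for (set_a, h_a), (set_b, h_b) in zip(ours, oracle):
            assert set_a == set_b
            assert h_a == pytest.approx(h_b)
        # UPGMA monotonicity: heights non-decreasing along merges
        heights = res.linkage[:, 2]
        assert (np.diff(heights) >= -1e-12).all()


class TestMannWhitneyDe:
    def test_most_extreme_ranking_small_groups(self):
        expr = frame({"T1": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]}, list("abcdef"))
        table = ch.de_test(expr, ["a", "b", "c"], ["d", "e", "f"])
        assert table.p.iloc[0] == pytest.approx(0.1)  # 2 / C(6,3)

    def test_identical_groups_give_p_one_fold_one(self):
        expr = frame({"T1": [5.0, 5.0, 5.0, 5.0]}, list("abcd"))
        table = ch.de_test(expr, ["a", "b"], ["c", "d"])
        assert table.p.iloc[0] == 1.0
        assert table.fold_change.iloc[0] == 1.0

    def test_empty_group_rejected(self):
        expr = frame({"T1": [1.0, 2.0]}, ["a", "b"])
        with pytest.raises(ch.CohortError):
            ch.de_test(expr, ["a", "b"], [])

    @pytest.mark.parametrize("n1,n2", [(2, 3), (4, 4), (5, 8), (8, 8)])
    def test_exact_p_equals_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 100 + n2)
        x = rng.normal(size=n1)
        y = rng.normal(size=n2) + 0.8
        _, p, method = ch.mann_whitney_p(x, y)
        assert method == "exact"
        assert p == pytest.approx(mann_whitney_enum_p(x, y))

    @pytest.mark.parametrize("n1,n2", [(9, 9), (12, 10), (20, 15)])
    def test_normal_approximation_close_to_exact(self, n1, n2):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(n1 + n2)
        x = rng.normal(size=n1)
        y = rng.normal(size=n2) + 0.5
        _, p, method = ch.mann_whitney_p(x, y)
        assert method == "asymptotic"
        exact = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert abs(p - exact) < 0.01

    def test_bh_stepup_example_and_monotonicity(self):
        """[0.01, 0.02, 0.04, 0.5] adjusts to [0.04, 0.04, 0.0533, 0.5]:
        two discoveries at FDR < 0.05."""
        p = np.array([0.01, 0.02, 0.04, 0.5])
        q = ch.benjamini_hochberg(p)
        assert q == pytest.approx([0.04, 0.04, 0.04 * 4 / 3, 0.5])
        assert q == pytest.approx(bh_stepup(p))
        assert (q >= p - 1e-12).all()
        assert int((q < 0.05).sum()) == 2
        # monotone in p on random vectors
        rng = np.random.default_rng(0)
        for _ in range(5):
            pv = rng.random(20)
            qv = ch.benjamini_hochberg(pv)
            order = np.argsort(pv)
            assert (np.diff(qv[order]) >= -1e-12).all()


class TestFisherAssoc:
    def test_three_zero_zero_three_table(self):
        assert ch.fisher_exact_p([[3, 0], [0, 3]]) == pytest.approx(0.1)

    def test_uniform_mutation_is_independent(self):
        profiles = frame(
            {"HS": ["mut", "wt", "mut", "wt", "mut", "wt"]}, list("abcdef")
        )
        labels = pd.Series([1, 1, 2, 2, 3, 3], index=list("abcdef"))
        table = ch.mutation_assoc(profiles, labels)
        assert (table.p == 1.0).all()

    def test_confined_mutation_detected(self):
        samples = [f"s{i}" for i in range(12)]
        profiles = frame({"HS": ["mut"] * 6 + ["wt"] * 6}, samples)
        labels = pd.Series([1] * 6 + [2] * 6, index=samples)
        table = ch.mutation_assoc(profiles, labels)
        best = table.iloc[0]
        assert best.hotspot == "HS"
        assert best.p == pytest.approx(fisher_enum_p([[6, 0], [0, 6]]))
        assert best.q < 0.01 and best.significant

    @pytest.mark.parametrize("seed", range(10))
    def test_p_matches_hypergeometric_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(0, 10, size=4)
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            pytest.skip("degenerate margin")
        table = [[int(a), int(b)], [int(c), int(d)]]
        assert ch.fisher_exact_p(table) == pytest.approx(fisher_enum_p(table))


class TestSurvival:
    @staticmethod
    def records(times, events, samples):
        return frame(
            {"survival_days": times, "event": events}, samples
        )

    def test_identical_groups_give_zero_statistic(self):
        surv = self.records([5, 10, 15, 5, 10, 15], [1] * 6, list("abcdef"))
        labels = pd.Series(list("xxxyyy"), index=list("abcdef"))
        res = ch.survival_compare(surv, labels)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_toy_separated_groups_match_closed_form(self):
        """Deaths at 1,2,3 vs 4,5,6 without censoring: the log-rank statistic
        equals the hand-computed hypergeometric-moment value."""
        surv = self.records([1, 2, 3, 4, 5, 6], [1] * 6, list("abcdef"))
        labels = pd.Series(list("AAABBB"), index=list("abcdef"))
        res = ch.survival_compare(surv, labels)
        expected = logrank_oracle([1, 2, 3], [1, 1, 1], [4, 5, 6], [1, 1, 1])
        assert res.statistic == pytest.approx(expected)

    def test_km_without_censoring_is_empirical_survivor_function(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(100.0, size=25).round(1)
        surv = self.records(times, [1] * 25, [f"s{i}" for i in range(25)])
        labels = pd.Series(["g"] * 25, index=surv.index)
        res = ch.survival_compare(surv, labels)
        curve = res.curves["g"].set_index("time")["survival"]
        for t, s in km_empirical(times).items():
            assert curve.loc[t] == pytest.approx(s)

    def test_median_not_reached_under_heavy_censoring(self):
        surv = self.records([100, 200, 300, 400], [1, 0, 0, 0], list("abcd"))
        labels = pd.Series(["g"] * 4, index=surv.index)
        res = ch.survival_compare(surv, labels)
        assert np.isinf(res.medians["g"])
        assert res.median_label("g") == "not reached"

    def test_empty_group_rejected(self):
        surv = self.records([1.0], [1], ["a"])
        labels = pd.Series([None], index=["a"], dtype=object)
        with pytest.raises(ch.CohortError):
            ch.survival_compare(surv, labels)


class TestSpearman:
    def test_monotone_decreasing_is_minus_one(self):
        rho, _ = ch.spearman_corr([1, 2, 3, 4], [8, 6, 5, 1])
        assert rho == pytest.approx(-1.0)

    def test_tied_ranks_still_perfectly_concordant(self):
        rho, _ = ch.spearman_corr([1, 2, 2, 4], [10, 20, 20, 40])
        assert rho == pytest.approx(1.0)

    def test_constant_vector_reported_undefined(self):
        rho, p = ch.spearman_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(rho) and np.isnan(p)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_rank_then_pearson_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 5, size=12).astype(float)  # plenty of ties
        b = rng.integers(0, 5, size=12).astype(float)
        if len(np.unique(a)) == 1 or len(np.unique(b)) == 1:
            pytest.skip("constant draw")
        rho, _ = ch.spearman_corr(a, b)
        assert rho == pytest.approx(spearman_oracle(a, b))


class TestActionable:
    def test_two_fold_over_cohort_mean_strict(self):
        expr = frame(
            {"EGFR_T": [25.0, 5.0, 5.0, 5.0], "MET_T": [10.0, 10.0, 10.0, 10.0]},
            ["s1", "s2", "s3", "s4"],
        )
        rep = ch.actionable_flags(expr)
        assert rep.loc["s1", "overexpressed_targets"] == "EGFR_T"  # 25 > 2 x 10
        assert rep.loc["s2", "overexpressed_targets"] == ""
        fold = rep.attrs["fold_vs_cohort"]
        assert fold.loc["s1", "EGFR_T"] == pytest.approx(2.5)

    def test_ca12v1_and_egfrviii_thresholds(self):
        expr = frame({"T": [1.0, 1.0, 1.0]}, ["s1", "s2", "s3"])
        iso = frame(
            {"CA12v1": [60.0, 50.0, 10.0], "EGFRvIII": [5.0, 4.99, 0.0]},
            ["s1", "s2", "s3"],
        )
        rep = ch.actionable_flags(expr, isoform_fpm=iso)
        assert rep["CA12v1_poor_prognosis"].tolist() == [True, False, False]
        assert rep["EGFRvIII_positive"].tolist() == [True, False, False]
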