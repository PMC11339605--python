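"""Permutation tests, BH-FDR, liability-threshold probabilities, rank tests,
age standardization and the Simpson's-paradox correlation scan."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from groupwise_risk import (
    CohortConfig,
    LTMParams,
    age_standardized_rate,
    bh_adjust,
    generate_base_cohort,
    ltm_case_probability,
    ltm_threshold,
    mann_whitney,
    pairwise_permutation_matrix,
    permutation_test,
    simpsons_scan,
)


def bh_direct(p):
    """Step-up BH reference: q_(i) = min_{j>=i} p_(j) * m / j, clipped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestPermutationTest:
    def test_complete_separation_attains_minimum_p(self, rng):
        a = rng.normal(size=40)
        b = a + 10 * a.std()
        labels = np.array(["a"] * 40 + ["b"] * 40)
        res = permutation_test(np.r_[a, b], labels, "a", "b", "mean", 2000, seed=1)
        assert res.p_value == pytest.approx(1 / 2001)

    def test_relabel_invariance_two_sided(self, rng):
        vals = rng.normal(size=55)
        labels = np.array(["x"] * 30 + ["y"] * 25)
        p_xy = permutation_test(vals, labels, "x", "y", "mean", 500, seed=3).p_value
        p_yx = permutation_test(vals, labels, "y", "x", "mean", 500, seed=3).p_value
        assert p_xy == p_yx

    def test_monte_carlo_matches_exhaustive_enumeration(self, rng):
        a, b = rng.normal(size=3), rng.normal(size=3)
        pooled = np.r_[a, b]
        obs = abs(a.mean() - b.mean())
        exact_hits = sum(
            abs(pooled[list(idx)].mean()
                - np.delete(pooled, list(idx)).mean()) >= obs - 1e-12
            for idx in combinations(range(6), 3)
        )
        p_exact = exact_hits / 20
        B = 100_000
        labels = np.array(["a"] * 3 + ["b"] * 3)
        p_mc = permutation_test(pooled, labels, "a", "b", "mean", B, seed=4).p_value
        se = np.sqrt(p_exact * (1 - p_exact) / B)
        assert abs(p_mc - p_exact) < 3 * se + 2 / B  # add-one offset allowance

    def test_null_pvalues_are_uniform(self):
        """Calibration: same-distribution groups give uniform p (KS at 1%)."""
        rng = np.random.default_rng(99)
        B = 99
        pvals = []
        for _ in range(500):
            vals = rng.normal(size=60)
            labels = np.array(["a"] * 30 + ["b"] * 30)
            seed = int(rng.integers(2**31))
            pvals.append(
                permutation_test(vals, labels, "a", "b", "mean", B, seed=seed).p_value
            )
        # p lives on {1/(B+1), ..., 1}; compare against its discrete uniform CDF
        d = stats.kstest(pvals, lambda x: np.clip(np.floor(np.asarray(x) * (B + 1)) / (B + 1), 0, 1)).pvalue
        assert d > 0.01

    @pytest.mark.parametrize("stat", ["median", "variance", "tail-proportion"])
    def test_alternative_statistics_run(self, rng, stat):
        vals = rng.normal(size=80)
        labels = np.array(["a"] * 40 + ["b"] * 40)
        res = permutation_test(vals, labels, "a", "b", stat, 200, seed=5)
        assert 0 < res.p_value <= 1

    def test_ltm_rate_statistic_needs_params(self, rng):
        vals = rng.normal(size=40)
        labels = np.array(["a"] * 20 + ["b"] * 20)
        with pytest.raises(ValueError):
            permutation_test(vals, labels, "a", "b", "ltm-rate", 50, seed=6)
        res = permutation_test(
            vals, labels, "a", "b", "ltm-rate", 50, seed=6,
            ltm_params=LTMParams(K=0.0321, V=0.05),
        )
        assert 0 < res.p_value <= 1

    def test_paper_literal_mode_is_one_sided_proportion(self, rng):
        vals = rng.normal(size=40)
        labels = np.array(["a"] * 20 + ["b"] * 20)
        res = permutation_test(
            vals, labels, "a", "b", "mean", 200, seed=7, paper_literal=True
        )
        assert res.mode == "paper-literal"
        assert 0.0 <= res.p_value <= 1.0

    def test_bad_arguments(self, rng):
        vals, labels = rng.normal(size=10), np.array(["a"] * 10)
        with pytest.raises(ValueError):
            permutation_test(vals, labels, "a", "missing", "mean", 10, seed=0)
        with pytest.raises(ValueError):
            permutation_test(vals, labels, "a", "a", "mean", 0, seed=0)
        with pytest.raises(ValueError):
            permutation_test(vals, labels, "a", "a", "kurtosis", 10, seed=0)


class TestPairwiseMatrix:
    def test_nine_groups_give_36_pairs(self, rng):
        vals = rng.normal(size=9 * 20)
        labels = np.repeat([f"g{i}" for i in range(9)], 20)
        raw, adj = pairwise_permutation_matrix(vals, labels, "mean", 99, seed=8)
        assert np.isfinite(raw.to_numpy()).sum() == 36 * 2  # symmetric fill
        assert np.isfinite(adj.to_numpy()).sum() == 36 * 2

    def test_identical_groups_rarely_significant(self):
        """Null false-positive rate stays at the nominal 5% level.

        The observed fraction is compared with 0.95 minus a one-sided 99%
        Monte-Carlo allowance for the finite number of replicates.
        """
        rng = np.random.default_rng(17)
        R = 200
        nonsig = 0
        for _ in range(R):
            vals = rng.normal(size=40)
            labels = np.array(["a"] * 20 + ["b"] * 20)
            _, adj = pairwise_permutation_matrix(
                vals, labels, "mean", 199, seed=int(rng.integers(2**31))
            )
            nonsig += adj.loc["a", "b"] > 0.05
        allowance = 2.33 * np.sqrt(0.05 * 0.95 / R)
        assert nonsig / R >= 0.95 - allowance

    def test_huge_shifts_all_at_minimum(self, rng):
        base = rng.normal(size=30)
        vals = np.r_[base, base + 50, base + 100]
        labels = np.repeat(["a", "b", "c"], 30)
        B = 199
        raw, adj = pairwise_permutation_matrix(vals, labels, "mean", B, seed=9)
        tri = [adj.loc[x, y] for x, y in combinations("abc", 2)]
        assert np.allclose(tri, 1 / (B + 1))

    def test_singleton_group_raises_with_name(self, rng):
        vals = rng.normal(size=21)
        labels = np.array(["a"] * 10 + ["b"] * 10 + ["lone"])
        with pytest.raises(ValueError, match="lone"):
            pairwise_permutation_matrix(vals, labels, "mean", 10, seed=0)


class TestBHAdjust:
    def test_spec_examples(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_matches_direct_step_up_formula(self, rng):
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), bh_direct(p), atol=1e-12)

    def test_adjusted_never_below_raw_and_monotone(self, rng):
        p = rng.uniform(size=25)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestLTM:
    def test_threshold_examples(self):
        assert ltm_threshold(0.5) == 0.0
        assert ltm_threshold(0.0321) == pytest.approx(1.8504, abs=1e-3)
        assert ltm_threshold(0.975) == pytest.approx(-1.95996, abs=1e-4)
        assert ltm_threshold(0.01) > ltm_threshold(0.02)  # decreasing in K

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_threshold_domain(self, bad):
        with pytest.raises(ValueError):
            ltm_threshold(bad)

    def test_case_probability_examples(self):
        params = LTMParams(K=0.0321, V=0.25)
        assert ltm_case_probability(params.T, params) == pytest.approx(0.5)
        assert ltm_case_probability(0.0, LTMParams(K=0.5, V=0.0)) == pytest.approx(0.5)
        # 1 - Phi((T - 1) / sqrt(0.75)) at T = 1.8504
        assert ltm_case_probability(1.0, params) == pytest.approx(0.1632, abs=1e-3)

    def test_case_probability_increasing_in_prs(self):
        params = LTMParams(K=0.0321, V=0.05)
        prs = np.linspace(-3, 3, 50)
        assert (np.diff(ltm_case_probability(prs, params)) > 0).all()

    def test_invalid_variance_raises(self):
        with pytest.raises(ValueError):
            LTMParams(K=0.1, V=1.0)

    def test_averaging_over_prs_recovers_prevalence(self, rng):
        params = LTMParams(K=0.0321, V=0.25)
        prs = rng.normal(0, np.sqrt(params.V), size=400_000)
        rate = ltm_case_probability(prs, params).mean()
        assert rate == pytest.approx(params.K, abs=4 * np.sqrt(params.K / 400_000))


class TestMannWhitney:
    def test_identical_singletons(self):
        assert mann_whitney([3.0], [3.0]) == 1.0

    def test_most_extreme_split_of_three_vs_three(self):
        assert mann_whitney([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_exact_agrees_with_enumeration_small_samples(self, rng):
        for na in (2, 3, 4, 5):
            nb = min(10 - na, na + 1)
            a, b = rng.normal(size=na), rng.normal(size=nb) + 0.5
            pooled = np.r_[a, b]
            # enumeration over all assignments of na pooled values to group a
            u_obs = stats.mannwhitneyu(a, b, alternative="two-sided").statistic
            n = na + nb
            mu = na * nb / 2
            hits = total = 0
            for idx in combinations(range(n), na):
                aa = pooled[list(idx)]
                bb = np.delete(pooled, list(idx))
                u = stats.mannwhitneyu(aa, bb, alternative="two-sided").statistic
                hits += abs(u - mu) >= abs(u_obs - mu) - 1e-12
                total += 1
            assert mann_whitney(a, b) == pytest.approx(hits / total, abs=1e-12)

    def test_normal_approximation_close_to_exact_at_n15(self, rng):
        a, b = rng.normal(size=15), rng.normal(size=15) + 0.6
        approx = mann_whitney(a, b)  # size 30 pooled -> asymptotic path
        exact = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        assert abs(approx - exact) < 0.01

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


def test_cohens_d_hand_value():
    from groupwise_risk.group_inference import cohens_d

    assert cohens_d([1, 2, 3], [3, 4, 5]) == pytest.approx(-2.0)
    assert cohens_d([3, 4, 5], [1, 2, 3]) == pytest.approx(2.0)


class TestAgeStandardizedRate:
    def test_direct_formula_and_trivia(self):
        assert age_standardized_rate([10, 30], [100, 100], [3, 1]) == pytest.approx(0.15)
        assert age_standardized_rate([5], [50], [0.123]) == pytest.approx(0.1)
        assert age_standardized_rate([1, 2], [10, 10], [1, 1]) == pytest.approx(0.15)

    def test_scale_invariance_in_weights(self, rng):
        c = rng.integers(0, 20, size=6)
        n = rng.integers(50, 100, size=6)
        w = rng.uniform(0.5, 2, size=6)
        r1 = age_standardized_rate(c, n, w)
        r2 = age_standardized_rate(c, n, 7.3 * w)
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_empty_band_handling(self):
        with pytest.raises(ValueError):
            age_standardized_rate([1, 2], [10, 0], [1, 1])
        with pytest.warns(UserWarning):
            r = age_standardized_rate([1, 0], [10, 0], [1, 1])
        assert r == pytest.approx(0.1)


class TestSimpsonsScan:
    def test_nine_variables_scan_36_pairs(self, rng):
        import pandas as pd

        n = 300
        df = pd.DataFrame(rng.normal(size=(n, 9)), columns=list("abcdefghi"))
        df["group"] = rng.integers(0, 5, size=n)
        scans = simpsons_scan(df, list("abcdefghi"))
        assert len(scans) == 36

    def test_needs_three_groups(self, small_cohort):
        two = small_cohort[small_cohort["group"].isin(["center_01", "center_02"])]
        with pytest.raises(ValueError):
            simpsons_scan(two, ["prs", "pce"])

    def test_constant_variable_skipped_with_warning(self, small_cohort):
        df = small_cohort.assign(flat=1.0)
        with pytest.warns(UserWarning):
            scans = simpsons_scan(df, ["prs", "pce", "flat"])
        assert len(scans) == 1  # only (prs, pce) survives

    def test_random_groups_rarely_flag_reversal(self):
        """Null calibration: reversal flags stay within the group-level screen rate."""
        rng = np.random.default_rng(23)
        flags = 0
        R = 200
        cfg = CohortConfig(n_groups=6, group_sizes=100, prevalence=0.2, seed=0)
        for rep in range(R):
            cohort = generate_base_cohort(
                CohortConfig(n_groups=6, group_sizes=100, prevalence=0.2, seed=rep)
            )
            scans = simpsons_scan(cohort, ["prs", "pce", "cad"])
            flags += any(s.reversal for s in scans)
        allowance = 2.33 * np.sqrt(0.05 * 0.95 / R)
        assert flags / R <= 0.05 + allowance
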