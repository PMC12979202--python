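"""Unit and property tests of the nonparametric statistics core."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmdcyto import (
    bh_adjust,
    bootstrap_roc_band,
    cliffs_delta,
    compare_at_matched_operating_point,
    empirical_roc,
    human_operating_point,
    lowess_trend,
    mann_whitney_one_sided,
    wilson_interval,
)

from conftest import brute_force_pairwise


class TestMannWhitney:
    def test_exact_p_by_enumeration(self):
        """ref=[1,2,3] vs comp=[4,5,6]: the most extreme of C(6,3)=20
        arrangements, so the one-sided p is exactly 1/20."""
        res = mann_whitney_one_sided([1, 2, 3], [4, 5, 6])
        assert res.p == pytest.approx(0.05, abs=1e-12)
        assert res.u_ref == 0.0
        assert res.delta == 1.0

    def test_enumeration_oracle_small_samples(self):
        """Exact p equals direct enumeration over all label assignments."""
        ref, comp = [1.2, 3.4, 0.5, 2.2], [2.9, 4.1, 1.9]
        res = mann_whitney_one_sided(ref, comp)
        pooled = np.array(ref + comp)
        n_comp = len(comp)
        u_obs = sum(
            1.0 if y > x else 0.5 if y == x else 0.0
            for x in ref
            for y in comp
        )
        count = 0
        total = 0
        for idx in itertools.combinations(range(pooled.size), n_comp):
            mask = np.zeros(pooled.size, bool)
            mask[list(idx)] = True
            u = sum(
                1.0 if y > x else 0.5 if y == x else 0.0
                for x in pooled[~mask]
                for y in pooled[mask]
            )
            count += u >= u_obs
            total += 1
        assert res.p == pytest.approx(count / total, abs=1e-12)

    def test_worst_ordering(self):
        assert mann_whitney_one_sided([1], [0]).p == pytest.approx(1.0)

    def test_identical_samples_symmetry(self):
        res = mann_whitney_one_sided([3, 1, 2], [1, 2, 3])
        assert res.u_ref == pytest.approx(9 / 2)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_one_sided([], [1.0])

    def test_exact_and_asymptotic_agree_at_n15(self):
        """Tie-free n=15 vs 15 samples: exact and normal-approximation
        p-values agree within 0.01."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            ref = rng.normal(0, 1, 15)
            comp = rng.normal(0.5, 1, 15)
            from scipy.stats import mannwhitneyu

            p_exact = mannwhitneyu(comp, ref, alternative="greater", method="exact").pvalue
            p_asym = mannwhitneyu(
                comp, ref, alternative="greater", method="asymptotic"
            ).pvalue
            assert abs(p_exact - p_asym) < 0.01

    def test_type_one_error_calibrated(self):
        """Under identical continuous distributions the one-sided test
        rejects at <= the nominal 5% rate (within binomial error)."""
        rng = np.random.default_rng(42)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            ref = rng.normal(size=12)
            comp = rng.normal(size=12)
            rejections += mann_whitney_one_sided(ref, comp).p < 0.05
        # 3-sigma binomial allowance above the nominal rate
        assert rejections / n_sim <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_sim)


class TestCliffsDelta:
    @pytest.mark.parametrize(
        "ref,comp,expected",
        [
            ([1, 2, 3], [1, 2, 3], 0.0),
            ([1, 2], [5, 6], 1.0),
            ([1, 3, 5], [2, 4, 6], 1 / 3),  # 6 wins, 3 losses, 9 pairs
            ([5, 6], [1, 2], -1.0),
        ],
    )
    def test_hand_counted_values(self, ref, comp, expected):
        assert cliffs_delta(ref, comp) == pytest.approx(expected, abs=1e-12)

    def test_delta_u_auc_consistency_random(self):
        """delta = 1 - 2 U_ref/(n1 n2) and AUC = (delta+1)/2, against brute
        force pairwise counting on random integer-valued samples."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            n1, n2 = rng.integers(1, 30, 2)
            ref = rng.integers(0, 10, n1).astype(float)
            comp = rng.integers(0, 10, n2).astype(float)
            u_ref, delta, auc = brute_force_pairwise(ref, comp)
            res = mann_whitney_one_sided(ref, comp)
            assert res.u_ref == pytest.approx(u_ref, abs=1e-9)
            assert cliffs_delta(ref, comp) == pytest.approx(delta, abs=1e-12)
            assert cliffs_delta(ref, comp) == pytest.approx(2 * auc - 1, abs=1e-12)
            assert res.delta == pytest.approx(1 - 2 * u_ref / (n1 * n2), abs=1e-12)


class TestBenjaminiHochberg:
    def test_worked_example(self):
        q = bh_adjust([0.005, 0.01, 0.03, 0.04])
        assert q == pytest.approx([0.02, 0.02, 0.04, 0.04], abs=1e-12)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_all_equal(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_q_dominates_p_and_order_invariance(self, pvals):
        p = np.array(pvals)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        perm = np.random.default_rng(0).permutation(p.size)
        assert bh_adjust(p[perm]) == pytest.approx(q[perm])

    def test_families_adjusted_independently(self):
        p = [0.01, 0.04, 0.01, 0.04]
        fam = ["a", "a", "b", "b"]
        q = bh_adjust(p, family=fam)
        assert q == pytest.approx(bh_adjust([0.01, 0.04]).tolist() * 2)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestRoc:
    def test_perfect_separation(self):
        assert empirical_roc([3, 4, 1, 2], [1, 1, 0, 0]).auc == 1.0

    def test_all_tied_scores(self):
        assert empirical_roc([5, 5, 5, 5], [1, 1, 0, 0]).auc == 0.5

    def test_pairwise_oracle_value(self):
        # pos=[3,1], neg=[2,0]: wins 3 of 4 pairs -> 0.75
        assert empirical_roc([3, 1, 2, 0], [1, 1, 0, 0]).auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            empirical_roc([1, 2], [1, 1])

    def test_curve_monotone_and_auc_is_trapezoid(self):
        rng = np.random.default_rng(3)
        scores = np.r_[rng.normal(1, 1, 40), rng.normal(0, 1, 60)]
        labels = np.r_[np.ones(40), np.zeros(60)]
        roc = empirical_roc(scores, labels)
        assert np.all(np.diff(roc.tpr) >= 0)
        assert np.all(np.diff(roc.fpr) >= 0)
        assert np.trapezoid(roc.tpr, roc.fpr) == pytest.approx(roc.auc, abs=1e-12)


class TestBootstrapBand:
    def test_deterministic_given_seed(self):
        scores = np.r_[np.random.default_rng(0).normal(1, 1, 30), np.zeros(30)]
        labels = np.r_[np.ones(30), np.zeros(30)]
        a = bootstrap_roc_band(scores, labels, n_resamples=50, seed=9)
        b = bootstrap_roc_band(scores, labels, n_resamples=50, seed=9)
        assert np.array_equal(a.band_lower, b.band_lower)
        assert a.auc_ci == b.auc_ci

    def test_separable_band_collapses(self):
        scores = np.r_[np.ones(20) * 5, np.zeros(20)]
        labels = np.r_[np.ones(20), np.zeros(20)]
        roc = bootstrap_roc_band(scores, labels, n_resamples=100, seed=0)
        inner = roc.grid > 0
        assert np.all(roc.band_lower[inner] == 1.0)
        assert roc.auc_ci == (1.0, 1.0)

    def test_band_brackets_point_curve(self):
        rng = np.random.default_rng(12)
        scores = np.r_[rng.normal(0.8, 1, 50), rng.normal(0, 1, 50)]
        labels = np.r_[np.ones(50), np.zeros(50)]
        roc = bootstrap_roc_band(scores, labels, n_resamples=400, seed=1)
        # percentile band should bracket the point estimate nearly everywhere
        ok = (roc.band_lower <= roc.tpr_grid + 1e-9) & (
            roc.tpr_grid - 1e-9 <= roc.band_upper
        )
        assert ok.mean() > 0.95
        assert roc.auc_ci[0] <= roc.auc <= roc.auc_ci[1]


class TestWilson:
    def test_boundaries(self):
        assert wilson_interval(0, 10)[0] == pytest.approx(0.0, abs=1e-12)
        assert wilson_interval(10, 10)[1] == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_value(self):
        lo, hi = wilson_interval(8, 10)
        assert (lo, hi) == pytest.approx((0.490, 0.943), abs=5e-4)

    def test_contains_point_estimate(self):
        for k, n in [(1, 7), (3, 9), (20, 31)]:
            lo, hi = wilson_interval(k, n)
            assert lo <= k / n <= hi

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            wilson_interval(0, 0)


class TestMatchedOperatingPoint:
    def test_self_comparison_is_zero(self):
        """Scoring with the human rule's own calls puts the curve through
        the operating point, so the matched-point delta is 0."""
        rng = np.random.default_rng(4)
        labels = rng.random(120) < 0.5
        calls = labels ^ (rng.random(120) < 0.25)  # noisy triage rule
        scores = calls.astype(float)
        res = compare_at_matched_operating_point(
            scores, labels, calls, matching="specificity", n_resamples=50, seed=0
        )
        assert res.delta == pytest.approx(0.0, abs=1e-12)

    def test_planted_superiority_detected(self):
        """A strictly more informative score wins at matched specificity
        with a small two-sided bootstrap p at n=400 slides."""
        rng = np.random.default_rng(21)
        n = 400
        labels = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(bool)
        # AI: strongly separated continuous score
        scores = np.where(labels, rng.normal(2.2, 1, n), rng.normal(0, 1, n))
        # human: noisier binary rule
        calls = labels ^ (rng.random(n) < 0.3)
        res = compare_at_matched_operating_point(
            scores, labels, calls, matching="specificity", n_resamples=400, seed=2
        )
        assert res.delta > 0
        assert res.p < 0.05
        res_f = compare_at_matched_operating_point(
            scores, labels, calls, matching="sensitivity", n_resamples=400, seed=2
        )
        assert res_f.delta < 0  # lower FPR at matched sensitivity

    def test_reproducible_p(self):
        rng = np.random.default_rng(0)
        labels = rng.random(60) < 0.5
        scores = rng.normal(labels.astype(float), 1)
        calls = rng.random(60) < 0.5
        a = compare_at_matched_operating_point(
            scores, labels, calls, n_resamples=10, seed=3
        )
        b = compare_at_matched_operating_point(
            scores, labels, calls, n_resamples=10, seed=3
        )
        assert a.p == b.p and a.delta == b.delta

    def test_human_point_wilson_intervals(self):
        labels = np.r_[np.ones(40), np.zeros(60)].astype(bool)
        calls = np.r_[np.ones(30), np.zeros(10), np.ones(12), np.zeros(48)].astype(bool)
        op = human_operating_point(calls, labels)
        assert op.sensitivity == pytest.approx(30 / 40)
        assert op.specificity == pytest.approx(48 / 60)
        assert op.sens_ci[0] <= op.sensitivity <= op.sens_ci[1]
        assert op.spec_ci == pytest.approx(wilson_interval(48, 60))


class TestLowess:
    def test_noiseless_linear_fit(self):
        x = np.linspace(0, 10, 40)
        y = 2.0 * x + 1.0
        xs, fit, lo, hi = lowess_trend(x, y, frac=0.5, n_boot=20, seed=0)
        interior = (xs > 1) & (xs < 9)
        assert np.allclose(fit[interior], 2.0 * xs[interior] + 1.0, atol=1e-6)

    def test_log_scale_recovers_exponential(self):
        x = np.linspace(20, 70, 60)
        y = np.exp(0.5 + 0.04 * x)
        xs, fit, lo, hi = lowess_trend(x, y, log_y=True, frac=0.5, n_boot=20, seed=0)
        interior = (xs > 30) & (xs < 60)
        assert np.allclose(fit[interior], np.exp(0.5 + 0.04 * xs[interior]), rtol=1e-5)

    def test_reproducible_band(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 10, 50)
        y = x + rng.normal(0, 0.5, 50)
        a = lowess_trend(x, y, n_boot=30, seed=5)
        b = lowess_trend(x, y, n_boot=30, seed=5)
        assert np.array_equal(a[2], b[2]) and np.array_equal(a[3], b[3])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            lowess_trend([1, 2, 3], [1, 2, 3])

    def test_log_requires_positive(self):
        with pytest.raises(ValueError):
            lowess_trend(np.arange(12), np.r_[np.ones(11), 0.0], log_y=True)
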