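from math import log, sqrt

import numpy as np
import pytest
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from cmjkit.spm import (
    estimate_fwhm,
    find_clusters,
    paired_t_curve,
    rft_threshold,
    spm_paired_test,
)

Q = 101
FWHM_TRUE = 12.0


def smooth_fields(rng, n, q=Q, fwhm=FWHM_TRUE, pad=40):
    """Gaussian random fields with known smoothness (white noise convolved
    with a Gaussian kernel; edges padded away)."""
    sigma = fwhm / sqrt(8 * log(2))
    w = rng.normal(0, 1, (n, q + 2 * pad))
    return gaussian_filter1d(w, sigma, axis=1)[:, pad : pad + q]


class TestPairedTCurve:
    def test_identical_conditions_give_zero_field(self, rng):
        a = smooth_fields(rng, 10)
        t, res, mask = paired_t_curve(a, a.copy())
        np.testing.assert_allclose(t[~mask], 0, atol=1e-12)

    def test_each_node_matches_scalar_paired_t(self, rng):
        a = smooth_fields(rng, 12)
        b = smooth_fields(rng, 12) + 0.3
        t, _, _ = paired_t_curve(a, b)
        for q in (0, 17, 50, 100):
            expected = stats.ttest_rel(a[:, q], b[:, q]).statistic
            assert t[q] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_node_masked(self, rng):
        a = smooth_fields(rng, 8)
        b = a.copy()
        b[:, 40] -= 1.0  # constant difference across participants
        b[:, :30] += rng.normal(0, 1, (8, 30))
        t, _, mask = paired_t_curve(a, b)
        assert mask[40]
        assert np.isnan(t[40])

    def test_antisymmetry(self, rng):
        a = smooth_fields(rng, 10)
        b = smooth_fields(rng, 10)
        t_ab, _, _ = paired_t_curve(a, b)
        t_ba, _, _ = paired_t_curve(b, a)
        np.testing.assert_allclose(t_ab, -t_ba, atol=1e-12)


class TestFwhmEstimator:
    def test_recovers_known_smoothness(self, rng):
        # 500 replicates of white noise convolved to FWHM 12 nodes
        estimates = []
        for _ in range(500):
            r = smooth_fields(rng, 10)
            r = r - r.mean(axis=0)
            estimates.append(estimate_fwhm(r))
        assert np.mean(estimates) == pytest.approx(FWHM_TRUE, rel=0.15)

    def test_smooth_limit_gives_large_fwhm(self):
        # constant-gradient residuals: nearly infinite smoothness
        base = np.linspace(0, 1, Q)
        r = np.vstack([base * s for s in (-2.0, -1.0, 1.0, 2.0)])
        assert estimate_fwhm(r) > 10 * Q


class TestRftThreshold:
    def test_zero_resel_limit_is_uncorrected_quantile(self):
        for df in (5, 9, 20):
            t_star = rft_threshold(df, 0.0, 0.05, two_tailed=True)
            assert t_star == pytest.approx(stats.t.isf(0.025, df), abs=1e-9)

    def test_monotone_in_smoothness_alpha_and_df(self):
        t_ref = rft_threshold(9, 100 / 12.0, 0.05)
        assert rft_threshold(9, 100 / 6.0, 0.05) > t_ref  # rougher -> higher
        assert rft_threshold(9, 100 / 24.0, 0.05) < t_ref
        assert rft_threshold(9, 100 / 12.0, 0.01) > t_ref
        assert rft_threshold(20, 100 / 12.0, 0.05) < t_ref  # more df -> lower

    def test_familywise_error_calibrated_on_smooth_fields(self, rng):
        # Monte-Carlo oracle: max |t| of 3000 null smooth t-fields (n=10)
        # should exceed the RFT threshold ~5% of the time
        n, reps = 10, 3000
        t_star = rft_threshold(n - 1, (Q - 1) / FWHM_TRUE, 0.05, two_tailed=True)
        zeros = np.zeros((n, Q))
        count = 0
        for _ in range(reps):
            y = smooth_fields(rng, n)
            t, _, _ = paired_t_curve(y, zeros)
            count += np.nanmax(np.abs(t)) > t_star
        ci = 1.96 * sqrt(0.05 * 0.95 / reps)
        assert abs(count / reps - 0.05) < ci + 0.01  # MC + EC-approximation slack


class TestClusters:
    def test_subthreshold_field_has_no_clusters(self):
        t = np.full(Q, 1.0)
        assert find_clusters(t, 3.0, 10.0, 9) == []

    def test_triangular_excursion_interpolated_endpoints(self):
        # |t| crosses the threshold between nodes 48/49 and 74/75
        t = np.zeros(Q)
        up = np.linspace(0, 6, 14)  # nodes 48..61 rise to the apex
        t[48:62] = up
        t[62:76] = np.linspace(6 - 6 / 14, 0, 14)
        clusters = find_clusters(t, 3.0, 10.0, 9)
        assert len(clusters) == 1
        c = clusters[0]
        assert c.start_percent == pytest.approx(48 + 3.0 / (6 / 13), abs=0.2)
        assert c.end_percent < 76
        assert c.sign == 1

    def test_cluster_p_decreasing_in_extent(self):
        from cmjkit.spm import _cluster_p

        ps = [_cluster_p(k, 3.5, 9, 8.0, True) for k in (0.5, 1.0, 2.0, 4.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert all(0 < p <= 1 for p in ps)


class TestSpmPairedTest:
    def test_swap_negates_field_same_clusters(self, rng):
        a = smooth_fields(rng, 10)
        b = smooth_fields(rng, 10) + np.linspace(0, 1.5, Q)
        r1 = spm_paired_test(a, b)
        r2 = spm_paired_test(b, a)
        np.testing.assert_allclose(r1.t_curve, -r2.t_curve, atol=1e-12)
        assert r1.t_star == pytest.approx(r2.t_star, abs=1e-12)
        assert [(c.start_percent, c.end_percent, c.p_value) for c in r1.clusters] == [
            (c.start_percent, c.end_percent, c.p_value) for c in r2.clusters
        ]
        assert [c.sign for c in r1.clusters] == [-c.sign for c in r2.clusters]

    def test_null_any_cluster_rate_near_alpha(self, rng):
        # 2000 replicate null studies on smooth Gaussian fields
        reps, n = 2000, 10
        count = 0
        for _ in range(reps):
            a = smooth_fields(rng, n)
            b = smooth_fields(rng, n)
            count += bool(spm_paired_test(a, b).clusters)
        ci = 1.96 * sqrt(0.05 * 0.95 / reps)
        assert abs(count / reps - 0.05) < ci + 0.01

    def test_deterministic_given_inputs(self, rng):
        a = smooth_fields(rng, 10)
        b = smooth_fields(rng, 10)
        r1 = spm_paired_test(a, b)
        r2 = spm_paired_test(a, b)
        np.testing.assert_array_equal(r1.t_curve, r2.t_curve)
        assert r1.t_star == r2.t_star
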