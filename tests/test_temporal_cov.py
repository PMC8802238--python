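"""Covariance estimators, noise corrections, variance decomposition, G."""

import numpy as np
import pytest

from tempocov.temporal_cov import (
    NoiseModel,
    covariance_matrix,
    g_statistic,
    interval_deltas,
    sampling_noise_var,
    total_variance,
)

from conftest import make_panel


class TestIntervalDeltas:
    def test_definition(self):
        panel = make_panel([[0.5, 0.6, 0.4, 0.7]])
        np.testing.assert_allclose(
            interval_deltas(panel).deltas, [[0.1, -0.2, 0.3]]
        )

    def test_constant_and_extreme(self):
        np.testing.assert_allclose(
            interval_deltas(make_panel([[0.3, 0.3, 0.3]])).deltas, [[0.0, 0.0]]
        )
        np.testing.assert_allclose(
            interval_deltas(make_panel([[0.0, 1.0]])).deltas, [[1.0]]
        )

    def test_single_time_point_is_error(self):
        with pytest.raises(ValueError):
            interval_deltas(make_panel([[0.5]]))


class TestSamplingNoiseVar:
    def test_zero_at_fixation_and_in_limit(self):
        model = NoiseModel(n=50, d=40)
        assert sampling_noise_var(0.0, model) == 0.0
        assert sampling_noise_var(1.0, model) == 0.0
        assert sampling_noise_var(0.5, NoiseModel(n=10**9, d=10**9)) < 1e-9

    def test_closed_form_limits(self):
        # a single read is a Bernoulli draw: variance p(1-p)
        assert sampling_noise_var(0.3, NoiseModel(n=50, d=1)) == pytest.approx(0.21)
        # a single diploid: p(1-p) * [1/2 + (1/2)/d]
        assert sampling_noise_var(0.5, NoiseModel(n=1, d=10)) == pytest.approx(
            0.25 * (0.5 + 0.05)
        )

    def test_matches_two_stage_monte_carlo(self):
        """Brute-force oracle: n diploids then d reads, 10^6 draws."""
        rng = np.random.default_rng(7)
        p, n, d = 0.5, 50, 40
        m = 10**6
        q = rng.binomial(2 * n, p, size=m) / (2 * n)
        obs = rng.binomial(d, q) / d
        sq = (obs - p) ** 2
        mc_var, mc_se = sq.mean(), sq.std() / np.sqrt(m)
        assert abs(sampling_noise_var(p, NoiseModel(n, d)) - mc_var) < 3 * mc_se


class TestCovarianceMatrix:
    def test_noise_free_matches_brute_force(self):
        """With noiseless data the corrected matrix equals a loop-computed
        loci-averaged covariance of the interval changes."""
        rng = np.random.default_rng(3)
        freq = rng.uniform(0.05, 0.95, size=(40, 4))
        panel = make_panel(freq, depth=10**12, pool_size=10**9)
        cm = covariance_matrix(panel)
        d = freq[:, 1:] - freq[:, :-1]
        expect = np.zeros((3, 3))
        for s in range(3):
            for t in range(3):
                expect[s, t] = np.mean(
                    (d[:, s] - d[:, s].mean()) * (d[:, t] - d[:, t].mean())
                )
        np.testing.assert_allclose(cm.raw, expect, atol=1e-12)
        np.testing.assert_allclose(cm.corrected, expect, atol=1e-9)

    def test_pure_noise_correction(self):
        """Constant true frequencies observed through two-stage sampling:
        the raw adjacent covariance is biased downward by the shared-point
        noise; the corrected diagonal and adjacent entries sit near zero."""
        rng = np.random.default_rng(5)
        L, n, d = 10**4, 50, 40
        p = rng.uniform(0.1, 0.9, size=L)
        obs = np.empty((L, 4))
        for t in range(4):
            q = rng.binomial(2 * n, p) / (2 * n)
            obs[:, t] = rng.binomial(d, q) / d
        panel = make_panel(obs, depth=d, pool_size=n)
        cm = covariance_matrix(panel)
        expected_bias = -np.mean(p * (1 - p)) * (1 / (2 * n) + (1 - 1 / (2 * n)) / d)
        assert cm.raw[0, 1] < expected_bias / 2  # clearly negative
        assert abs(cm.corrected[0, 1]) < 1e-3
        assert abs(cm.corrected[0, 0]) < 1.5e-3
        assert cm.raw[0, 0] > -expected_bias  # diagonal carries both endpoints' noise

    def test_polarity_invariance(self):
        """Ref/alt polarity is a bookkeeping choice: flipping any subset of
        loci leaves the uncentred matrices unchanged exactly, and flipping
        every locus leaves the centred ones unchanged exactly (a subset flip
        perturbs the centred estimator only through the rank-one loci-mean
        term, which vanishes as the mean change does)."""
        rng = np.random.default_rng(9)
        freq = rng.uniform(0, 1, size=(60, 4))
        subset = freq.copy()
        subset[::3] = 1.0 - subset[::3]
        a = covariance_matrix(make_panel(freq, depth=40), centered=False)
        b = covariance_matrix(make_panel(subset, depth=40), centered=False)
        np.testing.assert_allclose(a.raw, b.raw, atol=1e-14)
        np.testing.assert_allclose(a.corrected, b.corrected, atol=1e-14)
        np.testing.assert_allclose(a.standardized, b.standardized, atol=1e-12)
        c = covariance_matrix(make_panel(freq, depth=40))
        d = covariance_matrix(make_panel(1.0 - freq, depth=40))
        np.testing.assert_allclose(c.raw, d.raw, atol=1e-14)
        np.testing.assert_allclose(c.standardized, d.standardized, atol=1e-12)

    def test_single_locus_is_error(self):
        with pytest.raises(ValueError, match="2 loci"):
            covariance_matrix(make_panel([[0.5, 0.6, 0.4, 0.7]]))

    def test_all_fixed_loci_flag_undefined_standardizer(self):
        freq = np.array([[0.0, 0.1, 0.2, 0.3], [0.0, 0.2, 0.1, 0.4]])
        cm = covariance_matrix(make_panel(freq, depth=40))
        # reference time for entry (0, *) is t0 where every locus is fixed
        assert np.isnan(cm.standardized[0, 0])


class TestVarianceDecomposition:
    def test_identity_on_raw_quantities(self):
        """Total-change variance equals the interval decomposition exactly."""
        rng = np.random.default_rng(1)
        freq = rng.uniform(0, 1, size=(500, 4))
        panel = make_panel(freq, depth=40)
        cm = covariance_matrix(panel)
        direct = np.var(freq[:, 3] - freq[:, 0])
        assert total_variance(cm.raw, 3) == pytest.approx(direct, rel=1e-12)

    def test_diagonal_only_and_constant_matrix(self):
        assert total_variance(np.diag([1.0, 2.0, 3.0]), 3) == 6.0
        assert total_variance(np.ones((3, 3)), 3) == 9.0


class TestGStatistic:
    def test_single_interval_is_exactly_zero(self):
        """With one interval there is no covariance term, so G = 0."""
        res = g_statistic(np.array([[0.5]]), upto=1)
        assert res.g == 0.0 and res.numerator == 0.0

    def test_zero_off_diagonals(self):
        assert g_statistic(np.diag([1.0, 1.0, 1.0])).g == 0.0

    def test_hand_computed_ratio(self):
        m = np.full((3, 3), 0.25)
        np.fill_diagonal(m, 1.0)
        res = g_statistic(m)
        assert res.numerator == pytest.approx(1.5)
        assert res.denominator == pytest.approx(4.5)
        assert res.g == pytest.approx(1 / 3)

    def test_zero_denominator_reported_undefined(self):
        m = np.array([[0.0, 0.0], [0.0, 0.0]])
        assert np.isnan(g_statistic(m).g)
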