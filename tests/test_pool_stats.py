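"""Coverage subsampling, windowed Tajima's pi, per-SNP F_ST."""

import numpy as np
import pytest

from tempocov.io_sync import SyncRecord
from tempocov.pool_stats import (
    pairwise_fst_table,
    site_heterozygosity,
    snp_fst,
    subsample_coverage,
    window_pi,
)
from tempocov.temporal_cov import _noise_factor


def rec(a=0, t=0, c=0, g=0, contig="w", pos=1):
    return SyncRecord(contig=contig, pos=pos, ref_base="A",
                      counts=np.array([[a, t, c, g, 0, 0]]))


class TestSubsampleCoverage:
    def test_hypergeometric_draw_to_exact_target(self):
        out = subsample_coverage(rec(a=20, c=20), 30, np.random.default_rng(0))
        assert out.counts[0, :4].sum() == 30
        assert out.counts[0, 0] + out.counts[0, 2] == 30

    def test_below_target_site_dropped(self):
        assert subsample_coverage(rec(a=29), 30, np.random.default_rng(0)) is None

    def test_deterministic_under_seed(self):
        a = subsample_coverage(rec(a=50, c=30), 30, np.random.default_rng(9))
        b = subsample_coverage(rec(a=50, c=30), 30, np.random.default_rng(9))
        np.testing.assert_array_equal(a.counts, b.counts)


class TestSiteHeterozygosity:
    def test_hand_value_at_balanced_counts(self):
        # m=30, counts (15,15): h = 30/29 * (1 - 0.5) = 15/29
        assert site_heterozygosity([15, 15, 0, 0]) == pytest.approx(15 / 29)

    def test_minor_count_gate(self):
        assert site_heterozygosity([29, 1, 0, 0], min_minor_count=2) == 0.0
        assert site_heterozygosity([29, 1, 0, 0], min_minor_count=1) > 0.0

    def test_allele_relabelling_invariance(self):
        assert site_heterozygosity([10, 0, 20, 0]) == site_heterozygosity([0, 20, 0, 10])

    def test_unbiased_for_read_pool_heterozygosity(self):
        """Monte-Carlo oracle: reads multinomial from (0.7, 0.3) at m=30;
        without the minor-count gate the estimator is unbiased for 1 - sum p^2."""
        rng = np.random.default_rng(31)
        m, p = 30, np.array([0.7, 0.3, 0.0, 0.0])
        draws = rng.multinomial(m, p, size=20_000)
        vals = np.array([site_heterozygosity(d, min_minor_count=1) for d in draws])
        truth = 1 - np.sum(p**2)
        assert abs(vals.mean() - truth) < 3 * vals.std() / np.sqrt(len(vals))


class TestWindowPi:
    def _records(self, n_covered, window=10_000, poly_at=(), m=30):
        out = []
        for i in range(n_covered):
            counts = (15, 15) if i in poly_at else (m, 0)
            out.append(rec(a=counts[0], c=counts[1], pos=i + 1))
        return out

    def test_zero_polymorphism_full_coverage(self):
        table = window_pi(self._records(10_000), {"w": 10_000}, 0)
        assert table.loc[0, "pi"] == 0.0 and table.loc[0, "covered_fraction"] == 1.0

    def test_single_polymorphic_site_hand_value(self):
        table = window_pi(self._records(10_000, poly_at={5}), {"w": 10_000}, 0)
        assert table.loc[0, "pi"] == pytest.approx((15 / 29) / 10_000)
        assert table.loc[0, "n_sites"] == 1

    def test_covered_fraction_rule(self):
        below = window_pi(self._records(4_900), {"w": 10_000}, 0)
        at = window_pi(self._records(5_000, poly_at={1}), {"w": 10_000}, 0)
        assert np.isnan(below.loc[0, "pi"])
        # per-covered-base denominator keeps partial windows comparable
        assert at.loc[0, "pi"] == pytest.approx((15 / 29) / 5_000)

    def test_non_uniform_coverage_is_hard_error(self):
        records = [rec(a=30, pos=1), rec(a=29, pos=2)]
        with pytest.raises(ValueError, match="coverage"):
            window_pi(records, {"w": 10_000}, 0)


class TestSnpFst:
    def test_identical_pools_near_zero(self):
        res = snp_fst((30, 10), (30, 10), 50, 50)
        assert res.fst == 0.0 and abs(res.unclipped) < 0.05

    def test_fixed_opposite_alleles(self):
        assert snp_fst((40, 0), (0, 40), 1000, 1000).fst > 0.95
        assert snp_fst((40, 0), (0, 40), flavor="karlsson").fst == pytest.approx(1.0)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(41)
        for _ in range(50):
            ca = tuple(rng.integers(0, 60, 2) + 1)
            cb = tuple(rng.integers(0, 60, 2) + 1)
            x, y = snp_fst(ca, cb, 50, 50), snp_fst(cb, ca, 50, 50)
            assert x.fst == pytest.approx(y.fst)
            assert 0 <= x.fst <= 1

    def test_hand_evaluated_closed_form(self):
        """(30:10) vs (10:30) at equal pools and depths, against an
        independent inline evaluation of the pi-based estimator."""
        n, d = 50, 40
        p1, p2 = 10 / 40, 30 / 40
        a = 1 / (2 * n) + (1 - 1 / (2 * n)) / d
        h1 = 2 * p1 * (1 - p1) / (1 - a)
        h2 = 2 * p2 * (1 - p2) / (1 - a)
        pi_w = (h1 + h2) / 2
        pi_b = p1 * (1 - p2) + p2 * (1 - p1)
        pi_t = (pi_w + pi_b) / 2
        expected = (pi_t - pi_w) / pi_t
        res = snp_fst((30, 10), (10, 30), n, n)
        assert res.unclipped == pytest.approx(expected, rel=1e-12)
        assert _noise_factor(n, d) == pytest.approx(a)

    def test_undefined_when_monomorphic(self):
        assert np.isnan(snp_fst((40, 0), (40, 0), 50, 50).fst)

    def test_neutral_genome_mean_below_002(self):
        """Two pools sequenced from one panmictic population: the clipped
        genome-mean F_ST stays below 0.02 at large n and depth."""
        rng = np.random.default_rng(43)
        records = []
        p = rng.beta(0.5, 0.5, size=3000)
        p = p[(p > 0.05) & (p < 0.95)]
        for i, pi_ in enumerate(p):
            counts = np.zeros((2, 6), dtype=int)
            for pool in range(2):
                q = rng.binomial(200, pi_) / 200  # n = 100 diploids
                alt = rng.binomial(100, q)
                counts[pool, 0], counts[pool, 2] = 100 - alt, alt
            records.append(
                SyncRecord(contig="c", pos=i + 1, ref_base="A", counts=counts)
            )
        table = pairwise_fst_table(records, [(0, 1)], ["x"], [100, 100])
        assert 0 <= table["fst"].mean() < 0.02
        assert abs(table["fst_unclipped"].mean()) < 0.01
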