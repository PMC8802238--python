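"""Forward simulator: determinism, neutral behaviour, selection machinery."""

import numpy as np
import pytest

from tempocov import synthetic_data as sd
from tempocov.temporal_cov import NoiseModel, sampling_noise_var


def tiny(seed=0, **kw):
    base = dict(
        n_replicates=1,
        population_size=200,
        n_chromosomes=4,
        loci_per_chromosome=250,
    )
    base.update(kw)
    return sd.SimConfig(seed=seed, **base)


class TestDeterminismAndShapes:
    def test_same_seed_reproduces_counts(self):
        a, b = sd.simulate(tiny(5)), sd.simulate(tiny(5))
        np.testing.assert_array_equal(a.counts["R1"], b.counts["R1"])

    def test_different_seeds_differ(self):
        a, b = sd.simulate(tiny(5)), sd.simulate(tiny(6))
        assert (a.counts["R1"] != b.counts["R1"]).any()

    def test_records_round_trip_through_sync(self, tmp_path, demo_sim):
        from tempocov.io_sync import read_sync

        demo_sim.write(tmp_path)
        back = list(read_sync(tmp_path / "all_pools.sync", demo_sim.design))
        assert len(back) == demo_sim.config.n_loci
        orig = next(demo_sim.records())
        np.testing.assert_array_equal(back[0].counts, orig.counts)
        assert (tmp_path / "truth.tsv").exists()
        assert (tmp_path / "design.yaml").exists()

    def test_va_target_unreachable_without_selected_loci(self):
        with pytest.raises(ValueError, match="V_A"):
            tiny(fitness_variance=0.5)


class TestNeutralBehaviour:
    def test_mean_frequency_conserved(self):
        res = sd.simulate(tiny(7, population_size=500))
        traj = res.truth.freq_trajectories["R1"]
        drift = (traj[:, -1] - traj[:, 0]).mean()
        se = (traj[:, -1] - traj[:, 0]).std() / np.sqrt(traj.shape[0])
        assert abs(drift) < 4 * se + 1e-4

    def test_heterozygosity_decay_rate(self):
        """Mean heterozygosity decays by (1 - 1/2N) per generation."""
        cfg = tiny(
            8,
            population_size=50,
            loci_per_chromosome=2500,
            generations_per_interval=(2, 2, 2),
        )
        res = sd.simulate(cfg)
        traj = res.truth.freq_trajectories["R1"]
        het = (traj * (1 - traj)).mean(axis=0)
        observed = (het[-1] / het[0]) ** (1 / 6)
        assert observed == pytest.approx(1 - 1 / 100, abs=0.01)

    def test_expected_noise_check_table(self):
        table = sd.expected_noise_check(n_loci=10**5, seed=3)
        assert (table["relative_error"].abs() < 0.05).all()

    def test_noise_formula_degenerate_cases(self):
        # one read is Bernoulli; one diploid leaves 1/2 + 1/(2d)
        assert sampling_noise_var(0.4, NoiseModel(50, 1)) == pytest.approx(0.24)
        assert sampling_noise_var(0.4, NoiseModel(1, 8)) == pytest.approx(
            0.24 * (0.5 + 0.5 / 8)
        )


class TestSelectionMachinery:
    def test_realized_fitness_variance_near_target(self):
        res = sd.simulate(sd.sustained_config(9, n_replicates=1))
        va = res.truth.va_realized["R1"]
        assert va[0] == pytest.approx(0.2, rel=0.5)
        assert (va > 0).all()

    def test_directional_regimes_move_selected_loci(self):
        res = sd.simulate(sd.sustained_config(10, n_replicates=1))
        truth = res.truth
        tf = truth.cohort_freq["R1"]
        move = (tf[truth.selected, -1] - tf[truth.selected, 0]) * np.sign(truth.effects)
        assert move.mean() > 0.02  # signed displacement in the fitness direction

    def test_selected_region_confinement_and_spread(self):
        cfg = sd.scan_config(2)
        res = sd.simulate(cfg)
        pos = res.truth.positions[res.truth.selected] - 1
        ctg = res.truth.contigs[res.truth.selected]
        assert set(ctg) == {"chr1"} and pos.max() < 500_000
        # stratified placement reaches every 100-kb tile of the region
        assert set(pos // 100_000) == {0, 1, 2, 3, 4}

    def test_severe_episode_beats_mild_continuous_selection(self):
        """One strong generation per interval produces larger adjacent
        covariances than the same total differential spread over five
        generations, because LD decays between the spread-out episodes."""

        def true_cov01(res):
            tf = res.truth.cohort_freq["R1"]
            d = np.diff(tf, axis=1)
            dc = d - d.mean(axis=0)
            het = tf[:, 0] * (1 - tf[:, 0])
            return (dc[:, 0] * dc[:, 1]).mean() / het[het > 0].mean()

        severe, mild = [], []
        for seed in range(4):
            kw = dict(recomb_rate=1e-6, n_replicates=1)
            severe.append(
                true_cov01(
                    sd.simulate(
                        sd.sustained_config(
                            seed, v_a=0.4, generations_per_interval=(1, 1, 1), **kw
                        )
                    )
                )
            )
            mild.append(
                true_cov01(
                    sd.simulate(
                        sd.sustained_config(
                            seed, v_a=0.4 / 25, generations_per_interval=(5, 5, 5), **kw
                        )
                    )
                )
            )
        assert np.mean(severe) > np.mean(mild)
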