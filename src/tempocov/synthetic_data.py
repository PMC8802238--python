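"""Wright–Fisher cohort simulator with pooled-sequencing noise.

The generator emulates the study design that motivates this package: several
replicate forests, each an isolated population sampled as age-structured
cohorts (birth years 1680, 1850, 1960, 2008), pooled-sequenced at ~40x with
pools of 40–68 diploids.  Between cohorts the population advances through
discrete Wright–Fisher generations (one regeneration per interval by
default).  Under a directional regime, individual fitness is
``exp(± Σ effects · genotype)`` over a set of selected loci whose effects are
scaled to a target additive variance of log fitness (V_A); linked neutral
loci respond through linkage disequilibrium, which is what the temporal
covariance estimators are meant to detect.

Standing variation is initialized from a symmetric Beta frequency
distribution.  Realistic LD can be injected by founding the population from
a finite pool of haplotypes (``founder_haplotypes``), optionally block-wise
(``founder_block`` bp) so that LD does not extend beyond a chosen scale; the
default (``None``) founds in linkage equilibrium.

Each cohort pool is sampled without replacement from the population, read
depth is Poisson around the target mean, and read alleles are binomial draws
from the sampled chromosomes — exactly the two-stage noise model the
estimators correct for.  Output is Popoolation2 sync (plus contig lengths and
a ground-truth table), so the entire pipeline runs on simulated data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from tempocov.io_sync import CohortDesign, SyncRecord, write_sync
from tempocov.temporal_cov import NoiseModel, sampling_noise_var

REGIMES = ("neutral", "directional+", "directional-")


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings; defaults give a neutral three-forest design."""

    n_replicates: int = 3
    population_size: int = 10_000  # diploids
    n_chromosomes: int = 20
    loci_per_chromosome: int = 500
    chromosome_length: int = 1_000_000  # bp
    recomb_rate: float = 1e-8  # crossovers per bp per generation
    n_selected_loci: int = 0
    fitness_variance: float = 0.0  # target V_A of log fitness at founding
    regimes: tuple[str, ...] | Mapping[str, tuple[str, ...]] = ()
    shared_targets: bool = True  # replicates share founders and selected loci
    generations_per_interval: tuple[int, ...] = (1, 1, 1)
    cohort_times: tuple[int, ...] = (1680, 1850, 1960, 2008)
    pool_sizes: tuple[int, ...] = (50, 50, 50, 50)
    mean_depth: float = 40.0
    founder_haplotypes: int | None = None  # None = linkage equilibrium
    founder_block: int | None = None  # bp extent of founder haplotypes
    beta_shape: float = 0.5  # symmetric Beta for founder frequencies
    selected_region: tuple[str, int, int] | None = None  # confine targets
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cohort_times) != len(self.generations_per_interval) + 1:
            raise ValueError("need one generations_per_interval per cohort gap")
        if list(self.cohort_times) != sorted(set(self.cohort_times)):
            raise ValueError("cohort_times must be strictly increasing")
        if len(self.pool_sizes) != len(self.cohort_times):
            raise ValueError("one pool size per cohort")
        if not self.regimes:
            object.__setattr__(
                self, "regimes", ("neutral",) * len(self.generations_per_interval)
            )
        for reg in self._regime_table().values():
            for r in reg:
                if r not in REGIMES:
                    raise ValueError(f"unknown regime {r!r}")
        if self.fitness_variance > 0 and self.n_selected_loci == 0:
            raise ValueError(
                "fitness_variance > 0 requires n_selected_loci > 0: the V_A "
                "target is unreachable without selected loci"
            )

    @property
    def replicate_labels(self) -> tuple[str, ...]:
        return tuple(f"R{i + 1}" for i in range(self.n_replicates))

    @property
    def n_loci(self) -> int:
        return self.n_chromosomes * self.loci_per_chromosome

    def _regime_table(self) -> dict[str, tuple[str, ...]]:
        if isinstance(self.regimes, Mapping):
            return {r: tuple(self.regimes[r]) for r in self.replicate_labels}
        return {r: tuple(self.regimes) for r in self.replicate_labels}

    def design(self) -> CohortDesign:
        pool_sizes = {
            (r, t): n
            for r in self.replicate_labels
            for t, n in zip(self.cohort_times, self.pool_sizes)
        }
        return CohortDesign(
            replicates=self.replicate_labels,
            time_points=self.cohort_times,
            pool_sizes=pool_sizes,
        )


@dataclass
class SimTruth:
    """Ground truth for parameter-recovery tests."""

    contigs: np.ndarray  # (L,)
    positions: np.ndarray  # (L,) 1-based
    selected: np.ndarray  # locus indices under selection
    effects: np.ndarray  # log-fitness effect per selected locus (magnitude, signed)
    regimes: dict[str, tuple[str, ...]]
    freq_trajectories: dict[str, np.ndarray]  # rep -> (L, n_generations + 1)
    cohort_freq: dict[str, np.ndarray]  # rep -> (L, T) population freq at sampling
    sample_freq: dict[str, np.ndarray]  # rep -> (L, T) pooled-sample freq
    va_realized: dict[str, np.ndarray]  # rep -> (n_generations,) var of log fitness
    cohort_generations: tuple[int, ...]


@dataclass
class SimResult:
    config: SimConfig
    design: CohortDesign
    truth: SimTruth
    counts: dict[str, np.ndarray]  # rep -> (L, T, 6) sync count vectors
    contig_lengths: dict[str, int]

    def records(self, replicate: str | None = None) -> Iterator[SyncRecord]:
        """Sync records; all pools in design column order, or one replicate."""
        reps = [replicate] if replicate else list(self.design.replicates)
        stacked = np.concatenate([self.counts[r] for r in reps], axis=1)
        for i in range(len(self.truth.positions)):
            yield SyncRecord(
                contig=str(self.truth.contigs[i]),
                pos=int(self.truth.positions[i]),
                ref_base="A",
                counts=stacked[i],
            )

    def write(self, outdir: str | Path) -> None:
        """Emit per-replicate sync files, contig lengths, truth and manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for rep in self.design.replicates:
            write_sync(self.records(rep), outdir / f"{rep}.sync")
        write_sync(self.records(), outdir / "all_pools.sync")
        with open(outdir / "contig_lengths.tsv", "w") as fh:
            for contig, length in self.contig_lengths.items():
                fh.write(f"{contig}\t{length}\n")
        truth_frames = []
        for rep in self.design.replicates:
            frame = pd.DataFrame(
                self.truth.cohort_freq[rep],
                columns=[f"true_freq_{t}" for t in self.design.time_points],
            )
            frame.insert(0, "contig", self.truth.contigs)
            frame.insert(1, "pos", self.truth.positions)
            frame.insert(2, "replicate", rep)
            frame["selected"] = np.isin(
                np.arange(len(self.truth.positions)), self.truth.selected
            )
            truth_frames.append(frame)
        pd.concat(truth_frames).to_csv(outdir / "truth.tsv", sep="\t", index=False)
        manifest = {
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(self.config).items()
                if not isinstance(v, Mapping)
            },
            "replicates": list(self.design.replicates),
            "time_points": list(self.design.time_points),
        }
        with open(outdir / "sim_manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh)
        design_spec = {
            "replicates": list(self.design.replicates),
            "time_points": list(self.design.time_points),
            "pool_sizes": {
                r: {int(t): int(self.design.pool_sizes[(r, t)]) for t in self.design.time_points}
                for r in self.design.replicates
            },
        }
        with open(outdir / "design.yaml", "w") as fh:
            yaml.safe_dump(design_spec, fh)


def _founder_frequencies(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    return rng.beta(config.beta_shape, config.beta_shape, size=config.n_loci)


def _founder_pool(
    config: SimConfig, freq0: np.ndarray, rng: np.random.Generator
) -> np.ndarray | None:
    """The K distinct founder haplotypes (None = linkage equilibrium).

    With ``shared_targets`` the pool is drawn once and reused by every
    replicate, mimicking a shared refugial origin: replicates then share
    standing LD, which is what makes *parallel* linked selection visible
    between them.
    """
    if config.founder_haplotypes is None:
        return None
    K = config.founder_haplotypes
    return (rng.random((K, config.n_loci)) < freq0).astype(np.uint8)


def _found_population(
    config: SimConfig,
    freq0: np.ndarray,
    pool: np.ndarray | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Haplotype matrix (2N, L) of founder genomes."""
    n2 = 2 * config.population_size
    if pool is None:
        # Bernoulli via uniform comparison: much faster than binomial at this size
        return (rng.random((n2, config.n_loci)) < freq0).astype(np.uint8)
    K = pool.shape[0]
    pop = np.empty((n2, config.n_loci), dtype=np.uint8)
    block = config.founder_block or config.chromosome_length
    positions = _locus_positions(config)
    for c0, c1 in _chrom_slices(config):
        pos_c = positions[c0:c1]
        # independent founder assignment per block keeps LD local to blocks
        edges = np.arange(0, config.chromosome_length + block, block)
        block_of = np.searchsorted(edges, pos_c - 1, side="right") - 1
        for b in np.unique(block_of):
            cols = c0 + np.flatnonzero(block_of == b)
            assign = rng.integers(0, K, size=n2)
            pop[:, cols] = pool[assign[:, None], cols[None, :]]
    return pop


def _locus_positions(config: SimConfig) -> np.ndarray:
    step = config.chromosome_length / (config.loci_per_chromosome + 1)
    per_chrom = np.round(np.arange(1, config.loci_per_chromosome + 1) * step).astype(int)
    return np.tile(per_chrom, config.n_chromosomes)


def _locus_contigs(config: SimConfig) -> np.ndarray:
    return np.repeat(
        [f"chr{i + 1}" for i in range(config.n_chromosomes)],
        config.loci_per_chromosome,
    )


def _chrom_slices(config: SimConfig) -> list[tuple[int, int]]:
    L = config.loci_per_chromosome
    return [(i * L, (i + 1) * L) for i in range(config.n_chromosomes)]


def _pick_selected(
    config: SimConfig, freq0: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Selected locus indices and signed effects scaled to the V_A target."""
    if config.n_selected_loci == 0:
        return np.array([], dtype=int), np.array([])
    if config.selected_region is not None:
        contig, start, end = config.selected_region
        eligible = np.flatnonzero(
            (_locus_contigs(config) == contig)
            & (_locus_positions(config) - 1 >= start)
            & (_locus_positions(config) - 1 < end)
        )
        if len(eligible) < config.n_selected_loci:
            raise ValueError(
                f"selected_region holds {len(eligible)} loci, "
                f"fewer than n_selected_loci={config.n_selected_loci}"
            )
        # spread targets evenly over the region so every tile of it carries
        # signal: one locus per position-ordered chunk
        chunks = np.array_split(eligible, config.n_selected_loci)
        selected = np.sort([rng.choice(c) for c in chunks])
    else:
        eligible = np.arange(config.n_loci)
        selected = np.sort(
            rng.choice(eligible, size=config.n_selected_loci, replace=False)
        )
    magnitudes = rng.uniform(0.5, 1.5, size=config.n_selected_loci)
    signs = rng.choice([-1.0, 1.0], size=config.n_selected_loci)
    het = 2 * freq0[selected] * (1 - freq0[selected])
    denom = float((het * magnitudes**2).sum())
    if denom <= 0:
        raise ValueError(
            "V_A target unreachable: selected loci carry no founder variation"
        )
    scale = np.sqrt(config.fitness_variance / denom)
    return selected, signs * magnitudes * scale


def _advance_generation(
    pop: np.ndarray,
    config: SimConfig,
    regime: str,
    selected: np.ndarray,
    effects: np.ndarray,
    positions: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """One Wright–Fisher generation; returns (offspring, realized V_A)."""
    n2 = pop.shape[0]
    n = n2 // 2
    va = 0.0
    if regime == "neutral" or len(selected) == 0:
        parents = rng.integers(0, n, size=n2)
    else:
        sign = 1.0 if regime.endswith("+") else -1.0
        genotypes = pop[0::2][:, selected].astype(float) + pop[1::2][:, selected]
        log_w = sign * genotypes @ effects
        va = float(np.var(log_w))
        w = np.exp(log_w - log_w.max())
        parents = rng.choice(n, size=n2, p=w / w.sum())
    new = np.empty_like(pop)
    lam = config.recomb_rate * config.chromosome_length
    for c0, c1 in _chrom_slices(config):
        view = pop[:, c0:c1]
        pos_c = positions[c0:c1]
        choice = rng.integers(0, 2, size=n2)
        new[:, c0:c1] = view[2 * parents + choice]
        n_x = rng.poisson(lam, size=n2)
        for g in np.flatnonzero(n_x):
            breaks = np.sort(rng.uniform(0, config.chromosome_length, size=n_x[g]))
            parity = (choice[g] + np.searchsorted(breaks, pos_c)) % 2
            new[g, c0:c1] = np.where(
                parity == 1, view[2 * parents[g] + 1], view[2 * parents[g]]
            )
    return new, va


def _sample_pool(
    pop: np.ndarray, n_pool: int, mean_depth: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Pool n diploids, sequence at Poisson depth; returns (counts6, sample_freq)."""
    n = pop.shape[0] // 2
    chosen = rng.choice(n, size=n_pool, replace=False)
    rows = np.concatenate([2 * chosen, 2 * chosen + 1])
    q = pop[rows].mean(axis=0)
    depth = rng.poisson(mean_depth, size=pop.shape[1])
    alt = rng.binomial(depth, q)
    counts = np.zeros((pop.shape[1], 6), dtype=np.int64)
    counts[:, 0] = depth - alt  # ref base A
    counts[:, 2] = alt  # alt base C
    return counts, q


def simulate(config: SimConfig) -> SimResult:
    """Run the forward simulation for every replicate; deterministic per seed."""
    master = np.random.SeedSequence(config.seed)
    shared_ss, *rep_ss = master.spawn(config.n_replicates + 1)
    shared_rng = np.random.default_rng(shared_ss)
    positions = _locus_positions(config)
    contigs = _locus_contigs(config)
    regime_table = config._regime_table()

    shared_freq0 = _founder_frequencies(config, shared_rng)
    shared_selected, shared_effects = _pick_selected(config, shared_freq0, shared_rng)
    shared_pool = _founder_pool(config, shared_freq0, shared_rng)

    counts: dict[str, np.ndarray] = {}
    trajectories: dict[str, np.ndarray] = {}
    cohort_freq: dict[str, np.ndarray] = {}
    sample_freq: dict[str, np.ndarray] = {}
    va_realized: dict[str, np.ndarray] = {}
    T = len(config.cohort_times)

    for rep, ss in zip(config.replicate_labels, rep_ss):
        rng = np.random.default_rng(ss)
        if config.shared_targets:
            freq0, selected, effects = shared_freq0, shared_selected, shared_effects
            pool = shared_pool
        else:
            freq0 = _founder_frequencies(config, rng)
            selected, effects = _pick_selected(config, freq0, rng)
            pool = _founder_pool(config, freq0, rng)
        pop = _found_population(config, freq0, pool, rng)

        n_gens = sum(config.generations_per_interval)
        traj = np.empty((config.n_loci, n_gens + 1))
        traj[:, 0] = pop.mean(axis=0)
        va = np.zeros(n_gens)
        rep_counts = np.zeros((config.n_loci, T, 6), dtype=np.int64)
        rep_cohort = np.empty((config.n_loci, T))
        rep_sample = np.empty((config.n_loci, T))

        rep_counts[:, 0], rep_sample[:, 0] = _sample_pool(
            pop, config.pool_sizes[0], config.mean_depth, rng
        )
        rep_cohort[:, 0] = traj[:, 0]
        gen = 0
        for interval, n_int_gens in enumerate(config.generations_per_interval):
            regime = regime_table[rep][interval]
            for _ in range(n_int_gens):
                pop, va[gen] = _advance_generation(
                    pop, config, regime, selected, effects, positions, rng
                )
                gen += 1
                traj[:, gen] = pop.mean(axis=0)
            rep_counts[:, interval + 1], rep_sample[:, interval + 1] = _sample_pool(
                pop, config.pool_sizes[interval + 1], config.mean_depth, rng
            )
            rep_cohort[:, interval + 1] = traj[:, gen]

        counts[rep] = rep_counts
        trajectories[rep] = traj
        cohort_freq[rep] = rep_cohort
        sample_freq[rep] = rep_sample
        va_realized[rep] = va

    cohort_gens = tuple(
        int(g) for g in np.concatenate(
            [[0], np.cumsum(config.generations_per_interval)]
        )
    )
    truth = SimTruth(
        contigs=contigs,
        positions=positions,
        selected=shared_selected if config.shared_targets else selected,
        effects=shared_effects if config.shared_targets else effects,
        regimes=regime_table,
        freq_trajectories=trajectories,
        cohort_freq=cohort_freq,
        sample_freq=sample_freq,
        va_realized=va_realized,
        cohort_generations=cohort_gens,
    )
    contig_lengths = {
        f"chr{i + 1}": config.chromosome_length for i in range(config.n_chromosomes)
    }
    return SimResult(
        config=config,
        design=config.design(),
        truth=truth,
        counts=counts,
        contig_lengths=contig_lengths,
    )


def expected_noise_check(
    grid: Sequence[tuple[float, int, int]] = ((0.5, 50, 40), (0.2, 40, 60), (0.1, 68, 40)),
    n_loci: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo validation of the two-stage sampling-noise formula.

    For each (p, n, d): draw ``n_loci`` observed frequencies through the
    two-stage scheme (n diploids binomially from the population, d reads
    binomially from the 2n chromosomes) and compare the empirical variance of
    (observed − true) with :func:`tempocov.temporal_cov.sampling_noise_var`.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for p, n, d in grid:
        q = rng.binomial(2 * n, p, size=n_loci) / (2 * n)
        obs = rng.binomial(d, q) / d
        empirical = float(np.var(obs - p))
        expected = float(sampling_noise_var(p, NoiseModel(n=n, d=d)))
        rows.append(
            {
                "p": p,
                "n": n,
                "d": d,
                "empirical_var": empirical,
                "expected_var": expected,
                "relative_error": empirical / expected - 1.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fixture presets: the regimes exercised by the verification suite
# ---------------------------------------------------------------------------


def demo_config(seed: int, **overrides) -> SimConfig:
    """Miniature neutral design for demonstrations and smoke tests."""
    cfg = SimConfig(
        population_size=300, n_chromosomes=5, loci_per_chromosome=200, seed=seed
    )
    return replace(cfg, **overrides)


def neutral_config(seed: int, **overrides) -> SimConfig:
    """Pure drift at the study design's scale (N=10^4, 10^4 loci, 40x, n=50)."""
    return replace(SimConfig(seed=seed), **overrides)


def _selection_base(seed: int) -> SimConfig:
    # Desk-scale selection fixture: smaller population, LD from a finite
    # founder-haplotype pool (without LD, linked selection is undetectable
    # by construction: the signal scales as V_A / 2N), two regenerations per
    # interval.  The linked signal per neutral locus scales roughly as
    # (per-chromosome V_A / 2) / K per generation pair, so K and the
    # generation count are chosen to lift it above pooled-sequencing noise.
    return SimConfig(
        population_size=1000,
        n_chromosomes=10,
        loci_per_chromosome=500,
        founder_haplotypes=16,
        generations_per_interval=(2, 2, 2),
        n_selected_loci=50,
        fitness_variance=0.2,
        seed=seed,
    )


def sustained_config(seed: int, v_a: float = 0.2, **overrides) -> SimConfig:
    """Directional selection in the same direction through all intervals."""
    cfg = replace(
        _selection_base(seed),
        fitness_variance=v_a,
        regimes=("directional+", "directional+", "directional+"),
    )
    return replace(cfg, **overrides)


def reversal_config(seed: int, **overrides) -> SimConfig:
    """Selection reversing direction between the first two intervals.

    The planted effect is stronger than in the sustained preset because the
    reversal signature lives in a single matrix entry (no averaging over
    adjacent entries), so per-run sign recovery needs a larger V_A.
    """
    cfg = replace(
        _selection_base(seed),
        fitness_variance=0.6,
        regimes=("directional+", "directional-", "neutral"),
    )
    return replace(cfg, **overrides)


def parallel_config(seed: int, shared: bool = True, opposite: bool = False, **overrides) -> SimConfig:
    """Selection acting only in the first interval, parallel across replicates.

    With ``shared`` targets and the same direction this produces positive
    between-replicate covariance for the contemporary first period and
    near-zero covariance for non-overlapping periods.  ``opposite`` flips the
    direction in the second replicate.
    """
    regimes: tuple | dict = ("directional+", "neutral", "neutral")
    if opposite:
        labels = SimConfig().replicate_labels
        regimes = {
            lab: (("directional-", "neutral", "neutral") if i == 1 else ("directional+", "neutral", "neutral"))
            for i, lab in enumerate(labels)
        }
    cfg = replace(
        _selection_base(seed),
        fitness_variance=0.6,  # one severe episode, as in juvenile-stage selection
        regimes=regimes,
        shared_targets=shared,
    )
    return replace(cfg, **overrides)


def scan_config(seed: int, **overrides) -> SimConfig:
    """Sustained parallel selection confined to the first 500 kb of chr1.

    Founder haplotypes are drawn per 100-kb block, so linkage disequilibrium
    — and hence the linked-selection signal — is local to tiles, planting a
    recoverable outlier region among ~500 tiles.
    """
    cfg = SimConfig(
        population_size=1000,
        n_chromosomes=10,
        loci_per_chromosome=2000,
        chromosome_length=5_000_000,
        founder_haplotypes=16,
        founder_block=100_000,
        recomb_rate=2e-7,  # ~1 crossover per chromosome per meiosis
        generations_per_interval=(3, 3, 3),
        n_selected_loci=50,
        fitness_variance=1.5,
        pool_sizes=(68, 68, 68, 68),
        mean_depth=100.0,
        selected_region=("chr1", 0, 500_000),
        regimes=("directional+", "directional+", "directional+"),
        seed=seed,
    )
    return replace(cfg, **overrides)
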