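"""Pooled-sequencing diversity and differentiation.

Nucleotide diversity (Tajima's π) is estimated on non-overlapping windows
(10 kb by default) after subsampling every site to a uniform target coverage
(30 reads by default), which removes coverage heterogeneity between pools.
Per-SNP F_ST between two cohorts uses a Hudson-type π-based estimator with
pool-size/depth-corrected heterozygosities (a read-level Karlsson-style
variant is available, since tooling in this area offers both).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from tempocov.io_sync import SyncRecord
from tempocov.temporal_cov import _noise_factor


@dataclass(frozen=True)
class PiWindowConfig:
    """Windowed-π settings (window 10 kb, coverage 30, covered fraction 50%)."""

    window_size: int = 10_000
    target_coverage: int = 30
    min_covered_fraction: float = 0.5
    min_minor_count: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.min_covered_fraction <= 1:
            raise ValueError("min_covered_fraction must be in (0, 1]")


def subsample_coverage(
    record: SyncRecord, target: int, rng: np.random.Generator
) -> SyncRecord | None:
    """Downsample every pool to exactly ``target`` reads without replacement.

    The nucleotide counts of each pool are reduced by a multivariate
    hypergeometric draw; N/del columns are discarded.  Pools below ``target``
    make the whole site unusable for uniform-coverage π, so the site is
    dropped (returns ``None``).  Deterministic for a given generator state.
    """
    if target < 1:
        raise ValueError("target coverage must be >= 1")
    nuc = record.counts[:, :4]
    if (nuc.sum(axis=1) < target).any():
        return None
    new = np.zeros_like(record.counts)
    for i, pool in enumerate(nuc):
        new[i, :4] = rng.multivariate_hypergeometric(pool, target)
    return SyncRecord(
        contig=record.contig, pos=record.pos, ref_base=record.ref_base, counts=new
    )


def site_heterozygosity(counts4: np.ndarray, min_minor_count: int = 2) -> float:
    """Unbiased per-site heterozygosity at uniform read coverage m.

    For m reads with nucleotide counts c, the estimator is
    ``m/(m−1) · (1 − Σ (c/m)²)``, which is unbiased for the population
    heterozygosity of the read pool (reads are draws with replacement from
    the pooled chromosomes).  Sites whose minor-allele count is below
    ``min_minor_count`` are treated as monomorphic (the sequencing-error
    guard), which introduces a small downward bias at low coverage.
    """
    counts4 = np.asarray(counts4)
    m = counts4.sum()
    if m < 2:
        return 0.0
    nonzero = np.sort(counts4[counts4 > 0])[::-1]
    if len(nonzero) < 2 or nonzero[1:].sum() < min_minor_count:
        return 0.0
    freqs = counts4 / m
    return float(m / (m - 1) * (1.0 - np.square(freqs).sum()))


def window_pi(
    records: Iterable[SyncRecord],
    contig_lengths: Mapping[str, int],
    pool: int,
    config: PiWindowConfig | None = None,
) -> pd.DataFrame:
    """Tajima's π per non-overlapping window for one pool.

    ``records`` must already be subsampled to uniform coverage
    ``config.target_coverage`` (a hard error otherwise).  π of a window is
    the summed per-site heterozygosity divided by the number of covered
    bases (``window_size × covered_fraction``), so partially covered windows
    stay comparable; windows under ``min_covered_fraction`` are missing.
    """
    config = config or PiWindowConfig()
    het_sum: dict[tuple[str, int], float] = {}
    n_covered: dict[tuple[str, int], int] = {}
    n_poly: dict[tuple[str, int], int] = {}
    for rec in records:
        counts4 = rec.counts[pool, :4]
        m = counts4.sum()
        if m != config.target_coverage:
            raise ValueError(
                f"site {rec.contig}:{rec.pos} pool {pool} has coverage {m}, "
                f"expected uniform {config.target_coverage}; subsample first"
            )
        key = (rec.contig, (rec.pos - 1) // config.window_size * config.window_size)
        h = site_heterozygosity(counts4, config.min_minor_count)
        het_sum[key] = het_sum.get(key, 0.0) + h
        n_covered[key] = n_covered.get(key, 0) + 1
        if h > 0:
            n_poly[key] = n_poly.get(key, 0) + 1
    rows = []
    for contig, length in contig_lengths.items():
        for start in range(0, length, config.window_size):
            end = min(start + config.window_size, length)
            key = (contig, start)
            covered = n_covered.get(key, 0)
            frac = covered / (end - start)
            pi = (
                het_sum.get(key, 0.0) / covered
                if covered and frac >= config.min_covered_fraction
                else np.nan
            )
            rows.append(
                {
                    "contig": contig,
                    "start": start,
                    "end": end,
                    "covered_fraction": frac,
                    "n_sites": n_poly.get(key, 0),
                    "pi": pi,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FstResult:
    fst: float  # clipped to >= 0; NaN when undefined
    unclipped: float


def snp_fst(
    counts_a: Sequence[int],
    counts_b: Sequence[int],
    pool_size_a: int | None = None,
    pool_size_b: int | None = None,
    flavor: str = "hudson",
) -> FstResult:
    """Per-SNP F_ST between two pools from biallelic read counts.

    ``counts_a``/``counts_b`` are (ref, alt) read counts.  The default
    ``hudson`` flavor is π-based: F_ST = (π_total − π_within) / π_total with
    within-pool heterozygosities corrected for the two-stage pool sampling
    (n diploids, d reads), so E[F_ST] ≈ 0 for identical populations.  The
    ``karlsson`` flavor is the read-level estimator
    ``[(p₁−p₂)² − h₁/d₁ − h₂/d₂] / [(p₁−p₂)² − h₁/d₁ − h₂/d₂ + h₁ + h₂]``
    with hᵢ the unbiased read-sample heterozygosity, ignoring pool size.
    """
    ra, aa = (int(c) for c in counts_a)
    rb, ab = (int(c) for c in counts_b)
    da, db = ra + aa, rb + ab
    if da < 2 or db < 2:
        return FstResult(np.nan, np.nan)
    p1, p2 = aa / da, ab / db
    h1 = 2 * p1 * (1 - p1)
    h2 = 2 * p2 * (1 - p2)
    if flavor == "hudson":
        if pool_size_a and pool_size_b:
            h1 /= 1.0 - _noise_factor(pool_size_a, da)
            h2 /= 1.0 - _noise_factor(pool_size_b, db)
        else:  # read-level correction only
            h1 *= da / (da - 1)
            h2 *= db / (db - 1)
        pi_within = (h1 + h2) / 2
        # between-pool heterozygosity; unbiased because the pools are independent
        pi_between = p1 * (1 - p2) + p2 * (1 - p1)
        pi_total = (pi_within + pi_between) / 2
        if pi_total <= 0:
            return FstResult(np.nan, np.nan)
        unclipped = (pi_total - pi_within) / pi_total
    elif flavor == "karlsson":
        h1 *= da / (2 * (da - 1))  # sample heterozygosity of the reads
        h2 *= db / (2 * (db - 1))
        num = (p1 - p2) ** 2 - h1 / da - h2 / db
        den = num + h1 + h2
        if den <= 0:
            return FstResult(np.nan, np.nan)
        unclipped = num / den
    else:
        raise ValueError(f"unknown F_ST flavor {flavor!r}")
    return FstResult(fst=float(max(unclipped, 0.0)), unclipped=float(unclipped))


def pairwise_fst_table(
    records: Sequence[SyncRecord],
    pairs: Sequence[tuple[int, int]],
    pair_labels: Sequence[str] | None = None,
    pool_sizes: Sequence[int] | None = None,
    flavor: str = "hudson",
) -> pd.DataFrame:
    """Per-SNP F_ST for the given pool-index pairs (long format).

    At each site the two alleles are the nucleotides with the highest counts
    summed over the two pools of the pair.
    """
    pair_labels = pair_labels or [f"{i}-{j}" for i, j in pairs]
    rows = []
    for rec in records:
        for (i, j), label in zip(pairs, pair_labels):
            pooled = rec.counts[i, :4] + rec.counts[j, :4]
            order = np.argsort(pooled)
            ref_i, alt_i = order[3], order[2]
            res = snp_fst(
                (rec.counts[i, ref_i], rec.counts[i, alt_i]),
                (rec.counts[j, ref_i], rec.counts[j, alt_i]),
                pool_sizes[i] if pool_sizes else None,
                pool_sizes[j] if pool_sizes else None,
                flavor=flavor,
            )
            rows.append(
                {
                    "contig": rec.contig,
                    "pos": rec.pos,
                    "pair": label,
                    "fst": res.fst,
                    "fst_unclipped": res.unclipped,
                }
            )
    return pd.DataFrame(rows)
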