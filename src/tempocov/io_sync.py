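"""Popoolation2 "sync" IO, site/contig filters and frequency panels.

A sync file is tab-separated with three fixed columns (contig, 1-based
position, reference base) followed by one ``A:T:C:G:N:del`` count vector per
pool.  Pools are mapped to (replicate, time point) cohorts by a
:class:`CohortDesign`.  :func:`call_biallelic` applies the count-level site
filters (minimum coverage, per-pool maximum-coverage percentile, minimum minor
count, minimum MAF, depth at least the number of sampled alleles) and returns
one :class:`FrequencyPanel` per replicate — the loci × time-points frequency
and depth matrices every downstream estimator consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

NUCLEOTIDES = "ATCG"
#: column order of a sync count vector
SYNC_ALLELES = ("A", "T", "C", "G", "N", "del")


class SyncFormatError(ValueError):
    """Malformed sync input (wrong column count, non-integer counts...)."""


@dataclass(frozen=True)
class SyncRecord:
    """One genomic site: per-pool ``A:T:C:G:N:del`` counts.

    ``counts`` has shape ``(n_pools, 6)``; coverage of a pool is the sum of
    its first four entries.
    """

    contig: str
    pos: int  # 1-based
    ref_base: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[1] != 6:
            raise ValueError("counts must have shape (n_pools, 6)")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if (counts < 0).any():
            raise ValueError("negative allele count")
        object.__setattr__(self, "counts", counts)

    @property
    def coverage(self) -> np.ndarray:
        """Per-pool read coverage (A+T+C+G)."""
        return self.counts[:, :4].sum(axis=1)


@dataclass(frozen=True)
class CohortDesign:
    """Maps sync columns onto the (replicate forest, birth-year cohort) grid.

    Parameters
    ----------
    replicates : ordered replicate labels, e.g. ``("B", "R", "T")``.
    time_points : ordered birth years, strictly increasing, e.g.
        ``(1680, 1850, 1960, 2008)``.
    pool_sizes : diploid individuals per (replicate, time point).
    column_map : for each sync count column in file order, the
        (replicate, time point) it holds.  Defaults to replicate-major order.
    """

    replicates: tuple[str, ...]
    time_points: tuple[int, ...]
    pool_sizes: Mapping[tuple[str, int], int]
    column_map: tuple[tuple[str, int], ...] = field(default=())

    def __post_init__(self) -> None:
        if list(self.time_points) != sorted(set(self.time_points)):
            raise ValueError("time_points must be strictly increasing")
        if not self.column_map:
            object.__setattr__(
                self,
                "column_map",
                tuple((r, t) for r in self.replicates for t in self.time_points),
            )
        cells = {(r, t) for r in self.replicates for t in self.time_points}
        if set(self.column_map) != cells or len(self.column_map) != len(cells):
            raise ValueError("column_map must be a bijection onto replicate x time cells")
        for cell in cells:
            if self.pool_sizes[cell] < 1:
                raise ValueError(f"pool size must be >= 1 for {cell}")

    @property
    def n_pools(self) -> int:
        return len(self.column_map)

    def columns_for(self, replicate: str) -> list[int]:
        """Sync column indices of one replicate, ordered by time point."""
        if replicate not in self.replicates:
            raise KeyError(f"unknown replicate {replicate!r}")
        lookup = {cell: i for i, cell in enumerate(self.column_map)}
        return [lookup[(replicate, t)] for t in self.time_points]

    def first_time_columns(self) -> list[int]:
        lookup = {cell: i for i, cell in enumerate(self.column_map)}
        t0 = self.time_points[0]
        return [lookup[(r, t0)] for r in self.replicates]

    def pool_size_vector(self, replicate: str) -> np.ndarray:
        return np.array([self.pool_sizes[(replicate, t)] for t in self.time_points])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortDesign":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        pool_sizes = {
            (str(r), int(t)): int(n)
            for r, by_time in raw["pool_sizes"].items()
            for t, n in by_time.items()
        }
        column_map = tuple(
            (str(r), int(t)) for r, t in raw.get("column_map", [])
        )
        return cls(
            replicates=tuple(str(r) for r in raw["replicates"]),
            time_points=tuple(int(t) for t in raw["time_points"]),
            pool_sizes=pool_sizes,
            column_map=column_map,
        )


@dataclass(frozen=True)
class SiteFilterConfig:
    """Count-level SNP filters.

    Defaults are the study settings for real pool-seq data: minimum minor
    allele count 2, minimum coverage 40x in every pool, per-pool maximum
    coverage at the 90th percentile, MAF >= 0.02 pooled across a replicate's
    cohorts, depth at least the number of sampled alleles (2n), and contigs of
    non-N length >= 200 kb.
    """

    min_minor_count: int = 2
    min_coverage: int = 40
    max_coverage_quantile: float = 0.90
    min_maf: float = 0.02
    min_depth_vs_alleles: bool = True
    min_contig_length: int = 200_000

    def __post_init__(self) -> None:
        if not 0 <= self.min_maf < 0.5:
            raise ValueError("min_maf must be in [0, 0.5)")
        if not 0 < self.max_coverage_quantile <= 1:
            raise ValueError("max_coverage_quantile must be in (0, 1]")

    @classmethod
    def for_synthetic(cls) -> "SiteFilterConfig":
        """Preset for simulator output at ~40x mean depth.

        At a Poisson(40) depth the 40x floor would discard half of all sites
        from depth jitter alone and the 2n-alleles rule would discard every
        site for pools of >= 20 diploids, so the synthetic preset relaxes the
        coverage floor to 25 and turns the allele-count rule off.
        """
        return cls(min_coverage=25, min_depth_vs_alleles=False)


@dataclass
class FrequencyPanel:
    """Filtered biallelic loci for one replicate across all time points.

    ``freq[l, t]`` is the alt-allele frequency of locus ``l`` in the cohort of
    ``time_points[t]``; ``depth`` the read coverage behind it; ``pool_size``
    the diploid count of each cohort's pool.
    """

    replicate: str
    time_points: tuple[int, ...]
    contigs: np.ndarray  # (L,) str
    positions: np.ndarray  # (L,) int, 1-based
    ref_alleles: np.ndarray  # (L,) str
    alt_alleles: np.ndarray  # (L,) str
    freq: np.ndarray  # (L, T) float
    depth: np.ndarray  # (L, T) int
    pool_size: np.ndarray  # (T,) int

    def __post_init__(self) -> None:
        if self.freq.shape != self.depth.shape:
            raise ValueError("freq and depth shapes differ")
        if self.freq.size and (np.nanmin(self.freq) < 0 or np.nanmax(self.freq) > 1):
            raise ValueError("frequencies must lie in [0, 1]")

    @property
    def n_loci(self) -> int:
        return self.freq.shape[0]

    @property
    def n_time_points(self) -> int:
        return len(self.time_points)

    def locus_keys(self) -> list[tuple[str, int]]:
        return list(zip(self.contigs.tolist(), self.positions.tolist()))

    def subset(self, index: np.ndarray) -> "FrequencyPanel":
        return FrequencyPanel(
            replicate=self.replicate,
            time_points=self.time_points,
            contigs=self.contigs[index],
            positions=self.positions[index],
            ref_alleles=self.ref_alleles[index],
            alt_alleles=self.alt_alleles[index],
            freq=self.freq[index],
            depth=self.depth[index],
            pool_size=self.pool_size,
        )


def read_sync(
    source: str | Path | IO[str], design: CohortDesign
) -> Iterator[SyncRecord]:
    """Stream :class:`SyncRecord` objects from a sync file.

    Raises :class:`SyncFormatError` (naming the offending line) when the pool
    column count disagrees with ``design`` or a count field is malformed.
    """
    own = isinstance(source, (str, Path))
    fh: IO[str] = open(source) if own else source  # type: ignore[arg-type]
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3 + design.n_pools:
                raise SyncFormatError(
                    f"line {lineno}: expected {3 + design.n_pools} columns "
                    f"({design.n_pools} pools), found {len(fields)}"
                )
            contig, pos_s, ref = fields[:3]
            try:
                pos = int(pos_s)
                counts = np.array(
                    [f.split(":") for f in fields[3:]], dtype=np.int64
                )
            except ValueError as exc:
                raise SyncFormatError(f"line {lineno}: {exc}") from exc
            if counts.shape[1] != 6:
                raise SyncFormatError(
                    f"line {lineno}: count field must have 6 ':'-separated entries"
                )
            yield SyncRecord(contig=contig, pos=pos, ref_base=ref, counts=counts)
    finally:
        if own:
            fh.close()


def write_sync(records: Iterable[SyncRecord], sink: str | Path | IO[str]) -> None:
    """Write records as a sync file; inverse of :func:`read_sync`."""
    own = isinstance(sink, (str, Path))
    fh: IO[str] = open(sink, "w") if own else sink  # type: ignore[arg-type]
    try:
        for rec in records:
            pools = "\t".join(
                ":".join(str(c) for c in pool) for pool in rec.counts
            )
            fh.write(f"{rec.contig}\t{rec.pos}\t{rec.ref_base}\t{pools}\n")
    finally:
        if own:
            fh.close()


def filter_contigs(
    records: Iterable[SyncRecord],
    contig_lengths: Mapping[str, int],
    min_contig_length: int = 200_000,
) -> Iterator[SyncRecord]:
    """Drop records on contigs whose non-N length is below the threshold.

    ``contig_lengths`` must cover every contig seen; an unknown contig is a
    hard error (a silent pass-through would defeat the length filter).
    """
    for rec in records:
        try:
            length = contig_lengths[rec.contig]
        except KeyError:
            raise KeyError(
                f"contig {rec.contig!r} absent from the contig length table"
            ) from None
        if length >= min_contig_length:
            yield rec


def pool_coverage_cutoffs(
    records: Sequence[SyncRecord], quantile: float = 0.90
) -> np.ndarray:
    """Per-pool maximum-coverage cutoff: the given coverage quantile.

    This is the percentile reading of Popoolation2's ``--max-coverage N%``
    idiom: per pool, sites in the top ``1 - quantile`` of the coverage
    distribution are discarded downstream.
    """
    if not records:
        raise ValueError("cannot compute coverage quantiles from no records")
    cov = np.stack([rec.coverage for rec in records])  # (sites, pools)
    return np.quantile(cov, quantile, axis=0)


def call_biallelic(
    records: Sequence[SyncRecord],
    design: CohortDesign,
    filters: SiteFilterConfig | None = None,
    coverage_cutoffs: np.ndarray | None = None,
) -> dict[str, FrequencyPanel]:
    """Apply site filters and build one :class:`FrequencyPanel` per replicate.

    Sites are retained independently per replicate.  A site survives for a
    replicate when, across that replicate's pools: exactly two nucleotides
    have nonzero counts; every pool's coverage is within
    ``[min_coverage, per-pool cutoff]`` and, if ``min_depth_vs_alleles`` is
    on, at least ``2 * pool_size``; the pooled minor-allele count is at least
    ``min_minor_count``; and the pooled minor-allele frequency is at least
    ``min_maf``.

    The alt allele is the minor allele of the first time point pooled across
    *all* replicates, so the ref/alt polarity of a locus is identical in every
    panel (downstream covariances are polarity-invariant; the convention only
    fixes signs of individual frequency changes).
    """
    filters = filters or SiteFilterConfig()
    records = list(records)
    if not records:
        return {
            rep: _empty_panel(rep, design) for rep in design.replicates
        }
    counts = np.stack([rec.counts for rec in records])  # (S, P, 6)
    nuc = counts[:, :, :4]
    coverage = nuc.sum(axis=2)  # (S, P)
    if coverage_cutoffs is None:
        coverage_cutoffs = np.quantile(
            coverage, filters.max_coverage_quantile, axis=0
        )
    contigs = np.array([rec.contig for rec in records])
    positions = np.array([rec.pos for rec in records])
    refs = np.array([rec.ref_base for rec in records])

    # polarity reference: counts at the first time point pooled over replicates
    first_cols = design.first_time_columns()
    first_nuc = nuc[:, first_cols, :].sum(axis=1)  # (S, 4)

    panels: dict[str, FrequencyPanel] = {}
    for rep in design.replicates:
        cols = design.columns_for(rep)
        rep_nuc = nuc[:, cols, :]  # (S, T, 4)
        rep_cov = coverage[:, cols]  # (S, T)
        pooled = rep_nuc.sum(axis=1)  # (S, 4)
        n_alleles = (pooled > 0).sum(axis=1)
        keep = n_alleles == 2
        n0 = len(records)
        logger.info("%s: %d/%d sites biallelic", rep, keep.sum(), n0)

        keep &= (rep_cov >= filters.min_coverage).all(axis=1)
        keep &= (rep_cov <= coverage_cutoffs[cols]).all(axis=1)
        logger.info("%s: %d sites after coverage bounds", rep, keep.sum())
        if filters.min_depth_vs_alleles:
            pool_n = design.pool_size_vector(rep)
            keep &= (rep_cov >= 2 * pool_n).all(axis=1)
            logger.info("%s: %d sites after depth >= 2n rule", rep, keep.sum())

        # allele pair: the two highest pooled counts; computed for all sites,
        # only meaningful where biallelic
        order = np.argsort(pooled, axis=1)
        major_i, second_i = order[:, 3], order[:, 2]
        pair_counts = np.take_along_axis(
            pooled, np.stack([major_i, second_i], axis=1), axis=1
        )
        minor_count = pair_counts.min(axis=1)
        pair_total = pair_counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            maf = np.where(pair_total > 0, minor_count / pair_total, 0.0)
        keep &= minor_count >= filters.min_minor_count
        keep &= maf >= filters.min_maf
        logger.info(
            "%s: %d sites after minor count >= %d and MAF >= %g",
            rep, keep.sum(), filters.min_minor_count, filters.min_maf,
        )

        idx = np.flatnonzero(keep)
        if idx.size == 0:
            logger.warning("%s: no site passed the filters", rep)
            panels[rep] = _empty_panel(rep, design)
            continue

        a1 = major_i[idx]
        a2 = second_i[idx]
        # alt = pooled minor allele at the first time point (all replicates);
        # deterministic tie-break toward the higher base index
        c1 = first_nuc[idx, a1]
        c2 = first_nuc[idx, a2]
        alt_is_a2 = (c2 < c1) | ((c2 == c1) & (a2 > a1))
        alt_i = np.where(alt_is_a2, a2, a1)
        ref_i = np.where(alt_is_a2, a1, a2)

        alt_counts = np.take_along_axis(
            rep_nuc[idx], alt_i[:, None, None], axis=2
        )[:, :, 0]  # (L, T)
        depth = rep_cov[idx]
        freq = alt_counts / depth
        panels[rep] = FrequencyPanel(
            replicate=rep,
            time_points=design.time_points,
            contigs=contigs[idx],
            positions=positions[idx],
            ref_alleles=np.array([NUCLEOTIDES[i] for i in ref_i]),
            alt_alleles=np.array([NUCLEOTIDES[i] for i in alt_i]),
            freq=freq,
            depth=depth,
            pool_size=design.pool_size_vector(rep),
        )
    return panels


def _empty_panel(rep: str, design: CohortDesign) -> FrequencyPanel:
    T = len(design.time_points)
    return FrequencyPanel(
        replicate=rep,
        time_points=design.time_points,
        contigs=np.array([], dtype=str),
        positions=np.array([], dtype=int),
        ref_alleles=np.array([], dtype=str),
        alt_alleles=np.array([], dtype=str),
        freq=np.zeros((0, T)),
        depth=np.zeros((0, T), dtype=int),
        pool_size=design.pool_size_vector(rep),
    )
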