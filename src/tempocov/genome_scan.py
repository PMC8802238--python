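"""Tile-level covariance scans and outlier calling.

The genome is partitioned into fixed-width tiles (100 kb by default); the
within-replicate covariance estimator is applied to each tile's loci with the
same corrections and standardization as genome-wide, and a tile is called an
outlier when its covariance entry of interest exceeds a threshold (0.01) in
*every* replicate — the rule used to pick regions for downstream annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from tempocov.io_sync import FrequencyPanel
from tempocov.temporal_cov import matrices_from_aggregates, per_locus_aggregates

WHICH_INDEX = {"raw": 0, "corrected": 1, "standardized": 2}


@dataclass(frozen=True)
class Tile:
    """0-based half-open genomic window."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad tile bounds [{self.start}, {self.end})")

    @property
    def key(self) -> tuple[str, int]:
        return (self.contig, self.start)


def tile_genome(
    contig_lengths: Mapping[str, int], tile_size: int = 100_000
) -> list[Tile]:
    """Partition each contig into ``ceil(len / tile_size)`` tiles, last truncated."""
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    tiles = []
    for contig, length in contig_lengths.items():
        if length < 1:
            raise ValueError(f"contig {contig!r} has length {length}")
        for start in range(0, length, tile_size):
            tiles.append(Tile(contig, start, min(start + tile_size, length)))
    return tiles


def assign_tiles(panel: FrequencyPanel, tiles: Sequence[Tile]) -> np.ndarray:
    """Tile index per locus (−1 where a locus falls in no tile).

    Sync positions are 1-based; tiles are 0-based half-open, so position p
    lands in the tile containing p − 1.
    """
    size = tiles[0].end - tiles[0].start if tiles else 0
    lookup = {t.key: i for i, t in enumerate(tiles)}
    out = np.full(panel.n_loci, -1, dtype=int)
    for i, (contig, pos) in enumerate(panel.locus_keys()):
        start = (pos - 1) // size * size if size else 0
        idx = lookup.get((contig, start))
        if idx is not None and tiles[idx].start <= pos - 1 < tiles[idx].end:
            out[i] = idx
    return out


def per_tile_cov(
    panel: FrequencyPanel,
    tiles: Sequence[Tile],
    entry: tuple[int, int] = (0, 1),
    *,
    which: str = "standardized",
    min_snps_per_tile: int = 10,
    centered: bool = True,
) -> pd.DataFrame:
    """One covariance-matrix entry per tile.

    ``entry`` indexes the (T−1)×(T−1) matrix by interval, e.g. ``(0, 1)`` is
    the covariance between the two earliest intervals.  Tiles with fewer than
    ``min_snps_per_tile`` loci are reported with a missing value, not zero.
    """
    which_i = WHICH_INDEX[which]
    T = panel.n_time_points
    per_locus = per_locus_aggregates(panel)
    tile_of = assign_tiles(panel, tiles)
    values = np.full(len(tiles), np.nan)
    n_snps = np.zeros(len(tiles), dtype=int)
    agg = np.zeros((len(tiles), per_locus.shape[1]))
    inside = tile_of >= 0
    np.add.at(agg, tile_of[inside], per_locus[inside])
    np.add.at(n_snps, tile_of[inside], 1)
    for i in range(len(tiles)):
        if n_snps[i] >= max(min_snps_per_tile, 2):
            values[i] = matrices_from_aggregates(agg[i], T, centered=centered)[
                which_i
            ][entry]
    return pd.DataFrame(
        {
            "contig": [t.contig for t in tiles],
            "start": [t.start for t in tiles],
            "end": [t.end for t in tiles],
            "n_snps": n_snps,
            "value": values,
        }
    )


def call_outliers(
    scans: Mapping[str, pd.DataFrame], threshold: float = 0.01
) -> pd.DataFrame:
    """Flag tiles whose entry exceeds ``threshold`` in every replicate.

    A tile missing (too few SNPs) in any replicate is never an outlier.
    All scans must share the same tiling.
    """
    reps = list(scans)
    if not reps:
        raise ValueError("no scans given")
    base = scans[reps[0]][["contig", "start", "end"]]
    result = base.copy()
    for rep in reps:
        scan = scans[rep]
        if not scan[["contig", "start", "end"]].equals(base):
            raise ValueError(f"tiling of replicate {rep!r} differs")
        result[f"value_{rep}"] = scan["value"].to_numpy()
    values = result[[f"value_{r}" for r in reps]].to_numpy()
    n_valid = (~np.isnan(values)).sum(axis=1)
    result["mean_value"] = np.where(
        n_valid > 0, np.nansum(values, axis=1) / np.maximum(n_valid, 1), np.nan
    )
    result["outlier"] = (~np.isnan(values)).all(axis=1) & (values > threshold).all(
        axis=1
    )
    return result


def tile_fst_profile(
    fst: pd.DataFrame, tiles: Sequence[Tile]
) -> pd.DataFrame:
    """Mean per-SNP F_ST within each tile for each cohort pair.

    ``fst`` must have columns contig, pos (1-based), pair, fst — the per-SNP
    table from :mod:`tempocov.pool_stats`.  Tiles without SNPs are missing.
    """
    size = tiles[0].end - tiles[0].start if tiles else 0
    lookup = {t.key: i for i, t in enumerate(tiles)}
    start = (fst["pos"].to_numpy() - 1) // size * size if size else 0
    tile_idx = np.array(
        [
            lookup.get((c, s), -1)
            for c, s in zip(fst["contig"].to_numpy(), start)
        ]
    )
    frame = fst.assign(_tile=tile_idx).query("_tile >= 0")
    mean = (
        frame.groupby(["_tile", "pair"])["fst"].mean().unstack("pair")
    )
    out = pd.DataFrame(
        {
            "contig": [t.contig for t in tiles],
            "start": [t.start for t in tiles],
            "end": [t.end for t in tiles],
        }
    )
    return out.join(mean.reindex(range(len(tiles))))


def scan_to_bed(scan: pd.DataFrame, path, outliers_only: bool = False) -> None:
    """Write a tile scan as BED (0-based half-open) with value columns."""
    frame = scan[scan["outlier"]] if outliers_only and "outlier" in scan else scan
    cols = [c for c in frame.columns if c not in ("contig", "start", "end")]
    frame = frame[["contig", "start", "end", *cols]]
    frame.to_csv(path, sep="\t", header=False, index=False, na_rep="NA")
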