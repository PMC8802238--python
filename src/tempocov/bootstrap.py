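"""Block bootstrap over genomic tiles.

Genome-wide covariance statistics are means over loci that are locally
correlated through linkage disequilibrium; resampling individual SNPs would
understate their uncertainty.  The bootstrap here therefore resamples
*blocks* — by default the same 100-kb tiles used by the genome scan — with
replacement, recomputing the statistic from per-block sufficient aggregates
(sums of cross-products, counts, heterozygosity sums) on each iterate, and
returns percentile confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap settings: 5000 iterations and 95% intervals by default."""

    n_iterations: int = 5000
    alpha: float = 0.05
    block_unit: int = 100_000  # bp; tiling used to form blocks
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class BootstrapResult:
    """Point estimate (from all blocks) and percentile interval bounds.

    ``point``, ``low`` and ``high`` have whatever shape the statistic
    returns (scalar or ndarray).
    """

    point: np.ndarray
    low: np.ndarray
    high: np.ndarray
    n_blocks: int


def block_bootstrap(
    stat_fn: Callable[[Sequence], float | np.ndarray],
    blocks: Sequence,
    config: BootstrapConfig,
) -> BootstrapResult:
    """Percentile block bootstrap of ``stat_fn`` over ``blocks``.

    ``stat_fn`` must compute the statistic from any multiset of blocks (each
    block carrying per-block sufficient aggregates).  ``blocks`` may be a
    sequence of arbitrary objects or an ndarray whose first axis indexes
    blocks (the latter is resampled by fancy indexing and is much faster).
    Deterministic for a fixed ``config.seed``.
    """
    n = len(blocks)
    if n < 2:
        raise ValueError(f"block bootstrap needs >= 2 blocks, got {n}")
    rng = np.random.default_rng(config.seed)
    point = np.asarray(stat_fn(blocks), dtype=float)
    is_array = isinstance(blocks, np.ndarray)
    stats = np.empty((config.n_iterations,) + point.shape)
    for i in range(config.n_iterations):
        idx = rng.integers(0, n, size=n)
        resampled = blocks[idx] if is_array else [blocks[j] for j in idx]
        stats[i] = stat_fn(resampled)
    lo_q, hi_q = 100 * config.alpha / 2, 100 * (1 - config.alpha / 2)
    low = np.nanpercentile(stats, lo_q, axis=0)
    high = np.nanpercentile(stats, hi_q, axis=0)
    return BootstrapResult(point=point, low=low, high=high, n_blocks=n)
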