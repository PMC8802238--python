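"""Temporal covariances of allele-frequency change within one replicate.

Given a loci × time-points frequency panel, the estimators here compute the
(T−1)×(T−1) matrix of covariances between interval frequency changes
Δ_s = p(t_{s+1}) − p(t_s), averaged over loci, with two pool-seq bias
corrections:

* **diagonal** — the observed variance of Δ_s includes the sampling variance
  of both endpoint frequency estimates (n diploids pooled, d reads); the
  expected noise variance at both endpoints is subtracted;
* **adjacent off-diagonal** — Δ_s and Δ_{s+1} share the observed frequency at
  the joint time point, whose sampling error enters the two changes with
  opposite signs and biases the raw covariance downward by −Var(ε_shared);
  the expected shared-point noise variance is added back.

Non-adjacent entries share no time point and receive no correction.  Entries
are standardized by the loci-mean heterozygosity p(1−p) at the earlier of the
two intervals' start points.  The variance of the total change over a span
decomposes exactly into interval variances plus twice the interval
covariances, and the G statistic is the covariance share of that total — the
fraction of frequency-change variance attributable to linked selection.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np

from tempocov.bootstrap import BootstrapConfig, BootstrapResult, block_bootstrap
from tempocov.io_sync import FrequencyPanel


@dataclass(frozen=True)
class DeltaPanel:
    """Interval frequency changes: ``deltas[l, s] = freq[l, s+1] - freq[l, s]``."""

    deltas: np.ndarray  # (L, T-1)
    intervals: tuple[tuple[int, int], ...]  # adjacent (start_year, end_year)

    def __post_init__(self) -> None:
        if self.deltas.ndim != 2 or self.deltas.shape[1] != len(self.intervals):
            raise ValueError("deltas must be (loci, n_intervals)")


@dataclass(frozen=True)
class NoiseModel:
    """Two-stage pool-seq sampling: ``n`` diploids, then ``d`` reads."""

    n: int
    d: float

    def __post_init__(self) -> None:
        if self.n < 1 or self.d < 1:
            raise ValueError("pool size and depth must be >= 1")


@dataclass
class CovarianceMatrix:
    """Loci-averaged interval-change covariances for one replicate.

    ``raw`` is the uncorrected matrix, ``corrected`` the noise-corrected one,
    ``standardized`` the corrected matrix divided by ``standardizer`` (mean
    heterozygosity at each entry's reference time).  ``ci_low``/``ci_high``
    hold 95% block-bootstrap bounds for the standardized entries when a
    bootstrap was run.
    """

    replicate: str
    intervals: tuple[tuple[int, int], ...]
    raw: np.ndarray
    corrected: np.ndarray
    standardized: np.ndarray
    standardizer: np.ndarray
    n_loci: int
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None

    @property
    def n_intervals(self) -> int:
        return len(self.intervals)

    def total_variance(self, upto: int | None = None, which: str = "raw") -> float:
        return total_variance(getattr(self, which), upto or self.n_intervals)

    def to_frame(self):
        """Long-format report: one row per matrix entry."""
        import pandas as pd

        rows = []
        for s in range(self.n_intervals):
            for t in range(s, self.n_intervals):
                rows.append(
                    {
                        "replicate": self.replicate,
                        "interval_a": f"{self.intervals[s][0]}-{self.intervals[s][1]}",
                        "interval_b": f"{self.intervals[t][0]}-{self.intervals[t][1]}",
                        "raw": self.raw[s, t],
                        "corrected": self.corrected[s, t],
                        "standardized": self.standardized[s, t],
                        "ci_low": None if self.ci_low is None else self.ci_low[s, t],
                        "ci_high": None if self.ci_high is None else self.ci_high[s, t],
                        "n_loci": self.n_loci,
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class GResult:
    """The G statistic: covariance share of the total change variance."""

    g: float
    numerator: float  # 2 x sum of off-diagonal covariances
    denominator: float  # total variance of the span
    upto: int
    ci_low: float | None = None
    ci_high: float | None = None


def interval_deltas(panel: FrequencyPanel) -> DeltaPanel:
    """Frequency changes over adjacent time intervals."""
    if panel.n_time_points < 2:
        raise ValueError("need at least two time points to form an interval")
    deltas = np.diff(panel.freq, axis=1)
    intervals = tuple(
        (panel.time_points[i], panel.time_points[i + 1])
        for i in range(panel.n_time_points - 1)
    )
    return DeltaPanel(deltas=deltas, intervals=intervals)


def sampling_noise_var(p, model: NoiseModel):
    """Expected sampling variance of an observed pooled frequency.

    ``n`` diploids are drawn from the population and ``d`` reads from their
    2n chromosomes, so Var(p̂ | p) = p(1−p)·[1/(2n) + (1 − 1/(2n))/d].
    """
    p = np.asarray(p, dtype=float)
    a = _noise_factor(model.n, model.d)
    return p * (1.0 - p) * a


def _noise_factor(n, d):
    """a = 1/(2n) + (1 − 1/(2n))/d; note 1 − a = (1 − 1/(2n))(1 − 1/d)."""
    n = np.asarray(n, dtype=float)
    d = np.asarray(d, dtype=float)
    return 1.0 / (2 * n) + (1.0 - 1.0 / (2 * n)) / d


# ---------------------------------------------------------------------------
# per-locus sufficient aggregates
#
# Every covariance statistic here is a smooth function of block sums of
# per-locus quantities, so block-bootstrap resampling recombines these
# aggregates instead of raw loci.  Flat layout per locus / per block:
#   [count (1), sum Δ (T-1), sum ΔΔᵀ ((T-1)²), sum noise_hat (T),
#    sum het | non-fixed (T), count non-fixed (T)]
# ---------------------------------------------------------------------------


def per_locus_aggregates(panel: FrequencyPanel) -> np.ndarray:
    """Per-locus contributions to the covariance sufficient statistics, (L, K)."""
    T = panel.n_time_points
    deltas = np.diff(panel.freq, axis=1)  # (L, T-1)
    het = panel.freq * (1.0 - panel.freq)  # (L, T)
    a = _noise_factor(panel.pool_size[None, :], panel.depth)
    # unbiased estimate of p(1-p) from the observed frequency, then its
    # expected sampling variance; undefined at depth 1 where 1 - a = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        noise_hat = np.where(a < 1.0, het / (1.0 - a) * a, np.nan)
    nonfixed = (panel.freq > 0) & (panel.freq < 1)
    cross = deltas[:, :, None] * deltas[:, None, :]  # (L, T-1, T-1)
    L = panel.n_loci
    return np.concatenate(
        [
            np.ones((L, 1)),
            deltas,
            cross.reshape(L, (T - 1) ** 2),
            noise_hat,
            np.where(nonfixed, het, 0.0),
            nonfixed.astype(float),
        ],
        axis=1,
    )


def matrices_from_aggregates(agg_sum: np.ndarray, n_time_points: int, centered: bool = True):
    """Build (raw, corrected, standardized, standardizer) from summed aggregates."""
    T = n_time_points
    k = T - 1
    pos = 0
    n = agg_sum[pos]; pos += 1
    sd = agg_sum[pos : pos + k]; pos += k
    sc = agg_sum[pos : pos + k * k].reshape(k, k); pos += k * k
    sn = agg_sum[pos : pos + T]; pos += T
    sh = agg_sum[pos : pos + T]; pos += T
    nh = agg_sum[pos : pos + T]

    raw = sc / n
    if centered:
        mean_delta = sd / n
        raw = raw - np.outer(mean_delta, mean_delta)
    mean_noise = sn / n
    corrected = raw.copy()
    for s in range(k):
        corrected[s, s] -= mean_noise[s] + mean_noise[s + 1]
        if s + 1 < k:
            corrected[s, s + 1] += mean_noise[s + 1]
            corrected[s + 1, s] += mean_noise[s + 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        het_mean = np.where(nh > 0, sh / np.maximum(nh, 1), np.nan)
    ref = np.minimum.outer(np.arange(k), np.arange(k))
    standardizer = het_mean[ref]
    standardized = corrected / standardizer
    return raw, corrected, standardized, standardizer


def locus_blocks(panel: FrequencyPanel, block_unit: int) -> np.ndarray:
    """Integer block label per locus: contiguous ``block_unit``-bp tiles."""
    keys = [
        (c, (p - 1) // block_unit)
        for c, p in zip(panel.contigs.tolist(), panel.positions.tolist())
    ]
    uniq = {key: i for i, key in enumerate(dict.fromkeys(keys))}
    return np.array([uniq[key] for key in keys])


def block_aggregates(per_locus: np.ndarray, blocks: np.ndarray) -> np.ndarray:
    """Sum per-locus aggregates within blocks -> (n_blocks, K)."""
    n_blocks = int(blocks.max()) + 1
    out = np.zeros((n_blocks, per_locus.shape[1]))
    np.add.at(out, blocks, per_locus)
    return out


def covariance_matrix(
    panel: FrequencyPanel,
    *,
    centered: bool = True,
    bootstrap: BootstrapConfig | None = None,
) -> CovarianceMatrix:
    """Bias-corrected, standardized covariance matrix of interval changes.

    With a :class:`~tempocov.bootstrap.BootstrapConfig`, 95% percentile CIs
    for the standardized entries are attached, resampling ``block_unit``-bp
    tiles with replacement.
    """
    if panel.n_time_points < 2:
        raise ValueError("need at least two time points")
    if panel.n_loci < 2:
        raise ValueError(
            "covariance over loci needs at least 2 loci "
            f"(got {panel.n_loci})"
        )
    T = panel.n_time_points
    per_locus = per_locus_aggregates(panel)
    total = per_locus.sum(axis=0)
    raw, corrected, standardized, standardizer = matrices_from_aggregates(
        total, T, centered=centered
    )
    deltas = interval_deltas(panel)
    result = CovarianceMatrix(
        replicate=panel.replicate,
        intervals=deltas.intervals,
        raw=raw,
        corrected=corrected,
        standardized=standardized,
        standardizer=standardizer,
        n_loci=panel.n_loci,
    )
    if bootstrap is not None:
        blocks = block_aggregates(
            per_locus, locus_blocks(panel, bootstrap.block_unit)
        )

        def stat(sub):
            return matrices_from_aggregates(
                np.asarray(sub).sum(axis=0), T, centered=centered
            )[2]

        boot: BootstrapResult = block_bootstrap(stat, blocks, bootstrap)
        result.ci_low = boot.low
        result.ci_high = boot.high
    return result


def total_variance(cov: np.ndarray, upto: int) -> float:
    """Variance of the total change over intervals ``0..upto-1``.

    Sum of the first ``upto`` diagonal entries plus twice every off-diagonal
    entry among them.  On raw matrices from a common SNP set this equals the
    directly computed variance of freq(last) − freq(first) exactly, because
    the total change is the sum of the interval changes.
    """
    cov = np.asarray(cov)
    if not 1 <= upto <= cov.shape[0]:
        raise ValueError(f"upto must be in [1, {cov.shape[0]}]")
    sub = cov[:upto, :upto]
    return float(np.diag(sub).sum() + 2 * np.triu(sub, k=1).sum())


def g_statistic(
    cov: CovarianceMatrix | np.ndarray,
    upto: int | None = None,
    which: str = "corrected",
) -> GResult:
    """G = 2·Σ covariances / total variance over the first ``upto`` intervals.

    G is the fraction of the variance of the total frequency change that the
    interval covariances contribute — the linked-selection share.  With a
    single interval the covariance sum is empty and G is exactly 0.
    """
    matrix = getattr(cov, which) if isinstance(cov, CovarianceMatrix) else np.asarray(cov)
    upto = upto or matrix.shape[0]
    sub = matrix[:upto, :upto]
    numerator = float(2 * np.triu(sub, k=1).sum())
    denominator = total_variance(matrix, upto)
    if upto == 1:
        return GResult(g=0.0, numerator=0.0, denominator=denominator, upto=upto)
    g = numerator / denominator if denominator > 0 else float("nan")
    return GResult(g=g, numerator=numerator, denominator=denominator, upto=upto)


def g_with_ci(
    panel: FrequencyPanel,
    upto: int | None = None,
    which: str = "corrected",
    *,
    centered: bool = True,
    bootstrap: BootstrapConfig | None = None,
) -> GResult:
    """G statistic with a block-bootstrap confidence interval."""
    T = panel.n_time_points
    upto = upto or T - 1
    per_locus = per_locus_aggregates(panel)
    which_i = {"raw": 0, "corrected": 1, "standardized": 2}[which]

    def stat(sub):
        m = matrices_from_aggregates(
            np.asarray(sub).sum(axis=0), T, centered=centered
        )[which_i]
        return g_statistic(m, upto).g

    base = g_statistic(
        matrices_from_aggregates(per_locus.sum(axis=0), T, centered=centered)[which_i],
        upto,
    )
    if bootstrap is None:
        return base
    blocks = block_aggregates(per_locus, locus_blocks(panel, bootstrap.block_unit))
    boot = block_bootstrap(stat, blocks, bootstrap)
    return GResult(
        g=base.g,
        numerator=base.numerator,
        denominator=base.denominator,
        upto=upto,
        ci_low=float(boot.low),
        ci_high=float(boot.high),
    )
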