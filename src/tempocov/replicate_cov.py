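"""Covariances of allele-frequency change between replicates (forests).

A positive covariance between the changes two forests experienced over the
same period indicates parallel linked selection; comparing non-overlapping
periods (adjacent or distant) asks *when* selection acted in each forest.
Overlapping non-identical periods are refused outright: a shared sub-interval
would contribute the same frequency changes to both terms and inflate the
covariance mechanically.

Because the two replicates are sequenced from independent pools, their
sampling errors are independent and no shared-noise correction applies;
entries are standardized by the across-replicate mean heterozygosity at the
earlier period's start time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from tempocov.bootstrap import BootstrapConfig, block_bootstrap
from tempocov.io_sync import FrequencyPanel
from tempocov.temporal_cov import block_aggregates, locus_blocks

Period = tuple[int, int]


@dataclass(frozen=True)
class PeriodPair:
    """Two periods, one per replicate, and their temporal relation."""

    replicate_a: str
    replicate_b: str
    period_a: Period
    period_b: Period
    relation: str = ""

    def __post_init__(self) -> None:
        for period in (self.period_a, self.period_b):
            if period[0] >= period[1]:
                raise ValueError(f"period start must precede end: {period}")
        object.__setattr__(self, "relation", classify_periods(self.period_a, self.period_b))


def classify_periods(a: Period, b: Period) -> str:
    """contemporary (identical), adjacent (shared endpoint) or distant.

    Overlapping non-identical periods raise: allele-frequency changes over the
    shared stretch would appear in both covariance terms.
    """
    if a == b:
        return "contemporary"
    if max(a[0], b[0]) < min(a[1], b[1]):
        raise ValueError(f"periods {a} and {b} overlap but are not identical")
    if a[1] == b[0] or b[1] == a[0]:
        return "adjacent"
    return "distant"


@dataclass
class BetweenReplicateCov:
    pair: PeriodPair
    raw: float
    standardized: float
    standardizer: float
    n_loci: int
    ci_low: float | None = None
    ci_high: float | None = None


def intersect_panels(
    panel_a: FrequencyPanel, panel_b: FrequencyPanel
) -> tuple[FrequencyPanel, FrequencyPanel]:
    """Restrict two panels to shared loci with harmonized polarity.

    Loci are keyed by (contig, pos).  A locus present in both panels with
    swapped ref/alt has its frequencies flipped in ``panel_b``; loci whose
    allele pairs differ entirely are dropped.
    """
    keys_a = {k: i for i, k in enumerate(panel_a.locus_keys())}
    idx_a, idx_b, flip = [], [], []
    for j, key in enumerate(panel_b.locus_keys()):
        i = keys_a.get(key)
        if i is None:
            continue
        same = (
            panel_a.ref_alleles[i] == panel_b.ref_alleles[j]
            and panel_a.alt_alleles[i] == panel_b.alt_alleles[j]
        )
        swapped = (
            panel_a.ref_alleles[i] == panel_b.alt_alleles[j]
            and panel_a.alt_alleles[i] == panel_b.ref_alleles[j]
        )
        if not (same or swapped):
            continue
        idx_a.append(i)
        idx_b.append(j)
        flip.append(swapped)
    sub_a = panel_a.subset(np.array(idx_a, dtype=int))
    sub_b = panel_b.subset(np.array(idx_b, dtype=int))
    flip_arr = np.array(flip, dtype=bool)
    if flip_arr.any():
        sub_b.freq[flip_arr] = 1.0 - sub_b.freq[flip_arr]
        ref = sub_b.ref_alleles[flip_arr].copy()
        sub_b.ref_alleles[flip_arr] = sub_b.alt_alleles[flip_arr]
        sub_b.alt_alleles[flip_arr] = ref
    return sub_a, sub_b


def _span_delta(panel: FrequencyPanel, period: Period) -> np.ndarray:
    years = list(panel.time_points)
    try:
        i0, i1 = years.index(period[0]), years.index(period[1])
    except ValueError:
        raise ValueError(f"period {period} not on panel time points {years}") from None
    return panel.freq[:, i1] - panel.freq[:, i0]


def between_replicate_cov(
    panel_a: FrequencyPanel,
    panel_b: FrequencyPanel,
    period_a: Period,
    period_b: Period,
    *,
    centered: bool = True,
    bootstrap: BootstrapConfig | None = None,
) -> BetweenReplicateCov:
    """Loci-averaged covariance of Δ_a over ``period_a`` with Δ_b over ``period_b``.

    Standardized by the mean over the two replicates of loci-mean p(1−p) at
    the earlier period's start time (fixed loci excluded from the mean, not
    from the covariance).  Periods may span several adjacent intervals:
    Δ over a span is freq(end) − freq(start).
    """
    pair = PeriodPair(
        replicate_a=panel_a.replicate,
        replicate_b=panel_b.replicate,
        period_a=period_a,
        period_b=period_b,
    )
    a, b = intersect_panels(panel_a, panel_b)
    if a.n_loci < 2:
        raise ValueError("fewer than 2 shared loci between the panels")
    da = _span_delta(a, period_a)
    db = _span_delta(b, period_b)
    ref_year = min(period_a[0], period_b[0])

    def het_ref(panel: FrequencyPanel) -> tuple[np.ndarray, np.ndarray]:
        t = list(panel.time_points).index(ref_year)
        p = panel.freq[:, t]
        nonfixed = (p > 0) & (p < 1)
        return np.where(nonfixed, p * (1 - p), 0.0), nonfixed.astype(float)

    ha, nfa = het_ref(a)
    hb, nfb = het_ref(b)
    per_locus = np.column_stack(
        [np.ones_like(da), da, db, da * db, ha, nfa, hb, nfb]
    )

    def stat(sub):
        s = np.asarray(sub).sum(axis=0)
        n, sa, sb, sab, sha, snfa, shb, snfb = s
        raw = sab / n - (sa / n) * (sb / n) if centered else sab / n
        het_a = sha / snfa if snfa > 0 else np.nan
        het_b = shb / snfb if snfb > 0 else np.nan
        standardizer = (het_a + het_b) / 2
        return np.array([raw, raw / standardizer])

    raw, standardized = stat(per_locus)
    het_a = per_locus[:, 4].sum() / per_locus[:, 5].sum()
    het_b = per_locus[:, 6].sum() / per_locus[:, 7].sum()
    result = BetweenReplicateCov(
        pair=pair,
        raw=float(raw),
        standardized=float(standardized),
        standardizer=float((het_a + het_b) / 2),
        n_loci=a.n_loci,
    )
    if bootstrap is not None:
        blocks = block_aggregates(per_locus, locus_blocks(a, bootstrap.block_unit))
        boot = block_bootstrap(lambda s: stat(s)[1], blocks, bootstrap)
        result.ci_low = float(boot.low)
        result.ci_high = float(boot.high)
    return result
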