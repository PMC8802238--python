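import numpy as np
import pytest

from tempocov import synthetic_data as sd
from tempocov.io_sync import CohortDesign, FrequencyPanel, SiteFilterConfig, call_biallelic

OAK_YEARS = (1680, 1850, 1960, 2008)


def make_design(n_replicates=1, time_points=OAK_YEARS, pool_size=50):
    reps = tuple(f"R{i + 1}" for i in range(n_replicates))
    return CohortDesign(
        replicates=reps,
        time_points=time_points,
        pool_sizes={(r, t): pool_size for r in reps for t in time_points},
    )


def make_panel(freq, depth=1000, pool_size=50, contig="chr1", spacing=101, replicate="R1"):
    """Frequency panel straight from a (loci x time) frequency matrix."""
    freq = np.asarray(freq, dtype=float)
    L, T = freq.shape
    depth = np.broadcast_to(np.asarray(depth), (L, T)).copy()
    return FrequencyPanel(
        replicate=replicate,
        time_points=OAK_YEARS[:T],
        contigs=np.array([contig] * L),
        positions=np.arange(1, L + 1) * spacing,
        ref_alleles=np.array(["A"] * L),
        alt_alleles=np.array(["C"] * L),
        freq=freq,
        depth=depth,
        pool_size=np.full(T, pool_size),
    )


@pytest.fixture(scope="session")
def demo_sim():
    """Small neutral three-replicate simulation shared across tests."""
    return sd.simulate(sd.demo_config(11))


@pytest.fixture(scope="session")
def demo_panels(demo_sim):
    return call_biallelic(
        list(demo_sim.records()), demo_sim.design, SiteFilterConfig.for_synthetic()
    )
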