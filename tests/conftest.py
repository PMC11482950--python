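import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import torsionmap as tm

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture])
settings.load_profile("ci")


@pytest.fixture
def toy_genome():
    return tm.GenomeIndex(("chrI", "chrII"), (200, 100), bin_width=10)


def make_track(genome, **chrom_values):
    """Build a GenomicTrack from per-chromosome value lists (NaN = missing)."""
    data = {}
    for chrom in genome.names:
        vals = chrom_values.get(chrom)
        if vals is None:
            data[chrom] = np.zeros(genome.n_bins(chrom))
        else:
            arr = np.full(genome.n_bins(chrom), 0.0)
            arr[:len(vals)] = vals
            data[chrom] = arr
    return tm.GenomicTrack(genome, data)


@pytest.fixture(scope="session")
def default_sim():
    """One full simulation under the documented default study conditions."""
    truth, tracks = tm.simulate(tm.SimulationParams(seed=1))
    return truth, tracks


@pytest.fixture(scope="session")
def default_torsion(default_sim):
    truth, tracks = default_sim
    return tm.compute_torsion(tracks["with"], tracks["without"])
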