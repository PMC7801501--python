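import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from txnacetyl import (CoverageTrack, SimulationConfig, make_genome,
                       simulate_tracks)

settings.register_profile("ci", derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """A miniature, noise-free genome: every planted fact exactly recoverable."""
    return SimulationConfig(
        n_chromosomes=1, chrom_length=60_000, n_genes=12,
        n_planted_peaks=6, n_control_peaks=2, n_silent_bins=10,
        noise_sd=0.0, seed=7,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return make_genome(small_config)


@pytest.fixture(scope="session")
def small_sim(small_config, small_genome):
    return simulate_tracks(small_genome, small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def constant_track(chrom_sizes, value, units="RPGC", **meta):
    return CoverageTrack(
        data={c: np.full(n, float(value)) for c, n in chrom_sizes.items()},
        units=units, **meta)


def random_track(chrom_sizes, rng, units="RPGC", scale=1.0, **meta):
    return CoverageTrack(
        data={c: scale * rng.random(n) for c, n in chrom_sizes.items()},
        units=units, **meta)


@pytest.fixture()
def genes_table():
    return pd.DataFrame({
        "id": ["gA", "gB"],
        "chrom": ["chrI", "chrI"],
        "strand": ["+", "-"],
        "tss": [1000, 5000],
        "pas": [1300, 4700],
    })
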