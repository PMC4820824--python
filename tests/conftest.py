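import numpy as np
import pytest

import seqbind as sb


@pytest.fixture(scope="session")
def small_cfg():
    return sb.SimConfig(seed=42, n_chroms=2, chrom_length=300_000)


@pytest.fixture(scope="session")
def small_genome(small_cfg):
    return sb.simulate_genome(small_cfg)


@pytest.fixture(scope="session")
def small_features(small_genome):
    return sb.sequence_features(small_genome, small_genome.grid, k_set=(1, 2))


@pytest.fixture(scope="session")
def small_chip(small_cfg, small_features):
    return sb.simulate_chip_experiment(small_cfg, small_features)


def flat_grid(n: int, width: int = 150) -> sb.BinGrid:
    """Single-chromosome grid with n bins, for array-backed test tracks."""
    return sb.make_bins({"chrT": n * width}, width)


def as_track(values, width: int = 150) -> sb.SignalTrack:
    values = np.asarray(values, dtype=float)
    return sb.SignalTrack(flat_grid(values.size, width), values)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
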