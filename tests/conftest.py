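import numpy as np
import pandas as pd
import pytest

from nucarch import occupancy
from nucarch.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def sim():
    """Default-condition synthetic dataset shared across the suite."""
    return simulate_dataset(SimConfig(seed=7))


@pytest.fixture(scope="session")
def raw_tracks(sim):
    frags = occupancy.deduplicate_fragments(sim.fragments)
    return occupancy.compute_nos(frags, sim.chrom_sizes)


@pytest.fixture(scope="session")
def norm_tracks(raw_tracks):
    return occupancy.normalize_tracks(raw_tracks)


@pytest.fixture(scope="session")
def called_nucs(raw_tracks):
    return occupancy.call_nucleosomes(raw_tracks)


def make_fragments(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def nearest_distance(query: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Distance from each query position to its nearest reference position."""
    reference = np.sort(reference)
    i = np.searchsorted(reference, query)
    left = np.abs(query - reference[np.clip(i - 1, 0, len(reference) - 1)])
    right = np.abs(reference[np.clip(i, 0, len(reference) - 1)] - query)
    return np.minimum(left, right)
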