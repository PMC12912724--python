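import numpy as np
import pytest

from phasesync import bold, space


@pytest.fixture(scope="session")
def ring_starts():
    return space.sample_ring_starts(seed=0)


@pytest.fixture(scope="session")
def directions(ring_starts):
    return np.array([d for _, d in ring_starts])


@pytest.fixture(scope="session")
def event_design(directions):
    return bold.make_event_design(directions, seed=1)


@pytest.fixture(scope="session")
def noiseless_voxel(event_design):
    """Noiseless sixfold voxel with known orientation; (truth, series)."""
    truth = bold.GroundTruth(fold=6, phi=23.0, amplitude=1.0, noise_sd=0.0)
    series = bold.simulate_voxel(event_design, truth, seed=0)
    return truth, series
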