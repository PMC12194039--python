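import numpy as np
import pytest

from spikempc.model import GCAMP6S, CellModelParams
from spikempc.synthetic import SyntheticSpec, generate_spike_train, synth_recording


@pytest.fixture(scope="session")
def unit_cell():
    """GCaMP6s kinetics with unit gain/clearance for analytic checks."""
    return CellModelParams(indicator=GCAMP6S, alpha=1.0, gamma=1.0)


@pytest.fixture(scope="session")
def synth_cell():
    """Generator's default cell: calibrated-scale gain, 1/s clearance."""
    return CellModelParams(indicator=GCAMP6S, alpha=50.0, gamma=1.0)


@pytest.fixture(scope="session")
def clean_recording(synth_cell):
    """10 s noiseless 1 Hz Poisson recording shared across MPC tests."""
    spec = SyntheticSpec(duration=10.0, seed=7, mean_rate=1.0, noise_sigma=0.0)
    train = generate_spike_train(spec)
    clean, _ = synth_recording(synth_cell, train, spec)
    return spec, train, clean
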