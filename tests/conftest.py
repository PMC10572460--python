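import numpy as np
import pytest

from epiphys.recordings import FluorTrace
from epiphys.synthetic import CaSimConfig, gen_calcium_traces


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noiseless_ca_config():
    """Noiseless calcium config: exact recovery up to frame discretization."""
    return CaSimConfig(n_cells=5, noise_sd=0.0, amp_unit_au=30.0, seed=7)


@pytest.fixture
def noiseless_ca_dataset(noiseless_ca_config):
    traces, truth = gen_calcium_traces(noiseless_ca_config)
    return noiseless_ca_config, traces, truth


def make_flat_trace(n_frames=300, level=3000.0, noise_sd=0.0, seed=0,
                    background=200.0, frame_period_s=1.0):
    rng = np.random.default_rng(seed)
    values = np.full(n_frames, level)
    if noise_sd > 0:
        values = values + rng.normal(0, noise_sd, n_frames)
    return FluorTrace("flat", frame_period_s, values, background)
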