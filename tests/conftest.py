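import numpy as np
import pytest

from statekit import synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def calcium_recovery():
    """Isolated-spike calcium scenario: tau = 0.7 s, SNR 10 (amp 400,
    noise SD 40), 20 ROIs x 20 transients over 300 s."""
    ss = synth.gen_isolated_spikes(20, 20, 300.0, min_gap=2.5, seed=7)
    tm, gt = synth.gen_calcium(ss, tau=0.7, fs=30.0, seed=7, amp=400.0,
                               noise_sd=40.0)
    return tm, gt


@pytest.fixture(scope="session")
def planted_states():
    """Time x neuron matrix with k=4 planted temporal states."""
    r = np.random.default_rng(0)
    k, T, N = 4, 300, 40
    means = r.standard_normal((k, N)) * 3.0
    states = r.integers(0, k, T)
    return means[states] + r.standard_normal((T, N)), k
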