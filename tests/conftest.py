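import numpy as np
import pytest

from hydracal import SimulationConfig, render_trace, simulate_events


@pytest.fixture
def quiet_config():
    """Noiseless, bleach-free config for exact-value tests."""
    return SimulationConfig(
        seed=0, cb_burst_rate=0.0, rp1_rate=0.0, noise_sd=0.0,
        bleach_tau=np.inf,
    )


def make_snr_trace(seed: int, snr: float = 5.0):
    """A default 2-h neural recording at the requested SNR, with truth."""
    config = SimulationConfig(seed=seed).with_snr(snr)
    events = simulate_events(config)
    trace = render_trace(events, config)
    return config, events, trace
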