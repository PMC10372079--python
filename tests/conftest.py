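import numpy as np
import pytest

from hfosync.session import Epoch
from hfosync.synth import HfoConfig, SpikeConfig, SynthConfig, gen_session, preset

# Scaled study layout used by session-level tests: short epochs with the same
# pre/post-injection logic as the full-length protocol.
SCALED_BASELINE = Epoch("baseline", -130.0, -10.0)
SCALED_DRUG = Epoch("drug", 20.0, 230.0)


@pytest.fixture(scope="session")
def small_session():
    """One scaled 5HT2A-preset session (260 s) with ground truth, shared
    across tests that only read from it."""
    cfg = preset(
        "5HT2A",
        duration=260.0,
        injection_time=140.0,
        structures={"OB": 2, "vStr": 3},
        spikes=SpikeConfig(base_rate=5.0, n_units={"PC": 1, "IN": 1}),
        seed=11,
    )
    return gen_session(cfg)


@pytest.fixture(scope="session")
def lag_session():
    """8-channel session with configured inter-channel lags {0, +0.2, pi}."""
    cfg = preset(
        "5HT2A",
        duration=260.0,
        injection_time=20.0,
        structures={"OB": 4, "vStr": 4},
        hfo=HfoConfig(
            carrier_freq=150.0,
            phase_lags=[0.0, 0.0, 0.0, np.pi, 0.2, 0.2, 0.2, 0.2],
            amplitude=40.0,
            spindle_rate=10.0,
        ),
        spikes=SpikeConfig(n_units={}),
        seed=21,
    )
    return gen_session(cfg)
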