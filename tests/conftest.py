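import numpy as np
import pytest
from hypothesis import settings

from loomstrike import AttackGenParams, EscapeSequence, gen_attack

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noiseless_constant_attack():
    """Constant-speed escape approach with all noise off."""
    params = AttackGenParams(
        profile="constant_speed",
        peak_speed=0.2,
        end_distance=4.0,
        outcome="escape",
        digitization_noise_sd=0.0,
        hover_jitter_sd=0.0,
    )
    return gen_attack(params, 0)


def make_sequences(durations, reaction=100.0, **kw):
    """Take-off sequences with the given durations (ms) at a common reaction time."""
    return [
        EscapeSequence(took_off=True, wing_raise_time=reaction, legs_leave_time=reaction + d, **kw)
        for d in durations
    ]
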