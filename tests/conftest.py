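import numpy as np
import pytest

from p300kit import synth
from p300kit.io import ContinuousRecording, EventMarker


@pytest.fixture(scope="session")
def session_cfg() -> synth.SessionConfig:
    return synth.SessionConfig()


@pytest.fixture()
def quiet_params() -> synth.SubjectERPParams:
    """One target-responsive subject with every noise source switched off."""
    latency = {(c, ch): 450.0 for c in ("target", "nontarget") for ch in ("Fz", "Cz", "Pz")}
    amplitude = {(c, ch): 0.0 for c in ("target", "nontarget") for ch in ("Fz", "Cz", "Pz")}
    amplitude[("target", "Cz")] = 6.0
    return synth.SubjectERPParams(
        latency=latency,
        amplitude=amplitude,
        background_noise_sd=0.0,
        alpha_amplitude=0.0,
        blink_rate_per_min=0.0,
        eog_noise_sd=0.0,
    )


@pytest.fixture()
def small_recording() -> ContinuousRecording:
    """Tiny deterministic 4-channel recording with two stimulus events."""
    rng = np.random.default_rng(7)
    fs = 500.0
    n = 4000
    data = rng.standard_normal((4, n))
    events = [EventMarker(1000, "target", "S  2"), EventMarker(2500, "nontarget", "S  1")]
    return ContinuousRecording(["Fz", "Cz", "Pz", "EOG"], fs, data, events)
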