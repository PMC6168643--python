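import numpy as np
import pytest

from ffikit import synth


@pytest.fixture(scope="session")
def snr8_session():
    """One flat-firing unit at SNR 8 rendered into a noisy 60 s trace."""
    unit = synth.UnitSpec(
        unit_id="u0",
        profile=synth.RateProfile(10.0),
        waveform_width=0.7,
        snr=8.0,
        refractory=2.0,
    )
    session, truth = synth.gen_extracellular_session(
        [unit], n_trials=30, stim_period=2.0, fs=25_000.0, noise_sd=1.0,
        seed=42,
    )
    return session, truth


@pytest.fixture(scope="session")
def noise_only_trace():
    """60 s of pure white noise at 25 kHz (event-detector null input)."""
    rng = np.random.default_rng(7)
    return rng.normal(0.0, 1.0, int(60 * 25_000)), 25_000.0
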