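import numpy as np
import pytest
from hypothesis import settings

from ppgkit import synthetic as sy
from ppgkit.core import PPGSignal

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")

AGES = (25, 35, 45, 55, 65, 75)


def clean_profile(age=45.0, hr=70.0, cv=0.0, seed=0, **kw):
    """Noise-, wander- and artefact-free subject profile."""
    base = dict(age_years=age, hr_bpm=hr, hrv_cv=cv, wander_amp=0.0,
                noise_sd=0.0, artefact_rate_per_min=0.0, seed=seed)
    base.update(kw)
    return sy.SubjectProfile(**base)


@pytest.fixture(scope="session")
def age25_pulse():
    return sy.synth_pulse(sy.age_to_shape(25), 1.0, 500)


@pytest.fixture(scope="session")
def age_pulses():
    """One noise-free pulse per study age, at 500 Hz / 1 s period."""
    return {age: sy.synth_pulse(sy.age_to_shape(age), 1.0, 500)
            for age in AGES}


@pytest.fixture(scope="session")
def clean_signal_60bpm():
    """Exactly periodic 60 bpm pulse train, 60 s at 100 Hz."""
    return sy.synth_signal(clean_profile(hr=60.0), 60, 100)


@pytest.fixture()
def raised_sinusoid():
    fs = 100.0
    t = np.arange(0, 30, 1 / fs)
    return PPGSignal(1.0 + np.sin(2 * np.pi * t), fs)


def _spar_indices_of(profile, duration_s=60, fs=500.0):
    from ppgkit import beats, spar
    sig = sy.synth_signal(profile, duration_s, fs)
    cycle = beats.mean_cycle_length(sig)
    tau = spar.embedding_delay(cycle, fs)
    return spar.spar_indices(spar.embed_project(sig, tau))


@pytest.fixture(scope="session")
def aging_sweep():
    """Per age: noise-free FPA catalogue (single pulse) and SPAR
    catalogue (60 s signal, minimal physiological HRV, no noise)."""
    from ppgkit import fpa
    out = {}
    for age in AGES:
        pulse = sy.synth_pulse(sy.age_to_shape(age), 1.0, 500)
        fpa_set = fpa.compute_fpa_indices(pulse, fpa.locate_fiducials(pulse))
        spar_set = _spar_indices_of(clean_profile(age=age, cv=0.05, seed=3))
        out[age] = (fpa_set, spar_set)
    return out


@pytest.fixture(scope="session")
def hrv_sweep():
    """SPAR catalogues across beat-period CVs at fixed morphology."""
    return {cv: _spar_indices_of(clean_profile(cv=cv, seed=4))
            for cv in (0.02, 0.04, 0.07, 0.10, 0.12)}
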