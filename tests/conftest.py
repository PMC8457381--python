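import numpy as np
import pytest

from ctgrad import PatientSpec, generate_patient


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def noiseless_patient():
    """One dense-frame virtual patient with every noise source at zero."""
    spec = PatientSpec(seed=42, n_frames=50)
    return generate_patient(spec)


def cosine_series_times_volumes(edv, esv, t_systole, n_frames):
    """Cosine-emptying half-cycle from EDV to ESV; analytic peak slope is
    pi * (edv - esv) / (2 * t_systole)."""
    t = np.linspace(0.0, t_systole, n_frames)
    v = esv + (edv - esv) / 2.0 * (1.0 + np.cos(np.pi * t / t_systole))
    return t, v
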