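import numpy as np
import pytest

from fqrs.io_preprocess import ANALYSIS_LEADS, MultiLeadECG
from fqrs.segmentation import QRSComplex
from fqrs.synthetic import SyntheticConfig, gen_beat, gen_recording, inject_fqrs

FS = 500.0


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def sinus_recording():
    """Default clean 11-lead sinus recording + ground truth."""
    return gen_recording(SyntheticConfig(seed=42))


@pytest.fixture
def af_recording():
    return gen_recording(SyntheticConfig(seed=43, rhythm="af", rr_cv=0.2))


@pytest.fixture
def twelve_lead_ecg(rng):
    names = ["I", "II", "III", "aVR", "aVL", "aVF", "V1", "V2", "V3", "V4", "V5", "V6"]
    return MultiLeadECG(rng.standard_normal((5000, 12)), FS, names)


def make_beat_pair(seed, qrs_ms=None, n_notches=None, amp=None, width_ms=8.0, fs=FS):
    """Matched (clean, notched) QRSComplex pair from the generator."""
    rng = np.random.default_rng(seed)
    qrs_ms = qrs_ms if qrs_ms is not None else float(rng.uniform(75, 150))
    amp = amp if amp is not None else float(rng.uniform(0.2, 0.35))
    n_notches = n_notches if n_notches is not None else int(rng.integers(1, 4))
    wave, r, on, off = gen_beat(qrs_ms, fs=fs)
    notched, centers = inject_fqrs(wave, n_notches, amp, width_ms, fs, rng, r, qrs_ms)
    return QRSComplex(wave[on:off], fs), QRSComplex(notched[on:off], fs)


@pytest.fixture
def beat_pair():
    return make_beat_pair(seed=5)
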