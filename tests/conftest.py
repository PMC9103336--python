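import numpy as np
import pytest

from fecgsqi.preprocess import preprocess_recording
from fecgsqi.synth import (
    FOETAL_TEMPLATE,
    MATERNAL_TEMPLATE,
    SynthConfig,
    generate_beat_train,
    generate_recording,
    render_ecg,
)


@pytest.fixture(scope="session")
def clean_maternal():
    """10 s noise-free maternal render with its beat train (75 bpm)."""
    beats = generate_beat_train(75, 10, 0.02, 1000, seed=42)
    return render_ecg(MATERNAL_TEMPLATE, beats, 1000, 10000), beats


@pytest.fixture(scope="session")
def clean_foetal():
    """10 s noise-free foetal render with its beat train (140 bpm)."""
    beats = generate_beat_train(140, 10, 0.02, 1000, seed=43)
    return render_ecg(FOETAL_TEMPLATE, beats, 1000, 10000), beats


@pytest.fixture(scope="session")
def good_recording():
    """A 10 s high-foetal-SNR synthetic recording."""
    return generate_recording(SynthConfig(duration_s=10.0, target_foetal_snr_db=12.0, seed=11))


@pytest.fixture(scope="session")
def bad_recording():
    """A 10 s low-foetal-SNR synthetic recording."""
    return generate_recording(SynthConfig(duration_s=10.0, target_foetal_snr_db=-6.0, seed=12))


@pytest.fixture(scope="session")
def good_segments(good_recording):
    segs, imgs = preprocess_recording(good_recording)
    return segs, imgs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
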