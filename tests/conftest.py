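"""Shared fixtures: a scaled-down analysis rate keeps the suite fast while
preserving every algorithmic property (the analysis band tops out at 7250 Hz,
so any rate above 14.5 kHz is faithful)."""

import numpy as np
import pytest

import speechedge as se
from speechedge.synth import AudioScenario, make_audio

TEST_FS = 16_000.0


@pytest.fixture(scope="session")
def spec16k():
    return se.design_erb_filterbank(sample_rate=TEST_FS)


@pytest.fixture(scope="session")
def cds_audio():
    """30 s of CDS-like audio (2 + 5 Hz AM noise carrier)."""
    sig, _ = make_audio(AudioScenario(duration_s=30.0, sample_rate=TEST_FS, seed=11))
    return sig


@pytest.fixture(scope="session")
def cds_enhanced(cds_audio):
    """Enhancement result for the shared CDS fixture (expensive: computed once)."""
    return se.enhance(cds_audio)


@pytest.fixture(scope="session")
def faded_tone(spec16k):
    """Pure tone at a mid-bank channel centre with raised-cosine fades.

    The fades keep every channel envelope smooth, i.e. the degenerate
    constant-envelope case of the enhancement pipeline.
    """
    fs = TEST_FS
    n = int(4 * fs)
    tone = 0.5 * np.sin(2 * np.pi * spec16k.center_freqs[14] * np.arange(n) / fs)
    ramp = int(0.2 * fs)
    w = np.ones(n)
    w[:ramp] = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
    w[-ramp:] = w[:ramp][::-1]
    return se.AudioSignal(tone * w, fs)
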