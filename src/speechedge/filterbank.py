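"""ERB-spaced FIR analysis filter bank modelling cochlear frequency channels.

The bank splits a wideband speech signal into overlapping band-pass channels
whose edges are uniformly spaced on the ERB_N-number scale (the frequency warp
on which equal steps correspond to equal cochlear-filter bandwidths in normal
hearing).  With the default 100–7250 Hz span the bank has exactly 28 channels.

Filters are linear-phase windowed-sinc band-passes of identical odd length, so
the group delay is the same integer number of samples in every channel and can
be removed exactly.  Adjacent filters cross at −6 dB at their shared band
edge, which makes the channel sum approximately all-pass inside the analysis
span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "AudioSignal",
    "FilterBankSpec",
    "SubbandSet",
    "erb_number",
    "erb_to_hz",
    "design_erb_filterbank",
    "analyze",
    "synthesize",
]

DEFAULT_F_LO = 100.0
DEFAULT_F_HI = 7250.0
DEFAULT_N_CHANNELS = 28
#: taps at the 48 kHz reference rate; scaled proportionally for other rates
REFERENCE_FILTER_LENGTH = 4097
REFERENCE_SAMPLE_RATE = 48_000.0


@dataclass
class AudioSignal:
    """Uniformly sampled real-valued waveform."""

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)

    @property
    def duration_s(self) -> float:
        return self.samples.shape[-1] / self.sample_rate

    @property
    def n_samples(self) -> int:
        return self.samples.shape[-1]

    def to_mono(self) -> "AudioSignal":
        """Downmix multichannel audio by averaging channels."""
        if self.samples.ndim == 1:
            return self
        return AudioSignal(self.samples.mean(axis=1), self.sample_rate)


@dataclass
class FilterBankSpec:
    """Band-edge table and filter length of an ERB-spaced analysis bank."""

    sample_rate: float
    edge_freqs: np.ndarray
    filter_length: int
    center_freqs: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.edge_freqs = np.asarray(self.edge_freqs, dtype=np.float64)
        if np.any(np.diff(self.edge_freqs) <= 0):
            raise ValueError("edge_freqs must be strictly increasing")
        if self.filter_length % 2 == 0:
            raise ValueError("filter_length must be odd")
        # geometric centre on the ERB scale: midpoint between the two edges
        mid_erb = 0.5 * (erb_number(self.edge_freqs[:-1]) + erb_number(self.edge_freqs[1:]))
        self.center_freqs = erb_to_hz(mid_erb)

    @property
    def n_channels(self) -> int:
        return len(self.edge_freqs) - 1

    def to_table(self) -> str:
        """Plain-text channel table: index, low edge, center, high edge (Hz)."""
        lines = ["channel\tf_low_hz\tf_center_hz\tf_high_hz"]
        for i in range(self.n_channels):
            lines.append(
                f"{i}\t{self.edge_freqs[i]:.3f}\t{self.center_freqs[i]:.3f}"
                f"\t{self.edge_freqs[i + 1]:.3f}"
            )
        return "\n".join(lines) + "\n"


@dataclass
class SubbandSet:
    """Per-channel band-limited signals, delay compensated."""

    samples: np.ndarray  # (n_channels, n_samples)
    sample_rate: float
    spec: FilterBankSpec

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


def erb_number(frequency):
    """ERB_N-number (Cam) of a frequency in Hz.

    E(f) = 21.4 * log10(4.37 * f_kHz + 1); strictly increasing.
    """
    f = np.asarray(frequency, dtype=np.float64)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    return 21.4 * np.log10(4.37 * f / 1000.0 + 1.0)


def erb_to_hz(erb):
    """Inverse of :func:`erb_number`."""
    e = np.asarray(erb, dtype=np.float64)
    return (10.0 ** (e / 21.4) - 1.0) / 4.37 * 1000.0


def filter_length_for_rate(sample_rate: float) -> int:
    """Odd tap count scaled from the 48 kHz reference design."""
    n = int(round(REFERENCE_FILTER_LENGTH * sample_rate / REFERENCE_SAMPLE_RATE))
    return n if n % 2 == 1 else n + 1


def design_erb_filterbank(
    f_lo: float = DEFAULT_F_LO,
    f_hi: float = DEFAULT_F_HI,
    sample_rate: float = REFERENCE_SAMPLE_RATE,
    n_channels: int | None = None,
    filter_length: int | None = None,
) -> FilterBankSpec:
    """Design the band-edge table of the ERB-uniform analysis bank.

    Band edges are uniformly spaced on the ERB_N-number scale between
    ``erb_number(f_lo)`` and ``erb_number(f_hi)``.  For the default
    100–7250 Hz span the channel count is fixed at 28 (≈1.04 ERB per
    channel); for other spans the count defaults to the nearest integer
    number of ~unit-ERB channels.
    """
    if not (0 < f_lo < f_hi):
        raise ValueError("need 0 < f_lo < f_hi")
    if f_hi >= sample_rate / 2:
        raise ValueError("f_hi must be below the Nyquist frequency")
    if n_channels is None:
        if (f_lo, f_hi) == (DEFAULT_F_LO, DEFAULT_F_HI):
            n_channels = DEFAULT_N_CHANNELS
        else:
            n_channels = max(1, int(round(erb_number(f_hi) - erb_number(f_lo))))
    edges_erb = np.linspace(erb_number(f_lo), erb_number(f_hi), n_channels + 1)
    edges = erb_to_hz(edges_erb)
    edges[0], edges[-1] = f_lo, f_hi  # exact boundary values
    if filter_length is None:
        filter_length = filter_length_for_rate(sample_rate)
    return FilterBankSpec(sample_rate=sample_rate, edge_freqs=edges, filter_length=filter_length)


def _filter_taps(spec: FilterBankSpec) -> np.ndarray:
    """(n_channels, filter_length) windowed-sinc band-pass taps.

    ``firwin`` places the half-amplitude (−6 dB) point at each band edge, so
    adjacent channels cross at −6 dB and their in-phase sum is ~unity.
    """
    taps = np.empty((spec.n_channels, spec.filter_length))
    for i in range(spec.n_channels):
        taps[i] = sps.firwin(
            spec.filter_length,
            [spec.edge_freqs[i], spec.edge_freqs[i + 1]],
            fs=spec.sample_rate,
            pass_zero=False,
            scale=False,
        )
    return taps


def analyze(signal: AudioSignal, spec: FilterBankSpec) -> SubbandSet:
    """Split a mono signal into delay-compensated band-pass channels."""
    if signal.samples.ndim != 1:
        raise ValueError("analyze expects mono audio; downmix first (AudioSignal.to_mono)")
    if signal.sample_rate != spec.sample_rate:
        raise ValueError(
            f"sample rate mismatch: signal {signal.sample_rate} Hz, spec {spec.sample_rate} Hz"
        )
    x = signal.samples
    delay = (spec.filter_length - 1) // 2
    taps = _filter_taps(spec)
    out = np.empty((spec.n_channels, x.size))
    for i in range(spec.n_channels):
        full = sps.fftconvolve(x, taps[i], mode="full")
        out[i] = full[delay : delay + x.size]  # remove group delay, keep length
    return SubbandSet(samples=out, sample_rate=signal.sample_rate, spec=spec)


def synthesize(subbands: SubbandSet) -> AudioSignal:
    """Reconstruct a waveform as the sample-wise sum over channels."""
    return AudioSignal(subbands.samples.sum(axis=0), subbands.sample_rate)
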