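"""Speech-edge (amplitude rise time) detection and epoch extraction.

Speech edges are rapid, large-amplitude rises of the wideband envelope that
act as acoustic landmarks.  The detector works on a normalised 100 Hz
envelope and marks a sample as an onset when three conditions hold: a quiet
pre-onset stretch (mean < 0.05 over the preceding 400 ms), a sustained loud
post-onset stretch (mean > 0.05 over the following 1000 ms), and an
instantaneous jump (mean over the 20 ms after minus the 20 ms before
exceeding 0.05).  Onsets whose analysis epochs (−400…+1000 ms) would overlap
an already-accepted onset are discarded, scanning left to right.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .filterbank import AudioSignal

__all__ = [
    "EdgeDetectParams",
    "EdgeOnset",
    "EdgeEpoch",
    "detection_envelope",
    "detect_edges",
    "extract_epochs",
]

logger = logging.getLogger(__name__)


@dataclass
class EdgeDetectParams:
    env_rate: float = 100.0
    intermediate_rate: float = 1000.0
    amp_threshold: float = 0.05
    pre_low_ms: float = 400.0
    post_high_ms: float = 1000.0
    jump_window_ms: float = 20.0
    jump_threshold: float = 0.05
    epoch_pre_ms: float = 400.0
    epoch_post_ms: float = 1000.0

    def __post_init__(self) -> None:
        if not (0 < self.amp_threshold < 1 and 0 < self.jump_threshold < 1):
            raise ValueError("thresholds must be in (0, 1)")
        for name in ("pre_low_ms", "post_high_ms", "jump_window_ms", "epoch_pre_ms", "epoch_post_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def epoch_len_ms(self) -> float:
        return self.epoch_pre_ms + self.epoch_post_ms


@dataclass
class EdgeOnset:
    time_s: float
    pre_mean: float
    post_mean: float
    jump: float


@dataclass
class EdgeEpoch:
    onset: EdgeOnset
    samples: np.ndarray
    sample_rate: float


def _resample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    frac = Fraction(fs_out / fs_in).limit_denominator(10_000)
    return sps.resample_poly(x, frac.numerator, frac.denominator)


def detection_envelope(signal: AudioSignal, params: EdgeDetectParams | None = None) -> np.ndarray:
    """Normalised low-rate envelope the detector thresholds.

    Downsample to the intermediate rate (1 kHz), take the wideband Hilbert
    envelope, downsample (anti-aliased) to the envelope rate (100 Hz) and
    min-max scale to [0, 1] over the whole input.
    """
    params = params or EdgeDetectParams()
    x = signal.samples
    if x.ndim != 1:
        raise ValueError("detection_envelope expects mono audio")
    if np.ptp(x) == 0:
        raise ValueError("constant signal: detection envelope undefined")
    if signal.sample_rate != params.intermediate_rate:
        x = _resample(x, signal.sample_rate, params.intermediate_rate)
    env = np.abs(sps.hilbert(x))
    env = _resample(env, params.intermediate_rate, params.env_rate)
    lo, hi = env.min(), env.max()
    if hi == lo:
        raise ValueError("constant signal: detection envelope undefined")
    return (env - lo) / (hi - lo)


def _window_means(env: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """(mean of n samples ending before k, mean of n samples starting at k)."""
    c = np.concatenate([[0.0], np.cumsum(env)])
    k = np.arange(env.size)
    before = np.full(env.size, np.nan)
    after = np.full(env.size, np.nan)
    ok_b = k >= n
    before[ok_b] = (c[k[ok_b]] - c[k[ok_b] - n]) / n
    ok_a = k + n <= env.size
    after[ok_a] = (c[k[ok_a] + n] - c[k[ok_a]]) / n
    return before, after


def detect_edges(
    signal: AudioSignal, params: EdgeDetectParams | None = None
) -> list[EdgeOnset]:
    """Scan the detection envelope for rise-time onsets.

    Returns accepted onsets in increasing time order, pairwise separated by at
    least one epoch length.  An empty list is a valid result.
    """
    params = params or EdgeDetectParams()
    min_len_s = (params.pre_low_ms + params.post_high_ms) / 1000.0
    if signal.duration_s <= min_len_s:
        raise ValueError(f"signal must be longer than {min_len_s} s")
    try:
        env = detection_envelope(signal, params)
    except ValueError:
        return []  # constant signal (e.g. all silence): nothing to detect
    fs = params.env_rate
    n_pre = int(round(params.pre_low_ms / 1000.0 * fs))
    n_post = int(round(params.post_high_ms / 1000.0 * fs))
    n_jump = max(1, int(round(params.jump_window_ms / 1000.0 * fs)))

    pre_mean, _ = _window_means(env, n_pre)
    _, post_mean = _window_means(env, n_post)
    jump_before, jump_after = _window_means(env, n_jump)
    jump = jump_after - jump_before

    with np.errstate(invalid="ignore"):
        candidate = (
            (pre_mean < params.amp_threshold)
            & (post_mean > params.amp_threshold)
            & (jump > params.jump_threshold)
        )
    min_gap = int(round(params.epoch_len_ms / 1000.0 * fs))
    onsets: list[EdgeOnset] = []
    last_k = -min_gap
    for k in np.flatnonzero(candidate):
        if k - last_k < min_gap:
            continue  # same transition or overlapping epoch
        onsets.append(
            EdgeOnset(
                time_s=float(k / fs),
                pre_mean=float(pre_mean[k]),
                post_mean=float(post_mean[k]),
                jump=float(jump[k]),
            )
        )
        last_k = k
    return onsets


def extract_epochs(
    series: np.ndarray,
    sample_rate: float,
    onsets: list[EdgeOnset],
    params: EdgeDetectParams | None = None,
) -> list[EdgeEpoch]:
    """Cut fixed-length windows (−epoch_pre…+epoch_post) around onsets.

    Onsets whose window underruns or overruns the series are skipped with a
    logged warning; each returned epoch has exactly
    round(epoch_len_ms / 1000 × sample_rate) samples with the onset at the
    epoch_pre boundary.
    """
    params = params or EdgeDetectParams()
    series = np.asarray(series)
    n_total = int(round(params.epoch_len_ms / 1000.0 * sample_rate))
    n_pre = int(round(params.epoch_pre_ms / 1000.0 * sample_rate))
    epochs: list[EdgeEpoch] = []
    for onset in onsets:
        k = int(round(onset.time_s * sample_rate))
        start = k - n_pre
        if start < 0 or start + n_total > series.size:
            logger.warning(
                "onset at %.3f s too close to the series boundary; skipped", onset.time_s
            )
            continue
        epochs.append(
            EdgeEpoch(onset=onset, samples=series[start : start + n_total], sample_rate=sample_rate)
        )
    return epochs
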