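"""Synthetic test-signal generators with known ground truth.

Two generators cover the package's two pipelines:

* :func:`make_audio` builds child-directed-speech-like audio — a noise or
  harmonic-complex carrier amplitude-modulated at the ~2 Hz stress and ~5 Hz
  syllable rates — with optional planted silence-then-burst onsets that
  satisfy the edge detector's three conditions by construction.  The exact
  planted onset times are returned as ground truth.

* :func:`make_neural_trials` builds edge-locked neural epochs containing a
  2 Hz (delta) and a 6 Hz (theta) component of specified amplitudes plus
  broadband noise.  Each trial's phase offset to its stimulus-envelope epoch
  is drawn from a von Mises distribution whose concentration is chosen (by
  numerically inverting r = I1(kappa)/I0(kappa)) so the mean resultant length —
  the asymptotic phase-locking value — equals ``phase_lock_r`` exactly.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special
from scipy import signal as sps

from . import neural as neu
from .filterbank import AudioSignal

__all__ = [
    "AudioScenario",
    "NeuralScenario",
    "make_audio",
    "make_neural_trials",
    "make_envelope_epochs",
    "vonmises_kappa",
]

MIN_ONSET_SPACING_S = 2.0
ONSET_SILENCE_S = 0.6  # quiet stretch planted before each onset
ONSET_BURST_S = 1.2  # loud stretch planted after each onset


@dataclass
class AudioScenario:
    duration_s: float = 30.0
    sample_rate: float = 48_000.0
    carrier: str = "noise"  # or "harmonic_complex"
    am_rates: tuple[float, ...] = (2.0, 5.0)  # stress and syllable rates of CDS
    am_depths: tuple[float, ...] = (0.5, 0.5)
    onset_times_s: tuple[float, ...] = ()
    silence_floor: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.silence_floor < 0.02):
            raise ValueError("silence_floor must be below 0.02")
        if len(self.am_rates) != len(self.am_depths):
            raise ValueError("am_rates and am_depths must have equal length")
        onsets = np.sort(np.asarray(self.onset_times_s, dtype=np.float64))
        if onsets.size and np.any(np.diff(onsets) < MIN_ONSET_SPACING_S):
            raise ValueError(
                f"planted onsets must be >= {MIN_ONSET_SPACING_S} s apart "
                "(non-overlapping analysis epochs)"
            )
        self.onset_times_s = tuple(onsets)


@dataclass
class NeuralScenario:
    n_trials: int = 131  # per-condition speech-edge count of the reference study
    sample_rate: float = neu.REFERENCE_RATE
    delta_amp: float = 1.0
    theta_amp: float = 0.5
    phase_lock_r: float = 0.5
    # noise kept low enough (~20 dB in-band SNR) that phase_lock_r remains an
    # accurate ground truth for the measured PLV (the generator's purpose)
    noise_sd: float = 0.3
    delta_hz: float = 2.0
    theta_hz: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.phase_lock_r <= 1.0):
            raise ValueError("phase_lock_r must be in [0, 1]")


def vonmises_kappa(r: float) -> float:
    """Concentration kappa with mean resultant length r = I1(kappa)/I0(kappa)."""
    if r <= 0:
        return 0.0
    if r >= 1:
        return np.inf
    f = lambda k: special.i1e(k) / special.i0e(k) - r
    return float(optimize.brentq(f, 1e-9, 1e4))


def _carrier(kind: str, n: int, sample_rate: float, rng: np.random.Generator) -> np.ndarray:
    if kind == "noise":
        return rng.standard_normal(n)
    if kind == "harmonic_complex":
        # f0 and harmonics up to 4 kHz, CDS-like pitch
        t = np.arange(n) / sample_rate
        f0 = 220.0
        harmonics = np.arange(1, int(4000 // f0) + 1)
        phases = rng.uniform(0, 2 * np.pi, harmonics.size)
        return sum(
            np.sin(2 * np.pi * f0 * h * t + p) / h for h, p in zip(harmonics, phases)
        )
    raise ValueError(f"unknown carrier {kind!r}")


def make_audio(scenario: AudioScenario) -> tuple[AudioSignal, np.ndarray]:
    """CDS-like amplitude-modulated audio with planted edge onsets.

    Returns (signal, ground-truth onset times in seconds).  Before each onset
    the level drops to ``silence_floor`` for 600 ms; after it the full level
    holds for 1200 ms, giving the detector its quiet/loud/jump conditions.
    """
    fs = scenario.sample_rate
    n = int(round(scenario.duration_s * fs))
    rng = np.random.default_rng(scenario.seed)
    t = np.arange(n) / fs

    carrier = _carrier(scenario.carrier, n, fs, rng)
    modulator = np.ones(n)
    for rate, depth in zip(scenario.am_rates, scenario.am_depths):
        modulator += depth * np.sin(2 * np.pi * rate * t + rng.uniform(0, 2 * np.pi))
    modulator = np.clip(modulator, 0.0, None)
    modulator /= max(modulator.max(), 1e-12)

    gate = np.ones(n)
    for onset in scenario.onset_times_s:
        k = int(round(onset * fs))
        k_sil = max(0, k - int(round(ONSET_SILENCE_S * fs)))
        k_end = min(n, k + int(round(ONSET_BURST_S * fs)))
        gate[k_sil:k] = scenario.silence_floor
        gate[k:k_end] = 1.0
    x = carrier * modulator * gate
    if scenario.onset_times_s:
        # hold the burst fully modulated so the post-onset mean stays high
        for onset in scenario.onset_times_s:
            k = int(round(onset * fs))
            k_end = min(n, k + int(round(ONSET_BURST_S * fs)))
            x[k:k_end] = carrier[k:k_end]
    peak = np.max(np.abs(x))
    if peak > 0:
        x = 0.9 * x / peak
    return AudioSignal(x, fs), np.asarray(scenario.onset_times_s, dtype=np.float64)


def make_envelope_epochs(scenario: NeuralScenario) -> np.ndarray:
    """Stimulus-envelope epochs matched to :func:`make_neural_trials`.

    Each epoch carries the same 2 Hz + 6 Hz composition (with trial-specific
    random phases) that the neural trials lock to.
    """
    rng = np.random.default_rng(scenario.seed)
    t = neu.default_time_axis(scenario.sample_rate)
    alpha = rng.uniform(0, 2 * np.pi, scenario.n_trials)
    beta = rng.uniform(0, 2 * np.pi, scenario.n_trials)
    w = scenario.theta_amp / scenario.delta_amp if scenario.delta_amp else 1.0
    env = np.cos(2 * np.pi * scenario.delta_hz * t + alpha[:, None]) + w * np.cos(
        2 * np.pi * scenario.theta_hz * t + beta[:, None]
    )
    return env


def make_neural_trials(
    scenario: NeuralScenario, envelope_epochs: np.ndarray | None = None
) -> neu.TrialSet:
    """Edge-locked neural trials with controlled band power and phase locking.

    Each trial is delta_amp x (2 Hz oscillation) + theta_amp x (6 Hz
    oscillation) + white noise.  Both oscillations are shifted from their
    envelope-epoch counterparts by one common per-trial phase offset drawn
    von Mises with mean resultant length ``phase_lock_r``, so the asymptotic
    PLV of the cohort equals ``phase_lock_r``.
    """
    rng = np.random.default_rng(scenario.seed)
    t = neu.default_time_axis(scenario.sample_rate)
    alpha = rng.uniform(0, 2 * np.pi, scenario.n_trials)  # same stream as envelopes
    beta = rng.uniform(0, 2 * np.pi, scenario.n_trials)
    if envelope_epochs is None:
        w = scenario.theta_amp / scenario.delta_amp if scenario.delta_amp else 1.0
        envelope_epochs = np.cos(
            2 * np.pi * scenario.delta_hz * t + alpha[:, None]
        ) + w * np.cos(2 * np.pi * scenario.theta_hz * t + beta[:, None])

    kappa = vonmises_kappa(scenario.phase_lock_r)
    if np.isinf(kappa):
        psi = np.zeros(scenario.n_trials)
    else:
        psi = rng.vonmises(0.0, kappa, scenario.n_trials) if kappa > 0 else rng.uniform(
            -np.pi, np.pi, scenario.n_trials
        )

    trials = scenario.delta_amp * np.cos(
        2 * np.pi * scenario.delta_hz * t + alpha[:, None] + psi[:, None]
    ) + scenario.theta_amp * np.cos(
        2 * np.pi * scenario.theta_hz * t + beta[:, None] + psi[:, None]
    )
    if scenario.noise_sd > 0:
        noise = scenario.noise_sd * rng.standard_normal(trials.shape)
        # broadband conditioning matching the neural preprocessing band
        sos = sps.butter(2, [0.5, 48.0], btype="bandpass", fs=scenario.sample_rate, output="sos")
        trials = trials + sps.sosfiltfilt(sos, noise, axis=-1)

    onset_times = np.arange(scenario.n_trials) * 4.5  # ~131 edges over 10 min
    return neu.TrialSet(
        trials=trials,
        sample_rate=scenario.sample_rate,
        time_axis=t,
        condition_label=f"synthetic r={scenario.phase_lock_r}",
        stimulus_envelope=envelope_epochs,
        onset_times_s=onset_times,
    )
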