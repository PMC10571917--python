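# speechedge

Envelope modulation enhancement of speech, amplitude rise-time ("speech
edge") detection, and edge-locked neural analysis metrics — as a tested
Python library and command-line tool.

## Who this is for

Researchers in auditory and speech neuroscience who study how cortical
oscillations track the slow amplitude envelope of speech — in particular the
delta (0.5–4 Hz, stress/prosody rate) and theta (4–8 Hz, syllable rate)
bands that carry the rhythm of child-directed speech — and who want to
manipulate that envelope experimentally. Under temporal-sampling accounts of
developmental dyslexia, atypical low-frequency alignment of oscillations to
the envelope, and reduced sensitivity to amplitude rise times, contribute to
phonological deficits; stimuli whose slow modulation and rise times are
*enhanced* are a natural probe.

## What it computes

**Envelope modulation enhancement (EME).** Audio is split by a 28-channel
ERB_N-spaced FIR filter bank (100–7250 Hz, modelling cochlear channels of a
normal-hearing listener). Per channel, the Hilbert envelope is smoothed by a
zero-phase moving average with its −6 dB point at 15 Hz. Each channel gets a
modulation factor

    MF_i = rms(env_i) / max_j rms(env_j)  ∈ (0, 1]

and a dynamic-range-compressed gain: G(MF) = 20 dB for MF < 0.1, falling
linearly to 0 dB at MF = 1. Amplification is suppressed wherever a channel
envelope sits more than 60 dB below its own peak. The gained, peak-normalised
smoothed envelope re-modulates its subband; the channel sum is RMS
loudness-matched to the input. The net effect is selective amplification of
sub-10 Hz envelope modulation and sharper rise times.

**Speech-edge detection.** On a normalised 100 Hz wideband envelope, a sample
is an edge onset when (1) the mean over the preceding 400 ms is < 0.05,
(2) the mean over the following 1000 ms is > 0.05, and (3) the mean over the
20 ms after minus the 20 ms before exceeds 0.05. Epochs of 1400 ms
(−400…+1000 ms) are cut around onsets; overlapping epochs are discarded.

**Edge-locked neural metrics.** For trial-by-time matrices of source activity
(250 Hz) paired with stimulus-envelope epochs: ERP window-averaging with
baseline z-scoring and rectification; the phase-locking value

    PLV(t) = | (1/N) Σ_n exp(i·θ(t, n)) |,   θ = φ_trial − φ_envelope

after 0–8 Hz filtering (Hilbert phases); delta (0–4 Hz) and theta (4–8 Hz)
band power (mean squared analytic amplitude, post-stimulus interval) and the
per-epoch theta/delta power ratio.

**Statistics.** Monte-Carlo label-permutation two-sample t-tests (5000 draws,
automatic exhaustive enumeration for small groups), Benjamini–Hochberg FDR,
one-tailed paired baseline contrasts, and 3-scaled-MAD outlier replacement
with linear interpolation.

**Synthetic ground truth.** `speechedge.synth` generates child-directed-
speech-like audio (2 + 5 Hz AM, plantable silence-then-burst onsets) and
neural cohorts with specified delta/theta amplitudes and a von Mises phase
offset whose mean resultant length sets the true phase locking — so every
stage of both pipelines is testable against known answers.

## Worked example

```python
import numpy as np
import speechedge as se
from speechedge.synth import AudioScenario, NeuralScenario, make_audio, make_neural_trials

# --- audio pipeline: enhance CDS-like audio and find its edges
sig, truth = make_audio(AudioScenario(
    duration_s=25, sample_rate=16_000, onset_times_s=(3.0, 6.5, 10.0, 14.0, 19.0), seed=1))
enhanced = se.enhance(sig)

print("modulation power 0.5-10 Hz:",
      round(se.band_modulation_power(sig), 3), "->",
      round(se.band_modulation_power(enhanced.audio), 3))
print("detected onsets:", [round(o.time_s, 2) for o in se.detect_edges(sig)])

# --- neural pipeline: cohort with known phase locking and band powers
trials = make_neural_trials(NeuralScenario(phase_lock_r=0.5, seed=0))
print("mean PLV:", round(se.plv(trials).mean_plv, 3))
print("theta/delta ratio:", round(se.theta_delta_ratio(trials).mean_ratio, 3))
```

Output:

```
modulation power 0.5-10 Hz: 0.178 -> 0.232
detected onsets: [2.99, 6.49, 9.99, 13.99, 18.99]
mean PLV: 0.438
theta/delta ratio: 0.249
```

Enhancement raised the fraction of envelope power in the 0.5–10 Hz
modulation band from 0.18 to 0.23; all five planted onsets were recovered
within 10 ms; the measured phase locking matches the generated resultant
length 0.5 within single-cohort sampling error (averaging over seeds
converges to 0.49, see the test suite); and the theta/delta ratio matches
the generated amplitude pair (1.0, 0.5) → 0.5² = 0.25.

The same pipelines are available from the shell:

```sh
speechedge enhance in.wav out.wav --mode envelope_multiply --max-gain-db 20
speechedge edges in.wav --out edges.csv --labels edges.txt
speechedge modspec in.wav out.wav --out modspec.csv
speechedge synth neural --out cohort --seed 7
speechedge analyze --trials cohort --out metrics.csv
```

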