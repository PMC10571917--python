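# Methods

This note documents the models and procedures `speechedge` implements, the
parameters that matter, the numerical conventions, and what the synthetic
generators do and do not emulate.

## Cochlear-model filter bank

The analysis bank covers 100–7250 Hz with band edges uniformly spaced on the
ERB_N-number scale, E(f) = 21.4·log10(4.37·f/kHz + 1), approximating equal
cochlear-filter widths in a normal-hearing listener at moderate level. The
default span corresponds to ≈29.0 ERB_N units; the channel count is fixed at
28 (≈1.04 ERB per channel) rather than forced to unit-ERB width, so the
default bank always has exactly 28 channels. Channel centres are the ERB-scale
midpoints of their edges.

Filters are linear-phase windowed-sinc (Hamming) band-passes, 4097 taps at
the 48 kHz reference rate and scaled proportionally (kept odd) at other
rates, so every channel has the same integer group delay, removed exactly by
shifting. `firwin` places the half-amplitude point at each band edge, giving
adjacent channels a −6 dB crossover; because the filters are in phase, the
channel sum is flat within ±3 dB over 150–7000 Hz and the analyze/synthesize
round trip preserves band-limited energy within 10% (both are tested). The
lowest channel is only ≈39 Hz wide — comparable to the filter transition
width — so per-channel selectivity is poorest there; the summation property
is unaffected.

Stereo input is downmixed by averaging before analysis.

## Envelopes and the modulation spectrum

Channel envelopes are analytic-signal moduli. For enhancement they are
smoothed by a single-pass, zero-phase (centred) moving average whose length
is solved so the first −6 dB point lands at 15 Hz (1931 taps at 48 kHz, from
|sin(πfN/fs)/(N·sin(πf/fs))| = 1/2). DC gain is exactly 1 and response at
≤4 Hz stays above −3 dB, so the delta and theta modulation ranges pass
essentially untouched while pitch-rate fluctuation is removed. A single pass
is used deliberately: repeated passes would move the cutoff.

The modulation spectrum is the Welch PSD (Hann, 30 s segments, 50% overlap by
default; the segment length is a parameter) of the mean-removed wideband
Hilbert envelope, computed after decimating the envelope to 250 Hz — the
spectrum is only evaluated on a 0.1–40 Hz grid, where decimation is
transparent and removes a ~200× cost at 48 kHz. With normalization on, the
PSD is divided by the total envelope power (DC included), making it a
dimensionless modulation-depth density: invariant to amplitude scaling and
directly comparable between loudness-matched signals. The integrated
0.5–10 Hz band fraction is the scalar used to compare enhanced versus natural
audio. The wideband envelope (not the sum of subband envelopes) is used
throughout.

## Envelope modulation enhancement

Per processing section (default 60 s, padded with 500 ms of silence at each
end that is stripped afterwards):

1. analyze into 28 subbands; Hilbert envelopes; 15 Hz smoothing;
2. modulation factor MF_i = rms(env_i)/max_j rms(env_j), computed on the
   smoothed envelope as stored (DC included). Ties at the maximum all get
   MF = 1; silent channels get MF = 0;
3. channel gain G(MF): `max_gain_db` (20 dB) below the knee (0.1), then
   linear in MF down to 0 dB at MF = 1 — continuous and monotone;
4. noise-floor restriction: wherever a channel envelope is more than 60 dB
   below *that channel's own* envelope peak within the section, the gain
   reverts to 0 dB (the reference is per-channel peak because no absolute
   calibration exists);
5. re-modulation. Default mode `envelope_multiply`: per-sample multiplier =
   linear gain × (smoothed envelope / channel envelope peak). Multiplying a
   subband by its own normalised envelope squares the modulation depth, which
   is what actually amplifies <10 Hz envelope modulation; this mode
   reproduces the enhanced-greater-than-natural modulation-spectrum direction
   and is the default. `gain_only` (scalar gain per channel) is provided for
   comparison but does not deepen slow modulation;
6. channel sum, then a single broadband RMS scale factor matching the input's
   RMS. This replaces a perceptual loudness model deliberately: it is exactly
   testable and preserves the intent (equal-loudness comparison). Enhanced
   peaks may exceed |1| after RMS matching; output WAV is written as float32,
   which represents such peaks without clipping (players should apply their
   own headroom).

Degenerate inputs: all-silent sections pass through as silence (modulation
factors are undefined there); an all-silent file is rejected by the CLI. A
constant-envelope input (e.g. a faded pure tone) takes the 0 dB gain path and
is returned unchanged up to RMS matching; a second application changes the
result by <1% away from the fades, which is the practical idempotence of the
degenerate case. A switched-on tone is *not* such a case: its onset click is
a genuine broadband rise time and is amplified by design.

## Speech-edge detection

The detection envelope is computed by resampling to 1 kHz, taking the
wideband Hilbert envelope, resampling (anti-aliased) to 100 Hz, and min-max
scaling to [0, 1] over the whole input (per-file normalisation; the detector
is therefore invariant to global amplitude scaling). A sample k is an onset
when the mean over the 400 ms window ending at (and excluding) k is below
0.05, the mean over the 1000 ms window starting at (and including) k is above
0.05, and the 20 ms-after minus 20 ms-before means differ by more than 0.05.
The window anchoring (pre-window excludes, post-window includes the onset
sample) is a convention; the thresholds are in normalised envelope units.

Candidates are scanned left to right; the first qualifying sample of a rising
transition is kept and any candidate within 1400 ms (one epoch length) of an
accepted onset is discarded, which both suppresses duplicate candidates on
the same rise and enforces non-overlapping epochs. Epochs are cut as
round(1.4 s × rate) samples with the onset at the 400 ms boundary; onsets too
close to either end of the series are skipped with a logged warning. Manual
verification is replaced by this deterministic rule plus an optional
Audacity-style label export for review.

On synthetic audio with planted onsets (≥2 s spacing, silence floor < 0.02)
recall is 1.0 with ≤20 ms timing error at the 100 Hz envelope resolution;
silence and stationary noise yield zero detections (tested).

## Edge-locked neural metrics

Trials are (n_trials × n_samples) matrices at 250 Hz spanning −400…+1000 ms
(inclusive endpoints, 351 samples) with optional matched stimulus-envelope
epochs. Broadband conditioning (0.5–48 Hz) is the generator's job; the
metrics assume conditioned input.

*ERP pipeline*: trials are grouped by their original onset times into
consecutive 60 s bins, averaged per bin, z-scored against the mean/SD of the
averaged trace's pre-stimulus interval (−400…0 ms), and rectified. Ten
minutes of listening therefore yields 10 traces. Zero baseline variance is an
error, not a silent division.

*Band filtering*: zero-phase order-4 Butterworth run forward-backward
(low-pass for bands starting at 0 Hz: delta = 0–4 Hz low-pass, theta = 4–8 Hz
band-pass, PLV band = 0–8 Hz low-pass; cut-offs are arguments). Order 4 keeps
mid-band components essentially unattenuated (<1% amplitude at half the
cut-off), which an order-2 design does not (−12% power at 2 Hz) — band-power
recovery fixed the order. Two short-epoch precautions matter at 1.4 s: the
forward-backward pass uses a generous odd-extension pad (150 samples), and
the analytic modulus for band power is computed on a mirror-extended epoch
and cropped, removing the amplitude droop the FFT Hilbert transform otherwise
produces at epoch boundaries. Band power is the mean squared analytic modulus
over the post-stimulus interval (0–1 s), per trial; units are arbitrary
(squared source amplitude), so only ratios and comparisons are meaningful.
The theta/delta ratio is formed per epoch and summarised by the mean; zero
delta power raises an error naming the trial.

*PLV*: instantaneous phases of band-filtered trial and envelope epochs via
the Hilbert transform; PLV(t) = |mean over trials of exp(i·(φ₁−φ₂))|;
`mean_plv` is the time average over the full epoch. PLV estimates on short
noisy epochs carry a small downward bias (noise phase jitter, epoch-edge
phase error that no longer cancels between trial and envelope when noise is
present); at the generator's default noise level this attenuation is below
3% of the true resultant length, and recovery of r ∈ {0.2, 0.5, 0.8} at
N = 131 is within ±0.05 (tested over 100 seeds).

## Statistics

*Permutation t-test*: two-sided pooled-variance two-sample t per feature;
group labels permuted 5000 times by default (Monte Carlo, seeded); p =
(1 + #{|t*| ≥ |t|})/(1 + n) with the add-one rule so p ≥ 1/(n+1). When the
number of label arrangements does not exceed the requested permutations, all
arrangements are enumerated and p = count/total is exact. Features with zero
pooled variance get p = 1 with a warning. Sidedness: two-sided for group
contrasts; the ERP baseline contrast is the only one-tailed test (post >
baseline, paired), with a constant positive shift returning t = +∞ and the
numeric p floor.

*FDR*: Benjamini–Hochberg step-up at q = 0.05 (statsmodels backend); verified
in the tests against a brute-force search over all rejection prefixes of the
sorted p-values.

*Outlier replacement*: values more than 3 × 1.4826 × MAD from the median are
replaced by linear interpolation between the nearest unflagged neighbours
(edge outliers take the nearest unflagged value). The 1.4826 constant makes
the MAD consistent with a normal SD. One pass only; re-applying can flip
samples that straddle the threshold because replacement shifts the
median/MAD slightly — the operation is idempotent only when the inlier bulk
sits clear of the threshold.

## Synthetic generators

`make_audio` emulates child-directed speech's temporal structure: a noise or
harmonic-complex carrier amplitude-modulated at 2 Hz (stress rate) and 5 Hz
(syllable rate), depth 0.5 each by default, at a 48 kHz default rate. Planted
onsets insert 600 ms at the silence floor (default 0.01) followed by a
1200 ms full-level burst, satisfying the edge detector's three conditions by
construction with ≥2 s spacing. It does **not** emulate spectral tilt,
phonetic content, pitch contours, reverberation, or recording noise — so
passing tests demonstrate the algorithms' contracts on controlled modulation
structure, not performance on natural recordings.

`make_neural_trials` builds 131-trial cohorts (matching a typical
per-condition edge count) at 250 Hz: each trial is delta_amp × 2 Hz
oscillation + theta_amp × 6 Hz oscillation + white noise band-passed to
0.5–48 Hz. Both oscillations are shifted from their envelope-epoch
counterparts by one common per-trial phase offset drawn von Mises with
concentration κ obtained by numerically inverting r = I₁(κ)/I₀(κ), so the
cohort's asymptotic PLV equals `phase_lock_r` exactly; because trial and
envelope component amplitudes are proportional, the noise-free phase
difference is exactly the drawn offset. Defaults delta_amp = 1, theta_amp =
0.5 (theta/delta power ratio 0.25, between the natural-speech ≈0.33 and
enhanced-speech ≈0.17 regimes of interest), noise_sd = 0.3 (~20 dB in-band
SNR, low enough that phase_lock_r remains an accurate ground truth — the
generator's purpose). It does not simulate MEG sensor physics, source
leakage, 1/f background spectra, or inter-subject variability.

All generators are bit-reproducible under a fixed seed.

## Problem sizes and evaluation conventions

The test suite and examples run audio at 16 kHz and 25–60 s duration — fully
faithful to the algorithms, whose analysis band ends at 7250 Hz, and an order
of magnitude cheaper than the 48 kHz reference rate, which remains the
generator and filter-design default. Stochastic calibration checks use 500
null simulations (permutation type-I error), 100 seeds × 131 trials (PLV
recovery), and 1000 random p-vectors (FDR versus brute force).

## Known limitations

- RMS loudness matching is not a perceptual loudness model; enhanced files
  may sound slightly louder or quieter than level-matched originals.
- The exact band-edge table of the original 28-channel bank is not published;
  uniform ERB-number spacing over the stated span is a stated convention.
- The lowest filter-bank channel is under-resolved relative to the FIR
  transition width (see above).
- PLV on 1.4 s epochs has a small noise-dependent downward bias; comparisons
  between conditions at equal noise are unaffected, absolute values should
  not be over-interpreted.
- Enhancement is offline, per section; no streaming or real-time support.
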