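# Methods

`coughcount` implements an automatic cough-frequency counter for long
bedside audio recordings. This note documents the model, the defaults and
why they were chosen, the numerical decisions, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Problem and processing model

Cough frequency — the number of cough events per minute — is a clinically
useful index of respiratory state. The input is a long mono recording
(tens of minutes) captured near the patient's mouth in an ordinary room,
so it contains speech, impacts (objects hitting surfaces), and background
noise alongside coughs. The pipeline is:

1. **Wavelet-threshold denoising.** The signal is decomposed with an
   orthogonal `sym8` wavelet to 3 levels. Each detail band is thresholded
   (hard thresholding by default: coefficients below threshold are set to
   zero); the approximation band is untouched; the signal is
   reconstructed. Useful transients concentrate in few large coefficients
   while broadband noise spreads thinly, so thresholding removes noise
   while preserving cough onsets. The per-level threshold is the
   universal threshold `sigma_hat * sqrt(2 ln n)` with `sigma_hat`
   estimated as MAD/0.6745 of the finest detail band — the standard
   completion when only "a threshold per layer" is prescribed.
2. **Coarse segmentation.** The session is cut into fixed 20-s chunks;
   the last chunk is zero-padded. All later stages work per chunk, which
   bounds memory and makes the per-minute count a sum of three chunk
   counts.
3. **Dual-threshold endpoint detection.** Per 25-ms frame (10-ms hop) the
   short-time energy `E = sum x(m)^2` and zero-crossing rate
   `Z = (1/2) sum |sgn x(m) - sgn x(m-1)|` are computed. A candidate
   segment is seeded where `E` exceeds a high threshold, extended over
   the surrounding run where `E` stays above a low threshold, then
   extended outward while `Z` exceeds its threshold (bounded, see below).
   Nearby segments are merged. Two cough-specific gates follow: duration
   within [0.15 s, 1.2 s] (a cough is a short explosive event) and peak
   frame energy at least a multiple of the chunk's median (the explosive
   onset), which suppresses weak tails such as post-cough wheezes that
   would double-count.
4. **Segment features.** Each surviving candidate is described by 17
   numbers: mean amplitude, mean and max frame ZCR, mean and max frame
   energy, and the 12 per-frame mel-frequency cepstral coefficients
   (MFCC 1–12) averaged over the segment. Optionally 13 mean linear
   predictive cepstral coefficients (LPCC) extend the vector to 30.
5. **SVM recognition.** An RBF-kernel support vector machine (C=1,
   gamma = 1/(d·var), per-column z-scoring fitted on training folds only)
   labels each candidate Cough or Noise.
6. **Counting.** Per-chunk cough counts `N_i` are summed in consecutive
   triples: `F_C(j) = N_(3j+1) + N_(3j+2) + N_(3j+3)`. A trailing 1–2
   chunk remainder is reported as a partial minute, never padded into a
   fake full minute.

## Key parameters

| Parameter | Default | Unit | Rationale |
| --- | --- | --- | --- |
| sample rate | 8000 | Hz | cough energy spans ~30 Hz–4 kHz; 8 kHz Nyquist suffices and keeps portable-device cost low |
| wavelet / levels | sym8 / 3 | — | fixed by the method |
| threshold mode | hard | — | "set sub-threshold coefficients to zero" is hard thresholding; soft available |
| frame / hop | 25 / 10 | ms | conventional short-time analysis sizes; nothing in the method fixes them |
| energy_high_scale | 8 | × median frame energy | seeds segments well above the floor; median adapts to recorder gain |
| energy_low_scale | 2 | × median | extension threshold; must sit above floor fluctuation |
| zcr gate | max(10, 1.2 × median frame ZCR) | crossings/frame | see "bounded ZCR extension" below |
| duration gate | 0.15–1.2 | s | three-phase cough structure: burst + decaying body (+ optional second burst) |
| min_max_energy_scale | 15 | × median | explosive-onset requirement |
| merge gap | 0.12 | s | keeps one cough's onset and body (and its second burst) as one segment |
| mel scale | 1125·ln(1+f/700) | mel | natural-log form of the standard warping |
| filterbank | M=26, 30–4000 Hz, FFT 512 | — | covers the cough band; M, FFT size are free choices |
| LPC order / LPCC dim | 12 / 13 | — | 13 cepstral terms exercise both branches of the recursion past order p |
| SVM | RBF, C=1, gamma=scale | — | no kernel is prescribed; exposed in config |

All of these are configurable through YAML (`denoise.*`, `frames.*`,
`endpoint.*`, `cepstral.*`, `classifier.*`); unknown keys are rejected.

## Numerical and design decisions

- **Mean amplitude averages |x|.** Averaging signed samples is ≈ 0 for
  any zero-mean audio and useless as a loudness feature; the absolute
  value realizes the intended "sound intensity" reading.
- **sgn(0) := +1** in the ZCR so exact zeros cannot double-count
  crossings; the ZCR is then integer-valued and bounded by frame_len − 1.
- **Bounded ZCR extension.** The crossing rate of a noise floor depends
  on its bandwidth, not its amplitude, so a fixed "extend while ZCR > 10"
  rule would extend every segment indefinitely through any wideband
  floor. Extension is therefore (a) gated by an adaptive threshold
  `max(10, 1.2 × median frame ZCR)` and (b) capped at 0.10 s outward —
  the classical bounded form of the two-stage detector.
- **Padding excluded from statistics.** The zero-padded region of the
  final chunk is excluded from the median-energy/ZCR reference so it
  cannot bias adaptive thresholds down.
- **DWT boundary mode is periodization** by default: with an orthogonal
  wavelet the transform is orthonormal, so thresholding can only remove
  energy (output energy ≤ input energy exactly, asserted in tests) and
  zero-threshold reconstruction is the identity to machine precision.
  Symmetric extension is available when boundary artifacts matter more
  than exact energy accounting.
- **MFCC DCT indexing.** The DCT kernel is
  `cos(pi n (2m-1)/(2M))` over filters m = 1..M with the `sqrt(2/M)`
  scale, which annihilates constant log-energy profiles for every n ≥ 1
  (silence maps to the zero vector). MFCC 0 is omitted — it duplicates
  the energy feature. Filter center bins are rounded to integers so each
  triangle peaks at exactly 1 and adjacent responses sum to exactly 1
  between centers.
- **LPC sign convention** is `x(n) ≈ sum a_i x(n-i)` (autocorrelation
  method, Toeplitz solve with a 1e-9 ridge); the LPCC recursion is then
  the cepstrum of `1/(1 - sum a_i z^-i)`, e.g. a single pole a gives
  `c(n) = a^n / n`. All-zero frames return a zero vector with a
  degenerate flag instead of failing.
- **log floor 1e-10** on filterbank energies keeps silence finite.
- **Zero-denominator metrics are NaN**, never 0: a silent zero would
  corrupt comparisons between feature combinations.
- **Cohen's kappa** is computed from the confusion marginals
  (`p_o = ACC`, `p_e` from marginal products).
- **Evaluation protocol** is pooled stratified 5-fold cross-validation
  with a fixed seed: each segment is scored once by a model that never
  saw it, and standardization is refit inside every training fold.
- **Training data comes through the pipeline.** The classifier is
  trained on candidates extracted by the same denoise → detect →
  constrain path it will see at inference (`candidate_dataset`), labelled
  by ≥ 50% overlap with true cough events. Training on isolated clean
  clips measurably degrades end-to-end counting, because denoising and
  segment-boundary effects shift the feature distribution.
- **Event matching for scoring** uses ≥ 50% overlap of the true event's
  duration; the per-minute counting error is `|F_C − true count|` over
  the same three chunks.

## The synthetic-data generator

There is no public corpus of bedside cough recordings, so the generator
emulates the class signatures the detector and classifier actually sense:

- **cough**: 30 Hz–4 kHz band-limited noise with a three-phase envelope —
  0.08 s onset burst (fast attack to peak gain 1.0), 0.35 s body decaying
  exponentially to 35% (gain 0.8), and with probability 0.5 a weaker
  (gain 0.45) 0.12 s second burst after a 0.04 s gap. Durations sit
  inside the detector's duration gate by construction, mirroring how the
  gate was designed around real cough durations.
- **speech**: a six-harmonic stack on a 120–220 Hz fundamental with slow
  AM, at low level (peak frame energy far below a cough's).
- **impact**: a strictly positive low-frequency damped oscillation —
  cough-like energy but near-zero ZCR, so it passes the energy stage and
  must be rejected by the classifier.
- **background**: slowly ramping low-amplitude wideband noise.

Events are placed uniformly at random without overlap over a wideband
noise floor. The session SNR (mean event power over floor power)
defaults to 15 dB — a quiet room with clearly audible floor. Everything
is reproducible bit-for-bit from one seed.

What the generator does **not** emulate: reverberation, overlapping
events, other people's coughs at a distance, recorder nonlinearity and
automatic gain control, sneezes/throat clears (near-cough confusers), and
the within-patient correlation of real cough timbre. Passing tests
therefore demonstrate that the implementation is faithful and that the
method separates the idealized class signatures; they do not certify the
clinical accuracy figures reachable on real patient data, where published
results of this method family are ~93% accuracy and ~0.5 counting error
per minute.

Default benchmark sizes (chosen for a single-CPU run, and the same
conditions the acceptance script uses): 400-segment isolated-event
benchmark, 25 annotated training sessions of 60 s, 100 sessions for
endpoint recovery, 20 sessions for end-to-end counting.

## Known limitations

- Coughs that straddle a 20-s chunk boundary can be split and missed by
  the duration gate; overlap-aware chunking is deliberately not
  implemented.
- The adaptive energy thresholds assume coughs are sparse within a chunk
  (median ≈ floor); a chunk that is mostly coughing raises the floor
  estimate and can suppress detections.
- The reference-free SNR proxy (silent-frame based) is an operational
  figure for before/after comparison only.
- Loudness-based discrimination of the patient's own cough from a
  neighbour's is out of scope.
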