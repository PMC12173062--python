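# Methods

`broilervox` implements a desk-scale, fully testable version of an acoustic
monitoring chain for broiler-chicken vocalizations: seeded synthetic
soundscapes with exact ground truth stand in for farm recordings, and every
downstream stage — preprocessing, recognition, duration quantification, and
the treatment/time-of-day statistics — operates exactly as it would on real
audio. This note records the models, the defaults and why they were chosen,
and what the synthetic conditions do and do not demonstrate.

## Synthetic calls and soundscapes

Five call classes are generated. Each call is a harmonic tone (fundamental
plus two overtones at −6 and −12 dB, overtones above Nyquist dropped) with
a raised-cosine attack/decay envelope and an instantaneous fundamental that
follows the class's contour:

| type | contour | band (day-1 anchor) | duration | level |
|------|---------|---------------------|----------|-------|
| DC (distress call) | descending, 2–4 syllables | 3.4–4.0 → 2.6–3.2 kHz | 0.2–0.5 s/syllable, 50 ms gaps | +10 dB |
| SP (short peep) | descending | 3.3–3.7 → 2.3–2.7 kHz | 0.10–0.30 s | 0 dB |
| W (warble) | bow (arch, +15% excursion), 1–2 syllables | 1.0–1.6 kHz | 0.3–0.8 s | −6 dB |
| PN (pleasure note) | ascending | 2.8–3.2 → 3.5–3.85 kHz | 0.10–0.25 s | −6 dB |
| OV (other) | random monotone sweeps | mid-band gap ~1.9–2.4 kHz | 0.2–0.5 s | −3 dB |

Rationale for the non-obvious choices:

* **Durations are commensurate with the 240 ms prediction frame.** The
  duration quantifier counts 240 ms frames, so calls much shorter than half
  a frame are structurally invisible to it: a frame is (correctly) labeled
  with a call type only when the call covers at least half the frame
  (120 ms), which makes the frame-count estimator unbiased in expectation
  for calls longer than 120 ms and blind to shorter ones. SP and PN lower
  bounds are therefore set at 100 ms rather than tens of milliseconds;
  with these defaults the expected quantization bias per type is below
  ~10%. This is a property of any frame-quantized duration estimator, not
  of the classifier.
* **OV is necessarily arbitrary** — the class is defined as "everything
  else" and has no canonical acoustic description. Its generator draws
  random monotone sweeps confined to the spectral gap between the warble
  band (bow tops < 1.9 kHz) and the high-band sweep region used by
  SP/DC/PN (≥ 2.3 kHz). Early variants that let OV share W's band or bow in
  the high band produced classes that were *by construction*
  indistinguishable at the 240 ms scale; keeping the catch-all outside the
  named envelopes is what makes it a learnable class at all.
* **Age–pitch model**: fundamental frequencies are multiplied by
  `0.6 ** ((age_days − 1) / 41)` — log-linear from 1.0 at day 1 to 0.6 at
  day 42, monotonically non-increasing. The downward drift is
  well-established; its magnitude here is a package choice and is verified
  by a self-consistency test (measured median F0 ratio within 5%).
* **Event process**: each type is an independent inhomogeneous Poisson
  process realized by thinning at the peak intensity; the intensity at
  clock hour *h* is `rate(h) / 60 / E[duration]` so the expected active
  seconds per minute equals the configured profile. Events not fully inside
  the soundscape are discarded (edge deficit < E[duration]/T). A greedy
  non-overlap mode keeps only events that do not collide, for oracle tests
  and clean recovery studies.
* **Diurnal profiles** are piecewise-constant per clock hour. The bundled
  `demo_diurnal_profile` encodes the field-reported orderings (SP peaks in
  the evening and dips at night, DC peaks at midday, W is nocturnal, PN is
  highest at night/morning) with magnitudes scaled up from farm-reported
  W/PN values (which are fractions of a second per minute) so every type is
  measurable in minutes-long simulations. The 18L:6D photoperiod's dark
  intervals (22–23 h, 0–4 h, 5–6 h) are carried as profile metadata.
* **SNR** is defined as mean per-call RMS over background RMS in the
  500 Hz–8 kHz analysis band. Backgrounds: white, pink (1/f), or "fan"
  (120 Hz hum + harmonics over low-passed rumble).

Ground truth contains the event list, exact per-minute active seconds per
type (event–minute overlap), and one label per 240 ms frame (dominant type
if it covers ≥ half the frame, else background).

## Acoustic front end

1. Polyphase resampling to 8 kHz (Kaiser-windowed anti-aliasing,
   `padtype="line"` so constant signals pass through).
2. 5th-order Butterworth high-pass at 500 Hz, applied forward–backward
   (zero phase) so call onsets are not smeared across 240 ms frame
   boundaries; the dB attenuation therefore doubles relative to the
   analytic one-pass magnitude, which tests use as the reference curve.
3. Spectral gating: STFT with a 25 ms Hann window and 50% overlap; the
   per-band noise floor is the rolling 80th-percentile magnitude over ~3 s
   blocks (linearly interpolated); cells below floor + 6 dB are attenuated
   by up to 20 dB through a soft mask (3 dB ramp) smoothed over a 3×3
   time–frequency neighbourhood (the raw mask wins where it is fully open,
   so signal cells are never shaved by smoothing). The 80th percentile is
   the estimator's breakdown point: transient calls occupying < 20% of a
   3 s block leave the floor unaffected, while stationary noise — including
   persistent narrowband hum, deliberately — sits below the gate and is
   suppressed. A tone lasting the whole estimation window is statistically
   indistinguishable from narrowband stationary noise and is treated as
   such.
4. Log-mel spectrogram: 64 triangular HTK-mel filters from 50 Hz to the
   top of the band (clamped to Nyquist — the nominal 8 kHz band top exceeds
   the 4 kHz Nyquist of the 8 kHz working rate; the discrepancy is
   documented, not resolved), 100 frames/s (25 ms window, 10 ms hop,
   left-aligned grid so a 60 s segment gives exactly 6000 frames),
   compression `log(x + 1e-10)`.

## Recognizer

A fully-convolutional network maps the spectrogram to one prediction per
240 ms: eleven 3×3 2-D convolutions in four blocks (widths 16/48/112/224,
three + three + three + two layers), batch-norm + ReLU, with the leading
layer of each block striding time by (2, 2, 2, 3) — product 24 frames =
240 ms — and mel by 2; a frequency mean-pool then a kernel-3 1-D
convolution emits 7 channels per step: six class logits (softmax, rows sum
to 1) and a softplus age estimate in days (auxiliary target, L1 loss,
weight 0.1, exploiting the age-dependent pitch shift). The width plan puts
the trainable-parameter count at 1,012,327, inside the enforced
[0.96 M, 1.44 M] build-time contract band. Inputs are cropped to a
multiple of 24 frames so a raster has exactly `floor(frames/24)` rows.

The layers are a from-scratch numpy implementation with manual
backpropagation (im2col convolutions, standard batch-norm backward, Adam);
gradients are finite-difference-checked in the test suite, and inference
is a pure function of (parameters, input).

Training: cross-entropy with tempered (square-root) inverse-frequency
class weights — background dominates any realistic soundscape, but fully
inverse weights make background errors so cheap that rare-call false
alarms become confident; the square root is a compromise verified by the
recovery study. Steps whose dominant-call coverage falls in (0, 0.18) s
get a 3× loss weight so the half-frame labeling boundary is learned
sharply from both sides (these partial frames are exactly where a duration
estimator gains or loses its calibration). Two-phase schedule: a brief
head-only warm-up (15% of epochs), then all layers at half the learning
rate. Everything is seeded; identical seeds and data give identical
losses on a fixed machine.

Training data are sliced from seeded one-minute soundscapes at 20 dB SNR
with a busy constant profile (8 s/min per type, overlap allowed) and
random ages in 5–35 days, 2.4 s clips, labels from exact ground truth.
The reference configuration used by the test suite trains on 20 minutes of
audio for 21 epochs (≈ 7 minutes on one CPU); the acceptance script uses a
scaled-down 12 minutes / 12 epochs.

## Quantification

Rows with a class score ≥ 0.7 (inclusive — at float resolution the choice
is immaterial but it is pinned for the oracle tests) are counted per
wall-clock minute and multiplied by 0.24 s. Row normalization plus a
threshold above 0.5 make co-exceedance impossible, so per-minute type
totals never exceed 60 s. Minutes average into hourly means (recorded
minutes only; empty hours are missing, never zero, which would bias
diurnal means); hours map to night [22, 4), morning [4, 10), midday
[10, 16), evening [16, 22) (half-open bins); ages map to starter (0–9),
grower (10–22), finisher (23–41) days — the finisher boundary follows the
feed-phase definition (23–41) where captions disagree at day 22.

## Statistics

Binned durations are modeled per sound type with fixed effects for
treatment(s) and time-of-day bin plus their interaction, and random
intercepts for pen (the experimental unit; microphones are nested within
pens, either kept as repeated measures or averaged to pen level via
`aggregate_microphones`) and compartment (variance component). Estimation
is REML (statsmodels MixedLM). Omnibus F tests use containment
(split-plot) denominator degrees of freedom — between-pen effects against
the between-pen stratum, within-pen effects against the residual stratum —
which is exact for balanced designs and was preferred over an approximate
Satterthwaite implementation; the type-I simulation verifies the
calibration (5% ± MC error at α = 0.05). Non-significant interactions
(p ≥ 0.05) are pruned and the model refit. Pairwise comparisons use the
studentized range on estimated marginal means (for independent groups,
`tukey_hsd` wraps the exact scipy implementation), with an
insert-and-absorb compact letter display that is reconstructible from the
p-value matrix. Diagnostics (studentized residuals > 3, Shapiro normality
p) are reported, never auto-acted on. A singular or non-converging mixed
fit falls back to OLS with a logged warning. Zero-variance responses
short-circuit to an all-ones p-value report rather than dividing 0/0.

THI: the poultry formula cited in the source literature is not printed
there, so the default is an explicit stand-in,
`THI = 0.85·T_db + 0.15·T_wb` with the Stull (2011) wet-bulb
approximation, kept behind a registry (`THI_FORMULAS`) together with a
0.6/0.4 variant; both are monotone in temperature and produce values on
the observed 18–29 scale. The THI ANOVA is a full-factorial OLS
(treatment × round × time-of-day) with type-II sums of squares, a rank
check that names aliased terms, and Tukey post-hocs on significant
factors.

## Problem sizes and what passing shows

The test suite trains one shared recognizer (20 min audio / 21 epochs) and
evaluates: held-out balanced accuracy, duration recovery on a 60-minute
high-SNR (30 dB) non-overlapping soundscape with sinusoidally modulated
rates (Pearson r ≥ 0.9 and MAE ≤ 20% of the true mean per type), diurnal
rank recovery over a synthetic day, a 1000-replicate null calibration of
the duration model, and 100-seed rate fidelity of the simulator. The
acceptance script recomputes the same quantities at reduced sizes
(12 min/12 epochs training, 30-minute recovery, 400 null replicates).

Synthetic soundscapes emulate the *statistical* structure the analysis
assumes — contour/band/level/duration signatures, diurnal Poisson rates,
age-dependent pitch, stationary-ish backgrounds — not the full acoustics
of a farm: no reverberation, no flock chorus babble, no wind/machinery
transients, no microphone variation, and call types are acoustically
cleaner and more separable than real vocalizations. Passing therefore
demonstrates that the pipeline's machinery is correct and well calibrated
(frame arithmetic, normalization, estimator unbiasedness, statistical
error rates), not that the trained recognizer would reach comparable
accuracy on farm recordings.

## Known limitations

* The recognizer is trained and evaluated on the same generative family;
  domain transfer to real audio is out of scope.
* Calls shorter than 120 ms are invisible to the 240 ms frame-count
  estimator by construction.
* A constant tone spanning the whole gating window is suppressed as
  background (by design, but it means sustained monotone calls would be
  attenuated).
* The mixed model's containment df are exact only for balanced designs;
  heavily unbalanced observational tables would need a Satterthwaite or
  Kenward–Roger refinement.
* CPU training at desk scale (minutes of audio) leaves run-to-run variance
  of a few percentage points in per-class recall across seeds.
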