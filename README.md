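# broilervox

Acoustic monitoring of broiler-chicken vocalizations, end to end and fully
testable on a desk: seeded synthetic soundscapes with exact ground truth, an
8 kHz log-mel acoustic front end, a fully-convolutional call recognizer with
one prediction every 240 ms, threshold-based duration quantification in
seconds per minute, and the diurnal/treatment statistics used to analyze
the results.

Broiler flocks produce four well-characterized call types — distress calls
(DC, repetitive and high-intensity), short peeps (SP, short descending
sweeps), warbles (W, low bow-shaped contours) and pleasure notes (PN, short
ascending sweeps) — plus a catch-all "other vocalization" (OV) class. Their
prevalence carries welfare information, but it varies strongly with time of
day and bird age, so any treatment comparison has to ride on top of a
well-calibrated measurement chain. This package is for researchers in
precision livestock farming and computational bioacoustics who want that
chain as reusable, tested code: because no public farm recordings exist for
this task, a first-class synthetic-data module emulates the statistical
structure the analysis assumes and provides exact ground truth to validate
every stage against.

## The computation

1. **Soundscapes.** Each call type is an inhomogeneous Poisson process whose
   clock-hour intensity λ(h) = r(h)/60/E[dur] realizes a configured diurnal
   rate profile r in call-seconds per minute; calls are harmonic tones with
   type-specific contour, band, duration and level, an age-dependent pitch
   multiplier 0.6^((age−1)/41), mixed into background noise at a configured
   SNR.
2. **Front end.** Resample to 8 kHz → 5th-order Butterworth high-pass at
   500 Hz (zero-phase) → spectral gating against a rolling per-band
   80th-percentile noise floor (+6 dB threshold, ≤20 dB attenuation) →
   64-band HTK log-mel spectrogram at 100 frames/s.
3. **Recognizer.** Eleven 2-D convolutions (strided to a temporal factor of
   24 = 240 ms) plus one 1-D convolution, ≈1.0 M trainable parameters,
   emitting per step six softmax class scores (background, DC, PN, W, SP,
   OV; rows sum to 1) and an auxiliary age estimate. Implemented in pure
   numpy with manual backpropagation and gradient-checked; training is
   seeded and deterministic.
4. **Quantification.** Rows with a score ≥ 0.7 are counted per wall-clock
   minute and multiplied by 0.24 s to give s/min per type; minutes average
   into hours, hours into the diurnal bins night (22–04), morning (04–10),
   midday (10–16), evening (16–22); ages map to starter/grower/finisher.
5. **Statistics.** Per sound type, a REML mixed model of binned durations
   on treatment × time-of-day with pen and compartment random intercepts,
   containment-df F tests, interaction pruning at α = 0.05, Tukey-HSD
   pairwise comparisons with compact letter displays; plus a configurable
   temperature–humidity index (THI) and its treatment × round × time ANOVA.

See `docs/methods.md` for the model details, defaults, and limitations.

## Worked example

Synthesize one evening minute, run the chain with an untrained-but-built
model replaced by your trained checkpoint in practice, and quantify:

```python
import broilervox as bv

profile = bv.demo_diurnal_profile()          # SP peaks in the evening, W at night
cfg = bv.SoundscapeConfig(total_duration=60.0, profile=profile,
                          sample_rate=16000, age_days=14.0,
                          snr_db=20.0, seed=4, start_hour=18.0)
wave, truth = bv.synth_soundscape(cfg)
print(truth.minute_durations.round(2))
```

```
          DC     SP    W    PN    OV
minute
0       7.78  22.77  0.0  2.43  1.38
```

The ground truth says this evening minute contains 22.77 s of short peeps —
evening is SP's configured peak (24 s/min) — and 7.78 s of distress calls;
no warble happened to fall in this particular minute (W's evening rate is
low).
Passing the waveform through the front end and a trained recognizer (see
`tests/conftest.py` for the training recipe) and thresholding the raster at
0.7 returns the estimated table on the same scale; on a 60-minute high-SNR
soundscape the estimates track ground truth with Pearson r ≥ 0.9 and a mean
absolute error under 20% of the true mean for every type.

The statistical stage consumes tidy observation tables:

```python
from broilervox.stats import fit_duration_model, simulate_observation_table

table = simulate_observation_table(seed=1, bin_effects={"evening": 3.0})
report = fit_duration_model(table)           # enrichment + bin, pen random
print(report.anova.round(4).to_string(index=False))
print(report.letters["bin"])
```

```
         term       F  df_num  df_den      p
C(enrichment)  2.0451       1       6 0.2026
       C(bin) 47.4028       3      52 0.0000
{'evening': 'a', 'midday': 'b', 'morning': 'b', 'night': 'b'}
```

The +3 s/min evening shift is detected (time-of-day p < 0.0001) and evening
carries its own letter; the null enrichment contrast is correctly
non-significant.

A thin CLI wraps the same functions:
`broilervox simulate|preprocess|train|infer|quantify|analyze --help`.

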