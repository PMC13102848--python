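# Methods

This note documents the models, parameters and numerical choices behind
`erpkit`, and what the synthetic-data tests do and do not establish about
real recordings.

## Oddball design and sequence generation

A session is `n_blocks` blocks of `n_per_block` auditory stimuli at
proportions 70/15/15% Standard/Target/Novel (defaults: 8 × 80, giving 448
Standard, 96 Target and 96 Novel trials).  Sound durations default to 50 ms
for tones and 300 ms for Novel sounds; the inter-stimulus interval (1 s) is
**offset-to-onset**.  Two ordering constraints hold per block: the first
and last five stimuli are Standards, and a Target is never adjacent to a
Novel.  Orders are drawn by rejection sampling over uniform shuffles of the
middle segment with a 10,000-retry cap before raising an infeasibility
error; rejection sampling is unbiased among valid orders, which simpler
constructive schemes are not.  A block's span is defined from its first
onset to the end of the trailing ISI; with the default durations this is
exactly 87.0 s (79 gaps + 7.0 s of sound + the trailing 1 s gap), while the
offset of the 80th stimulus falls at 86.0 s.

## Montage geometry

Electrode coordinates are generated from the construction of the 10–20 /
10–10 placement standard itself: on a unit sphere, midline electrodes sit
at 10% fractions of the nasion–inion arc, lateral electrodes at 25/50/75/
100% of the great-circle arc from their midline row position to the row's
point on the 10% ring, and sub-ring electrodes (P9/P10, TP9/TP10, earlobes,
mastoids) 10–18° below the ring.  2D positions are the azimuthal-equidistant
projection from the vertex with the ring at radius 1.  No third-party
montage file is used; `src/erpkit/data/montage_1020.tsv` is written by the
package's own generator (72 positions).

Neighbour graphs connect channels closer than δ.  The floor δ = 0.45 makes
each electrode of the classic 10–20 grid adjacent to its row and column
neighbours (Fz–Cz = 0.40, Fz–F3 = 0.41) but not to second-order ones
(Fz–Pz = 0.80); on sparser montages δ widens adaptively to
`1.1 × max_i(min_j d_ij)` so that no channel is isolated (the 14-channel
preset needs δ ≈ 0.68).  An explicit δ can always be passed.

## Signal model

Each trial is `template(condition) + noise`:

* **Templates.**  Gaussian-windowed deflections, σ = 15 ms for the N100 and
  σ = 45 ms for the P300, at per-subject latencies and per-condition
  amplitudes (N100 ≤ 0 for all conditions; P300 ≥ 0, substantial mainly for
  Novel).  The scalp pattern is a single Gaussian patch
  `exp(−d²/2w²)` centred frontocentrally (default midway between Fz and
  FCz, w = 0.6 head radii).  The whole response is shifted by the system's
  acquisition lag.
* **Noise.**  1/f-shaped ("pink") Gaussian noise, generated by spectral
  shaping of white noise (amplitude ∝ 1/√f above 1 Hz, flat below),
  normalized to unit variance and scaled by the system's noise level, drawn
  independently per trial and channel.  Spatially correlated noise is a
  documented extension point, not implemented.
* **Artifacts.**  A configurable fraction of trials (default 5% in the
  pipeline) has its noise multiplied by 10, emulating movement artifacts
  for the rejection stage to find.

**Population distribution** (per subject, drawn once and reused across
runs; run-to-run differences are trial noise only):

| parameter | default | why |
| --- | --- | --- |
| N100 amplitude, µV (S/T/N) | −4 / −4.5 / −5.5 × gain | canonical frontocentral N100 range |
| P300 amplitude, µV (S/T/N) | 0.5 / 1.5 / 6 × gain | P300 mainly for Novel sounds |
| component gains | lognormal, sd 0.3 (N100), 0.4 (P300), independent | subjects must differ in N100:P300 *ratio*: Pearson-based typicality is blind to common scaling |
| Target P300 gain | × uniform(0, 2) | some people produce little or no target P3b |
| N100 latency | 100 ± 15 ms | adult N1 latency spread |
| P300 latency | 300 ± 35 ms, + Target-only jitter sd 40 ms | later components are temporally more variable, most of all to Targets |
| topography centre / width | (0, 0.3) ± 0.05 / 0.6 ± 0.05 | frontocentral maximum with mild individual shift |

These spreads were chosen so the generator expresses the structure the
analyses are built to measure: a subject's two runs correlate better with
each other than with any other subject in expectation, typicality is
ordered Novel ≳ Standard > Target, and detection rates rise with component
amplitude.  They also mean group-level cluster significance at n ≈ 9 is
*marginal* per component — with large between-subject variability a
max-mass permutation test at that sample size genuinely hovers around the
0.05 family threshold, and single draws can report one component
significant and the other not.

**System presets.**  (channels, rate, lag, noise scale): 64 ch / 1024 Hz /
0 ms / 8 µV; 24 ch / 250 Hz / +4 ms / 10 µV; 21 ch / 300 Hz / −50 ms /
10 µV; 14 ch / 128 Hz / +250 ms / 18 µV.  The 14-channel montage has no
midline frontal electrode, so single-electrode analyses fall back from Fz
to F4 (chain Fz → F4 → F3 → FCz → Cz, configurable).

All randomness flows through explicit integer seeds (`numpy.random`
SeedSequence spawning); identical inputs give bit-identical epochs.

## Preprocessing

Stages, in order: re-reference → 0.5–40 Hz band-pass → STD rejection →
per-condition averaging (average → 12 Hz low-pass → baseline subtraction;
the SEM is computed across trials before filtering).

* **Reference.**  Mean of two channels subtracted from all channels.
  Schemes resolve through candidate chains (mastoids: M1/M2 → TP9/TP10 →
  TP7/TP8 → P7/P8; earlobes: A1/A2 → M1/M2 → P7/P8) because mastoid
  electrodes are external to most montages; the pair used is logged, and
  the stage is skipped with a log line when no pair exists.
* **Filters.**  4th-order Butterworth applied forward–backward
  (`sosfiltfilt`), so the effective magnitude response is 8th-order and
  the group delay is zero.  The band-pass is a high-pass/low-pass cascade
  to avoid the numerical fragility of a narrow band design at 0.5 Hz.
  Note the 12 Hz low-pass attenuates a σ = 15 ms Gaussian peak by roughly
  25–30%; peak amplitudes read off averaged ERPs are smaller than the
  injected values by that factor.
* **Rejection.**  A trial is rejected iff the maximum over channels of its
  within-trial standard deviation exceeds the threshold, interpreted in
  absolute µV (25/25/35/40 µV per preset).  A z-scored variant of the
  metric is provided (`zscore_trial_std`) but the absolute form is the
  default.  Rejection only flags the mask; retained data are untouched.
* **Detrending** (per-epoch linear + demean) is available but not part of
  the default pipeline; the band-pass already removes drift, and per-epoch
  detrending interacts with the baseline definition.
* **Baselines.**  (−0.1, 0) s, except (+0.05, +0.15) s for systems whose
  acquisition lag exceeds 100 ms, where the true pre-stimulus interval is
  not observed within the epoch.
* **Epoch windows.**  (−0.1, 0.7) s for the multi-system mode, (−0.1, 0.4) s
  for the test–retest mode.  Windows snap to the sampling grid so t = 0 is
  always exactly on a sample.

## Cluster-permutation testing

One-sample, against zero (the designs here never test between conditions).
Pointwise t statistics are formed from the data mean and the sign-flip-
invariant sum of squares, which lets all permutations share one
precomputed quantity.  Forming threshold: two-sided tests run both tails at
α/2 (default 0.025 each); candidate clusters are runs of consecutive
suprathreshold samples (temporal) or connected components of
suprathreshold channels on the neighbour graph (spatial).  Cluster mass is
the summed t; the null is the maximal |mass| per permutation, shared
across both tails, so the correction is family-wise over the tested
dimension and the two tails jointly.

Numerical conventions: with n observations and 2ⁿ ≤ 4096 all sign
assignments are enumerated and `p = #{null ≥ |mass|} / 2ⁿ` (the identity
assignment makes p ≥ 2/2ⁿ for two-sided tests and never 0); otherwise
Monte-Carlo with `p = (count + 1) / (n_perm + 1)` (default 1000
permutations).  Zero-variance points get t = ±∞ (sign of the mean) or 0,
so degenerate noise-free fixtures behave exactly.  Component windows are
read off a single-electrode temporal result: earliest significant negative
cluster → N100 (peak = most negative sample), earliest significant
positive cluster after it → P300 (peak = most positive sample); missing
components are reported as not significant rather than as empty windows.

Cross-system comparison resamples both grand-average waveforms to 250 Hz
(polyphase), then scans Pearson r over every integer-sample lag within
±300 ms of overlap; positive lag means the second waveform lags the first,
and ties break toward the smaller |lag|.  The correlation uses the full
overlapping segment.

## Individual-level analyses

1. **Binned significance maps.**  Per subject, trials are averaged within
   20 ms bins per channel (bin edges aligned to t = 0; the bin width must
   be an integer number of samples, so mixed-rate cohorts are resampled
   first) and a one-tailed one-sample t-test is run per (channel, bin) at
   uncorrected α = 0.05.  Both tails are computed and stored; the reported
   map is selectable, since the appropriate direction depends on the
   component of interest.  The map value is the fraction of subjects
   flagged.
2. **Temporal clustering at one electrode** (Fz or fallback), both tails at
   α = 0.025, on single trials per condition.
3. **Spatial clustering in group windows.**  Trials are averaged within the
   group-level component window per channel; per-channel t-tests at the
   component's tail feed the graph-clustering variant.

**Typicality** is computed at one electrode over t ≥ 0 (the baseline is
excluded: it is noise by construction and would dilute r toward 0).
Detection tables report the rounded percentage of subjects with at least
one significant cluster of the component's sign; for temporal detection
both an unconstrained count and a count requiring ≥ 1 sample of overlap
with the group window are emitted, since either convention is defensible.
Mixed-effects modelling of typicality is out of scope; the package emits
the tidy long-format table such models consume.

## Reliability statistics

* **ICC(3,1)** from the ANOVA mean squares, CI by the exact F method
  (`F/F_{1−α/2}(df1,df2)` and `F·F_{1−α/2}(df2,df1)` transformed through
  `(F−1)/(F+k−1)`), p from `F = BMS/EMS`.  A zero residual mean square
  (e.g. runs identical up to a constant) returns ICC = 1 with a degenerate
  flag instead of dividing by zero.
* **Cronbach's α** uses the raw-variance definition.  For k = 2 it equals
  Spearman–Brown `2r/(1+r)` exactly when the runs have equal variance;
  tests enforce the identity on standardized fixtures.
* **d′** clips rates to `[1/(2N), 1 − 1/(2N)]` with N the respective
  stimulus count; the false-alarm denominator is the non-target count
  (Standards + Novels), an explicit assumption since a press can follow any
  stimulus.
* **Peaks** are window-constrained extrema of the stated polarity;
  boundary extrema are flagged (`at_edge`) because they usually indicate a
  monotone segment, not a peak.
* Run matrices are assembled with listwise deletion of subjects missing in
  any run; dropped subjects are recorded.

## Pipeline and problem sizes

`run_pipeline` executes simulate → preprocess → group → individual
(→ reliability in test–retest mode) from a validated YAML-serializable
config whose defaults are the full design (8 × 80 stimuli; 10/9/11/7
subjects per system in multi-system mode; 38 subjects × 2 runs in
test–retest mode).  Outputs are CSV tables, a JSON manifest with a config
hash, and a log that records every rejection, reference fallback and
exclusion.  All derived seeds are SHA-256 hashes of (seed, system,
subject), keeping streams independent and below 2³¹.

The test suite and the acceptance script run scaled-down problems chosen as
the smallest sizes at which each property is expressed: cohorts of 4–10
subjects, 1–4 blocks, 100–500 permutations, and one full-trial-count
single-system run (9 subjects × 640 trials).  Calibration checks use their
spec'd sizes (500 null datasets × 200 permutations; ICC recovery at
n = 200; CI coverage at n = 38 over 500 simulations).

## What the synthetic tests do and do not show

The generator reproduces the statistical *structure* the analyses assume —
condition-specific components, 1/f noise, between-subject amplitude/latency
/topography variability, within-subject stability, system-specific lag and
noise — so green tests establish that the estimators are correct, calibrated
(family-wise error ≈ 5% on null data) and monotone in signal strength.
They do not certify performance on real EEG: no spatially correlated noise,
no ocular/cardiac artifacts (ICA removal is out of scope), a single
template per condition (real Novel sounds are heterogeneous exemplars), no
forward head model, and no drift or electrode-impedance dynamics.  Detection
rates and typicality values on real data will differ; the tables this
package produces for real recordings should be read with those limits in
mind.
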