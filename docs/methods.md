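# Methods

## System model

One trial is a grasp of a single object under one of two control schemes,
sampled on a canonical 50 Hz grid. An object is categorical (shape,
size class, compliance class) plus two physical surrogates: the *contact
aperture* (hand-opening angle in degrees at which the fingertips first
touch it — strictly increasing with size) and a *contact stiffness*
(N per degree of closure beyond contact — strictly increasing with
compliance class, "hard" being stiffest). Contact is a pure linear spring:

```
F_contact(a) = k · (a_contact − a)   for a < a_contact, else 0
```

with no damping and no slip. The reported grip force is the maximum over
three simulated fingertip sensors that see the same contact force plus
independent Gaussian noise (SD 0.05 N per sensor by default), clipped at
zero — mirroring max-pooling over index/middle/ring sensors while keeping
one contact model. The force is low-pass filtered (below) before encoding.

### Glove-proportional control

The contralateral glove aperture maps identically onto the prosthesis
aperture (both span 90° open → 0° closed; calibration offsets are out of
scope). A closure starts after a jittered reaction time (Gaussian, SD
0.2 s by default) and is rate-limited: *ballistic* (250 deg/s, the default,
reflecting rapid contralateral movements) or *smooth* (40 deg/s). Closure
stops at a randomized squeeze depth past contact (Gaussian, 15 ± 2 deg,
clipped to [5, 30]), so peak force is `k · squeeze`.

### EMG threshold control

A surrogate raw EMG is generated at 2000 Hz: band-limited (20–450 Hz)
zero-mean noise amplitude-modulated by an intent profile — baseline 0.01,
a 120 ms flexion burst at a jittered reaction time (≈1.0 ± 0.2 s), then
sustained activation (amplitude 0.9 ± 0.1 of maximal) starting after a
*flexion-to-grasp delay* drawn from an exponential distribution. The
delay scale is `NoiseConfig.command_onset_jitter_sd`, default **1.5 s**
for EMG presets: impaired ipsilateral control produces multi-second
hesitation between the first EMG activity and the sustained grasp, and
this delay — not sensor noise — is what erases object-size information
from stimulation onset timing under this scheme.

The envelope chain is the real-time one: 2nd-order Butterworth high-pass
at 10 Hz (the order is a config; only the cutoff is fixed by the design),
non-overlapping 20 ms bin means (exactly one output sample per bin → 50 Hz;
a sliding average with decimation would be an alternative reading of
"moving average" but does not land exactly on 50 Hz), then rectification.
Rectify-after-average is the default order; because averaging zero-mean
EMG first leaves a half-normal (high-variance) envelope, the default EMG
threshold is a low 0.05 of the MVC peak, and `rectify_after_average=False`
is available as the conventional mean-absolute alternative. Normalization
divides by the peak of an identically processed simulated maximum
voluntary contraction, drawn once per session.

The control law integrates −15 deg/s while the normalized envelope is at
or above threshold and +30 deg/s otherwise, clamped to the aperture range.
Envelope noise makes the effective closing velocity ≈ 9–10 deg/s with
occasional re-opening dips, which is part of the intended variability.

## Force filter

The 4th-order low-pass Butterworth at 4 Hz is discretized by **impulse
invariance** from the analog prototype and renormalized to exactly unity
DC gain, then applied causally (single pass, zero initial state). Impulse
invariance was chosen over the bilinear transform deliberately: at a 50 Hz
sample rate the bilinear warp crushes the stopband (≈5e-5 instead of the
analog 1.6e-3 at 20 Hz), whereas impulse invariance keeps the digital
magnitude on the analog Butterworth curve across the band, which is the
response the analytic checks in the test suite assert. Aliasing error is
below a few parts in 10⁴ at this order and rate. The first 0.5 s of any
filtered series is treated as settling and excluded from slope-based
checks.

## Encoding

Linear scheme: force normalized between calibration limits (`F_min` 0 N,
`F_max` 10 N, free parameters — the physical sensor units are a
calibration choice), clipped to [0, 1], mapped affinely to
[`A_min` 1 mA, `A_max` 6 mA]. Stimulation is withheld while force is at or
below `contact_threshold` (default 0.2 N ≈ 4× the per-sensor noise SD):
an affine map alone would stimulate at `A_min` with the hand at rest, which
contradicts the existence of a stimulation onset; the inclusive gate also
keeps the onset from re-triggering on the sensor noise floor.

Exponential scheme: `A = A_min·e^(ωF)` above a threshold, 0 at or below
it, with `F` in raw sensor counts. The empirical range of ω
(0.005–0.025 per count) implies raw forces of order 10²–10³ counts, so a
calibration `sensor_counts_per_newton` (default 50) converts the contact
model's newtons; preset configs set the gate at 10 counts (0.2 N) for the
same noise-floor reason, while the bare function defaults to 1 count. The
scheme is unbounded in force, so the output is capped at
`min(A_max, 6 mA)`; the onset discontinuity (0 → `A_min·e^(ω·thr)`) is
reported by `exponential_onset_jump`, never smoothed. Every commanded
amplitude, both schemes, is clamped to the 6 mA ganged-channel ceiling.
Pulse-train parameters are validated against 1–300 Hz, 50–1000 µs per
phase, charge-balanced anodic-first symmetric pulses.

## Task presets

Six built-in designs: S1-virtual size/compliance (9 spheres = 3 sizes × 3
compliances, 8 or 10 reps → 72/90 trials, glove control, exponential
encoding, 10 s timeout); S1-physical size (4 cube sizes of one foam,
9/18/12/16 reps → 55 trials, glove, linear); S2-virtual compliance (3
large cylinders × 25 → 75 trials, EMG, linear, 10 s); S2-physical size
(3 hard cylinders × 10 → 30 trials, EMG, linear, 20 s) and compliance
(3 medium cylinders × 20 → 60 trials, EMG, linear, 20 s). Randomization
is one uniform shuffle of the trial multiset (a block-randomized mode is
available behind a flag, off by default). Both object properties are
stored per trial together with the single queried property.

Surrogate values are documented defaults chosen once: sphere/cube sizes
contact at 18/30/45/60° (XS/S/M/L); the S2 cylinder set at 52/56/60° — a
deliberately narrow, graded diameter range for a purpose-machined set;
stiffness 0.05/0.15/0.45 N/deg for soft/medium/hard. All statistics
downstream depend only on the orderings, never the specific values.

## Features and statistics

Stimulation onset is the first sample with nonzero commanded amplitude;
command onset is the first envelope threshold crossing (EMG) or the first
sample with closing velocity beyond 5 deg/s (glove). Features: onset lag,
peak amplitude, rate of change (mean slope from onset to the *first*
sample reaching 98% of the peak — the global argmax wanders across the
noisy force plateau and would bias the rate toward zero), and hand
aperture at stimulation onset. No-contact trials yield null features with
a reason code; they are excluded from statistics and counted in the
report.

The battery: exact upper-tail binomial tests against chance 1/K (the null
is "no better than chance"; a two-sided option exists), one-way MANOVA
per factor computed from between/within scatter matrices (Wilks' Λ with
Rao's F approximation; cross-checked against `statsmodels` in the tests),
per-feature one-way ANOVA with Tukey-HSD post-hocs (`scipy`/
`statsmodels`), and standard deviational ellipses at 1 SD (the multiplier
is a config) from the covariance eigendecomposition. Ellipse overlap is
decided by 720-point boundary sampling plus containment tests, tangency
counting as overlap and a zero-width ellipse handled as a segment. No
multiple-testing correction is applied across the many ANOVAs beyond
Tukey's family-wise adjustment; the report flags this.

The ideal observer is a Gaussian nearest-centroid classifier with pooled
covariance, trained and tested on disjoint split halves (even/odd
trials). It is a lower bound on available information, not a model of
human perception. Its default feature set is scheme-dependent: under EMG
control only stimulation features (onset lag, peak amplitude, rate) —
the prosthesis aperture is imperceptible to the user — while under glove
control the aperture at onset is included, since the glove is the
subject's own, proprioceptively sensed hand.

## What the generator does and does not emulate

It reproduces: contact timing ordered by object size; force growth rate
ordered by compliance; trial-to-trial variability in reaction time,
squeeze depth, EMG intent and sensor noise; max-pooled fingertip sensing;
and the real-time signal chain end to end. It does not model 3-D
geometry, slip (the reason the physical object set moved from cubes to
cylinders), multi-DOF kinematics, day-by-day learning, perceptual
thresholds for stimulation dynamics, or electrode–tissue physics. Tests
passing here show the *encoding pipeline and statistics* behave as
designed under these idealized conditions; they cannot certify behavior
on real sensor data.

## Numerical choices and degenerate inputs

Causal filtering with zero initial state everywhere; per-trial seeds are
counter-based (`SeedSequence(master_seed, spawn_key=(trial_index,))`), so
any trial is reproducible independently of execution order and the whole
run is byte-deterministic given (config, seed) — outputs contain no
timestamps. Ties in the observer resolve to the first class in
size/compliance order. Degenerate inputs raise explicit errors: empty
series, zero-variance ANOVA groups, collinear MANOVA features (named in
the message), missing training classes, non-monotone object surrogates.
An instant-rise stimulation gets a one-sample floor on its rise time
rather than an infinite rate.

## Problem sizes

Stochastic suites run 20 independent seeds of full sessions (30–90 trials
each); the encoder safety sweep uses 10,000 synthetic force profiles in
the tests and 1,000 fully simulated trials in `scripts/acceptance.py`;
null-distribution checks use 500 replicates. These sizes give stable
statistics while keeping the whole suite in the low minutes on one core.
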