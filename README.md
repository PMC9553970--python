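# scstim

Closed-loop sensory feedback for prosthetic hands: when an amputee grasps an
object with a sensorized prosthesis, the measured grip force can be encoded
into the amplitude of spinal cord stimulation (SCS), evoking a touch percept
whose intensity tracks the grasp. `scstim` is a desk-scale re-creation of
such a system for researchers studying which stimulation features (onset
timing, peak amplitude, rate of change) can carry information about object
**size** and **compliance**, and how the prosthesis **control scheme**
gates that information.

The package simulates 50 Hz grasp trials under two control schemes —

* **glove-proportional**: a data glove on the contralateral hand drives the
  prosthesis aperture proportionally (variable, often ballistic closures);
* **EMG threshold**: surface EMG from the residual limb is envelope-extracted
  (2000 Hz → 10 Hz high-pass → 20 ms bin means → rectification → MVC
  normalization) and the hand closes at a constant 15 deg/s while the
  envelope is above threshold, opening at 30 deg/s otherwise —

encodes the low-pass-filtered grip force *F* into stimulation amplitude *A*
by two schemes,

```
linear:       F_n = (F − F_min) / (F_max − F_min)        (clipped to [0, 1])
              A   = F_n · (A_max − A_min) + A_min

exponential:  A   = A_min · e^(ω·F)   if F > threshold,  else 0
```

with every commanded amplitude capped at the 6 mA ganged-channel hardware
ceiling, and then runs the discrimination statistics: per-trial feature
extraction, exact binomial tests against chance (1/K), one-way MANOVA
(Wilks' Λ), per-feature ANOVA with Tukey-HSD post-hocs, 1-SD standard
deviational ellipses with an overlap audit, and a Gaussian nearest-centroid
ideal observer producing confusion matrices.

Object contact is a linear spring: larger objects are touched at larger
apertures (earlier in the closure), stiffer objects produce more force per
degree of squeeze. That is all the structure needed to reproduce the
system-level result: under glove control, aperture at stimulation onset
cleanly separates sizes; under constant-velocity EMG control, onset timing
is swamped by flexion-to-grasp variability (size is lost) while the rate of
change of stimulation robustly encodes compliance.

## Worked example

Simulate one 75-trial compliance-discrimination session under EMG control
with the linear encoder, analyze it, and render the report:

```sh
scstim --quiet simulate --preset S2-virtual-compliance --seed 7 --out demo
scstim --quiet analyze demo
scstim report demo/report.json
```

```
scheme: emg_threshold_velocity   queried: compliance
trials: 75   null-feature trials: 3

ideal observer (3-alternative, chance: 33%)
confusion (rows = true):
              soft    medium      hard
    soft        15         0         0
  medium         0         8         0
    hard         0         0        11
overall accuracy 100.0% (k=34, n=34, p0=0.333, exact p=6e-17)

MANOVA [compliance_class]: Wilks lambda=0.0249 F(6,134.0)=119.11 p=3.27e-51
ANOVA onset_lag~compliance_class: F=1.42 p=0.25
ANOVA peak_amp~compliance_class: F=105.03 p=1.16e-21
ANOVA rate_of_change~compliance_class: F=603.05 p=1.99e-44
```

Reading it: 3 of 75 trials never produced stimulation (null features,
excluded and counted). The split-half ideal observer decodes compliance
perfectly from stimulation features alone — because the hand closes at a
fixed velocity, the rate of change of stimulation is proportional to object
stiffness (ANOVA F = 603, p ≈ 2e-44), while onset lag carries no compliance
information (p = 0.25). Run the same pipeline on `S2-physical-size` and
size decoding collapses to chance; on `S1-virtual-size` (glove control) it
is nearly perfect via aperture at onset.

`scstim presets` lists the six built-in task designs (72, 90, 55, 75, 30
and 60 presentations).

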