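"""Synthetic grasp trials at 50 Hz under two prosthesis-control schemes.

The generator reproduces the statistical structure the discrimination
analysis rests on, without any physics engine:

* object contact is a linear spring — zero force while the hand aperture is
  above the object's contact aperture, ``stiffness x (contact - aperture)``
  newtons beyond it (no damping, no slip);
* the reported grasp force is the maximum across three simulated fingertip
  sensors that see the same contact force plus independent Gaussian noise,
  mirroring max-pooling over index/middle/ring sensors;
* glove-proportional control: the contralateral glove aperture maps
  identically onto the hand aperture; closures are ballistic (rate-limited
  near-step) or smooth constant-rate, starting after a jittered reaction
  time and stopping at a randomized squeeze depth past contact;
* EMG threshold control: a 2000 Hz surrogate EMG (band-limited zero-mean
  noise amplitude-modulated by an intent profile) runs through the real
  signal chain; the hand closes at a constant velocity while the normalized
  envelope is above threshold and opens otherwise. The intent profile has a
  brief initial flexion burst followed, after a jittered delay, by the
  sustained grasp — this flexion-to-grasp delay is the dominant source of
  stimulation-onset variability under EMG control.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import signal as _sig

from .signal_chain import (
    EmgChainConfig,
    ForceFilterConfig,
    lowpass_force,
    normalize_to_mvc,
    process_emg,
    threshold_velocity_controller,
)
from .stim_encoder import EncodingConfig, StimTrace, StimTrain, run_encoder
from .task_design import ObjectSpec, SessionSchedule

GLOVE_SCHEME = "glove_proportional"
EMG_SCHEME = "emg_threshold_velocity"


@dataclass(frozen=True)
class ControlConfig:
    scheme: str = GLOVE_SCHEME
    close_velocity: float = 15.0  # deg/s, EMG scheme constant closing speed
    open_velocity: float = 30.0  # deg/s, EMG scheme opening speed
    emg_threshold: float = 0.05  # fraction of MVC-peak envelope
    aperture_range: tuple[float, float] = (90.0, 0.0)  # (fully open, fully closed) deg
    sample_rate: float = 50.0  # Hz
    glove_ballistic_rate: float = 250.0  # deg/s, rapid contralateral closures
    glove_smooth_rate: float = 40.0  # deg/s, deliberate closures

    def __post_init__(self) -> None:
        if self.scheme not in (GLOVE_SCHEME, EMG_SCHEME):
            raise ValueError(f"unknown control scheme {self.scheme!r}")
        if self.close_velocity <= 0 or self.open_velocity <= 0:
            raise ValueError("velocities must be positive")
        if not 0 < self.emg_threshold < 1:
            raise ValueError("emg_threshold must lie in (0, 1)")

    @property
    def open_aperture(self) -> float:
        return self.aperture_range[0]

    @property
    def closed_aperture(self) -> float:
        return self.aperture_range[1]


@dataclass(frozen=True)
class NoiseConfig:
    sensor_noise_sd: float = 0.05  # N per fingertip sensor
    command_onset_jitter_sd: float = 0.2  # s; see class docstring below
    glove_ballistic: bool = True
    rng_seed: int | None = None

    # For the glove scheme the jitter SD randomizes the reaction time before
    # closure begins. For the EMG scheme it is the scale of the
    # (exponentially distributed) delay between the first flexion burst and
    # the sustained grasp — prosthesis users with impaired ipsilateral
    # control show multi-second flexion-to-grasp delays, so EMG presets
    # default this to 1.5 s.

    def __post_init__(self) -> None:
        if self.sensor_noise_sd < 0 or self.command_onset_jitter_sd < 0:
            raise ValueError("noise SDs must be >= 0")


EMG_NOISE_DEFAULT = NoiseConfig(command_onset_jitter_sd=1.5, glove_ballistic=False)

EMG_RAW_RATE = 2000.0
_EMG_BAND = (20.0, 450.0)
_MAX_GRASP_DELAY_S = 6.0
_BLIP_DURATION_S = 0.12
_SQUEEZE_MEAN_DEG = 15.0
_SQUEEZE_SD_DEG = 2.0


@dataclass
class GraspTrace:
    """One trial's 50 Hz time series plus provenance."""

    time: np.ndarray  # s
    command: np.ndarray  # normalized aperture (glove) or MVC-fraction envelope (EMG)
    aperture: np.ndarray  # deg
    raw_force: np.ndarray  # N, max across the three fingertip sensors
    filtered_force: np.ndarray  # N
    obj: ObjectSpec
    command_onset_time: float  # s, ground-truth movement/intent onset
    scheme: str
    command_threshold: float | None = None  # EMG threshold, for onset detection

    def __post_init__(self) -> None:
        n = self.time.size
        for name in ("command", "aperture", "raw_force", "filtered_force"):
            if getattr(self, name).size != n:
                raise ValueError(f"series {name!r} length mismatch")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def contact_force(aperture, obj: ObjectSpec) -> np.ndarray | float:
    """Linear-spring contact: 0 above the contact aperture, stiffness times
    closure depth beyond it."""
    aperture = np.asarray(aperture, dtype=float)
    f = np.where(
        aperture >= obj.contact_aperture,
        0.0,
        obj.stiffness * (obj.contact_aperture - aperture),
    )
    return float(f) if f.ndim == 0 else f


def _sensor_pool(clean: np.ndarray, rng: np.random.Generator, sd: float) -> np.ndarray:
    """Max over three fingertip sensors seeing the same contact force plus
    independent noise; each sensor reads >= 0."""
    if sd == 0:
        return np.clip(clean, 0.0, None)
    sensors = clean[None, :] + rng.normal(0.0, sd, size=(3, clean.size))
    return np.clip(sensors, 0.0, None).max(axis=0)


def _finalize(
    t, command, aperture, obj, rng, noise_cfg, onset, scheme, threshold=None
) -> GraspTrace:
    clean = contact_force(aperture, obj)
    raw = _sensor_pool(np.asarray(clean, dtype=float), rng, noise_cfg.sensor_noise_sd)
    filt = lowpass_force(raw, ForceFilterConfig())
    return GraspTrace(
        time=t, command=command, aperture=aperture, raw_force=raw,
        filtered_force=filt, obj=obj, command_onset_time=float(onset),
        scheme=scheme, command_threshold=threshold,
    )


def simulate_glove_trial(
    obj: ObjectSpec,
    control_cfg: ControlConfig | None = None,
    noise_cfg: NoiseConfig | None = None,
    timeout: float = 10.0,
    seed=None,
) -> GraspTrace:
    """One trial under contralateral-glove proportional aperture control."""
    cfg = control_cfg or ControlConfig(scheme=GLOVE_SCHEME)
    if cfg.scheme != GLOVE_SCHEME:
        raise ValueError("control scheme must be glove_proportional")
    noise = noise_cfg or NoiseConfig()
    if timeout <= 0:
        raise ValueError("timeout must be positive")
    rng = _rng(seed)
    n = int(round(timeout * cfg.sample_rate))
    t = np.arange(n) / cfg.sample_rate

    onset = max(0.1, rng.normal(0.6, noise.command_onset_jitter_sd))
    rate = cfg.glove_ballistic_rate if noise.glove_ballistic else cfg.glove_smooth_rate
    squeeze = float(np.clip(rng.normal(_SQUEEZE_MEAN_DEG, _SQUEEZE_SD_DEG), 5.0, 30.0))
    target = max(obj.contact_aperture - squeeze, cfg.closed_aperture)

    # Rate-limited ramp from fully open to the target aperture.
    aperture = np.maximum(cfg.open_aperture - rate * np.clip(t - onset, 0.0, None), target)
    lo, hi = sorted(cfg.aperture_range)
    aperture = np.clip(aperture, lo, hi)

    span = cfg.open_aperture - cfg.closed_aperture
    command = (aperture - cfg.closed_aperture) / span  # glove == hand aperture
    return _finalize(t, command, aperture, obj, rng, noise, onset, GLOVE_SCHEME)


def synthetic_emg(
    intent: np.ndarray, rng: np.random.Generator, raw_rate: float = EMG_RAW_RATE
) -> np.ndarray:
    """Band-limited zero-mean noise amplitude-modulated by an intent profile
    (a surrogate for raw surface EMG)."""
    noise = rng.standard_normal(intent.size)
    sos = _sig.butter(4, _EMG_BAND, btype="bandpass", fs=raw_rate, output="sos")
    carrier = _sig.sosfilt(sos, noise)
    carrier /= max(carrier.std(), 1e-12)
    return carrier * intent


def mvc_envelope_peak(
    rng,
    emg_cfg: EmgChainConfig | None = None,
    duration: float = 3.0,
) -> float:
    """Peak of the processed envelope during a simulated maximum voluntary
    contraction, used as the session's normalization constant."""
    emg_cfg = emg_cfg or EmgChainConfig()
    rng = _rng(rng)
    n = int(duration * emg_cfg.raw_rate)
    raw = synthetic_emg(np.ones(n), rng, emg_cfg.raw_rate)
    return float(process_emg(raw, emg_cfg).max())


def _intent_profile(
    n_raw: int, raw_rate: float, rng: np.random.Generator, jitter_sd: float
) -> tuple[np.ndarray, float]:
    """Flexion burst at a jittered reaction time, sustained grasp after an
    exponentially distributed flexion-to-grasp delay."""
    t = np.arange(n_raw) / raw_rate
    amp = float(np.clip(rng.normal(0.9, 0.1), 0.5, 1.2))
    t_blip = max(0.2, rng.normal(1.0, 0.2))
    delay = float(min(rng.exponential(jitter_sd), _MAX_GRASP_DELAY_S)) if jitter_sd > 0 else 0.0
    t_grasp = t_blip + _BLIP_DURATION_S + delay
    intent = np.full(n_raw, 0.01)
    intent[(t >= t_blip) & (t < t_blip + _BLIP_DURATION_S)] = amp
    intent[t >= t_grasp] = amp
    return intent, t_blip


def simulate_emg_trial(
    obj: ObjectSpec,
    control_cfg: ControlConfig | None = None,
    noise_cfg: NoiseConfig | None = None,
    timeout: float = 20.0,
    seed=None,
    mvc_peak: float | None = None,
    emg_cfg: EmgChainConfig | None = None,
    emg_generator: Callable[[np.ndarray, np.random.Generator], np.ndarray] | None = None,
) -> GraspTrace:
    """One trial under EMG threshold-crossing constant-velocity control.

    ``emg_generator(intent, rng)`` may replace the built-in raw-EMG
    surrogate; it must return one sample per intent sample (2000 Hz grid).
    """
    cfg = control_cfg or ControlConfig(scheme=EMG_SCHEME)
    if cfg.scheme != EMG_SCHEME:
        raise ValueError("control scheme must be emg_threshold_velocity")
    noise = noise_cfg or EMG_NOISE_DEFAULT
    if timeout <= 0:
        raise ValueError("timeout must be positive")
    emg_cfg = emg_cfg or EmgChainConfig()
    if emg_cfg.raw_rate != EMG_RAW_RATE:
        raise ValueError(f"EMG generator must run at {EMG_RAW_RATE:g} Hz")
    rng = _rng(seed)

    n_raw = int(round(timeout * emg_cfg.raw_rate))
    intent, _ = _intent_profile(n_raw, emg_cfg.raw_rate, rng, noise.command_onset_jitter_sd)
    gen = emg_generator or (lambda prof, r: synthetic_emg(prof, r, emg_cfg.raw_rate))
    raw_emg = np.asarray(gen(intent, rng), dtype=float)
    if raw_emg.size != n_raw:
        raise ValueError("emg_generator returned wrong number of samples")

    if mvc_peak is None:
        mvc_peak = mvc_envelope_peak(rng, emg_cfg)
    envelope = normalize_to_mvc(process_emg(raw_emg, emg_cfg), mvc_peak)

    aperture = threshold_velocity_controller(
        envelope, cfg.emg_threshold, cfg, start_aperture=cfg.open_aperture
    )
    t = np.arange(envelope.size) / cfg.sample_rate
    above = np.nonzero(envelope >= cfg.emg_threshold)[0]
    onset = t[above[0]] if above.size else float("nan")
    return _finalize(
        t, envelope, aperture, obj, rng, noise, onset, EMG_SCHEME,
        threshold=cfg.emg_threshold,
    )


def simulate_trial(
    obj: ObjectSpec,
    control_cfg: ControlConfig,
    noise_cfg: NoiseConfig,
    timeout: float,
    seed=None,
    mvc_peak: float | None = None,
) -> GraspTrace:
    if control_cfg.scheme == GLOVE_SCHEME:
        return simulate_glove_trial(obj, control_cfg, noise_cfg, timeout, seed)
    return simulate_emg_trial(obj, control_cfg, noise_cfg, timeout, seed, mvc_peak=mvc_peak)


def trial_seed_sequence(master_seed: int, trial_index: int) -> np.random.SeedSequence:
    """Counter-based per-trial seeding: reproducible independently of
    execution order."""
    return np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(trial_index),))


def simulate_session(
    schedule: SessionSchedule,
    control_cfg: ControlConfig,
    noise_cfg: NoiseConfig,
    encoding_cfg: EncodingConfig,
    train: StimTrain | None = None,
    master_seed: int | None = None,
) -> list[tuple[GraspTrace, StimTrace]]:
    """Simulate every scheduled trial and encode its force into stimulation.

    Per-trial seeds derive deterministically from the master seed (default:
    the schedule's seed); for EMG sessions one MVC calibration is drawn per
    session, as in practice.
    """
    if master_seed is None:
        master_seed = schedule.rng_seed
    mvc = None
    if control_cfg.scheme == EMG_SCHEME:
        mvc_ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(0x5C5,))
        mvc = mvc_envelope_peak(np.random.default_rng(mvc_ss))
    out = []
    for trial in schedule.trials:
        rng = np.random.default_rng(trial_seed_sequence(master_seed, trial.trial_index))
        grasp = simulate_trial(
            trial.obj, control_cfg, noise_cfg, schedule.exploration_timeout,
            seed=rng, mvc_peak=mvc,
        )
        stim = run_encoder(grasp.filtered_force, encoding_cfg, train, time=grasp.time)
        out.append((grasp, stim))
    return out
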