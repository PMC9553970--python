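"""Force -> stimulation-amplitude encoding and pulse-train validation.

Two encoding schemes map the filtered grasp force to a commanded current
amplitude at a 50 Hz update rate:

* linear — the force is normalized to [0, 1] between calibration limits
  ``F_min``/``F_max`` and mapped affinely onto [``A_min``, ``A_max``]
  (milliamps). No stimulation is delivered while the force is at or below
  ``contact_threshold``, so stimulation has a well-defined onset.
* exponential — ``A = A_min * exp(omega * F)`` for sensor readings above a
  small threshold, 0 otherwise, capped at the hardware ceiling. ``F`` here
  is in raw sensor units (counts); ``sensor_counts_per_newton`` converts
  the simulator's newtons.

The stimulator gangs four 1.5 mA channels, so no commanded amplitude may
exceed 6 mA; pulse trains are charge-balanced anodic-first symmetric square
pulses with frequency 1-300 Hz, per-phase width 50-1000 us and a 60 us
interphase interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

HARDWARE_MAX_MA = 6.0
FREQ_RANGE_HZ = (1.0, 300.0)
PULSE_WIDTH_RANGE_US = (50.0, 1000.0)


@dataclass(frozen=True)
class EncodingConfig:
    scheme: str = "linear"  # "linear" or "exponential"
    F_min: float = 0.0  # N, sensor calibration lower limit
    F_max: float = 10.0  # N, sensor calibration upper limit
    A_min: float = 1.0  # mA, perceptual threshold amplitude
    A_max: float = 6.0  # mA, perceptual ceiling amplitude
    omega: float = 0.01  # 1/sensor-unit, exponential scaling factor
    contact_threshold: float = 0.2  # N, linear-scheme no-stim gate
    exp_threshold: float = 1.0  # sensor units, exponential no-stim gate
    sensor_counts_per_newton: float = 50.0
    hardware_max: float = HARDWARE_MAX_MA  # mA, ganged-channel ceiling
    update_rate: float = 50.0  # Hz

    def __post_init__(self) -> None:
        if self.scheme not in ("linear", "exponential"):
            raise ValueError(f"unknown encoding scheme {self.scheme!r}")
        if not self.F_min < self.F_max:
            raise ValueError("require F_min < F_max")
        if not (0 <= self.A_min < self.A_max <= self.hardware_max):
            raise ValueError("require 0 <= A_min < A_max <= hardware_max")
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if not 0.005 <= self.omega <= 0.025:
            log.warning("omega=%g outside the empirical range [0.005, 0.025]", self.omega)

    @property
    def amplitude_cap(self) -> float:
        return min(self.A_max, self.hardware_max)

    @property
    def linear_gain(self) -> float:
        """d(amplitude)/d(force) of the linear scheme, mA/N."""
        return (self.A_max - self.A_min) / (self.F_max - self.F_min)


@dataclass(frozen=True)
class StimTrain:
    frequency: float = 100.0  # Hz
    pulse_width: float = 200.0  # us per phase
    interphase: float = 60.0  # us
    polarity: str = "anodic-first"
    configuration: str = "monopolar"
    electrode_id: str = "SCS-1"


@dataclass
class StimTrace:
    """Commanded amplitude on the 50 Hz grid for one trial."""

    time: np.ndarray  # s
    amplitude: np.ndarray  # mA
    encoding: EncodingConfig
    train: StimTrain


def normalize_force(F, cfg: EncodingConfig) -> np.ndarray | float:
    """Normalize force to [0, 1] between the calibration limits, clipped."""
    if not cfg.F_max > cfg.F_min:
        raise ValueError("degenerate calibration: F_max must exceed F_min")
    out = (np.asarray(F, dtype=float) - cfg.F_min) / (cfg.F_max - cfg.F_min)
    out = np.clip(out, 0.0, 1.0)
    return float(out) if np.isscalar(F) else out


def encode_linear(F_n, cfg: EncodingConfig, raw_force=None):
    """Affine map of normalized force onto [A_min, A_max].

    If ``raw_force`` is supplied, samples at or below ``contact_threshold``
    command zero amplitude (no stimulation before object contact).
    """
    F_n = np.asarray(F_n, dtype=float)
    amp = F_n * (cfg.A_max - cfg.A_min) + cfg.A_min
    if raw_force is not None:
        amp = np.where(np.asarray(raw_force, dtype=float) <= cfg.contact_threshold, 0.0, amp)
    amp = np.minimum(amp, cfg.amplitude_cap)
    return float(amp) if amp.ndim == 0 else amp


def encode_exponential(F, cfg: EncodingConfig):
    """Exponential scheme on raw sensor units: 0 at or below the threshold,
    ``A_min * exp(omega * F)`` above it, capped at the hardware ceiling."""
    F = np.asarray(F, dtype=float)
    with np.errstate(over="ignore"):
        amp = cfg.A_min * np.exp(cfg.omega * F)
    amp = np.where(F <= cfg.exp_threshold, 0.0, np.minimum(amp, cfg.amplitude_cap))
    return float(amp) if amp.ndim == 0 else amp


def exponential_onset_jump(cfg: EncodingConfig) -> float:
    """Amplitude discontinuity at the exponential scheme's onset threshold.

    The scheme jumps from 0 to ``A_min * exp(omega * threshold)``; the jump
    is reported so it can be audited, never smoothed away.
    """
    return min(cfg.A_min * float(np.exp(cfg.omega * cfg.exp_threshold)), cfg.amplitude_cap)


def validate_stim_params(train: StimTrain) -> list[str]:
    """Check a pulse train against the stimulator's limits.

    Returns a list of human-readable violations; empty means ok.
    """
    violations = []
    lo, hi = FREQ_RANGE_HZ
    if not lo <= train.frequency <= hi:
        violations.append(f"frequency {train.frequency} Hz outside [{lo:g}, {hi:g}] Hz")
    lo, hi = PULSE_WIDTH_RANGE_US
    if not lo <= train.pulse_width <= hi:
        violations.append(f"pulse_width {train.pulse_width} us outside [{lo:g}, {hi:g}] us")
    if train.interphase < 0:
        violations.append(f"interphase {train.interphase} us negative")
    if train.polarity != "anodic-first":
        violations.append(f"polarity {train.polarity!r} not anodic-first")
    if train.configuration not in ("monopolar", "multipolar"):
        violations.append(f"configuration {train.configuration!r} unknown")
    return violations


def charge_per_phase_nc(train: StimTrain, amplitude_ma) -> np.ndarray | float:
    """Per-phase charge (nC) = amplitude (mA) x pulse width (us); symmetric
    phases, so anodic and cathodic charge are equal by construction."""
    return np.asarray(amplitude_ma, dtype=float) * train.pulse_width


def run_encoder(
    filtered_force: np.ndarray,
    cfg: EncodingConfig,
    train: StimTrain | None = None,
    time: np.ndarray | None = None,
) -> StimTrace:
    """Sample-wise encoding of a 50 Hz filtered-force series.

    The output amplitude grid is identical to the input grid; every sample
    is clamped to [0, hardware_max].
    """
    train = train or StimTrain()
    violations = validate_stim_params(train)
    if violations:
        raise ValueError("invalid stimulation train: " + "; ".join(violations))
    force = np.asarray(filtered_force, dtype=float)
    if time is None:
        time = np.arange(force.size) / cfg.update_rate
    if cfg.scheme == "linear":
        amp = encode_linear(normalize_force(force, cfg), cfg, raw_force=force)
    else:
        counts = force * cfg.sensor_counts_per_newton
        amp = encode_exponential(counts, cfg)
    amp = np.clip(amp, 0.0, cfg.hardware_max)
    return StimTrace(time=np.asarray(time, dtype=float), amplitude=amp, encoding=cfg, train=train)
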