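"""Real-time signal processing: EMG envelope, MVC normalization, force
low-pass filtering, and the threshold-crossing velocity control law.

All filters are causal single-pass IIR filters with zero initial state,
matching a real-time system; nothing here is zero-phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EmgChainConfig:
    """EMG conditioning chain: high-pass, bin-average to 50 Hz, rectify.

    ``rectify_after_average`` applies rectification after the 20 ms bin
    means (the order the chain is described in); the alternative order
    (rectify, then average) yields a conventional mean-absolute envelope.
    Because MVC normalization uses an identically processed recording, the
    normalized envelope is comparable under either order, but the
    after-average order leaves a much noisier (half-normal) envelope.
    """

    raw_rate: float = 2000.0
    highpass_cutoff: float = 10.0
    bin_width: float = 0.020
    highpass_order: int = 2
    rectify_after_average: bool = True

    def __post_init__(self) -> None:
        n = self.raw_rate * self.bin_width
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise ValueError("raw_rate * bin_width must be a positive integer")

    @property
    def bin_samples(self) -> int:
        return int(round(self.raw_rate * self.bin_width))

    @property
    def output_rate(self) -> float:
        return 1.0 / self.bin_width


@dataclass(frozen=True)
class ForceFilterConfig:
    """Causal low-pass Butterworth applied to the 50 Hz force signal."""

    order: int = 4
    cutoff: float = 4.0
    sample_rate: float = 50.0

    def __post_init__(self) -> None:
        if not 0 < self.cutoff < self.sample_rate / 2:
            raise ValueError("cutoff must lie in (0, Nyquist)")


def process_emg(raw: np.ndarray, cfg: EmgChainConfig | None = None) -> np.ndarray:
    """Raw EMG (``cfg.raw_rate`` Hz) -> 50 Hz envelope.

    High-pass filter, non-overlapping bin means (one bin per output sample),
    rectification; output length is ``floor(len(raw)/bin_samples)``.
    """
    cfg = cfg or EmgChainConfig()
    raw = np.asarray(raw, dtype=float)
    if raw.size < cfg.bin_samples:
        raise ValueError("input shorter than one bin")
    sos = signal.butter(
        cfg.highpass_order, cfg.highpass_cutoff, btype="highpass", fs=cfg.raw_rate,
        output="sos",
    )
    hp = signal.sosfilt(sos, raw)
    nbins = raw.size // cfg.bin_samples
    binned = hp[: nbins * cfg.bin_samples].reshape(nbins, cfg.bin_samples)
    if cfg.rectify_after_average:
        return np.abs(binned.mean(axis=1))
    return np.abs(binned).mean(axis=1)


def normalize_to_mvc(envelope: np.ndarray, mvc_peak: float) -> np.ndarray:
    """Express an envelope as a fraction of the peak MVC envelope.

    Values above 1 are allowed (effort beyond the calibration contraction)
    and logged, not clipped.
    """
    if not mvc_peak > 0:
        raise ValueError("mvc_peak must be positive")
    out = np.asarray(envelope, dtype=float) / mvc_peak
    if np.any(out > 1.0):
        log.debug("envelope exceeds MVC peak on %d samples", int(np.sum(out > 1.0)))
    return out


@lru_cache(maxsize=None)
def _force_filter_ba(order: int, cutoff: float, sample_rate: float):
    # Impulse-invariant discretization of the analog Butterworth prototype,
    # renormalized to exactly unity DC gain. This keeps the digital magnitude
    # response on the analog Butterworth curve across the whole band
    # (a bilinear design would warp the stopband hard toward Nyquist).
    b_a, a_a = signal.butter(order, 2 * np.pi * cutoff, btype="low", analog=True)
    A, B, C, D = signal.tf2ss(b_a, a_a)
    Ad, Bd, Cd, Dd, _ = signal.cont2discrete((A, B, C, D), 1.0 / sample_rate, method="impulse")
    b, a = signal.ss2tf(Ad, Bd, Cd, Dd)
    b = np.atleast_2d(b)[0]
    dc = np.sum(b) / np.sum(a)
    return b / dc, a


def lowpass_force(force: np.ndarray, cfg: ForceFilterConfig | None = None) -> np.ndarray:
    """Causal low-pass filtering of a force series; unity DC gain."""
    cfg = cfg or ForceFilterConfig()
    force = np.asarray(force, dtype=float)
    if force.size == 0:
        raise ValueError("empty force series")
    b, a = _force_filter_ba(cfg.order, cfg.cutoff, cfg.sample_rate)
    return signal.lfilter(b, a, force)


def threshold_velocity_controller(
    envelope: np.ndarray,
    threshold: float,
    control_cfg,
    start_aperture: float,
) -> np.ndarray:
    """Bang-bang aperture control from a normalized EMG envelope.

    Per 50 Hz sample: close at ``close_velocity`` while the envelope is at
    or above threshold, otherwise open at ``open_velocity``; Euler
    integration clamped to the aperture range. ``control_cfg`` needs
    ``close_velocity``, ``open_velocity``, ``aperture_range`` and
    ``sample_rate`` attributes.
    """
    envelope = np.asarray(envelope, dtype=float)
    lo, hi = sorted(control_cfg.aperture_range)
    if not lo <= start_aperture <= hi:
        raise ValueError("start_aperture outside aperture_range")
    dt = 1.0 / control_cfg.sample_rate
    ap = np.empty(envelope.size, dtype=float)
    a = float(start_aperture)
    for i, e in enumerate(envelope):
        v = -control_cfg.close_velocity if e >= threshold else control_cfg.open_velocity
        a = min(hi, max(lo, a + v * dt))
        ap[i] = a
    return ap
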