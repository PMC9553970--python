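"""Object sets and randomized presentation schedules for discrimination tasks.

An object-discrimination session presents a fixed multiset of objects in
random order. Objects differ categorically in size and/or compliance; each
categorical class is backed by a physical surrogate used by the grasp
simulator: the hand aperture (deg) at which the fingertips first contact the
object, and a contact stiffness (N per degree of further closure). Larger
objects are touched at larger apertures (less closure); stiffer objects
produce more force per degree of squeeze.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SIZE_ORDER = ("XS", "S", "M", "L")
COMPLIANCE_ORDER = ("soft", "medium", "hard")
SHAPES = ("sphere", "cylinder", "cube")


@dataclass(frozen=True)
class ObjectSpec:
    """One presentable object: categorical classes plus physical surrogates."""

    shape: str
    size_class: str
    compliance_class: str
    contact_aperture: float  # deg of hand opening at first fingertip contact
    stiffness: float  # N per deg of closure beyond contact

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.size_class not in SIZE_ORDER:
            raise ValueError(f"unknown size class {self.size_class!r}")
        if self.compliance_class not in COMPLIANCE_ORDER:
            raise ValueError(f"unknown compliance class {self.compliance_class!r}")
        if not self.stiffness > 0:
            raise ValueError("stiffness must be > 0")
        if not self.contact_aperture > 0:
            raise ValueError("contact_aperture must be > 0")


@dataclass(frozen=True)
class ScheduledTrial:
    trial_index: int
    obj: ObjectSpec
    queried_property: str  # "size" or "compliance"


@dataclass
class SessionSchedule:
    """Ordered trial list for one discrimination session."""

    task_label: str  # "size_discrimination" or "compliance_discrimination"
    trials: list[ScheduledTrial]
    rng_seed: int
    exploration_timeout: float  # seconds

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "trial_index": t.trial_index,
                "shape": t.obj.shape,
                "size_class": t.obj.size_class,
                "compliance_class": t.obj.compliance_class,
                "contact_aperture_deg": t.obj.contact_aperture,
                "stiffness_N_per_deg": t.obj.stiffness,
                "queried_property": t.queried_property,
                "timeout_s": self.exploration_timeout,
                "seed": self.rng_seed,
            }
            for t in self.trials
        ]
        return pd.DataFrame(rows)


def _check_monotone(mapping: Mapping[str, float], order: Sequence[str], what: str) -> None:
    present = [c for c in order if c in mapping]
    vals = [mapping[c] for c in present]
    if any(b <= a for a, b in zip(vals, vals[1:])):
        raise ValueError(
            f"{what} must be strictly increasing across classes {present}: got {vals}"
        )


def build_object_set(
    shape: str,
    sizes: Mapping[str, float],
    compliances: Mapping[str, float],
) -> list[ObjectSpec]:
    """Full factorial object set from size→contact-aperture and
    compliance→stiffness maps.

    Apertures must increase strictly with size class and stiffness strictly
    with compliance class; violations raise ``ValueError``. A property held
    fixed is a single-entry map, yielding a singleton factor.
    """
    if not sizes or not compliances:
        raise ValueError("need at least one size class and one compliance class")
    _check_monotone(sizes, SIZE_ORDER, "contact_aperture")
    _check_monotone(compliances, COMPLIANCE_ORDER, "stiffness")
    out = []
    for size in (c for c in SIZE_ORDER if c in sizes):
        for comp in (c for c in COMPLIANCE_ORDER if c in compliances):
            out.append(
                ObjectSpec(
                    shape=shape,
                    size_class=size,
                    compliance_class=comp,
                    contact_aperture=float(sizes[size]),
                    stiffness=float(compliances[comp]),
                )
            )
    return out


def make_schedule(
    object_set: Sequence[ObjectSpec],
    repetitions: int | Sequence[int],
    seed: int,
    timeout: float,
    queried_property: str = "size",
    block_randomized: bool = False,
) -> SessionSchedule:
    """Randomized presentation schedule.

    ``repetitions`` is either one count applied to every object or a
    per-object sequence aligned with ``object_set``. The default is a single
    uniform shuffle of the full trial multiset; ``block_randomized`` instead
    shuffles one copy of each object per block (requires a uniform count).
    """
    if timeout <= 0:
        raise ValueError("timeout must be positive")
    if queried_property not in ("size", "compliance"):
        raise ValueError("queried_property must be 'size' or 'compliance'")
    if isinstance(repetitions, (int, np.integer)):
        reps = [int(repetitions)] * len(object_set)
    else:
        reps = [int(r) for r in repetitions]
        if len(reps) != len(object_set):
            raise ValueError("per-object repetition list length mismatch")
    if any(r < 0 for r in reps):
        raise ValueError("repetition counts must be >= 0")

    rng = np.random.default_rng(seed)
    if block_randomized:
        if len(set(reps)) > 1:
            raise ValueError("block randomization requires a uniform repetition count")
        order: list[ObjectSpec] = []
        for _ in range(reps[0] if reps else 0):
            block = list(object_set)
            order.extend(block[i] for i in rng.permutation(len(block)))
    else:
        pool = [obj for obj, r in zip(object_set, reps) for _ in range(r)]
        order = [pool[i] for i in rng.permutation(len(pool))]

    trials = [
        ScheduledTrial(trial_index=i, obj=obj, queried_property=queried_property)
        for i, obj in enumerate(order)
    ]
    label = f"{queried_property}_discrimination"
    return SessionSchedule(
        task_label=label, trials=trials, rng_seed=int(seed), exploration_timeout=float(timeout)
    )


# ---------------------------------------------------------------------------
# Built-in presets mirroring the published task designs.
# Contact apertures / stiffnesses are surrogate calibration values (the study
# reports only categorical sizes and compliances); every statistic downstream
# depends only on their ordering.

_S1_SIZES = {"S": 30.0, "M": 45.0, "L": 60.0}
_S1_CUBE_SIZES = {"XS": 18.0, "S": 30.0, "M": 45.0, "L": 60.0}
_S2_CYL_SIZES = {"S": 52.0, "M": 56.0, "L": 60.0}
_STIFF = {"soft": 0.05, "medium": 0.15, "hard": 0.45}


@dataclass(frozen=True)
class TaskPreset:
    name: str
    shape: str
    sizes: Mapping[str, float]
    compliances: Mapping[str, float]
    repetitions: int | tuple[int, ...]
    queried_property: str
    timeout: float
    control_scheme: str  # "glove_proportional" or "emg_threshold_velocity"
    encoding_scheme: str  # "linear" or "exponential"

    def object_set(self) -> list[ObjectSpec]:
        return build_object_set(self.shape, self.sizes, self.compliances)

    def schedule(self, seed: int, block_randomized: bool = False) -> SessionSchedule:
        return make_schedule(
            self.object_set(),
            self.repetitions,
            seed=seed,
            timeout=self.timeout,
            queried_property=self.queried_property,
            block_randomized=block_randomized,
        )


PRESETS: dict[str, TaskPreset] = {
    # Subject 1, glove-proportional control, virtual hand: 9 spheres
    # (3 sizes x 3 compliances), exponential encoding.
    "S1-virtual-size": TaskPreset(
        "S1-virtual-size", "sphere", _S1_SIZES, _STIFF, 8, "size", 10.0,
        "glove_proportional", "exponential",
    ),
    "S1-virtual-compliance": TaskPreset(
        "S1-virtual-compliance", "sphere", _S1_SIZES, _STIFF, 10, "compliance", 10.0,
        "glove_proportional", "exponential",
    ),
    # Subject 1, physical hand: 4 cube sizes of one foam (9/18/12/16 reps).
    "S1-physical-size": TaskPreset(
        "S1-physical-size", "cube", _S1_CUBE_SIZES, {"medium": 0.15},
        (9, 18, 12, 16), "size", 10.0, "glove_proportional", "linear",
    ),
    # Subject 2, EMG threshold control, linear encoding, cylinders.
    "S2-virtual-compliance": TaskPreset(
        "S2-virtual-compliance", "cylinder", {"L": 60.0}, _STIFF, 25,
        "compliance", 10.0, "emg_threshold_velocity", "linear",
    ),
    "S2-physical-size": TaskPreset(
        "S2-physical-size", "cylinder", _S2_CYL_SIZES, {"hard": 0.45}, 10,
        "size", 20.0, "emg_threshold_velocity", "linear",
    ),
    "S2-physical-compliance": TaskPreset(
        "S2-physical-compliance", "cylinder", {"M": 56.0}, _STIFF, 20,
        "compliance", 20.0, "emg_threshold_velocity", "linear",
    ),
}


def get_preset(name: str) -> TaskPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


def chance_level(preset: TaskPreset) -> float:
    """Guessing probability 1/K for the preset's queried property."""
    k = len(preset.sizes) if preset.queried_property == "size" else len(preset.compliances)
    return 1.0 / k
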