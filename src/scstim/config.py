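"""Experiment configuration: schema-validated, YAML round-trippable."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from . import grasp_sim, stim_encoder, task_design


class ControlModel(BaseModel):
    scheme: Literal["glove_proportional", "emg_threshold_velocity"] = "glove_proportional"
    close_velocity: float = Field(15.0, gt=0)
    open_velocity: float = Field(30.0, gt=0)
    emg_threshold: float = Field(0.05, gt=0, lt=1)
    aperture_open: float = 90.0
    aperture_closed: float = 0.0
    sample_rate: float = Field(50.0, gt=0)
    glove_ballistic_rate: float = Field(250.0, gt=0)
    glove_smooth_rate: float = Field(40.0, gt=0)

    def to_dataclass(self) -> grasp_sim.ControlConfig:
        return grasp_sim.ControlConfig(
            scheme=self.scheme,
            close_velocity=self.close_velocity,
            open_velocity=self.open_velocity,
            emg_threshold=self.emg_threshold,
            aperture_range=(self.aperture_open, self.aperture_closed),
            sample_rate=self.sample_rate,
            glove_ballistic_rate=self.glove_ballistic_rate,
            glove_smooth_rate=self.glove_smooth_rate,
        )


class NoiseModel(BaseModel):
    sensor_noise_sd: float = Field(0.05, ge=0)
    command_onset_jitter_sd: float = Field(0.2, ge=0)
    glove_ballistic: bool = True

    def to_dataclass(self) -> grasp_sim.NoiseConfig:
        return grasp_sim.NoiseConfig(
            sensor_noise_sd=self.sensor_noise_sd,
            command_onset_jitter_sd=self.command_onset_jitter_sd,
            glove_ballistic=self.glove_ballistic,
        )


class EncodingModel(BaseModel):
    scheme: Literal["linear", "exponential"] = "linear"
    F_min: float = 0.0
    F_max: float = 10.0
    A_min: float = Field(1.0, ge=0)
    A_max: float = Field(6.0, le=stim_encoder.HARDWARE_MAX_MA)
    omega: float = Field(0.01, gt=0)
    contact_threshold: float = Field(0.2, ge=0)
    exp_threshold: float = 10.0
    sensor_counts_per_newton: float = Field(50.0, gt=0)

    @model_validator(mode="after")
    def _ranges(self):
        if not self.F_min < self.F_max:
            raise ValueError("F_min must be < F_max")
        if not self.A_min < self.A_max:
            raise ValueError("A_min must be < A_max")
        return self

    def to_dataclass(self) -> stim_encoder.EncodingConfig:
        return stim_encoder.EncodingConfig(
            scheme=self.scheme, F_min=self.F_min, F_max=self.F_max,
            A_min=self.A_min, A_max=self.A_max, omega=self.omega,
            contact_threshold=self.contact_threshold,
            exp_threshold=self.exp_threshold,
            sensor_counts_per_newton=self.sensor_counts_per_newton,
        )


class StimTrainModel(BaseModel):
    frequency: float = Field(100.0, ge=1.0, le=300.0)
    pulse_width: float = Field(200.0, ge=50.0, le=1000.0)
    interphase: float = Field(60.0, ge=0)
    configuration: Literal["monopolar", "multipolar"] = "monopolar"
    electrode_id: str = "SCS-1"

    def to_dataclass(self) -> stim_encoder.StimTrain:
        return stim_encoder.StimTrain(
            frequency=self.frequency, pulse_width=self.pulse_width,
            interphase=self.interphase, configuration=self.configuration,
            electrode_id=self.electrode_id,
        )


class AnalysisOptions(BaseModel):
    feature_subset: Optional[list[str]] = None
    ellipse_n_std: float = Field(1.0, gt=0)


class ExperimentConfig(BaseModel):
    """Everything needed to reproduce a simulated session byte-for-byte."""

    preset: Optional[str] = None
    control: ControlModel = ControlModel()
    noise: NoiseModel = NoiseModel()
    encoding: EncodingModel = EncodingModel()
    train: StimTrainModel = StimTrainModel()
    analysis: AnalysisOptions = AnalysisOptions()
    master_seed: int = 0
    block_randomized: bool = False

    @model_validator(mode="after")
    def _preset_known(self):
        if self.preset is not None and self.preset not in task_design.PRESETS:
            raise ValueError(
                f"unknown preset {self.preset!r}; available: {sorted(task_design.PRESETS)}"
            )
        return self


def config_for_preset(name: str, master_seed: int = 0) -> ExperimentConfig:
    """A full config with control/noise/encoding defaults matched to the
    named task preset."""
    preset = task_design.get_preset(name)
    control = ControlModel(scheme=preset.control_scheme)
    if preset.control_scheme == grasp_sim.EMG_SCHEME:
        noise = NoiseModel(command_onset_jitter_sd=1.5, glove_ballistic=False)
    else:
        noise = NoiseModel(command_onset_jitter_sd=0.2, glove_ballistic=True)
    encoding = EncodingModel(scheme=preset.encoding_scheme)
    return ExperimentConfig(
        preset=name, control=control, noise=noise, encoding=encoding,
        master_seed=master_seed,
    )


def load_config(path: str | Path) -> ExperimentConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return ExperimentConfig.model_validate(data)


def dump_config(cfg: ExperimentConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(mode="json"), fh, sort_keys=True)


def config_hash(cfg: ExperimentConfig) -> str:
    canon = json.dumps(cfg.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(canon).hexdigest()
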