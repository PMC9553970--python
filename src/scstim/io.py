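"""Trial-trace serialization and run-directory manifests.

CSV files are RFC-4180, UTF-8, '.' decimal separator, mandatory header.
A run directory is self-describing: schedule.csv, one trace CSV per trial,
and manifest.json holding the config, seeds, and per-file checksums.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ExperimentConfig, config_hash
from .grasp_sim import GraspTrace
from .stim_encoder import StimTrace
from .task_design import ObjectSpec, SessionSchedule

TRACE_COLUMNS = ("time_s", "command", "aperture_deg", "raw_force_N", "filtered_force_N", "stim_mA")


def trace_frame(grasp: GraspTrace, stim: StimTrace) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_s": grasp.time,
            "command": grasp.command,
            "aperture_deg": grasp.aperture,
            "raw_force_N": grasp.raw_force,
            "filtered_force_N": grasp.filtered_force,
            "stim_mA": stim.amplitude,
        }
    )


def write_trial_csv(path: Path, grasp: GraspTrace, stim: StimTrace) -> None:
    trace_frame(grasp, stim).to_csv(path, index=False, float_format="%.9g")


def read_trial(path: Path, row: pd.Series, scheme: str, command_threshold: float | None):
    """Rebuild (GraspTrace, amplitude array) from a trace CSV plus its
    schedule row (which carries the object labels and surrogates)."""
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path.name}: missing columns {sorted(missing)}")
    obj = ObjectSpec(
        shape=row["shape"], size_class=row["size_class"],
        compliance_class=row["compliance_class"],
        contact_aperture=float(row["contact_aperture_deg"]),
        stiffness=float(row["stiffness_N_per_deg"]),
    )
    t = df["time_s"].to_numpy(float)
    cmd = df["command"].to_numpy(float)
    if scheme == "emg_threshold_velocity" and command_threshold is not None:
        above = np.nonzero(cmd >= command_threshold)[0]
        onset = float(t[above[0]]) if above.size else float("nan")
    else:
        onset = float("nan")
    grasp = GraspTrace(
        time=t, command=cmd, aperture=df["aperture_deg"].to_numpy(float),
        raw_force=df["raw_force_N"].to_numpy(float),
        filtered_force=df["filtered_force_N"].to_numpy(float),
        obj=obj, command_onset_time=onset, scheme=scheme,
        command_threshold=command_threshold,
    )
    return grasp, df["stim_mA"].to_numpy(float)


def sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(
    run_dir: Path, cfg: ExperimentConfig, schedule: SessionSchedule, files: list[str]
) -> None:
    manifest = {
        "config": cfg.model_dump(mode="json"),
        "config_hash": config_hash(cfg),
        "master_seed": cfg.master_seed,
        "schedule_seed": schedule.rng_seed,
        "n_trials": len(schedule),
        "files": {name: sha256_file(run_dir / name) for name in files},
    }
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def read_manifest(run_dir: Path) -> dict:
    path = Path(run_dir) / "manifest.json"
    if not path.exists():
        raise FileNotFoundError(f"no manifest.json in {run_dir}")
    with open(path) as fh:
        return json.load(fh)


class _JsonEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        return super().default(o)


def dump_report(report: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, cls=_JsonEncoder, allow_nan=True)
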