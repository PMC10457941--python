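"""File formats and validated run configuration.

CSV dialect: comma-separated, ``.`` decimal, UTF-8, LF. Tri-axial series use
the header ``time_s,x,y,z`` (one row per sample, strictly increasing time,
uniform step to 1e-9 s); the nine-channel reference array uses
``time_s,a0x,a0y,a0z,axy,axz,ayx,ayz,azx,azy``. Units and frame travel in a
JSON sidecar or in the run configuration, never in the CSV itself.

Run configurations are pydantic-validated with unknown keys rejected, so a
typo in a config file fails loudly instead of silently using a default.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .core import HeadKinematics, TimeSeries3
from .exceptions import FormatError
from .headform import CHANNEL_NAMES, ArrayGeometry, AtdChannels
from .mouthguard import ImgSpec
from .rig import CampaignConfig, NoiseSpec

__all__ = [
    "read_timeseries_csv",
    "write_timeseries_csv",
    "read_atd_csv",
    "write_atd_csv",
    "ImgSpecModel",
    "GeometryModel",
    "NoiseModel",
    "CampaignModel",
    "RunConfig",
    "load_img_spec",
    "load_geometry",
    "load_run_config",
    "kinematics_to_dict",
    "write_event_json",
]

_TIME_TOL = 1e-9


def _check_time_column(t: np.ndarray) -> float:
    """Validate strict monotonicity and uniform step; return the sample rate."""
    if t.size < 2:
        raise FormatError("need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.flatnonzero(dt <= 0)[0]) + 1
        raise FormatError(f"time not strictly increasing at row {row}")
    if np.any(np.abs(dt - dt[0]) > _TIME_TOL):
        row = int(np.flatnonzero(np.abs(dt - dt[0]) > _TIME_TOL)[0]) + 1
        raise FormatError(f"non-uniform sample interval at row {row}")
    return 1.0 / float(dt[0])


def _read_csv(path, columns) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def read_timeseries_csv(path, units: str = "m/s^2", frame: str = "sensor") -> TimeSeries3:
    """Read a ``time_s,x,y,z`` CSV into a :class:`TimeSeries3`."""
    df = _read_csv(path, ("time_s", "x", "y", "z"))
    t = df["time_s"].to_numpy(dtype=float)
    rate = _check_time_column(t)
    return TimeSeries3(
        df[["x", "y", "z"]].to_numpy(dtype=float),
        rate=rate, start_time=float(t[0]), units=units, frame=frame,
    )


def write_timeseries_csv(ts: TimeSeries3, path) -> None:
    """Write a series as ``time_s,x,y,z`` at full float precision."""
    df = pd.DataFrame(
        {"time_s": ts.times(), "x": ts.data[:, 0], "y": ts.data[:, 1], "z": ts.data[:, 2]}
    )
    df.to_csv(path, index=False, float_format="%.17g", lineterminator="\n")


def read_atd_csv(path) -> AtdChannels:
    """Read the nine-channel 3-2-2-2 array CSV (m/s^2, head frame)."""
    df = _read_csv(path, ("time_s",) + CHANNEL_NAMES)
    t = df["time_s"].to_numpy(dtype=float)
    rate = _check_time_column(t)
    return AtdChannels(
        df[list(CHANNEL_NAMES)].to_numpy(dtype=float), rate=rate, start_time=float(t[0])
    )


def write_atd_csv(ch: AtdChannels, path) -> None:
    df = pd.DataFrame({"time_s": ch.times()})
    for k, name in enumerate(CHANNEL_NAMES):
        df[name] = ch.data[:, k]
    df.to_csv(path, index=False, float_format="%.17g", lineterminator="\n")


# ---------------------------------------------------------------------------
# validated configuration models
# ---------------------------------------------------------------------------

class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ImgSpecModel(_StrictModel):
    """JSON-facing mouthguard sensor specification."""

    accel_rate: float = 1000.0
    gyro_rate: float = 1666.0
    accel_range_g: float = 400.0
    gyro_range: float = 35.0
    resolution_bits: int = 12
    cutoff: float = 160.0
    filter_order: int = 4
    trigger_threshold_g: float = 10.0
    pre_ms: float = 10.0
    post_ms: float = 94.0
    r_sensor_to_com: list[float] = Field(default=[0.0, 0.0, -0.08])
    R_sensor_to_head: list[list[float]] = Field(
        default=[[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )

    def build(self) -> ImgSpec:
        return ImgSpec(
            accel_rate=self.accel_rate, gyro_rate=self.gyro_rate,
            accel_range_g=self.accel_range_g, gyro_range=self.gyro_range,
            resolution_bits=self.resolution_bits, cutoff=self.cutoff,
            filter_order=self.filter_order,
            trigger_threshold_g=self.trigger_threshold_g,
            pre_ms=self.pre_ms, post_ms=self.post_ms,
            r_sensor_to_com=np.array(self.r_sensor_to_com),
            R_sensor_to_head=np.array(self.R_sensor_to_head),
        )


class GeometryModel(_StrictModel):
    rho_x: float = 0.0635
    rho_y: float = 0.0635
    rho_z: float = 0.0635

    def build(self) -> ArrayGeometry:
        return ArrayGeometry(rho_x=self.rho_x, rho_y=self.rho_y, rho_z=self.rho_z)


class NoiseModel(_StrictModel):
    accel_noise_sd: float = 0.3 * 9.80665
    gyro_noise_sd: float = 0.03
    misalignment_deg: float = 2.0
    quantize: bool = True
    atd_noise_sd: float = 0.0

    def build(self) -> NoiseSpec:
        return NoiseSpec(**self.model_dump())


class CampaignModel(_StrictModel):
    n_trials: int = 80
    mode: str = "random"
    locations: list[str] = Field(default=["front", "side", "rear", "rear_side"])
    speeds: list[float] = Field(default=[2, 3, 4, 5, 6, 7, 8])
    duration_range_ms: list[float] = Field(default=[6.0, 18.0])
    noise: NoiseModel = Field(default_factory=NoiseModel)
    seed: int = 0
    master_rate: float = 50000.0

    def build(self) -> CampaignConfig:
        return CampaignConfig(
            n_trials=self.n_trials, mode=self.mode,
            locations=tuple(self.locations), speeds=tuple(self.speeds),
            duration_range_ms=tuple(self.duration_range_ms),
            noise=self.noise.build(), seed=self.seed, master_rate=self.master_rate,
        )


class RunConfig(_StrictModel):
    """Top-level run configuration for the command-line interface."""

    campaign: CampaignModel = Field(default_factory=CampaignModel)
    img: ImgSpecModel = Field(default_factory=ImgSpecModel)
    geometry: GeometryModel = Field(default_factory=GeometryModel)


def _load_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def load_img_spec(path) -> ImgSpec:
    return ImgSpecModel.model_validate(_load_json(path)).build()


def load_geometry(path) -> ArrayGeometry:
    return GeometryModel.model_validate(_load_json(path)).build()


def load_run_config(path) -> RunConfig:
    return RunConfig.model_validate(_load_json(path))


# ---------------------------------------------------------------------------
# event serialization
# ---------------------------------------------------------------------------

def _series_to_dict(ts: TimeSeries3) -> dict:
    return {
        "rate": ts.rate,
        "start_time": ts.start_time,
        "units": ts.units,
        "frame": ts.frame,
        "data": ts.data.tolist(),
    }


def kinematics_to_dict(hk: HeadKinematics) -> dict:
    return {
        "lin_acc_com": _series_to_dict(hk.lin_acc_com),
        "rot_vel": _series_to_dict(hk.rot_vel),
        "rot_acc": _series_to_dict(hk.rot_acc),
        "peaks": hk.peak_metrics(),
    }


def write_event_json(hk: HeadKinematics, path, qc_flags=(), extra=None) -> None:
    doc = kinematics_to_dict(hk)
    doc["qc_flags"] = sorted(qc_flags)
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh)


def write_campaign(trials, outdir) -> Path:
    """Write per-trial raw CSVs plus ``manifest.json``; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = []
    for k, trial in enumerate(trials):
        tid = f"trial_{k:03d}"
        paths = {
            "img_accel": f"{tid}_img_accel.csv",
            "img_gyro": f"{tid}_img_gyro.csv",
            "atd": f"{tid}_atd.csv",
        }
        write_timeseries_csv(trial.img_accel, outdir / paths["img_accel"])
        write_timeseries_csv(trial.img_gyro, outdir / paths["img_gyro"])
        write_atd_csv(trial.atd, outdir / paths["atd"])
        spec = trial.spec
        records.append({
            "trial_id": tid,
            "location": spec.location,
            "speed": spec.speed,
            "duration_s": spec.duration,
            "seed": spec.seed,
            "truth_peaks": dict(trial.truth_peaks),
            "files": paths,
        })
    manifest = outdir / "manifest.json"
    with open(manifest, "w") as fh:
        json.dump({"schema_version": "1", "trials": records}, fh, indent=2)
    return manifest
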