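"""File formats, session manifests and the end-to-end pipeline driver.

Sensor streams are plain CSV: IMU files carry ``time_s, gyro_x_degs,
gyro_y_degs, gyro_z_degs`` (the chest file adds ``pitch_deg``); the
ergometer file carries ``time_s, torque_l_nm, torque_r_nm, v_l_ms,
v_r_ms``.  A YAML manifest links the files to athlete and wheelchair
constants.  Readers validate headers and time monotonicity, report
sample gaps and reinterpolate onto a uniform grid.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coastdown import RollingResistanceModel, process_trial, solve_coefficients
from .errors import DependencyError, ParseError
from .kinematics import ImuRecording, field_outcomes, process_recording
from .lab import ErgometerTrace, sprint_outcomes, wingate_p30
from .params import CourseSpec, SimulationParams
from .power import sprint_power
from .simulate import GroundTruth
from .stats import best_attempt

IMU_COLUMNS = ["time_s", "gyro_x_degs", "gyro_y_degs", "gyro_z_degs"]
ERG_COLUMNS = ["time_s", "torque_l_nm", "torque_r_nm", "v_l_ms", "v_r_ms"]


# ---------------------------------------------------------------------------
# low-level readers/writers


def _read_csv(path: Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed beyond recovery
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: line 1: missing columns {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    bad = np.nonzero(dt <= 0)[0]
    if bad.size:
        raise ParseError(f"{path}: line {int(bad[0]) + 3}: non-monotone time")
    return df


def _uniform_grid(path: Path, df: pd.DataFrame, channels: list[str]) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Reinterpolate onto a uniform grid if the stream has gaps."""
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    step = float(np.median(dt))
    gaps = np.nonzero(dt > 1.5 * step)[0]
    if gaps.size == 0:
        return t, {c: df[c].to_numpy(dtype=float) for c in channels}
    n_dropped = int(round(float(np.sum(dt[gaps])) / step)) - gaps.size
    warnings.warn(f"{path}: {gaps.size} gap(s), ~{n_dropped} dropped sample(s); reinterpolated")
    n = int(round((t[-1] - t[0]) / step))
    tu = t[0] + np.arange(n + 1) * step
    return tu, {c: np.interp(tu, t, df[c].to_numpy(dtype=float)) for c in channels}


def write_imu_csv(path, t: np.ndarray, gyro: np.ndarray, pitch: Optional[np.ndarray] = None) -> None:
    data = {
        "time_s": t,
        "gyro_x_degs": gyro[:, 0],
        "gyro_y_degs": gyro[:, 1],
        "gyro_z_degs": gyro[:, 2],
    }
    if pitch is not None:
        data["pitch_deg"] = pitch
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def read_imu_csv(path) -> tuple[np.ndarray, np.ndarray, Optional[np.ndarray]]:
    """Read one sensor stream; returns ``(t, gyro (n,3), pitch or None)``."""
    path = Path(path)
    df = _read_csv(path, IMU_COLUMNS)
    channels = IMU_COLUMNS[1:] + (["pitch_deg"] if "pitch_deg" in df.columns else [])
    t, chan = _uniform_grid(path, df, channels)
    gyro = np.column_stack([chan["gyro_x_degs"], chan["gyro_y_degs"], chan["gyro_z_degs"]])
    pitch = chan.get("pitch_deg")
    return t, gyro, pitch


def write_ergometer_csv(path, trace: ErgometerTrace) -> None:
    pd.DataFrame({
        "time_s": trace.t,
        "torque_l_nm": trace.torque_left,
        "torque_r_nm": trace.torque_right,
        "v_l_ms": trace.v_left,
        "v_r_ms": trace.v_right,
    }).to_csv(path, index=False, float_format="%.17g")


def read_ergometer_csv(path, wheel_radius: float, body_mass: float) -> ErgometerTrace:
    path = Path(path)
    df = _read_csv(path, ERG_COLUMNS)
    t, chan = _uniform_grid(path, df, ERG_COLUMNS[1:])
    return ErgometerTrace(
        t=t,
        torque_left=chan["torque_l_nm"],
        torque_right=chan["torque_r_nm"],
        v_left=chan["v_l_ms"],
        v_right=chan["v_r_ms"],
        wheel_radius=wheel_radius,
        body_mass=body_mass,
    )


def write_ground_truth_csv(path, truth: GroundTruth) -> None:
    pd.DataFrame({
        "time_s": truth.t,
        "v_lin_ms": truth.v_lin,
        "v_rot_degs": truth.v_rot,
        "x_m": truth.x,
        "y_m": truth.y,
        "trunk_pitch_deg": truth.trunk_pitch,
        "f_push_n": truth.F_push,
        "f_roll_n": truth.F_roll,
    }).to_csv(path, index=False, float_format="%.17g")


def write_model_yaml(path, model: RollingResistanceModel) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(model), fh, sort_keys=False)


def read_model_yaml(path) -> RollingResistanceModel:
    with open(path) as fh:
        return RollingResistanceModel(**yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# session writing (simulator output -> files + manifest)


def _params_dict(params: SimulationParams) -> dict[str, Any]:
    d = asdict(params)
    d["course"] = asdict(params.course)
    d["course"]["waypoints"] = [list(p) for p in params.course.waypoints]
    d["course"]["posture_schedule"] = [list(p) for p in params.course.posture_schedule]
    return d


def params_from_dict(d: dict[str, Any]) -> SimulationParams:
    d = dict(d)
    c = dict(d.pop("course"))
    c["waypoints"] = tuple(tuple(p) for p in c.get("waypoints", ()))
    c["posture_schedule"] = tuple(tuple(p) for p in c.get("posture_schedule", ()))
    return SimulationParams(course=CourseSpec(**c), **d)


def write_session(
    outdir,
    params: SimulationParams,
    truth: GroundTruth,
    imu: Optional[ImuRecording] = None,
    erg: Optional[ErgometerTrace] = None,
    test: Optional[str] = None,
    prefix: str = "",
) -> Path:
    """Write a simulated session (CSV per sensor + YAML manifest).

    Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    if imu is not None:
        for sensor in ("left_wheel", "right_wheel", "frame", "chest"):
            name = f"{prefix}{sensor}.csv"
            pitch = imu.chest_pitch if sensor == "chest" else None
            write_imu_csv(outdir / name, imu.t, imu.gyro[sensor], pitch)
            files[sensor] = name
    if erg is not None:
        name = f"{prefix}ergometer.csv"
        write_ergometer_csv(outdir / name, erg)
        files["ergometer"] = name
    name = f"{prefix}ground_truth.csv"
    write_ground_truth_csv(outdir / name, truth)
    files["ground_truth"] = name

    manifest = {
        "session": {"test": test or params.course.kind, "seed": params.seed},
        "athlete": {"body_mass": params.body_mass, "group": None},
        "wheelchair": {
            "wheel_radius": params.wheel_radius,
            "wheel_circumference": params.wheel_circumference,
            "camber": params.camber,
            "total_mass": params.m_total,
        },
        "files": files,
        "params": _params_dict(params),
    }
    mpath = outdir / f"{prefix}manifest.yaml"
    with open(mpath, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return mpath


# ---------------------------------------------------------------------------
# study manifest + pipeline driver


def load_imu_recording(base: Path, files: dict[str, str], wheel_circumference: float, camber: float) -> ImuRecording:
    gyro: dict[str, np.ndarray] = {}
    pitch = None
    t = None
    for sensor in ("left_wheel", "right_wheel", "frame", "chest"):
        if sensor not in files:
            continue
        ts, g, p = read_imu_csv(base / files[sensor])
        gyro[sensor] = g
        if sensor == "chest":
            pitch = p
        t = ts
    if t is None:
        raise ParseError("no IMU sensor files in manifest entry")
    return ImuRecording(
        t=t, gyro=gyro, chest_pitch=pitch,
        wheel_circumference=wheel_circumference, camber=camber,
    )


def _manifest_hash(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(manifest_path, outdir=None, filter_mode: str = "causal") -> dict[str, Any]:
    """Dispatch all stages a study manifest asks for.

    Manifest layout::

        athlete:    {body_mass, group}
        wheelchair: {wheel_radius, wheel_circumference, camber, total_mass}
        field_power: auto | true | false
        tests:
          - {type: lab_sprint|wingate, ergometer: file}
          - {type: sprint|illinois|spider, attempt: 1, imu: {left_wheel: ..., ...}}
          - {type: coastdown, posture: upright|forward, trunk_pitch: deg, imu: {...}}

    Returns a results dict; when ``outdir`` is given also writes
    ``outcomes.csv`` and a ``provenance.json`` record that suffices to
    re-run the bundle bit-identically.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    athlete = manifest["athlete"]
    chair = manifest["wheelchair"]
    body_mass = float(athlete["body_mass"])
    m_total = float(chair["total_mass"])
    wc = float(chair["wheel_circumference"])
    camber = float(chair["camber"])
    want_power = manifest.get("field_power", "auto")

    results: dict[str, Any] = {"outcomes": {}, "stages": []}
    coast_trials = []
    field_attempts: dict[str, list] = {}
    field_kin: dict[str, list] = {}

    for entry in manifest.get("tests", []):
        kind = entry["type"]
        try:
            if kind in ("lab_sprint", "wingate"):
                trace = read_ergometer_csv(
                    base / entry["ergometer"], float(chair["wheel_radius"]), body_mass
                )
                if kind == "lab_sprint":
                    out = sprint_outcomes(trace)
                    results["outcomes"]["lab_sprint_po_mean"] = out.po_mean
                    results["outcomes"]["lab_sprint_v_peak"] = out.v_peak
                else:
                    results["outcomes"]["lab_wingate_p30"] = wingate_p30(trace)
            elif kind in ("sprint", "illinois", "spider"):
                rec = load_imu_recording(base, entry["imu"], wc, camber)
                kin = process_recording(rec, kind, filter_mode=filter_mode)
                out = field_outcomes(kin, kind)
                field_attempts.setdefault(kind, []).append(out)
                field_kin.setdefault(kind, []).append((kin, rec))
            elif kind == "coastdown":
                rec = load_imu_recording(base, entry["imu"], wc, camber)
                coast_trials.append(
                    process_trial(
                        rec, entry.get("posture", "upright"), m_total,
                        trunk_pitch=entry.get("trunk_pitch"), filter_mode=filter_mode,
                    )
                )
            else:
                raise ParseError(f"unknown test type {kind!r}")
        except Exception as exc:
            raise type(exc)(f"stage {kind!r}: {exc}") from exc
        results["stages"].append(kind)

    model = None
    if coast_trials:
        model = solve_coefficients(coast_trials)
        results["outcomes"]["mu_front"] = model.mu_front
        results["outcomes"]["mu_rear"] = model.mu_rear

    for kind, attempts in field_attempts.items():
        chosen = best_attempt(attempts)
        idx = attempts.index(chosen)
        results["outcomes"][f"field_{kind}_duration"] = chosen.duration
        if chosen.v_peak_lin is not None:
            results["outcomes"][f"field_{kind}_v_peak_lin"] = chosen.v_peak_lin
        if chosen.v_peak_rot is not None:
            results["outcomes"][f"field_{kind}_v_peak_rot"] = chosen.v_peak_rot
        if kind == "sprint":
            if model is not None:
                kin, rec = field_kin[kind][idx]
                if rec.chest_pitch is None:
                    raise DependencyError("field power needs the chest pitch stream")
                _, po = sprint_power(kin, rec.chest_pitch, model, m_total, body_mass)
                results["outcomes"]["field_sprint_po_mean"] = po
            elif want_power is True:
                raise DependencyError(
                    "field power requested but the manifest has no coast-down trials"
                )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = [{"outcome": k, "value": v} for k, v in sorted(results["outcomes"].items())]
        pd.DataFrame(rows).to_csv(outdir / "outcomes.csv", index=False)
        provenance = {
            "wheelperf_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "manifest": str(manifest_path),
            "manifest_sha256": _manifest_hash(manifest_path),
            "seed": manifest.get("session", {}).get("seed"),
            "filter_mode": filter_mode,
            "stages": results["stages"],
        }
        with open(outdir / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2, sort_keys=True)
    return results
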