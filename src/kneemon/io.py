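"""CSV/JSON readers and writers.

All CSVs are UTF-8, comma-separated, with a mandatory header row.  Floats
are written with six decimal places, matching the precision of the study
tables this package reproduces, and every write -> read round trip is
lossless at that precision.  Malformed inputs raise :class:`ParseError`
naming the offending column and line.
"""

from __future__ import annotations

import json
from dataclasses import asdict, fields as _dc_fields
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParseError
from .features import EmgRecording, WindowFeatures
from .filters import FilterChainSpec
from .kinematics import AngleTrace, DetectionParams, Repetition, accel_to_angle
from .reporting import GroupSummary, SubjectSummary
from .session import SessionConfig, SessionResult, Targets

__all__ = [
    "load_emg_csv",
    "write_emg_csv",
    "load_angle_csv",
    "write_angle_csv",
    "load_config_json",
    "write_config_json",
    "config_from_dict",
    "config_to_dict",
    "write_session_result",
    "write_window_features_csv",
    "write_summary_csv",
    "load_summary_csv",
    "load_reference_cohort",
    "render_report",
]

_FLOAT_FMT = "%.6f"


def _read_csv(path, required: tuple[str, ...], optional_schemas=()) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: file is empty") from None
    except Exception as exc:  # malformed rows, bad tokens
        raise ParseError(f"{path}: {exc}") from None
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    schemas = (required, *optional_schemas)
    for schema in schemas:
        if all(c in df.columns for c in schema):
            df.attrs["schema"] = schema
            break
    else:
        missing = [c for c in required if c not in df.columns]
        raise ParseError(f"{path}: missing column(s) {missing} (header {list(df.columns)})")
    schema = df.attrs["schema"]
    for col in schema:
        vals = pd.to_numeric(df[col], errors="coerce") if col not in (
            "subject_id", "group_label", "week_label") else df[col]
        if col not in ("subject_id", "group_label", "week_label") and vals.isna().any():
            line = int(vals.index[vals.isna()][0]) + 2  # header is line 1
            raise ParseError(f"{path}: non-numeric value in column '{col}' at line {line}")
    return df


def load_emg_csv(path) -> EmgRecording:
    """Read a two-channel EMG CSV with columns time_s, vl_v, vm_v."""
    df = _read_csv(path, ("time_s", "vl_v", "vm_v"))
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) > 1:
        dts = np.diff(t)
        if np.any(dts <= 0):
            line = int(np.argmax(dts <= 0)) + 3
            raise ParseError(f"{path}: time_s not strictly increasing at line {line}")
        fs = 1.0 / float(np.median(dts))
    else:
        fs = 1.0
    return EmgRecording(
        vl=df["vl_v"].to_numpy(dtype=float),
        vm=df["vm_v"].to_numpy(dtype=float),
        sampling_rate_hz=fs,
        t0_s=float(t[0]),
    )


def write_emg_csv(recording: EmgRecording, path) -> None:
    df = pd.DataFrame(
        {"time_s": recording.times_s, "vl_v": recording.vl, "vm_v": recording.vm}
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def load_angle_csv(path) -> AngleTrace:
    """Read an angle CSV; auto-detects by header.

    Either pre-fused angles (time_s, theta_deg) or raw accelerometer
    samples (time_s, ax_g, ay_g, az_g), which are converted by tilt.
    """
    df = _read_csv(
        path,
        ("time_s", "theta_deg"),
        optional_schemas=(("time_s", "ax_g", "ay_g", "az_g"),),
    )
    t = df["time_s"].to_numpy(dtype=float)
    if "theta_deg" in df.attrs["schema"]:
        return AngleTrace(t, df["theta_deg"].to_numpy(dtype=float))
    accel = df[["ax_g", "ay_g", "az_g"]].to_numpy(dtype=float)
    return accel_to_angle(accel, timestamps_s=t)


def write_angle_csv(trace: AngleTrace, path) -> None:
    df = pd.DataFrame({"time_s": trace.timestamps_s, "theta_deg": trace.theta_deg})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# session configuration JSON

_NESTED = {
    "targets": Targets,
    "filter_chain": FilterChainSpec,
    "detection": DetectionParams,
}


def _build_dataclass(cls, data: dict, context: str):
    allowed = {f.name for f in _dc_fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in {context}; allowed: {sorted(allowed)}"
        )
    return cls(**data)


def config_from_dict(data: dict) -> SessionConfig:
    """Build a SessionConfig from a plain dict; unknown keys are rejected."""
    if not isinstance(data, dict):
        raise ConfigurationError(f"session config must be an object, got {type(data).__name__}")
    data = dict(data)
    kwargs = {}
    for key, cls in _NESTED.items():
        if key in data:
            kwargs[key] = _build_dataclass(cls, data.pop(key), f"'{key}'")
    if "hold_target_s" in data:
        data["hold_target_s"] = tuple(data["hold_target_s"])
    allowed = {f.name for f in _dc_fields(SessionConfig)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in session config; allowed: {sorted(allowed)}"
        )
    return SessionConfig(**data, **kwargs)


def config_to_dict(config: SessionConfig) -> dict:
    d = asdict(config)
    d["hold_target_s"] = list(d["hold_target_s"])
    return d


def load_config_json(path) -> SessionConfig:
    path = Path(path)
    try:
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from None
    except FileNotFoundError:
        raise ParseError(f"{path}: file not found") from None
    return config_from_dict(data)


def write_config_json(config: SessionConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(config_to_dict(config), fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# session results

_REP_COLUMNS = [
    "row_type", "index", "t_start_s", "t_peak_s", "t_end_s",
    "theta_max_deg", "theta_min_deg", "rom_deg", "sustained_s",
    "rise_s", "fall_s",
    "mav_vl_v", "mav_vm_v", "rms_vl_v", "rms_vm_v",
    "mav_pass", "rms_pass", "rom_pass",
]


def _fmt(x) -> str:
    return "" if x is None else (_FLOAT_FMT % x if isinstance(x, float) else str(x))


def write_session_result(result: SessionResult, out_dir) -> tuple[Path, Path]:
    """Write session_result.csv (per-rep rows + summary row) and .json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rf in result.per_rep:
        rep = rf.repetition
        rows.append(
            {
                "row_type": "rep",
                "index": rep.index,
                "t_start_s": rep.t_start_s,
                "t_peak_s": rep.t_peak_s,
                "t_end_s": rep.t_end_s,
                "theta_max_deg": rep.theta_max_deg,
                "theta_min_deg": rep.theta_min_deg,
                "rom_deg": rep.rom_deg,
                "sustained_s": rep.sustained_s,
                "rise_s": rep.rise_s,
                "fall_s": rep.fall_s,
                "mav_vl_v": rf.mav_vl_v,
                "mav_vm_v": rf.mav_vm_v,
                "rms_vl_v": rf.rms_vl_v,
                "rms_vm_v": rf.rms_vm_v,
                "mav_pass": None,
                "rms_pass": None,
                "rom_pass": None,
            }
        )
    avg, flags = result.averages, result.pass_flags
    rows.append(
        {
            "row_type": "summary",
            "index": None,
            "t_start_s": None,
            "t_peak_s": None,
            "t_end_s": None,
            "theta_max_deg": None,
            "theta_min_deg": None,
            "rom_deg": avg.avg_rom_deg,
            "sustained_s": None,
            "rise_s": None,
            "fall_s": None,
            "mav_vl_v": avg.avg_mav_vl_v,
            "mav_vm_v": avg.avg_mav_vm_v,
            "rms_vl_v": avg.avg_rms_vl_v,
            "rms_vm_v": avg.avg_rms_vm_v,
            "mav_pass": flags.mav_pass,
            "rms_pass": flags.rms_pass,
            "rom_pass": flags.rom_pass,
        }
    )
    csv_path = out_dir / "session_result.csv"
    with open(csv_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(_REP_COLUMNS) + "\n")
        for row in rows:
            fh.write(",".join(_fmt(row[c]) for c in _REP_COLUMNS) + "\n")

    payload = {
        "subject_id": result.config.subject_id,
        "knee_side": result.config.knee_side,
        "completed": result.completed,
        "n_repetitions": len(result.per_rep),
        "averages": asdict(avg),
        "pass_flags": asdict(flags),
        "per_rep": [
            {**asdict(rf.repetition),
             "mav_vl_v": rf.mav_vl_v, "mav_vm_v": rf.mav_vm_v,
             "rms_vl_v": rf.rms_vl_v, "rms_vm_v": rf.rms_vm_v,
             "hold_in_target": rf.hold_in_target}
            for rf in result.per_rep
        ],
        "config": config_to_dict(result.config),
    }
    json_path = out_dir / "session_result.json"
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return csv_path, json_path


def write_window_features_csv(windows: list[WindowFeatures], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("window_start_s,window_end_s,mav_vl,mav_vm,rms_vl,rms_vm\n")
        for w in windows:
            fh.write(
                ",".join(
                    _FLOAT_FMT % v
                    for v in (w.window_start_s, w.window_end_s,
                              w.mav_vl, w.mav_vm, w.rms_vl, w.rms_vm)
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# subject summaries

_SUMMARY_COLUMNS = (
    "subject_id", "group_label", "week_label",
    "avg_rom_deg", "mav_vl_v", "mav_vm_v", "rms_vl_v", "rms_vm_v",
)


def write_summary_csv(summaries: list[SubjectSummary], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(_SUMMARY_COLUMNS) + "\n")
        for s in summaries:
            fh.write(
                f"{s.subject_id},{s.group_label},{s.week_label},"
                + ",".join(
                    _FLOAT_FMT % v
                    for v in (s.avg_rom_deg, s.mav_vl_v, s.mav_vm_v, s.rms_vl_v, s.rms_vm_v)
                )
                + "\n"
            )


def load_summary_csv(path) -> list[SubjectSummary]:
    df = _read_csv(path, _SUMMARY_COLUMNS)
    return [
        SubjectSummary(
            subject_id=str(r.subject_id),
            group_label=str(r.group_label),
            week_label=str(r.week_label),
            avg_rom_deg=float(r.avg_rom_deg),
            mav_vl_v=float(r.mav_vl_v),
            mav_vm_v=float(r.mav_vm_v),
            rms_vl_v=float(r.rms_vl_v),
            rms_vm_v=float(r.rms_vm_v),
        )
        for r in df.itertuples(index=False)
    ]


def load_reference_cohort() -> list[SubjectSummary]:
    """Bundled per-subject reference dataset (see module docstring)."""
    ref = resources.files("kneemon.data") / "reference_cohort.csv"
    with resources.as_file(ref) as path:
        return load_summary_csv(path)


def render_report(summaries: list[SubjectSummary], groups: list[GroupSummary] = (),
                  progress=()) -> str:
    """Plain-text report of subject rows, group means and progress calls."""
    lines = ["Subject summaries", "-" * 17]
    header = f"{'subject':<10}{'group':<12}{'week':<8}{'ROM(deg)':>10}{'MAV VL':>10}{'MAV VM':>10}{'RMS VL':>10}{'RMS VM':>10}"
    lines.append(header)
    for s in summaries:
        lines.append(
            f"{s.subject_id:<10}{s.group_label:<12}{s.week_label:<8}"
            f"{s.avg_rom_deg:>10.2f}{s.mav_vl_v:>10.4f}{s.mav_vm_v:>10.4f}"
            f"{s.rms_vl_v:>10.4f}{s.rms_vm_v:>10.4f}"
        )
    if groups:
        lines += ["", "Group means", "-" * 11]
        for g in groups:
            lines.append(
                f"{g.group_label:<12}{g.week_label:<8}(n={g.n_subjects})  "
                f"ROM {g.mean_rom_deg:.2f} deg  MAV {g.mean_mav_vl_v:.4f}/{g.mean_mav_vm_v:.4f} V  "
                f"RMS {g.mean_rms_vl_v:.4f}/{g.mean_rms_vm_v:.4f} V"
            )
    for p in progress:
        lines += ["", f"Progress: {p.entity} ({p.first_week} -> {p.last_week})", "-" * 11]
        for d in p.deltas:
            lines.append(f"  {d.field:<14} {d.first:>10.4f} -> {d.last:>10.4f}  "
                         f"delta {d.delta:+.4f}  [{d.direction}]")
    return "\n".join(lines) + "\n"
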