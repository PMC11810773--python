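"""Readers and writers for the package's text formats.

Pose-tracking tables use the common three-header-row CSV dialect
(scorer / bodypart / coordinate rows, then x, y, likelihood columns per
bodypart, one row per frame).  Event logs are plain CSV with columns
(t_s, event, value) and sorted timestamps.  Calibration parameters and
ground-truth records travel as JSON.  All writers use stable column order
and fixed float formatting so seeded runs are byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .eyetrack import POINT_NAMES, CalibrationParams, EyeFramePoints

__all__ = [
    "Config",
    "read_config",
    "write_config",
    "read_pose_csv",
    "write_pose_csv",
    "read_event_log",
    "write_event_log",
    "read_calibration_json",
    "write_calibration_json",
    "write_gaze_csv",
    "EVENT_NAMES",
]

EVENT_NAMES = ("lick", "reward", "trial_start", "trial_end", "loom_onset")

_FLOAT_FMT = "%.6f"


class FormatError(ValueError):
    """Raised when an input file does not match its expected dialect."""


@dataclass
class Config:
    """Analysis configuration with overridable module defaults.

    Geometry constants, analysis parameters and seeds in one place; CLI
    flags override file values, file values override these defaults.
    Unknown keys in a config file are rejected.
    """

    resolution_px_per_deg: float = 1.57
    half_fov_deg: float = 70.0
    axis_azimuth_deg: float = 45.0
    axis_elevation_deg: float = 15.0
    pupil_radius_mm: float = 1.3
    confidence_threshold: float = 0.6
    track_length_cm: float = 150.0
    bin_cm: float = 3.0
    smooth_sd_cm: float = 3.0
    speed_min_cm_s: float = 5.0
    n_shuffles: int = 500
    seed: int = 0


def read_config(path) -> Config:
    """Load a YAML config, rejecting unknown keys."""
    payload = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(Config)}
    unknown = set(payload) - known
    if unknown:
        raise FormatError(f"{path}: unknown config key(s) {sorted(unknown)}")
    return Config(**payload)


def write_config(path, config: Config) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=True))


def write_pose_csv(path, frames: list[EyeFramePoints], scorer: str = "goggleskit") -> None:
    """Write labeled frames in the three-header-row pose CSV dialect."""
    names = [n for n in POINT_NAMES if frames and n in frames[0].points]
    cols = []
    for n in names:
        cols += [(scorer, n, "x"), (scorer, n, "y"), (scorer, n, "likelihood")]
    rows = []
    for i, f in enumerate(frames):
        row = [i]
        for n in names:
            x, y = f.points[n]
            row += [x, y, f.conf(n)]
        rows.append(row)
    header = pd.MultiIndex.from_tuples([("scorer", "bodyparts", "coords")] + cols)
    df = pd.DataFrame(rows)
    df.columns = header
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_pose_csv(path) -> list[EyeFramePoints]:
    """Read a three-header-row pose CSV into per-frame labeled points.

    Validates the scorer/bodypart/coordinate header structure and that
    every bodypart carries x, y and likelihood columns; malformed rows are
    reported with their line number.
    """
    path = Path(path)
    df = pd.read_csv(path, header=[0, 1, 2])
    if df.shape[1] < 4:
        raise FormatError(
            f"{path}: expected the scorer/bodypart/coordinate pose dialect "
            "with x, y, likelihood columns per bodypart"
        )
    body_cols = df.columns[1:]
    parts: dict[str, set] = {}
    for _, part, coord in body_cols:
        parts.setdefault(part, set()).add(coord)
    for part, coords in parts.items():
        if coords != {"x", "y", "likelihood"}:
            raise FormatError(
                f"{path}: bodypart '{part}' must have x, y and likelihood "
                f"columns (found {sorted(coords)})"
            )
    frames = []
    for i, row in df.iterrows():
        pts, conf = {}, {}
        for part in parts:
            sel = [c for c in body_cols if c[1] == part]
            vals = {c[2]: row[c] for c in sel}
            if any(pd.isna(v) for v in vals.values()):
                raise FormatError(f"{path}: malformed row at data line {i + 1}")
            pts[part] = (float(vals["x"]), float(vals["y"]))
            conf[part] = float(vals["likelihood"])
        frames.append(EyeFramePoints(points=pts, confidence=conf))
    return frames


def write_event_log(path, events: list) -> None:
    """Write (t_s, event, value) rows as CSV (timestamps sorted)."""
    df = pd.DataFrame(sorted(events, key=lambda e: e[0]), columns=["t_s", "event", "value"])
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_event_log(path) -> pd.DataFrame:
    """Read a (t_s, event, value) CSV into a typed event frame.

    Timestamps must be sorted and event names known; the first violation
    is reported with its position.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != ["t_s", "event", "value"]:
        raise FormatError(f"{path}: expected columns t_s, event, value")
    if len(df) == 0:
        return df
    t = df["t_s"].to_numpy(dtype=float)
    bad = np.where(np.diff(t) < 0)[0]
    if len(bad):
        # file line number: header is line 1, violating data row is bad+2
        raise FormatError(f"{path}: timestamps not sorted at row {bad[0] + 3}")
    unknown = set(df["event"]) - set(EVENT_NAMES)
    if unknown:
        raise FormatError(f"{path}: unknown event name(s) {sorted(unknown)}")
    return df


def write_calibration_json(path, params: CalibrationParams) -> None:
    payload = {
        "a": params.a,
        "b": params.b,
        "c": params.c,
        "d": params.d,
        "k": params.k,
        "horizon_deg": params.horizon_deg,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_calibration_json(path) -> CalibrationParams:
    payload = json.loads(Path(path).read_text())
    return CalibrationParams(**payload)


def write_gaze_csv(path, gaze_samples, fps: float = 30.0) -> None:
    """Write gaze output as tidy CSV: frame, time_s, yaw_deg, pitch_deg,
    diameter_mm, valid."""
    rows = [
        (i, i / fps, g.yaw_deg, g.pitch_deg, g.diameter_mm, bool(g.valid))
        for i, g in enumerate(gaze_samples)
    ]
    df = pd.DataFrame(
        rows, columns=["frame", "time_s", "yaw_deg", "pitch_deg", "diameter_mm", "valid"]
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
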