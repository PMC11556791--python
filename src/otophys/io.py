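"""Trace-table and sidecar I/O, run manifests, and typed input errors.

On-disk conventions: delimited text (CSV, or TSV by sniffing) with a header
whose first column is time; a JSON sidecar next to each trace table carries
units, protocol and recording metadata.  Ground truth is JSON; puncta images
are TIFF.  Every CLI invocation writes a RunManifest (resolved config, input
checksums, timestamps, warnings).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, is_dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .core import EyeHeadTrial, MotionRecording, RecordingMeta, StepFamily

__all__ = [
    "InputError", "RunManifest",
    "read_trace_table", "write_trace_table",
    "read_step_family", "write_step_family",
    "read_trial", "write_trial",
    "read_motion_recording", "write_motion_recording",
    "write_json", "read_json",
]

#: relative tolerance for the uniform-sampling check
_UNIFORM_RTOL = 1e-6


class InputError(ValueError):
    """Malformed or inconsistent input data (CLI exit status 2)."""


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def read_trace_table(path: str | Path, expected_channels: list[str] | None = None) -> pd.DataFrame:
    """Read a delimited trace table (first column time) with validation.

    Checks: required channels present, time strictly increasing and uniform
    to 1 ppm, no NaNs.  Returns the table with the time column first.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    df = pd.read_csv(path, sep=_sniff_sep(path))
    if df.shape[1] < 2:
        raise InputError(f"{path}: need a time column plus >= 1 channel")
    if expected_channels:
        missing = set(expected_channels) - set(df.columns[1:])
        if missing:
            raise InputError(f"{path}: missing channels {sorted(missing)}")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise InputError(f"{path}: time column is not strictly increasing")
    dt = np.diff(t)
    if dt.size and np.max(np.abs(dt - dt[0])) > _UNIFORM_RTOL * abs(dt[0]):
        raise InputError(f"{path}: sampling is not uniform (tolerance 1 ppm)")
    if df.isna().any().any():
        raise InputError(f"{path}: NaN values present")
    return df


def write_trace_table(path: str | Path, time: np.ndarray, channels: dict[str, np.ndarray],
                      time_label: str = "time") -> None:
    df = pd.DataFrame({time_label: time, **channels})
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# step families


def write_step_family(directory: str | Path, name: str, family: StepFamily) -> None:
    """Trace table ``<name>.csv`` (one column per step) + sidecar ``<name>.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cols = {f"step_{lvl:g}": family.traces[i] for i, lvl in enumerate(family.step_levels)}
    write_trace_table(directory / f"{name}.csv", family.time, cols, time_label="time_ms")
    sidecar = {
        "step_levels": family.step_levels.tolist(),
        "sample_interval_ms": family.sample_interval,
        "step_onset_ms": family.step_onset,
        "step_offset_ms": family.step_offset,
        "kind": family.kind,
        "n_repeats": family.n_repeats,
        "meta": asdict(family.meta),
    }
    write_json(directory / f"{name}.json", sidecar)


def read_step_family(directory: str | Path, name: str) -> StepFamily:
    directory = Path(directory)
    df = read_trace_table(directory / f"{name}.csv")
    sidecar = read_json(directory / f"{name}.json")
    levels = np.asarray(sidecar["step_levels"], dtype=float)
    step_cols = [c for c in df.columns if c.startswith("step_")]
    if len(step_cols) != levels.size:
        raise InputError(f"{name}: sidecar lists {levels.size} steps, table has {len(step_cols)}")
    traces = df[step_cols].to_numpy(dtype=float).T
    return StepFamily(
        step_levels=levels,
        traces=traces,
        sample_interval=float(sidecar["sample_interval_ms"]),
        step_onset=float(sidecar["step_onset_ms"]),
        step_offset=float(sidecar["step_offset_ms"]),
        kind=sidecar.get("kind", "displacement"),
        n_repeats=int(sidecar.get("n_repeats", 1)),
        meta=RecordingMeta(**sidecar.get("meta", {})),
    )


# ---------------------------------------------------------------------------
# behavioral trials


def write_trial(directory: str | Path, name: str, trial: EyeHeadTrial) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_trace_table(directory / f"{name}.csv", trial.time,
                      {"eye_velocity": trial.eye_velocity,
                       "head_velocity": trial.head_velocity},
                      time_label="time_s")
    sidecar = {
        "sample_rate_hz": trial.sample_rate,
        "stimulus_frequency_hz": trial.stimulus_frequency,
        "rotation_velocity_dps": trial.rotation_velocity,
        "plateau_start_s": trial.plateau_start,
    }
    write_json(directory / f"{name}.json", sidecar)


def read_trial(directory: str | Path, name: str) -> EyeHeadTrial:
    directory = Path(directory)
    df = read_trace_table(directory / f"{name}.csv",
                          expected_channels=["eye_velocity", "head_velocity"])
    sidecar = read_json(directory / f"{name}.json")
    return EyeHeadTrial(
        time=df.iloc[:, 0].to_numpy(dtype=float),
        eye_velocity=df["eye_velocity"].to_numpy(dtype=float),
        head_velocity=df["head_velocity"].to_numpy(dtype=float),
        sample_rate=float(sidecar["sample_rate_hz"]),
        stimulus_frequency=sidecar.get("stimulus_frequency_hz"),
        rotation_velocity=sidecar.get("rotation_velocity_dps"),
        plateau_start=float(sidecar.get("plateau_start_s") or 0.0),
    )


def write_motion_recording(path: str | Path, rec: MotionRecording) -> None:
    n = len(next(iter(rec.channels.values())))
    t = np.arange(n) / rec.sample_rate
    write_trace_table(path, t, rec.channels, time_label="time_s")


def read_motion_recording(path: str | Path) -> MotionRecording:
    df = read_trace_table(path)
    t = df.iloc[:, 0].to_numpy(dtype=float)
    fs = 1.0 / (t[1] - t[0])
    channels = {c: df[c].to_numpy(dtype=float) for c in df.columns[1:]}
    return MotionRecording(channels=channels, sample_rate=float(round(fs, 6)))


# ---------------------------------------------------------------------------
# JSON + manifests


class _Encoder(json.JSONEncoder):
    def default(self, o: Any):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if is_dataclass(o) and not isinstance(o, type):
            return asdict(o)
        return super().default(o)


def write_json(path: str | Path, payload: Any) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, cls=_Encoder) + "\n")


def read_json(path: str | Path) -> Any:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    return json.loads(path.read_text())


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written for every CLI invocation."""

    stage: str
    config: dict[str, Any]
    package_version: str = ""
    input_checksums: dict[str, str] = field(default_factory=dict)
    started: str = ""
    finished: str = ""
    warnings: list[str] = field(default_factory=list)
    exit_status: int = 0

    def start(self) -> "RunManifest":
        self.started = datetime.now(timezone.utc).isoformat()
        return self

    def add_inputs(self, *paths: str | Path) -> None:
        for p in paths:
            p = Path(p)
            if p.is_file():
                self.input_checksums[str(p)] = _sha256(p)
            elif p.is_dir():
                for f in sorted(p.glob("*")):
                    if f.is_file():
                        self.input_checksums[str(f)] = _sha256(f)

    def finish(self, out_dir: str | Path, exit_status: int = 0) -> None:
        from . import __version__

        self.package_version = __version__
        self.exit_status = exit_status
        self.finished = datetime.now(timezone.utc).isoformat()
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_json(out_dir / "manifest.json", asdict(self))
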