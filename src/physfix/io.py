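"""File formats and pipeline configuration.

Traces and marker streams are plain delimited text (comma, tab or semicolon;
auto-detected).  Canonical units are fixed at this boundary: seconds,
newton-metres, degrees, millimetres.  A trace file carries columns
``time_s, torque_Nm, angle_deg`` (or ``angle_rad``, converted on read); a
marker file carries ``time_s, marker_id, label, segment, x_mm, y_mm, z_mm``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from .errors import ConfigurationError, TraceFormatError
from .types import MARKER_LABELS, SEGMENTS, LoadProtocol, MarkerTrajectory, TorsionTrace

TRACE_COLUMNS = ("time_s", "torque_Nm", "angle_deg")
MARKER_COLUMNS = ("time_s", "marker_id", "label", "segment", "x_mm", "y_mm", "z_mm")


def _read_delimited(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except pd.errors.EmptyDataError as exc:
        raise TraceFormatError(f"{path}: empty file") from exc
    except Exception as exc:  # noqa: BLE001
        raise TraceFormatError(f"{path}: unparseable ({exc})") from exc
    if df.empty:
        raise TraceFormatError(f"{path}: no data rows")
    return df


def read_trace(path: str | Path, protocol: LoadProtocol | None = None) -> TorsionTrace:
    """Read a machine trace; angle may be given in degrees or radians."""
    df = _read_delimited(path)
    cols = set(df.columns)
    if "time_s" not in cols or "torque_Nm" not in cols:
        raise TraceFormatError(f"{path}: missing column(s) among {TRACE_COLUMNS[:2]}")
    if "angle_deg" in cols:
        angle = df["angle_deg"].to_numpy(dtype=float)
    elif "angle_rad" in cols:
        angle = np.degrees(df["angle_rad"].to_numpy(dtype=float))
    else:
        raise TraceFormatError(f"{path}: missing angle column (angle_deg or angle_rad)")
    for col in ("time_s", "torque_Nm"):
        bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise TraceFormatError(f"{path}: non-numeric {col}", line=int(bad.index[0]) + 2)
    time = df["time_s"].to_numpy(dtype=float)
    torque = df["torque_Nm"].to_numpy(dtype=float)
    if len(time) >= 2:
        dt = np.diff(time)
        if np.any(dt <= 0):
            line = int(np.argmax(dt <= 0)) + 3  # +1 for header, +1 for 1-based, +1 diff offset
            raise TraceFormatError(f"{path}: time not strictly increasing", line=line)
    if protocol is None:
        if len(time) < 2:
            raise TraceFormatError(f"{path}: cannot infer sample rate from < 2 samples")
        sample_rate = 1.0 / float(np.mean(np.diff(time)))
        protocol = LoadProtocol(
            torque_amplitude=float(np.max(np.abs(torque))) or 2.0,
            frequency=0.5,
            n_cycles=max(int(np.ceil(time[-1] * 0.5)), 1),
            sample_rate=sample_rate,
        )
    return TorsionTrace(time=time, torque=torque, angle=angle, protocol=protocol)


def write_trace(trace: TorsionTrace, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": trace.time, "torque_Nm": trace.torque, "angle_deg": trace.angle}
    ).to_csv(path, index=False, float_format="%.12g")


def read_markers(path: str | Path) -> dict[str, MarkerTrajectory]:
    """Read a marker stream file into one trajectory per marker id."""
    df = _read_delimited(path)
    missing = [c for c in MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: missing column(s) {missing}")
    bad_label = df[~df["label"].isin(MARKER_LABELS)]
    if len(bad_label):
        raise TraceFormatError(
            f"{path}: unknown label {bad_label['label'].iloc[0]!r}",
            line=int(bad_label.index[0]) + 2,
        )
    bad_seg = df[~df["segment"].isin(SEGMENTS)]
    if len(bad_seg):
        raise TraceFormatError(
            f"{path}: unknown segment {bad_seg['segment'].iloc[0]!r}",
            line=int(bad_seg.index[0]) + 2,
        )
    dup = df.duplicated(subset=["time_s", "marker_id"])
    if dup.any():
        raise TraceFormatError(
            f"{path}: duplicate (time, marker) row", line=int(df.index[dup.argmax()]) + 2
        )
    out: dict[str, MarkerTrajectory] = {}
    for mid, g in df.groupby("marker_id", sort=True):
        t = g["time_s"].to_numpy(dtype=float)
        if len(t) >= 2 and np.any(np.diff(t) <= 0):
            raise TraceFormatError(f"{path}: marker {mid}: time not strictly increasing")
        out[str(mid)] = MarkerTrajectory(
            marker_id=str(mid),
            label=str(g["label"].iloc[0]),
            segment=str(g["segment"].iloc[0]),
            time=t,
            position=g[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
        )
    return out


def write_markers(markers: dict[str, MarkerTrajectory], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "time_s": m.time,
                "marker_id": m.marker_id,
                "label": m.label,
                "segment": m.segment,
                "x_mm": m.position[:, 0],
                "y_mm": m.position[:, 1],
                "z_mm": m.position[:, 2],
            }
        )
        for m in markers.values()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.12g")


class PipelineConfig(BaseModel):
    """Validated end-to-end analysis configuration.

    Defaults mirror the bench protocol: +/-2 Nm at 0.5 Hz for 250 cycles
    sampled at 1 kHz under 20 N preload, terminal fits at R^2 >= 0.995 from
    a 10-point initial set, analysis at cycles 60/120/180.  The machine
    stream is decimated to ``analysis_rate_hz`` before terminal fitting so a
    10-point window spans a mechanically meaningful arc.
    """

    schema_version: int = 1
    torque_amplitude: float = Field(2.0, gt=0)
    frequency: float = Field(0.5, gt=0)
    n_cycles: int = Field(250, ge=1)
    sample_rate: float = Field(1000.0, gt=0)
    axial_preload: float = Field(20.0, gt=0)
    analysis_cycles: tuple[int, ...] = (60, 120, 180)
    r2_min: float = Field(0.995, gt=0.0, le=1.0)
    n_init: int = Field(10, ge=3)
    analysis_rate_hz: float = Field(25.0, gt=0)
    min_marker_radius_mm: float = Field(1.0, gt=0)
    angle_noise_sd: float = Field(0.02, ge=0)
    transition_torque: float = Field(0.2, gt=0)
    n_specimens: int = Field(12, ge=2)
    specimen_effect_sd: float = Field(1.0, ge=0)
    marker_effect_sd: float = Field(0.3, ge=0)
    slippage_factor: float = Field(2.6, ge=1.0)
    holm: bool = False
    seed: int = 0

    @field_validator("analysis_cycles")
    @classmethod
    def _cycles_valid(cls, v, info):
        if not v or any(int(c) != c or c < 1 for c in v):
            raise ValueError("analysis_cycles must be positive integers")
        return tuple(sorted(int(c) for c in v))

    def model_post_init(self, __context) -> None:
        if max(self.analysis_cycles) > self.n_cycles:
            raise ValueError("analysis_cycles exceed n_cycles")
        if self.sample_rate % self.analysis_rate_hz:
            raise ValueError("analysis_rate_hz must divide sample_rate")

    def protocol(self) -> LoadProtocol:
        return LoadProtocol(
            torque_amplitude=self.torque_amplitude,
            frequency=self.frequency,
            n_cycles=self.n_cycles,
            sample_rate=self.sample_rate,
            axial_preload=self.axial_preload,
        )

    @property
    def decimation_factor(self) -> int:
        return int(round(self.sample_rate / self.analysis_rate_hz))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            data = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"{path}: invalid YAML ({exc})") from exc
        try:
            return cls(**data)
        except Exception as exc:  # pydantic ValidationError
            raise ConfigurationError(f"{path}: invalid configuration: {exc}") from exc

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))
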