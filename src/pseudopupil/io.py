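"""File I/O: TIFF frame stacks, CSV traces/sessions, YAML configs.

CSV dialect: comma-separated, UTF-8, '.' decimal, header required.
TIFF: multi-page grayscale, written as 16-bit.
"""
from __future__ import annotations

from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import (
    EyeTrace,
    FrameStack,
    GapSession,
    LightingEpoch,
    SchemaError,
)

TRACE_COLUMNS = ["time_s", "x_deg", "y_deg"]
SESSION_COLUMNS = ["time_s", "wheel_pos", "xL_deg", "yL_deg",
                   "xR_deg", "yR_deg", "lighting"]


# --------------------------------------------------------------------------
# TIFF stacks
# --------------------------------------------------------------------------

def write_frames(path: str | Path, stack: FrameStack) -> None:
    """Write a stack as multi-page 16-bit grayscale TIFF (values clipped)."""
    frames = np.clip(stack.frames, 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), frames, metadata={
        "frame_rate_hz": stack.frame_rate})


def read_frames(path: str | Path, frame_rate: float | None = None) -> FrameStack:
    """Read a multi-page TIFF; frame rate from metadata unless overridden."""
    with tifffile.TiffFile(str(path)) as tf:
        frames = tf.asarray()
        if frame_rate is None:
            meta = tf.shaped_metadata or ({},)
            frame_rate = float(meta[0].get("frame_rate_hz", 100.0))
    if frames.ndim == 2:
        frames = frames[None]
    return FrameStack(frames.astype(float), frame_rate)


# --------------------------------------------------------------------------
# trace / session tables
# --------------------------------------------------------------------------

def write_trace(path: str | Path, trace: EyeTrace,
                channel: str = "pseudopupil") -> None:
    pd.DataFrame({"time_s": trace.times, "x_deg": trace.x,
                  "y_deg": trace.y, "eye": trace.eye,
                  "channel": channel}).to_csv(path, index=False)


def write_session(path: str | Path, session: GapSession) -> None:
    labels = [session.lighting_label(t) for t in session.times]
    pd.DataFrame({"time_s": session.times, "wheel_pos": session.wheel,
                  "xL_deg": session.left.x, "yL_deg": session.left.y,
                  "xR_deg": session.right.x, "yR_deg": session.right.y,
                  "lighting": labels}).to_csv(path, index=False)


def _load_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"file not found: {path}")
    df = pd.read_csv(path)
    if df.empty:
        raise SchemaError(f"empty table: {path}")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    if not np.all(np.diff(t) > 0):
        raise SchemaError(f"{path}: time_s must be strictly increasing")
    return df


def _resample(t: np.ndarray, columns: dict[str, np.ndarray],
              rate: float) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    tu = np.arange(t[0], t[-1] + 0.5 / rate, 1.0 / rate)
    return tu, {k: np.interp(tu, t, v) for k, v in columns.items()}


def read_trace_table(path: str | Path,
                     schema: str = "trace",
                     resample_rate: float | None = None,
                     ) -> EyeTrace | GapSession:
    """Read and validate a trace or session CSV.

    ``schema`` is ``"trace"`` (time_s, x_deg, y_deg [, eye]) or
    ``"session"`` (time_s, wheel_pos, xL_deg, yL_deg, xR_deg, yR_deg
    [, lighting]).  With ``resample_rate`` non-uniform timestamps are
    linearly interpolated onto a uniform grid (units: seconds/degrees are
    assumed and validated to be finite).
    """
    if schema == "trace":
        df = _load_table(path, TRACE_COLUMNS)
        t = df["time_s"].to_numpy(dtype=float)
        cols = {c: df[c].to_numpy(dtype=float) for c in ("x_deg", "y_deg")}
        if not all(np.isfinite(v).all() for v in cols.values()):
            raise SchemaError(f"{path}: non-finite values")
        if resample_rate:
            t, cols = _resample(t, cols, resample_rate)
        eye = str(df["eye"].iloc[0]) if "eye" in df.columns else "right"
        return EyeTrace(t, cols["x_deg"], cols["y_deg"], eye=eye)
    if schema == "session":
        df = _load_table(path, SESSION_COLUMNS[:-1])
        t = df["time_s"].to_numpy(dtype=float)
        names = ("wheel_pos", "xL_deg", "yL_deg", "xR_deg", "yR_deg")
        cols = {c: df[c].to_numpy(dtype=float) for c in names}
        if not all(np.isfinite(v).all() for v in cols.values()):
            raise SchemaError(f"{path}: non-finite values")
        if resample_rate:
            t, cols = _resample(t, cols, resample_rate)
        lighting: tuple[LightingEpoch, ...] = ()
        if "lighting" in df.columns and not resample_rate:
            lab = df["lighting"].fillna("").astype(str).to_numpy()
            edges = np.r_[0, np.nonzero(lab[1:] != lab[:-1])[0] + 1, lab.size]
            lighting = tuple(
                LightingEpoch(lab[i0], float(t[i0]),
                              float(t[i1 - 1]) + float(np.median(np.diff(t))))
                for i0, i1 in zip(edges[:-1], edges[1:]) if lab[i0])
        return GapSession(
            t, cols["wheel_pos"],
            EyeTrace(t.copy(), cols["xL_deg"], cols["yL_deg"], eye="left"),
            EyeTrace(t.copy(), cols["xR_deg"], cols["yR_deg"], eye="right"),
            lighting=lighting)
    raise SchemaError(f"unknown schema {schema!r}")


def write_saccades(path: str | Path, saccades) -> None:
    pd.DataFrame([{"onset_s": s.onset, "offset_s": s.offset,
                   "amp_x_deg": s.amp_x, "amp_y_deg": s.amp_y,
                   "peak_vel_deg_s": s.peak_velocity}
                  for s in saccades]).to_csv(path, index=False)


# --------------------------------------------------------------------------
# configs
# --------------------------------------------------------------------------

def load_yaml(path: str | Path) -> dict[str, Any]:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return data or {}


def dump_yaml(path: str | Path, data: dict[str, Any]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
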