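"""Visual front-end: 3D facial-landmark series -> T x 204 feature matrix.

Input is a per-video time series of 68 landmarks x (x, y, z) at 25 fps,
as produced by standard 68-point face-alignment networks (x, y in pixel
units, z an estimated depth).  Preprocessing: an 8 Hz causal low-pass to
suppress frame-to-frame estimation jitter, a one-frame delay of the
video stream relative to audio, flattening to T x 204, and per-video
standardization pooled within each spatial dimension (all x coordinates
jointly, likewise y and z).

Column layout of the flattened matrix is landmark-major:
column 3*l + d holds landmark l, axis d (0=x, 1=y, 2=z), so
``values.reshape(T, 68, 3)`` recovers the coordinate array.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "N_LANDMARKS",
    "LandmarkSeries",
    "LandmarkFeatures",
    "read_landmarks",
    "write_landmarks",
    "preprocess_landmarks",
]

N_LANDMARKS = 68
AXES = ("x", "y", "z")


@dataclass
class LandmarkSeries:
    positions: np.ndarray  # (T, 68, 3)
    frame_rate: float = 25.0
    video_id: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[1:] != (N_LANDMARKS, 3):
            raise ValueError(
                f"positions must be (T, {N_LANDMARKS}, 3), got {self.positions.shape}"
            )


@dataclass
class LandmarkFeatures:
    """T x 204 preprocessed landmark features (landmark-major columns)."""

    values: np.ndarray
    video_id: str = ""
    frame_rate: float = 25.0

    def as_positions(self) -> np.ndarray:
        return self.values.reshape(len(self.values), N_LANDMARKS, 3)


def _wide_columns() -> list[str]:
    return [f"l{l:02d}_{ax}" for l in range(N_LANDMARKS) for ax in AXES]


def read_landmarks(path, frame_rate: float = 25.0, video_id: str = "") -> LandmarkSeries:
    """Read a landmark table in the long or wide text dialect.

    Long: columns ``frame, landmark, x, y, z`` (one row per landmark per
    frame).  Wide: one row per frame with a ``frame`` column and 204
    columns named ``l00_x .. l67_z``.  The dialect is detected from the
    header.
    """
    df = pd.read_csv(path)
    if "landmark" in df.columns:  # long dialect
        required = {"frame", "landmark", "x", "y", "z"}
        if not required.issubset(df.columns):
            raise ValueError(f"long dialect needs columns {sorted(required)}")
        frames = np.sort(df["frame"].unique())
        T = len(frames)
        counts = df.groupby("frame")["landmark"].agg(["count", "nunique"])
        bad = counts[(counts["count"] != N_LANDMARKS) | (counts["nunique"] != N_LANDMARKS)]
        if len(bad):
            f0 = int(bad.index[0])
            present = set(df.loc[df["frame"] == f0, "landmark"])
            missing = sorted(set(range(N_LANDMARKS)) - present)
            raise ValueError(
                f"frame {f0} has {len(present)} landmarks "
                f"(missing ids {missing[:5]}{'...' if len(missing) > 5 else ''})"
            )
        df = df.sort_values(["frame", "landmark"])
        pos = df[["x", "y", "z"]].to_numpy(float).reshape(T, N_LANDMARKS, 3)
    else:  # wide dialect
        cols = _wide_columns()
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"wide dialect missing columns: {missing[:5]} ...")
        if "frame" in df.columns:
            df = df.sort_values("frame")
        pos = df[cols].to_numpy(float).reshape(len(df), N_LANDMARKS, 3)
    if not np.all(np.isfinite(pos)):
        raise ValueError(f"non-finite landmark coordinates in {path}")
    return LandmarkSeries(positions=pos, frame_rate=frame_rate, video_id=video_id)


def write_landmarks(path, series: LandmarkSeries, dialect: str = "long") -> None:
    """Write a landmark table in the long (default) or wide dialect."""
    pos = series.positions
    T = len(pos)
    if dialect == "long":
        frames = np.repeat(np.arange(T), N_LANDMARKS)
        lms = np.tile(np.arange(N_LANDMARKS), T)
        flat = pos.reshape(T * N_LANDMARKS, 3)
        df = pd.DataFrame(
            {"frame": frames, "landmark": lms,
             "x": flat[:, 0], "y": flat[:, 1], "z": flat[:, 2]}
        )
    elif dialect == "wide":
        df = pd.DataFrame(pos.reshape(T, -1), columns=_wide_columns())
        df.insert(0, "frame", np.arange(T))
    else:
        raise ValueError("dialect must be 'long' or 'wide'")
    df.to_csv(path, index=False, float_format="%.8g")


def preprocess_landmarks(
    s: LandmarkSeries,
    cutoff: float = 8.0,
    order: int = 4,
    shift: bool = True,
    shift_mode: str = "pad",
) -> LandmarkFeatures:
    """Low-pass, one-frame delay, flatten and per-dimension standardize.

    ``shift_mode='pad'`` (default) repeats the first filtered frame so the
    frame count matches the audio features; ``'drop'`` discards it.
    Constant coordinate dimensions (degenerate synthetic input) are set
    to zero with a warning.
    """
    pos = s.positions
    T = pos.shape[0]
    if T < s.frame_rate:
        raise ValueError(f"need at least 1 s of video ({int(s.frame_rate)} frames), got {T}")
    b, a = signal.butter(order, cutoff, btype="low", fs=s.frame_rate)
    filt = signal.lfilter(b, a, pos, axis=0)
    if shift:
        if shift_mode == "pad":
            filt = np.concatenate([filt[:1], filt[:-1]], axis=0)
        elif shift_mode == "drop":
            filt = filt[:-1]  # frame t of the output reflects input frame t-1
        else:
            raise ValueError("shift_mode must be 'pad' or 'drop'")
    Z = standardize_per_dimension(filt, video_id=s.video_id)
    return LandmarkFeatures(values=Z.reshape(len(Z), -1), video_id=s.video_id,
                            frame_rate=s.frame_rate)


def standardize_per_dimension(pos: np.ndarray, video_id: str = "") -> np.ndarray:
    """Zero mean / unit variance pooled over landmarks per spatial axis."""
    pos = np.asarray(pos, dtype=float)
    out = np.empty_like(pos)
    for d in range(3):
        block = pos[:, :, d]
        mu, sd = block.mean(), block.std()
        if sd == 0:
            warnings.warn(
                f"constant {AXES[d]} dimension set to zero (video {video_id or '<unnamed>'})",
                stacklevel=2,
            )
            out[:, :, d] = 0.0
        else:
            out[:, :, d] = (block - mu) / sd
    return out
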