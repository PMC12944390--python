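"""Tracklet data model, file I/O, cleaning and window segmentation.

A *tracklet* is one agent's time-ordered sequence of planar positions as
produced by an upstream multi-object tracker.  Two text dialects are read:

* ``csv`` — header ``track_id,frame,x,y``, one row per observation.
* ``mot`` — MOT-challenge style ``frame,track_id,x,y,w,h,...``; the bounding
  box centre ``(x + w/2, y + h/2)`` is used as the position.

Coordinates are generic planar units in a 0-based, y-down image convention.
Motion is handed to the model as frame-to-frame displacements
``dp_t = p_t - p_{t-1}``; future positions are recovered by cumulatively
summing predicted displacements from the last observed point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Tracklet",
    "Window",
    "read_tracklets",
    "write_tracklets",
    "clean_tracklets",
    "to_displacements",
    "reconstruct_positions",
    "make_windows",
    "DEFAULT_T_PAST",
    "DEFAULT_T_FUT",
    "DEFAULT_MIN_LENGTH",
]

DEFAULT_T_PAST = 8
DEFAULT_T_FUT = 60
DEFAULT_MIN_LENGTH = DEFAULT_T_PAST + DEFAULT_T_FUT  # 68


@dataclass
class Tracklet:
    """One agent's time-ordered planar positions with frame indices."""

    track_id: str
    frames: np.ndarray        # strictly increasing integers, shape (N,)
    positions: np.ndarray     # shape (N, 2)
    frame_rate: float = 30.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.int64).ravel()
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an N x 2 matrix")
        if self.frames.size != self.positions.shape[0]:
            raise ValueError("frames and positions must have equal length")
        if self.frames.size < 2:
            raise ValueError("a tracklet needs at least 2 observations")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError(f"frames of track {self.track_id!r} are not strictly increasing")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError(f"track {self.track_id!r} contains non-finite coordinates")

    def __len__(self) -> int:
        return self.frames.size

    @property
    def is_contiguous(self) -> bool:
        return bool(np.all(np.diff(self.frames) == 1))


@dataclass
class Window:
    """One observation--prediction sample cut from a contiguous tracklet."""

    track_id: str
    anchor_frame: int                 # frame index of the last observed position
    past_positions: np.ndarray        # (T_past, 2)
    future_positions: np.ndarray      # (T_fut, 2)
    past_displacements: np.ndarray = field(init=False)   # (T_past - 1, 2)
    future_displacements: np.ndarray = field(init=False)  # (T_fut, 2)

    def __post_init__(self):
        self.past_positions = np.asarray(self.past_positions, dtype=np.float64)
        self.future_positions = np.asarray(self.future_positions, dtype=np.float64)
        self.past_displacements = np.diff(self.past_positions, axis=0)
        # first future displacement is relative to the last observed position
        prev = np.vstack([self.past_positions[-1:], self.future_positions[:-1]])
        self.future_displacements = self.future_positions - prev

    @property
    def T_past(self) -> int:
        return self.past_positions.shape[0]

    @property
    def T_fut(self) -> int:
        return self.future_positions.shape[0]

    @property
    def last_observed(self) -> np.ndarray:
        return self.past_positions[-1]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_tracklets(path, dialect: str = "csv", frame_rate: float = 30.0) -> list[Tracklet]:
    """Parse a tracklet file into one Tracklet per distinct track id.

    Rows are sorted by frame within each track; duplicate (id, frame) pairs
    raise a validation error.
    """
    path = Path(path)
    if dialect == "csv":
        try:
            df = pd.read_csv(path, dtype={"track_id": str}, float_precision="round_trip")
        except pd.errors.EmptyDataError:
            return []
        required = {"track_id", "frame", "x", "y"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"{path}: csv dialect requires columns {sorted(required)}, "
                f"got {list(df.columns)}"
            )
    elif dialect == "mot":
        try:
            df = pd.read_csv(path, header=None, float_precision="round_trip")
        except pd.errors.EmptyDataError:
            return []
        if df.shape[1] < 6:
            raise ValueError(f"{path}: mot dialect requires at least 6 columns")
        df = df.iloc[:, :6].copy()
        df.columns = ["frame", "track_id", "x", "y", "w", "h"]
        df["track_id"] = df["track_id"].astype(str)
        df["x"] = df["x"] + df["w"] / 2.0  # bbox centre
        df["y"] = df["y"] + df["h"] / 2.0
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'csv' or 'mot'")

    for col in ("frame", "x", "y"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna() | df[col].isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise ValueError(f"{path}: malformed value in column {col!r} near line {line}")
        df[col] = pd.to_numeric(df[col])

    tracks: list[Tracklet] = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy(dtype=np.int64)
        if np.any(np.diff(frames) == 0):
            dup = int(frames[np.flatnonzero(np.diff(frames) == 0)[0]])
            raise ValueError(f"{path}: duplicate frame {dup} within track {tid!r}")
        tracks.append(
            Tracklet(
                track_id=str(tid),
                frames=frames,
                positions=grp[["x", "y"]].to_numpy(dtype=np.float64),
                frame_rate=frame_rate,
            )
        )
    return tracks


def write_tracklets(tracks: Iterable[Tracklet], path) -> None:
    """Write the csv dialect bit-exactly: fixed column order, \\n endings,
    full float precision (repr round-trip)."""
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        fh.write("track_id,frame,x,y\n")
        for tr in tracks:
            for f, (x, y) in zip(tr.frames, tr.positions):
                fh.write(f"{tr.track_id},{int(f)},{float(x)!r},{float(y)!r}\n")


# ---------------------------------------------------------------------------
# Cleaning and transforms
# ---------------------------------------------------------------------------

def clean_tracklets(tracks: Sequence[Tracklet], min_length: int = DEFAULT_MIN_LENGTH) -> list[Tracklet]:
    """Split tracks at frame gaps and drop segments shorter than min_length.

    No interpolation is performed: a gap indicates a tracking failure and the
    segments on either side are treated as independent tracklets.
    """
    if min_length < 2:
        raise ValueError("min_length must be >= 2")
    out: list[Tracklet] = []
    for tr in tracks:
        gaps = np.flatnonzero(np.diff(tr.frames) > 1) + 1
        pieces = np.split(np.arange(len(tr)), gaps)
        n_seg = 0
        for idx in pieces:
            if idx.size < min_length:
                continue
            suffix = f".{n_seg}" if len(pieces) > 1 else ""
            out.append(
                Tracklet(
                    track_id=tr.track_id + suffix,
                    frames=tr.frames[idx],
                    positions=tr.positions[idx],
                    frame_rate=tr.frame_rate,
                )
            )
            n_seg += 1
    return out


def to_displacements(positions: np.ndarray) -> np.ndarray:
    """Frame-to-frame displacements: row t is p_{t+1} - p_t, shape (N-1, 2)."""
    positions = np.asarray(positions, dtype=np.float64)
    if positions.ndim != 2 or positions.shape[0] < 2:
        raise ValueError("need an N x 2 position matrix with N >= 2")
    return np.diff(positions, axis=0)


def reconstruct_positions(last_pos: np.ndarray, displacements: np.ndarray) -> np.ndarray:
    """Cumulatively sum displacements starting from last_pos, shape (M, 2)."""
    last_pos = np.asarray(last_pos, dtype=np.float64).ravel()
    displacements = np.asarray(displacements, dtype=np.float64)
    return last_pos + np.cumsum(displacements, axis=0)


def make_windows(track: Tracklet, T_past: int = DEFAULT_T_PAST, T_fut: int = DEFAULT_T_FUT,
                 stride: int = 1) -> list[Window]:
    """Cut a contiguous tracklet into overlapping observation-prediction windows.

    Yields max(0, floor((N - T_past - T_fut)/stride) + 1) windows.
    """
    if T_past < 2 or T_fut < 1 or stride < 1:
        raise ValueError("require T_past >= 2, T_fut >= 1, stride >= 1")
    if not track.is_contiguous:
        raise ValueError(
            f"track {track.track_id!r} has frame gaps; run clean_tracklets first"
        )
    N = len(track)
    span = T_past + T_fut
    windows: list[Window] = []
    for start in range(0, N - span + 1, stride):
        past = track.positions[start:start + T_past]
        fut = track.positions[start + T_past:start + span]
        windows.append(
            Window(
                track_id=track.track_id,
                anchor_frame=int(track.frames[start + T_past - 1]),
                past_positions=past,
                future_positions=fut,
            )
        )
    return windows
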