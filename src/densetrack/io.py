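"""Trajectory container and file I/O.

Conventions: internal coordinates are 0-based pixels with ``x = column``,
``y = row``; output CSVs are MOTChallenge-style with 1-based frame numbers.
Each tracked point is written as a square box of radius 15 centred on it,
since the objects themselves are only a few pixels across.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "BOX_RADIUS",
    "write_tracks",
    "read_tracks",
    "write_detections",
    "read_detections",
    "load_frames",
]

BOX_RADIUS = 15.0

_DET_COLUMNS = ["frame", "det_id", "x", "y", "area"]
_TRACK_COLUMNS = [
    "frame", "id", "bb_left", "bb_top", "bb_width", "bb_height", "conf", "x", "y", "z",
]


@dataclass
class Trajectory:
    """One tracked object: (frame, x, y) points; missed frames are simply
    absent (gap markers)."""

    track_id: int
    points: list = field(default_factory=list)   # (frame, x, y), frames ascending

    def add(self, frame: int, x: float, y: float) -> None:
        if self.points and frame <= self.points[-1][0]:
            raise ValueError("frames must be strictly increasing")
        self.points.append((frame, float(x), float(y)))

    def position_at(self, frame: int):
        for f, x, y in self.points:
            if f == frame:
                return np.array([x, y])
        return None

    @property
    def frames(self) -> list:
        return [p[0] for p in self.points]


def write_tracks(trajectories: list, path) -> None:
    """MOTChallenge CSV ``frame,id,bb_left,bb_top,bb_width,bb_height,conf,
    x,y,z`` with radius-15 boxes and 1-based frames."""
    rows = []
    for traj in trajectories:
        for frame, x, y in traj.points:
            rows.append(
                (
                    frame + 1,
                    traj.track_id,
                    x - BOX_RADIUS,
                    y - BOX_RADIUS,
                    2 * BOX_RADIUS,
                    2 * BOX_RADIUS,
                    1,
                    -1,
                    -1,
                    -1,
                )
            )
    rows.sort(key=lambda r: (r[0], r[1]))
    df = pd.DataFrame(rows, columns=_TRACK_COLUMNS)
    df.to_csv(path, index=False)


def read_tracks(path) -> list:
    df = pd.read_csv(path)
    missing = set(_TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: dict[int, Trajectory] = {}
    for idx, row in enumerate(df.itertuples(index=False)):
        try:
            tid = int(row.id)
            frame = int(row.frame) - 1
            x = float(row.bb_left) + float(row.bb_width) / 2
            y = float(row.bb_top) + float(row.bb_height) / 2
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {idx + 2}") from exc
        out.setdefault(tid, Trajectory(tid)).add(frame, x, y)
    return [out[tid] for tid in sorted(out)]


def write_detections(detections_per_frame: list, path) -> None:
    """Detections CSV ``frame,det_id,x,y,area`` (0-based frames, fractional
    x = col / y = row centroids)."""
    rows = []
    for dets in detections_per_frame:
        for d in dets:
            if d.is_dummy:
                continue
            rows.append((d.frame_index, d.detection_id, d.position[0], d.position[1], len(d.pixel_set)))
    pd.DataFrame(rows, columns=_DET_COLUMNS).to_csv(path, index=False)


def read_detections(path) -> list:
    """Read a detections CSV back into per-frame lists of Detection."""
    from .malc import Detection

    df = pd.read_csv(path)
    missing = set(_DET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if len(df) == 0:
        return []
    n_frames = int(df["frame"].max()) + 1
    frames: list[list] = [[] for _ in range(n_frames)]
    for idx, row in enumerate(df.itertuples(index=False)):
        try:
            f = int(row.frame)
            frames[f].append(
                Detection(
                    frame_index=f,
                    centroid=(float(row.y), float(row.x)),
                    detection_id=int(row.det_id),
                )
            )
        except (TypeError, ValueError, IndexError) as exc:
            raise ValueError(f"{path}: malformed row at line {idx + 2}") from exc
    return frames


def load_frames(path) -> list:
    """Load a grayscale sequence from a directory of PNG/TIFF frames
    (lexicographic order) or a multi-page TIFF; returns float arrays."""
    import imageio.v3 as iio

    p = Path(path)
    if p.is_dir():
        files = sorted(
            f for f in p.iterdir() if re.search(r"\.(png|tif|tiff)$", f.name, re.I)
        )
        frames = [np.asarray(iio.imread(f), dtype=float) for f in files]
    else:
        stack = np.asarray(iio.imread(p))
        if stack.ndim == 2:
            stack = stack[None]
        frames = [np.asarray(fr, dtype=float) for fr in stack]
    out = []
    for fr in frames:
        if fr.ndim == 3:       # collapse RGB(A) to luminance
            fr = fr[..., :3].mean(axis=-1)
        out.append(fr)
    return out
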