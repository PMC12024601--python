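"""Landmark data model, stream readers/writers and cross-camera alignment.

Two plain-text dialects are supported for landmark streams:

* JSON-lines: one frame per line, ``{"kind": "body", "frame_index": 0,
  "timestamp": 0.0, "camera_label": "A", "points": [[x, y, z, visibility],
  ...]}``.
* CSV: one row per (frame, point) with columns
  ``frame,idx,x,y,z,visibility`` (kind and camera metadata in a header
  comment line ``# kind=body camera=A fps=30``).

Body frames carry exactly 33 points, face frames exactly 478.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import (AlignmentError, EmptyInputError, OrderingError,
                     SchemaError)
from .reba_core import RebaPoints

__all__ = [
    "BODY_POINT_COUNT", "FACE_POINT_COUNT", "BODY_LANDMARKS",
    "LandmarkPoint", "LandmarkFrame", "CameraStream", "SyncSession",
    "PointsSeries",
    "read_landmark_stream", "write_landmark_stream", "synchronize",
    "write_points_table", "read_points_table",
]

BODY_POINT_COUNT = 33
FACE_POINT_COUNT = 478

POINT_COUNTS = {"body": BODY_POINT_COUNT, "face": FACE_POINT_COUNT}

#: Index map for the 33-point body schema (subset used by the pipeline).
BODY_LANDMARKS = {
    "nose": 0,
    "left_shoulder": 11, "right_shoulder": 12,
    "left_elbow": 13, "right_elbow": 14,
    "left_wrist": 15, "right_wrist": 16,
    "left_index": 19, "right_index": 20,
    "left_hip": 23, "right_hip": 24,
    "left_knee": 25, "right_knee": 26,
    "left_ankle": 27, "right_ankle": 28,
}


@dataclass(frozen=True)
class LandmarkPoint:
    """One landmark: normalized image coordinates (origin top-left, y down),
    relative depth and a [0, 1] visibility confidence."""

    x: float
    y: float
    z: float = 0.0
    visibility: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise SchemaError(f"non-finite landmark coordinates ({self.x}, {self.y})")
        if not 0.0 <= self.visibility <= 1.0:
            raise SchemaError(f"visibility {self.visibility} outside [0, 1]")


@dataclass(frozen=True)
class LandmarkFrame:
    kind: str  # "body" | "face"
    points: tuple
    frame_index: int = 0
    timestamp: float = 0.0
    camera_label: str = "A"

    def __post_init__(self) -> None:
        if self.kind not in POINT_COUNTS:
            raise SchemaError(f"unknown frame kind {self.kind!r}")
        expected = POINT_COUNTS[self.kind]
        if len(self.points) != expected:
            raise SchemaError(
                f"frame {self.frame_index}: {self.kind} frame carries "
                f"{len(self.points)} points, expected {expected}")
        if self.frame_index < 0:
            raise SchemaError(f"negative frame_index {self.frame_index}")


@dataclass
class CameraStream:
    camera_label: str
    kind: str
    frames: list
    fps: float = 30.0
    resolution: tuple[int, int] = (1280, 720)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise SchemaError(f"fps must be positive, got {self.fps}")
        last = -1
        for f in self.frames:
            if f.kind != self.kind:
                raise SchemaError(
                    f"frame {f.frame_index} kind {f.kind!r} != stream kind "
                    f"{self.kind!r}")
            if f.frame_index <= last:
                raise OrderingError(
                    f"frame_index {f.frame_index} not strictly increasing "
                    f"(previous {last})")
            last = f.frame_index

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class SyncSession:
    """One to three co-indexed body streams, plus optional per-camera face
    streams (typically only camera A carries one)."""

    streams: list
    aligned_length: int
    face_streams: dict = field(default_factory=dict)

    def frames_at(self, i: int) -> list:
        return [s.frames[i] for s in self.streams]


@dataclass
class PointsSeries:
    """Per-frame REBA points for one camera (0 = occlusion sentinel)."""

    camera_label: str
    frames: list  # list[RebaPoints]

    def __post_init__(self) -> None:
        if not self.frames:
            raise EmptyInputError("points series must contain at least one frame")
        for p in self.frames:
            p.validate(allow_sentinel=True)

    def __len__(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# Landmark stream I/O
# ---------------------------------------------------------------------------

def _frame_from_record(rec: dict, kind: str, line_no: int) -> LandmarkFrame:
    pts = rec.get("points")
    if pts is None:
        raise SchemaError(f"line {line_no}: missing 'points'")
    points = tuple(LandmarkPoint(*map(float, p)) for p in pts)
    return LandmarkFrame(
        kind=rec.get("kind", kind),
        points=points,
        frame_index=int(rec.get("frame_index", line_no)),
        timestamp=float(rec.get("timestamp", 0.0)),
        camera_label=str(rec.get("camera_label", "A")),
    )


def read_landmark_stream(path: str, kind: str, camera_label: Optional[str] = None,
                         fps: Optional[float] = None) -> CameraStream:
    """Read a landmark stream (JSON-lines by default, CSV for ``.csv`` paths).

    Point-count, ordering and emptiness violations raise SchemaError /
    OrderingError / EmptyInputError naming the offending frame.
    """
    if kind not in POINT_COUNTS:
        raise SchemaError(f"unknown stream kind {kind!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if str(path).endswith(".csv"):
        return _read_stream_csv(path, kind, camera_label, fps)

    frames = []
    meta: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            if "points" not in rec and ("fps" in rec or "resolution" in rec):
                meta = rec  # optional leading metadata record
                continue
            frames.append(_frame_from_record(rec, kind, line_no))
    if not frames:
        raise EmptyInputError(f"{path}: no frames")
    label = camera_label or frames[0].camera_label
    return CameraStream(
        camera_label=label, kind=kind, frames=frames,
        fps=fps or float(meta.get("fps", 30.0)),
        resolution=tuple(meta.get("resolution", (1280, 720))),
    )


def _read_stream_csv(path, kind, camera_label, fps):
    meta = {}
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first[1:].split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    meta[k] = v
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    if df.empty:
        raise EmptyInputError(f"{path}: no rows")
    frames = []
    label = camera_label or meta.get("camera", "A")
    file_kind = meta.get("kind", kind)
    stream_fps = fps or float(meta.get("fps", 30.0))
    for frame_idx, grp in df.groupby("frame", sort=True):
        grp = grp.sort_values("idx")
        points = tuple(
            LandmarkPoint(r.x, r.y, r.z, r.visibility)
            for r in grp.itertuples())
        frames.append(LandmarkFrame(kind=file_kind, points=points,
                                    frame_index=int(frame_idx),
                                    timestamp=float(frame_idx) / stream_fps,
                                    camera_label=label))
    return CameraStream(camera_label=label, kind=kind, frames=frames,
                        fps=stream_fps)


def write_landmark_stream(stream: CameraStream, path: str) -> None:
    """Write a stream in the dialect implied by the path suffix."""
    if str(path).endswith(".csv"):
        rows = []
        for f in stream.frames:
            for i, p in enumerate(f.points):
                rows.append((f.frame_index, i, p.x, p.y, p.z, p.visibility))
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# kind={stream.kind} camera={stream.camera_label} "
                     f"fps={stream.fps}\n")
            pd.DataFrame(rows, columns=["frame", "idx", "x", "y", "z",
                                        "visibility"]).to_csv(fh, index=False)
        return
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(json.dumps({"fps": stream.fps,
                             "resolution": list(stream.resolution)}) + "\n")
        for f in stream.frames:
            fh.write(json.dumps({
                "kind": f.kind,
                "frame_index": f.frame_index,
                "timestamp": f.timestamp,
                "camera_label": f.camera_label,
                "points": [[p.x, p.y, p.z, p.visibility] for p in f.points],
            }) + "\n")


def synchronize(streams: Sequence[CameraStream],
                offsets: Optional[Sequence[int]] = None) -> SyncSession:
    """Co-index streams by discarding each stream's first ``offset`` frames.

    All streams must share fps (no resampling is attempted).  Raises
    AlignmentError when an offset exhausts its stream.
    """
    streams = list(streams)
    if not streams:
        raise EmptyInputError("synchronize requires at least one stream")
    if offsets is None:
        offsets = [0] * len(streams)
    if len(offsets) != len(streams):
        raise SchemaError("one offset per stream required")
    if any(o < 0 or int(o) != o for o in offsets):
        raise SchemaError("offsets must be nonnegative integers")
    fps0 = streams[0].fps
    if any(abs(s.fps - fps0) > 1e-9 for s in streams):
        raise SchemaError("streams with differing fps cannot be synchronized")

    trimmed = []
    for s, off in zip(streams, offsets):
        remaining = s.frames[int(off):]
        if not remaining:
            raise AlignmentError(
                f"camera {s.camera_label}: offset {off} exhausts stream of "
                f"length {len(s)}")
        trimmed.append(CameraStream(camera_label=s.camera_label, kind=s.kind,
                                    frames=remaining, fps=s.fps,
                                    resolution=s.resolution))
    n = min(len(s) for s in trimmed)
    for i, s in enumerate(trimmed):
        trimmed[i] = CameraStream(camera_label=s.camera_label, kind=s.kind,
                                  frames=s.frames[:n], fps=s.fps,
                                  resolution=s.resolution)
    return SyncSession(streams=trimmed, aligned_length=n)


# ---------------------------------------------------------------------------
# REBA points tables
# ---------------------------------------------------------------------------

_POINTS_COLUMNS = ["frame", "camera", "neck", "trunk", "leg",
                   "upper_arm", "lower_arm", "wrist"]


def write_points_table(series: Iterable[PointsSeries], path: str) -> None:
    """Write per-frame REBA points (one row per frame and camera) as CSV.

    Zero sentinels are preserved verbatim; round-trips losslessly with
    :func:`read_points_table`.
    """
    series = list(series)
    if not series or all(len(s) == 0 for s in series):
        raise EmptyInputError("no points to write")
    rows = []
    for s in series:
        for i, p in enumerate(s.frames):
            rows.append((i, s.camera_label) + p.as_tuple())
    pd.DataFrame(rows, columns=_POINTS_COLUMNS).to_csv(path, index=False)


def read_points_table(path: str) -> list:
    """Read a points CSV back into one PointsSeries per camera."""
    df = pd.read_csv(path)
    if df.empty:
        raise EmptyInputError(f"{path}: no rows")
    missing = set(_POINTS_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for cam in pd.unique(df["camera"]):
        grp = df[df["camera"] == cam].sort_values("frame")
        frames = [RebaPoints(int(r.neck), int(r.trunk), int(r.leg),
                             int(r.upper_arm), int(r.lower_arm), int(r.wrist))
                  for r in grp.itertuples()]
        out.append(PointsSeries(camera_label=str(cam), frames=frames))
    return out
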