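"""Reading, writing and normalising 2D keypoint streams.

Three on-disk dialects are supported, all plain text:

* **Body25 JSON** — an array of frame objects, each with a flat
  ``"keypoints"`` list of 75 numbers ``(x1, y1, c1, ..., x25, y25, c25)``,
  the usual OpenPose output shape.
* **Panoptic pose JSON** — an array of frames, each an array of 15
  ``[x, y]`` or ``[x, y, confidence]`` landmarks.
* **Generic long CSV** — header ``video_id,frame,joint_id,x,y[,confidence]``;
  one file may hold several videos.

All readers normalise into :class:`KeypointStream`: a per-video array-backed
time series with an explicit :class:`~poseagree.layouts.SkeletonLayout` and a
per-landmark missingness mask.  By the OpenPose convention a landmark with
confidence 0 **or** coordinates exactly (0, 0) is a detection loss and is
flagged missing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import AmbiguityError, LayoutError, ParseError, PoseagreeError
from .layouts import BODY25, PANOPTIC15, SkeletonLayout


@dataclass(frozen=True)
class KeypointFrame:
    """A single skeleton observation: one row of a :class:`KeypointStream`."""

    frame_index: int
    coords: np.ndarray  # (n_landmarks, 2) pixels
    confidence: np.ndarray | None  # (n_landmarks,) in [0, 1], or None
    missing: np.ndarray  # (n_landmarks,) bool


@dataclass
class KeypointStream:
    """Per-video keypoint time series in one skeleton layout.

    ``coords`` has shape (n_frames, n_landmarks, 2); where ``missing`` is
    True the coordinates are ignored downstream (they may be NaN or the
    (0, 0) sentinel as read).
    """

    video_id: str
    fps: float
    layout: SkeletonLayout
    frame_index: np.ndarray  # (n_frames,) strictly increasing ints
    coords: np.ndarray  # (n_frames, n_landmarks, 2)
    missing: np.ndarray  # (n_frames, n_landmarks) bool
    confidence: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise PoseagreeError(f"fps must be positive, got {self.fps}")
        fi = np.asarray(self.frame_index)
        if fi.size > 1 and not np.all(np.diff(fi) > 0):
            raise PoseagreeError(
                f"video {self.video_id!r}: frame_index not strictly increasing"
            )
        if self.coords.shape[1] != self.layout.n_landmarks:
            raise LayoutError(
                f"video {self.video_id!r}: {self.coords.shape[1]} landmarks "
                f"per frame, layout {self.layout.name!r} expects "
                f"{self.layout.n_landmarks}"
            )
        valid = ~self.missing
        if not np.all(np.isfinite(self.coords[valid])):
            raise PoseagreeError(
                f"video {self.video_id!r}: non-finite coordinates at "
                "landmarks not flagged missing"
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in seconds (frame_index / fps)."""
        return np.asarray(self.frame_index, dtype=float) / self.fps

    def frame(self, i: int) -> KeypointFrame:
        conf = None if self.confidence is None else self.confidence[i]
        return KeypointFrame(
            frame_index=int(self.frame_index[i]),
            coords=self.coords[i],
            confidence=conf,
            missing=self.missing[i],
        )

    def frames(self) -> Iterator[KeypointFrame]:
        for i in range(self.n_frames):
            yield self.frame(i)


def _missing_mask(coords: np.ndarray, confidence: np.ndarray | None) -> np.ndarray:
    """OpenPose loss sentinel: confidence == 0 or coords exactly (0, 0)."""
    zero_xy = (coords[..., 0] == 0.0) & (coords[..., 1] == 0.0)
    nan_xy = ~np.isfinite(coords).all(axis=-1)
    miss = zero_xy | nan_xy
    if confidence is not None:
        miss |= confidence == 0.0
    return miss


def read_body25_json(
    path: str | Path,
    *,
    video_id: str | None = None,
    fps: float = 30.0,
) -> KeypointStream:
    """Read an OpenPose-style Body25 JSON file into a stream.

    The file holds a JSON array of frame objects; each object carries a flat
    ``"keypoints"`` list of 75 numbers and optionally ``"frame_index"``.
    A top-level object with ``"fps"``/``"video_id"``/``"frames"`` keys is
    also accepted and overrides the keyword defaults.
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)

    if isinstance(doc, dict):
        fps = float(doc.get("fps", fps))
        video_id = doc.get("video_id", video_id)
        records = doc.get("frames")
        if records is None:
            raise ParseError(f"{path}: top-level object lacks 'frames'")
    else:
        records = doc
    if video_id is None:
        video_id = path.stem

    n = len(records)
    coords = np.empty((n, 25, 2))
    conf = np.empty((n, 25))
    frame_index = np.empty(n, dtype=int)
    for i, rec in enumerate(records):
        if isinstance(rec, dict):
            flat = rec.get("keypoints")
            frame_index[i] = int(rec.get("frame_index", i))
        else:
            flat = rec
            frame_index[i] = i
        if flat is None:
            raise ParseError(f"{path}: frame {i} has no 'keypoints' field")
        flat = np.asarray(flat, dtype=float)
        if flat.ndim != 1 or flat.size != 75:
            raise LayoutError(
                f"{path}: frame {i} carries {flat.size} numbers, "
                "expected 75 (25 landmarks x [x, y, confidence])"
            )
        trip = flat.reshape(25, 3)
        coords[i] = trip[:, :2]
        conf[i] = trip[:, 2]

    missing = _missing_mask(coords, conf)
    return KeypointStream(
        video_id=video_id,
        fps=fps,
        layout=BODY25,
        frame_index=frame_index,
        coords=coords,
        missing=missing,
        confidence=conf,
    )


def write_body25_json(stream: KeypointStream, path: str | Path) -> None:
    """Write a 25-landmark stream in the Body25 JSON dialect.

    Missing landmarks are written with the (0, 0, 0) loss sentinel so the
    file round-trips through :func:`read_body25_json`.
    """
    if stream.layout.n_landmarks != 25:
        raise LayoutError("write_body25_json requires a 25-landmark layout")
    frames = []
    conf = stream.confidence
    for i in range(stream.n_frames):
        c = stream.coords[i].copy()
        cf = np.ones(25) if conf is None else conf[i].copy()
        m = stream.missing[i]
        c[m] = 0.0
        cf[m] = 0.0
        flat = np.column_stack([c, cf]).reshape(-1)
        frames.append(
            {"frame_index": int(stream.frame_index[i]), "keypoints": flat.tolist()}
        )
    doc = {"video_id": stream.video_id, "fps": stream.fps, "frames": frames}
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_panoptic_pose(
    path: str | Path,
    *,
    video_id: str | None = None,
    fps: float = 30.0,
) -> KeypointStream:
    """Read a 15-landmark reference-style pose JSON file.

    Each frame is an array of 15 ``[x, y]`` (confidence optional).  A frame
    entry may be ``null`` for a fully lost frame.  If a landmark slot holds
    ``null`` the landmark is declared absent for that frame.
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)

    if isinstance(doc, dict):
        fps = float(doc.get("fps", fps))
        video_id = doc.get("video_id", video_id)
        records = doc.get("frames")
        if records is None:
            raise ParseError(f"{path}: top-level object lacks 'frames'")
    else:
        records = doc
    if video_id is None:
        video_id = path.stem

    n = len(records)
    coords = np.full((n, 15, 2), np.nan)
    conf = np.ones((n, 15))
    missing = np.zeros((n, 15), dtype=bool)
    frame_index = np.arange(n)
    for i, rec in enumerate(records):
        if rec is None:
            missing[i, :] = True
            continue
        if len(rec) != 15:
            raise LayoutError(
                f"{path}: frame {i} has {len(rec)} landmarks, expected 15"
            )
        for j, lm in enumerate(rec):
            if lm is None:
                missing[i, j] = True
                continue
            if len(lm) < 2:
                raise ParseError(f"{path}: frame {i} landmark {j} malformed")
            coords[i, j] = (float(lm[0]), float(lm[1]))
            if len(lm) >= 3:
                conf[i, j] = float(lm[2])
    missing |= _missing_mask(coords, conf)
    return KeypointStream(
        video_id=video_id,
        fps=fps,
        layout=PANOPTIC15,
        frame_index=frame_index,
        coords=coords,
        missing=missing,
        confidence=conf,
    )


def write_panoptic_pose(stream: KeypointStream, path: str | Path) -> None:
    """Write a 15-landmark stream as Panoptic-style pose JSON."""
    if stream.layout.n_landmarks != 15:
        raise LayoutError("write_panoptic_pose requires a 15-landmark layout")
    frames = []
    for i in range(stream.n_frames):
        rec = []
        for j in range(15):
            if stream.missing[i, j]:
                rec.append(None)
            else:
                x, y = stream.coords[i, j]
                rec.append([float(x), float(y)])
        frames.append(rec)
    doc = {"video_id": stream.video_id, "fps": stream.fps, "frames": frames}
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_keypoints_csv(
    path: str | Path,
    layout: SkeletonLayout,
    *,
    fps: float = 30.0,
) -> list[KeypointStream]:
    """Read a long-format keypoint CSV into one stream per video.

    Expected columns: ``video_id, frame, joint_id, x, y[, confidence]``.
    A (video, frame, joint) triple absent from the file is flagged missing;
    a duplicated triple is an error.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"video_id", "frame", "joint_id", "x", "y"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    dup = df.duplicated(subset=["video_id", "frame", "joint_id"])
    if dup.any():
        first = df[dup].iloc[0]
        raise AmbiguityError(
            f"{path}: duplicate row for video {first['video_id']!r} "
            f"frame {int(first['frame'])} joint {int(first['joint_id'])}"
        )
    has_conf = "confidence" in df.columns

    streams = []
    for vid, g in df.groupby("video_id", sort=True):
        frames = np.sort(g["frame"].unique()).astype(int)
        pos = {f: i for i, f in enumerate(frames)}
        n, nl = len(frames), layout.n_landmarks
        coords = np.full((n, nl, 2), np.nan)
        conf = np.ones((n, nl))
        rows = g["frame"].map(pos).to_numpy()
        jid = g["joint_id"].to_numpy(dtype=int)
        if jid.min() < 0 or jid.max() >= nl:
            raise LayoutError(
                f"{path}: joint_id outside 0..{nl - 1} for layout "
                f"{layout.name!r}"
            )
        coords[rows, jid, 0] = g["x"].to_numpy(dtype=float)
        coords[rows, jid, 1] = g["y"].to_numpy(dtype=float)
        if has_conf:
            conf[rows, jid] = g["confidence"].to_numpy(dtype=float)
        missing = _missing_mask(coords, conf if has_conf else None)
        streams.append(
            KeypointStream(
                video_id=str(vid),
                fps=fps,
                layout=layout,
                frame_index=frames,
                coords=coords,
                missing=missing,
                confidence=conf if has_conf else None,
            )
        )
    return streams


def write_keypoints_csv(streams: list[KeypointStream], path: str | Path) -> None:
    """Write streams as a single long-format CSV (missing landmarks omitted)."""
    rows = []
    for s in streams:
        conf = s.confidence
        for i in range(s.n_frames):
            for j in range(s.layout.n_landmarks):
                if s.missing[i, j]:
                    continue
                rows.append(
                    (
                        s.video_id,
                        int(s.frame_index[i]),
                        j,
                        s.coords[i, j, 0],
                        s.coords[i, j, 1],
                        1.0 if conf is None else conf[i, j],
                    )
                )
    df = pd.DataFrame(
        rows, columns=["video_id", "frame", "joint_id", "x", "y", "confidence"]
    )
    # %.17g is the shortest format guaranteed to round-trip a double
    df.to_csv(path, index=False, float_format="%.17g")


READERS = {
    "body25": read_body25_json,
    "panoptic": read_panoptic_pose,
}
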