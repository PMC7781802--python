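"""Joint angles from 2D keypoint triplets.

Each tracked joint is defined by an ordered landmark triplet (A, B, C) with B
the vertex; its angle is the unsigned interior angle between the rays B→A and
B→C, in degrees in [0, 180].  The default registry covers the ten standard
whole-body joints:

====================  =====================================
joint                 triplet (A, vertex, C)
====================  =====================================
right/left shoulder   hip, shoulder, elbow (same side)
right/left elbow      shoulder, elbow, wrist (same side)
right/left hip        shoulder, hip, knee (same side)
right/left knee       hip, knee, ankle (same side)
neck                  pelvis, neck, head
pelvis                left knee, pelvis, right knee
====================  =====================================

Interior angles are invariant to translation, rotation and uniform scaling of
the keypoints, so the pixel-coordinate convention of the source never enters
the analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, DegenerateGeometryError
from .io import KeypointStream

JOINT_NAMES = (
    "right_shoulder",
    "left_shoulder",
    "right_elbow",
    "left_elbow",
    "right_hip",
    "left_hip",
    "right_knee",
    "left_knee",
    "neck",
    "pelvis",
)


@dataclass(frozen=True)
class JointTripletDef:
    """An (A, vertex, C) landmark triplet defining one joint angle."""

    joint_name: str
    triplet: tuple[str, str, str]


DEFAULT_TRIPLETS: tuple[JointTripletDef, ...] = (
    JointTripletDef("right_shoulder", ("r_hip", "r_shoulder", "r_elbow")),
    JointTripletDef("left_shoulder", ("l_hip", "l_shoulder", "l_elbow")),
    JointTripletDef("right_elbow", ("r_shoulder", "r_elbow", "r_wrist")),
    JointTripletDef("left_elbow", ("l_shoulder", "l_elbow", "l_wrist")),
    JointTripletDef("right_hip", ("r_shoulder", "r_hip", "r_knee")),
    JointTripletDef("left_hip", ("l_shoulder", "l_hip", "l_knee")),
    JointTripletDef("right_knee", ("r_hip", "r_knee", "r_ankle")),
    JointTripletDef("left_knee", ("l_hip", "l_knee", "l_ankle")),
    JointTripletDef("neck", ("pelvis", "neck", "head")),
    JointTripletDef("pelvis", ("l_knee", "pelvis", "r_knee")),
)


def load_triplet_registry(path: str | Path) -> tuple[JointTripletDef, ...]:
    """Load a triplet registry from a JSON file.

    The file maps joint names to three-element landmark lists, e.g.
    ``{"right_elbow": ["r_shoulder", "r_elbow", "r_wrist"]}``.
    """
    with open(path) as fh:
        doc = json.load(fh)
    defs = []
    for joint, triplet in doc.items():
        if len(triplet) != 3:
            raise ConfigurationError(
                f"joint {joint!r}: triplet must list exactly 3 landmarks"
            )
        defs.append(JointTripletDef(joint, tuple(triplet)))
    return tuple(defs)


def save_triplet_registry(
    defs: tuple[JointTripletDef, ...], path: str | Path
) -> None:
    with open(path, "w") as fh:
        json.dump({d.joint_name: list(d.triplet) for d in defs}, fh, indent=2)


@dataclass
class AngleSeries:
    """Angle-versus-frame series for one joint of one video, in degrees.

    ``values`` is NaN wherever ``missing`` is True.
    """

    video_id: str
    joint_name: str
    fps: float
    frame_index: np.ndarray
    values: np.ndarray
    missing: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.frame_index, dtype=float) / self.fps

    def copy_with(self, values: np.ndarray, missing: np.ndarray) -> "AngleSeries":
        return AngleSeries(
            video_id=self.video_id,
            joint_name=self.joint_name,
            fps=self.fps,
            frame_index=self.frame_index.copy(),
            values=values,
            missing=missing,
        )


def interior_angle(a, b, c) -> float:
    """Unsigned interior angle at vertex ``b`` between rays b→a and b→c.

    Returns degrees in [0, 180].  Raises
    :class:`~poseagree.errors.DegenerateGeometryError` when either ray has
    zero length.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    u = a - b
    v = c - b
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
        raise DegenerateGeometryError("non-finite input point")
    if (u == 0).all() or (v == 0).all():
        raise DegenerateGeometryError("zero-length ray at the vertex")
    # atan2 of (|cross|, dot) is numerically stable near 0 and 180 degrees,
    # unlike arccos of the normalized dot product.
    cross = u[0] * v[1] - u[1] * v[0]
    dot = u[0] * v[0] + u[1] * v[1]
    return float(np.degrees(np.arctan2(abs(cross), dot)))


def interior_angles(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Vectorised :func:`interior_angle` over (..., 2) point arrays.

    Degenerate rows (zero-length ray or non-finite input) yield NaN instead
    of raising, so one bad frame cannot abort a whole video.
    """
    u = np.asarray(a, dtype=float) - b
    v = np.asarray(c, dtype=float) - b
    cross = u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]
    dot = (u * v).sum(axis=-1)
    bad = (
        ~np.isfinite(u).all(axis=-1)
        | ~np.isfinite(v).all(axis=-1)
        | ((u == 0).all(axis=-1))
        | ((v == 0).all(axis=-1))
    )
    with np.errstate(invalid="ignore"):
        ang = np.degrees(np.arctan2(np.abs(cross), dot))
    ang = np.where(bad, np.nan, ang)
    return ang


def _landmark_track(
    stream: KeypointStream, canonical: str
) -> tuple[np.ndarray, np.ndarray]:
    """(coords, missing) time series of one canonical landmark.

    For layouts with no explicit pelvis, pelvis falls back to the midpoint of
    the two hips.  Any other absent landmark raises.
    """
    idx = stream.layout.resolve(canonical)
    if idx is not None:
        return stream.coords[:, idx, :], stream.missing[:, idx]
    if canonical == "pelvis":
        li = stream.layout.resolve("l_hip")
        ri = stream.layout.resolve("r_hip")
        if li is not None and ri is not None:
            mid = 0.5 * (stream.coords[:, li, :] + stream.coords[:, ri, :])
            miss = stream.missing[:, li] | stream.missing[:, ri]
            return mid, miss
    raise ConfigurationError(
        f"landmark {canonical!r} is absent from layout "
        f"{stream.layout.name!r} and has no documented approximation"
    )


def extract_angle_series(
    stream: KeypointStream,
    defs: tuple[JointTripletDef, ...] = DEFAULT_TRIPLETS,
) -> list[AngleSeries]:
    """Compute one :class:`AngleSeries` per triplet definition.

    A frame is missing in a joint's output iff any of its three landmarks is
    missing at that frame or the triplet is geometrically degenerate there.
    """
    out = []
    for d in defs:
        try:
            pa, ma = _landmark_track(stream, d.triplet[0])
            pb, mb = _landmark_track(stream, d.triplet[1])
            pc, mc = _landmark_track(stream, d.triplet[2])
        except ConfigurationError as exc:
            raise ConfigurationError(f"joint {d.joint_name!r}: {exc}") from exc
        miss = ma | mb | mc
        values = interior_angles(pa, pb, pc)
        miss |= ~np.isfinite(values)
        values = np.where(miss, np.nan, values)
        out.append(
            AngleSeries(
                video_id=stream.video_id,
                joint_name=d.joint_name,
                fps=stream.fps,
                frame_index=np.asarray(stream.frame_index).copy(),
                values=values,
                missing=miss,
            )
        )
    return out
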