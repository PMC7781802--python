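"""Skeleton layouts and canonical landmark naming.

A :class:`SkeletonLayout` maps canonical anatomical landmark names (the ones
joint-angle triplets are written in) onto integer indices of a concrete
skeleton convention.  Two conventions ship by default:

* ``BODY25`` — the 25-landmark convention emitted by OpenPose-style 2D
  estimators.  It has no explicit head landmark, so ``head`` resolves to the
  nose, and ``pelvis`` resolves to the MidHip landmark.
* ``PANOPTIC15`` — the 15-anatomical-landmark convention of multiview
  reference-standard 2D skeletons (neck, nose, body center, and per-side
  shoulder/elbow/wrist/hip/knee/ankle).

Canonical names used by the default triplet registry::

    head, neck, pelvis,
    r_shoulder, l_shoulder, r_elbow, l_elbow, r_wrist, l_wrist,
    r_hip, l_hip, r_knee, l_knee, r_ankle, l_ankle
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import LayoutError

CANONICAL_LANDMARKS = (
    "head",
    "neck",
    "pelvis",
    "r_shoulder",
    "l_shoulder",
    "r_elbow",
    "l_elbow",
    "r_wrist",
    "l_wrist",
    "r_hip",
    "l_hip",
    "r_knee",
    "l_knee",
    "r_ankle",
    "l_ankle",
)


@dataclass(frozen=True)
class SkeletonLayout:
    """A named skeleton convention with canonical-landmark resolution.

    Parameters
    ----------
    name:
        Identifier of the convention (e.g. ``"body25"``).
    joint_names:
        Ordered landmark names of the raw skeleton; its length is the
        per-frame landmark count.
    index_of:
        Mapping from canonical landmark name to raw index.  A canonical name
        not present in the mapping is *declared absent*; downstream triplet
        resolution may substitute a documented approximation (e.g. pelvis as
        the hip midpoint) or raise a configuration error.
    """

    name: str
    joint_names: tuple[str, ...]
    index_of: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.joint_names)
        seen: set[int] = set()
        for canonical, idx in self.index_of.items():
            if not 0 <= idx < n:
                raise LayoutError(
                    f"layout {self.name!r}: canonical landmark {canonical!r} "
                    f"maps to index {idx}, outside 0..{n - 1}"
                )
            if idx in seen:
                raise LayoutError(
                    f"layout {self.name!r}: index {idx} mapped twice"
                )
            seen.add(idx)

    @property
    def n_landmarks(self) -> int:
        return len(self.joint_names)

    def resolve(self, canonical: str) -> int | None:
        """Index of a canonical landmark, or ``None`` if declared absent."""
        return self.index_of.get(canonical)


_BODY25_NAMES = (
    "Nose", "Neck",
    "RShoulder", "RElbow", "RWrist",
    "LShoulder", "LElbow", "LWrist",
    "MidHip",
    "RHip", "RKnee", "RAnkle",
    "LHip", "LKnee", "LAnkle",
    "REye", "LEye", "REar", "LEar",
    "LBigToe", "LSmallToe", "LHeel",
    "RBigToe", "RSmallToe", "RHeel",
)

# head := nose (the 25-landmark convention carries no vertex-of-skull point);
# pelvis := MidHip.
BODY25 = SkeletonLayout(
    name="body25",
    joint_names=_BODY25_NAMES,
    index_of={
        "head": 0,
        "neck": 1,
        "r_shoulder": 2,
        "r_elbow": 3,
        "r_wrist": 4,
        "l_shoulder": 5,
        "l_elbow": 6,
        "l_wrist": 7,
        "pelvis": 8,
        "r_hip": 9,
        "r_knee": 10,
        "r_ankle": 11,
        "l_hip": 12,
        "l_knee": 13,
        "l_ankle": 14,
    },
)

_PANOPTIC15_NAMES = (
    "Neck", "Nose", "BodyCenter",
    "lShoulder", "lElbow", "lWrist", "lHip", "lKnee", "lAnkle",
    "rShoulder", "rElbow", "rWrist", "rHip", "rKnee", "rAnkle",
)

PANOPTIC15 = SkeletonLayout(
    name="panoptic15",
    joint_names=_PANOPTIC15_NAMES,
    index_of={
        "neck": 0,
        "head": 1,  # nose stands in for the head on both conventions
        "pelvis": 2,
        "l_shoulder": 3,
        "l_elbow": 4,
        "l_wrist": 5,
        "l_hip": 6,
        "l_knee": 7,
        "l_ankle": 8,
        "r_shoulder": 9,
        "r_elbow": 10,
        "r_wrist": 11,
        "r_hip": 12,
        "r_knee": 13,
        "r_ankle": 14,
    },
)

LAYOUTS: dict[str, SkeletonLayout] = {
    "body25": BODY25,
    "panoptic15": PANOPTIC15,
}
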