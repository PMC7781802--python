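"""Synthetic paired keypoint streams with known ground truth.

The generator emulates the structure of a pose-validation study: a set of
videos (default 10, ~2.5 min each at 30 fps) of a single person exercising
joints through their range of motion, observed simultaneously by a
reference-quality system (15-landmark layout, noise-free truth) and a
candidate estimator (25-landmark layout, truth degraded by Gaussian pixel
noise, landmark dropout, sparse large-displacement outliers, and an optional
integer temporal lag).

The skeleton is a pelvis-rooted 2D kinematic chain with fixed segment
lengths.  Nine joint angles (both shoulders, elbows, hips, knees, and the
neck) are *driven* directly by sum-of-sinusoid trajectories, so their true
angle series are known in closed form; the pelvis angle (left knee – pelvis
– right knee) is a derived consequence of the leg geometry and its truth is
computed analytically from the constructed keypoints.

Everything is deterministic given ``MotionSpec.seed``; per-video randomness
(trajectory phases, noise draws) comes from seed sequences spawned from it,
and the manifest records every drawn parameter.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .angles import AngleSeries, interior_angles
from .errors import ValidationError
from .io import KeypointStream
from .layouts import BODY25, PANOPTIC15

DRIVEN_JOINTS = (
    "right_shoulder",
    "left_shoulder",
    "right_elbow",
    "left_elbow",
    "right_hip",
    "left_hip",
    "right_knee",
    "left_knee",
    "neck",
)

# rotation sense per driven joint: mirrored left/right so the figure is
# roughly symmetric; the interior angle itself is sign-independent
_ROT_SIGN = {
    "right_shoulder": -1.0,
    "left_shoulder": 1.0,
    "right_elbow": -1.0,
    "left_elbow": 1.0,
    "right_hip": -1.0,
    "left_hip": 1.0,
    "right_knee": -1.0,
    "left_knee": 1.0,
    "neck": 1.0,
}

DEFAULT_LIMB_LENGTHS = {
    "torso": 150.0,  # pelvis -> neck, px
    "head": 60.0,  # neck -> nose
    "shoulder_halfwidth": 50.0,
    "hip_halfwidth": 35.0,
    "upper_arm": 80.0,
    "forearm": 75.0,
    "thigh": 110.0,
    "shank": 100.0,
}


@dataclass(frozen=True)
class JointMotion:
    """Sum-of-sinusoids angular trajectory for one driven joint (degrees)."""

    mean: float
    amplitudes: tuple[float, ...]
    frequencies: tuple[float, ...]  # Hz
    phases: tuple[float, ...] | None = None  # radians; None -> drawn per video

    def total_amplitude(self) -> float:
        return float(sum(abs(a) for a in self.amplitudes))


def default_movement() -> dict[str, JointMotion]:
    """Range-of-motion trajectories keeping every angle inside (0, 180).

    Each joint carries a dominant tone plus two smaller incommensurate
    harmonics: natural movement is broadband, and a pure tone would leave
    the series' autocorrelation so flat that frame-level lag diagnosis is
    ill-posed.
    """
    return {
        "right_shoulder": JointMotion(60.0, (32.0, 8.0, 4.0), (0.20, 0.43, 0.91)),
        "left_shoulder": JointMotion(60.0, (32.0, 8.0, 4.0), (0.23, 0.47, 0.97)),
        "right_elbow": JointMotion(100.0, (40.0, 10.0, 5.0), (0.25, 0.52, 1.10)),
        "left_elbow": JointMotion(100.0, (40.0, 10.0, 5.0), (0.27, 0.56, 1.19)),
        "right_hip": JointMotion(150.0, (16.0, 5.0, 3.0), (0.15, 0.33, 0.71)),
        "left_hip": JointMotion(150.0, (16.0, 5.0, 3.0), (0.17, 0.37, 0.79)),
        "right_knee": JointMotion(140.0, (24.0, 8.0, 4.0), (0.18, 0.41, 0.87)),
        "left_knee": JointMotion(140.0, (24.0, 8.0, 4.0), (0.21, 0.44, 0.93)),
        "neck": JointMotion(160.0, (12.0, 4.0, 2.0), (0.10, 0.29, 0.63)),
    }


@dataclass
class MotionSpec:
    """Study-structure parameters of the synthetic dataset."""

    n_videos: int = 10
    duration_s: float = 145.0  # per-video duration (~2 min 25 s)
    fps_reference: float = 30.0
    fps_candidate: float = 30.0
    movement: dict[str, JointMotion] = field(default_factory=default_movement)
    limb_lengths: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LIMB_LENGTHS)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_videos < 1 or self.duration_s <= 0:
            raise ValidationError("n_videos >= 1 and duration_s > 0 required")
        if self.fps_reference <= 0 or self.fps_candidate <= 0:
            raise ValidationError("frame rates must be positive")
        nyquist = min(self.fps_reference, self.fps_candidate) / 2.0
        for joint, m in self.movement.items():
            if len(m.amplitudes) != len(m.frequencies):
                raise ValidationError(f"{joint}: amplitude/frequency length mismatch")
            if any(f >= nyquist for f in m.frequencies):
                raise ValidationError(f"{joint}: frequency at or above Nyquist")
            amp = m.total_amplitude()
            if not (0 < m.mean - amp and m.mean + amp < 180):
                raise ValidationError(
                    f"{joint}: trajectory {m.mean}±{amp} leaves (0, 180)"
                )


@dataclass
class NoiseSpec:
    """Degradation model applied to the candidate stream.

    ``injected_bias`` is an angle-level offset in degrees (scalar for all
    joints or a per-joint mapping) applied to the candidate angle series
    after extraction — keypoint-level corruption cannot realise an exact
    angular offset.  All other fields act at keypoint level.
    """

    keypoint_noise_sd: float = 4.0  # px
    dropout_prob: float = 0.02
    outlier_prob: float = 0.002
    outlier_shift: float = 60.0  # px
    injected_lag: int = 0  # frames; positive -> candidate trails reference
    injected_bias: float | dict[str, float] = 0.0

    def validate(self) -> None:
        if not 0 <= self.dropout_prob <= 1 or not 0 <= self.outlier_prob <= 1:
            raise ValidationError("probabilities must lie in [0, 1]")
        if self.keypoint_noise_sd < 0 or self.outlier_shift < 0:
            raise ValidationError("noise magnitudes must be non-negative")

    def bias_for(self, joint_name: str) -> float:
        if isinstance(self.injected_bias, dict):
            return float(self.injected_bias.get(joint_name, 0.0))
        return float(self.injected_bias)


def _rotate(u: np.ndarray, theta_deg: np.ndarray) -> np.ndarray:
    """Rotate 2D vectors u (n,2) by per-frame angles (degrees)."""
    th = np.radians(theta_deg)
    cos, sin = np.cos(th), np.sin(th)
    x, y = u[..., 0], u[..., 1]
    return np.stack([cos * x - sin * y, sin * x + cos * y], axis=-1)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def _video_phases(
    spec: MotionSpec, video_index: int
) -> dict[str, tuple[float, ...]]:
    """Per-video trajectory phases: as specified, or drawn deterministically."""
    rng = np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), int(video_index)])
    )
    phases = {}
    for joint in DRIVEN_JOINTS:
        m = spec.movement[joint]
        if m.phases is not None:
            if len(m.phases) != len(m.frequencies):
                raise ValidationError(f"{joint}: phase/frequency length mismatch")
            phases[joint] = tuple(m.phases)
        else:
            phases[joint] = tuple(
                rng.uniform(0.0, 2 * np.pi, size=len(m.frequencies))
            )
    return phases


def _trajectory(m: JointMotion, phases: tuple[float, ...], t: np.ndarray) -> np.ndarray:
    theta = np.full(t.shape, m.mean)
    for amp, f, ph in zip(m.amplitudes, m.frequencies, phases):
        theta = theta + amp * np.sin(2 * np.pi * f * t + ph)
    return theta


def _build_keypoints(
    spec: MotionSpec, theta: dict[str, np.ndarray], t: np.ndarray
) -> dict[str, np.ndarray]:
    """Forward kinematics: canonical landmark positions, each (n, 2)."""
    L = spec.limb_lengths
    n = t.size
    # fixed root: interior angles are translation-invariant, so a moving
    # root would add nothing the angle analysis can see
    pelvis = np.stack([np.full(n, 960.0), np.full(n, 700.0)], axis=-1)
    neck = pelvis + np.array([0.0, -L["torso"]])
    down = _unit(pelvis - neck)
    head = neck + L["head"] * _rotate(down, _ROT_SIGN["neck"] * theta["neck"])

    pts = {"pelvis": pelvis, "neck": neck, "head": head}
    for side, s in (("r", "right"), ("l", "left")):
        sx = -1.0 if side == "r" else 1.0
        sho = neck + np.array([sx * L["shoulder_halfwidth"], 0.0])
        hip = pelvis + np.array([sx * L["hip_halfwidth"], 0.0])
        th_s = theta[f"{s}_shoulder"]
        th_e = theta[f"{s}_elbow"]
        th_h = theta[f"{s}_hip"]
        th_k = theta[f"{s}_knee"]
        elb = sho + L["upper_arm"] * _rotate(
            _unit(hip - sho), _ROT_SIGN[f"{s}_shoulder"] * th_s
        )
        wri = elb + L["forearm"] * _rotate(
            _unit(sho - elb), _ROT_SIGN[f"{s}_elbow"] * th_e
        )
        kne = hip + L["thigh"] * _rotate(
            _unit(sho - hip), _ROT_SIGN[f"{s}_hip"] * th_h
        )
        ank = kne + L["shank"] * _rotate(
            _unit(hip - kne), _ROT_SIGN[f"{s}_knee"] * th_k
        )
        pts[f"{side}_shoulder"] = sho
        pts[f"{side}_hip"] = hip
        pts[f"{side}_elbow"] = elb
        pts[f"{side}_wrist"] = wri
        pts[f"{side}_knee"] = kne
        pts[f"{side}_ankle"] = ank
    return pts


def _assemble_stream(
    pts: dict[str, np.ndarray],
    layout,
    video_id: str,
    fps: float,
) -> KeypointStream:
    n = next(iter(pts.values())).shape[0]
    coords = np.zeros((n, layout.n_landmarks, 2))
    for canonical, idx in layout.index_of.items():
        coords[:, idx, :] = pts[canonical]
    if layout is BODY25:
        # decorative landmarks unused by any triplet, placed deterministically
        head, ankr, ankl = pts["head"], pts["r_ankle"], pts["l_ankle"]
        coords[:, 15] = head + np.array([-8.0, -5.0])  # REye
        coords[:, 16] = head + np.array([8.0, -5.0])  # LEye
        coords[:, 17] = head + np.array([-16.0, 0.0])  # REar
        coords[:, 18] = head + np.array([16.0, 0.0])  # LEar
        coords[:, 19] = ankl + np.array([4.0, 12.0])  # LBigToe
        coords[:, 20] = ankl + np.array([10.0, 12.0])  # LSmallToe
        coords[:, 21] = ankl + np.array([0.0, 6.0])  # LHeel
        coords[:, 22] = ankr + np.array([-4.0, 12.0])  # RBigToe
        coords[:, 23] = ankr + np.array([-10.0, 12.0])  # RSmallToe
        coords[:, 24] = ankr + np.array([0.0, 6.0])  # RHeel
    return KeypointStream(
        video_id=video_id,
        fps=fps,
        layout=layout,
        frame_index=np.arange(n),
        coords=coords,
        missing=np.zeros((n, layout.n_landmarks), dtype=bool),
        confidence=np.ones((n, layout.n_landmarks)),
    )


def generate_truth_stream(
    spec: MotionSpec,
    video_index: int,
    *,
    fps: float | None = None,
    layout=PANOPTIC15,
) -> tuple[KeypointStream, dict[str, AngleSeries]]:
    """Noise-free kinematic-chain stream plus its true angle series.

    The nine driven joints follow their specified trajectories exactly; the
    pelvis angle is derived from the leg geometry.  Deterministic given
    ``spec.seed`` and ``video_index``.
    """
    spec.validate()
    fps = spec.fps_reference if fps is None else fps
    n = int(round(spec.duration_s * fps))
    t = np.arange(n) / fps
    phases = _video_phases(spec, video_index)
    theta = {
        j: _trajectory(spec.movement[j], phases[j], t) for j in DRIVEN_JOINTS
    }
    pts = _build_keypoints(spec, theta, t)
    video_id = f"synthetic_{video_index:02d}"
    stream = _assemble_stream(pts, layout, video_id, fps)

    truth: dict[str, AngleSeries] = {}
    frame_index = np.arange(n)
    no_missing = np.zeros(n, dtype=bool)
    for j in DRIVEN_JOINTS:
        truth[j] = AngleSeries(
            video_id, j, fps, frame_index.copy(), theta[j].copy(), no_missing.copy()
        )
    pelvis_angle = interior_angles(pts["l_knee"], pts["pelvis"], pts["r_knee"])
    truth["pelvis"] = AngleSeries(
        video_id, "pelvis", fps, frame_index.copy(), pelvis_angle, no_missing.copy()
    )
    return stream, truth


def corrupt_stream(
    truth: KeypointStream,
    noise: NoiseSpec,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> KeypointStream:
    """Degrade a truth stream into a candidate observation.

    Applies, in order: an integer temporal lag (frame t shows truth frame
    t − lag, clamped at the start), i.i.d. Gaussian pixel noise, sparse
    large-displacement outliers, and landmark dropout (flagged missing with
    the (0, 0) loss sentinel).
    """
    noise.validate()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n, nl, _ = truth.coords.shape
    src = np.clip(np.arange(n) - int(noise.injected_lag), 0, n - 1)
    coords = truth.coords[src].copy()
    missing = truth.missing[src].copy()

    if noise.keypoint_noise_sd > 0:
        coords += rng.normal(0.0, noise.keypoint_noise_sd, size=coords.shape)
    if noise.outlier_prob > 0:
        hit = rng.random((n, nl)) < noise.outlier_prob
        angles = rng.uniform(0, 2 * np.pi, size=(n, nl))
        shift = noise.outlier_shift * np.stack(
            [np.cos(angles), np.sin(angles)], axis=-1
        )
        coords[hit] += shift[hit]
    if noise.dropout_prob > 0:
        drop = rng.random((n, nl)) < noise.dropout_prob
        missing = missing | drop
    coords[missing] = 0.0  # loss sentinel

    conf = np.ones((n, nl))
    conf[missing] = 0.0
    return KeypointStream(
        video_id=truth.video_id,
        fps=truth.fps,
        layout=truth.layout,
        frame_index=np.asarray(truth.frame_index).copy(),
        coords=coords,
        missing=missing,
        confidence=conf,
    )


def apply_angle_bias(series: AngleSeries, bias_deg: float) -> AngleSeries:
    """Shift an angle series by a constant offset (degrees)."""
    return series.copy_with(series.values + bias_deg, series.missing.copy())


@dataclass
class PairedDataset:
    """Reference and candidate streams plus the generation manifest."""

    reference: list[KeypointStream]
    candidate: list[KeypointStream]
    truth_angles: list[dict[str, AngleSeries]]  # per video, at reference fps
    manifest: dict


def generate_paired_dataset(
    motion: MotionSpec, noise: NoiseSpec
) -> PairedDataset:
    """Generate the full paired study: reference (15-landmark, noise-free
    truth) and candidate (25-landmark, corrupted truth) streams per video.

    The manifest records every spec field and the phases drawn per video, so
    ground truth is fully reconstructable for recovery tests.
    """
    motion.validate()
    noise.validate()
    reference, candidate, truth_angles, phases_log = [], [], [], []
    for v in range(motion.n_videos):
        ref, truth = generate_truth_stream(
            motion, v, fps=motion.fps_reference, layout=PANOPTIC15
        )
        cand_truth, _ = generate_truth_stream(
            motion, v, fps=motion.fps_candidate, layout=BODY25
        )
        corrupt_seed = np.random.SeedSequence([int(motion.seed), int(v), 1])
        cand = corrupt_stream(cand_truth, noise, corrupt_seed)
        reference.append(ref)
        candidate.append(cand)
        truth_angles.append(truth)
        phases_log.append(
            {j: list(p) for j, p in _video_phases(motion, v).items()}
        )
    manifest = {
        "motion": {
            **asdict(motion),
            "movement": {
                j: asdict(m) for j, m in motion.movement.items()
            },
        },
        "noise": asdict(noise),
        "phases_per_video": phases_log,
    }
    return PairedDataset(
        reference=reference,
        candidate=candidate,
        truth_angles=truth_angles,
        manifest=manifest,
    )
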