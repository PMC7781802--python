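"""Interior-angle geometry and per-joint series extraction."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

import poseagree as pg
from poseagree.angles import DEFAULT_TRIPLETS, JOINT_NAMES
from poseagree.errors import ConfigurationError, DegenerateGeometryError
from poseagree.layouts import BODY25


@pytest.mark.parametrize(
    "a, b, c, expected",
    [
        ((0, 1), (0, 0), (1, 0), 90.0),  # perpendicular rays
        ((-1, 0), (0, 0), (2, 0), 180.0),  # collinear, opposite directions
        ((1, 0), (0, 0), (2, 0), 0.0),  # collinear, same direction
        ((1, 0), (0, 0), (1, np.sqrt(3)), 60.0),  # 30-60-90 construction
    ],
)
def test_interior_angle_known_geometry(a, b, c, expected):
    assert pg.interior_angle(a, b, c) == pytest.approx(expected, abs=1e-12)


def test_interior_angle_degenerate_ray_raises():
    with pytest.raises(DegenerateGeometryError):
        pg.interior_angle((0, 0), (0, 0), (1, 0))
    with pytest.raises(DegenerateGeometryError):
        pg.interior_angle((1, 0), (0, 0), (0, 0))


def test_interior_angle_matches_arccos_oracle():
    """atan2 implementation agrees with the arccos-of-dot-product formula."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        a, b, c = rng.normal(0, 10, size=(3, 2))
        u, v = a - b, c - b
        cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        oracle = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
        assert pg.interior_angle(a, b, c) == pytest.approx(oracle, abs=1e-9)


_coord = st.floats(-1e3, 1e3, allow_nan=False, width=64)


@settings(max_examples=200, derandomize=True)
@given(
    ax=_coord, ay=_coord, bx=_coord, by=_coord, cx=_coord, cy=_coord,
    scale=st.floats(1e-3, 1e3),
)
def test_interior_angle_bounded_and_scale_invariant(
    ax, ay, bx, by, cx, cy, scale
):
    """For any non-degenerate triplet the angle lies in [0, 180] and is
    unchanged by uniform scaling about the vertex."""
    a, b, c = np.array([ax, ay]), np.array([bx, by]), np.array([cx, cy])
    assume(np.linalg.norm(a - b) > 1e-3 and np.linalg.norm(c - b) > 1e-3)
    ang = pg.interior_angle(a, b, c)
    assert 0.0 <= ang <= 180.0
    # near 0/180 the angle is ill-conditioned in the inputs; invariance is
    # asserted away from the fold where rounding cannot be amplified
    assume(0.001 < ang < 179.999)
    scaled = pg.interior_angle(b + scale * (a - b), b, b + scale * (c - b))
    assert scaled == pytest.approx(ang, abs=1e-6)


def test_interior_angles_vectorised_matches_scalar():
    rng = np.random.default_rng(1)
    a, b, c = rng.normal(0, 5, size=(3, 50, 2))
    vec = pg.interior_angles(a, b, c)
    for i in range(50):
        assert vec[i] == pytest.approx(pg.interior_angle(a[i], b[i], c[i]))


def _random_stream(rng, n_frames=10):
    coords = rng.uniform(50, 1000, size=(n_frames, 25, 2))
    return pg.KeypointStream(
        video_id="rand",
        fps=30.0,
        layout=BODY25,
        frame_index=np.arange(n_frames),
        coords=coords,
        missing=np.zeros((n_frames, 25), dtype=bool),
    )


def test_similarity_invariance_of_all_joint_angles():
    """Translation, rotation and uniform scaling leave every angle unchanged."""
    rng = np.random.default_rng(2024)
    stream = _random_stream(rng, n_frames=100)
    base = {s.joint_name: s.values for s in pg.extract_angle_series(stream)}
    for _ in range(5):
        theta = rng.uniform(0, 2 * np.pi)
        scale = rng.uniform(0.1, 10)
        shift = rng.uniform(-500, 500, size=2)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        coords = scale * stream.coords @ rot.T + shift
        t_stream = pg.KeypointStream(
            video_id="t",
            fps=30.0,
            layout=BODY25,
            frame_index=stream.frame_index,
            coords=coords,
            missing=stream.missing,
        )
        for s in pg.extract_angle_series(t_stream):
            np.testing.assert_allclose(
                s.values, base[s.joint_name], atol=1e-9
            )


def test_mirror_symmetry_swaps_left_right_series():
    """An anatomical mirror (reflect x, relabel left/right landmarks)
    exchanges the left and right joint series exactly."""
    rng = np.random.default_rng(7)
    stream = _random_stream(rng, n_frames=20)
    mirrored = stream.coords.copy()
    mirrored[..., 0] *= -1.0
    for canon in ("shoulder", "elbow", "wrist", "hip", "knee", "ankle"):
        r, l = BODY25.resolve(f"r_{canon}"), BODY25.resolve(f"l_{canon}")
        mirrored[:, [r, l]] = mirrored[:, [l, r]]
    m_stream = pg.KeypointStream(
        video_id="m",
        fps=30.0,
        layout=BODY25,
        frame_index=stream.frame_index,
        coords=mirrored,
        missing=stream.missing,
    )
    base = {s.joint_name: s.values for s in pg.extract_angle_series(stream)}
    mirr = {s.joint_name: s.values for s in pg.extract_angle_series(m_stream)}
    for j in JOINT_NAMES:
        swapped = (
            j.replace("right", "LEFT").replace("left", "right").replace("LEFT", "left")
        )
        np.testing.assert_array_equal(mirr[j], base[swapped])


def test_missing_landmark_propagates_to_one_joint_only():
    rng = np.random.default_rng(3)
    stream = _random_stream(rng, n_frames=10)
    stream.missing[5, BODY25.resolve("r_wrist")] = True
    series = {s.joint_name: s for s in pg.extract_angle_series(stream)}
    assert series["right_elbow"].missing[5]
    assert np.isnan(series["right_elbow"].values[5])
    for j in JOINT_NAMES:
        if j != "right_elbow":
            assert not series[j].missing.any()


def test_rigid_arm_rotation_sweeps_elbow_angle():
    """A forearm rotating from straight to perpendicular sweeps 180 -> 90."""
    n = 50
    sweep = np.radians(np.linspace(0, 90, n))
    coords = np.tile(np.arange(50, 50 + 25 * 2, 2.0).reshape(1, 25, 1), (n, 1, 2))
    sho, elb, wri = (
        BODY25.resolve("r_shoulder"),
        BODY25.resolve("r_elbow"),
        BODY25.resolve("r_wrist"),
    )
    coords[:, sho] = (0.0, 0.0)
    coords[:, elb] = (100.0, 0.0)
    # wrist starts collinear beyond the elbow, rotates about it by the sweep
    coords[:, wri, 0] = 100.0 + 80.0 * np.cos(sweep)
    coords[:, wri, 1] = 80.0 * np.sin(sweep)
    stream = pg.KeypointStream(
        video_id="arm",
        fps=30.0,
        layout=BODY25,
        frame_index=np.arange(n),
        coords=coords,
        missing=np.zeros((n, 25), dtype=bool),
    )
    defs = tuple(d for d in DEFAULT_TRIPLETS if d.joint_name == "right_elbow")
    (series,) = pg.extract_angle_series(stream, defs)
    assert series.values[0] == pytest.approx(180.0, abs=1e-9)
    assert series.values[-1] == pytest.approx(90.0, abs=1e-9)
    assert np.all(np.diff(series.values) < 0)


def test_panoptic_stream_yields_all_ten_series(small_truth):
    _, stream, _ = small_truth
    assert stream.layout.name == "panoptic15"
    series = pg.extract_angle_series(stream)
    assert sorted(s.joint_name for s in series) == sorted(JOINT_NAMES)
    neck = next(s for s in series if s.joint_name == "neck")
    assert not neck.missing.any()


def test_unresolvable_landmark_raises_configuration_error():
    layout = pg.SkeletonLayout(
        name="torso_only",
        joint_names=("a", "b", "c"),
        index_of={"neck": 0, "pelvis": 1, "head": 2},
    )
    stream = pg.KeypointStream(
        video_id="t",
        fps=30.0,
        layout=layout,
        frame_index=np.arange(3),
        coords=np.ones((3, 3, 2)),
        missing=np.zeros((3, 3), dtype=bool),
    )
    with pytest.raises(ConfigurationError, match="right_shoulder"):
        pg.extract_angle_series(stream)


def test_pelvis_falls_back_to_hip_midpoint():
    """Layouts without an explicit pelvis use the mid-hip approximation."""
    names = ("RS", "RH", "RK", "LH", "LK")
    layout = pg.SkeletonLayout(
        name="no_pelvis",
        joint_names=names,
        index_of={"r_shoulder": 0, "r_hip": 1, "r_knee": 2, "l_hip": 3, "l_knee": 4},
    )
    rng = np.random.default_rng(5)
    coords = rng.uniform(10, 100, size=(4, 5, 2))
    stream = pg.KeypointStream(
        video_id="t",
        fps=30.0,
        layout=layout,
        frame_index=np.arange(4),
        coords=coords,
        missing=np.zeros((4, 5), dtype=bool),
    )
    defs = tuple(d for d in DEFAULT_TRIPLETS if d.joint_name == "pelvis")
    (series,) = pg.extract_angle_series(stream, defs)
    mid = 0.5 * (coords[:, 1] + coords[:, 3])
    expected = pg.interior_angles(coords[:, 4], mid, coords[:, 2])
    np.testing.assert_allclose(series.values, expected)


def test_triplet_registry_roundtrip(tmp_path):
    path = tmp_path / "registry.json"
    pg.angles.save_triplet_registry(DEFAULT_TRIPLETS, path)
    loaded = pg.angles.load_triplet_registry(path)
    assert loaded == DEFAULT_TRIPLETS
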