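import numpy as np
import pytest

import poseagree as pg


def make_angle_series(
    values,
    missing=None,
    video_id="v0",
    joint_name="right_elbow",
    fps=30.0,
    frame_index=None,
):
    values = np.asarray(values, dtype=float)
    if missing is None:
        missing = ~np.isfinite(values)
    else:
        missing = np.asarray(missing, dtype=bool)
    if frame_index is None:
        frame_index = np.arange(values.size)
    vals = np.where(missing, np.nan, values)
    return pg.AngleSeries(
        video_id=video_id,
        joint_name=joint_name,
        fps=fps,
        frame_index=np.asarray(frame_index),
        values=vals,
        missing=missing,
    )


def make_pairs(candidate, reference, joint_name="right_elbow", video_id="v0", fps=30.0):
    return pg.PairedAngleSeries(
        video_id=video_id,
        joint_name=joint_name,
        candidate=np.asarray(candidate, dtype=float),
        reference=np.asarray(reference, dtype=float),
        fps=fps,
    )


@pytest.fixture(scope="session")
def small_truth():
    """One noise-free 20-second video with fixed phases on the right elbow."""
    movement = pg.synthetic.default_movement()
    movement["right_elbow"] = pg.JointMotion(100.0, (30.0,), (0.2,), (0.0,))
    spec = pg.MotionSpec(n_videos=1, duration_s=20.0, movement=movement, seed=7)
    stream, truth = pg.generate_truth_stream(spec, 0)
    return spec, stream, truth


@pytest.fixture(scope="session")
def small_study_bundle():
    """A small default-noise synthetic study run end to end (shared)."""
    motion = pg.MotionSpec(n_videos=2, duration_s=40.0, seed=3)
    return pg.run_synthetic_study(motion, pg.NoiseSpec())
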