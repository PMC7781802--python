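"""Extract joint angles from a keypoint stream and handle missing landmarks.

Builds a tiny 25-landmark stream by hand (an arm flexing at the elbow with
one lost wrist detection), extracts the right-elbow angle series, and shows
how missingness propagates and is imputed.  The printed angles are interior
angles in degrees: 180 is a fully extended joint.
"""

import numpy as np

import poseagree as pg
from poseagree.angles import DEFAULT_TRIPLETS
from poseagree.layouts import BODY25

n = 10
coords = np.tile(np.linspace(100, 148, 25)[None, :, None], (n, 1, 2))
sho, elb, wri = (BODY25.resolve(k) for k in ("r_shoulder", "r_elbow", "r_wrist"))
flex = np.radians(np.linspace(0, 60, n))  # elbow flexes 0 -> 60 degrees
coords[:, sho] = (0.0, 0.0)
coords[:, elb] = (100.0, 0.0)
coords[:, wri, 0] = 100.0 + 80.0 * np.cos(flex)
coords[:, wri, 1] = 80.0 * np.sin(flex)

missing = np.zeros((n, 25), dtype=bool)
missing[4, wri] = True  # the estimator lost the wrist at frame 4

stream = pg.KeypointStream(
    video_id="demo", fps=30.0, layout=BODY25,
    frame_index=np.arange(n), coords=coords, missing=missing,
)

defs = tuple(d for d in DEFAULT_TRIPLETS if d.joint_name == "right_elbow")
(series,) = pg.extract_angle_series(stream, defs)
print("extracted right-elbow angles (deg, nan = landmark lost):")
print(np.round(series.values, 2))

imputed = pg.impute_moving_average(series, window=5)
print("\nafter moving-average imputation:")
print(np.round(imputed.values, 2))
print("\nframe 4 was rebuilt from its neighbours; observed frames are untouched.")
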