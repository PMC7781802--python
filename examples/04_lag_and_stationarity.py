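"""Diagnose a temporal shift between two measurement systems.

Injects a 3-frame delay into the candidate stream and shows that the
cross-correlation function peaks at lag +3 (positive = candidate trails the
reference), while the ADF test confirms the series are stationary — the
prerequisite for reading the CCF at all.
"""

import poseagree as pg

motion = pg.MotionSpec(n_videos=1, duration_s=120.0, seed=3)
noise = pg.NoiseSpec(keypoint_noise_sd=2.0, dropout_prob=0.0, outlier_prob=0.0,
                     injected_lag=3)

ref_stream, _ = pg.generate_truth_stream(motion, 0)
cand_truth, _ = pg.generate_truth_stream(motion, 0, layout=pg.BODY25)
cand_stream = pg.corrupt_stream(cand_truth, noise, seed=3)

cand = {s.joint_name: s for s in pg.extract_angle_series(cand_stream)}
ref = {s.joint_name: s for s in pg.extract_angle_series(ref_stream)}

for joint in ("right_elbow", "left_knee", "neck"):
    pairs = pg.pair_series(cand[joint], ref[joint])
    ccf = pg.cross_correlation(pairs, max_lag=10)
    adf = pg.adf_test(pairs.differences, joint_name=joint)
    print(
        f"{joint:12s} best lag {ccf.best_lag:+d} "
        f"(corr {ccf.best_corr:.3f}, band ±{ccf.conf_bound:.3f}); "
        f"differences stationary: {adf.stationary} (ADF p = {adf.p_value:.2e})"
    )

print("\nA peak at +3 on every joint exposes the injected 3-frame delay.")
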