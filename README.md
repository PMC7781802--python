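# poseagree

Agreement analysis between two 2D human-pose keypoint streams via joint
angles.

Markerless 2D pose estimation promises clinical movement assessment from a
single camera, but before a clinician can trust the joint angles such an
estimator reports, it has to be validated against a reference-quality
system.  `poseagree` implements that validation end to end: it reads
candidate and reference keypoint time series (OpenPose Body25-style JSON,
15-landmark multiview pose JSON, or a generic long CSV), computes interior
joint angles from landmark triplets, prepares the two series (Bartlett
smoothing, moving-average imputation, cross-rate frame alignment), and
reports a full method-comparison panel per joint plus temporal diagnostics.

## The statistics

For each of ten joints (both shoulders, elbows, hips, knees, the neck, and
the pelvis) the angle at the triplet vertex is the unsigned interior angle
in degrees, and all statistics act on the frame-paired differences
d_t = candidate_t − reference_t (n pairs per joint):

- **bias** = mean(d), with SD, SE = SD/√n and the 95% CI bias ± 1.96·SE;
- **MAE** = mean|d|, **MAD** = median|d − median(d)|,
  **RMSE** = √(mean d²) (which satisfies RMSE² = bias² + SD²·(n−1)/n),
  **sMAPE** = 100·mean( |c−r| / ((|c|+|r|)/2) ), bounded at 200 %;
- **ICC(A,2)**: the two-way ANOVA intraclass correlation for absolute
  agreement of k = 2 averaged measurements (McGraw & Wong),
  ICC = (MSR − MSE)/(MSR + (MSC − MSE)/n), with the exact F-based 95% CI and
  the Fleiss bands (< 0.40 poor, 0.40–0.75 fair to good, ≥ 0.75 excellent);
- per-video ICC, box-plot summaries with 1.5 × IQR whiskers;
- the **augmented Dickey-Fuller** stationarity test and the normalised
  **cross-correlation function** over integer lags — a peak away from lag 0
  diagnoses a temporal shift between the systems (positive lag = candidate
  trails the reference).

A synthetic-study module generates paired streams from a pelvis-rooted
kinematic chain with known sum-of-sinusoid joint trajectories, degraded by
Gaussian pixel noise, landmark dropout, sparse outliers, an optional integer
lag, and an optional angle-level bias — so every stage of the pipeline is
testable against ground truth without any external data.

## Worked example

```python
import poseagree as pg
from poseagree.pipeline import render_table1, render_table2

motion = pg.MotionSpec(n_videos=2, duration_s=40.0, seed=42)
bundle = pg.run_synthetic_study(motion, pg.NoiseSpec())
print(render_table1(bundle.reports).to_string(index=False))
```

prints (excerpt):

```
         joint              key_points_used        difference_mean_sd_ci  mae  mad rmse smape                 icc_ci   se
right_shoulder   r_hip, r_shoulder, r_elbow   0.02 (1.64); -0.05 to 0.08 1.25 0.97 1.64  2.40 0.999 (0.999 to 0.999) 0.03
          neck           pelvis, neck, head -0.94 (2.87); -1.06 to -0.83 2.25 1.74 3.02  1.42 0.972 (0.962 to 0.978) 0.06
        pelvis       l_knee, pelvis, r_knee -0.06 (1.33); -0.12 to -0.01 1.03 0.83 1.33  1.38 0.998 (0.998 to 0.998) 0.03
```

Each row reads: the candidate's right-shoulder angle is essentially
unbiased (0.02°, CI spanning zero), typically within 1.25° of the reference
(MAE), and the two systems agree excellently (ICC 0.999).  The neck — whose
head landmark is approximated by the nose — is the weakest joint, exactly
the pattern a real validation shows.  `render_table2(bundle.ccf)` lists the
lag of maximum cross-correlation per joint; 0 everywhere means no temporal
shift.

More narrative scripts live in `examples/` (angle extraction and
imputation, the agreement panel on raw arrays, lag injection and recovery).

There is also a thin CLI:

```sh
poseagree simulate --out study/                      # synthetic paired study
poseagree validate --candidate cand.json --reference ref.json --out report/
```

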