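# Methods

## Problem and model

`poseagree` quantifies how well a candidate 2D pose estimator reproduces
the joint angles of a reference-quality system on the same recordings.  The
unit of analysis is the per-frame, per-joint angle difference
d_t = candidate_t − reference_t.  Angles are unsigned interior angles at the
vertex of a landmark triplet (A, B, C): the angle between rays B→A and B→C,
computed as atan2(|u×v|, u·v) — numerically stable near 0° and 180°, where
the arccos form loses precision.  Interior angles are invariant under
translation, rotation and uniform scaling, so camera framing and resolution
never enter the analysis; they are *not* invariant to non-uniform scaling
or projective distortion, which is a genuine limitation of any 2D angle
comparison.

Ten joints ship in the default registry: each shoulder (hip–shoulder–elbow),
elbow (shoulder–elbow–wrist), hip (shoulder–hip–knee), knee
(hip–knee–ankle), the neck (pelvis–neck–head) and the pelvis
(left knee–pelvis–right knee).  The 25-landmark layout has no head vertex,
so `head` resolves to the nose on both layouts; layouts without an explicit
pelvis use the hip midpoint.  These approximations are applied identically
to both streams, so they cancel in the differences up to estimator error.

## Preparation pipeline

Order: smooth → impute → pair.

**Bartlett smoothing** (default window 11): convolution with the normalised
triangular taper, reflect-padded so output length equals input length.  The
weights sum to 1 (constants pass through) and the filter is symmetric
(linear trends are preserved away from the edges).  Missing frames are
linearly bridged for the convolution only and stay missing on output.  By
default **both** streams are filtered: comparing a filtered candidate
against an unfiltered reference would attribute the filter's passband
attenuation to the candidate as spurious disagreement, and symmetric
treatment makes the noise-free limit exact (a clean candidate agrees with
its reference perfectly).  `smooth_target="candidate"` restores the
asymmetric arrangement for pipelines whose candidate estimator embeds the
filter.

**Imputation** (default window 5, centred): each missing value becomes the
mean of the observed values in its window; a missing run longer than the
window is linearly interpolated between its valid neighbours, and
leading/trailing gaps take the nearest observed value.  Observed values are
never altered.  Window 5 is a compromise between bridging the short
dropouts a pose estimator produces and not smearing genuine movement; it is
configurable.

**Pairing**: equal-rate series pair on common frame indices; with unequal
rates the higher-rate series is linearly resampled in time onto the
lower-rate series' frame times over the overlapping range.  Linear
interpolation at 25–30 fps on movement band-limited to a few Hz carries an
error bound of max|f″|·h²/8, far below the noise floor of any estimator.
No dynamic time warping is applied: temporal misalignment is *diagnosed*
(below), not corrected.

## Agreement panel

- bias, SD (n−1 denominator), SE, and the normal-approximation 95% CI
  (multiplier 1.96; at the pair counts involved, tens of thousands, the
  Student-t correction is far below printed precision).
- MAE; RMSE (which satisfies RMSE² = bias² + SD²·(n−1)/n exactly — used as
  an internal consistency check on every report); sMAPE with the half-sum
  denominator, bounded at 200 %, 0/0 summands defined as 0.
- MAD defaults to the **median absolute deviation about the median** of the
  differences.  Validation reports are inconsistent in what they call
  "MAD"; the robust reading is the default here and the mean absolute
  deviation about the mean is available via `mad_kind="mean"`.  Neither is
  asserted to be what any particular published table used.
- ICC(A,2): two-way single-observation ANOVA on the n×2 frame-by-rater
  matrix; ICC(A,k) = (MSR − MSE)/(MSR + (MSC − MSE)/n) with k = 2.  The 95%
  CI is the McGraw & Wong exact F interval for the single-measure
  coefficient with Satterthwaite degrees of freedom, stepped up to average
  measures by the Spearman–Brown relation.  At very small n (≲ 6) the
  interval's denominators can change sign and the formula stops bracketing
  the estimate; the implementation then falls back to the uninformative
  bound (−1 or 1) rather than report an inverted interval.  Identical
  non-constant columns short-circuit to ICC = 1 exactly.  Zero
  between-subject variance raises an error: with no signal, "agreement" is
  undefined.
- Fleiss bands: poor < 0.40 ≤ fair-to-good < 0.75 ≤ excellent (boundary
  values are assigned upward).
- Box plots use linear-interpolation quantiles; whiskers sit on the most
  extreme observations within 1.5 × IQR of the quartiles, points beyond are
  outliers.  The quantile rule is stated because outlier counts depend on it.

## Temporal diagnostics

The ADF unit-root test (constant, no trend; lag order by AIC up to
⌊12·(n/100)^0.25⌋, the conventional ceiling) is applied to the candidate
series and to the differences of every (video, joint) group; rejection at
α = 0.05 is reported as stationary.  Bounded range-of-motion angle series
are stationary by construction, and this is what the test confirms on the
synthetic study.

The cross-correlation function uses mean-centred series and the
full-series n-denominator normalisation, so ccf(0) equals the Pearson
correlation of the pairs.  Convention: **positive lag means the candidate
trails the reference** (candidate_t matches reference_{t−lag}).  The
default window is min(10·log10 n, n/4).  A known property of this
(standard) estimator: the n-denominator tapers ccf(h) by roughly a factor
(n−|h|)/n, biasing the argmax toward 0 by about 1/n per frame.  For series
whose autocorrelation decays more slowly than that — very smooth,
low-frequency joints on short recordings — the detected lag can sit one
frame closer to zero than the truth.  At the default study length
(4,350 frames per video) the effect is negligible; the lag-recovery tests
state their tolerances accordingly (±1 frame on the flattest joints at
scaled-down lengths, exact elsewhere).

## Synthetic study design

The generator emulates a ten-video validation study (145 s per video at
30 fps — matching a ~24-minute corpus yielding tens of thousands of pairs
per joint) of one person moving joints through their range of motion.  The
skeleton is a pelvis-rooted 2D kinematic chain with fixed segment lengths
(torso 150 px, head 60, upper arm 80, forearm 75, thigh 110, shank 100,
shoulder/hip half-widths 50/35 — a person occupying roughly 400 px of a
1080p frame).  Nine joints are driven directly by sum-of-sinusoid
trajectories whose means and amplitudes keep every angle strictly inside
(0°, 180°); the pelvis angle is a derived consequence of the leg geometry.
Each trajectory carries a dominant tone plus two smaller incommensurate
harmonics: natural movement is broadband, and pure tones would make the
autocorrelation so flat that frame-level lag diagnosis becomes ill-posed.
Per-video phases are drawn from seed sequences spawned from the study seed;
the manifest records every drawn value, so generation is bit-reproducible
and ground truth fully reconstructable.

The candidate stream degrades the truth with i.i.d. Gaussian pixel noise
(default SD 4 px), landmark dropout (2 %, flagged with the (0, 0)/zero-
confidence loss sentinel), sparse fixed-magnitude outliers (0.2 % at
60 px — producing the heavy-tailed difference outliers real estimators
show), an optional integer frame lag, and an optional angle-level bias
applied after extraction (keypoint-level corruption cannot realise an exact
angular offset; the study runner adds it to the candidate angle series).
The 4 px default puts the pooled ICCs of the default study in roughly
0.96–0.995 with the neck lowest — the regime a credible estimator
validation reports, with the weakest joint being the one whose head
landmark is a nose approximation.

What the generator does **not** model: correlated (structured) estimator
error, confidence-dependent noise, person-against-background confusions,
projective foreshortening, multi-person scenes, or any learned estimator's
actual failure modes.  Passing tests on synthetic data therefore
demonstrate that the *analysis pipeline* is correct and sensitive — they do
not certify any particular pose estimator.

## Numerical and design choices

- Degenerate triplets (zero-length rays) yield missing frames, not errors;
  one bad frame cannot abort a video.
- Landmark loss sentinel: confidence 0 or coordinates exactly (0, 0).
- Rounding in rendered tables is decimal half-up at 2 decimals (3 for
  ICC), applied once to the unrounded value (no double rounding).
- CSV I/O writes `%.17g` and parses with round-trip float precision, so
  streams survive a write/read cycle bit-exactly.
- Problem sizes in tests: the noise-free identity runs the full default
  study; stochastic recovery checks run 20 seeds of a 2-video study (40 s
  for bias/ICC, 120 s for lag — long enough that the CCF estimator's
  small-lag bias stays below one frame on all but the flattest joints).
  Stated tolerances: per-seed recovered bias within ±0.5° of the injection
  (the Gaussian keypoint noise induces a small curvature bias of order
  σ²/L² in the extracted angles, ≲ 0.3°), seed-mean within ±0.1°; all
  pooled ICCs in [0.95, 1]; per-joint lag within ±1 frame, ≥ 8 of 10 joints
  exact.

## Known limitations

- 2D angles only; no clinical flexion/extension decomposition, no 3D
  lifting, no joint-centre regression.
- Confidence scores are carried through I/O but not used as weights.
- The ADF test is applied to raw and differenced series without
  multiple-testing correction across (video, joint) cells; it is a
  diagnostic, not an inference target.
- Lag is diagnosed, never corrected.
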