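# Methods

This note documents the models, conventions and design choices behind
`safefall`, in the order the pipeline runs.

## Coordinate conventions and landmarks

All kinematics are computed in image coordinates: origin top-left, x right,
y down, units pixels, time in frames at a stated frame rate (default
60 fps). Descent therefore means *increasing* y, and the vertical velocity
`v_y(t) = (y(t) − y(t−1)) · fps` is positive while falling. The time step of
every finite difference is one frame; multiplying by fps yields px/s (and
px/s² after a second difference).

The centre of mass is proxied by the **mid-hip** point (mean of the two hip
keypoints); the trunk vector runs mid-hip → mid-shoulder. The COCO-17
keypoint set contains neither a chin nor a sternum, so the neck-protection
distance uses the nearest stable proxies: chin := nose, sternum := shoulder
midpoint. This overestimates the absolute chin-to-chest distance but
preserves its ordering across falls, which is what the analysis consumes.
Landmarks are defined only where their source keypoints are visible, and
they are equivariant under translation and scaling of the pose (tested).

## Gap repair

Pose estimators drop keypoints during self-occlusion. `repair_gaps` masks
keypoints below a confidence floor (default 0.5, mirroring the upstream
detector threshold) and linearly interpolates invisible runs of at most
`max_gap` frames (default 10 ≈ 167 ms at 60 fps, deliberately shorter than
the impact half-window) when bounded by visible frames on both sides.
Endpoints are never extrapolated; repaired points are flagged `imputed` and
are trusted on re-runs, which makes the operation idempotent.

## Phase segmentation

The smoothed vertical velocity (centered moving average, default width
5 frames) defines a *descent episode*: the contiguous run above a motion
floor (default 50 px/s) that contains the velocity maximum, extended
outward to the nearest zero crossings. The extension matters: at ground
contact the velocity collapses back *through* the floor, and the
deceleration peak — the argmax of −a_y computed from the smoothed velocity —
sits in that tail. The impact phase is the ±200 ms window
(±`round(0.2·fps)` frames) around the peak, clipped at the sequence bounds;
pre-fall and post-fall are everything before and after. Ties in the argmax
(e.g. a constant-velocity descent with zero interior deceleration) resolve
to the earliest frame, which lands the peak at the descent onset — the
documented degenerate convention. On noiseless synthetic falls of all three
profiles the detected peak is within ±2 frames of the generator's template
truth (tested).

## The 15-metric vector

Metrics aggregate over the full segmented episode (pre-fall start through
post-fall end, i.e. the whole recorded sequence) rather than the impact
window alone: spatial ranges of a rolling fall accumulate over the entire
descent-and-roll, not 25 frames around contact. Velocities and
accelerations are computed from landmark coordinates smoothed with the same
centered moving average (raw second differences of pixel tracks at 60 fps
are noise-dominated); positional ranges and variabilities use raw
coordinates. Descent rates take the positive part of v_y, with the average
including zero frames — so a brief decisive squat in a long recording still
yields a small average, as intended. Total vertical change is defined as
max − min of mid-hip y, which makes it identical to the vertical movement
range by construction; both are reported because the category framework
treats them as a fall metric and a movement metric respectively.

The high-movement threshold τ_move defaults to 15 px/frame of mid-hip
displacement. It is intentionally high: most sequences never exceed it, so
the high-movement-frame count and movement intensity have zero medians and
respond only to genuinely violent motion.

Categories: **fall** = {avg/max descent rate, total vertical change};
**stability** = {position variability x/y, velocity variability};
**movement** = the remaining nine.

## Frame-level features

The supervised fall-quality task uses a frame-level expansion (versioned
schema, 150 columns): the 51 raw keypoint values, 8 derived landmark
coordinates, first and second raw finite-difference derivatives of all 42
point coordinates, the three postural signals with first derivatives, and
the per-frame centroid displacement. Derivative boundary rows hold NaN and
are imputed to zero only inside the evaluation harness. Derivatives here
are deliberately unsmoothed so they match an independent brute-force
finite-difference oracle exactly (tested).

## Composite score

`fit_score_model` filters features by |Cohen's d| ≥ 0.5 between hazardous
and safe falls (a medium effect — conservative relative to the large
effects the score should rest on), orients each feature by the sign of d,
and weights by the mean-decrease-in-impurity importances of a 100-tree Gini
random forest refitted on the retained features. Normalisation anchors are
the 2.5th/97.5th percentiles of the fitting cohort with clipping — robust
min-max that ignores simulator outliers. The score is a convex combination,
hence in [0, 1] and monotone in every direction-aligned feature. Labels
come from generator ground truth on synthetic data or a user-supplied
column on real data; the clinical labelling rule itself (chin tuck, trunk
roll, no straight-arm landing) is encoded only as the simulator's
convention.

## Synthetic cohorts

The generator emulates pose-estimator output with a 2D stick-figure
forward-kinematics template: a torso segment, head offset, and four
two-segment limbs, driven by smoothstep ramps for hip descent, horizontal
roll and trunk rotation. It reproduces the *structure* of three motor
profiles, not biomechanical ground truth:

- **controlled** — short decisive squat (0.40 s) to a deep descent
  (380 px), long roll (350 px), chin tuck near 1;
- **chaotic** — short hesitation, moderately sharp crumple (300 px in
  0.42 s), 6 Hz flail on wrists/elbows/ankles plus lateral whole-body sway
  (the sway is x-only so the vertical template stays closed-form);
- **freezing** — long hesitation (1 s), slow shallow descent (180 px in
  1.5 s), near-zero roll, extended straight arms, no chin tuck.

Magnitudes were calibrated once so that the noiseless templates satisfy the
orderings the analysis rests on — descent commitment: controlled > freezing
with chaotic intermediate on all three fall metrics; movement intensity:
chaotic > controlled > freezing; neck distance: controlled < freezing — and
so the default cohort mixes produce the qualitative study patterns (fall
metrics 3/3 significant, three recoverable clusters, post-test
concentration in the controlled cluster). Defaults: 60 fps, 1920×1080, 3 s,
Gaussian keypoint noise σ = 2 px, dropout 2%; cohort mixes
pre = (0.10 chaotic, 0.55 controlled, 0.35 freezing),
post = (0.02, 0.83, 0.15); per-subject lognormal jitter (10–20%) on depths,
durations and distances emulates anthropometric variation. Each subject's
stream derives from the cohort seed by a fixed affine map, so generation is
order-independent and reproducible.

What the simulator does **not** model: true multibody dynamics, 3D
perspective, camera distortion, identity switches, occlusion-correlated
(rather than independent Bernoulli) keypoint dropout, and within-profile
learning effects (cohorts differ only through their profile mixes). Passing
tests therefore demonstrate that the *analysis machinery* recovers known
structure under realistic noise — not that the pipeline is validated on
real video. One consequence: because the intervention signature is spread
over several correlated metrics (rolling ranges and variabilities shift as
strongly as descent rates), random-forest importance for the skill task is
diffuse, and no single metric dominates the ranking.

## Statistics

Shapiro–Wilk gates normality per cohort (pixel-kinematic metrics
essentially always reject; constant samples are flagged as rejected). The
pre/post contrast uses the two-sided Mann–Whitney U test: the exact null
distribution when both groups have ≤ 20 tie-free observations, the
tie-corrected normal approximation otherwise; a constant pooled sample is
vacuous (p = 1). Multiplicity across the 15 metrics is controlled with
Benjamini–Hochberg (the field-default FDR procedure; the choice of BH over
BY is deliberate). Effect sizes are Cohen's d with n−1 pooled variances.
Percent change is reported on both medians (robust, matches the tabulated
summaries) and means, since the two can disagree for skewed metrics.
α defaults to 0.05.

## Clustering

The 15 metrics are z-standardised before PCA and k-means — unscaled pixel
metrics would otherwise dominate the objective. k = 3 is fixed by the
three-profile hypothesis; k-means uses 10 restarts and a required seed, and
clusters are relabelled canonically by descending movement-intensity
centroid so "cluster 0" is always the chaotic-like group. Cluster profiles
are reported as percent deviation from the sample mean (undefined where the
mean is zero). The cohort×cluster association uses Pearson's chi-square
without continuity correction, warning when expected counts drop below 5.
Clustering operates on the joint pre+post sample.

## Evaluation protocol

Both supervised tasks are evaluated subject-independently: grouped
(optionally stratified) k-fold with k = 5 by default, or leave-one-subject-
out. Frame rows always follow their subject, and a hard leakage assertion
checks every fold. Metrics are accuracy, macro precision/recall/F1 and
ROC-AUC, reported as mean ± sd across folds; for frame-level tasks both
frame-level and sequence-pooled (mean predicted score per subject) numbers
are given, since the two poolings answer different questions. Class
imbalance is reported, not resampled away. Model defaults beyond the
100-tree Gini forest: gradient boosting (100 stages, lr 0.1), L2 logistic
regression, RBF-SVM with probability outputs, and a one-hidden-layer (64)
MLP with early stopping; the last three are fitted on standardised
features. Identical seeds and inputs give bit-identical reports.

## Problem sizes

The test suite and acceptance script run cohorts at the study sizes (285
pre / 130 post, 3 s at 60 fps) for single-cohort analyses, and smaller
replicates (e.g. 50/35) for the 100-fold null-calibration Monte Carlo; the
frame-level classification demonstration uses 120 subjects with every third
frame. These sizes are the package's chosen defaults for its own
verification experiments and keep any single check in the seconds-to-
minutes range.

## Known limitations

- 2D projection only: out-of-plane rotation compresses apparent ranges.
- The chin/sternum proxies bias the neck-protection distance upward.
- Impact detection assumes a single dominant descent episode per sequence;
  multi-fall recordings should be pre-segmented.
- The composite score's weights inherit the impurity measure's bias toward
  correlated feature groups; weights are interpretable only jointly.
- Percent-change summaries are undefined for zero-median metrics.
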