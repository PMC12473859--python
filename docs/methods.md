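# Methods

This note documents the models, conventions and numerical choices behind
`gaitcomp`: what each stage computes, which parameters matter, what the
synthetic-cohort generator does and does not emulate, and where the design
was genuinely open.

## 1. Pose ingestion and repair

Sequences are per-frame outputs of a 2-D pose estimator: 17 COCO-numbered
keypoints, each `(x, y, score)` in image-pixel coordinates (origin top-left,
x rightward, y downward, 0-based frame indices at a nominal 30 fps).
Downstream kinematics use only the five upper-body keypoints that define the
center of mass (CoM): nose (0), left/right shoulder (5, 6), left/right hip
(11, 12).

A CoM keypoint is treated as missing when its confidence is below
`min_score` (default **0.3**) or a coordinate is non-finite.  Pose
estimators report confidence but publish no universal acceptance cutoff;
0.3 is a common working threshold and is fully configurable.  Missing runs
of at most `max_gap` frames (default **5**, i.e. ~170 ms at 30 fps) flanked
by valid frames are repaired by per-keypoint, per-coordinate linear
interpolation against frame index; longer runs and runs touching a sequence
edge are dropped rather than extrapolated, because extrapolated coordinates
would fabricate displacement.  Repairs never touch frames outside logged
gaps, and interpolated coordinates lie within the per-coordinate hull of
their anchors by construction.

Quantiles everywhere in the package (confidence summaries, percentile
thresholds, stratum summaries) use linear interpolation between closest
ranks — the numpy default — fixed once so that thresholds are reproducible.

## 2. Gait dynamics

Per frame the CoM is the unweighted mean of the five selected keypoints.
For each pair of consecutive valid frames:

* center displacement `center_dis = sqrt(dx^2 + dy^2)` (pixels/frame);
* directional shift `theta = arctan(dy/dx)`, range `(-pi/2, pi/2]`.

The arctangent of the ratio is used literally, with defined degenerate
cases: `theta = +pi/2` if `dx = 0, dy > 0`, `-pi/2` if `dy < 0`, and `0`
for a zero step.  A quadrant-aware `atan2` convention is available
(`angle="atan2"`) but is not the default, because the ratio form is the
field's printed definition for this statistic.  Dynamics are never computed
across dropped frames or frame-index jumps — one dropped frame costs both
adjacent entries — so gaps cannot inflate displacement.

Per-participant aggregation supports two definitions of
`mean_directional_shift`, because the quantity is used ambiguously in the
literature (an angle by its formula, yet often reported in pixels/frame):

* `angular` (default): mean of `|theta|` in radians, range `[0, pi/2]`;
* `horizontal`: mean of `|dx|` in pixels/frame.

Both are computed on every run (the alternate mode is written to
`features_alt_mode.csv`).  Variances are sample variances (n−1); a single
surviving step reports variance 0 with a warning instead of failing the
run.  Angular-mode shift is invariant to uniform coordinate scaling;
horizontal-mode shift and mean displacement scale linearly — tested
properties.

## 3. Percentile outlier filtering

Center-displacement distributions from pose-estimated gait are right-skewed
with a long tail (frame freezes, abrupt posture adjustments).  Cleaning
thresholds are percentiles of the displacement sample — default the
**95th**, with 90th/99th always reported for sensitivity — computed by
default on the distribution **pooled across the cohort** (one global cut),
with per-participant scope available by flag.  "Exceeding" is strict:
entries equal to the threshold are kept.  A removed entry is removed
entirely, directional shift included, since a corrupted displacement
implies a corrupted angle for the same frame pair.  Filtering is idempotent
and bounds the post-filter maximum by the threshold; on continuous data the
removed fraction converges to the nominal tail mass.

## 4. SPPB 4-m walk scoring

Trial times are scored 0–4 with the standard SPPB gait-speed categories
(≤4.82 s → 4, 4.83–6.20 → 3, 6.21–8.70 → 2, >8.70 → 1, unable/missing → 0);
the table is a package default, overridable in the run config, not a claim
about any particular study's internal cut points.  Both per-trial scores and
a combined score are emitted; the combined score is computed on the mean of
the present trial times (the alternative — mean of trial scores — is a
coarser statistic and is not emitted).

## 5. Body composition

Records carry the 21 standard bioimpedance indicators plus demographics.
Consistency checks with tolerances sized to absorb 1–3-decimal device
rounding: water sum |ICW+ECW−TBW| ≤ 0.05 L, ratio |ECW/TBW−stored| ≤ 0.001,
BMI recomputation ≤ 0.3 kg/m²; violations warn by default and raise under
`--strict`.  SMI is stored as measured and never recomputed from
SMM/height², because device-reported SMI uses appendicular muscle mass as
its numerator; recomputing from whole-body SMM would corrupt the data.
Sarcopenia screening applies the AWGS 2019 cutoffs — at risk iff
SMI < 7.0 kg/m² (male) or < 5.7 kg/m² (female), strict less-than.

## 6. Statistical battery

* **Normality screen**: Shapiro–Wilk per variable (3 ≤ n ≤ 5000), conforming
  iff p > 0.05; constant vectors are flagged degenerate.
* **Correlations**: Pearson's r computed from the explicit product-moment
  formula; two-sided p from the exact transform
  `t = r sqrt(n-2)/sqrt(1-r^2)` on n−2 df.  Spearman is Pearson on average
  ranks.  Cells use pairwise-complete observations with per-cell n recorded
  explicitly, because silently dropped cases make printed t-statistics
  irreproducible.  Cells whose indicator failed the normality screen are
  annotated, not suppressed.
* **Markers**: `***` p<0.001, `**` p<0.01, `*` p<0.05; markers are derived
  from the computed p and can never disagree with it (asserted invariant).
* **Regression**: per-indicator simple OLS of mean directional shift on the
  indicator (statsmodels); the slope t equals the Pearson-implied t to
  1e-10 on every dataset — an algebraic identity the tests assert
  numerically.  Perfect fits are flagged rather than reported with a
  meaningless t.
* **Multiplicity**: no correction by default (exploratory screening);
  Benjamini–Hochberg adjusted p-values by flag, appended without changing
  markers.
* **Stratified analysis**: per-sex grids plus five-number summaries of
  mean directional shift; strata under 3 members are skipped, strata under
  10 carry an explicit low-n flag.

Correlation cells render as `r marker(p)` (e.g. `0.561 *(0.019)`) in the
report tables, with machine-readable CSV/JSON alongside.

## 7. Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
validated.  A latent mobility factor `m ~ N(0,1)` per participant couples
everything:

* **Indicators** follow a single-factor model
  `x_j = mu_j + sd_j (rho_j m + sqrt(1-rho_j^2) eps)`, with means/SDs set to
  the published cohort summary and default planted correlations matching
  the published pattern (muscle/lean ~ +0.45…+0.56, water +0.41…+0.50,
  fat −0.05…−0.34).  A single factor is the simplest structure realizing
  the signed pattern; cross-indicator correlations are therefore
  `rho_j rho_k`, weaker than the near-collinearity of real bioimpedance
  outputs — a documented simplification.
* **Identities** hold exactly: TBW is drawn directly and split via the
  drawn water ratio (ECW = ratio·TBW, ICW = TBW−ECW); weight is derived
  from BMI and height.  ICW and ECW consequently inherit TBW's correlation
  (~0.49) rather than carrying independent planted values; they are marked
  derived in the ground truth and excluded from exact recovery checks.
* **Floored indicators** (FAT, PBF, VFA at small positive floors;
  FFM_control at its published minimum of 0) would have their correlations
  attenuated by truncation; the pre-floor correlation is divided by the
  analytic attenuation factor `Phi(alpha)/sd(max(Z,-alpha))` (Stein's
  lemma) so the planted value is achieved on the observed scale.
* **Gait**: each participant's target shift level is
  `mu_i = clip(0.36 + 0.15 m, 0.03, 1.1)` radians (population level 0.36 ±
  0.15).  Steps have direction `theta_t = sign_t · mu_i · U(0.6, 1.4)` —
  so E|theta| = mu_i exactly — with the sign driven by a 0.9 Hz sway
  sinusoid plus noise, and forward step length |N(4, 0.8)| px/frame.
  Outliers are multiplicative spikes (×U(3,15)) on isolated steps at rate
  0.05, reproducing the right-skewed long tail; joint scaling of dx and dy
  leaves theta untouched, as a frame-freeze pixel jump would.
* **Keypoints** sit at fixed anthropometric offsets around the CoM (the
  five CoM offsets re-centered to zero mean, so the pipeline's CoM is the
  true CoM up to jitter) with 0.3 px Gaussian jitter.  Confidences are
  N(base, 0.06) with base ~ U(0.61, 0.67), hard-capped at a per-participant
  maximum ~ U(0.77, 0.83); 2% of detections are low-confidence dropouts
  (score ~ U(0.05, 0.25)) with 40 px corrupted coordinates, exercising the
  repair path.
* **Walk times**: speed = 0.85 + 0.12 m ± noise m/s (usual pace for this
  age range, spreading scores over the 2–4 categories), time = 4/speed per
  trial with 0.15 s timing noise.

What the generator does **not** emulate: camera perspective and
distance-dependent scale, autocorrelated estimator noise, within-trial
fatigue, realistic inter-indicator covariance beyond one factor, and
missingness that clusters in long runs.  Passing recovery tests therefore
demonstrates that the pipeline is an unbiased, correctly calibrated
estimator of the planted structure — not that the published effect sizes
would replicate on new recordings.

A reduced path (`generate_feature_table`) draws the aggregated feature
table directly, with Gaussian measurement noise (sd 0.015 rad) matching the
dispersion the full pipeline exhibits at the default frame count; it exists
for replicate-heavy calibration studies (10^4 null replicates) where
rendering keypoints would dominate runtime.

All randomness flows from one seed through named substreams
(`latent`, `indicators`, `trials`, `pose:<i>`, …), so any modality can be
regenerated independently and cohorts are bit-reproducible.

## 8. Problem sizes used in validation

Oracle-equivalence checks run 100 random instances per primitive at 1e-10
tolerance.  End-to-end parameter recovery uses 2000 participants × 300
frames (each planted correlation recovered within ±0.05, consistent with
the 3(1−rho²)/√n sampling bound).  Type-I calibration uses 10^4 null
replicates at n = 17 — the number of complete cases that reconciles the
published correlation and regression tables — over the full 21-indicator
grid.  Filter behaviour is checked on 10^5 continuous draws.  The
19-participant demo cohort matches the published cohort's size and sex
ratio (16 male / 3 female).

## 9. Known limitations

* The pixel-space metrics are camera-dependent; no scale normalization,
  Kalman smoothing or temporal alignment is applied (out of scope).
* The angular/horizontal ambiguity of `mean_directional_shift` cannot be
  resolved from published material; both modes are first-class and every
  run reports both.
* Published percentile thresholds (7.93/9.42/30.23 px) depend on raw
  recordings that were never deposited; they are documentation, not
  reproduction targets.
* At n = 19 the per-cell sampling error of r is ≈ 0.2; single-cohort
  correlation grids at that size are exploratory, which is why markers are
  uncorrected and per-cell n is always printed.
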