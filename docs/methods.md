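# Methods

## Problem and measurement model

Grading aortic stenosis (AS) severity normally relies on Doppler-derived
hemodynamics (mean gradient, peak velocity, calculated aortic valve area,
AVA), yet the very first echocardiographic view acquired — the parasternal
long axis (PLAX) — already shows the restricted motion of the aortic
leaflets that the sonographer judges qualitatively. `leafletmotion`
quantifies that judgement. Five landmarks are annotated on the anterior
(right coronary) leaflet in one systolic (open) and one diastolic (closed)
frame of a single PLAX clip:

* `B` — leaflet base / hinge point,
* `M` — mid-leaflet,
* `T` — leaflet tip,
* `A` — aortic wall at the sinotubular junction,
* `OB` — opposing leaflet hinge point.

Pixel coordinates are converted to millimetres per axis using the clip
calibration (taken per study, since one PLAX clip is analysed per patient;
extracted from DICOM ultrasound-region physical deltas when available,
falling back to the pixel-spacing attribute, with region deltas taking
precedence). Vectors `B→M`, `B→T`, `B→A`, `B→OB` and the *global* vector
`v_G = (v_M + v_T)/2` are formed per phase, and eight per-patient metrics
derived:

* **Linear displacement** (mm) at mid, tip, and global:
  `ld_x = ‖v_x(systole) − v_x(diastole)‖₂`. The global value is the
  displacement of the averaged vector `v_G` (not the average of the two
  scalar displacements — that alternative is available behind
  `global_ld_convention="scalar_mean"`). By construction
  `ld_global ≤ (ld_mid + ld_tip)/2`, with equality iff both leaflet
  points translate identically.
* **Angular displacement** (°) at mid and tip: the change between phases
  of the vector's angle to the `B→A` aortic-wall axis, each phase
  re-referenced to its own axis; `ad_global = (ad_mid + ad_tip)/2`.
  The scalar mean is the only reading of the global angular metric
  consistent with the per-landmark values it summarises; the
  vector-of-means alternative sits behind `global_ad_convention`.
* **Linearity** (°): the diastolic internal leaflet angle at apex `M`
  between `M→B` and `M→T`; 180° is a perfectly straight (stiff,
  calcified) leaflet.
* **Flexibility** (°): the absolute change of the internal angle between
  phases; rigid leaflets change little.

Angles are computed in millimetre space *after* per-axis calibration, so
anisotropic pixels do not distort them; normalized dot products are
clamped to [−1, 1] before `arccos`; nothing is rounded before output.
Degenerate configurations (coincident `B`/`A`, `B`/`M`, `M`/`T`) raise
errors rather than returning silent zeros; `validate_study` reports the
same invariants as data for QC workflows.

### Cardiac-rotation correction

The heart itself translates and rotates between the two annotated frames.
Because both the leaflet vector and the `B→A` reference are re-derived per
phase, the default (uncorrected) angular metrics are already invariant to
any rigid motion applied to a whole frame. An optional correction
(`correct_rotation=True`) instead measures each vector's signed
absolute-frame rotation (atan2-based, counterclockwise-positive in
anatomical orientation) and subtracts the phase-to-phase rotation of the
`B→OB` axis — the opposing hinge tracks whole-heart rotation — before
taking the absolute value. The two paths agree exactly on rigid-motion
fixtures; they differ only when the wall landmark `A` moves relative to
the heart. The correction defaults to off.

## Synthetic cohorts

The underlying echocardiograms are not publicly deposited, so the package
ships a generator that reproduces the study's cohort structure
(60 control / 70 moderate / 70 severe) at three levels.

**Feature level.** Every motion metric and clinical covariate is drawn
from a marginal moment-matched to the published per-class mean ± SD.
Non-negative, strongly right-skewed quantities (displacements, angular
displacements, flexibility, AVA, gradient, velocity, dimensionless index,
wall thicknesses) use a lognormal whose log-scale parameters
`σ² = ln(1 + s²/m²)`, `μ = ln m − σ²/2` reproduce the target moments
exactly — a truncated normal would bias the means badly where s ≈ m (e.g.
severe mid-leaflet displacement 1.7 ± 1.6 mm). Linearity and LVEF use
normals truncated to (0, 180] and (0, 100]; the truncation shifts the
severe-class linearity mean a few degrees below its nominal 159 ± 21 —
this is deterministic and accepted rather than re-calibrated. Age is
normal, floored at 18 years outside the control class. Within a class,
features are coupled by a single-latent-factor Gaussian copula: each
patient carries a severity factor `z ~ N(0,1)` and each feature's normal
score is `d·λ·z + √(1−λ²)·ε` with loading λ = 0.8. The sign `d` is +1 for
quantities that increase with leaflet health (motion metrics, AVA,
dimensionless index, LVEF) and −1 for those that increase with disease
(gradient, velocity, septal/posterior wall thickness, linearity, age);
linearity and age are not covered by any published correlation and their
signs follow the same physiological orientation. The loading is the one
deliberately stylised knob: true inter-feature correlations in the study
cohort are unpublished, and λ controls how much independent information
the classifier can pool. Severe patients are labelled high- vs
low-gradient at the conventional 40 mmHg mean-gradient threshold (a label
only; the study found the subgroups statistically indistinguishable, so no
separate generative model is fitted). Septal and posterior wall
diameters are not published per class; the defaults (9 ± 1.5, 11 ± 1.8,
12 ± 2.0 mm) encode a plausible hypertrophy gradient and are flagged as
artifact choices.

**Landmark level.** The leaflet is modelled as two rigid 7 mm segments
hinged at `B` and articulated at `M`, placed in a fixed scene (wall axis
tilted −15° from the image rows, `A` 22 mm and `OB` 20 mm from `B`,
diastolic base angle N(80°, 4°)). Opening rotates the base segment by a
class-conditional `ad_mid` draw and increases the internal angle by a
class flexibility draw; configurations that fold past the wall axis or
collapse a segment are resampled (counts logged). The analytic metrics of
the noiseless configuration are returned as ground truth; the annotation
then receives an optional whole-heart rigid motion (rotation within ±8°,
translation within ±3 mm applied to the systolic frame), conversion to
pixels at 0.3 mm/px, and isotropic Gaussian landmark jitter (0.5 px
default). With zero noise the geometry module recovers the truth to
machine precision; with rigid motion enabled, angular metrics remain
exactly recoverable (linear ones intentionally do not — translation is
real displacement to a base-anchored vector).

**Rater replicates.** A seeded 10% subsample receives a second-rater
annotation (1.0 px landmark jitter) and a same-rater repeat (0.7 px),
feeding the reliability analysis.

What the generator does *not* emulate: speckle, dropout and shadowing
(annotation error enters only as isotropic jitter), multi-frame temporal
kinematics, bicuspid/rheumatic morphology, asymmetric calcification, and
any real correlation structure beyond the single factor. Passing tests
therefore demonstrate correctness of the measurement and analysis
machinery under a known generative model — not clinical performance on
real echocardiograms.

## Statistical stage

Group differences use the Kruskal–Wallis rank sum test (tie-corrected,
chosen for the strong heteroscedasticity across classes), with
Games–Howell pairwise post-hoc comparisons: Welch-type t on the two
variance terms, Welch–Satterthwaite degrees of freedom, p from the
studentized-range distribution with k = 3 groups at `|t|·√2`, and
Holm–Bonferroni adjustment applied within each metric's three-pair family
(not pooled across metrics; the pooled alternative is a flag). Sex uses a
Pearson chi-square without continuity correction. Correlation of motion
metrics with AVA is Pearson's r.

Reliability uses ICC(2,1) — two-way random effects, absolute agreement,
single measure, the standard form for interrater reliability of
continuous echo measurements (the model form is not otherwise pinned
down) — with the F-based 95% interval, computed per metric on the
replicate subsample; the summary value per mode is the unweighted mean of
the eight per-metric ICCs.

A Monte-Carlo power routine estimates the power of the omnibus test on
`ad_global` (the metric used for the study's sample-size statement) across
a grid of total sample sizes under configurable class distributions. At
the published class effects, power at n = 126 is essentially 1 — the
pilot effect sizes behind the original n = 126 calculation were evidently
smaller and are not recoverable, so the routine exposes the machinery
rather than reproducing that number.

## Classification

Task 1 predicts significant AS (moderate-or-worse vs control) from the
eight motion metrics; Task 2 predicts the three severity classes from
those eight plus the septal and posterior wall diameters. Doppler-derived
fields never enter the features. Protocol: iterative collinearity filter
at |r| > 0.9 (drop the member of the worst pair with the larger mean
absolute correlation; name-order tie-break), outcome-stratified 80:20
split, 5-fold stratified CV grid search, refit at the chosen point,
one-shot evaluation on the holdout. Three families are implemented:
elastic-net logistic regression (saga; C ∈ 12 log-spaced points in
[10⁻², 10²] × l1_ratio ∈ {0.1, 0.3, 0.5, 0.7, 0.9}), k-NN (k = 3…25,
uniform weights), and a 500-tree random forest (split-candidate grid
{2, 3, √p}); the elastic net and k-NN standardize features with
training-set statistics inside the pipeline, the forest consumes raw
features.

CV selection maximizes mean (one-vs-rest) AUC but is calibration-aware:
on these cohorts the CV-AUC surface is a near-flat ridge, and a raw
argmax picks fold noise — occasionally an over-shrunk elastic net whose
coefficients are essentially zero and whose predicted probabilities
collapse to the base rate (rank information survives, so AUC barely
moves, but accuracy at the 0.5 threshold drops to the prevalence).
Selection therefore takes all grid points within one standard error of
the best mean CV AUC and picks the lowest mean CV log-loss among them;
remaining exact ties go to the earliest point of the
conservative-first-ordered grid (stronger penalty, larger k, fewer split
candidates).

Binary evaluation reports rank-statistic ROC/AUC plus confusion metrics
at the 0.5 probability threshold; multiclass reports per-class
one-vs-rest AUCs, their unweighted mean, and macro-averaged sensitivity /
specificity / PPV / NPV from the argmax confusion matrix. Models are
compared on common holdout predictions with the DeLong test for
correlated ROC curves (binary) or a 2000-resample stratified bootstrap of
the difference in mean one-vs-rest AUC (multiclass); the global p is the
Holm-adjusted minimum across pairs. Feature importance defaults to
absolute standardized coefficients (summed across classes for the
multinomial model) or impurity importance for the forest, normalized to a
maximum of 1; permutation importance is available separately.

## Numerical and design notes

* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; every operation is bit-reproducible under a
  fixed seed, and the pipeline manifest records artifact checksums (its
  timestamps are excluded from the determinism contract).
* Angles are reported in degrees; dot products clamped before `arccos`;
  signed angles wrapped to (−180°, 180°].
* Games–Howell with both variances zero and equal means returns p = 1 by
  convention; zero variance with unequal means is an error.
* The Monte-Carlo sizes used by the test-suite and the acceptance script
  (20 cohort draws for per-class means, 25 seeds for classifier metrics,
  2000 replicates for null calibration, 10⁵ random studies for the
  triangle-inequality sweep, 10⁶ draws for moment matching) were chosen so
  each check resolves its tolerance comfortably at desk scale.

## Known limitations

* The copula loading is a stylised stand-in for an unpublished
  correlation structure; classifier metrics on synthetic cohorts track
  the published ones by construction of the marginals, not as an
  independent replication.
* Landmark-level simulation covers only two phases of a rigid two-segment
  leaflet; no speckle-level realism, no automated landmark detection.
* The power routine cannot reproduce the original sample-size
  calculation (pilot effects unreported).
* Only the right coronary leaflet is modelled; posterior-leaflet and
  short-axis/3D geometry are out of scope.
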