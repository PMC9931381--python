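# Methods

## Problem and measurement model

Cylinder-grip manugraphy measures the force each pressure sensor on a
cylinder's surface receives while a hand grips it (sensors of 7 mm² at a
density of 2 per cm²; forces are the components perpendicular to the
surface).  The contact area is segmented into seven anatomical regions —
thumb (I), index (II), middle (III), ring (IV) and little finger (V), plus
the thenar (TH) and hypothenar (HY) eminences — and each trial is reduced
to the total grip force and the percent contribution of each region.
Segmentation masks are accepted as input, never inferred: how the seven
regions are drawn on the raster depends on anatomical landmarks that the
raw grid does not encode.

`manugrip` asks whether a single grip measurement was performed sincerely
(maximal voluntary effort) or insincerely (deliberately submaximal, as
when feigning weakness), and compares two answers:

1. **Conventional threshold method.** The two hands of one subject are
   compared area by area on the percent scale.  An area is "significantly
   different" when the absolute bimanual difference strictly exceeds
   3 percentage points, the physiological between-hand bound reported for
   this modality.  The number of differing areas (0–7) is the test
   statistic; a pair is called insincere when at least `cutoff` areas
   differ.  Sweeping the cutoff over 0–8 traces a nine-point ROC
   staircase; its trapezoidal area equals the tie-corrected Mann–Whitney
   probability that an insincere pair out-counts a sincere one.  The
   operating point maximises Youden's J (sensitivity + specificity − 1),
   with ties resolved toward the **higher** cutoff, i.e. higher
   specificity: falsely branding a sincere subject carries the greater
   clinical harm, so the method errs toward low sensitivity.

2. **Machine-learning method.** Each single record (no bimanual
   comparison) becomes a feature vector: age, sex, handedness, total grip
   force, the percent loads of II, III, IV, V, HY and TH, the sample
   variance of all seven percent loads, and the natural log of the total
   contact load.  Records are split 80/20 with class stratification; four
   classifier families (random forest, linear-kernel SVM, gradient
   boosting, XGBoost) are tuned by five-fold cross-validated grid search
   on AUC and evaluated on the held-out 20%.

Both methods are reported as sensitivity, specificity and accuracy (exact
Clopper–Pearson 95% CI on accuracy) plus AUC with a DeLong 95% CI, in a
table with methods as columns.  The positive class is always
"submaximal/insincere": sensitivity is the probability of detecting a
submaximal effort.

## Synthetic cohort generator

No public manugraphy dataset exists, so the package ships a generator
that reproduces the study design it analyses: 54 subjects (25 male,
52 right-handed, ages 19–53), two sessions, three 5-second trials per
hand per session, one hand maximal and the other submaximal per session
with the submaximal hand randomised in session 1 and swapped in
session 2 — 324 maximal and 324 submaximal records in total.

Generative assumptions, with defaults and rationale:

- **Grip capacity** (`strength`): log-normal, median 420 N (males) /
  280 N (females), log-scale SD 0.20 — typical cylinder-grip forces for
  healthy adults with a realistic ~20% between-subject spread.
- **Population mean composition**: I 20, II 12, III 16, IV 13, V 8,
  TH 16, HY 15 (percent).  This is a configuration default chosen as a
  plausible cylinder-grip pattern, *not* an empirical value; subject
  means are Dirichlet draws around it (concentration 150).
- **Between-hand asymmetry** (`asymmetry_sd`, default 1 point): Gaussian
  per-area perturbations of scale `1/√2` per hand, so sincere bimanual
  differences have scale ≈1 point and rarely exceed the 3-point
  threshold — consistent with 3 points being the accepted physiological
  bound.
- **Trial-to-trial compositional noise** (`trial_concentration`,
  default 600): Dirichlet around the hand baseline, giving per-area SDs
  of roughly 1–1.5 points for mid-sized areas; `inf` disables the noise
  (used by the deterministic-limit tests).
- **Submaximal effort**: total force is capacity × *f* with
  *f* ~ U(0.5, 0.75) (the instructed "half to three-quarter strength"),
  times a mean-one log-normal trial noise (CV 4%).  The realised *f* is
  recorded on the generated record as provenance.
- **Load redistribution** (`redistribution_delta`): percentage-point
  shifts applied to the baseline before renormalisation, default
  I +2.5, II +1.5, III −0.5, IV −0.5, V −0.5, TH −1.5, HY −1.0 (zero
  sum), jittered per trial (SD 0.5).  Direction: the thumb and index
  are neglected least under submaximal effort (their relative share
  rises) and the thenar most.  Whether the hypothenar's share rises or
  falls under submaximal effort is ambiguous in the available evidence;
  the default keeps HY mildly negative and the sign is fully
  configurable — it is a choice, not a fact.
- **Randomness**: all streams are keyed `SeedSequence([seed, domain,
  subject, session, hand, trial])`, so any single record can be
  regenerated in isolation and record order never affects values.  The
  maximal-effort path draws (and discards) the same effort-fraction
  uniform as the submaximal path, so a null effort model (fraction
  pinned at 1, zero deltas) makes the two classes *identical* draw for
  draw, not merely equal in distribution.

**Rendered sensor grids.** `render_map` inverts the aggregation for
testing and visualisation: seven disjoint circular templates (five
fingertip blobs of radius 2.35 cells, two palm blobs of radius 3.0 cells
at 2 sensors/cm²) receive Gaussian force profiles scaled so each area's
force sum equals its target exactly; template centres are jittered
sub-cell.  A default render activates ≈135–155 sensors, inside the
120–200 range typical of a real cylinder grip.  Aggregating a render
reproduces the input loads to well within 1 percentage point per area.

What the generator does **not** emulate: finger kinematics, time-resolved
force curves, fatigue across trials, pathology-altered load patterns, or
any correlation between demographics and composition.  Tests passing on
this synthetic cohort therefore validate the *pipeline* — bookkeeping,
statistics, calibration, ordering of methods — not the real-world
performance numbers, which depend on the undeposited clinical data.

## Negative-class construction

The threshold method needs sincere (negative) bimanual pairs.  How the
original study formed them is unstated, so this package makes an explicit
choice: sincere pairs combine the maximal-effort hand of session 1 with
the maximal-effort hand of session 2 of the same subject and trial index
(opposite hands, both sincere), yielding 162 sincere vs 324 insincere
pairs under the default design.  Session-to-session variability makes
these slightly noisier than a true simultaneous bimanual test; reported
specificities should be read with that in mind.

## Split modes and subject leakage

The default split is record-level stratified, which allows the same
subject's trials in both partitions.  This mirrors common practice but
inflates ML performance: a model can partly memorise a subject's force
level and composition.  A grouped split (`group_by_subject`) holds out
whole subjects and is the honest estimate of generalisation to new
subjects; both are first-class and the report names the mode used.

A subtler artifact appears under the **null** (no effect): with
record-level cross-validation folds, a subject's held-out labels
anti-correlate with its residual training-fold label imbalance, biasing
the null AUC *below* 0.5 (≈0.36 in our experiments) — anti-learning, not
signal.  The calibration tests therefore evaluate null AUC with
subject-grouped stratified folds, where every method sits at 0.5 within
Monte-Carlo error.

## Numerical choices

- Exceedance is strict (`> 3.0` points); a difference of exactly 3 does
  not count.
- The cutoff classification is `count ≥ cutoff → insincere`; cutoff 0 is
  the degenerate all-positive rule, cutoff 8 the all-negative one.
- ROC points for continuous scores group tied scores into one threshold
  step; AUC is trapezoidal and equals the tie-corrected U-statistic.
- DeLong variance uses midrank placement values; perfectly separated
  scores give zero variance, a collapsed CI and a `degenerate` flag.
- Accuracy CIs are exact Clopper–Pearson (the conservative standard for
  small validation sets); the method is named in the report.
- Percent compositions must close to 100 within 1e-6; file input is
  renormalised when within ±0.5 of 100 and rejected otherwise.
- Hyperparameter grids are deliberately small and seed-stable (tree
  count × depth for the ensembles, C for the SVM); the linear SVM runs
  on standardised features and contributes its signed decision value as
  the ROC score, the others their class-1 probability.
- Default experiment scale is the full 54-subject design (648 records);
  the `--smoke` flag runs a 6-subject miniature.  ROC figures are not
  produced; all outputs are CSV/text.

## Known limitations

- The published feature list names 13 criteria but enumerates 12; the
  thumb percent is the likeliest omission and is available behind
  `FeatureConfig(include_thumb=True)`, off by default.
- The real study's headline numbers are not reconstructable (data not
  deposited; negative-class pairing and exact validation split unknown),
  so this package reproduces the *qualitative* finding — ML beats the
  threshold rule by a wide AUC margin — not the printed values.
- Sensor-by-sensor (maskless) classification is out of scope.
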