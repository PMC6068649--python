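# Methods

This note records the models, conventions and numerical choices behind
`ppgavf`, in the order the pipeline runs.

## Signal model and synthetic generator

A recording is a uniformly sampled single-channel PPG trace (default
1 kHz) tagged with hand (`left`/`right`) and phase (`before_HD`/
`after_HD`). The synthetic generator builds each beat from two half-cosine
segments: an upstroke from the pulse foot (amplitude 0) to the systolic
peak over `rise_time` seconds, and a decay back to the foot over the rest
of the `period`, optionally warped by a shape exponent. Landmarks are
therefore exact by construction — feet at multiples of the period, peak at
`rise_time` with value `amplitude` — giving closed-form per-beat slopes

    RS_true = amplitude / rise_time,   FS_true = amplitude / (period − rise_time),

independent of the interpolating shape. Per-beat fractional Gaussian
jitter on rise time (3%) and amplitude (2%) produces realistic
beat-to-beat slope variance while keeping the truth exact. Disturbances
are additive and never touch the truth: DC offset (0.5 a.u.), sinusoidal
baseline drift (0.1 a.u., 8 s period) and white noise (SD 0.02 a.u.).

Cohort defaults mirror the clinical development cohort: 5/4/2 subjects in
the mild/moderate/severe classes, DOS drawn uniformly inside
class-specific ranges spanning the observed per-class values
((14, 29), (34, 49), (74, 95) %), 15 beats per recording at 1 kHz, a beat
period of 0.8 s. No published quantitative model links DOS to pulse
shape, so the generator uses a configurable monotone stand-in: the mean
rising slope of the fistula hand is `base_rs · (1 + 0.8·DOS/100)` before
dialysis and rises by a further factor `(1 + 0.5·DOS/100)` after it, with
3% between-subject spread; the control hand has no DOS or phase
structure. `sample_cohort_slopes` draws exactly the per-beat slope values
the renderer would encode, without waveform synthesis; it is used for
statistical calibration studies (hundreds of replicate cohorts) where
rendering and re-detecting waveforms adds cost but no information.

What the generator does **not** emulate: dicrotic notches, heart-rate
variability within a recording, motion artefacts, sensor saturation, or
any physiologically calibrated DOS→morphology relation. Passing tests
therefore demonstrate that the pipeline recovers structure that is present
and detectable, not that real stenosis produces that structure.

## Preprocessing

Smoothing is robust local polynomial regression (LOESS): at each sample a
weighted least-squares polynomial (degree 2) is fitted over a window
spanning 1% of the record, with tricube distance weights, and re-weighted
over up to 5 robustness iterations by bisquare weights of residuals scaled
by six times their median absolute value. Implementation notes:

* windows are truncated at the record boundaries (no padding);
* the batched normal equations carry a 1e-12 ridge so that windows whose
  robust weights vanish almost everywhere remain solvable;
* when the residual scale falls to numerical-noise level
  (≤ 1e-12 · max|y|) the robust loop stops — reweighting on noise-level
  residuals would zero out arbitrary points;
* a plain moving average is available as an explicit alternative but is
  not the default.

De-trending subtracts the ordinary least-squares line, removing offset and
linear drift in one step; outlier suppression is the robust smoother's
job. Slope features are local differences, so they are insensitive to the
removed trend.

## Feature extraction

Peaks come from local-maximum detection with a minimum separation of
0.4 s (≤150 bpm) and a minimum prominence of 10% of the signal's
inter-quartile range (both configurable). Feet (valleys) are the minima
between consecutive accepted peaks, plus a leading and a trailing foot;
peaks not strictly above both flanking feet are dropped and the feet
recomputed. The first 12 complete valley–peak–valley beats per recording
enter the analysis. The falling slope of a descending limb is
algebraically negative; it is reported as a magnitude (matching how the
feature is tabulated), with the signed value retained.

Slope values are min–max rescaled to [0, 1] before summarisation. The
default scope pools all beats of the cohort per feature (RS and FS
separately): a monotone affine map that preserves between-subject and
between-phase contrasts. A per-recording scope is available but maps
every recording onto the same range, destroying exactly the phase-mean
differences the classifier uses — hence not the default. Summaries use
the sample mean and the n−1 variance.

## Feature selection

The paired two-sided t-test on the 11 per-patient before/after values is
the default: the same subjects are measured twice, and it is the variant
that reproduces the published decisions (rising slope p ≈ 0.021,
rejected; falling slope p ≈ 0.59, not rejected). The unpaired
unequal-variance (Welch) statistic with Welch–Satterthwaite degrees of
freedom is implemented alongside, since the printed test formula is of
that form; on the same tables it gives p ≈ 0.19 and would not change the
selection. Rejection uses strict inequality p < α, α = 0.05; a feature
exactly at α is not selected. No multiple-testing correction is applied
across the two candidate features, matching the original analysis. When
nothing is significant the pipeline warns and keeps all candidates.

## Labelling

DOS is computed from the diameter pair and partitioned with half-open
intervals [0, 30] → class 1, (30, 50] → class 2, (50, 100] → class 3; the
published partition overlaps at 30 and 50 and no tabulated patient sits on
a boundary, so this resolution changes no label. When a table supplies a
reported DOS, rows whose recomputed value does not round (2 d.p.) to the
reported one are flagged (`dos_mismatch`) but still labelled — such
disagreements arise when the tabulated diameters were themselves rounded.

## Network and trainers

The classifier is a 4-35-3 fully connected network with logistic sigmoid
at both layers. The four inputs are [mean RS before, mean RS after,
var RS before, var RS after] of the fistula hand (an RS/FS mixed set is a
config option). Bias terms are included (the published layer equation
omits them, but saturated outputs near 0/1 require them) and can be
disabled. Error convention e = target − output; weights initialise from a
seeded uniform with layer-scaled bounds ±√(6/(fan_in+fan_out)), biases at
zero. Loss is the mean of squared errors over all samples and output
units; training stops at MSE ≤ 10⁻³, at 1000 epochs, or on an
algorithm-specific condition. All trainers are full batch (LM requires
it; the others follow for comparability) and bit-reproducible given a
seed.

* **Levenberg–Marquardt**: damped Gauss–Newton on the per-sample error
  Jacobian, x ← x − (JᵀJ + μI)⁻¹Jᵀe, solved by Cholesky factorisation of
  the damped normal equations (never an explicit inverse). Damping
  schedule μ₀ = 10⁻³, ×10 on a rejected step, ÷10 on acceptance, stop at
  μ > 10¹⁰; accepted steps strictly decrease the loss.
* **Scaled conjugate gradient** (Møller): conjugate directions with a
  second-order step length from a σ-perturbation curvature probe
  (σ = 5·10⁻⁵) and a Levenberg-style scale λ (initial 5·10⁻⁷) enforcing
  positive curvature; periodic restart along steepest descent every
  n-parameters iterations; additional stop when the gradient norm falls
  below 10⁻¹⁰.
* **Rprop** (with weight backtracking): per-weight steps start at 0.07,
  grow by 1.2 on gradient-sign agreement (cap 50), shrink by 0.5 on a
  flip (floor 10⁻⁶) with the previous move retracted and the flip's
  adaptation suppressed for one step.
* **Delta rule** (baseline): w ← w + η Σ y_j δ_k + momentum·previous,
  with the published η = 0.1 and momentum 0.95 — the only trainer that
  uses them; the three main algorithms have no learning rate by
  construction. Divergence (MSE > 10⁶) stops the run.

## Evaluation

Held-out predictions are decoded by arg-max over the three outputs (ties
toward the lower class index) and pooled per repeat into one 3×3
confusion matrix, collapsed into micro-aggregated TP/FP/FN/TN. For three
classes this aggregation forces FP = FN and TN = N + TP, hence REC = PPV,
ACC = (1 + 2·REC)/3 and SPE = (1 + REC)/2; the identities are asserted on
every evaluation. Metrics are reported in percent as mean ± SD (n−1)
over 10 repeats of stratified 5-fold cross-validation. Stratification
deals each class's shuffled members round-robin across folds; with only
two severe-class subjects some folds lack a class, which pooling makes
benign. Per-fold metric averaging exists behind a flag. Wall-clock
training and per-sample prediction times are recorded for reporting only.

## Problem sizes

The default study design is the development cohort's: 11 subjects
(5/4/2), 12 analysed beats from ≥15 recorded per recording, 1 kHz, 5-fold
× 10-repeat evaluation. Calibration checks run 200 replicate cohorts at
the slope-sample level. The optimizer oracles use a 20×6 linear
least-squares problem, a 10-dimensional quadratic, the 4-sample XOR
benchmark and 18-sample three-class blobs.

## Known limitations

* The DOS→slope mapping is a stand-in; absolute slope values and effect
  sizes are not calibrated to haemodynamics.
* The 1%-span smoother attenuates sharp systolic peaks (the attenuation
  is monotone in pulse sharpness, so class ordering survives, but
  absolute slopes shrink).
* With 11 subjects a single misclassified subject moves micro-averaged
  recall by ~9 percentage points; cross-validated metrics on cohorts of
  this size have large seed variance.
* The t-test's validity rests on approximate normality of per-subject
  mean slopes; with 12 beats per mean this is mild, but heavy-tailed
  artefact contamination would require a rank test instead.
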