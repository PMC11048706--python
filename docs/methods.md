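# Methods

## Scope and data model

The package implements an ordinal-target training scheme for lymph-node
malignancy detection and the evaluation protocol needed to compare it
against binary-target training and the classical short-axis-diameter (SAD)
size rule.  The clinical dataset that motivates it (398 B-mode ultrasound
images with LN-RADS grades and histopathology outcomes) is restricted, so a
seeded synthetic cohort generator reproduces its published statistical
structure; every claim the tests make is therefore a claim about the
method's behaviour under those study conditions, not about the restricted
images themselves.

A cohort is a table of nodes with SAD/LAD (mm), L/S ratio, cortex
thickness, hilum presence, echogenicity ∈ [0, 1], LN-RADS level
(`1,2,3,4a,4b,5`), a binary malignancy flag, and a hidden severity latent.
Serialisation is plain CSV with a fixed header; floats are written with
`%.17g` and read with round-trip parsing so `read ∘ write` is the identity.

## Synthetic cohort generator

* **Level and malignancy.**  The latent severity is Uniform(0, 1); the
  level is its bucket under the cumulative level marginals
  (21, 28, 58, 83, 89, 119)/398, so mean severity strictly increases with
  level.  Malignancy is Bernoulli with the per-level conditionals
  (0/21, 0/28, 1/58, 30/83, 77/89, 118/119) — drawn from the level, not the
  latent, so the conditionals hold exactly in expectation.
* **SAD.**  Class-conditional lognormal.  Only two ROC operating points of
  the size rule constrain the distribution (10 mm: TPR 138/226, FPR 25/172;
  8 mm: sensitivity 0.77, specificity 0.66), and two survival quantiles
  determine a lognormal uniquely, so the model is fixed in closed form via
  log t = μ + σ Φ⁻¹(1 − p).  The calibrated defaults are μ_b ≈ 1.937,
  σ_b ≈ 0.346, μ_m ≈ 2.440, σ_m ≈ 0.487, with implied SAD AUC
  Φ(Δμ/√(σ_m² + σ_b²)) ≈ 0.800 — close to the 0.81 reported for the real
  cohort, which is a consistency check, not a fit.  Any positive family
  matching both points would be admissible; the lognormal was chosen for
  positive support and closed-form quantiles.
* **Morphology.**  Per-level uniform draws inside the clinical bounds that
  define each grade (cortex ≤ 3 mm for levels 1–2, 3–3.8 mm for level 3,
  3–4 mm for 4a, > 4 mm for 4b/5; L/S ratio shifting from oval > 2 toward
  round ≤ 2; hilum presence probability falling from 0.99 to 0.05;
  echogenicity centres falling from 0.85 to 0.20).  The cortex ranges for
  levels 3 and 4a are deliberately staggered so the per-level population
  means increase strictly; with tied means the "mean cortex non-decreasing
  in level" property would only hold up to sampling noise.  The grades
  describe clinical criteria, not distributions, so these ranges are the
  package's own defaults and are documented here rather than derived.
* **Images.**  Optional phantoms: an ellipse of axes LAD × SAD at
  `mm_per_pixel` scale (default 0.1 on 224×224; tests use 0.5 on 64×64), a
  cortex band of the stated thickness, a bright central hilum region iff
  present, interior intensity scaled by echogenicity, multiplicative
  gamma(8) speckle, over a darker fat background.  Non-hilum tissue is
  capped at 0.78 and the hilum band starts at 0.85, so hilum presence is
  recoverable from pixel values by construction.  The phantom emulates the
  geometry and first-order texture of B-mode images, not wave physics,
  Doppler, or inter-observer variability — tests passing on phantoms show
  the pipeline is correct, not that it would reach the same scores on
  clinical images.
* **Determinism.**  One `numpy` Generator seeded from the config draws all
  cohort fields vectorised in a fixed order; images are seeded per record
  from `(seed, crc32(id))`.  Identical seeds give bit-identical cohorts and
  images.
* **Fast feature path.**  `features_from_records` emits the 10-d vectors
  the heads consume directly from the tabular fields (log-SAD, L/S ratio,
  cortex, hilum, echogenicity, latent, each with additive Gaussian noise of
  s.d. 0.35, plus four pure-noise dimensions).  The noise keeps classes
  overlapping so threshold selection and ROC behaviour are exercised
  non-trivially.

## Heads and training

The feature extractor contract is image → 10 raw features (no output
nonlinearity, since the ordinal layer consumes them linearly).  The shipped
backbone is a small frozen seeded CNN (two conv-ReLU-avgpool blocks, global
average pooling, linear map to 10); inputs are standardised per image, and
only the heads are trained.  Head variants:

* `binary_narrow` — logistic regression on the 10 features, binary target;
* `binary_wide` — shared-weight sigmoid intermediate of width 5 (default;
  6 selectable) then a final sigmoid, for parameter-count comparability;
* `lnrads_fc` — five independent sigmoid rows, thermometer targets;
* `lnrads_mlr` — the shared-weight ordinal head (one weight vector, five
  intercepts), thermometer targets.

Thermometer targets are trained with per-bit binary cross-entropy summed
over the five bits (probabilities clamped at 1e-7), the standard
cumulative-ordinal objective matching the per-bit sigmoids; binary targets
use single-output BCE.  Optimisation is SGD with momentum 0.1, batch 32,
100 epochs, lr 0.1 divided by 10 every 10 epochs.  The literal schedule
underflows to 1e-11 by epoch 90; a `min_lr` floor is exposed but defaults
to 0 (the literal rule).  Features are standardised with training-split
statistics.  Gradients are analytic (the shared weight's gradient is the
sum of the per-bit gradients) and verified against finite differences.

Two numerical consequences of this protocol worth knowing: (i) on cleanly
separable ordinal data every bit ends on the correct side of 0.5, but the
summed BCE plateaus well above zero (logistic margins grow only
logarithmically, and with six equally likely levels on one shared predictor
the normalised half-gap between adjacent level clusters is at most ≈ 0.3);
(ii) parameter motion per epoch falls below 1e-6 once the lr has decayed
~10⁷-fold (around epoch 70), which is the plateau visible in per-epoch
curves.

## Evaluation

* Confusion-matrix metrics (accuracy, specificity, sensitivity, precision,
  F1); a metric with a zero denominator is reported as undefined, never 0.
* ROC over all distinct thresholds with trapezoidal AUC, required to agree
  with the tie-corrected Mann–Whitney pair statistic to 1e-12 (two
  independent routes, computed on every call).
* Threshold selection maximises Youden J over midpoints of consecutive
  distinct scores plus sentinels; ties break toward the smallest threshold
  (higher sensitivity).  The threshold is learned on the **training**
  split by default — the leakage-free reading of the protocol, which is
  stated ambiguously in its source; `threshold_from_eval=True` reproduces
  the test-split reading.
* SAD baseline: malignant iff SAD strictly greater than the cut-off
  (a node at exactly 10 mm is benign).
* Stratified k-fold CV (scikit-learn splitter) repeated R times with
  per-repeat seeds derived from one root seed; per-fold positive counts
  differ from perfect stratification by at most 1.
* Per-run metrics and per-epoch curves are averaged arithmetically over
  the k × R runs, with standard deviations alongside.

## Problem sizes

The shipped experiment default is the fast feature-vector mode with an
n = 2000 cohort and 5-fold CV × 2 repeats (40 trainings, ≈ half a minute on
one core); the generator-calibration checks use n = 10⁵.  These sizes give
the law-of-large-numbers checks ±0.01 headroom and keep the full suite
interactive.  Image mode exercises the render → backbone → head path at
64×64 in tests.

## Known limitations

* The absolute scores of models trained on the restricted clinical images
  are not reproducible here; the package asserts the qualitative ordering
  (all trained variants beat the SAD baseline; ordinal targets perform at
  least comparably to binary ones) on synthetic cohorts instead.  On the
  synthetic feature distribution the binary and ordinal variants land
  within ≈ 0.01 AUC of each other — the generator's features carry the
  malignancy signal directly, so the ordinal targets' real-data advantage
  (regularising intermediate morphologies) is only partially emulated.
* The frozen random backbone is a feature-extractor stand-in; no
  convolutional weights are learned.
* No confidence intervals (DeLong), calibration analysis, or multi-observer
  modelling.
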