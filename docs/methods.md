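# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical conventions that had to be fixed where the underlying workflow
leaves them open.

## Synthetic slides

A slide is a composition of boolean fields on an 8-bit RGB canvas
(default 512 × 512 px at 2 µm/px):

* **Villi** are the upper-quantile set of a Gaussian-smoothed white-noise
  field (characteristic scale 60 µm), thresholded so the villous pixel
  fraction equals the requested value exactly up to integer rounding. This
  produces irregular, connected blob morphology without attempting
  photorealism.
* **Fibrin** is a second smoothed field (scale 25 µm) thresholded inside the
  non-villous canvas; **artifacts** are small achromatic speckle discs
  confined to the intervillous space.
* **Vessels** are discs with radii uniform in 3–9 µm, Poisson-placed at
  interior villous pixels (centers keep one disc radius of clearance from
  the villous boundary so vessel pixels are strictly inside villi). A
  configurable 10% of discs is deliberately placed overlapping a neighbour
  by 10% of a radius, to exercise the watershed split. Defaults: 1324
  discs/mm² villous area, which with E[disc area] ≈ 123 µm² also yields a
  vessel area fraction of ≈ 16% of the villous area — both matching the
  cohort-mean histology the package simulates.

Color is rendered forward through Beer–Lambert using fixed
Ruifrok–Johnston hematoxylin and AEC optical-density vectors (stored in
`config.STAIN_MATRIX`) with per-pixel lognormal concentration jitter
(σ = 0.08 in log): villous stroma is hematoxylin-dominated (luminance
≈ 123), vessels AEC-dominated (≈ 74), fibrin pale pink (≈ 185),
intervillous space near-white (≥ 240), artifacts neutral gray ≈ 45. Because
the generator and the deconvolution share the same stain matrix, channel
recovery is exact up to 8-bit quantization.

The generator emulates class geometry, stain color statistics and object
counts; it does **not** emulate out-of-focus blur, stain gradients across a
slide, tissue folds, touching villi/fibrin interfaces with partial-volume
mixing, or scanner-specific color response. Passing tests therefore
establish the correctness and internal calibration of the measurement
chain, not its accuracy on scanner images; on real slides the trainable
pixel classifier (below) would need labeled tiles.

## Imaging

* **Tissue threshold.** "Tissue" is luminance (arithmetic mean of R, G, B,
  rounded half-up) strictly below 210. Which side of 210 counts as tissue is
  a convention; it is fixed here and documented, and the boundary is tested
  at 209/210.
* **Pixel classifier.** The default classifier is deterministic decision
  rules on the boxcar-smoothed (3 px) deconvolved channels: high residual
  channel (≥ 0.15) → artifact (achromatic material projects strongly on the
  third stain axis, while AEC-red vessels do not); AEC ≥ 0.40 or
  hematoxylin ≥ 0.22 → villi; AEC ≥ 0.07 → fibrin; else background. The
  thresholds were fitted once against tiles rendered at the generator's
  concentration settings — placed midway between the smoothed
  within-class and across-boundary window responses — and are frozen in
  `config.py`. On axis-aligned pure-color fixtures classification is exact.
  A trainable alternative (`TrainablePixelClassifier`, a small random
  forest on the same features) is provided behind the same contract for
  stain appearance the rules do not cover; the default stays rule-based so
  the pipeline is CPU-deterministic with no stored model weights.
* **Artifact reassignment.** Artifact blobs whose one-pixel dilation ring is
  ≥ 50% background are merged into background (artifacts inside the
  intervillous space do not belong to tissue); blobs embedded in villi or
  fibrin are kept. The pre-merge artifact share of tissue is preserved on
  the mask for QC.
* **Vessel segmentation.** The AEC field is thresholded inside villous
  pixels by per-slide Otsu (per-slide adaptivity mirrors per-sample
  processing; no cross-slide normalization exists in the chain), holes
  (lumina) are filled, and touching blobs are split by a watershed on the
  distance transform with seeds at local maxima separated by at least
  0.5 × the minimum expected radius (3 µm). Instances below 20 µm² — a
  capillary cross-section lower bound — are dropped. An instance belongs to
  the villous area iff its centroid pixel is villi-class.
* **QC.** A slide fails when the (pre-merge) artifact fraction of tissue
  exceeds 0.15 or the median villous AEC optical density falls below 0.02
  (≈ 40% of the normal stroma level; a 10× stain dilution falls far below
  it). Both thresholds are configurable.

## Stereology

The three normalized metrics are plain pixel/instance ratios (formulas in
the README); fibrin is included in the villous-density denominator, the
convention of the quantification workflow this package follows (a legend
variant omitting fibrin exists in the source material; the Methods-text
formula is implemented and the difference is ~1–3 points at the default
3% fibrin). Circle probes default to 1 mm diameter, up to k = 3 per slide
(2 accepted), non-overlapping — overlap would double-count vessels — and are
chosen greedily by villous fraction over a seeded candidate grid
(stride = radius/4) with a 0.30 minimum villous fraction; all three choices
are conventions the workflow leaves open, fixed and configurable here.
Instances cut by the probe boundary count iff their centroid is inside,
consistent with the whole-section rule; no unbiased-counting-frame edge
correction is applied. Two sections per woman are averaged before analysis.

## Accelerometry

Freedson cut-points are hard-coded constants (config). The non-wear rule
(≥ 60 min of zeros), the 600-min valid-day floor, the ≥ 3 valid days per
period and ≥ 2 valid periods per subject rules are standard conventions,
declared and configurable. Swim diary minutes are added to MVPA but not to
wear time, so % ST remains a proportion of measured wear. Light activity is
computed and reported but deliberately kept out of the regression models
(it is collinear with the other two classes given wear time).

The accelerometer generator draws a per-subject activity composition
(sedentary fraction Normal(0.723, 0.076) truncated; MVPA minutes with
between-subject SD 18.4/900 of wear) and then iid per-minute categories
within a contiguous 900-min wear block, with counts uniform within each
Freedson band. Calibration targets are cohort-level only — per-woman count
distributions are not modeled — so cohort means (≈ 39.5 MVPA min/day of
which 1.5 diary swim; ≈ 72.3% ST) are reproduced while within-day
autocorrelation, bout structure and day-of-week effects are not.

## Cohort generator and statistics

The outcome model is `y = Xβ + u_country + ε` with `ε ~ N(0, σ)` and
optional country random intercepts. The MVPA and ST coefficients default to
the adjusted whole-section villous-density estimates (0.12 and 0.23; a
second set, 0.17/0.35, for the selected-regions outcome). The nuisance
coefficients (age −0.05, BMI −0.10, GDM −1.0, sex +0.5) are not reported
anywhere and are fixed small plausible values; MVPA/ST recovery does not
depend on them. Outcome SDs are derived from the standardized betas: with
sd(MVPA) = IQR/1.349 = 18.4 min/day, SB = β·sd(x)/sd(y) gives sd(y) ≈ 6.1
(whole section) and ≈ 8.7 (regions, matching the printed 8.9 ± SD);
variance subtraction then sets residual σ = 5.0 and 7.8. The printed
whole-section SD of 0.5 is inconsistent with the tertile medians and the
standardized betas and is treated as a standard error.

Covariates: age Normal(33.3, 5.4); BMI lognormal matched to median 32.9 and
IQR 4.2; GDM/smoking/PE–PIH Bernoulli at 34.8/10.9/9.0%; MVPA gamma with
mean 39.5 and SD 18.4; ST Normal(72.3, 7.6) truncated to [30, 95]; nine
countries of near-equal size.

Statistical conventions fixed here (the workflow states the tests used but
not the selection rules): ANOVA-vs-Kruskal–Wallis is gated by per-group
Shapiro–Wilk at α = 0.05 (groups with n < 3 take the nonparametric path);
tertile cuts are the 33.33/66.67 linear-interpolation percentiles with ties
to the lower group; the mixed-model LRT compares random-slope vs
random-intercept fits by maximum likelihood with a χ²(2) reference
(slope variance + covariance) — anticonservative df bookkeeping aside, the
null pins a variance to the boundary, making the test conservative;
complete-case analysis throughout; GDM serves as both adjustment covariate
and sensitivity-exclusion flag, and is dropped as a covariate in the no-GDM
subset where it is constant.

## Problem sizes and numerical choices

Simulation sizes were chosen for desk-scale runs: coefficient-recovery and
CI-coverage suites use 500–1000 cohorts of n = 92 (OLS recovery is exact to
the normal-equations solution at 1e−8; estimates are invariant to row
permutation at 1e−10); imaging calibration uses 20 slides of 512² px at
2 µm/px (≈ 1 mm² each; real 20× scans are ≈ 0.5 µm/px and ~40 mm², both
reachable through `SlideParams`). Degenerate inputs fail loudly: empty
villous scope raises "no villous tissue"; constant exposure vectors,
rank-deficient designs and single-cluster mixed models raise validation
errors naming the problem.

## Known limitations

Rule thresholds are tied to the configured stain vectors; scanner images
need the trainable classifier plus labeled tiles. Vessel-count recovery
runs ~5% low at 2 µm/px (merged near-touching discs below the watershed
seed separation), well inside the 15% calibration band but systematic.
The mixed-model variance SE is a Wald quantity and unreliable near the
boundary. The accelerometer generator cannot validate bout-based or
raw-acceleration processing.
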