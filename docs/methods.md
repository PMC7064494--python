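# Methods

## Problem and pipeline

The package predicts a binary pregnancy-test outcome (serum b-hCG ≥ 20
mUI/mL seven days after single-blastocyst transfer) from one static
micrograph of the blastocyst plus the patient's age. The pipeline is
deliberately "top-down": hand-annotated anatomy → engineered
morphometric features → classical classifiers, so that it remains
usable at cohort sizes (n ≈ 100–250) where image-to-label deep learning
is not.

Stages:

1. **Annotation ingestion.** Images are 8-bit grayscale with a known
   µm/px calibration. Region annotations delimit three boundaries (ZP
   outer, ZP/TE interface, TE/inner interface), supplied either as
   polygon JSON or as a label-mask PNG. Rasterization assigns a pixel
   to a region when its centre lies inside (or exactly on) the
   enclosing boundary; each boundary is owned by the region it
   encloses. Nesting and simplicity of the polygons are validated, and
   rasterization is checked against a brute-force point-in-polygon
   oracle in the tests.
2. **Feature extraction (24 features).** Eight per region: area,
   perimeter, mean/SD intensity, mean/SD local entropy, Canny edge
   length and edge density. The feature count and the five metric
   families (geometry, intensity pattern variation via an entropy
   filter, its dispersion, and edge content) are fixed contracts of the
   pipeline; the exact 8×3 composition is this package's definition,
   chosen so that each family is measured independently per region.
3. **Reduction.** Features are z-scored (they mix µm², µm, bits and
   8-bit units, so correlation-PCA is the only scale-free choice) and
   projected onto the smallest leading set of principal components
   reaching 99% cumulative explained variance. Age never enters the
   PCA; it is z-scored and appended afterwards. On realistic feature
   tables the rule retains ~12–14 of 24 components.
4. **Evaluation.** Five classifier families under stratified 10-fold
   cross-validation, metrics averaged over folds, best model by F1
   (ties: AUC, then family order naive_bayes → nu_svm → neural_net →
   decision_tree → random_forest). A label-permutation control re-runs
   the identical evaluation on shuffled labels.

## Phantom generator

Real cohorts of transferred blastocysts with outcomes are
access-restricted, so validation uses phantoms: three concentric
ellipses (ZP annulus, TE annulus, inner disk) of constant wall
thickness, random orientation and mild eccentricity, rendered as a
per-region mean intensity plus Gaussian-smoothed noise on a darker
background. Defaults emulate the structure of the clinical cohorts this
pipeline targets: 180 µm nominal embryo diameter; 18 µm zona and 16 µm
trophectoderm walls; two calibration regimes (0.5 and 0.25 µm/px,
standing in for 20x and 40x objectives, split 2:1 by default); ages
~N(34.4, 5.5²) years clipped to (18, 50); positive prevalence 52.98%.

The outcome is drawn from an explicit logistic model on three
standardized per-sample latents — ZP thickness (which also deforms the
rendered geometry), TE noise SD (which also drives the rendered
texture), and age — so the image→outcome signal strength is a testable
knob: zero coefficients give pure-noise labels; the test suite's
"moderate" (0.8/0.6/0.4) and "strong" (2.0/1.5/1.0) settings must
produce monotonically increasing cross-validated AUC. b-hCG magnitudes
are lognormal above/below the 20 mUI/mL threshold; only the threshold
is clinically meaningful. Per-sample seeds derive from
(master seed, index), so cohorts are byte-reproducible and samples
independent. An `exact_prevalence` mode pins the positive count at the
model's expected value via Gumbel-top-k sampling on the logistic
scores, for experiments that must match a stated class balance exactly;
the default remains per-sample Bernoulli draws.

What the phantom does **not** emulate: cell-scale structure (no
trophectoderm cells, no inner-cell-mass/blastocoel contrast), hatching
and expansion morphology, uneven illumination, and optics differences
between objectives beyond pixel pitch. Texture parameters are free
design knobs, not estimates from real micrographs — no quantitative
intensity statistics of such images are available. Consequently,
passing tests demonstrate that the pipeline recovers signal that is
present and reports chance when it is absent; they do not certify
predictive performance on real embryos.

## Parameters

| parameter | default | notes |
|---|---|---|
| entropy radius | 9 px at normalized resolution | disk neighbourhood of the 256-bin, base-2 entropy filter; bounded by [0, 8] bits |
| Canny smoothing σ | 1.0 px | at normalized resolution |
| Canny hysteresis | 60th/90th gradient-magnitude percentiles | adaptive per image because acquisition settings vary freely between microscopes |
| normalization target | 1.0 µm/px | texture/edge operations only; geometry uses native-resolution masks and calibration |
| PCA variance threshold | 0.99 | minimal-k selection |
| ν-SVM | ν = 0.5, RBF γ = 0.14 | ν is unstated upstream; 0.5 is the conventional midpoint |
| neural net | (30, 30, 30, 10), ReLU, Adam, L2 1e-4, 500 epochs | seeded init, no early stopping; non-convergence is warned and the fold still scored |
| decision tree / random forest | unrestricted depth / 100 trees | seeded |
| k folds | 10 | stratified; per-fold class counts within ±1 of proportional |

## Numerical and design choices

- **Micrograph ingestion.** RGB converts by ITU-R 601 luminance; inputs
  deeper than 8 bits max-normalize so the brightest pixel maps to 255
  (absolute exposure is not comparable across devices).
- **Perimeter** is the longest marching-squares contour at level 0.5,
  no sub-pixel smoothing; a 10% estimator tolerance is accepted on
  blocky shapes.
- **Leakage control.** The reduction (standardization + PCA + age
  statistics) is fitted inside each training fold by default. A
  `pca_global` flag fits it once on the whole table, reproducing the
  preprocessing some published pipelines appear to use; it risks
  optimistic estimates and is off by default.
- **Classifier input scaling.** The reduced design matrix (component
  scores + z-scored age) is min-max scaled to [0, 1] per training fold.
  Raw PCA scores carry eigenvalue-sized variances, under which an RBF
  kernel with γ = 0.14 sees only near-zero similarities and the ν-SVM
  degenerates into a constant majority vote; γ = 0.14 is a sensible
  bandwidth precisely for compact-range inputs (it approximates the
  1/(n_features·Var) heuristic at ~15 unit-range features). Tree-based
  families are invariant to this monotone rescaling.
- **Component signs** follow a fixed convention (largest-magnitude
  loading element positive), making repeated fits bit-identical.
- **Degenerate metrics** (zero-denominator precision/F1 in a fold) are
  recorded as 0 with a `degenerate` flag and a warning, keeping fold
  averages defined.
- **AUC** is the normalized Mann–Whitney rank statistic (ties counted
  half), computed per fold and averaged; it is checked against an
  exhaustive pairwise oracle.
- **ν-SVM scores** for AUC are signed decision values. An optional
  regression mode (ν-SVR on 0/1 targets, thresholded at 0.5) exists for
  fidelity experiments with pipelines described in regression terms.
- **Permutation control** permutes labels once per run (seeded),
  preserving the label multiset and hence stratification; chance-level
  F1 under permutation tracks the cohort prevalence, which is why
  control cohorts should match the prevalence under study.

## Problem sizes

The test suite and the acceptance script validate at desk scale:
feature-contract and I/O round-trips on 10–12-sample cohorts; the PCA
rule and signal recovery on 200-sample cohorts (signal levels zero /
moderate / strong); the permutation control on a 134-sample cohort at
52.98% prevalence with 20 permutation seeds; end-to-end byte-stability
on a 44-sample cohort. Extraction runs at well under a second per
image on one CPU.

## Known limitations

- The 24-feature composition is this package's reconstruction of a
  fixed-count contract; other 24-way decompositions of the same metric
  families are possible.
- The inner area pools blastocoel and inner cell mass; no attempt is
  made to separate them, nor to grade expansion/hatching stage.
- Whether texture should be measured before or after resolution
  normalization is a genuine ambiguity; this package normalizes first
  so neighbourhood sizes are physically comparable across objectives.
- Metrics on the phantom say nothing quantitative about clinical
  performance; the phantom exists to validate the machinery, not the
  biology.
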