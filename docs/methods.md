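# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `histoprog`. Everything
quantitative stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from external sources.

## Tissue classes and the global segmentation map

The fixed six-class legend is 0 = BG (glass/background), 1 = LT
(peri-tumor liver), 2 = TT-p (tumor parenchyma), 3 = TT-s (tumor
stroma), 4 = HN (hemorrhage/necrosis), 5 = TLS (tertiary lymphoid
structure); TT denotes TT-p ∪ TT-s. Coordinates are 0-based and
row-major; tile windows are half-open; partial edge tiles are dropped.
The GSM has one cell per tile; the cell value is the argmax of the
tile's class probabilities, with ties broken to the lowest class code.
Connected components use 8-connectivity; both conventions are tested
against brute-force oracles.

A tile's `scale` records its magnification label relative to an
assumed base magnification of 20. In the synthetic pipeline, tiles are
rendered at native resolution and the scale is metadata: magnification
resampling only becomes operative for pyramidal slide sources, which
are out of scope.

## Classifier and risk-model architectures

All learned components are compact and CPU-trainable by design:

- The **tile classifier** is a fixed bank of ~15 tile descriptors
  (RGB moments, HSV saturation/value, hematoxylin-channel statistics,
  Sobel edge energy, and blob statistics of the thresholded stain
  channel) feeding a small MLP head (two hidden layers, 64 and 32
  units, Adam, seeded). Class imbalance is handled by resampling each
  class to the majority count before fitting. The two stages (5-way
  top level; TT-p/TT-s dichotomization) are trained independently and
  composed hierarchically at inference, so non-TT calls equal the
  top-level calls exactly.
- The **risk heads** are linear maps trained by minimizing the Breslow
  negative log partial likelihood (plus a small ridge term, 1e-2, for
  conditioning) with L-BFGS from a zero start — the objective is
  convex, so training is deterministic given the data. GS pools the
  one-hot GSM into class fractions inside/outside the filled tumor
  zone (12 numbers); this pooling is translation-invariant and lets
  the model separate intra- from peri-tumoral TLS. TiRS mean-pools the
  descriptor embeddings of the sampled tiles (a simple
  multiple-instance scheme). CRS concatenates both representations
  before a single jointly trained head.

Scores are z-scored on the training cohort and frozen; the patient
representative is the mean over slides, with min/max/sd (population
convention, divide by n) also reported.

## Survival statistics

`survival_stats` is self-contained: Harrell's C with 0.5 credit for
score ties; the product-limit estimator; the 1-df log-rank test with
hypergeometric variance; Cox regression by Newton–Raphson on the
Breslow partial likelihood (convergence when the largest score
component falls below 1e-8, at most 50 iterations, step-halving, SEs
from the inverse observed information, separation warning at
|beta| > 15); the Mann–Whitney U test with full-enumeration exact
p-values for pooled samples up to 20 and the tie-corrected normal
approximation beyond. Breslow tie handling and two-sided p-values at
α = 0.05 are used everywhere. The median split assigns values strictly
above the median to the high group; exact ties go low. The test suite
cross-checks the C-index, log-rank and Cox fits against lifelines and
against enumeration oracles.

## Interpretation layer

**Occlusion sensitivity.** Windows of `window_cells` (default 4, stride
2) are replaced by the background class — background is used so no
tissue signal is injected — and the risk difference
risk(original) − risk(occluded) is accumulated; overlapping windows
average per cell. Positive values mark risk-elevating regions. The map
of a linear class-count surrogate equals the analytic delta exactly.

**Architectural parameters.** Area ratios are pixel counts; intra-
tumoral ratios use TT pixels as denominator, the peri-TLS ratio uses
LT pixels. A TLS component is intra-tumoral iff its centroid lies in
the hole-filled TT ∪ HN mask. "Distribution variance" — a named but
otherwise unspecified dispersion summary — is defined here as the mean
squared distance of component centroids from their barycenter, divided
by map area (scale-comparable; 0 for one component). Margin smoothness
is the convex-hull perimeter of the tumor mask divided by its boundary
length, clipped to (0, 1]; the boundary length uses the Crofton
perimeter estimator because a raw boundary-pixel count overestimates
diagonal sections and would compress the dynamic range. On synthetic
slides the rank correlation between planted contour irregularity and
(1 − smoothness) exceeds 0.8.

**Nuclear morphometry.** Segmentation: illumination correction (divide
by a heavy Gaussian background estimate) → hematoxylin channel via the
published Ruifrok–Johnston H&E absorbance matrix → Otsu → hole filling
→ distance-transform watershed → discard objects under 40 px² (config)
or touching the border. Measurements are taken on the *raw*
hematoxylin optical density (not the illumination-corrected channel,
whose correction halo would distort intensity features): area,
perimeter, eccentricity, orientation, solidity, central moments to
order 3, mean and integrated-edge intensity, GLCM
contrast/entropy/correlation (16 levels, offsets {1, 2} px, 4
directions averaged, out-of-mask co-occurrences removed), and three
equal-area radial intensity fractions. Tiles need ≥ 3 nuclei; tile
vectors are mean/median/sd per measurement, z-scored across tiles.
This ~60-column vector is a deliberately compact counterpart of a full
CellProfiler export: it covers every feature family used for
interpretation without reproducing the full export schema.

**Lasso association.** scikit-learn coordinate descent at tolerance
1e-7; the lambda path is anchored at λ_max = max|Xᵀ(y − ȳ)|/n (all
coefficients zero) and the working λ minimizes seeded k-fold CV MSE.
The reported "selected" support comprises coefficients within an
order of magnitude (≥ 10%) of the largest, since CV-minimum solutions
retain tiny noise coefficients that no analyst would report. The
response may be the continuous TiRS or a ±1 high/low label.

**Omics.** ssGSEA follows the standard single-sample formulation: per
sample, genes are ranked descending (average ranks on ties) and the
score is the summed difference between the |rank|^0.25-weighted in-set
ECDF and the unweighted out-of-set ECDF, then the whole score matrix is
rescaled by its global max−min spread. Immune scores are marker-gene
means of log expression. Set scores are correlated with TiRS by
Spearman's rho with BH correction across sets; Spearman is chosen for
rank-robustness. Proteomic matrices flow through the same code path.

## The synthetic-data generator

The generator defines the study conditions; its defaults are fixed
and the tests run at these conditions.

- **Geometry.** The tumor is an ellipse centred on the canvas with
  radial contour perturbation ρ ≤ 1 + a·sin(fθ + φ); the amplitude
  `a` is the planted irregularity, f is drawn from {5, 6, 7} (high
  enough that amplitude maps monotonically to concavity), φ uniform.
  Necrosis is planted by thresholding low-pass Gaussian noise at the
  exact within-tumor quantile, so the realized HN fraction matches the
  specification to pixel resolution; the remaining tumor is a smoothed
  random mosaic of parenchyma and stroma (thresholded low-pass noise),
  interleaving the two as in desmoplastic tumors rather than as
  annuli. TLS discs are rejection-sampled (1000 attempts, then a
  placement error) with centers strictly inside (or outside) the tumor
  by more than one radius, so the intra/peri ground truth is
  unambiguous. A background frame models the glass margin.
- **Rendering.** Per-class base colors with Gaussian speckle; nuclei
  are perturbed ellipses (third-order contour distortion, random
  orientation and axis ratio) at class-specific densities per 256²
  tile (defaults: TT-p 150, TLS 500, LT 60, TT-s 40 — the TLS/LT ratio
  mimics lymphocyte aggregates). Mean parenchyma nucleus area scales
  as base_area·(1 + 0.3·risk) with the planted nucleus-size risk; a
  per-tile lognormal area jitter (sd 0.15) models within-slide
  heterogeneity, which is what makes 1-tile models noisier than
  32-tile models.
- **Survival.** Planted features are drawn per patient from documented
  distributions (necrosis U(0, 0.4), stroma U(0.2, 0.7), irregularity
  U(0, 0.22), TLS counts uniform on 0–4, nucleus-size factor standard
  normal), standardized by their population moments, and combined by
  the `beta` coefficients into η; times are Exponential(h₀·e^η) with
  h₀ = 0.02/month. Censoring is an independent exponential whose rate
  is calibrated by bisection on the realized sample so the censored
  fraction lands within ±0.05 of the target (0.3 by default) — no
  censoring model is claimed beyond this calibration. Patients with
  several slides re-draw slide parameters with multiplicative
  lognormal jitter (sd 0.05, a free parameter not claimed faithful to
  any measured inter-section variability).
- **Expression.** Genes in a set shift by effect·risk on the log scale
  plus N(0, 1) noise; background genes are pure noise.
- **Seeding.** All randomness flows from one root seed through named
  CRC-keyed substreams; equal seeds give byte-identical outputs.

What the generator does **not** emulate: stain variation and scanner
artifacts, realistic chromatin texture, nucleus crowding/overlap
statistics, spatially correlated survival confounders, multi-
resolution pyramids. Passing tests therefore demonstrate that the
implementation recovers structure it is pointed at — not that the
learned models transfer to real H&E slides.

## Problem sizes and numerics

The benchmark suite runs at reduced sizes chosen to keep a full run on
one CPU around five minutes while leaving all recovery margins wide:
192×192-px slides, 8-px GSM cells (24×24 GSMs), 64-px rendered tiles,
16 tiles per slide for consensus training, cohorts of 150–300
patients, and 20 replicate cohorts for the end-to-end recovery check.
Tile and GSM sizes are configurable; nothing in the code depends on
the reduced values.

Numerical conventions collected in one place: Breslow ties everywhere;
risk-head ridge 1e-2; Cox Newton tolerance 1e-8 (max 50 iterations);
lasso tolerance 1e-7; GSM argmax ties to the lowest class code;
z-scores frozen on training data; population sd for patient
aggregates; NaN codes a missing architectural feature (empty
denominator or no components) and such features are skipped, not
zero-filled, in the univariate Cox tables.

## Known limitations

- The classifier and risk heads are deliberately small; they establish
  correctness of the surrounding machinery, not state-of-the-art
  accuracy on real slides.
- The GS representation pools over two spatial zones; finer spatial
  weight maps (per-cell weights) would need regularization schemes not
  explored here.
- Exact Mann–Whitney enumeration is limited to pooled samples of 20.
- ssGSEA reproduces the rank-based single-sample formulation only; no
  kernel-CDF variants.
- The occlusion map re-scores the full GSM per window (O(windows)
  model evaluations); fine strides on large grids are correspondingly
  slower.
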