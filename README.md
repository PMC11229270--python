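# histoprog

Interpretable whole-slide-image (WSI) prognosis for intrahepatic
cholangiocarcinoma (iCCA) and similar solid tumors: tissue-class
segmentation maps, survival-trained risk scores, and a full
interpretation layer — occlusion attribution, architectural
tumor-microenvironment parameters, nuclear morphometry, and omics
correlation. The whole pipeline is exercised end to end on synthetic
slides with planted, recoverable ground truth, so every stage is
testable without access to patient data.

Intended users: computational pathology researchers who want a tested,
CPU-friendly reference implementation of the stepwise
"segment → score → interrogate" prognosis workflow.

## The model

A slide is divided into non-overlapping 256×256 tiles (size
configurable for small synthetic slides). A two-stage tile classifier
assigns each tile one of six classes — background (BG), peri-tumor
liver (LT), tumor parenchyma (TT-p), tumor stroma (TT-s),
hemorrhage/necrosis (HN), tertiary lymphoid structure (TLS) — and the
argmax classes form the **global segmentation map (GSM)**, one cell per
tile.

Three risk scores are trained with the negative log Cox partial
likelihood (Breslow ties) as the objective, using overall survival
(time `T`, event `δ`) as the label:

- **GS** (GSM score): zonal class-composition pooling of the one-hot
  GSM (class fractions inside/outside the filled tumor zone) → linear
  risk head.
- **TiRS** (tile risk score): `n` tiles sampled from the slide
  (global-random, tumor-only, or parenchyma-only; default 32 tiles) are
  embedded with a fixed descriptor bank, mean-pooled, and mapped by a
  linear risk head.
- **CRS** (consensus risk score): the concatenated GS and TiRS branch
  representations share one jointly trained risk head.

Scores are z-scored on the training cohort (they are relative risks);
patients with several slides are summarized by the mean score, with
min/max/sd also reported. Model quality is measured by Harrell's
concordance index

C = Pr(score_i > score_j | T_i < T_j, δ_i = 1),

and high/low median-split groups are compared by Kaplan–Meier curves
with the log-rank test. All survival statistics (C-index, KM, log-rank,
Newton–Raphson Cox regression, Mann–Whitney U with exact small-sample
p-values) are implemented in `histoprog.survival_stats` and
cross-checked against independent oracles in the test suite.

The interpretation layer deconstructs a trained GSM model with
**occlusion sensitivity maps** (risk change when a window of the GSM is
replaced by background; positive = risk-elevating) and a predefined
**architectural parameter set**: area ratios of HN / TLS / TT-p / TT-s
to tumor or liver tissue, spatial dispersion of TLS and HN components,
invasive-margin smoothness (convex-hull perimeter over boundary
length), and TLS-to-margin distances — each tested in univariate Cox
models. Tile-level interpretation segments nuclei
(stain separation → Otsu → watershed), measures ~20 shape / intensity /
texture / radial features per nucleus, aggregates mean/median/sd per
tile, and associates the tile features with TiRS by cross-validated
lasso. `histoprog.omics_link` scores gene sets per sample (ssGSEA),
computes marker-mean immune scores, and correlates both with TiRS
(Spearman, Benjamini–Hochberg across sets).

## Worked example

Simulate a 150-patient cohort whose hazard loads on necrosis extent
(harmful), intra-tumoral TLS (protective) and nucleus size (harmful),
train the consensus model on 100 patients, and interrogate it:

```python
import numpy as np
from histoprog import synthetic_data as sd, risk_models as rm
from histoprog import survival_stats as ss, interpret_architecture as ia

slide = sd.SlideSpec(height_px=192, width_px=192, tumor_axes=(60, 52),
                     tls_radius_px=8)
render = sd.RenderSpec()
cohort = sd.CohortSpec(
    n_patients=150, baseline_hazard=0.02,
    beta={"necrosis_ratio": 0.8, "intra_tls_ratio": -0.8,
          "nucleus_mean_area": 0.8},
    censor_rate_target=0.3, seed=7)
patients, slides, truth = sd.generate_cohort(cohort, slide, render)

gsms = {s.slide_id: sd.oracle_gsm(s.label_map, 8) for s in slides}
tiles = sd.CohortTileSource(slides, truth, render, seed=7)

train, test = patients[:100], patients[100:]
cfg = rm.RiskTrainConfig(tile_count=16, strategy="parenchyma_only", seed=7)
crs = rm.train_consensus(gsms, tiles, train, cfg)

surv = ss.SurvivalData([p.time_months for p in test],
                       [p.event for p in test])
scores = np.array([np.mean([crs.score_slide(gsms[s], tiles)
                            for s in p.slide_ids]) for p in test])
print(f"held-out CRS C-index: {ss.harrell_c(surv, scores):.3f}")

groups = ss.median_split(scores)
chi2, p = ss.logrank(
    ss.SurvivalData(surv.times[groups == 0], surv.events[groups == 0]),
    ss.SurvivalData(surv.times[groups == 1], surv.events[groups == 1]))
print(f"log-rank high vs low CRS: chi2 = {chi2:.2f}, p = {p:.4f}")

fv = ia.architectural_features(slides[100].label_map)
print(f"necrosis/TT area ratio: {fv.ratio_hn_TT:.3f}")
print(f"intra-TLS/TT area ratio: {fv.ratio_tls_intra_TT:.3f}")
print(f"margin smoothness: {fv.margin_smoothness:.3f}")
```

Output:

```
held-out CRS C-index: 0.726
log-rank high vs low CRS: chi2 = 8.33, p = 0.0039
necrosis/TT area ratio: 0.264
intra-TLS/TT area ratio: 0.052
margin smoothness: 0.948
```

The C-index of 0.726 on 50 held-out patients shows the consensus model
recovered the planted prognostic structure (0.5 is chance); the
log-rank p confirms that the median split separates survival; the
architectural parameters quantify what the slide shows (26% of tumor
tissue necrotic, a small intra-tumoral TLS burden, a smooth invasive
margin).

A command-line interface mirrors the library
(`histoprog simulate / build-gsm / sample / train-classifier /
train-risk / occlude / arch-features / nuclei / omics / km`); run
`histoprog --help`.

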