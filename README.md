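# islet-cytotyper

Label-free recognition of α and β cells in living human islets of
Langerhans, from autofluorescence-intensity and phasor-FLIM micrographs.

Human islets intermingle glucagon-secreting α cells and insulin-secreting
β cells; telling them apart normally requires fixation and immunostaining,
which destroys the living tissue. This package implements, as a tested and
reusable pipeline, a machine-learning route around that: the intrinsic
NAD(P)H and lipofuscin autofluorescence of each segmented cell — collected
as an intensity image plus per-pixel fluorescence-lifetime phasor maps at
two glucose concentrations (2.2 mM and 16.7 mM) — is distilled into 151
numeric features per cell, and a boosted-decision-tree classifier trained
on immunofluorescence-derived labels predicts cell identity for new,
unstained cells. A synthetic-islet generator reproduces the statistical
structure this analysis relies on (2:1 β:α abundance, twofold β lipofuscin
content, a β-specific glucose-stimulated metabolic shift), so every stage
is testable without access to the original microscope data.

## The model in brief

**Phasor transform.** A per-pixel lifetime decay `c(t)` over one laser
period (80 MHz → 12.5 ns) maps to phasor coordinates

```
g = Σ c(tᵢ) cos(ω tᵢ) / Σ c(tᵢ),   s = Σ c(tᵢ) sin(ω tᵢ) / Σ c(tᵢ),  ω = 2π/T.
```

Monoexponential decays of lifetime τ fall on the universal semicircle
`(g − ½)² + s² = ¼` at `g = 1/(1+(ωτ)²)`; mixtures of free (τ ≈ 0.4 ns) and
protein-bound (τ ≈ 3.4 ns) NAD(P)H fall on the chord between the two pure
points, so a cell's phasor barycenter reads out its glycolytic/oxidative
balance, and the barycenter displacement between low and high glucose —
projected on the free→bound axis — is its metabolic-shift descriptor.

**Features.** Per cell and glucose condition: descriptive statistics
(min, max, mean, median, sd, quartiles, Tukey whiskers, modal bin,
skewness) of the intensity over all / lipofuscin / non-lipofuscin pixels
and of the lipofuscin-excluded g and s maps; phasor-cloud barycenter and
dispersion; lipofuscin granule area fraction and counts (bright-outlier
segmentation at median + 3·MAD, 8-connected components); cell area,
perimeter and circularity `4πA/P²`; donor age, BMI and insulin stimulatory
index; and the glucose-condition encoding — 151 columns in a frozen,
versioned schema.

**Classification.** Cleaning (manifest-driven), zero imputation (missing
means absent signal), local-outlier-factor row substitution, min-max
scaling, a cell-grouped stratified split, SMOTE rebalancing of the 2:1
training imbalance to 1:1, then repeated stratified 5×3 cross-validated
tuning of an XGBoost classifier with ROC-AUC as the objective, gain-based
importance ranking with feature-cutoff selection, and a stability battery:
tenfold CV variant, the Salzberg label-shuffle control, and classification
of the cleaning-excluded records.

## Worked example

Generate a 300-cell synthetic islet cohort and run the whole pipeline:

```bash
echo '{"n_cells": 300, "seed": 0}' > demo_cfg.json
islet-cytotyper run --config demo_cfg.json --seed 1 --budget 10 --out demo_run
```

On this configuration the summary (`demo_run/summary.json`) reports:

* `synth`: 600 rows × 151 features (300 cells × 2 glucose conditions),
  400 β / 200 α rows — the 2:1 abundance of the tissue.
* `explore`: the first two principal components explain 30% + 21% of the
  variance; the two-cluster k-means baseline reaches ROC-AUC **0.587** and
  the mean Gini impurity at the elbow is **0.42** — unsupervised clustering
  captures only mild cell-type structure, motivating the supervised model.
* `evaluate`: held-out ROC-AUC **0.870**, with β precision 0.81 > α
  precision 0.65 — the class asymmetry expected when β-specific effects
  (lipofuscin load, metabolic shift) carry most of the signal and β cells
  are twice as abundant.
* `stability.salzberg`: retraining the identical pipeline on shuffled
  labels collapses the held-out ROC-AUC to **0.416** (a 52% relative
  drop), confirming the score is signal, not pipeline leakage.

The top-ranked features (`s_high_q1`, `shift_delta_g`,
`lipo_granule_count_high`, …) are exactly the phasor, metabolic-shift and
lipofuscin quantities the generator endows with class information.

The library surface mirrors the pipeline: `synthetic_islet` (cohort and
feature-matrix generation), `phasor_core` (decay→phasor, cloud summaries,
granule segmentation, metabolic shift), `cell_features` (schema and
extraction), `explore` (PCA, WCSS elbow, Gini, cluster AUC), `preprocess`
(cleaning → SMOTE chain), `classify` (four model families, tuning,
importances, cutoff sweep), `stability` (metrics and controls), and
`pipeline`/`cli` for orchestration. See `docs/methods.md` for the science
and the design choices.

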