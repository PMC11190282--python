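# Methods

This note documents the models, conventions and design choices behind
`islet-cytotyper`, in the package's own terms: what each stage computes,
which knobs matter, what the synthetic generator does and does not
emulate, and the numerical decisions that had to be frozen for
reproducibility.

## Phasor-FLIM model

Each pixel's fluorescence decay is histogrammed over one laser period
(repetition rate 80 MHz, period T = 12.5 ns, 256 bins by default) and
transformed at the first harmonic:

    g = Σᵢ cᵢ cos(ω tᵢ) / Σᵢ cᵢ,  s = Σᵢ cᵢ sin(ω tᵢ) / Σᵢ cᵢ,  ω = 2π/T.

For a wrapped (periodically re-excited) monoexponential decay the
continuous transform is exactly `g = 1/(1+(ωτ)²)`, `s = ωτ/(1+(ωτ)²)` — the
universal semicircle — and the 256-bin discretization perturbs this by
less than 3·10⁻⁴, which sets the 10⁻³ tolerance used in the analytic
tests. Photon-weighted mixtures transform linearly, so two-component
free/bound NAD(P)H pixels fall on the chord between the two pure-lifetime
points. Only the first harmonic is used; multi-harmonic analysis and
instrument-response deconvolution are out of scope.

Conventions, fixed once:

* **Cloud summaries** are frequency-weighted means; dispersion uses the
  population convention (divide by total weight), so a single point has
  sd exactly 0.
* **Non-physical points** (outside the semicircle disk, possible under
  photon noise) are flagged, never clamped — clamping would distort the
  dispersion statistics the classifier consumes.
* An **all-zero decay** yields a missing phasor, which propagates as an
  absent feature and is imputed to zero downstream (absence of signal is
  meaningful: no NAD(P)H, no lipofuscin).

## Lipofuscin segmentation

Granules are segmented per cell as intensity outliers above
`median + n_mads · MAD` (default `n_mads = 3`), grouped by 8-connectivity,
with components under `min_size = 4` px discarded. The MAD is **one-sided**
(median deviation of the below-median pixels only): granules are always
bright, and a two-sided MAD inflates once granules occupy more than
roughly 15% of the cell, raising the threshold and under-segmenting
exactly the lipofuscin-rich cells the measurement is supposed to
characterize. With the one-sided estimator the threshold is governed by
the background texture alone for any granule load below 50% of the cell.
Both knobs are config-exposed. The granule set feeds area fraction
(granule px / cell px), counts and granule-area summaries; granule pixels
are excluded from all NAD(P)H phasor statistics (pixel exclusion, not
vector subtraction in phasor space — the simpler of the two and the one
that needs no model of the granule spectrum).

## Morphology

Area is the pixel count (times `pixel_size²`; the default pixel size of 1
leaves features in pixel units — the classifier is scale-insensitive after
min-max scaling). The perimeter is measured by contour tracing: the
marching-squares boundary at the 0.5 level, smoothed with a 3-point
moving average to remove the rasterization staircase, summed as a closed
polygon. Among the estimators evaluated (chain-code, Crofton, raw and
smoothed contours) this is the only one that keeps a rasterized disk's
circularity `4πA/P²` within [0.95, 1.05] while a square mask stays near
π/4 — both anchors the feature is expected to satisfy. Masks must be a
single 8-connected component with non-empty interior; one-pixel-wide
degenerate masks are rejected with the offending cell named.

## The 151-feature schema

The published feature list is not available in full, so the schema is
reconstructed from its described families and frozen in a versioned JSON
sidecar: a (signal × pixel-subset × condition × statistic) grid — intensity
over {all, lipofuscin, non-lipofuscin} pixels × {low, high} glucose × 12
statistics (72 columns), lipofuscin-excluded g and s maps × condition × 12
(48), phasor-cloud barycenter/sd per condition (8), six metabolic-shift
descriptors, three morphology values, eight lipofuscin quantities, two
integrated intensities, three donor covariates and the glucose encoding —
exactly 151 columns. "Trends" is interpreted as (population) skewness and
"range of most common values" as the center of the fullest bin of a fixed
64-bin histogram over [min, max]; quantiles use linear interpolation;
Tukey whiskers are the most extreme observations within 1.5·IQR of the
quartiles. These interpretations are frozen in the schema descriptors so
column semantics are reproducible.

Row layout follows the deposited-data convention: each cell contributes
one row per glucose condition (966 cells → 1932 rows), distinguished by
the `glucose_code` column, with the label replicated across a cell's
rows. Because the two rows share all cross-condition features, the
train/test split groups by cell so no cell straddles the boundary; a
row-level split would place near-duplicates on both sides and inflate
held-out scores. A `per_cell` layout (one row per cell) is available.

## Synthetic islet generator

The generator defines the conditions under which the pipeline is tested:

* **Composition**: β fraction 2/3 (the deposited 654:312 ratio), four
  donors with ages uniform on 46–85, BMI on 23.0–27.7 and stimulatory
  index on 1.0–4.0 (the only donor statistics available; SI range chosen
  as a typical ELISA-derived stimulation ratio), 15 islets, intermingled
  (spatially random) type placement.
* **Cells**: star-convex polygons (16 vertices, radius perturbation
  ≤ 20%, radius ~ N(14, 2) px clipped at 8), rasterized to masks.
* **Decays**: per pixel, `I(t) = A·[f_b e^(−t/τ_bound) + (1−f_b) e^(−t/τ_free)]`
  with τ = 0.4/3.4 ns, 256 bins over 12.5 ns, Poisson photon noise per
  bin; intensity is the per-pixel photon total and the g/s maps are the
  phasor transform of the same decays, so every phasor identity holds by
  construction. `f_b` is the amplitude fraction of the bound component:
  0.25 at low glucose for both types, rising by 0.10 (β) versus 0.02 (α)
  at high glucose — the β-specific oxidative shift. Cell-level scatter
  (sd 0.08, shared across conditions) and residual per-condition scatter
  (sd 0.04) make the shift a noisy, realistic discriminator.
* **Lipofuscin**: per-cell Poisson granule counts with β mean = 2× α mean
  (2.0 vs 4.0 by default), granule radii 2–6 px weighted toward small
  (0.5/0.3/0.13/0.05/0.02), each granule a bright disk (3–6× the cell's
  NAD(P)H level) with a fixed τ = 1.2 ns phasor signature. Placement uses
  best-candidate rejection sampling in a zone of 0.85× the cell radius and
  total nominal granule area is capped at 45% of the cell: granule overlap
  would otherwise deflate the high-count class's total area
  disproportionately, compressing the configured 2× area-fraction effect,
  and loads above ~50% would put the segmentation threshold's median on
  granule signal. Boundary clipping, unlike overlap, affects both classes
  proportionally and is tolerated.
* **Brightness**: lognormal cell budgets (median 60 photons/px for α, 66
  for β, σ = 0.45), lognormal donor multipliers (σ = 0.35) and pixel
  texture (σ = 0.2). The deliberate choice here is that most of the β
  intensity excess emerges *through* lipofuscin granules rather than from
  a large imposed NAD(P)H gap; together with the scatter levels this
  places the synthetic task in the difficulty regime the method is
  reported to face on real tissue (held-out ROC-AUC around 0.85–0.90, β
  precision above α precision) instead of a saturated, trivially
  separable one.

Two generation paths consume identical per-cell random streams: the islet
renderer composites non-overlapping cells into shared 512×512 canvases
(one per condition), while the fast path renders each cell in its own
bounding box and extracts features directly. Because placement does not
alter per-cell pixels, the two paths agree bit-for-bit and serve as
mutual oracles in the tests. Seeds derive from a single `SeedSequence`
spawn tree, so a fixed seed yields bit-identical cohorts.

What the generator does **not** emulate: photophysics beyond
two-component NAD(P)H plus a single lipofuscin species, 3D islet
geometry, cell–cell contact effects, segmentation errors, focal-plane
mismatch between conditions, and immunofluorescence channels. Passing
tests therefore demonstrate that the pipeline recovers the effects it
assumes, at realistic noise — not that those effects suffice on any
particular real instrument.

## Exploratory analysis

PCA is mean-centered with the component sign fixed by the
largest-|loading|-positive convention. WCSS is normalized by the total
point count (`(1/N) Σ min‖xᵢ − cⱼ‖²`), making it invariant to duplicating
the data. K-means uses k-means++ with 10 restarts and a fixed seed. The
elbow is the interior point of maximum discrete curvature of the WCSS
curve **on a log scale** (second difference of log WCSS): raw-scale second
differences are dominated by the large early-k drops and systematically
under-shoot the knee, whereas the log rule asks where the *relative*
per-cluster improvement collapses and recovers k = 10 exactly on
ten equally separated blobs. A knee is flagged low-confidence when its
curvature peak is shallow (< 0.25 log units) or barely dominates the rest
of the curve — the signature of a structureless single-cluster decay.
Gini impurity is `G(j) = 1 − Σ_k (n_kj/n_j)²` per cluster, averaged
**unweighted** over clusters (this differs from pooled impurity; empty
clusters are excluded with a warning). The two-cluster baseline scores
each point by its cluster's β fraction, making the ROC-AUC invariant to
cluster relabelling; a degenerate single-cluster outcome scores 0.5.

## Preprocessing chain

Frozen order: clean → encode → impute → outliers → scale → split → SMOTE.
Cleaning is manifest-driven (reason-coded cell ids: ambiguous identity,
rearrangement, focal-plane mismatch, shape change, duplicate), with exact
duplicate rows dropped; the excluded partition is retained for the
stability battery. Missing values become zeros (absence of signal). The
local outlier factor (20 neighbors, auto contamination) flags whole rows;
every feature of a flagged row is replaced by the feature's mean over
inliers (LOF is a row-level detector; finer granularity would be
arbitrary). Min-max scaling maps the fitted minimum to 0 and maximum
to 1; constant features map to 0; unseen values are not clipped. In the
default mode all fitted statistics come from the training partition only
and SMOTE (synthetic rows `x + u(x_nn − x)`, u ~ U(0,1), k = 5 minority
neighbors) is applied to the training partition only, because the held-out
set is meant to be untouched real data; a `pool_before_split` mode fits and
rebalances on the whole cleaned dataset before splitting, for replication
of analyses that rebalance the pooled dataset. The test fraction of 0.25 reproduces the reference
arithmetic (861 cleaned records → 216 held out).

## Classification and tuning

Four families — logistic regression, boosted trees (XGBoost), an SVC and
k-nearest neighbors — are tuned by repeated stratified cross-validation
(5 folds × 3 repeats; a tenfold variant re-runs everything at 10 folds)
with ROC-AUC as the objective. The hyperparameter spaces are compact
declared grids (not replicas of any published space); search is either
exhaustive or a seeded uniform sample of the grid with an optional
median-rule pruner (a trial is abandoned when its partial mean falls
below the median of earlier trials at the same fold checkpoint, after at
least three completed trials). Class-weight balancing is exposed but off
by default when SMOTE is on, to avoid double-correcting the imbalance.
Boosted-tree importances are gain-based, normalized to sum to 1; the
cutoff sweep retrains on the top-m features and breaks score ties toward
fewer features. The decision threshold is 0.5 throughout, configurable.
Determinism: model seeds, CV seeds and search seeds are all derived from
the stage seed, and two runs of the same configuration produce identical
reports.

## Stability battery

Held-out metrics are class-wise (β and α precision/recall/F1 reported
separately, never averaged); metrics with zero denominators are reported
as missing, never as 0. The Salzberg control retrains the identical
pipeline (same CV, search and budget) on label-shuffled training data and
reports shuffled train and test metrics beside the real run's, with
relative drops for both — the three interpretations of a "drop" (train,
test, both) are all printed. Classification of the cleaning-excluded
records uses the final model and the training-fitted preprocessing state.

## Problem sizes and runtime

The study-scale checks run on a 900-cell cohort (1800 rows) with a
50-trial sampled search — sizes chosen so the full suite completes in
roughly a quarter hour on a single core while keeping every class-effect
estimate well inside its tolerance (for example, the 2× lipofuscin ratio
is recovered within 10% at n = 900, where its sampling SE is ~5%).
Smaller fixtures (60–300 cells) cover structural and determinism
properties. The acceptance script's quantities are desk-scale and exact.

## Known limitations

* The schema's column *names* are a reconstruction; analyses that depend
  on the original supplementary feature list column-for-column will match
  in structure and semantics but not necessarily in order or naming.
* The generator's per-condition rows duplicate cross-condition features
  by construction; models trained on this layout lean on the grouped
  split for honest evaluation.
* CV scores on the rebalanced training partition are optimistic (SMOTE
  neighbors of a row can land in its validation fold); held-out metrics
  are the quantity to trust, and the Salzberg control guards the
  pipeline end to end.
* The proprietary microscope container is not parsed; rasters enter as
  TIFF (or the generator's in-memory bundles), with conversion expected
  upstream.
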