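# Methods

This note documents the models, parameters and numerical choices behind
`nanohisto`, in the order the pipeline runs.

## 1. Synthetic stained-tissue fields (`synthgen.make_tissue_image`)

Each field is a 512 × 512 multichannel raster (intensities in [0, 1]) with
nine channels: CD31, lectin, αSMA, VEGFR2, LYVE-1, collagen I, collagen IV,
F4/80 and nuclei.

**Vessels.** CD31⁺ vessels are filled ellipses with semi-axes drawn
uniformly from the profile's radius range (default 3–7 px) and random
orientation. Placement is rejection sampling (≤ 10 000 retries, then an
explicit placement-failure error) with bounding-circle separation of 3 px,
so objects can never touch even diagonally — 8-connectivity segmentation
therefore recovers the rendered count exactly. Profiles are validated so
vessels can cover at most 40% of the field, which keeps disjoint placement
feasible.

**Co-stains.** Each co-stain channel (lectin, αSMA, VEGFR2, Col I, Col IV)
re-renders `round_half_up(fraction × n_vessels)` of the *same* ellipses,
chosen by seeded sampling without replacement. Because the full footprint
is re-rendered, an object's overlap with the co-stain channel is either
100% or 0%, and the 30% double-positivity rule recovers the subset exactly.

**Macrophages.** The F4/80 channel is filled with random disks (radius
4–12 px) whose pixels are added until the requested area fraction is hit
*exactly* at the pixel level (the last disk is trimmed in draw order).
The budget is split between the central quarter of the field and its
complement in proportion to area, so the emulated 20× crop (central
quarter) sees the same area fraction as the full 10× field.

**Noise.** Uniform background noise (default amplitude 0.2) is added to
every channel last. Stained pixels render at 0.9; profiles are validated so
the noise amplitude stays strictly below the default segmentation threshold
of 0.5, hence thresholding recovers the noiseless masks exactly. This is a
deliberate idealization: the generator provides unambiguous ground truth
for round-trip testing, not realistic stain texture (no uneven
illumination, no stain bleed-through, no out-of-focus blur). Passing the
round-trip tests shows the operators are correct, not that they are robust
to real-slide artefacts.

**Packaged profiles.** Three profiles encode the training panel's printed
per-model quantification: CT26 (89 vessels, 54.9% lectin⁺, 7.7% F4/80 AF),
A431 (28 vessels — the printed mean of 28.5 rounded to an integer object
count — 91.3% lectin⁺, 2.2% AF) and MLS (62.7% lectin⁺, 5.1% AF). Values
not printed numerically were set once to plausible mid-range defaults: MLS
total vessels 55 (between A431 and CT26, consistent with its intermediate
accumulation); αSMA/VEGFR2/Col I/Col IV co-stain fractions 0.30–0.60;
LYVE-1 counts 22/11/12 for CT26/A431/MLS (the high accumulator having
about twice the lymphatics of the other two); nuclear densities 450–500
per field.

## 2. Feature quantification (`histoquant`)

Segmentation is plain thresholding (default 0.5) followed by 8-connected
component labelling (the common default of interactive image-analysis
tools) with a minimum object size of 8 px; both are overridable. An
A-object counts as B-positive when ≥ 30% of its pixels are supra-threshold
in B — robust to rim effects on ring-shaped vessel profiles. The 23-feature
panel mixes three modes (absolute counts, area fractions, relative
fractions of CD31⁺ vessels) at two magnification bases; 20×-basis features
are computed on the central quarter crop of the 10× field, a deterministic
stand-in for acquiring a second magnification. The exact membership of the
full published panel is not public; the registry ships the features named
in the main analysis plus the natural per-channel counts/area fractions to
reach 23, and `compute_feature_panel` accepts any user-supplied panel. A
missing channel yields missing feature values rather than an error, so the
learner's missing-data path is exercised end to end.

`%ID` readouts are normalized to the 250 mm³ reference volume by linear
rescaling `raw × (250 / volume)`. Drug exposure over time is the plain
trapezoid rule; trendlines are ordinary least squares with
R² = 1 − SS_res/SS_tot.

## 3. Synthetic animal panel (`synthgen.make_feature_dataset`)

The table emulates the 14-animal training study: animals are cycled over
three tumour-model archetypes and causal features are drawn per animal
around the printed per-model means —

| archetype | CD31 count | F4/80 AF |
|-----------|------------|----------|
| A431-like | 28.5 ± 4.4 | 0.022 ± 0.012 |
| MLS-like  | 55.0 ± 8.0 | 0.051 ± 0.015 |
| CT26-like | 89.0 ± 10.4 | 0.077 ± 0.018 |

Vessel spreads are the printed image-level standard deviations scaled by
1/√12 for the twelve images averaged per animal; TAM spreads encode the
large between-animal heterogeneity of macrophage infiltration (CV roughly
25–55%). The outcome is

    accumulation = intercept + β_vessel·CD31 + β_TAM·F4/80AF + ε,
    ε ~ N(0, noise_sd²)

with defaults intercept 2 %ID, β_vessel 0.05 %ID/vessel, β_TAM 50 %ID per
unit area fraction and noise_sd 0.3 %ID, giving per-model outcomes of
roughly 4.5/7.3/10.3 %ID — matching the span of the measured accumulation
data. The remaining 21 features are nuisance variables: scaled/shifted
copies of one causal feature's z-score mixed with independent Gaussian
noise at correlation ρ (default 0.5), preserving — controllably — the
inter-correlation of real microenvironment panels. Missing cells are
injected uniformly over the feature columns (default 5%), never in the
outcome. The clustered design matters: with unclustered (uniform) causal
features, no learner of this class predicts a 14-sample leave-one-out
panel well, because the 21 nuisance dimensions dominate the greedy split
search; grouping animals into tumour models is both what the emulated
study actually did and what makes its cross-validation informative.

## 4. Gradient tree boosting (`gtb`)

Squared-error boosting: base prediction = mean outcome; each tree fits the
current residuals; predictions add `learning_rate ×` leaf value. Defaults
follow the emulated analysis: 10 trees, maximum depth 8, and a learning
rate of 0.3 (a conventional mid-range choice; the emulated analysis used
an unstated rate). `min_leaf` defaults to 1. There is no row or feature
subsampling, so the fit is fully deterministic.

**Splits.** Exhaustive search over every feature and every midpoint
between consecutive distinct observed values; variance reduction decides.
Missing values are excluded from the threshold statistics; each internal
node learns a default direction — the child assignment minimizing the
post-split squared error (ties default left) — which is reused for missing
values at prediction (the sparsity-aware rule familiar from xgboost).
A split must strictly reduce the node SSE (tolerance 10⁻¹²) or the node
becomes a leaf.

**Tie-breaking.** Exact ties in variance reduction are frequent at small
nodes, where many features induce the very same sample partition (at a
two-sample node, *every* separating feature does). Breaking such ties by
column position would hand every tied split to the leftmost column of the
feature table, making occurrence-based importance an artifact of panel
ordering; in experiments the macrophage feature went from unused to
top-ranked merely by moving its column. Ties are therefore resolved toward
the feature whose observed values are most strongly |Pearson|-correlated
with the tree's current residuals (then lower index, then lower
threshold) — deterministic, invariant to column order, and attributing
co-equal splits to the feature most associated with the response. This
sensitivity of occurrence-based importance to tie attribution at small n
is a genuine limitation of the statistic worth remembering when reading
importance rankings from any implementation.

**Evaluation.** Leave-one-out cross-validation (each of the n samples
predicted by a model trained on the other n − 1) suits the very small
sample sizes of in vivo accumulation studies. The reported R² between
measured and predicted is the squared Pearson correlation (what one reads
off a predicted-vs-measured scatter with a fitted line); 1 − SS_res/SS_tot
is available as an option and can be negative for a predictor worse than
the mean. Feature importance is the occurrence statistic: a feature's
share of the ensemble's internal nodes, reported as mean and population SD
(ddof = 0) across the LOO fold ensembles, ranked by mean. No depth
weighting is applied. Note that with learning-rate-only shrinkage and
pure-leaf-capable depth, successive trees largely refit the same
structure, so occurrence importance is effectively a census of one tree's
splits repeated.

## 5. Ordinal scoring and ROC (`scoring`)

Densities map to the 1–4 rubric via three strictly ascending edges with
left-closed bins (a value on an edge takes the higher grade); edges can be
user-supplied or derived as the quartiles of a reference distribution.
Observer scores are simulated by adding Gaussian noise (default SD 0.35,
chosen so most simulated observers stay within one grade of consensus; no
published inter-observer statistics exist to calibrate against) to the
model's consensus grade, rounding to the nearest integer and clamping to
[1, 4]. Consensus over observers × sections is the median, half-integer
medians rounding down. The product score is vessel grade × TAM grade
(1–16); products ≥ 6 (inclusive cutoff — the smallest product of an
intermediate and a low grade) predict high accumulation, with high
accumulation the positive class throughout. The ROC sweeps thresholds over
the distinct pooled per-(observer, section) product scores — pooling
matches treating each scored section as one rating — and the trapezoidal
area equals the Mann–Whitney U/(n₁n₀) with ties counting ½.

The packaged ten-model panel encodes the published classification pattern
as fixtures: three low accumulators with products < 6 (SW620 4, A549 2,
Calu-6 2), six high accumulators with products ≥ 8, and E35CR — a high
accumulator scoring (vessel 3, TAM 1) = 3 — as the designated false
negative, giving 6 TP / 3 TN / 1 FN / 0 FP at cutoff 6.

## 6. Pipeline determinism and problem sizes

A single global seed fans out to fixed per-stage offsets (images +101+i,
feature table +211, observer scores +307), so adding a stage never
perturbs earlier stages' random streams. Artifacts are plain CSV
(comma-separated, UTF-8, `NA` missing, `.` decimal) and sorted-key JSON,
byte-reproducible for identical (config, seed); the run manifest records a
SHA-256 per artifact. Default problem sizes — 512² px fields, a 14-animal
table, 10 observers × 3 sections × 10 models — run the full pipeline in a
few seconds on one CPU; the test suite's 20-seed LOO recovery study is the
largest computation at about a minute.

## Known limitations

* The image generator idealizes staining (flat foreground, sub-threshold
  noise, disjoint vessels); it validates operator correctness, not
  robustness to real histology.
* Occurrence-based importance at n = 14 is dominated by tie attribution
  (see §4); gain-based importance would be less brittle but is not what
  the emulated analysis used.
* The LOO R² at n = 14 has large seed-to-seed spread (roughly 0.2–0.9
  around a median near 0.78 under defaults); single-seed values should not
  be over-interpreted.
* Inter-observer agreement statistics (e.g. kappa), AUROC confidence
  intervals and calibration curves are out of scope.
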