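# Methods

This note documents the models, conventions and numerical choices behind
`tmekit`, and what the synthetic generators do and do not emulate.

## Coordinate and zone conventions

All nucleus coordinates are (x = column, y = row), origin top-left, 0-based,
in pixels of the full-resolution nucleus frame; physical scale is `mpp`
(microns per pixel). The tumor mask lives at an integer `downsample`; a
point (x, y) belongs to mask pixel `(floor(y/ds), floor(x/ds))`. Tumor
regions are 8-connected components of the mask. Zone membership of a
nucleus is decided at its centroid only: *tumor* when its region id is
positive, else *vicinity* when the centroid falls on the ring obtained by
Euclidean dilation of the tumor by `round(1000·width_mm / (mpp·ds))` mask
pixels (default width 1 mm) minus the tumor itself, else *outside*. The
three zones are disjoint and partition the slide; *whole* aggregates them.
Zone areas are measured at mask resolution; the whole-slide area comes from
the image dimensions.

## Class refinement

Tumor-class nuclei (code 5) with region id 0 are relabelled non-neoplastic
epithelial (code 6). The operation is idempotent, conserves classes 1–4,
and satisfies `n_tumor_before = n_tumor_after + n_relabelled`. It requires
region assignment first and fails loudly otherwise.

## The feature catalogue (317 features, 107-feature analysis subset)

The registry is one versioned enumeration (`tmekit/registry.py`):

| block | definition | count | structure flag |
|---|---|---|---|
| fractions | 6 classes × 4 zones | 24 | yes |
| densities (mm⁻²) | 6 classes × 4 zones | 24 | yes |
| repartitions | 6 classes × 3 zones, minus epithelial-in-tumor | 17 | yes |
| within-zone ratios η | 10 unordered base-class pairs × {whole, tumor, vicinity} | 30 | yes |
| in-tumor distances (µm) | 12 ordered pairs of {granulocyte, lymphocyte, plasma, tumor} | 12 | yes |
| cross-zone ratios η | ordered distinct pairs of 15 (base class, zone) marks | 210 | no |

Totals: 317 features, 107 structure-flagged; the structure subset is the
default input to response modelling. The epithelial-in-tumor repartition is
omitted because the refinement makes it identically zero; the corresponding
fraction/density grid entries are kept so per-zone fractions always sum
to 1 over the full class set. No nucleus-morphology features (area,
circularity) exist anywhere in the catalogue. Undefined values (empty zone,
zero class count, no usable distance pair) are NaN internally and `null` in
the feature JSON.

η uses the natural log with ε = 10⁻³ added outside the log; η is undefined
when either count is zero (missing), and η(a,b)·η(b,a) = 1 exactly.

## Expanding-rectangle distance

Per source cell, the smallest capture step λ₀ is found in closed form
(vectorised): a target at offset (dx, dy) enters the schedule at
λ = max(⌈2dx/(f·lₜ)⌉, ⌈2dy/(f·wₜ)⌉, 1); closed inequalities, so boundary
targets count as inside. The rectangle is centred on the source with *full*
side lengths f·λ·lₜ and f·λ·wₜ (half-extent f·λ·lₜ/2). λ is capped at
⌈2/f⌉ + 1 (the smallest step guaranteed to cover the region's bounding box
from any interior source, plus one); hitting the cap, or an empty target
list, yields *not found*. Sources in regions without any target-class cell
are skipped and counted; the slide-level average runs over sources that
produced a value and is computed on a sorted array so it is bit-identical
under any nucleus ordering. Same-class queries exclude the source itself
(by zero distance; coincident distinct cells are a measure-zero event of
the generator). Distances are reported in pixels and microns.

The per-source result never underestimates the true nearest-neighbour
distance (the captured set contains real cells) but can overestimate it
when the nearest cell sits just outside a rectangle corner. The Monte-Carlo
module measures this: N points uniform in the circle of radius r₁√2 in
which the square of full side 2r₁ is inscribed; the error event is "at
least one point in the square and the globally nearest point outside it".
The reported probability is conditional on the square capturing at least
one point — the error rate of a search that stops at this square — because
a capture-free draw just grows the rectangle and finds the true minimum.
With 2×10⁶ replicates this gives ≈ 0.0219 (N=2) and ≈ 2.8×10⁻⁴ (N=10); the
unconditional frequency (`conditional=False`) and the alternative disk
radius 2r₁ (`geometry="wide"`) are exposed as flags.

## Response modelling protocol

Stratified 3-fold cross-validation (train 2/3), fixed seed; stratification
guarantees both labels in every fold at the 28/17 cohort size. Inside each
training fold, in order: median imputation of missing feature values, then
greedy mRMR ranking. The mRMR variant is FCQ-style: relevance is the
one-way ANOVA F statistic against the binary label (constant features get
relevance 0), redundancy the mean absolute Pearson correlation with the
already-selected set, and each step maximises relevance / redundancy with
the denominator floored at 0.01; ties resolve to the earliest column, so
selection is deterministic. The greedy ranking is nested, so one ranking
per fold serves every N of the sweep.

The sweep fits an XGBoost classifier with default hyperparameters (only
`random_state`, `n_jobs=1` and the evaluation metric are pinned) on the
top-N features and scores balanced accuracy on the held-out fold; N_best is
the smallest N attaining the maximal fold-averaged balanced accuracy.
Aggregation over splits uses 1-based ranks: occurrence count
c_f ∈ {0..3} and score s_f = log₁₀ Σₗ 10^(N_best − rank_l(f)) (base 10, so
pre-scores are decade-separated by rank; a feature ranked first in all
three splits at N_best = 19 scores log₁₀(3·10¹⁸) ≈ 18.477). The ROC
evaluation re-runs imputation + selection per fold at a fixed operating
point (default N_best = 19, the protocol's reference configuration),
averages fold ROC curves vertically on a 101-point false-positive-rate
grid, and reports mean AUROC ± SD. Nothing outside the training fold ever
touches imputation statistics, selection, or model fitting; permuted-label
runs centre on 0.5.

## Synthetic data

**Slides.** Tumor blobs are harmonic-perturbed circles (radius 0.35 mm,
relative boundary amplitude 0.15) rasterised at mask resolution; nuclei are
placed per (class, zone) by Poisson sampling with intensities in cells/mm²,
uniformly over the zone's mask pixels with sub-pixel jitter, so every
ground-truth count is exact and zone membership is consistent with the
package's floor-division convention. Baseline intensities depict a
moderately inflamed carcinoma (tumor zone dominated by tumor cells at
700/mm², immune infiltrate concentrated in the vicinity ring, sparse distal
tissue). Contours are small octagons — the generator emulates annotation
*outputs*, not stain appearance, texture, or segmentation errors, so
passing tests validate the analysis layer, not upstream models. An optional
hard-core interaction places one class uniformly conditional on keeping a
minimum distance from an anchor class (rejection sampling, bounded rounds),
which moves closest-cell distances without changing any count.

**Slide-level cohorts** (default 28 responders / 17 non-responders) draw
group-conditional intensities: responders carry more lymphocytes inside and
around the tumor, non-responders more granulocytes around it, and in
non-responders intratumoral plasma cells keep ≥ 60 µm from granulocytes.
Each patient gets a shared log-normal cellularity factor (σ = 0.35; section
thickness and staining vary between slides — the reason relative features
beat absolute densities) plus independent per-intensity scatter (σ = 0.25).
Because any intensity effect necessarily moves a whole family of correlated
features (fractions, densities, repartitions, ratios, and every distance
involving that class), this generator serves end-to-end checks, group
tests, and permutation nulls — not exact marker-set recovery.

**Feature-level cohorts** generate the 107-column structure table directly,
which is the only way to realise the condition "exactly k features carry
signal". Null columns come in correlated blocks (size 7, ρ = 0.5),
mirroring family structure. Each of the four planted markers carries a
shared responder shift of 1.6 SD plus an extra 1.8 SD in one quarter of the
responders: response arises through distinct immune configurations, so no
single marker separates the cohort and accuracy keeps improving as markers
accumulate. Ten further features carry a weak diffuse shift (0.5 SD), the
faint secondary signature real cohorts show. Under these conditions the
protocol recovers all four planted markers in the top 8 of the (c, s)
ranking and reaches mean test AUROC ≥ 0.9 in ≈ 93 % of seeds (28/30
measured).

## Problem sizes used in the verification suite

The oracle-bound check runs 1,000 single-blob slides (~110 in-tumor cells
each) and compares every per-source expanding-search distance against exact
enumeration; the Monte-Carlo check uses 2×10⁶ replicates per N; marker
recovery uses 20 seeded 45-sample cohorts; the permutation null uses 12
label permutations. These sizes give comfortable statistical resolution for
every asserted bound while keeping the default test run short.

## Known limitations

* The 317-feature enumeration reproduces the documented families, counts
  and the 107-feature analysis subset, but the exact composition of the
  original catalogue is not public; the registry is versioned so it can be
  replaced verbatim without touching the engine.
* Membership is centroid-based; cells straddling a region boundary are
  attributed wholly to one side.
* The rectangle-search overestimation is inherited by design (it is the
  method's documented speed/accuracy trade-off), so distance features are
  upper bounds that become exact as density grows.
* The simulators produce homogeneous Poisson placement within zones; real
  tissue shows clustering, gradients and segmentation noise that the
  synthetic tests do not exercise.
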