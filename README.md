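# tmekit

Tumor-microenvironment feature extraction and immunotherapy-response
modelling for H&E whole-slide images (WSIs), operating downstream of nucleus
and tumor-region segmentation.

Modern segmentation models turn a gigapixel skin-cancer WSI into (a) a set
of classified cell nuclei — granulocytes, lymphocytes, plasma cells, stromal
cells, tumor cells — and (b) a binary tumor-region mask. `tmekit` is the
analysis layer on top of those outputs, built around the workflow used for
cutaneous squamous cell carcinoma (cSCC):

1. **Class refinement.** Non-neoplastic epidermis and tumor cells are
   morphologically indistinguishable in isolation; tissue context separates
   them. Every nucleus classified as tumor that falls outside all segmented
   tumor regions is relabelled *non-neoplastic epithelial* (class 6).
2. **Slide encoding.** The slide is compressed into a fixed, ordered vector
   of **317 named features** over four zones — the whole slide, the tumor
   regions, the 1 mm *vicinity* ring around them, and the remaining
   *outside* tissue: class fractions, densities per mm², zone repartitions,
   smoothed log count ratios, and in-tumor closest-cell distances.
3. **Response modelling.** On a cohort of labelled slides
   (responder / non-responder to checkpoint inhibition), a curated
   **107-feature tissue-structure subset** feeds an mRMR + gradient-boosted
   trees protocol inside stratified 3-fold cross-validation, with a
   balanced-accuracy sweep over the number of kept features and an
   occurrence/rank score that aggregates the selected features across folds.
4. **Synthetic ground truth.** A marked-point-process slide simulator and
   two cohort simulators generate data with exactly known composition and
   effects, so every stage is testable end to end without any WSI.

## The statistics at the core

**Expanding-rectangle closest-cell distance.** For a source cell of class
*A* at (xᵢ, yᵢ) inside a tumor region with bounding box lₜ × wₜ, candidate
target cells of class *B* are collected from a rectangle centred on the
source with full side lengths *f*·λ·lₜ and *f*·λ·wₜ (*f* = 0.05), growing
λ = 1, 2, … until at least one target is captured (λ₀); the reported value
is the minimum Euclidean distance among the targets captured at λ₀, and the
slide-level feature is the average over all source cells:

    d̄(A→B) = (1/n_A) Σᵢ min_{k ∈ captured(λ₀,i)} √((xᵢ−x_k)² + (yᵢ−y_k)²)

The search never leaves the source's tumor region. Because the capturing
rectangle need not contain the global nearest neighbour, the result can
overestimate the true nearest-neighbour distance (never underestimate it);
`mc_overestimation_probability` quantifies that event — ≈ 2.2 % for 2
points, ≈ 2.8 × 10⁻⁴ for 10 points in the reference geometry — and shows it
vanishing as cell density grows.

**Smoothed log ratio.** Count ratios use
η(n_A, n_B) = (ln n_A + ε) / (ln n_B + ε) with ε = 10⁻³, which tempers
extreme abundance differences relative to a raw quotient; η(n, n) = 1.

**Selection scoring.** With L = 3 CV splits and N_best kept features per
split, each feature gets an occurrence count c = Σₗ [f selected in split l]
and a rank score s = log₁₀ Σₗ 10^(N_best − rank_l(f)), so earlier ranks
dominate by whole decades; features are reported ordered by (c, s).

## Worked example

```python
import tmekit as tk

# one synthetic slide: two tumor blobs, Poisson-placed nuclei per zone
annotation, mask, truth = tk.simulate_slide(tk.SlideSimConfig(seed=7))
regions = tk.label_tumor_regions(mask)
assigned = tk.assign_nuclei_to_regions(annotation, regions)
refined, n_reclassified = tk.reclassify_epithelial(assigned, regions)
fv = tk.compute_all_features(refined, regions)

print(len(annotation.nuclei), regions.n_regions, n_reclassified)
print(fv.values["fraction_lymphocyte_tumor"])
print(fv.values["dist_granulocyte_to_plasma_tumor_um"])
```

prints

```
5421 2 169
0.21353251318101933
76.28105004461787
```

i.e. the slide carries 5,421 nuclei in and around 2 tumor regions; 169
tumor-class calls outside the regions were relabelled epithelial; 21.4 % of
in-tumor cells are lymphocytes; and a granulocyte inside the tumor sits on
average 76 µm from its nearest plasma cell.

Running the selection protocol on a simulated 45-patient cohort (28
responders / 17 non-responders) with four known signal-carrying features:

```python
sim = tk.simulate_feature_cohort(tk.FeatureCohortSimConfig(seed=0))
res = tk.fit_and_evaluate(sim["features"], sim["labels"],
                          tk.CVPlan(seed=0), n_best=19)
print(res.mean_auc)   # 1.0 on this draw
```

and the (c, s) ranking puts the four planted markers —
`fraction_lymphocyte_tumor`, `fraction_lymphocyte_vicinity`,
`ratio_granulocyte_to_lymphocyte_vicinity`,
`dist_granulocyte_to_plasma_tumor_um` — in its top five.

A `tmekit` command-line tool wraps the same steps
(`refine`, `features`, `distances`, `select`, `classify`, `simulate`,
`mc-overestimate`); see `tmekit --help`.

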