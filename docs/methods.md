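# Methods

This note documents the models, conventions and numerical choices behind
`pestspec`, in the spirit of a statistical package's model documentation.

## Damage scoring

The ground-truth severity statistic is the leaf loss rate
`LLR = 100·Ld/(Lh+Ld)` (percent), computed from counted healthy (`Lh`)
and damaged (`Ld`) needles. The formula yields 0 when no needles are
damaged, so the implemented range is [0, 100]. Levels are assigned from
half-open LLR intervals with breakpoints belonging to the *higher* level;
the default breakpoints — healthy [0, 10), mild [10, 35), moderate
[35, 70), severe [70, 100] — are a documented stand-in for field-survey
grading schemes, which vary by agency, and are fully configurable.

## The synthetic cohort and scene

The generator is first-class, tested code; it defines the study
conditions under which the pipeline's guarantees are stated.

**Spectral model.** Each damage level ℓ ∈ {1..4} has a class-mean 5-band
reflectance `m_b(ℓ) = m_b(1) + k_b·(ℓ−1)` with default healthy means
(B, G, R, RE, NIR) = (0.035, 0.080, 0.050, 0.300, 0.550) — typical
closed-canopy conifer reflectances — and per-level slopes
k = (+0.0256, +0.004, +0.0329, −0.058, −0.1077): blue and red rise as
pigments and leaf area are lost, red-edge and NIR fall steeply.
Within-class noise is truncated normal on [0, 1], independent across
bands by default (a shared-factor correlation option exists, off by
default). The red-edge standard deviation is derived per level as the
NIR sd minus a configured gap (defaults 0.02846, 0.02926, 0.02178,
0.01702 with NIR sd 0.05): red-edge responds almost as strongly as NIR
but with visibly tighter within-class spread, which is the property that
makes red-edge indices competitive.

**Green-band soil mixing.** Trees whose LLR exceeds an onset (default
70 %, i.e. the severe class) mix bright understory soil into the green
band linearly with weight `LLR/100`: severe crowns are sparse enough for
the background to contribute, producing the green-band upturn at the
severe level while the other levels follow the gentle green slope.

**Needle counts.** Total needles per tree are uniform on [800, 1500];
target LLRs are drawn uniformly inside each level's interval with a
0.5 % edge margin so integer rounding of `Ld` can never flip a tree
across a breakpoint. Realized LLR and level are recomputed from the
integer counts, keeping the record internally consistent.

**Scene geometry.** Crown centres sit on a jittered grid (dense,
non-overlapping, aperiodic) over a default 600 m × 300 m extent at
0.5 m/pixel, crown radii uniform on [1.5, 3] m. Under the `aggregated`
pattern, trees are ranked by distance from the aggregation centre plus
Gaussian jitter (sd = 0.15 × the 80 m decay scale) and levels are
assigned severe-first — severity probability decays monotonically
outward, the geometry of a defoliator spreading from its origin.
`saltatory` additionally moves a few (default 5) of the outermost severe
trees onto isolated positions in the healthy margin (wind-carried larvae
ahead of the front); `random` shuffles levels freely. Severe trees in
the inner half of the severe ring are flagged `core`; moved trees are
flagged `planted_outlier` — these generator-truth flags are what the
spatial-statistics checks score against. Rasterisation paints each
crown's spectrum (plus 0.005-sd pixel noise) over a soil background;
overlapping pixels go to the nearest crown centre.

**What the generator does not emulate:** illumination/BRDF effects,
shadows, radiometric calibration error, crown-shape irregularity,
understory gradients, spatially correlated noise, and mixed pixels at
crown edges beyond the nearest-centre rule. Tests passing on this
benchmark demonstrate the correctness and internal consistency of the
algorithms, not field-accuracy levels: the default benchmark is
deliberately high-separability, so classifier accuracies here sit above
what crown-level surveys typically reach.

## The index bank

62 registered indices, 31 CONV + 31 RE, names unique; the registry is
data-driven and replaceable, and any departure from the 31+31 canon
warns rather than fails. RE variants are generated mechanically from the
registered base formula — `reg` substitutes the red-edge band for NIR,
`reg*` for red — so each variant provably equals its counterpart under
the documented swap. Intrinsic RE indices (lnRE, SCCI, ARI, TCARI, MTCI,
CIre, NDSIreg, NDSIreg*) use their standard literature formulas. Family
membership follows band usage strictly: an index belongs to RE iff its
formula reads the red-edge band (this is also enforced by test).

ROI means use pixel-centre containment (simple and deterministic; no
area weighting). Index values whose domain guard fails (zero
denominators, negative radicands) are flagged NaN; the table builder
drops the affected rows by default (logged) or median-imputes on
request.

## Feature selection

* **ANOVA**: one-way F per feature over the four levels; keep features
  with F strictly greater than the threshold. The threshold defaults to
  the F quantile `critical_f(k−1, n−k, p)` at p = 1e−10; published
  thresholds do not always state their degrees-of-freedom convention, so
  an explicit F override is supported and both values are reported in
  the diagnostics.
* **SPA**: greedy chains by largest projection onto the orthogonal
  complement of the selected span (iterative deflation; ties to the
  lowest column index; chains truncate with a flag at numerical rank
  exhaustion, tolerance 1e−10 relative to the largest column norm).
  Chains from every start are scored by k-fold CV RMSE of a linear
  regression of the ordinal level (coded 1–4 — a documented convention)
  on the standardized subset. Chosen size: the smallest m with
  `RMSE(m) ≤ min + max(rel_tol·min, abs_tol)`, defaults rel_tol = 1 %,
  abs_tol = 0.01 level units. The absolute floor exists because a purely
  relative rule degenerates when the minimum RMSE approaches zero:
  sub-percent noise fluctuations would otherwise push the choice to
  arbitrarily larger subsets.
* **SFS**: features ranked by random-forest permutation importance
  (mean decrease in accuracy on held-out folds, default 10 shuffles per
  fold, averaged over stratified folds; importance ties resolved by
  table column order for determinism), then the prefix with maximal
  cross-validated accuracy is returned, ties toward fewer features.

All three are deterministic given (inputs, seed).

## Classifiers and evaluation

Features are standardized inside each fit (scaler learned on training
folds only — leakage guard). Hyperparameters come from small documented
grids via stratified 5-fold CV:

* **RF** — 500 trees, √p features per split, grid over max depth
  {None, 12};
* **BPNN** — one hidden layer of `max(8, ⌈2/3·(p+k)⌉)` logistic units,
  Adam, cross-entropy, ≤400 iterations;
* **1D-CNN** — the ordered index vector as a length-p sequence:
  conv(k=3, 16 ch) → ReLU → maxpool(2) → conv(k=3, 32 ch) → ReLU →
  dense softmax; Adam (lr 0.01, batch 32, 120 epochs, weight decay
  1e−4), implemented directly in numpy and seed-deterministic; diverging
  runs retry with a halved learning rate (bounded).

Evaluation follows remote-sensing conventions: confusion matrix with
true levels in rows; OA = trace/S; kappa = (OA − Pe)/(1 − Pe) with
Pe = Σ Np·Nt/S²; recall and F1 per class from TP/FP/FN then
macro-averaged (classes are balanced by design, where macro and
weighted averaging coincide); PA = per-class recall, UA = per-class
precision. A class absent from the test truth yields NaN per-class
metrics, a warning, and macro averages over the defined classes. The
split is stratified 3:1 by default (840 → 630/210, 52–53 per class in
test).

## Spatial statistics

Damage levels enter as ordinal values 1–4 (a documented convention).
Weights default to k-nearest-neighbour, k = 8, row-standardized, knn
ties to the lowest tree id; a symmetric distance-band alternative is
provided. Global Moran's I uses the standard cross-product form with
E[I] = −1/(n−1) and full-permutation inference (default 999). Local
Moran's I uses conditional permutations (the focal value held fixed,
others permuted into the neighbour slots), one-sided pseudo-p in the
direction of the observed statistic, α = 0.05, no multiple-testing
correction by default (standard LISA practice). Significant points are
categorised by the quadrant of (z, spatial lag) and mapped to
distribution types: HH → spread, HL → saltatory, LH → latent,
LL → healthy, not-significant → unclassified. Gi\* uses binary
self-inclusive weights and the analytical moments; class thresholds
default to the two-sided 1 % ("extremely significant hot") and 5 %
z-values. Note that conditional permutation cannot flag a high outlier
whose *entire complement* is homogeneous — detectability requires
heterogeneity among the other values, which real (and synthetic) stands
have.

## Problem sizes and determinism

Default sizes — 840 trees, 1200×600×5 raster, 62 indices, all 18
selection×model×family combinations, 999 permutations — run end to end
in a few minutes on one CPU; the test suite uses these defaults for the
end-to-end checks and smaller planted-signal datasets (100–160 samples,
10–11 features) for the 100-seed selection simulations. Every stage
seeds from a single integer through `numpy.random.SeedSequence`; fixed
seeds reproduce rasters bit for bit and metric files byte for byte.

## Known limitations

* The CNN is sized for tens of features and hundreds of samples; it is
  not a raw-image patch classifier.
* SPA's RMSE scoring assumes the ordinal-as-numeric coding; strongly
  non-linear level responses would favour the SFS path.
* The LISA → distribution-type reading is a fixed mapping on
  significance categories, not a dispersal model; latent/saltatory
  labels inherit all the usual caveats of local spatial statistics at
  α = 0.05 without multiplicity control.
* GeoTIFFs carry a planar local frame (pixel scale + tiepoint tags),
  not a full CRS definition; real-survey ingestion assumes projected
  coordinates in metres.
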