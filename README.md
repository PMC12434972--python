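# pestspec

Crown-level detection of defoliator damage in conifer stands from
UAV multispectral imagery: red-edge vegetation indices, sensitive-feature
screening, machine-learning damage-level classification, and spatial
autocorrelation mapping of the predicted outbreak — with a synthetic-scene
generator so the whole workflow is testable without flying a drone.

## The problem

Geometrid larvae strip larch needles; the canopy leaf loss rate of tree
*i*,

```
LLR_i = Ld_i / (Lh_i + Ld_i) × 100 %
```

(`Lh`, `Ld` = counts of healthy and damaged needles on sampled branches),
grades each tree into an ordinal damage level — healthy, mild, moderate,
severe. From 5-band surface reflectance (blue, green, red, red-edge, NIR)
over each crown ROI, a bank of 62 vegetation indices is computed: 31
conventional (CONV) indices that never use the red-edge band, and 31
red-edge (RE) indices (`<name>reg` = red edge substituted for NIR,
`<name>reg*` = red edge substituted for red, plus intrinsic RE indices
such as ARI, TCARI, SCCI). Defoliation raises blue/red reflectance and
sharply lowers red-edge/NIR reflectance; red-edge responds almost as
strongly as NIR but with tighter within-class spread, which is what makes
RE indices good damage predictors.

The pipeline then:

1. **screens features** three ways — one-way ANOVA F-filter, the
   successive projections algorithm (SPA, greedy minimum-collinearity
   chains scored by cross-validated RMSE of an ordinal regression), and
   importance-ranked sequential forward selection (SFS, random-forest
   permutation importance + best-prefix search);
2. **classifies damage levels** with a random forest, a 1-D CNN over the
   index vector, and a back-propagation neural network, evaluated on a
   stratified 3:1 split with overall accuracy, Cohen's kappa,
   macro recall/F1 and per-class producer/user accuracy;
3. **maps the outbreak**: global Moran's I, Anselin local Moran's I with
   the cluster-outlier categories read as pest-distribution types
   (HH → spread, HL → saltatory, LH → latent, LL → healthy area), and
   Getis-Ord Gi\* hot/cold spots.

The synthetic generator draws balanced cohorts (default 210 trees per
level) whose class-conditional band means, within-class spreads, green-band
soil-mixing upturn at the severe level, and center-outward severity
geometry emulate the spectral and spatial structure of a real outbreak.

## Worked example

```python
import pandas as pd
import pestspec as ps

cohort = ps.generate_cohort(ps.CohortConfig(), seed=7)
scene = ps.generate_scene(cohort, ps.SceneConfig(), seed=8)
spectra = ps.extract_roi_means(
    scene.raster, scene.rois, scene.resolution, scene.origin,
    scene.trees["tree_id"].tolist(),
)
labels = pd.Series(scene.trees["damage_level"].to_numpy(), index=spectra.index)
table = ps.build_feature_table(spectra, labels)

sel = ps.spa_select(table.subset(family="RE"), seed=9)
train, test = ps.split_train_test(
    table.subset(features=sel.selected), ps.SplitSpec(seed=10)
)
model = ps.train_model("BPNN", train, seed=11)
result = ps.evaluate(model, test)

analysis = ps.analyze_spatial(
    scene.trees[["x", "y"]].to_numpy(),
    scene.trees["damage_level"].to_numpy(float),
    permutations=999, seed=12,
)
```

prints (via the obvious `print` statements):

```
SPA selected 16 RE features: NLIreg, MTCI, SCCI, NDVIreg*, TCARI, ...
BPNN held-out OA=0.9857  kappa=0.9810  recall=0.9858  F1=0.9857
Global Moran's I = 0.9177 (E[I] = -0.0012, z = 54.1, pseudo-p = 0.001)
Distribution types: {'unclassified': 318, 'spread': 262, 'healthy': 260}
```

SPA kept 16 of the 31 red-edge indices; the BPNN classifies the held-out
quarter of the stand almost perfectly because the synthetic benchmark is
deliberately high-separability; the strongly positive Moran's I (against
a null expectation of −1/(n−1) ≈ −0.001) says damage levels cluster in
space, and the LISA categories read the aggregated core as a spread-type
infestation surrounded by healthy area.

The same workflow is scriptable end to end:

```bash
pestspec run --seed 20 --out-dir runs/demo
pestspec report --out-dir runs/demo
```

which writes the scene (GeoTIFF + GeoJSON ROIs), the feature table, every
selection diagnostic, the 18 model results (3 selections × 3 models × 2
families), the predicted damage map, the spatial statistics, a manifest
and a rendered `report.md`.

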