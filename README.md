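# standalloc

Stand spatial structure and aboveground biomass allocation in Chinese fir
(*Cunninghamia lanceolata*) plantations.

`standalloc` is a reusable Python implementation of a complete
LiDAR-era forest-structure workflow, aimed at quantitative forest
ecologists working with stem maps and canopy height models (CHMs):

1. **Synthetic stand generation** — stem maps for five plantation age
   classes (random / hard-core / Matérn-clustered patterns), cone-crowned
   CHM rasters at 0.1 m, and per-organ dry biomass, so every downstream
   stage is testable without field data.
2. **Individual-tree segmentation** — fixed-window local-maximum tree-top
   detection and marker-controlled watershed crown delineation on the CHM,
   scored with detection rate *r* = TP/(TP+FN), precision *p* = TP/(TP+FP)
   and F-score *F* = 2*rp*/(*r*+*p*).
3. **Allometry** — nine candidate organ-biomass model forms (power-law and
   log-log families in D, H and D²H), best-form selection by R², the
   selected equations being

   W_stem = 0.054 (D²H)^0.786,
   ln W_branch = −5.907 + 1.921 ln D + 0.779 ln H,
   ln W_leaf = −0.238 + 0.214 ln D + 0.656 ln H,

   plus a linear DBH ~ H + CW inversion model and the stem/branch/leaf
   mass fractions SMF, BMF, FMF (= organ biomass / AGB).
4. **Spatial structure** — multiplicatively weighted Voronoi structural
   units (weights from min-max-normalised H, DBH, CW) with an edge buffer,
   and six per-tree indices: uniform angle **W**, size ratio **U**, angle
   competition index **UCI**, forest layer index **S**, openness **K**,
   openness ratio **OP**, each with its five-class interpretation scale.
5. **Allocation analysis** — VIF screening, stepwise selection, path
   analysis splitting each predictor's correlation with a mass fraction
   into direct and indirect effects with decision coefficients
   R_i = 2 p_i r_iy − p_i², and 25 × 25 "four-element" grids of mean
   fraction over joint (UCI, K) × (OP, S) classes.

## Worked example

```python
from standalloc import allometry, segmentation, structure, synthetic
from standalloc.datasets import load_harvest_trees

# 1. organ allometry from the packaged 20-tree harvest table
harvest = load_harvest_trees()
best = {o: allometry.select_best(allometry.fit_all_forms(harvest, o))
        for o in allometry.ORGANS}
for o, f in best.items():
    print(o, f.form_id, round(f.a, 3), round(f.b, 3), f.c, round(f.r2, 3))

# 2. a clustered young stand and its CHM
cfg = synthetic.StandConfig.from_age_group(
    "young", seed=7, pattern="clustered", pattern_param=1.5)
trees = synthetic.generate_stand(cfg)
chm = synthetic.synthesize_chm(trees, 0.1, cfg.plot_width, cfg.plot_height)

# 3. tree-top detection with window selection
w, res = segmentation.select_window(chm, trees, [(s, s) for s in (0.2, 0.3, 0.4, 0.5)])
print(w, round(res[w].f, 3))

# 4. the six structure indices for every core tree
idx = structure.compute_indices(trees)
print(idx[["W", "U", "UCI", "S", "K", "OP"]].mean().round(3))
```

prints

```
stem 3 0.054 0.786 None 0.98
branch 9 -5.907 1.921 0.779 0.974
leaf 9 -0.238 0.214 0.656 0.922
(0.2, 0.2) 0.958
W 0.443  U 0.566  UCI 0.368  S 0.302  K 0.166  OP 0.585
```

i.e. stems are best described by the power law in D²H (R² = 0.980),
branches and leaves by the two-predictor log-log form; on this 197-tree
clustered stand a 0.2 m detection window recovers tree tops with F = 0.958;
and the index means describe a moderately aggregated (W = 0.44), strongly
lit (OP = 0.59) young stand under medium competitive pressure (UCI = 0.37).

Feeding the indices plus per-tree biomass fractions into the path analysis
(`allocation.stepwise_select` → `allocation.path_decompose`) then
quantifies which structural axes drive stem/branch/leaf allocation, and
`allocation.four_element_grid` maps where in structure space each fraction
peaks.

The same pipeline is scriptable from the shell:

```sh
standalloc simulate --age-group young --seed 7 --out-stem stand.csv --out-chm chm.asc
standalloc segment --chm chm.asc --window 0.3 0.3 --reference stand.csv --out seg/
standalloc fit-allometry --out allom/
standalloc indices --stem-map stand.csv --out indices.csv
```

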