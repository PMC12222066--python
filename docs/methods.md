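# Methods

This note records the models implemented in `standalloc`, the conventions
chosen where the underlying methodology is underspecified, and what the
synthetic-data tests do and do not demonstrate.

## Synthetic stands

A stand is a square plot (default 25.82 × 25.82 m ≈ 1/15 ha, the survey
plot geometry) populated by one of three point processes:

- **random** — homogeneous Poisson: the count is Poisson(density × area),
  positions uniform;
- **regular** — hard-core by dart throwing with minimum inter-tree distance
  `pattern_param` (m); placement fails explicitly after 500 attempts per
  tree, since sufficiently dense hard-core packings do not exist (e.g. the
  young-forest density of 2533.7 trees/ha is not packable at a 1.8 m core);
- **clustered** — Matérn cluster process: Poisson parents in a window
  expanded by the cluster radius (keeping intensity uniform inside the
  plot), Poisson(µ = 5 by default) offspring per parent, uniform in a disc
  of radius `pattern_param`.

Attribute distributions (height m, crown width m, DBH cm; mean ± SD) and
densities for the five age classes — young, middle-aged, near-ripe, mature,
overripe — are the survey values (e.g. overripe: H 22.9 ± 3.9 m, CW
3.0 ± 0.7 m, DBH 21.4 ± 6.0 cm, 1279.4 trees/ha). Heights and crown widths
are truncated normals (lower bound 0.1 m) to exclude nonphysical draws.

The joint (H, CW, DBH) distribution within a plot is not known, so DBH is
generated from the linear inversion model used later in the pipeline,

    DBH = 1.475 H + 2.965 CW − 13.117 + ε,  ε ~ N(0, σ),

clipped at 1 cm, with σ defaulting to the age-class DBH standard deviation.
This is a deliberate stand-in: it guarantees the DBH-model stage has a
recoverable signal, but it means synthetic DBH means need not match the
survey DBH means for every age class, and any analysis of the H–CW–DBH
correlation structure on synthetic stands tests the generator, not nature.

Crowns are right cones — height falls linearly from H at the apex to 0 at
the crown edge (radius CW/2) — matching the conical habit of Chinese fir.
The CHM pixel value is the maximum cone surface over all trees, and the
pixel containing each apex is set to exactly H (tree height is carried by
the apex pixel in CHM workflows). Organ biomass is generated from the
fitted allometric equations with multiplicative log-normal noise
exp(N(0, σ_log)); σ_log = 0 reproduces the equations to machine precision.

What the generator does **not** emulate: terrain, LiDAR occlusion and point
density effects, crown asymmetry and plasticity, CHM pits and interpolation
artefacts, species mixtures, or measurement error in stem maps. Perfect or
near-perfect segmentation scores on synthetic stands therefore bound the
algorithmic error only, not performance on real CHMs.

## Tree-top detection and crown delineation

A pixel is a tree apex iff its value is at least `min_height` (default 2 m,
separating canopy from ground returns) and is the strict maximum of the
rectangular window of physical size `window_x × window_y` metres centred on
it. Window sizes convert to pixels by rounding up to an odd count at the
raster resolution (0.1 m default). Exact ties on plateaus are broken in
favour of the first pixel in row-major order, so a flat top yields exactly
one apex. Crowns are the watershed basins of the inverted CHM seeded at the
apexes, masked below `min_height`. Extracted height is the CHM value at the
apex pixel; extracted crown width is the mean of the crown's north–south
and east–west bounding extents.

Detected apexes are matched to reference stems greedily by increasing
distance within `match_radius` (default 2 m; the radius behind published
detection counts is not reported, so it is configurable), each side matched
at most once. Window selection maximises F over a candidate list, ties
going to the smaller window area.

## Allometry

Nine model forms are fitted per organ (stem, branch, leaf): power laws
W = aH^b, W = aD^b, W = a(D²H)^b; the linear form W = a + b·D²H; and five
log-scale forms ln W in ln D, (D, D²), ln H, ln(D²H), and (ln D, ln H).
Log and linear forms use OLS; power laws use Levenberg–Marquardt NLS
(parameter tolerance 1e-10) started from the linearised log-log fit, which
on well-behaved allometric data converges in a handful of iterations.

Goodness of fit is computed on the **fit scale**: R² = 1 − SSE/SST,
RMSE = √(SSE/n) (no degree-of-freedom correction), MAE — so log-form errors
are in ln-kg and are not directly comparable to natural-scale errors.
Best-form selection maximises R² across all nine forms (ties to lower
RMSE). On the packaged harvest table this selects the power law in D²H for
stems and the two-predictor log-log form for branches and leaves.

Back-transformation of log-scale predictions uses plain exponentiation;
the Baskerville-style bias correction exp(σ²/2) is available behind a flag
but off by default, matching the published equations. AGB for fraction
computation is defined as the **sum of the three organ predictions** (not a
separately fitted AGB model), which guarantees SMF + BMF + FMF = 1 exactly.

The DBH model regresses DBH on H and CW by OLS on a random 70% training
split (seeded, reproducible), reports VIF for both predictors (flagged
against the usual < 5 rule; with two predictors both VIFs equal
1/(1−r²_H,CW)), and validates by a two-sided paired t-test of observed vs
predicted DBH on the held-out 30%.

## Weighted Voronoi structural units

Competition weights combine the three size attributes: each of H, DBH, CW
is min-max normalised within the plot, the three are averaged and the mean
is mapped to [0.5, 1.5]. A constant attribute contributes a neutral 0.5;
a fully degenerate plot gets uniform weights. The multiplicatively weighted
Voronoi diagram assigns each raster cell (0.1 m default) to the tree
minimising distance/weight; adjacency is raster-edge sharing between cells.
With equal weights this reduces to the ordinary Voronoi diagram, and the
raster adjacency agrees with an exact computational-geometry construction
(clipped to the plot) on ≥ 99% of pairs; disagreements are cell interfaces
shorter than one raster cell.

Edge effects are handled by distance buffering: only trees inside the
central 20 × 20 m core (≈ 2.91 m buffer per side) are centres; buffer trees
appear only as neighbours. A classical fixed-n nearest-neighbour mode
(default n = 4) is provided as an alternative to Voronoi adjacency —
relevant because the 0.5 reference value of the uniform-angle index W
(random stands) is calibrated for the 4-neighbour convention; Voronoi
neighbourhoods, which surround the centre by construction, shift W
downwards.

## The six indices

For centre *i* with n neighbours *j* at distances d_ij (azimuths measured
from north, clockwise):

- **U** = mean(H_j > H_i): 0 = locally dominant.
- **W** = share of consecutive azimuth gaps below the standard angle
  a₀ = 360/(n+1). Gaps always sum to 360°; W needs n ≥ 2.
- **UCI** = U/(180 n) × Σ (α1 + α2), with α1 = atan(H_i/d) for taller
  neighbours, atan(H_j/d) otherwise, and α2 = atan(|H_i−H_j|/d) for taller
  neighbours, 0 otherwise (degrees). The published α2 is written with a
  sign that would make it negative exactly when it applies; the magnitude
  is used, which keeps UCI in [0, 1] and reproduces the published worked
  interpretation (centre-tallest ⇒ UCI = 0).
- **K** = mean(d_ij / H_j). The reference height in the source formula is
  ambiguous ("H_ij"); neighbour height is the default, mean(H_i, H_j) a
  documented option.
- **OP** = mean(d_ij > |H_i − H_j|).
- **S** = (z/3) × mean(neighbour in centre's layer), z = number of distinct
  layers among centre and neighbours. Layers cut the plot height range into
  thirds (upper: H ≥ H_min + ⅔ H_dist; lower: H ≤ H_min + ⅓ H_dist; a
  zero range puts all trees in the upper layer). The same-layer convention
  is the printed one (an all-one-layer unit scores ⅓, consistent with
  young-stand values ≈ 0.35); the complementary different-layer convention
  is a toggle.

Classification uses five classes per index: {0} ∪ four quarter-intervals
for the unit-interval indices, and (0,0.2], (0.2,0.3], (0.3,0.4],
(0.4,0.5], (0.5,∞) for K, all right-closed. Group summaries report
mean ± SD per age class with one-way ANOVA, Tukey HSD and compact letter
displays at α = 0.05 and 0.1 (letters from maximal cliques of the
non-significant-pair graph).

## Path analysis and four-element grids

Predictors (UCI, K, OP, W, S, H, DBH) are screened by iterated VIF
elimination (threshold 10), then selected by classical forward–backward
stepwise regression on standardised variables (entry p < 0.05, removal
p > 0.10 — conventional defaults; deterministic given column order, with a
perfect-fit stop and a visited-state guard against entry/removal cycling).

Direct effects are the standardised coefficients p_i solving the normal
equations R_rr p = r_ry over the retained set; the indirect effect of
variable *i* through retained *k* is r_ik p_k; the total effect is the
plain correlation r_iy. For retained predictors the identity
r_iy = p_i + Σ_{k≠i} r_ik p_k holds to machine precision. Unretained
variables are reported with direct effect 0 and their correlation as total.
The decision coefficient R_i = 2 p_i r_iy − p_i² ranks net contributions —
this closed form is adopted because it exactly reproduces the published
worked cells; the published "residual" column matches neither 1 − R² nor
√(1 − R²) and its definition is unresolved, so 1 − R² is the default with
√(1 − R²) as an option. Significance stars: ** p < 0.05, * p < 0.1.

The four-element grid crosses the five classes of (UCI, K) on one axis with
(OP, S) on the other: 625 cells, each holding the mean of a chosen fraction
over the trees in that joint class, with per-cell counts and an empty-cell
mask; the argmax cell (row-major first on ties) identifies the structural
combination maximising the fraction.

## Numerical conventions and edge cases

- All randomness flows through explicitly seeded `numpy.random.Generator`
  streams; identical seed + configuration gives bit-identical stands, CHMs
  and splits. No hidden global state.
- Degenerate inputs fail loudly: infeasible hard-core packing, coincident
  stems, apexes on background pixels, zero-variance observations,
  perfectly collinear predictors, negative noise scales.
- Paired t-tests with zero-variance differences are reported as degenerate
  (T = 0, p = 1 when the mean difference is 0; p = 0 otherwise).
- Raster I/O is plot-local (no CRS): ESRI ASCII grids as the text format,
  single-band TIFF via tifffile with the pixel size in the image
  description.

## Problem sizes in the test suite

The suite exercises stands of 25–200 trees on 259²–517² CHM grids, 1000
random structural units for the dual-implementation checks, 10 000 for
bound checks, n = 353 for DBH-model recovery (the field sample size), and
n = 2000 structural simulations for path-effect recovery. These sizes give
stable statistics for every assertion while keeping the full suite around
half a minute.

## Known limitations

- The analysis chain starts at the CHM; point-cloud processing (ground
  filtering, DEM/DSM interpolation) is out of scope.
- Published per-plot index means for the real stands are not reproducible
  without the unreleased stem maps; synthetic stands recover the
  qualitative pattern (clustered stands W > 0.5, hard-core stands W < 0.5
  under the 4-neighbour convention) but not the printed values.
- Terrain-adjusted distances, species mingling and tree-health weighting
  are not implemented (single-species, plot-local analysis).
- Multiplicatively weighted Voronoi cells are computed by raster
  discretisation, not an exact Apollonius-graph construction; accuracy is
  bounded by the raster resolution (≤ 0.2 m enforced).
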