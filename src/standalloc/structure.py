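"""Weighted-Voronoi structural units and stand spatial structure indices.

Each core tree (the "centre") and its Voronoi-adjacent neighbours form a
structural unit.  Cells come from a multiplicatively weighted Voronoi
diagram (a pixel belongs to the tree minimising distance/weight), rasterised
at 0.1 m by default; weights combine min-max-normalised height, DBH and
crown width.  Trees in the plot's edge buffer act only as neighbours, never
as centres (distance-buffering edge correction, core region 20 x 20 m inside
the 25.82 x 25.82 m plot by default).

Six per-centre indices are computed (n = number of neighbours):

W  (uniform angle)        share of consecutive neighbour azimuth gaps below
                          the standard angle a0 = 360/(n+1); 0 = uniform
                          spacing, 1 = tight clustering.
U  (size ratio)           share of neighbours taller than the centre.
UCI (angle competition)   U/(180 n) x sum over neighbours of two
                          arctangent elevation angles mixing heights and
                          distances; competitive-pressure measure in [0, 1].
K  (openness)             mean of d_ij / H_j (neighbour distance over
                          neighbour height); growing-space measure.
OP (openness ratio)       share of neighbours with d_ij > |H_i - H_j|;
                          light-exposure measure.
S  (forest layer index)   (layers present in the unit / 3) x share of
                          neighbours in the centre's layer; the plot is cut
                          into lower/middle/upper height thirds.

Azimuths are measured from north, clockwise, in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PlotGeometry",
    "StructuralUnit",
    "LayerAssignment",
    "compute_weights",
    "weighted_voronoi",
    "structural_units",
    "assign_layers",
    "index_U",
    "index_W",
    "index_UCI",
    "index_K",
    "index_OP",
    "index_S",
    "compute_indices",
    "classify_index",
    "class_bin",
    "summarize_plot",
    "INDEX_CLASS_MEANINGS",
]


@dataclass
class PlotGeometry:
    """Plot extent with an inner core whose trees are eligible centres."""

    width: float = 25.82
    height: float = 25.82
    core_width: float = 20.0
    core_height: float = 20.0

    def __post_init__(self) -> None:
        if not (0 < self.core_width <= self.width and 0 < self.core_height <= self.height):
            raise ValueError("core must be positive and fit inside the plot extent")

    @property
    def buffer_x(self) -> float:
        return (self.width - self.core_width) / 2.0

    @property
    def buffer_y(self) -> float:
        return (self.height - self.core_height) / 2.0

    def in_core(self, x, y) -> np.ndarray:
        bx, by = self.buffer_x, self.buffer_y
        return (
            (np.asarray(x) >= bx)
            & (np.asarray(x) <= self.width - bx)
            & (np.asarray(y) >= by)
            & (np.asarray(y) <= self.height - by)
        )


def compute_weights(trees: pd.DataFrame, scheme: str = "minmax_mean") -> np.ndarray:
    """Competition weights from height, DBH and crown width.

    Default scheme: each attribute is min-max normalised within the plot,
    the three are averaged, and the mean is rescaled to [0.5, 1.5].  An
    attribute that is constant across the plot contributes a neutral 0.5;
    a fully degenerate plot gets uniform weight 1.
    """
    if scheme != "minmax_mean":
        raise ValueError(f"unknown weight scheme {scheme!r}")
    attrs = trees[["height", "dbh", "crown_width"]].to_numpy(dtype=float)
    if np.any(attrs <= 0):
        raise ValueError("tree attributes must be positive")
    lo = attrs.min(axis=0)
    hi = attrs.max(axis=0)
    span = hi - lo
    norm = np.where(span > 0, (attrs - lo) / np.where(span == 0, 1, span), 0.5)
    return 0.5 + norm.mean(axis=1)


def weighted_voronoi(
    trees: pd.DataFrame,
    weights: np.ndarray | None = None,
    plot: PlotGeometry | None = None,
    resolution: float = 0.1,
) -> tuple[np.ndarray, set]:
    """Multiplicatively weighted Voronoi diagram on a raster grid.

    Each pixel is assigned to the tree minimising (distance / weight).
    Returns ``(labels, adjacency)`` where ``labels`` holds 0-based tree
    indices (row 0 = north) and ``adjacency`` is the set of unordered index
    pairs whose cells share a raster edge.
    """
    if resolution <= 0 or resolution > 0.2:
        raise ValueError("resolution must be in (0, 0.2] m")
    if len(trees) < 2:
        raise ValueError("need at least 2 trees")
    plot = plot or PlotGeometry()
    xy = trees[["x", "y"]].to_numpy(dtype=float)
    if weights is None:
        weights = compute_weights(trees)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    # coincident positions make ownership ambiguous
    order = np.lexsort((xy[:, 1], xy[:, 0]))
    dup = np.flatnonzero((np.diff(xy[order], axis=0) == 0).all(axis=1))
    if len(dup):
        ids = trees["tree_id"].to_numpy()[order]
        pairs = [(ids[i], ids[i + 1]) for i in dup]
        raise ValueError(f"coincident tree positions: {pairs}")

    nc = int(np.ceil(plot.width / resolution))
    nr = int(np.ceil(plot.height / resolution))
    px = (np.arange(nc) + 0.5) * resolution
    py = (nr - np.arange(nr) - 0.5) * resolution
    labels = np.empty((nr, nc), dtype=np.int32)
    inv_w2 = 1.0 / weights**2
    # chunk rows to bound memory at ~ nc * n_trees doubles per row-block
    block = max(1, int(4e6 / (nc * len(trees))))
    for r0 in range(0, nr, block):
        r1 = min(nr, r0 + block)
        dx = px[None, :, None] - xy[None, None, :, 0]
        dy = py[r0:r1, None, None] - xy[None, None, :, 1]
        cost = (dx * dx + dy * dy) * inv_w2[None, None, :]
        labels[r0:r1] = np.argmin(cost, axis=2)

    adjacency: set[tuple[int, int]] = set()
    for a, b in ((labels[:, :-1], labels[:, 1:]), (labels[:-1, :], labels[1:, :])):
        diff = a != b
        pairs = np.stack([a[diff], b[diff]], axis=1)
        if len(pairs):
            pairs.sort(axis=1)
            adjacency.update(map(tuple, np.unique(pairs, axis=0)))
    return labels, adjacency


@dataclass
class StructuralUnit:
    """A centre tree with its Voronoi-adjacent neighbours."""

    center_index: int
    center_id: object
    neighbor_indices: np.ndarray
    neighbor_ids: np.ndarray
    distances: np.ndarray
    azimuths: np.ndarray  # degrees from north, clockwise, [0, 360)

    @property
    def n(self) -> int:
        return len(self.neighbor_indices)


def structural_units(
    adjacency: set,
    trees: pd.DataFrame,
    plot: PlotGeometry | None = None,
) -> list[StructuralUnit]:
    """One unit per core tree; neighbours may be core or buffer trees.

    A tree is a centre iff it lies in the plot core and is not flagged
    ``is_buffer``.  Centres with no adjacency partners (degenerate plots)
    are excluded.
    """
    plot = plot or PlotGeometry()
    xy = trees[["x", "y"]].to_numpy(dtype=float)
    ids = trees["tree_id"].to_numpy()
    core = plot.in_core(xy[:, 0], xy[:, 1])
    if "is_buffer" in trees.columns:
        core &= ~trees["is_buffer"].to_numpy(dtype=bool)
    partners: dict[int, list[int]] = {}
    for i, j in adjacency:
        partners.setdefault(i, []).append(j)
        partners.setdefault(j, []).append(i)
    units = []
    for i in np.flatnonzero(core):
        nb = sorted(partners.get(i, []))
        if not nb:
            continue
        nb = np.asarray(nb)
        d = np.hypot(*(xy[nb] - xy[i]).T)
        if np.any(d <= 0):
            raise ValueError(f"zero distance between tree {ids[i]} and a neighbour")
        az = np.degrees(np.arctan2(xy[nb, 0] - xy[i, 0], xy[nb, 1] - xy[i, 1])) % 360.0
        units.append(
            StructuralUnit(
                center_index=int(i),
                center_id=ids[i],
                neighbor_indices=nb,
                neighbor_ids=ids[nb],
                distances=d,
                azimuths=az,
            )
        )
    return units


def nearest_neighbor_units(
    trees: pd.DataFrame,
    plot: PlotGeometry | None = None,
    n_neighbors: int = 4,
) -> list[StructuralUnit]:
    """Fixed-n nearest-neighbour structural units (classical Winkelmass
    convention, default n = 4) as an alternative to Voronoi adjacency."""
    plot = plot or PlotGeometry()
    xy = trees[["x", "y"]].to_numpy(dtype=float)
    ids = trees["tree_id"].to_numpy()
    if len(trees) <= n_neighbors:
        raise ValueError(f"need more than {n_neighbors} trees")
    core = plot.in_core(xy[:, 0], xy[:, 1])
    if "is_buffer" in trees.columns:
        core &= ~trees["is_buffer"].to_numpy(dtype=bool)
    from scipy.spatial import cKDTree

    tree = cKDTree(xy)
    units = []
    for i in np.flatnonzero(core):
        d, nb = tree.query(xy[i], k=n_neighbors + 1)
        d, nb = d[1:], nb[1:]  # drop self
        if np.any(d <= 0):
            raise ValueError(f"zero distance between tree {ids[i]} and a neighbour")
        az = np.degrees(np.arctan2(xy[nb, 0] - xy[i, 0], xy[nb, 1] - xy[i, 1])) % 360.0
        units.append(
            StructuralUnit(
                center_index=int(i),
                center_id=ids[i],
                neighbor_indices=np.asarray(nb),
                neighbor_ids=ids[nb],
                distances=np.asarray(d),
                azimuths=az,
            )
        )
    return units


@dataclass
class LayerAssignment:
    """Forest layer of every tree plus the plot height band."""

    layers: np.ndarray  # 'lower' | 'middle' | 'upper'
    h_min: float
    h_max: float

    @property
    def h_dist(self) -> float:
        return self.h_max - self.h_min

    @property
    def n_layers(self) -> int:
        return len(np.unique(self.layers))


def assign_layers(heights) -> LayerAssignment:
    """Cut the plot height range into thirds.

    upper: H >= H_min + (2/3) H_dist; lower: H <= H_min + (1/3) H_dist;
    middle: strictly between.  A zero height range puts every tree in the
    upper layer by convention.
    """
    h = np.asarray(heights, dtype=float)
    if h.size == 0:
        raise ValueError("need at least one tree")
    h_min, h_max = float(h.min()), float(h.max())
    h_dist = h_max - h_min
    if h_dist == 0:
        return LayerAssignment(np.full(h.shape, "upper"), h_min, h_max)
    lo = h_min + h_dist / 3.0
    hi = h_min + 2.0 * h_dist / 3.0
    layers = np.where(h >= hi, "upper", np.where(h <= lo, "lower", "middle"))
    return LayerAssignment(layers, h_min, h_max)


# -- per-unit indices ------------------------------------------------------
def index_U(center_h: float, neighbor_h) -> float:
    """Size ratio: share of neighbours strictly taller than the centre."""
    nh = np.asarray(neighbor_h, dtype=float)
    if nh.size == 0:
        raise ValueError("need at least one neighbour")
    return float(np.mean(nh > center_h))


def index_W(azimuths) -> float:
    """Uniform angle: share of consecutive azimuth gaps below 360/(n+1)."""
    az = np.sort(np.asarray(azimuths, dtype=float) % 360.0)
    n = az.size
    if n < 2:
        raise ValueError("uniform angle needs at least 2 neighbours")
    gaps = np.diff(np.append(az, az[0] + 360.0))
    a0 = 360.0 / (n + 1)
    return float(np.mean(gaps < a0))


def index_UCI(center_h: float, neighbor_h, distances) -> float:
    """Angle competition index.

    UCI = U/(180 n) x sum_j (alpha1_j + alpha2_j), angles in degrees:
    alpha1 = atan(H_i/d) if the neighbour is taller else atan(H_j/d);
    alpha2 = atan(|H_i - H_j|/d) if the neighbour is taller else 0.
    """
    nh = np.asarray(neighbor_h, dtype=float)
    d = np.asarray(distances, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distances must be positive")
    taller = nh > center_h
    a1 = np.degrees(np.arctan(np.where(taller, center_h, nh) / d))
    a2 = np.where(taller, np.degrees(np.arctan(np.abs(center_h - nh) / d)), 0.0)
    u = index_U(center_h, nh)
    return float(u / (180.0 * nh.size) * np.sum(a1 + a2))


def index_K(distances, neighbor_h, center_h: float | None = None, denominator: str = "neighbor") -> float:
    """Openness: mean of d_ij over a reference height.

    The canonical denominator is the neighbour height H_j; set
    ``denominator='mean'`` for the mean of centre and neighbour heights.
    """
    d = np.asarray(distances, dtype=float)
    nh = np.asarray(neighbor_h, dtype=float)
    if np.any(nh <= 0):
        raise ValueError("neighbour heights must be positive")
    if denominator == "neighbor":
        href = nh
    elif denominator == "mean":
        if center_h is None:
            raise ValueError("denominator='mean' needs center_h")
        href = (nh + center_h) / 2.0
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return float(np.mean(d / href))


def index_OP(center_h: float, neighbor_h, distances) -> float:
    """Openness ratio: share of neighbours with d_ij > |H_i - H_j|."""
    nh = np.asarray(neighbor_h, dtype=float)
    d = np.asarray(distances, dtype=float)
    return float(np.mean(d > np.abs(center_h - nh)))


def index_S(center_layer: str, neighbor_layers, same_layer: bool = True) -> float:
    """Forest layer index.

    S = (z/3) x mean(t_j) with z the number of distinct layers among the
    centre and its neighbours and t_j = 1 when neighbour j shares the
    centre's layer (``same_layer=False`` counts differing layers instead,
    the complementary convention found in part of the literature).
    """
    nl = np.asarray(neighbor_layers)
    if nl.size == 0:
        raise ValueError("need at least one neighbour")
    z = len(set(nl.tolist()) | {center_layer})
    t = nl == center_layer
    if not same_layer:
        t = ~t
    return float(z / 3.0 * np.mean(t))


def compute_indices(
    trees: pd.DataFrame,
    plot: PlotGeometry | None = None,
    resolution: float = 0.1,
    weights: np.ndarray | None = None,
    k_denominator: str = "neighbor",
    s_same_layer: bool = True,
    neighbor_mode: str = "voronoi",
    n_neighbors: int = 4,
) -> pd.DataFrame:
    """Full per-centre index table for one plot.

    Runs weights -> weighted Voronoi -> structural units -> layers -> the
    six indices.  ``neighbor_mode='nearest'`` swaps Voronoi adjacency for
    fixed-n nearest neighbours.  Returns one row per core tree with columns
    ``tree_id, n, W, U, UCI, S, K, OP, layer`` (W is NaN for single-
    neighbour units).
    """
    plot = plot or PlotGeometry()
    if neighbor_mode == "voronoi":
        _, adjacency = weighted_voronoi(trees, weights=weights, plot=plot, resolution=resolution)
        units = structural_units(adjacency, trees, plot=plot)
    elif neighbor_mode == "nearest":
        units = nearest_neighbor_units(trees, plot=plot, n_neighbors=n_neighbors)
    else:
        raise ValueError(f"unknown neighbor_mode {neighbor_mode!r}")
    heights = trees["height"].to_numpy(dtype=float)
    layers = assign_layers(heights)
    rows = []
    for u in units:
        ch = heights[u.center_index]
        nh = heights[u.neighbor_indices]
        nl = layers.layers[u.neighbor_indices]
        cl = layers.layers[u.center_index]
        rows.append(
            {
                "tree_id": u.center_id,
                "n": u.n,
                "W": index_W(u.azimuths) if u.n >= 2 else np.nan,
                "U": index_U(ch, nh),
                "UCI": index_UCI(ch, nh, u.distances),
                "S": index_S(cl, nl, same_layer=s_same_layer),
                "K": index_K(u.distances, nh, center_h=ch, denominator=k_denominator),
                "OP": index_OP(ch, nh, u.distances),
                "layer": cl,
            }
        )
    return pd.DataFrame(rows)


# -- classification --------------------------------------------------------
_UNIT_BINS = (0.25, 0.5, 0.75, 1.0)
_K_BINS = (0.2, 0.3, 0.4, 0.5)

INDEX_CLASS_MEANINGS = {
    "U": ("superior", "sub-superior", "moderation", "disadvantage", "absolute disadvantage"),
    "UCI": ("no pressure", "less pressure", "medium pressure", "greater pressure", "great pressure"),
    "OP": ("completely occluded", "occluded", "medium open", "open", "extremely open"),
    "W": ("absolute uniform", "uniform", "random", "aggregation", "cluster distributions"),
    "S": ("single", "slightly simple", "medium", "slightly complex", "complex"),
    "K": ("serious insufficiency", "insufficiency", "basic sufficiency", "sufficient", "more than sufficient"),
}


def class_bin(value: float, index_name: str) -> int:
    """0-based class index (5 classes per index)."""
    v = float(value)
    if index_name == "K":
        if v <= 0:
            raise ValueError(f"K must be > 0, got {v}")
        for i, edge in enumerate(_K_BINS):
            if v <= edge:
                return i
        return 4
    if index_name in {"W", "U", "UCI", "S", "OP"}:
        if v < 0 or v > 1:
            raise ValueError(f"{index_name} must be in [0, 1], got {v}")
        if v == 0:
            return 0
        for i, edge in enumerate(_UNIT_BINS):
            if v <= edge:
                return i + 1
        return 4  # unreachable; v <= 1 is caught above
    raise ValueError(f"unknown index {index_name!r}")


def classify_index(value: float, index_name: str) -> str:
    """Interval label of a value, e.g. OP=0.9 -> '(0.75,1]'."""
    b = class_bin(value, index_name)
    if index_name == "K":
        labels = ("(0,0.2]", "(0.2,0.3]", "(0.3,0.4]", "(0.4,0.5]", "(0.5,inf)")
    else:
        labels = ("0", "(0,0.25]", "(0.25,0.5]", "(0.5,0.75]", "(0.75,1]")
    return labels[b]


# -- plot/age-group summaries ---------------------------------------------
def _compact_letters(groups: list, sig: dict, order: np.ndarray) -> dict:
    """Compact letter display from pairwise significance via maximal cliques
    of the non-significant graph; letters follow descending group means."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(groups)
    for (a, b), is_sig in sig.items():
        if not is_sig:
            g.add_edge(a, b)
    cliques = list(nx.find_cliques(g))
    # stable ordering: cliques containing higher-mean groups get earlier letters
    rank = {grp: i for i, grp in enumerate(np.asarray(groups)[order])}
    cliques.sort(key=lambda c: min(rank[m] for m in c))
    letters = {grp: "" for grp in groups}
    for i, clique in enumerate(cliques):
        ch = chr(ord("a") + i)
        for grp in clique:
            letters[grp] += ch
    return {g_: "".join(sorted(v)) for g_, v in letters.items()}


def summarize_plot(
    indices: pd.DataFrame,
    group_col: str,
    value_cols: tuple = ("W", "U", "UCI", "S", "K", "OP"),
    alphas: tuple = (0.05, 0.1),
) -> pd.DataFrame:
    """Group means +/- SD with one-way ANOVA and compact letter displays.

    Returns one row per (index, group) with mean, sd, n, the ANOVA F and p
    for that index, and one letter column per alpha (groups sharing a letter
    are not significantly different by Tukey HSD at that alpha).  With a
    single group only means are reported.
    """
    out = []
    groups = list(pd.unique(indices[group_col]))
    for col in value_cols:
        sub = indices[[group_col, col]].dropna()
        samples = [sub.loc[sub[group_col] == g, col].to_numpy() for g in groups]
        means = [s.mean() if len(s) else np.nan for s in samples]
        sds = [s.std(ddof=1) if len(s) > 1 else np.nan for s in samples]
        f_stat = p_val = np.nan
        letters = {a: {g: "" for g in groups} for a in alphas}
        usable = [s for s in samples if len(s) > 1]
        if len(groups) >= 2 and len(usable) == len(samples):
            f_stat, p_val = stats.f_oneway(*samples)
            tuk = stats.tukey_hsd(*samples)
            order = np.argsort(means)[::-1]
            for a in alphas:
                sig = {}
                for i in range(len(groups)):
                    for j in range(i + 1, len(groups)):
                        sig[(groups[i], groups[j])] = tuk.pvalue[i, j] < a
                letters[a] = _compact_letters(groups, sig, order)
        for g, m, s, smp in zip(groups, means, sds, samples):
            row = {
                "index": col,
                "group": g,
                "n": len(smp),
                "mean": m,
                "sd": s,
                "anova_F": f_stat,
                "anova_p": p_val,
            }
            for a in alphas:
                row[f"letters_{a}"] = letters[a][g]
            out.append(row)
    return pd.DataFrame(out)
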