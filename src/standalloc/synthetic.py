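"""Synthetic Chinese-fir stand generator.

Generates stem maps (tree positions plus height / crown width / DBH
attributes), per-organ dry biomass, and cone-crowned canopy height rasters
with the statistical structure the downstream pipeline assumes, so that
segmentation, allometry, spatial-structure and allocation analyses are all
testable without field data.

Plots default to the survey geometry of 25.82 x 25.82 m (1/15 ha).  Age-group
attribute means, standard deviations and stand densities follow the plantation
survey summary (five age classes from young to overripe).  Spatial patterns:

``random``
    Homogeneous Poisson process (count ~ Poisson(density x area)).
``regular``
    Hard-core (minimum inter-tree distance) process via dart throwing.
``clustered``
    Matern cluster process: Poisson parents, Poisson offspring counts,
    offspring uniform in a disc of radius ``pattern_param`` around each
    parent.  Parents are placed in a window expanded by the cluster radius so
    intensity stays uniform inside the plot.

Crowns are right cones (linear height falloff from apex to crown edge),
matching the conical crown habit of Chinese fir.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .raster import CHMRaster

__all__ = [
    "AGE_GROUPS",
    "DBH_FROM_H_CW",
    "STEM_COEFFS",
    "BRANCH_COEFFS",
    "LEAF_COEFFS",
    "StandConfig",
    "generate_positions",
    "assign_attributes",
    "generate_stand",
    "synthesize_chm",
    "synthesize_biomass",
    "write_stem_map",
    "read_stem_map",
]

#: Survey attribute distributions per age group: (mean, sd) for height (m),
#: crown width (m) and DBH (cm), plus stand density (trees/ha).
AGE_GROUPS: Mapping[str, dict] = {
    "young": {"height": (9.1, 0.8), "crown_width": (2.4, 0.2), "dbh": (12.2, 1.5), "density": 2533.7},
    "middle-aged": {"height": (13.2, 1.8), "crown_width": (2.5, 0.6), "dbh": (14.6, 2.3), "density": 2006.5},
    "near-ripe": {"height": (16.4, 1.2), "crown_width": (2.6, 0.6), "dbh": (17.9, 1.5), "density": 2088.9},
    "mature": {"height": (17.7, 1.1), "crown_width": (2.8, 0.3), "dbh": (21.1, 2.5), "density": 1256.8},
    "overripe": {"height": (22.9, 3.9), "crown_width": (3.0, 0.7), "dbh": (21.4, 6.0), "density": 1279.4},
}

#: Linear DBH model used as the generative link between (H, CW) and DBH:
#: DBH = 1.475 H + 2.965 CW - 13.117 (cm; H, CW in m).
DBH_FROM_H_CW: tuple[float, float, float] = (1.475, 2.965, -13.117)

#: Power-law stem biomass coefficients: W_stem = a (D^2 H)^b  (kg).
STEM_COEFFS: tuple[float, float] = (0.054, 0.786)
#: Log-log branch biomass coefficients: ln W = a + b ln D + c ln H.
BRANCH_COEFFS: tuple[float, float, float] = (-5.907, 1.921, 0.779)
#: Log-log leaf biomass coefficients: ln W = a + b ln D + c ln H.
LEAF_COEFFS: tuple[float, float, float] = (-0.238, 0.214, 0.656)

#: Lower truncation bounds for sampled attributes.
_H_MIN, _CW_MIN, _DBH_MIN = 0.1, 0.1, 1.0


@dataclass
class StandConfig:
    """Configuration of one synthetic stand."""

    plot_width: float = 25.82
    plot_height: float = 25.82
    density: float = 2000.0          # trees per hectare
    pattern: str = "random"          # random | regular | clustered
    pattern_param: float = 1.0       # hard-core radius m, or cluster radius m
    cluster_offspring: float = 5.0   # mean offspring per Matern parent
    age_group: str | None = None
    attr_means: dict = field(default_factory=lambda: {"height": 15.0, "crown_width": 2.6, "dbh": 18.0})
    attr_sds: dict = field(default_factory=lambda: {"height": 1.5, "crown_width": 0.4, "dbh": 2.0})
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.plot_width <= 0 or self.plot_height <= 0:
            raise ValueError("plot dimensions must be > 0")
        if self.density < 0:
            raise ValueError("density must be >= 0")
        if self.pattern not in {"random", "regular", "clustered"}:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        for attr in ("height", "crown_width", "dbh"):
            if self.attr_means[attr] <= 0 or self.attr_sds[attr] < 0:
                raise ValueError(f"attribute {attr}: mean must be > 0 and sd >= 0")

    @classmethod
    def from_age_group(cls, age_group: str, seed: int | None = None, **overrides) -> "StandConfig":
        """Build a config from the surveyed age-group parameters."""
        try:
            row = AGE_GROUPS[age_group]
        except KeyError:
            raise ValueError(
                f"unknown age group {age_group!r}; expected one of {sorted(AGE_GROUPS)}"
            ) from None
        cfg = cls(
            density=row["density"],
            age_group=age_group,
            attr_means={k: row[k][0] for k in ("height", "crown_width", "dbh")},
            attr_sds={k: row[k][1] for k in ("height", "crown_width", "dbh")},
            seed=seed,
        )
        return replace(cfg, **overrides) if overrides else cfg

    @property
    def area_ha(self) -> float:
        return self.plot_width * self.plot_height / 1e4


def _rng(config_seed, rng=None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(config_seed)


def generate_positions(config: StandConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw tree positions for one plot.

    Returns an ``(n, 2)`` array of (x, y) in metres.  The expected count is
    ``density x plot area``.  Identical seeds give identical output.

    Raises
    ------
    RuntimeError
        If ``pattern='regular'`` and the requested density cannot be packed
        at the hard-core radius within a bounded number of attempts.
    """
    rng = _rng(config.seed, rng)
    w, h = config.plot_width, config.plot_height
    n_expected = config.density * config.area_ha
    if n_expected == 0:
        return np.empty((0, 2))

    if config.pattern == "random":
        n = rng.poisson(n_expected)
        return rng.uniform((0, 0), (w, h), size=(n, 2))

    if config.pattern == "regular":
        n = rng.poisson(n_expected)
        r2 = config.pattern_param**2
        pts: list[np.ndarray] = []
        attempts, max_attempts = 0, max(1000, 500 * n)
        while len(pts) < n:
            if attempts >= max_attempts:
                raise RuntimeError(
                    f"hard-core packing infeasible: placed {len(pts)}/{n} trees at "
                    f"radius {config.pattern_param} m after {attempts} attempts"
                )
            cand = rng.uniform((0, 0), (w, h))
            attempts += 1
            if all(np.sum((cand - p) ** 2) >= r2 for p in pts):
                pts.append(cand)
        return np.array(pts) if pts else np.empty((0, 2))

    # clustered: Matern cluster process
    radius = config.pattern_param
    mu = config.cluster_offspring
    parent_intensity = n_expected / (w * h) / mu  # per m^2
    ew, eh = w + 2 * radius, h + 2 * radius
    n_parents = rng.poisson(parent_intensity * ew * eh)
    out = []
    for _ in range(n_parents):
        parent = rng.uniform((-radius, -radius), (w + radius, h + radius))
        k = rng.poisson(mu)
        if k == 0:
            continue
        theta = rng.uniform(0, 2 * np.pi, k)
        rad = radius * np.sqrt(rng.uniform(0, 1, k))
        pts = parent + np.column_stack([rad * np.cos(theta), rad * np.sin(theta)])
        inside = (pts[:, 0] >= 0) & (pts[:, 0] <= w) & (pts[:, 1] >= 0) & (pts[:, 1] <= h)
        out.append(pts[inside])
    return np.vstack(out) if out else np.empty((0, 2))


def assign_attributes(
    positions: np.ndarray,
    config: StandConfig,
    rng: np.random.Generator | None = None,
    dbh_noise_sd: float | None = None,
    plot_id: str = "P1",
) -> pd.DataFrame:
    """Attach height, crown width and DBH to positions.

    Heights and crown widths are drawn from normals truncated at 0.1 m.  DBH
    is generated from the linear (H, CW) link ``DBH_FROM_H_CW`` plus Gaussian
    noise (sd = ``dbh_noise_sd``, default the configured DBH sd), clipped to
    >= 1 cm, so the DBH-model stage has a recoverable signal.  The joint
    (H, CW, DBH) distribution of real stands is unknown; this generative link
    is a stand-in.

    Returns a stem-map DataFrame with columns
    ``tree_id, x, y, height, crown_width, dbh, plot_id, age_group, is_buffer``.
    """
    rng = _rng(config.seed, rng)
    positions = np.asarray(positions, dtype=float).reshape(-1, 2)
    n = len(positions)
    if n and (
        positions[:, 0].min() < 0
        or positions[:, 0].max() > config.plot_width
        or positions[:, 1].min() < 0
        or positions[:, 1].max() > config.plot_height
    ):
        raise ValueError("positions must lie within the plot")

    def trunc_normal(mean, sd, lower):
        if sd == 0:
            return np.full(n, mean)
        a = (lower - mean) / sd
        return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)

    height = trunc_normal(*_pair(config, "height"), _H_MIN)
    cw = trunc_normal(*_pair(config, "crown_width"), _CW_MIN)
    bh, bcw, b0 = DBH_FROM_H_CW
    noise_sd = config.attr_sds["dbh"] if dbh_noise_sd is None else dbh_noise_sd
    noise = rng.normal(0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    dbh = np.maximum(bh * height + bcw * cw + b0 + noise, _DBH_MIN)

    return pd.DataFrame(
        {
            "tree_id": np.arange(1, n + 1),
            "x": positions[:, 0],
            "y": positions[:, 1],
            "height": height,
            "crown_width": cw,
            "dbh": dbh,
            "plot_id": plot_id,
            "age_group": config.age_group or "",
            "is_buffer": False,
        }
    )


def _pair(config: StandConfig, attr: str) -> tuple[float, float]:
    return config.attr_means[attr], config.attr_sds[attr]


def generate_stand(
    config: StandConfig, dbh_noise_sd: float | None = None, plot_id: str = "P1"
) -> pd.DataFrame:
    """Positions + attributes in one deterministic call (single RNG stream)."""
    rng = _rng(config.seed)
    positions = generate_positions(config, rng=rng)
    return assign_attributes(positions, config, rng=rng, dbh_noise_sd=dbh_noise_sd, plot_id=plot_id)


def synthesize_chm(
    trees: pd.DataFrame,
    resolution: float = 0.1,
    plot_width: float | None = None,
    plot_height: float | None = None,
) -> CHMRaster:
    """Rasterize cone crowns into a canopy height model.

    Each tree contributes a right cone ``H * max(0, 1 - 2 d / CW)`` around
    its stem; pixels take the maximum over all trees, and the pixel
    containing each apex is set to the exact tree height (the apex carries
    the tree height in CHM-based workflows).  Pixels outside all crowns are 0.
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    if plot_width is None:
        plot_width = 25.82 if trees.empty else max(25.82, float(trees["x"].max()))
    if plot_height is None:
        plot_height = 25.82 if trees.empty else max(25.82, float(trees["y"].max()))
    nc = int(np.ceil(plot_width / resolution))
    nr = int(np.ceil(plot_height / resolution))
    values = np.zeros((nr, nc))
    chm = CHMRaster(values=values, resolution=resolution, origin=(0.0, 0.0))
    if trees.empty:
        return chm

    if float(trees["crown_width"].min()) < 4 * resolution:
        import warnings

        warnings.warn(
            "some crowns are narrower than 4 pixels; neighbouring apexes may merge",
            stacklevel=2,
        )

    cols = np.arange(nc)
    rows = np.arange(nr)
    px = (cols + 0.5) * resolution
    py = (nr - rows - 0.5) * resolution
    for _, t in trees.iterrows():
        r_crown = t.crown_width / 2.0
        c0 = max(0, int((t.x - r_crown) / resolution) - 1)
        c1 = min(nc, int((t.x + r_crown) / resolution) + 2)
        rr1 = min(nr, nr - int((t.y - r_crown) / resolution) + 1)
        rr0 = max(0, nr - int((t.y + r_crown) / resolution) - 2)
        if c0 >= c1 or rr0 >= rr1:
            continue
        dx = px[c0:c1] - t.x
        dy = py[rr0:rr1] - t.y
        dist = np.hypot(dx[None, :], dy[:, None])
        cone = t.height * np.maximum(0.0, 1.0 - dist / r_crown)
        np.maximum(values[rr0:rr1, c0:c1], cone, out=values[rr0:rr1, c0:c1])
    # exact apex fidelity
    ar, ac = chm.world_to_pixel(trees["x"].to_numpy(), trees["y"].to_numpy())
    np.maximum.at(values, (ar, ac), trees["height"].to_numpy())
    chm.values = values
    return chm


def synthesize_biomass(
    trees: pd.DataFrame,
    coeffs: dict | None = None,
    sigma_log: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate organ dry weights from the allometric equations.

    Each organ is the deterministic allometric prediction multiplied by
    ``exp(N(0, sigma_log))`` (multiplicative log-normal noise, independent
    per organ and tree).  ``sigma_log=0`` reproduces the equations exactly.

    Returns a DataFrame with columns ``stem, branch, leaf, agb`` (kg);
    ``agb`` is the sum of the three organs.
    """
    if sigma_log < 0:
        raise ValueError("sigma_log must be >= 0")
    coeffs = coeffs or {"stem": STEM_COEFFS, "branch": BRANCH_COEFFS, "leaf": LEAF_COEFFS}
    rng = _rng(seed, rng)
    D = trees["dbh"].to_numpy(dtype=float)
    H = trees["height"].to_numpy(dtype=float)
    if np.any(D <= 0) or np.any(H <= 0):
        raise ValueError("DBH and height must be positive")

    a_s, b_s = coeffs["stem"]
    stem = a_s * (D**2 * H) ** b_s
    a_b, b_b, c_b = coeffs["branch"]
    branch = np.exp(a_b + b_b * np.log(D) + c_b * np.log(H))
    a_l, b_l, c_l = coeffs["leaf"]
    leaf = np.exp(a_l + b_l * np.log(D) + c_l * np.log(H))

    if sigma_log > 0:
        stem = stem * np.exp(rng.normal(0, sigma_log, len(D)))
        branch = branch * np.exp(rng.normal(0, sigma_log, len(D)))
        leaf = leaf * np.exp(rng.normal(0, sigma_log, len(D)))

    out = pd.DataFrame({"stem": stem, "branch": branch, "leaf": leaf}, index=trees.index)
    out["agb"] = out.sum(axis=1)
    return out


# -- stem-map CSV I/O ------------------------------------------------------
STEM_MAP_COLUMNS: Sequence[str] = (
    "tree_id", "x", "y", "height", "crown_width", "dbh", "plot_id", "age_group", "is_buffer",
)


def write_stem_map(trees: pd.DataFrame, path) -> None:
    trees.loc[:, STEM_MAP_COLUMNS].to_csv(path, index=False)


def read_stem_map(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    missing = set(STEM_MAP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"stem map missing columns: {sorted(missing)}")
    df["is_buffer"] = df["is_buffer"].astype(bool)
    return df
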