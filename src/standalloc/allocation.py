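"""Path analysis and four-element distribution of biomass fractions.

Quantifies how stand spatial structure (UCI, K, OP, W, S) together with tree
size (H, DBH) shapes the stem/branch/leaf mass fractions:

* collinearity screening by iterated VIF elimination,
* forward-backward stepwise selection on standardised variables,
* path decomposition of each predictor's correlation with the response into
  a direct effect (standardised coefficient p_i) and indirect effects routed
  through the other retained predictors (r_ik p_k), with the decision
  coefficient R_i = 2 p_i r_iy - p_i^2 ranking net contributions,
* 25 x 25 "four-element" grids of mean fraction over joint classes of
  (UCI, K) on one axis and (OP, S) on the other (625 combinations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .structure import class_bin

__all__ = [
    "PathResult",
    "FourElementGrid",
    "PairedTTest",
    "collinearity_screen",
    "stepwise_select",
    "path_decompose",
    "four_element_grid",
    "paired_validation",
    "decision_coefficient",
]

STRUCTURE_VARS = ("UCI", "K", "OP", "W", "S", "H", "DBH")
FRACTIONS = ("smf", "bmf", "fmf")


def decision_coefficient(direct: float, total_corr: float) -> float:
    """R_i = 2 p_i r_iy - p_i^2: net contribution of predictor i."""
    return 2.0 * direct * total_corr - direct**2


def _vif(X: np.ndarray) -> np.ndarray:
    """VIF of each column of X (intercept added internally)."""
    n, k = X.shape
    out = np.empty(k)
    for i in range(k):
        others = sm.add_constant(np.delete(X, i, axis=1)) if k > 1 else np.ones((n, 1))
        r2 = sm.OLS(X[:, i], others).fit().rsquared
        out[i] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def collinearity_screen(
    X: pd.DataFrame, threshold: float = 10.0
) -> tuple[list, pd.DataFrame]:
    """Iteratively drop the highest-VIF predictor while any VIF > threshold.

    Returns ``(retained columns, report)``; the report logs each round's
    VIFs and the column dropped.
    """
    cols = list(X.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 predictors")
    report = []
    round_no = 0
    while True:
        vals = _vif(X[cols].to_numpy(dtype=float))
        worst = int(np.argmax(vals))
        drop = cols[worst] if vals[worst] > threshold else None
        for c, v in zip(cols, vals):
            report.append({"round": round_no, "predictor": c, "vif": v, "dropped": c == drop})
        if drop is None:
            break
        cols.remove(drop)
        round_no += 1
        if len(cols) < 2:
            if _vif(X[cols].to_numpy(dtype=float)).max() > threshold:
                raise ValueError("all predictors mutually collinear")
            break
    return cols, pd.DataFrame(report)


def _standardize(a: np.ndarray) -> np.ndarray:
    return (a - a.mean(axis=0)) / a.std(axis=0, ddof=1)


def stepwise_select(
    X: pd.DataFrame,
    y,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
) -> list:
    """Classical forward-backward stepwise regression on standardised data.

    A candidate enters when its partial-F p-value (equivalently its
    coefficient t-test in the augmented model) is the smallest below
    ``alpha_enter``; after each entry, retained predictors with p-value
    above ``alpha_remove`` are removed (worst first).  Deterministic given
    column order; ties go to the earlier column.
    """
    if not alpha_enter < alpha_remove:
        raise ValueError("alpha_enter must be < alpha_remove")
    cols = list(X.columns)
    Xz = pd.DataFrame(_standardize(X.to_numpy(dtype=float)), columns=cols)
    yz = _standardize(np.asarray(y, dtype=float).reshape(-1, 1)).ravel()
    retained: list = []
    seen: set[frozenset] = set()
    while True:
        state = frozenset(retained)
        if state in seen:  # guard against forward/backward cycling
            break
        seen.add(state)
        changed = False
        # perfect fit: partial-F tests for further entry are meaningless
        if retained:
            r2 = sm.OLS(yz, sm.add_constant(Xz[retained].to_numpy())).fit().rsquared
            if r2 >= 1 - 1e-12:
                break
        candidates = [c for c in cols if c not in retained]
        best_c, best_p = None, np.inf
        for c in candidates:
            exog = sm.add_constant(Xz[retained + [c]].to_numpy())
            res = sm.OLS(yz, exog).fit()
            p = res.pvalues[-1]
            if np.isfinite(p) and p < best_p - 1e-15:
                best_c, best_p = c, p
        if best_c is not None and best_p < alpha_enter:
            retained.append(best_c)
            changed = True
        # backward pass
        while len(retained) > 0:
            exog = sm.add_constant(Xz[retained].to_numpy())
            pvals = sm.OLS(yz, exog).fit().pvalues[1:]
            worst = int(np.argmax(pvals))
            if pvals[worst] > alpha_remove:
                retained.pop(worst)
                changed = True
            else:
                break
        if not changed:
            break
    if not retained:
        import warnings

        warnings.warn("no predictor met the entry threshold; empty model")
    return retained


@dataclass
class PathResult:
    """Direct/indirect/total effects and decision coefficients.

    ``directs[i]`` is the standardised coefficient of retained predictor i
    (0 for unretained variables); ``indirect[i][k] = r_ik p_k`` is the
    indirect effect of variable i routed through retained predictor k; the
    total effect of i is its plain correlation with the response, and for
    retained i the identity r_iy = p_i + sum_k r_ik p_k holds exactly.
    """

    response: str
    variables: list
    retained: list
    directs: dict
    indirect: dict           # var -> {retained var -> r_ik p_k}
    totals: dict             # var -> r_iy
    decision: dict           # var -> 2 p_i r_iy - p_i^2
    direct_pvalues: dict
    total_pvalues: dict
    r_squared: float
    residual: float
    residual_kind: str = "one_minus_r2"

    def indirect_total(self, var) -> float:
        return sum(self.indirect[var].values())

    @staticmethod
    def stars(p: float) -> str:
        if np.isnan(p):
            return ""
        if p < 0.05:
            return "**"
        if p < 0.1:
            return "*"
        return ""

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v in self.variables:
            row = {
                "response": self.response,
                "factor": v,
                "correlation": self.totals[v],
                "corr_sig": self.stars(self.total_pvalues[v]),
                "direct": self.directs[v],
                "direct_sig": self.stars(self.direct_pvalues.get(v, np.nan)),
            }
            for k in self.variables:
                row[f"via_{k}"] = self.indirect[v].get(k, np.nan) if k != v else np.nan
            row["indirect_total"] = self.indirect_total(v)
            row["decision"] = self.decision[v]
            rows.append(row)
        return pd.DataFrame(rows)


def path_decompose(
    X: pd.DataFrame,
    y,
    retained: list | None = None,
    response: str = "y",
    residual: str = "one_minus_r2",
) -> PathResult:
    """Path-analysis decomposition of correlations into direct and indirect
    effects.

    Variables are standardised internally; direct effects solve the normal
    equations ``R_rr p = r_ry`` over the retained set.  Unretained variables
    are reported with direct effect 0, their indirect effects through each
    retained predictor, and their raw correlation as total.  The residual is
    1 - R^2 by default (``residual='sqrt'`` for sqrt(1 - R^2)).
    """
    variables = list(X.columns)
    if retained is None:
        retained = variables
    if not retained:
        raise ValueError("retained predictor set must be non-empty")
    Xa = X.to_numpy(dtype=float)
    ya = np.asarray(y, dtype=float).ravel()
    full = np.column_stack([Xa, ya])
    R = np.corrcoef(full, rowvar=False)
    r_xy = {v: R[i, -1] for i, v in enumerate(variables)}
    r_xx = R[:-1, :-1]
    idx = {v: i for i, v in enumerate(variables)}
    ri = [idx[v] for v in retained]
    R_rr = r_xx[np.ix_(ri, ri)]
    cond = np.linalg.cond(R_rr)
    if cond > 1e12:
        off = np.abs(R_rr - np.eye(len(ri)))
        a, b = np.unravel_index(np.argmax(off), off.shape)
        raise ValueError(
            f"singular correlation matrix among retained predictors "
            f"(worst pair: {retained[a]}, {retained[b]})"
        )
    p_vec = np.linalg.solve(R_rr, np.array([r_xy[v] for v in retained]))
    p = {v: float(p_vec[k]) for k, v in enumerate(retained)}

    directs = {v: p.get(v, 0.0) for v in variables}
    indirect = {
        v: {k: float(r_xx[idx[v], idx[k]] * p[k]) for k in retained if k != v}
        for v in variables
    }
    totals = {v: float(r_xy[v]) for v in variables}
    decision = {v: decision_coefficient(directs[v], totals[v]) for v in variables}
    r2 = float(sum(p[v] * r_xy[v] for v in retained))
    resid = float(np.sqrt(max(0.0, 1 - r2))) if residual == "sqrt" else float(1 - r2)

    # significance: coefficient t-tests on the standardised OLS, and
    # correlation t-tests for the totals
    n = len(ya)
    Xz = _standardize(Xa)
    yz = _standardize(ya.reshape(-1, 1)).ravel()
    ols = sm.OLS(yz, sm.add_constant(Xz[:, ri])).fit()
    direct_pvalues = {v: float(ols.pvalues[k + 1]) for k, v in enumerate(retained)}
    total_pvalues = {}
    for v in variables:
        r = totals[v]
        if abs(r) >= 1:
            total_pvalues[v] = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1 - r**2))
            total_pvalues[v] = float(2 * stats.t.sf(abs(t), n - 2))

    return PathResult(
        response=response,
        variables=variables,
        retained=list(retained),
        directs=directs,
        indirect=indirect,
        totals=totals,
        decision=decision,
        direct_pvalues=direct_pvalues,
        total_pvalues=total_pvalues,
        r_squared=r2,
        residual=resid,
        residual_kind=residual,
    )


@dataclass
class FourElementGrid:
    """25 x 25 grid of mean fraction over joint structure classes.

    Columns (x) encode (UCI class, K class) as ``uci_bin * 5 + k_bin``;
    rows (y) encode (OP class, S class) as ``op_bin * 5 + s_bin``.  Empty
    combinations are NaN in ``values`` and 0 in ``counts``.
    """

    fraction: str
    values: np.ndarray          # (25, 25), NaN where empty
    counts: np.ndarray          # (25, 25) int
    argmax_cell: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.values.size

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for yi in range(25):
            for xi in range(25):
                rows.append(
                    {
                        "uci_bin": xi // 5,
                        "k_bin": xi % 5,
                        "op_bin": yi // 5,
                        "s_bin": yi % 5,
                        "n": int(self.counts[yi, xi]),
                        f"mean_{self.fraction}": self.values[yi, xi],
                    }
                )
        return pd.DataFrame(rows)


def four_element_grid(obs: pd.DataFrame, fraction_name: str) -> FourElementGrid:
    """Mean biomass fraction in each of the 625 structure-class combinations.

    ``obs`` needs columns ``UCI, K, OP, S`` (index values) and the fraction.
    The argmax cell (row-major first on ties) is recorded with its class
    bins; its combination identifies the structural conditions maximising
    the fraction.
    """
    if obs.empty:
        raise ValueError("empty observation table")
    if fraction_name not in obs.columns:
        raise ValueError(f"no column {fraction_name!r}")
    values = np.full((25, 25), np.nan)
    counts = np.zeros((25, 25), dtype=int)
    sums = np.zeros((25, 25))
    for _, row in obs.iterrows():
        xi = class_bin(row["UCI"], "UCI") * 5 + class_bin(row["K"], "K")
        yi = class_bin(row["OP"], "OP") * 5 + class_bin(row["S"], "S")
        sums[yi, xi] += row[fraction_name]
        counts[yi, xi] += 1
    nz = counts > 0
    values[nz] = sums[nz] / counts[nz]
    best = np.nanmax(values[nz]) if nz.any() else np.nan
    argmax_cell = {}
    if nz.any():
        yi, xi = np.argwhere(np.where(np.isnan(values), -np.inf, values) == best)[0]
        argmax_cell = {
            "uci_bin": int(xi) // 5,
            "k_bin": int(xi) % 5,
            "op_bin": int(yi) // 5,
            "s_bin": int(yi) % 5,
            "mean": float(best),
        }
    return FourElementGrid(
        fraction=fraction_name, values=values, counts=counts, argmax_cell=argmax_cell
    )


def plot_four_element_grid(grid: FourElementGrid, ax=None):
    """Heat-map rendering of a four-element grid (masked empty cells)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 6))
    masked = np.ma.masked_invalid(grid.values)
    im = ax.imshow(masked, origin="lower", cmap="viridis")
    ax.set_xlabel("UCI class x 5 + K class")
    ax.set_ylabel("OP class x 5 + S class")
    ax.set_title(f"Mean {grid.fraction.upper()} by structure combination")
    plt.colorbar(im, ax=ax, label=f"mean {grid.fraction}")
    return ax


@dataclass
class PairedTTest:
    mean_diff: float
    sd: float
    se: float
    t_stat: float
    df: int
    p_value: float
    degenerate: bool = False


def paired_validation(observed, predicted) -> PairedTTest:
    """Two-sided paired t-test of observed vs predicted values."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or len(obs) < 2:
        raise ValueError("need equal-length 1-D vectors with n >= 2")
    d = obs - pred
    n = len(d)
    mean, sd = d.mean(), d.std(ddof=1)
    se = sd / np.sqrt(n)
    if sd == 0:
        if mean == 0:
            return PairedTTest(0.0, 0.0, 0.0, 0.0, n - 1, 1.0, degenerate=True)
        return PairedTTest(mean, 0.0, 0.0, np.inf, n - 1, 0.0, degenerate=True)
    t, p = stats.ttest_rel(obs, pred)
    return PairedTTest(mean, sd, se, float(t), n - 1, float(p))
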