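"""Allometric biomass and DBH models.

Nine candidate model forms relate an organ's dry weight W (kg) to DBH D (cm)
and height H (m):

====  =======================  =========  ==========
form  equation                 fit scale  predictors
====  =======================  =========  ==========
1     W = a H^b                natural    H
2     W = a D^b                natural    D
3     W = a (D^2 H)^b          natural    D^2 H
4     W = a + b (D^2 H)        natural    D^2 H
5     ln W = a + b ln D        log        D
6     ln W = a + b D + c D^2   log        D
7     ln W = a + b ln H        log        H
8     ln W = a + b ln(D^2 H)   log        D^2 H
9     ln W = a + b lnD + c lnH log        D, H
====  =======================  =========  ==========

Forms 4-9 are fitted by OLS; forms 1-3 by Levenberg-Marquardt nonlinear
least squares initialised from the linearised log-log fit.  Goodness of fit
(R^2, RMSE = sqrt(SSE/n), MAE) is reported on the fit scale, so log-form
errors are in ln-kg.  The best form per organ is the one with maximal R^2
(ties to lower RMSE).  Back-transformation of log forms uses plain
exponentiation by default; a Baskerville-style correction is optional.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit
from scipy import stats

__all__ = [
    "FitResult",
    "DBHModel",
    "fit_form",
    "fit_all_forms",
    "goodness",
    "select_best",
    "predict_organs",
    "fit_dbh",
    "compute_fractions",
    "ORGANS",
    "LOG_FORMS",
]

ORGANS = ("stem", "branch", "leaf")
LOG_FORMS = frozenset({5, 6, 7, 8, 9})
_VALID_FORMS = range(1, 10)


@dataclass
class FitResult:
    """One fitted model form for one organ."""

    organ: str
    form_id: int
    a: float
    b: float
    c: float | None
    r2: float
    rmse: float
    mae: float
    n: int

    @property
    def scale(self) -> str:
        return "log" if self.form_id in LOG_FORMS else "natural"

    def predict(self, dbh, height, bias_correction: bool = False) -> np.ndarray:
        """Organ biomass (kg) at DBH (cm) and height (m), natural scale."""
        D = np.asarray(dbh, dtype=float)
        H = np.asarray(height, dtype=float)
        if np.any(D <= 0) or np.any(H <= 0):
            raise ValueError("DBH and height must be positive")
        f, a, b, c = self.form_id, self.a, self.b, self.c
        if f == 1:
            return a * H**b
        if f == 2:
            return a * D**b
        if f == 3:
            return a * (D**2 * H) ** b
        if f == 4:
            return a + b * (D**2 * H)
        if f == 5:
            ln = a + b * np.log(D)
        elif f == 6:
            ln = a + b * D + c * D**2
        elif f == 7:
            ln = a + b * np.log(H)
        elif f == 8:
            ln = a + b * np.log(D**2 * H)
        else:  # 9
            ln = a + b * np.log(D) + c * np.log(H)
        if bias_correction:
            ln = ln + self.rmse**2 / 2.0  # log-scale RMSE as sigma estimate
        return np.exp(ln)

    def to_dict(self) -> dict:
        return asdict(self)


def goodness(observed, predicted, n_params: int | None = None):
    """R^2 = 1 - SSE/SST, RMSE = sqrt(SSE/n), MAE, on the supplied scale.

    Raises ``ValueError`` when the observed vector has zero variance (R^2
    undefined).  ``n_params`` is accepted for interface symmetry; errors are
    not degree-of-freedom adjusted.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be equal-length 1-D vectors")
    if len(obs) < 2:
        raise ValueError("need at least 2 observations")
    sst = np.sum((obs - obs.mean()) ** 2)
    if sst == 0:
        raise ValueError("observed values have zero variance; R^2 undefined")
    resid = obs - pred
    sse = np.sum(resid**2)
    return 1 - sse / sst, np.sqrt(sse / len(obs)), np.mean(np.abs(resid))


def _design(form_id: int, D: np.ndarray, H: np.ndarray) -> np.ndarray:
    if form_id == 4:
        return np.column_stack([D**2 * H])
    if form_id == 5:
        return np.column_stack([np.log(D)])
    if form_id == 6:
        return np.column_stack([D, D**2])
    if form_id == 7:
        return np.column_stack([np.log(H)])
    if form_id == 8:
        return np.column_stack([np.log(D**2 * H)])
    if form_id == 9:
        return np.column_stack([np.log(D), np.log(H)])
    raise ValueError(form_id)


def fit_form(records: pd.DataFrame, organ: str, form_id: int) -> FitResult:
    """Fit one model form for one organ on a harvest table.

    ``records`` needs columns ``dbh``, ``height`` and the organ weight.
    OLS forms are fitted on their stated (possibly log) transform; power-law
    forms 1-3 by nonlinear least squares started from the linearised fit.
    """
    if form_id not in _VALID_FORMS:
        raise ValueError(f"form_id must be 1-9, got {form_id}")
    if organ not in records.columns:
        raise ValueError(f"no column {organ!r} in harvest records")
    D = records["dbh"].to_numpy(dtype=float)
    H = records["height"].to_numpy(dtype=float)
    W = records[organ].to_numpy(dtype=float)
    if len(W) < 4:
        raise ValueError("need at least 4 records")
    if np.any(D <= 0) or np.any(H <= 0) or np.any(W <= 0):
        raise ValueError("predictors and weights must be positive")

    if form_id in (1, 2, 3):
        x = {1: H, 2: D, 3: D**2 * H}[form_id]
        if np.ptp(x) == 0:
            raise ValueError(f"singular design: predictor for form {form_id} is constant")
        # linearised initial guess: ln W = ln a + b ln x
        slope, intercept = np.polyfit(np.log(x), np.log(W), 1)
        p0 = (float(np.exp(intercept)), float(slope))
        popt, _ = curve_fit(
            lambda x, a, b: a * x**b, x, W, p0=p0, method="lm", xtol=1e-10, maxfev=20000
        )
        a, b, c = float(popt[0]), float(popt[1]), None
        pred = a * x**b
        r2, rmse, mae = goodness(W, pred)
        return FitResult(organ, form_id, a, b, c, r2, rmse, mae, len(W))

    y = W if form_id == 4 else np.log(W)
    X = _design(form_id, D, H)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), X])) < X.shape[1] + 1:
        raise ValueError(f"singular design for form {form_id} (constant predictor)")
    res = sm.OLS(y, sm.add_constant(X)).fit()
    params = res.params
    a = float(params[0])
    b = float(params[1])
    c = float(params[2]) if len(params) > 2 else None
    r2, rmse, mae = goodness(y, res.fittedvalues)
    return FitResult(organ, form_id, a, b, c, r2, rmse, mae, len(y))


def fit_all_forms(records: pd.DataFrame, organ: str) -> list[FitResult]:
    return [fit_form(records, organ, f) for f in _VALID_FORMS]


def select_best(fits: list[FitResult]) -> FitResult:
    """Best form = maximal R^2; ties broken by lower RMSE."""
    if not fits:
        raise ValueError("no fits to select from")
    return max(fits, key=lambda f: (f.r2, -f.rmse))


def fits_table(fits: list[FitResult]) -> pd.DataFrame:
    """All fits as a tidy table (organ, form, a, b, c, r2, rmse, mae)."""
    return pd.DataFrame([f.to_dict() for f in fits])


def predict_organs(
    trees: pd.DataFrame, fits: dict, bias_correction: bool = False
) -> pd.DataFrame:
    """Per-tree organ biomass from selected fits (one per organ).

    AGB is defined as the sum of the three organ predictions so that the
    mass fractions always sum to one.
    """
    missing = set(ORGANS) - set(fits)
    if missing:
        raise ValueError(f"missing fitted forms for organs: {sorted(missing)}")
    out = pd.DataFrame(
        {
            organ: fits[organ].predict(
                trees["dbh"], trees["height"], bias_correction=bias_correction
            )
            for organ in ORGANS
        },
        index=trees.index,
    )
    out["agb"] = out[list(ORGANS)].sum(axis=1)
    return out


def compute_fractions(organs: pd.DataFrame) -> pd.DataFrame:
    """Stem/branch/leaf mass fractions: organ biomass / AGB.

    AGB is recomputed as the component sum, so ``smf + bmf + fmf == 1``.
    """
    agb = organs[list(ORGANS)].sum(axis=1)
    if (agb <= 0).any():
        raise ValueError("AGB must be positive for every tree")
    return pd.DataFrame(
        {
            "smf": organs["stem"] / agb,
            "bmf": organs["branch"] / agb,
            "fmf": organs["leaf"] / agb,
        },
        index=organs.index,
    )


@dataclass
class DBHModel:
    """Linear DBH ~ height + crown width model with split validation."""

    coef_h: float
    coef_cw: float
    intercept: float
    r2: float
    vif: dict
    t_stat: float
    df: int
    p_value: float
    n_train: int
    n_test: int

    def predict(self, trees: pd.DataFrame) -> np.ndarray:
        return (
            self.coef_h * trees["height"].to_numpy()
            + self.coef_cw * trees["crown_width"].to_numpy()
            + self.intercept
        )


def fit_dbh(
    trees: pd.DataFrame, split_fraction: float = 0.7, seed: int | None = 0
) -> DBHModel:
    """Fit DBH = b_H H + b_CW CW + b_0 with a random train/validation split.

    VIF is computed for both predictors (flagged against the usual < 5
    rule); validation is a two-sided paired t-test of observed vs predicted
    DBH on the held-out split.  Identical seeds give identical splits.
    """
    if len(trees) < 10:
        raise ValueError("need at least 10 trees")
    if not 0 < split_fraction < 1:
        raise ValueError("split_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(trees))
    n_train = int(round(split_fraction * len(trees)))
    train = trees.iloc[idx[:n_train]]
    test = trees.iloc[idx[n_train:]]

    X = train[["height", "crown_width"]].to_numpy(dtype=float)
    r_hc = np.corrcoef(X[:, 0], X[:, 1])[0, 1]
    if abs(r_hc) > 1 - 1e-12:
        raise ValueError("height and crown width are perfectly collinear (VIF infinite)")
    vif = 1.0 / (1.0 - r_hc**2)  # identical for both predictors in a 2-var model
    res = sm.OLS(train["dbh"].to_numpy(dtype=float), sm.add_constant(X)).fit()
    model = DBHModel(
        coef_h=float(res.params[1]),
        coef_cw=float(res.params[2]),
        intercept=float(res.params[0]),
        r2=float(res.rsquared),
        vif={"height": vif, "crown_width": vif},
        t_stat=np.nan,
        df=len(test) - 1,
        p_value=np.nan,
        n_train=len(train),
        n_test=len(test),
    )
    if vif >= 5:
        warnings.warn(f"VIF {vif:.2f} >= 5: height and crown width collinear")
    if len(test) >= 2:
        t, p = stats.ttest_rel(test["dbh"].to_numpy(dtype=float), model.predict(test))
        model.t_stat, model.p_value = float(t), float(p)
    return model


# -- model persistence -----------------------------------------------------
def save_fits(fits: dict, path) -> None:
    """Write selected per-organ fits as JSON for downstream prediction."""
    with open(path, "w") as fh:
        json.dump({organ: fit.to_dict() for organ, fit in fits.items()}, fh, indent=1)


def load_fits(path) -> dict:
    with open(path) as fh:
        raw = json.load(fh)
    return {organ: FitResult(**d) for organ, d in raw.items()}
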