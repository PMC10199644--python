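"""ALS canopy metrics and the area-based regression models.

The area-based approach regresses plot-level forest attributes on canopy
metrics of the ALS point cloud — nine height percentiles, the mean return
height, and ten cumulative densities (proportions of returns above equally
spaced levels from breast height to the 95th percentile) — and applies the
fitted models wall-to-wall over grid cells.  Models are time-invariant: fitted
on observations from both survey epochs with a dummy T (0 for the first epoch,
1 for the second).

Four models are used, in the printed fixed forms:

  ln(D)   = b0 + b1*D_ALS_4 + b2*H_ALS_mean + b3*T
  Hdom    = b0 + b1*D_ALS_2 + b2*D_ALS_8 + b3*H_ALS_80 + b4*T
  ln(BMS) = b0 + b1*D_ALS_2 + b2*H_ALS_80 + b3*T
  H       = b0 + b1*Hdom + b2*T

A BIC/VIF subset-selection routine is provided for re-deriving such forms from
the candidate metric pool.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "HEIGHT_THRESHOLD",
    "METRIC_COLUMNS",
    "ALSMetricsError",
    "compute_als_metrics",
    "AreaModel",
    "AreaModelSet",
    "MODEL_FORMS",
    "fit_area_models",
    "select_area_model",
    "predict_cell_state",
]

HEIGHT_THRESHOLD = 1.3  # m; returns at or below are ground/understory

PERCENTILES = tuple(range(10, 100, 10))
METRIC_COLUMNS = (
    [f"H_ALS_{p}" for p in PERCENTILES]
    + ["H_ALS_mean"]
    + [f"D_ALS_{i}" for i in range(1, 11)]
)

#: response -> (log transform?, predictor columns); T is appended to each.
MODEL_FORMS = {
    "lnD": (True, "D", ["D_ALS_4", "H_ALS_mean"]),
    "Hdom": (False, "Hdom", ["D_ALS_2", "D_ALS_8", "H_ALS_80"]),
    "lnBMS": (True, "BMS", ["D_ALS_2", "H_ALS_80"]),
    "H": (False, "H", ["Hdom"]),
}

# physical floors for degenerate predictions
D_FLOOR = 0.1    # cm
H_FLOOR = 1.3    # m
BMS_FLOOR = 0.0  # Mg ha^-1


class ALSMetricsError(ValueError):
    pass


def compute_als_metrics(heights, threshold: float = HEIGHT_THRESHOLD) -> pd.Series:
    """Canopy metrics from a list of return heights (m above ground).

    Percentiles and the mean are computed over canopy returns (strictly above
    ``threshold``) using linear interpolation between order statistics.  The
    ten density levels are equally spaced from ``threshold`` to the 95th
    percentile of the canopy returns, and each density is the proportion of
    canopy returns strictly above its level.

    With no canopy returns a zero-canopy sentinel record (all metrics 0) is
    returned; an empty height list is an error.
    """
    heights = np.asarray(heights, dtype=float)
    if heights.size == 0:
        raise ALSMetricsError("empty height list")
    canopy = heights[heights > threshold]
    values = {}
    if canopy.size == 0:
        for col in METRIC_COLUMNS:
            values[col] = 0.0
        return pd.Series(values)
    for p in PERCENTILES:
        values[f"H_ALS_{p}"] = float(np.percentile(canopy, p))
    values["H_ALS_mean"] = float(canopy.mean())
    p95 = float(np.percentile(canopy, 95))
    levels = np.linspace(threshold, p95, 10)
    for i, lev in enumerate(levels, start=1):
        values[f"D_ALS_{i}"] = float(np.mean(canopy > lev))
    return pd.Series(values)


@dataclass
class AreaModel:
    name: str
    response: str
    log_response: bool
    predictors: list[str]  # excluding intercept, including "T"
    beta: np.ndarray
    cov: np.ndarray
    resid_sd: float
    n_obs: int = 0

    def design(self, table: pd.DataFrame, t=None) -> np.ndarray:
        cols = [np.ones(len(table))]
        for name in self.predictors:
            if name == "T" and "T" not in table:
                cols.append(np.broadcast_to(np.asarray(t, dtype=float), (len(table),)))
            else:
                cols.append(table[name].to_numpy(dtype=float))
        return np.column_stack(cols)

    def predict(self, table: pd.DataFrame, t=None) -> np.ndarray:
        lin = self.design(table, t) @ self.beta
        return np.exp(lin) if self.log_response else lin


@dataclass
class AreaModelSet:
    models: dict[str, AreaModel] = field(default_factory=dict)

    def __getitem__(self, name: str) -> AreaModel:
        return self.models[name]

    def to_json(self) -> str:
        return json.dumps(
            {
                name: {
                    "response": m.response, "log_response": m.log_response,
                    "predictors": m.predictors, "beta": m.beta.tolist(),
                    "cov": m.cov.tolist(), "resid_sd": m.resid_sd, "n_obs": m.n_obs,
                }
                for name, m in self.models.items()
            }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "AreaModelSet":
        doc = json.loads(text)
        return cls({
            name: AreaModel(
                name, m["response"], m["log_response"], list(m["predictors"]),
                np.asarray(m["beta"]), np.asarray(m["cov"]), float(m["resid_sd"]),
                int(m.get("n_obs", 0)))
            for name, m in doc.items()})


def _fit_ols(y: np.ndarray, x: np.ndarray):
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("collinear design")
    return sm.OLS(y, x).fit()


def fit_area_models(plots: pd.DataFrame) -> AreaModelSet:
    """Fit the four fixed-form area models on a both-epoch plot table.

    ``plots`` holds one row per plot per epoch with the metric columns, T and
    the field-observed D (cm), Hdom (m), H (m) and BMS (Mg ha^-1).
    """
    missing = {"T", "D", "Hdom", "H", "BMS"} - set(plots.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    mset = AreaModelSet()
    for name, (logr, response, preds) in MODEL_FORMS.items():
        predictors = preds + ["T"]
        x = np.column_stack(
            [np.ones(len(plots))] + [plots[p].to_numpy(dtype=float) for p in predictors])
        y = plots[response].to_numpy(dtype=float)
        if logr:
            if np.any(y <= 0):
                raise ValueError(f"non-positive {response} in log model")
            y = np.log(y)
        res = _fit_ols(y, x)
        mset.models[name] = AreaModel(
            name, response, logr, predictors, res.params, res.cov_params(),
            float(np.sqrt(res.scale)), len(plots))
    return mset


def _vif(x_pred: np.ndarray) -> np.ndarray:
    """Variance inflation factor of each predictor column (intercept added)."""
    n, p = x_pred.shape
    out = np.empty(p)
    for j in range(p):
        others = np.column_stack([np.ones(n), np.delete(x_pred, j, axis=1)])
        y = x_pred[:, j]
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        tss = np.sum((y - y.mean()) ** 2)
        if tss == 0:
            out[j] = np.inf
            continue
        r2 = 1.0 - resid @ resid / tss
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def bic(y: np.ndarray, x: np.ndarray) -> float:
    """n*ln(RSS/n) + p*ln(n) for the OLS fit of y on x.

    RSS is floored at 1e-10 of the response's total sum of squares so that
    numerically exact fits tie on the likelihood term and the parameter
    penalty decides between them.
    """
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    n, p = x.shape
    tss = float(np.sum((y - y.mean()) ** 2))
    rss = max(float(resid @ resid), 1e-10 * max(tss, 1e-300))
    return n * np.log(rss / n) + p * np.log(n)


def select_area_model(
    table: pd.DataFrame,
    response: str,
    candidates: list[str] | None = None,
    log_response: bool = False,
    max_params: int = 5,
    max_vif: float = 5.0,
) -> list[str]:
    """BIC-minimal predictor subset under parameter and collinearity limits.

    Exhaustive search over subsets of the candidate metrics; the epoch dummy T
    is always retained and the intercept counts toward the ``max_params``
    limit, so at most ``max_params - 2`` metrics enter.  Subsets whose maximum
    VIF exceeds ``max_vif`` are rejected.  If no subset is feasible the
    intercept-plus-T fallback is returned with a warning.
    """
    if candidates is None:
        candidates = [c for c in METRIC_COLUMNS if c in table.columns]
    y = table[response].to_numpy(dtype=float)
    if log_response:
        y = np.log(y)
    n = len(table)
    t = table["T"].to_numpy(dtype=float)
    best, best_bic = None, np.inf
    max_extra = max(max_params - 2, 0)
    for size in range(0, max_extra + 1):
        for subset in itertools.combinations(candidates, size):
            x_pred = np.column_stack(
                [table[c].to_numpy(dtype=float) for c in subset] + [t])
            if np.linalg.matrix_rank(np.column_stack([np.ones(n), x_pred])) < x_pred.shape[1] + 1:
                continue
            if x_pred.shape[1] > 1 and np.max(_vif(x_pred)) > max_vif:
                continue
            value = bic(y, np.column_stack([np.ones(n), x_pred]))
            if value < best_bic - 1e-12:
                best, best_bic = list(subset), value
    if best is None:
        warnings.warn("no feasible subset; falling back to intercept + T")
        return ["T"]
    return best + ["T"]


def predict_cell_state(
    mset: AreaModelSet, metrics: pd.DataFrame, t: float
) -> pd.DataFrame:
    """Predict (D, Hdom, H, BMS) for each metrics row at epoch dummy ``t``.

    D and BMS come from exponentiated log-scale models; H is predicted from
    the *predicted* dominant height (two-step prediction).  Values are clipped
    at physical floors (D >= 0.1 cm, H >= 1.3 m, BMS >= 0).
    """
    d = np.maximum(mset["lnD"].predict(metrics, t), D_FLOOR)
    hdom = np.maximum(mset["Hdom"].predict(metrics, t), H_FLOOR)
    bms = np.maximum(mset["lnBMS"].predict(metrics, t), BMS_FLOOR)
    h = np.maximum(mset["H"].predict(pd.DataFrame({"Hdom": hdom}), t), H_FLOOR)
    h = np.minimum(h, hdom)  # mean height cannot exceed dominant height
    return pd.DataFrame({"D": d, "Hdom": hdom, "H": h, "BMS": bms}, index=metrics.index)
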