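"""Model-based uncertainty by parametric bootstrap over the chained models.

Six model groups contribute parameter uncertainty: the four area-based
regressions (biomass, dominant height, mean height, diameter), the allometric
component model set, and the soil model parameters.  Each bootstrap draw
samples every group's parameters from its estimated joint normal distribution
(or, for the soil model, from a supplied sample table) and recomputes the
entire chain of predictions; the standard error of a change estimator is the
standard deviation of its bootstrap outcomes, with 95% confidence intervals
taken as the estimate plus/minus two standard errors.

Each group consumes an independent random stream derived from (seed, group),
so that the one-model-at-a-time attribution runs reproduce exactly the draws
the full run used for that group.  Residual (within-model) errors are
excluded by design; only parameter uncertainty propagates.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .soil import DEFAULT_SOIL_PARAMS, params_from_vector, sample_parameter_table

__all__ = [
    "MODEL_GROUPS",
    "ParameterDraw",
    "draw_parameters",
    "ChangeDistribution",
    "bootstrap_changes",
    "attribute_errors",
    "summarize",
]

#: the six model groups whose parameters are resampled
MODEL_GROUPS = ("lnBMS", "Hdom", "H", "lnD", "allometry", "soil")


@dataclass
class ParameterDraw:
    index: int
    area_mset: object
    allo_mset: object
    soil_params: object


def _mvn(rng: np.random.Generator, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance not symmetric")
    eig = np.linalg.eigvalsh(cov)
    if eig.min() < -1e-8 * max(eig.max(), 1.0):
        # nearest-PSD repair: clip negative eigenvalues
        w, v = np.linalg.eigh(cov)
        cov = (v * np.clip(w, 0.0, None)) @ v.T
    return rng.multivariate_normal(mean, cov, method="svd")


def draw_parameters(
    area_mset,
    allo_mset,
    soil_params=DEFAULT_SOIL_PARAMS,
    soil_sample: np.ndarray | None = None,
    b: int = 1000,
    seed: int = 0,
    active: set | None = None,
) -> list[ParameterDraw]:
    """B parameter draws from the joint distributions of the model groups.

    ``active`` restricts sampling to a subset of :data:`MODEL_GROUPS`; the
    rest stay at their estimated means (used for error attribution).  Soil
    draws resample rows of ``soil_sample`` (synthesised around the defaults
    when absent) with replacement.
    """
    active = set(MODEL_GROUPS) if active is None else set(active)
    unknown = active - set(MODEL_GROUPS)
    if unknown:
        raise ValueError(f"unknown model groups {sorted(unknown)}")
    rngs = {g: np.random.default_rng([seed, gi]) for gi, g in enumerate(MODEL_GROUPS)}
    if "soil" in active and soil_sample is None:
        soil_sample = sample_parameter_table(soil_params, 1000, seed=np.random.default_rng([seed, 97]).integers(2**31))
    draws = []
    for i in range(b):
        area = copy.deepcopy(area_mset)
        for name in ("lnBMS", "Hdom", "H", "lnD"):
            model = area.models[name]
            if name in active:
                model.beta = _mvn(rngs[name], model.beta, model.cov)
        allo = copy.deepcopy(allo_mset)
        if "allometry" in active:
            for key in sorted(allo.models):
                m = allo.models[key]
                m.beta = _mvn(rngs["allometry"], m.beta, m.cov)
        soil = soil_params
        if "soil" in active:
            row = int(rngs["soil"].integers(len(soil_sample)))
            soil = params_from_vector(soil_sample[row], soil_params)
        draws.append(ParameterDraw(i, area, allo, soil))
    return draws


@dataclass
class ChangeDistribution:
    """Bootstrap outcomes of the per-stand (and landscape) change estimators."""

    stand_ids: np.ndarray
    pools: list
    outcomes: np.ndarray           # (B_ok, n_stands, n_pools)
    landscape: np.ndarray          # (B_ok, n_pools)
    point: pd.DataFrame            # per-stand point estimates (dC_* columns)
    point_landscape: dict
    n_failed: int = 0
    b_requested: int = 0

    @staticmethod
    def _sd(arr: np.ndarray) -> np.ndarray:
        """Sample sd along axis 0; exactly 0 for degenerate distributions
        (identical outcomes would otherwise pick up summation rounding)."""
        if len(arr) < 2:
            return np.zeros(arr.shape[1:])
        sd = arr.std(axis=0, ddof=1)
        return np.where(np.ptp(arr, axis=0) == 0.0, 0.0, sd)

    @property
    def se(self) -> pd.DataFrame:
        return pd.DataFrame(self._sd(self.outcomes),
                            index=self.stand_ids, columns=self.pools)

    @property
    def landscape_se(self) -> pd.Series:
        return pd.Series(self._sd(self.landscape), index=self.pools)

    def intervals(self) -> dict:
        """(lower, upper) DataFrames of the 2-SE 95% confidence intervals."""
        est = self.point.set_index("stand_id")[[f"dC_{p}" for p in self.pools]]
        est.columns = self.pools
        se = self.se
        return {"lower": est - 2.0 * se, "upper": est + 2.0 * se}

    def significant(self) -> pd.DataFrame:
        ci = self.intervals()
        return (ci["lower"] > 0) | (ci["upper"] < 0)


def bootstrap_changes(
    run_chain,
    draws: list[ParameterDraw],
    pools: list | None = None,
    max_failure_fraction: float = 0.2,
) -> ChangeDistribution:
    """Re-run the full chain per parameter draw and collect change distributions.

    ``run_chain(draw_or_none)`` must return ``(stand_results, landscape)`` as
    produced by the pipeline's aggregation; it is called once with ``None``
    for the point-estimate run.  Failed draws are excluded and counted; more
    than ``max_failure_fraction`` failures aborts.
    """
    point_stands, point_landscape = run_chain(None)
    pools = pools or ["AGB", "BGB", "litter", "deadwood", "SO",
                      "litter_incl_old", "SO_incl_old", "total"]
    cols = [f"dC_{p}" for p in pools]
    stand_ids = point_stands["stand_id"].to_numpy()
    outcomes, landscapes, failed = [], [], 0
    for draw in draws:
        try:
            stands_b, land_b = run_chain(draw)
        except (ValueError, FloatingPointError, RuntimeError, np.linalg.LinAlgError):
            failed += 1
            continue
        outcomes.append(stands_b.set_index("stand_id").loc[stand_ids, cols].to_numpy())
        landscapes.append([land_b[c] for c in cols])
    if failed > max_failure_fraction * len(draws):
        raise RuntimeError(f"{failed}/{len(draws)} bootstrap draws failed")
    return ChangeDistribution(
        stand_ids, pools, np.asarray(outcomes), np.asarray(landscapes),
        point_stands, point_landscape, n_failed=failed, b_requested=len(draws))


def attribute_errors(
    make_run_chain,
    area_mset,
    allo_mset,
    soil_params=DEFAULT_SOIL_PARAMS,
    soil_sample: np.ndarray | None = None,
    b: int = 200,
    seed: int = 0,
    pools: list | None = None,
) -> tuple[pd.DataFrame, ChangeDistribution]:
    """Per-model error shares from one-model-at-a-time bootstrapping.

    For each model group, parameters of that group alone are resampled (with
    the same random stream the all-models run uses for it) while the rest stay
    at their means; the group's share is its landscape-level SE as a
    percentage of the all-models SE.  Interactions between models make the
    shares deliberately non-additive — they do not sum to 100%.

    ``make_run_chain()`` returns a fresh ``run_chain`` callable for
    :func:`bootstrap_changes`.
    """
    common = dict(soil_params=soil_params, soil_sample=soil_sample, b=b, seed=seed)
    full = bootstrap_changes(
        make_run_chain(), draw_parameters(area_mset, allo_mset, **common), pools=pools)
    se_total = full.landscape_se
    rows = {}
    for group in MODEL_GROUPS:
        draws_g = draw_parameters(area_mset, allo_mset, active={group}, **common)
        dist_g = bootstrap_changes(make_run_chain(), draws_g, pools=full.pools)
        with np.errstate(invalid="ignore", divide="ignore"):
            rows[group] = 100.0 * dist_g.landscape_se / se_total.replace(0.0, np.nan)
    table = pd.DataFrame(rows).T
    table.index.name = "model"
    return table.fillna(0.0), full


def summarize(dist: ChangeDistribution, percentile_filter: float = 99.0) -> pd.DataFrame:
    """Per-pool report: mean relative SE, significant-stand share, landscape SE.

    Relative SEs (percent of the stand's point change estimate) blow up where
    the estimate is near zero, so values above the given percentile are
    filtered out before averaging — mirroring standard reporting practice for
    change estimators.
    """
    est = dist.point.set_index("stand_id")[[f"dC_{p}" for p in dist.pools]]
    est.columns = dist.pools
    se = dist.se
    sig = dist.significant()
    rows = []
    for pool in dist.pools:
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = 100.0 * se[pool].to_numpy() / np.abs(est[pool].to_numpy())
        rel = rel[np.isfinite(rel)]
        if len(rel):
            cut = np.percentile(rel, percentile_filter)
            rel = rel[rel <= cut]
        rows.append({
            "pool": pool,
            "mean_se_pct": float(np.mean(rel)) if len(rel) else np.nan,
            "significant_share_pct": float(100.0 * sig[pool].mean()),
            "landscape_se": float(dist.landscape_se[pool]),
        })
    return pd.DataFrame(rows).set_index("pool")
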