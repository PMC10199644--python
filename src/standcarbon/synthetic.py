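"""Synthetic study system with known ground truth.

Generates everything the estimation chain consumes — an individual-tree
allometry dataset, a stand map with cells, field plots with coincident canopy
metrics at two epochs, a disturbance map and an annual climate series — from
known generating coefficients, so that every downstream stage can be tested
for exact parameter and truth recovery.

Construction
------------
A latent growth process (site-index driven height curve, logistic biomass
accumulation, a harvest event for disturbed cells) drives noise-free canopy
metrics through fixed monotone maps: height percentiles are fixed fractions of
the latent top height, the mean return height and the cumulative densities
respond to both top height and canopy closure.  The *truth* biophysical fields
(D, Hdom, H, BMS) are then defined by applying the generating area-based model
forms to those metrics, with optional residual noise, so that ordinary
least-squares refits on noise-free data recover the generating coefficients
exactly and the full pipeline reproduces the recorded truth.  Measurement
noise perturbs the latent drivers (not the individual metrics), which
preserves the percentile/density ordering invariants for every seed.

The latent dynamics are deliberately simple — monotone and smooth — because
the estimator under test never sees them, only their imprint on metrics and
field values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import als
from .allometry import FORM_TABLE, design_matrix
from .constants import CELL_SIDE, COMPONENTS, EPOCH_END, EPOCH_START, PLOT_AREA, SPECIES, STAND_MAP_YEAR
from .growth import DEFAULT_GROWTH_SPECS

__all__ = [
    "SyntheticConfig",
    "TRUE_AREA_BETA",
    "true_allometry_beta",
    "gen_tree_dataset",
    "gen_landscape",
    "gen_als_metrics",
    "gen_climate",
    "LandscapeBundle",
]

#: Generating coefficients of the four area-based models (intercept first,
#: epoch dummy last), chosen to yield boreal-plausible D/Hdom/H/BMS ranges.
TRUE_AREA_BETA = {
    "lnD": np.array([1.62, 0.15, 0.100, 0.020]),      # 1, D_ALS_4, H_ALS_mean, T
    "Hdom": np.array([1.00, 2.00, 1.00, 1.050, 0.10]),  # 1, D_ALS_2, D_ALS_8, H_ALS_80, T
    "lnBMS": np.array([1.50, 2.20, 0.100, 0.050]),    # 1, D_ALS_2, H_ALS_80, T
    "H": np.array([0.30, 0.800, 0.050]),              # 1, Hdom, T
}

#: Reference tree (D cm, H m) and target component masses (kg) used to anchor
#: the generating allometric intercepts.
_REF_D, _REF_H = 15.0, 12.0
_REF_MASS = dict(SW=70.0, BR=18.0, DB=3.0, SB=10.0, SU=7.0, FL=9.0, RF=4.0, RC=14.0)
_SPECIES_SCALE = {"spruce": 1.0, "pine": 0.95, "birch": 0.85}
_SLOPES = {1: (6.5,), 2: (6.0, 0.6), 3: (6.5, 0.02, 0.6)}


def true_allometry_beta(species: str, component: str) -> np.ndarray:
    """Generating coefficient vector for a fitted (species, component) pair.

    Slopes are fixed per model form; the intercept is calibrated so the
    reference tree carries the target component mass (scaled per species).
    """
    cell = FORM_TABLE[species][component]
    if cell is None:
        raise KeyError(f"({species}, {component}) has no fitted model")
    form, k = cell
    slopes = np.asarray(_SLOPES[form])
    x_ref = design_matrix(form, k, [_REF_D], [_REF_H])[0]
    target = np.log(_REF_MASS[component] * _SPECIES_SCALE[species])
    b0 = target - x_ref[1:] @ slopes
    return np.concatenate([[b0], slopes])


#: Default per-species counts follow the reference allometry dataset pattern:
#: per-component availability, with birch lacking stump/foliage/root data.
TREE_COUNTS = {"spruce": 546, "pine": 494, "birch": 241}
COMPONENT_COUNTS = {
    "spruce": dict(SW=521, BR=540, DB=525, SB=521, SU=323, FL=540, RF=324, RC=333),
    "pine": dict(SW=471, BR=486, DB=472, SB=471, SU=305, FL=485, RF=305, RC=314),
    "birch": dict(SW=218, BR=235, DB=221, SB=218, SU=0, FL=0, RF=0, RC=0),
}


@dataclass(frozen=True)
class SyntheticConfig:
    n_stands: int = 500
    cells_per_stand: tuple[int, int] = (4, 16)
    cell_side: float = CELL_SIDE          # m
    n_plots: int = 116
    plot_area: float = PLOT_AREA          # m^2
    species_mix: dict = field(
        default_factory=lambda: {"spruce": 0.55, "pine": 0.33, "birch": 0.12})
    si_levels: tuple = (8, 11, 14, 17, 20)
    age_range: tuple[int, int] = (25, 120)  # stand age at the map year
    epoch_years: tuple[int, int] = (EPOCH_START, EPOCH_END)
    disturbance_fraction: float = 0.157
    #: residual / measurement noise scales; zero everywhere gives exact truth
    noise_sd: dict = field(default_factory=lambda: {
        "latent_height": 0.04, "latent_density": 0.06,
        "lnD": 0.05, "Hdom": 0.6, "lnBMS": 0.08, "H": 0.4,
        "allometry": 0.15,
    })
    seed: int = 1

    def __post_init__(self):
        if abs(sum(self.species_mix.values()) - 1.0) > 1e-9:
            raise ValueError("species proportions must sum to 1")
        if not 0.0 <= self.disturbance_fraction <= 1.0:
            raise ValueError("disturbance_fraction must lie in [0, 1]")
        if abs(self.cell_side**2 - self.plot_area) / self.plot_area > 0.005:
            raise ValueError("cell area must match plot area within 0.5%")

    def zero_noise(self) -> "SyntheticConfig":
        return SyntheticConfig(**{**self.__dict__, "noise_sd": {k: 0.0 for k in self.noise_sd}})


# ---------------------------------------------------------------------------
# individual-tree allometry dataset
# ---------------------------------------------------------------------------


def gen_tree_dataset(config: SyntheticConfig, counts: dict | None = None) -> pd.DataFrame:
    """Individual-tree table (species, D, H, component masses in kg).

    Component masses are log-normal around the generating allometric models;
    per-component availability follows the bundled count pattern (NaN where a
    component was not measured).
    """
    counts = counts or TREE_COUNTS
    for sp in counts:
        if sp not in SPECIES:
            raise ValueError(f"invalid species label {sp!r}")
    rng = np.random.default_rng([config.seed, 101])
    sd = config.noise_sd.get("allometry", 0.0)
    frames = []
    for sp, n in counts.items():
        d = np.exp(rng.normal(np.log(15.0), 0.45, n)).clip(4.0, 45.0)
        h = (1.3 + 0.72 * d**0.85 * np.exp(rng.normal(0, 0.08, n))).clip(2.0, 35.0)
        row = {"species": sp, "D": d, "H": h}
        scale = n / TREE_COUNTS.get(sp, n)
        for comp in COMPONENTS:
            if FORM_TABLE[sp][comp] is None:
                row[comp] = np.full(n, np.nan)
                continue
            beta = true_allometry_beta(sp, comp)
            form, k = FORM_TABLE[sp][comp]
            x = design_matrix(form, k, d, h)
            mass = np.exp(x @ beta + sd * rng.standard_normal(n))
            n_avail = int(round(COMPONENT_COUNTS.get(sp, {}).get(comp, n) * scale))
            if n_avail < n:
                drop = rng.choice(n, size=n - n_avail, replace=False)
                mass[drop] = np.nan
            row[comp] = mass
        frames.append(pd.DataFrame(row))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# landscape: stands, cells, latent dynamics, metrics and truth
# ---------------------------------------------------------------------------

#: fixed percentile fractions of latent top height (strictly increasing)
_PCTL_FRAC = {10: 0.44, 20: 0.52, 30: 0.60, 40: 0.67, 50: 0.74, 60: 0.80,
              70: 0.86, 80: 0.90, 90: 0.96}


def _latent_height(si: np.ndarray, age: np.ndarray, species: np.ndarray) -> np.ndarray:
    """Latent top height (m) from the default growth family's height curve."""
    out = np.empty(len(si))
    for sp in SPECIES:
        mask = species == sp
        spec = DEFAULT_GROWTH_SPECS[sp]
        out[mask] = spec.h1 * si[mask] * (1.0 - np.exp(-spec.lam * age[mask]))
    return np.maximum(out, 2.0)


def _latent_biomass(si: np.ndarray, age: np.ndarray) -> np.ndarray:
    """Latent standing stock (arbitrary Mg-like scale) — logistic in age."""
    return 330.0 * (si / 14.0) / (1.0 + np.exp(-(age - 45.0) / 18.0))


def gen_als_metrics(
    hdom_latent: np.ndarray,
    biomass_latent: np.ndarray,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Canopy metrics from latent top height and standing stock.

    Measurement noise perturbs the two latent drivers multiplicatively before
    the monotone metric maps are applied, so percentile ordering
    (H_ALS_10 <= ... <= H_ALS_90) and density ordering
    (D_ALS_1 >= ... >= D_ALS_10) hold for every seed.
    """
    hdom_latent = np.asarray(hdom_latent, dtype=float)
    biomass_latent = np.asarray(biomass_latent, dtype=float)
    n = len(hdom_latent)
    if rng is not None:
        hdom_latent = hdom_latent * np.exp(
            config.noise_sd.get("latent_height", 0.0) * rng.standard_normal(n))
        biomass_latent = biomass_latent * np.exp(
            config.noise_sd.get("latent_density", 0.0) * rng.standard_normal(n))
    closure = biomass_latent / (biomass_latent + 150.0)
    cols = {}
    for p, frac in _PCTL_FRAC.items():
        cols[f"H_ALS_{p}"] = frac * hdom_latent
    cols["H_ALS_mean"] = 0.72 * hdom_latent * (0.55 + 0.45 * closure)
    for i in range(1, 11):
        cols[f"D_ALS_{i}"] = closure ** (0.8 + 0.15 * (i - 1))
    return pd.DataFrame(cols)


def _truth_from_metrics(
    metrics: pd.DataFrame, t: int, rng: np.random.Generator | None, noise: dict
) -> pd.DataFrame:
    """Apply the generating area models (+ residual noise) to metrics."""
    n = len(metrics)
    z = (lambda key: rng.standard_normal(n) * noise.get(key, 0.0)) if rng is not None \
        else (lambda key: 0.0)
    ln_d = (TRUE_AREA_BETA["lnD"][0]
            + TRUE_AREA_BETA["lnD"][1] * metrics["D_ALS_4"]
            + TRUE_AREA_BETA["lnD"][2] * metrics["H_ALS_mean"]
            + TRUE_AREA_BETA["lnD"][3] * t + z("lnD"))
    hdom = (TRUE_AREA_BETA["Hdom"][0]
            + TRUE_AREA_BETA["Hdom"][1] * metrics["D_ALS_2"]
            + TRUE_AREA_BETA["Hdom"][2] * metrics["D_ALS_8"]
            + TRUE_AREA_BETA["Hdom"][3] * metrics["H_ALS_80"]
            + TRUE_AREA_BETA["Hdom"][4] * t + z("Hdom"))
    ln_bms = (TRUE_AREA_BETA["lnBMS"][0]
              + TRUE_AREA_BETA["lnBMS"][1] * metrics["D_ALS_2"]
              + TRUE_AREA_BETA["lnBMS"][2] * metrics["H_ALS_80"]
              + TRUE_AREA_BETA["lnBMS"][3] * t + z("lnBMS"))
    h = (TRUE_AREA_BETA["H"][0] + TRUE_AREA_BETA["H"][1] * hdom
         + TRUE_AREA_BETA["H"][2] * t + z("H"))
    out = pd.DataFrame({
        "D": np.exp(ln_d), "Hdom": np.maximum(hdom, 1.4),
        "BMS": np.exp(ln_bms),
    })
    out["H"] = np.clip(h, 1.3, out["Hdom"])
    return out


@dataclass
class LandscapeBundle:
    """Everything gen_landscape produces, ready for the pipeline."""

    stands: pd.DataFrame      # stand_id, SI, AGE, SP, n_cells, area_ha
    cells: pd.DataFrame       # cell_id, stand_id + metrics at both epochs
    plots: pd.DataFrame       # plot rows at both epochs with metrics + field values
    truth: pd.DataFrame       # per-cell truth at both epochs + disturbance + ΔC
    disturbance: pd.DataFrame  # cell_id, year (disturbed cells only)
    climate: pd.DataFrame     # year, precipitation, temperature, amplitude
    climate_ref: tuple        # pre-epoch average (precipitation, temperature, amplitude)
    config: SyntheticConfig = None


def _tree_totals(d: np.ndarray, h: np.ndarray, species: str) -> np.ndarray:
    """Whole-tree dry mass (kg) under the generating allometry.

    Birch follows the bundled convention: the branch model includes foliage,
    and the ratio-derived foliage is excluded from the total.
    """
    total = np.zeros(len(np.atleast_1d(d)))
    for comp in COMPONENTS:
        if FORM_TABLE[species][comp] is None:
            if comp == "SU":  # delegated to pine
                beta = true_allometry_beta("pine", comp)
                form, k = FORM_TABLE["pine"][comp]
                total += np.exp(design_matrix(form, k, d, h) @ beta)
            elif comp in ("RF", "RC"):
                beta = true_allometry_beta(species, "SW")
                form, k = FORM_TABLE[species]["SW"]
                sw = np.exp(design_matrix(form, k, d, h) @ beta)
                total += (0.042 / 0.52) * sw
            # ratio FL excluded: birch BR already includes foliage
            continue
        beta = true_allometry_beta(species, comp)
        form, k = FORM_TABLE[species][comp]
        total += np.exp(design_matrix(form, k, d, h) @ beta)
    return total


def gen_landscape(config: SyntheticConfig) -> LandscapeBundle:
    """Generate the full synthetic landscape with per-cell ground truth."""
    rng = np.random.default_rng([config.seed, 202])
    y0, y1 = config.epoch_years
    span = y1 - y0

    n_cells_per = rng.integers(config.cells_per_stand[0], config.cells_per_stand[1] + 1,
                               config.n_stands)
    sp_names = list(config.species_mix)
    stands = pd.DataFrame({
        "stand_id": np.arange(config.n_stands),
        "SI": rng.choice(config.si_levels, config.n_stands),
        "AGE": rng.integers(config.age_range[0], config.age_range[1] + 1, config.n_stands),
        "SP": rng.choice(sp_names, config.n_stands, p=[config.species_mix[s] for s in sp_names]),
        "n_cells": n_cells_per,
    })
    stands["area_ha"] = stands["n_cells"] * config.cell_side**2 / 1e4

    cell_stand = np.repeat(stands["stand_id"].to_numpy(), n_cells_per)
    n_cells = len(cell_stand)
    cells_base = pd.DataFrame({"cell_id": np.arange(n_cells), "stand_id": cell_stand})
    si = stands["SI"].to_numpy()[cell_stand]
    age_map = stands["AGE"].to_numpy()[cell_stand]
    species = stands["SP"].to_numpy()[cell_stand]
    # stand age at the first epoch, per the map-year bookkeeping convention
    age0 = np.maximum(age_map - (STAND_MAP_YEAR - y0), 1)

    height_factor = rng.uniform(0.85, 1.15, n_cells)
    density_factor = rng.uniform(0.70, 1.30, n_cells)

    hdom0 = _latent_height(si.astype(float), age0.astype(float), species) * height_factor
    hdom1 = _latent_height(si.astype(float), (age0 + span).astype(float), species) * height_factor
    b0 = _latent_biomass(si.astype(float), age0.astype(float)) * density_factor
    b1 = _latent_biomass(si.astype(float), (age0 + span).astype(float)) * density_factor

    # harvest / heavy thinning events removing 40-75% of the standing stock;
    # only stands with worthwhile stock are eligible, with the selection
    # probability scaled so the expected disturbed share still matches the
    # configured fraction
    eligible = b0 >= 60.0
    n_elig = max(int(eligible.sum()), 1)
    p_sel = min(config.disturbance_fraction * n_cells / n_elig, 1.0)
    disturbed = eligible & (rng.random(n_cells) < p_sel)
    event_year = np.where(disturbed, rng.integers(y0 + 1, y1, n_cells), -1)
    retain = rng.uniform(0.25, 0.60, n_cells)
    b1 = np.where(disturbed, retain * b0, b1)
    # removal slightly lowers the top height (thinning spares most dominants)
    hdom1 = np.where(disturbed, retain**0.15 * hdom1, hdom1)

    metrics0 = gen_als_metrics(hdom0, b0, config, rng)
    metrics1 = gen_als_metrics(hdom1, b1, config, rng)

    truth0 = _truth_from_metrics(metrics0, 0, rng, config.noise_sd)
    truth1 = _truth_from_metrics(metrics1, 1, rng, config.noise_sd)

    # the truth record keeps only events that survive as an actual biomass
    # decrease (the indirect-change detection rule), so the disturbance
    # invariant holds exactly
    disturbed &= truth1["BMS"].to_numpy() < truth0["BMS"].to_numpy()
    event_year = np.where(disturbed, event_year, -1)

    truth = cells_base.copy()
    truth["SP"] = species
    truth["SI"] = si
    truth["AGE_start"] = age0
    for t, tr in ((0, truth0), (1, truth1)):
        year = y0 if t == 0 else y1
        for col in ("D", "Hdom", "H", "BMS"):
            truth[f"{col}_{year}"] = tr[col].to_numpy()
    truth["disturbed"] = disturbed
    truth["event_year"] = event_year

    # stems per hectare and true biomass-pool carbon changes per the
    # generating allometry (N = BMS / mean-tree mass)
    from .allometry import BIRCH_RATIOS  # local import to avoid cycle at module load

    agb_frac = np.empty(n_cells)
    for t, tr in ((0, truth0), (1, truth1)):
        year = y0 if t == 0 else y1
        total = np.empty(n_cells)
        agb = np.empty(n_cells)
        for sp in SPECIES:
            mask = species == sp
            if not mask.any():
                continue
            d, h = tr["D"].to_numpy()[mask], tr["H"].to_numpy()[mask]
            tot = _tree_totals(d, h, sp)
            bgb = np.zeros(mask.sum())
            for comp in ("RF", "RC"):
                if FORM_TABLE[sp][comp] is None:
                    beta = true_allometry_beta(sp, "SW")
                    form, k = FORM_TABLE[sp]["SW"]
                    bgb += BIRCH_RATIOS[comp] * np.exp(design_matrix(form, k, d, h) @ beta)
                else:
                    beta = true_allometry_beta(sp, comp)
                    form, k = FORM_TABLE[sp][comp]
                    bgb += np.exp(design_matrix(form, k, d, h) @ beta)
            total[mask] = tot
            agb[mask] = tot - bgb
        truth[f"N_{year}"] = tr["BMS"].to_numpy() * 1000.0 / total
        truth[f"C_AGB_{year}"] = 0.5 * tr["BMS"].to_numpy() * agb / total
        truth[f"C_BGB_{year}"] = 0.5 * tr["BMS"].to_numpy() * (total - agb) / total
    truth["dC_AGB_true"] = (truth[f"C_AGB_{y1}"] - truth[f"C_AGB_{y0}"]) / span
    truth["dC_BGB_true"] = (truth[f"C_BGB_{y1}"] - truth[f"C_BGB_{y0}"]) / span

    cells = cells_base.copy()
    for col in als.METRIC_COLUMNS:
        cells[f"{col}_{y0}"] = metrics0[col].to_numpy()
        cells[f"{col}_{y1}"] = metrics1[col].to_numpy()

    # field plots: sampled cell locations, observed truth at both epochs,
    # with stratum labels (estimation itself does not use strata)
    plot_cells = rng.choice(n_cells, size=min(config.n_plots, n_cells), replace=False)
    rows = []
    for t, (mets, tr) in ((0, (metrics0, truth0)), (1, (metrics1, truth1))):
        year = y0 if t == 0 else y1
        sub = mets.iloc[plot_cells].reset_index(drop=True).copy()
        sub["T"] = t
        sub["year"] = year
        for col in ("D", "Hdom", "H", "BMS"):
            sub[col] = tr[col].to_numpy()[plot_cells]
        sub["plot_id"] = np.arange(len(plot_cells))
        si_p, age_p = si[plot_cells], age0[plot_cells]
        sub["stratum"] = np.where(age_p < 40, "young",
                                  np.where(si_p <= 11, "mature-poor", "mature-good"))
        rows.append(sub)
    plots = pd.concat(rows, ignore_index=True)

    disturbance = pd.DataFrame({
        "cell_id": cells_base["cell_id"][disturbed],
        "year": event_year[disturbed],
    })
    climate, climate_ref = gen_climate(range(1957, y1 + 1), config)
    return LandscapeBundle(stands, cells, plots, truth, disturbance,
                           climate, climate_ref, config)


def gen_climate(years, config: SyntheticConfig | int, ref_window=(1957, 2000)):
    """Plausible boreal annual climate series plus the pre-epoch average.

    Returns ``(frame, (precip, temp, amplitude))`` where the triple averages
    the series over the (inclusive) reference window.
    """
    years = np.asarray(list(years))
    if years.size == 0:
        raise ValueError("empty year range")
    seed = config.seed if isinstance(config, SyntheticConfig) else int(config)
    rng = np.random.default_rng([seed, 303])
    n = len(years)
    frame = pd.DataFrame({
        "year": years,
        "precipitation": 700.0 + 90.0 * rng.standard_normal(n),
        "temperature": 4.0 + 0.8 * rng.standard_normal(n),
        "amplitude": 20.0 + 2.0 * rng.standard_normal(n),
    })
    frame["precipitation"] = frame["precipitation"].clip(lower=200.0)
    window = frame[(frame["year"] >= ref_window[0]) & (frame["year"] <= ref_window[1])]
    if len(window):
        ref = (float(window["precipitation"].mean()),
               float(window["temperature"].mean()),
               float(window["amplitude"].mean()))
    else:
        ref = (float(frame["precipitation"].mean()),
               float(frame["temperature"].mean()),
               float(frame["amplitude"].mean()))
    return frame, ref
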