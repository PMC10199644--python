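"""Per-cell estimation chain and stand/landscape aggregation.

For every grid cell the chain predicts the mean tree and standing biomass at
both epochs from ALS metrics, branches on disturbance (reconstructing pre- and
post-event trees with forward and inverse growth), converts biomass states to
annual chemically partitioned litter, initialises legacy soil carbon, steps
the soil model through the timeframe per cohort, and reports carbon stocks and
annualised changes in five pools:

  AGB, BGB   : 0.5 x standing dry biomass, split by the mean tree's
               above-/below-ground component proportions (the area-based
               biomass prediction acts as the scale factor)
  litter     : A+W+E+N of the turnover+harvest cohort
  deadwood   : A+W+E+N of the mortality cohort
  SO         : humus of both cohorts

A second variant adds the traced legacy ("old") stocks, with deadwood merged
into the litter pool.  The engine is vectorised over cells; ``run_cell`` wraps
it for a single cell.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import als
from .allometry import AllometricModelSet, predict_components_vec
from .constants import (
    AGB_COMPONENTS,
    CARBON_FRACTION,
    COMPONENTS,
    EPOCH_END,
    EPOCH_START,
    SPECIES,
    STAND_MAP_YEAR,
)
from .growth import DEFAULT_GROWTH_SPECS, invert_growth_arrays
from .litter import awen_partition_frame, turnover_fractions_frame
from .soil import (
    ClimateYear,
    DEFAULT_SOIL_PARAMS,
    build_flow_matrix,
    ramp_operator,
    transition_operator,
)

__all__ = [
    "PipelineOptions",
    "load_long_term_table",
    "detect_disturbance",
    "stems_per_ha",
    "run_cells",
    "run_cell",
    "aggregate",
]

POOL_COLUMNS = ["AGB", "BGB", "litter", "deadwood", "SO"]
OLD_POOL_COLUMNS = ["litter_incl_old", "SO_incl_old"]


def load_long_term_table() -> pd.DataFrame:
    """Bundled long-term per-(species, site index) soil carbon equilibria."""
    path = importlib.resources.files("standcarbon.data") / "long_term_soil_carbon.csv"
    return pd.read_csv(path)


@dataclass
class PipelineOptions:
    """Constants and policy switches of the estimation chain."""

    carbon_fraction: float = CARBON_FRACTION
    start_year: int = EPOCH_START
    end_year: int = EPOCH_END
    map_year: int = STAND_MAP_YEAR
    background_mortality: float = 0.004
    #: attribute stem-number decline in disturbed cells to harvest (constant
    #: background mortality) rather than to mortality
    disturbed_constant_mortality: bool = True
    turnover: pd.DataFrame = field(default_factory=turnover_fractions_frame)
    awen: pd.DataFrame = field(default_factory=awen_partition_frame)
    growth_specs: dict = field(default_factory=lambda: dict(DEFAULT_GROWTH_SPECS))
    long_term_table: pd.DataFrame | None = None
    keep_annual: bool = False

    def __post_init__(self):
        if self.long_term_table is None:
            self.long_term_table = load_long_term_table()
        if not self.start_year < self.end_year:
            raise ValueError("timeframe start must precede end")

    @property
    def span(self) -> int:
        return self.end_year - self.start_year

    @property
    def midpoint_year(self) -> int:
        # floor rounding of the interval midpoint
        return self.start_year + self.span // 2


def detect_disturbance(
    bms_start: float, bms_end: float, map_year: int | None = None,
    options: PipelineOptions | None = None,
) -> tuple[bool, int | None]:
    """Disturbance flag and event year for one cell.

    A cell is disturbed when the area-based biomass prediction decreased over
    the timeframe; the event year comes from the disturbance map, defaulting
    to the (floored) interval midpoint when unmapped.
    """
    options = options or PipelineOptions()
    if not bms_end < bms_start:
        return False, None
    return True, int(map_year) if map_year is not None and map_year > 0 \
        else options.midpoint_year


def stems_per_ha(bms: float, tree_mass_kg: float) -> float:
    """N = per-hectare biomass divided by the mean tree's biomass."""
    if np.any(np.asarray(tree_mass_kg) <= 0):
        raise ValueError("mean-tree biomass must be positive")
    return np.asarray(bms, dtype=float) * 1000.0 / tree_mass_kg


# ---------------------------------------------------------------------------
# vectorised helpers
# ---------------------------------------------------------------------------


def _metrics_frame(cells: pd.DataFrame, year: int) -> pd.DataFrame:
    cols = {c: cells[f"{c}_{year}"].to_numpy() for c in als.METRIC_COLUMNS}
    return pd.DataFrame(cols, index=cells.index)


def _components_by_species(mset, d, h, species_arr):
    """(n, 8) kg component matrix across a mixed-species cell array."""
    out = np.empty((len(d), len(COMPONENTS)))
    for sp in SPECIES:
        mask = species_arr == sp
        if mask.any():
            out[mask] = predict_components_vec(mset, d[mask], h[mask], sp)
    return out


def _agb_mask(species_arr, mset) -> np.ndarray:
    """(n, 8) indicator of components counted above ground, per species."""
    base = np.array([c in AGB_COMPONENTS for c in COMPONENTS], dtype=float)
    out = np.tile(base, (len(species_arr), 1))
    if not mset.birch_fl_in_agb:
        out[species_arr == "birch", COMPONENTS.index("FL")] = 0.0
    return out


def _awen_matrices(options: PipelineOptions) -> dict:
    """Per-species (8, 4) chemistry matrices from the partition table."""
    return {
        sp: options.awen.loc[sp].reindex(list(COMPONENTS)).to_numpy()
        for sp in SPECIES
    }


def _turnover_rows(options: PipelineOptions) -> dict:
    return {
        sp: options.turnover.loc[sp].reindex(list(COMPONENTS)).to_numpy()
        for sp in SPECIES
    }


def _species_apply(species_arr, comps_ha, mats) -> np.ndarray:
    """comps (n, 8) @ per-species matrix -> (n, 4)."""
    out = np.empty((len(species_arr), 4))
    for sp in SPECIES:
        mask = species_arr == sp
        if mask.any():
            out[mask] = comps_ha[mask] @ mats[sp]
    return out


# ---------------------------------------------------------------------------
# the chain
# ---------------------------------------------------------------------------


def run_cells(
    cells: pd.DataFrame,
    stands: pd.DataFrame,
    climate: pd.DataFrame,
    climate_ref: tuple,
    area_mset,
    allo_mset: AllometricModelSet,
    soil_params=DEFAULT_SOIL_PARAMS,
    disturbance: pd.DataFrame | None = None,
    options: PipelineOptions | None = None,
) -> pd.DataFrame:
    """Execute the full chain for every cell; returns the cell result table.

    ``cells`` carries the metric columns suffixed with both epoch years plus
    ``stand_id``; ``stands`` the attributes SI/AGE/SP/area_ha; ``climate`` the
    annual series covering the timeframe; ``climate_ref`` the pre-timeframe
    average (precipitation, temperature, amplitude) triple used for spin-up
    and the silvicultural-cycle reconstruction.
    """
    opt = options or PipelineOptions()
    y0, y1, span = opt.start_year, opt.end_year, opt.span
    n = len(cells)
    st = stands.set_index("stand_id")
    sid = cells["stand_id"].to_numpy()
    orphans = set(sid) - set(st.index)
    if orphans:
        raise KeyError(f"cells reference unknown stands: {sorted(orphans)[:5]}")
    species = st["SP"].to_numpy()[st.index.get_indexer(sid)]
    si = st["SI"].to_numpy(dtype=float)[st.index.get_indexer(sid)]
    age_map = st["AGE"].to_numpy(dtype=float)[st.index.get_indexer(sid)]
    age0 = np.maximum(age_map - (opt.map_year - y0), 1.0)

    # 1. per-epoch cell state predictions
    s0 = als.predict_cell_state(area_mset, _metrics_frame(cells, y0), 0)
    s1 = als.predict_cell_state(area_mset, _metrics_frame(cells, y1), 1)

    # 2. disturbance branch bookkeeping
    map_year = np.full(n, -1)
    if disturbance is not None and len(disturbance):
        lookup = disturbance.set_index("cell_id")["year"]
        idx = lookup.reindex(cells["cell_id"]).to_numpy()
        map_year = np.where(np.isnan(idx), -1, idx).astype(int)
    disturbed = s1["BMS"].to_numpy() < s0["BMS"].to_numpy()
    event_year = np.where(map_year > 0, map_year, opt.midpoint_year)
    event_year = np.where(disturbed, np.clip(event_year, y0 + 1, y1 - 1), -1)

    # 3. mean-tree components and biomass pools at the epochs
    comps0 = _components_by_species(allo_mset, s0["D"].to_numpy(), s0["H"].to_numpy(), species)
    comps1 = _components_by_species(allo_mset, s1["D"].to_numpy(), s1["H"].to_numpy(), species)
    agbm = _agb_mask(species, allo_mset)
    # total counted mass = AGB components (per convention) + BGB components
    bgb_cols = [COMPONENTS.index(c) for c in ("RF", "RC")]
    agb0 = (comps0 * agbm).sum(1)
    agb1 = (comps1 * agbm).sum(1)
    bgb0 = comps0[:, bgb_cols].sum(1)
    bgb1 = comps1[:, bgb_cols].sum(1)
    tot0 = agb0 + bgb0
    tot1 = agb1 + bgb1
    bms0, bms1 = s0["BMS"].to_numpy(), s1["BMS"].to_numpy()
    n0 = stems_per_ha(bms0, tot0)
    n1 = stems_per_ha(bms1, tot1)
    cf = opt.carbon_fraction
    c_agb0, c_agb1 = cf * bms0 * agb0 / tot0, cf * bms1 * agb1 / tot1
    c_bgb0, c_bgb1 = cf * bms0 * bgb0 / tot0, cf * bms1 * bgb1 / tot1

    # per-ha component masses (Mg ha^-1): kg/tree x trees/ha / 1000
    comps_ha0 = comps0 * (bms0 / tot0)[:, None]
    comps_ha1 = comps1 * (bms1 / tot1)[:, None]

    # 4. mortality rate (geometric; disturbed cells use the background rate)
    with np.errstate(invalid="ignore"):
        geo = 1.0 - (n1 / n0) ** (1.0 / span)
    mort = np.where(n1 >= n0, opt.background_mortality, geo)
    if opt.disturbed_constant_mortality:
        mort = np.where(disturbed, opt.background_mortality, mort)

    # 5. litter anchors (AWEN carbon) for the two cohorts
    awen_mats = _awen_matrices(opt)
    to_rows = _turnover_rows(opt)
    to_frac = np.empty((n, 8))
    for sp in SPECIES:
        to_frac[species == sp] = to_rows[sp]

    def turnover_awen(comps_ha):
        return cf * _species_apply(species, comps_ha * to_frac, awen_mats)

    def mortality_awen(comps_kg, n_ha):
        per_ha = comps_kg * (mort * n_ha / 1000.0)[:, None]
        return cf * _species_apply(species, per_ha, awen_mats)

    to_awen0, to_awen1 = turnover_awen(comps_ha0), turnover_awen(comps_ha1)
    mo_awen0, mo_awen1 = mortality_awen(comps0, n0), mortality_awen(comps1, n1)

    # disturbance anchors: "before" by forward growth from the first epoch,
    # "after" by inverse growth from the second
    to_bef, mo_bef = to_awen0.copy(), mo_awen0.copy()
    to_aft, mo_aft = to_awen1.copy(), mo_awen1.copy()
    hv_awen = np.zeros((n, 4))
    if disturbed.any():
        dmask = disturbed
        yrs_before = (event_year - y0).astype(float)
        yrs_after = (y1 - event_year).astype(float)
        d_b = np.empty(n)
        h_b = np.empty(n)
        d_a = np.empty(n)
        h_a = np.empty(n)
        for sp in SPECIES:
            m = dmask & (species == sp)
            if not m.any():
                continue
            spec = opt.growth_specs[sp]
            d_b[m], h_b[m] = spec.grow_arrays(
                s0["D"].to_numpy()[m], s0["Hdom"].to_numpy()[m], si[m], age0[m],
                n0[m], yrs_before[m])
            d_a[m], h_a[m], _ = invert_growth_arrays(
                spec, s1["D"].to_numpy()[m], s1["Hdom"].to_numpy()[m], si[m],
                age0[m] + span, n1[m], yrs_after[m])
        hmod = area_mset["H"]
        hm_b = np.clip(hmod.predict(pd.DataFrame({"Hdom": h_b[dmask]}), 0), 1.3, None)
        hm_a = np.clip(hmod.predict(pd.DataFrame({"Hdom": np.maximum(h_a[dmask], 1.4)}), 1), 1.3, None)
        comps_b = _components_by_species(
            allo_mset, np.maximum(d_b[dmask], 0.1), np.maximum(hm_b, 1.3), species[dmask])
        comps_a = _components_by_species(
            allo_mset, np.maximum(d_a[dmask], 0.1), np.maximum(hm_a, 1.3), species[dmask])
        comps_ha_b = comps_b * (n0[dmask] / 1000.0)[:, None]
        comps_ha_a = comps_a * (n1[dmask] / 1000.0)[:, None]
        to_bef[dmask] = cf * _species_apply(species[dmask], comps_ha_b * to_frac[dmask], awen_mats)
        to_aft[dmask] = cf * _species_apply(species[dmask], comps_ha_a * to_frac[dmask], awen_mats)
        mo_bef[dmask] = cf * _species_apply(
            species[dmask], comps_b * (mort[dmask] * n0[dmask] / 1000.0)[:, None], awen_mats)
        mo_aft[dmask] = cf * _species_apply(
            species[dmask], comps_a * (mort[dmask] * n1[dmask] / 1000.0)[:, None], awen_mats)
        # harvest residues: everything removed except 95% of the stem wood
        removed = np.clip(comps_ha_b - comps_ha_a, 0.0, None)
        removed[:, COMPONENTS.index("SW")] *= 0.05
        hv_awen[dmask] = cf * _species_apply(species[dmask], removed, awen_mats)

    # 6. annual AWEN inputs per cohort (year y drives the step y -> y+1)
    years = np.arange(y0, y1)
    lit_in = np.zeros((span, n, 4))
    dead_in = np.zeros((span, n, 4))
    und = ~disturbed
    for i, y in enumerate(years):
        w = (y - y0) / span
        lit_in[i, und] = (1 - w) * to_awen0[und] + w * to_awen1[und]
        dead_in[i, und] = (1 - w) * mo_awen0[und] + w * mo_awen1[und]
    if disturbed.any():
        dm = disturbed
        ev = event_year[dm].astype(float)
        for i, y in enumerate(years):
            pre = y <= ev
            denom_pre = np.maximum(ev - y0, 1.0)
            w_pre = np.clip((y - y0) / denom_pre, 0.0, 1.0)
            denom_post = np.maximum(y1 - (ev + 1), 1.0)
            w_post = np.clip((y - (ev + 1)) / denom_post, 0.0, 1.0)
            w = np.where(pre, w_pre, w_post)
            a0 = np.where(pre[:, None], to_awen0[dm], to_aft[dm])
            a1 = np.where(pre[:, None], to_bef[dm], to_awen1[dm])
            lit_in[i, dm] = (1 - w[:, None]) * a0 + w[:, None] * a1
            m0 = np.where(pre[:, None], mo_awen0[dm], mo_aft[dm])
            m1 = np.where(pre[:, None], mo_bef[dm], mo_awen1[dm])
            dead_in[i, dm] = (1 - w[:, None]) * m0 + w[:, None] * m1
            hit = y == event_year[dm]
            lit_in[i, dm] += hit[:, None] * hv_awen[dm]

    # 7. soil stepping: per-year operators from the climate series
    cl = climate.set_index("year")
    ops = []
    for y in years:
        row = cl.loc[y]
        cy = ClimateYear(float(row["precipitation"]), float(row["temperature"]),
                         float(row["amplitude"]))
        ops.append(transition_operator(build_flow_matrix(soil_params, cy)[0]))

    ref_climate = ClimateYear(*climate_ref)
    p_ref, r_ref = transition_operator(build_flow_matrix(soil_params, ref_climate)[0])

    # legacy carbon: per-(SP, SI) equilibrium, silvicultural-cycle ramp to the
    # first-epoch litter level, then split into AWEN (old litter) and H (old SO)
    eq = np.zeros((n, 5))
    table = opt.long_term_table
    for sp in SPECIES:
        for s in np.unique(si[species == sp]):
            mask = (species == sp) & (si == s)
            rows = table[(table["SP"] == sp) & (np.isclose(table["SI"], s))]
            if not len(rows):
                raise KeyError(f"no long-term reference for ({sp}, SI={s})")
            eq[mask] = rows.iloc[0][["A", "W", "E", "N", "H"]].to_numpy(dtype=float)
    l2001 = np.zeros((n, 5))
    l2001[:, :4] = to_awen0 + mo_awen0
    old_init = np.zeros((n, 5))
    for a in np.unique(age0):
        mask = age0 == a
        p_pow = np.linalg.matrix_power(p_ref, int(a))
        s_ramp = ramp_operator(p_ref, r_ref, int(a))
        old_init[mask] = eq[mask] @ p_pow.T + l2001[mask] @ s_ramp.T
    old_lit0 = old_init.copy()
    old_lit0[:, 4] = 0.0
    old_so0 = np.zeros((n, 5))
    old_so0[:, 4] = old_init[:, 4]

    lit_state = np.zeros((n, 5))
    dead_state = np.zeros((n, 5))
    old_lit = old_lit0.copy()
    old_so = old_so0.copy()
    annual = [] if opt.keep_annual else None
    for i in range(span):
        p, r = ops[i]
        u_l = np.zeros((n, 5))
        u_l[:, :4] = lit_in[i]
        u_d = np.zeros((n, 5))
        u_d[:, :4] = dead_in[i]
        lit_state = lit_state @ p.T + u_l @ r.T
        dead_state = dead_state @ p.T + u_d @ r.T
        old_lit = old_lit @ p.T
        old_so = old_so @ p.T
        if annual is not None:
            annual.append({
                "year": int(years[i]) + 1,
                "litter": lit_state[:, :4].sum(1).copy(),
                "deadwood": dead_state[:, :4].sum(1).copy(),
                "SO": lit_state[:, 4] + dead_state[:, 4],
                "litter_old": old_lit[:, :4].sum(1).copy(),
                "SO_old": old_so[:, 4] + old_lit[:, 4],
            })

    # 8. pools and annualised changes
    out = pd.DataFrame({
        "cell_id": cells["cell_id"].to_numpy(), "stand_id": sid,
        "species": species, "SI": si, "AGE_start": age0,
        "disturbed": disturbed, "event_year": event_year,
        f"D_{y0}": s0["D"].to_numpy(), f"D_{y1}": s1["D"].to_numpy(),
        f"Hdom_{y0}": s0["Hdom"].to_numpy(), f"Hdom_{y1}": s1["Hdom"].to_numpy(),
        f"H_{y0}": s0["H"].to_numpy(), f"H_{y1}": s1["H"].to_numpy(),
        f"BMS_{y0}": bms0, f"BMS_{y1}": bms1,
        f"N_{y0}": n0, f"N_{y1}": n1, "mortality_rate": mort,
    })
    stocks = {
        "AGB": (c_agb0, c_agb1),
        "BGB": (c_bgb0, c_bgb1),
        "litter": (np.zeros(n), lit_state[:, :4].sum(1)),
        "deadwood": (np.zeros(n), dead_state[:, :4].sum(1)),
        "SO": (np.zeros(n), lit_state[:, 4] + dead_state[:, 4]),
        "litter_incl_old": (
            old_lit0[:, :4].sum(1),
            lit_state[:, :4].sum(1) + dead_state[:, :4].sum(1) + old_lit[:, :4].sum(1),
        ),
        "SO_incl_old": (
            old_so0[:, 4],
            lit_state[:, 4] + dead_state[:, 4] + old_lit[:, 4] + old_so[:, 4],
        ),
    }
    for pool, (a, b) in stocks.items():
        out[f"C_{pool}_{y0}"] = a
        out[f"C_{pool}_{y1}"] = b
        out[f"dC_{pool}"] = (b - a) / span
    out["dC_total"] = (out["dC_AGB"] + out["dC_BGB"]
                       + out["dC_litter_incl_old"] + out["dC_SO_incl_old"])
    if annual is not None:
        out.attrs["annual"] = annual
    return out


def run_cell(cell_metrics: dict, stand: dict, climate, climate_ref,
             area_mset, allo_mset, soil_params=DEFAULT_SOIL_PARAMS,
             map_year: int | None = None, options: PipelineOptions | None = None) -> pd.Series:
    """Single-cell convenience wrapper over the vectorised engine.

    ``cell_metrics`` maps metric names to per-epoch values as
    ``{"H_ALS_80_2001": ..., "H_ALS_80_2016": ..., ...}``; ``stand`` needs
    SI, AGE, SP (and optionally area_ha).
    """
    cells = pd.DataFrame([{**cell_metrics, "cell_id": 0, "stand_id": 0}])
    stands = pd.DataFrame([{**{"area_ha": 1.0}, **stand, "stand_id": 0}])
    dist = None
    if map_year is not None:
        dist = pd.DataFrame({"cell_id": [0], "year": [map_year]})
    res = run_cells(cells, stands, climate, climate_ref, area_mset, allo_mset,
                    soil_params, dist, options)
    return res.iloc[0]


def aggregate(cell_results: pd.DataFrame, stands: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Stand means (unweighted over member cells) and area-weighted landscape summary."""
    value_cols = [c for c in cell_results.columns
                  if c.startswith(("dC_", "C_", "BMS_", "N_"))]
    orphan = set(cell_results["stand_id"]) - set(stands["stand_id"])
    if orphan:
        raise KeyError(f"orphan cells for stands {sorted(orphan)[:5]}")
    by_stand = cell_results.groupby("stand_id")[value_cols].mean()
    by_stand["n_cells"] = cell_results.groupby("stand_id").size()
    stand_results = by_stand.merge(
        stands.set_index("stand_id")[["SI", "AGE", "SP", "area_ha"]],
        left_index=True, right_index=True)
    w = stand_results["area_ha"].to_numpy()
    landscape = {"area_ha": float(w.sum()), "n_stands": int(len(stand_results))}
    for col in value_cols:
        v = stand_results[col].to_numpy()
        landscape[col] = float(np.sum(w * v) / w.sum())
    for col in [c for c in value_cols if c.startswith("dC_")]:
        landscape[f"{col}_min"] = float(stand_results[col].min())
        landscape[f"{col}_max"] = float(stand_results[col].max())
    return stand_results.reset_index(), landscape
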