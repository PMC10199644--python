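"""Litter production: turnover, mortality and harvest, with AWEN chemistry.

Standing biomass feeds the soil through three mechanisms.  Normal turnover
sheds a fixed annual fraction of each biomass component; mortality transfers
whole trees at an annual rate derived from the change in stem numbers; harvest
transfers, in the event year only, everything removed from the standing stock
except the extracted share (95%) of the stem wood.  Litter masses are
converted to carbon (50% of dry mass) and partitioned into the four chemical
compartments A, W, E, N per species and component.

Turnover- and harvest-sourced carbon feed the "litter" cohort, mortality the
"deadwood" cohort; the cohorts are decomposed independently (the soil model is
linear) so the two pools can be reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import (
    AWEN,
    CARBON_FRACTION,
    COMPONENTS,
    DEFAULT_MORTALITY_RATE,
    HARVEST_SW_EXTRACTION,
    SPECIES,
)

__all__ = [
    "DEFAULT_TURNOVER",
    "DEFAULT_AWEN",
    "turnover_fractions_frame",
    "awen_partition_frame",
    "turnover_litter",
    "mortality_rate",
    "mortality_litter",
    "harvest_litter",
    "awen_partition",
    "build_annual_litter_series",
    "LitterSeries",
]

# ---------------------------------------------------------------------------
# Bundled default constants.  The turnover fractions (yr^-1) and AWEN splits
# are drawn from the range of values used with Yasso-family models for boreal
# conifers and birch; they are configuration data, substitutable via the run
# configuration.
# ---------------------------------------------------------------------------

DEFAULT_TURNOVER = {
    #            SW     BR      DB     SB      SU   FL     RF    RC
    "spruce": dict(SW=0.0, BR=0.0125, DB=0.05, SB=0.0, SU=0.0, FL=0.139, RF=0.85, RC=0.0125),
    "pine":   dict(SW=0.0, BR=0.027,  DB=0.05, SB=0.0, SU=0.0, FL=0.278, RF=0.85, RC=0.027),
    "birch":  dict(SW=0.0, BR=0.0135, DB=0.05, SB=0.0, SU=0.0, FL=0.79,  RF=0.85, RC=0.0135),
}

_FOLIAGE_AWEN = {
    "spruce": (0.4826, 0.1317, 0.0658, 0.3199),
    "pine": (0.5180, 0.1773, 0.0887, 0.2160),
    "birch": (0.5689, 0.1286, 0.0643, 0.2382),
}
_WOODY_AWEN = (0.72, 0.03, 0.08, 0.17)
_FINEROOT_AWEN = {sp: _FOLIAGE_AWEN[sp] for sp in SPECIES}


def _default_awen() -> dict:
    table = {}
    for sp in SPECIES:
        for comp in COMPONENTS:
            if comp == "FL":
                table[(sp, comp)] = _FOLIAGE_AWEN[sp]
            elif comp == "RF":
                table[(sp, comp)] = _FINEROOT_AWEN[sp]
            else:
                table[(sp, comp)] = _WOODY_AWEN
    return table


DEFAULT_AWEN = _default_awen()


def turnover_fractions_frame(table: dict | None = None) -> pd.DataFrame:
    """Species x component turnover fractions as a validated DataFrame."""
    table = table or DEFAULT_TURNOVER
    df = pd.DataFrame(table).T.reindex(columns=list(COMPONENTS))
    if ((df < 0) | (df > 1)).any().any():
        raise ValueError("turnover fractions must lie in [0, 1]")
    return df


def awen_partition_frame(table: dict | None = None) -> pd.DataFrame:
    """(species, component) x AWEN proportions, validated to sum to 1."""
    table = table or DEFAULT_AWEN
    df = pd.DataFrame(
        {k: list(v) for k, v in table.items()}, index=list(AWEN)
    ).T
    df.index = pd.MultiIndex.from_tuples(df.index, names=["species", "component"])
    sums = df.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-12) or (df < 0).any().any():
        bad = sums[~np.isclose(sums, 1.0, atol=1e-12)]
        raise ValueError(f"AWEN rows must be non-negative and sum to 1: {bad.to_dict()}")
    return df


# ---------------------------------------------------------------------------
# Litter source operations.  Component vectors are pandas Series (or aligned
# numpy arrays) indexed by COMPONENTS, in Mg dry mass per hectare unless noted.
# ---------------------------------------------------------------------------


def turnover_litter(components_ha, fractions) -> pd.Series:
    """Annual turnover litter: elementwise biomass x fraction (Mg ha^-1 yr^-1)."""
    comp = pd.Series(components_ha, index=list(COMPONENTS), dtype=float)
    frac = pd.Series(fractions, index=list(COMPONENTS), dtype=float)
    if (comp < 0).any():
        raise ValueError("negative biomass")
    return comp * frac


def mortality_rate(
    n_start: float,
    n_end: float,
    years: float = 15.0,
    disturbed: bool = False,
    background: float = DEFAULT_MORTALITY_RATE,
) -> float:
    """Annual stem mortality rate from the change in stems per hectare.

    A decline in stem numbers in an undisturbed cell is attributed to
    mortality, compounding geometrically: m = 1 - (N_end/N_start)^(1/years).
    If stem numbers do not decrease — or the cell is disturbed, where the
    decline is attributed to harvest — the constant background rate applies.
    """
    if n_start <= 0 or n_end <= 0:
        raise ValueError("stem numbers must be positive")
    if disturbed or n_end >= n_start:
        return background
    return 1.0 - (n_end / n_start) ** (1.0 / years)


def mortality_litter(tree_components_kg, n_per_ha: float, rate: float) -> pd.Series:
    """Annual mortality litter: rate x N x whole-tree components (Mg ha^-1 yr^-1)."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    comp = pd.Series(tree_components_kg, index=list(COMPONENTS), dtype=float)
    return rate * n_per_ha * comp / 1000.0


def harvest_litter(before_ha, after_ha) -> pd.Series:
    """Event-year harvest residues from the removed standing biomass.

    95% of the removed stem wood is extracted (5% remains as litter); all
    other removed components remain on site entirely.  Negative removals
    (growth between the anchor states) are clipped to zero.
    """
    before = pd.Series(before_ha, index=list(COMPONENTS), dtype=float)
    after = pd.Series(after_ha, index=list(COMPONENTS), dtype=float)
    removed = (before - after).clip(lower=0.0)
    litter = removed.copy()
    litter["SW"] = (1.0 - HARVEST_SW_EXTRACTION) * removed["SW"]
    return litter


def awen_partition(
    component_litter,
    partition: pd.DataFrame,
    species: str,
    carbon_fraction: float = CARBON_FRACTION,
) -> np.ndarray:
    """Carbon in the four chemical compartments from component litter masses.

    carbon = carbon_fraction x dry mass, distributed over A/W/E/N by the
    species- and component-specific chemistry rows.  Conserves carbon exactly:
    the AWEN sum equals carbon_fraction x total litter mass.
    """
    comp = pd.Series(component_litter, index=list(COMPONENTS), dtype=float)
    rows = partition.loc[species].reindex(list(COMPONENTS))
    if rows.isna().any().any():
        raise ValueError(f"missing AWEN rows for {species}")
    return carbon_fraction * (comp.to_numpy() @ rows.to_numpy())


# ---------------------------------------------------------------------------
# Annual series over the timeframe
# ---------------------------------------------------------------------------


@dataclass
class LitterSeries:
    """Annual AWEN carbon inputs (Mg C ha^-1 yr^-1) per cohort.

    ``years[i]`` is the calendar year whose input drives the soil step from
    ``years[i]`` to ``years[i] + 1``; arrays have shape (n_years, 4).
    """

    years: np.ndarray
    litter: np.ndarray    # turnover + harvest cohort
    deadwood: np.ndarray  # mortality cohort

    def validate(self) -> None:
        if np.any(self.litter < -1e-12) or np.any(self.deadwood < -1e-12):
            raise ValueError("negative annual litter input")


def _interp_rows(y0: float, y1: float, v0: np.ndarray, v1: np.ndarray, years: np.ndarray) -> np.ndarray:
    if y1 == y0:
        return np.tile(v0, (len(years), 1))
    w = (years - y0) / (y1 - y0)
    return np.outer(1.0 - w, v0) + np.outer(w, v1)


def build_annual_litter_series(
    anchors: dict,
    start_year: int,
    end_year: int,
    event_year: int | None = None,
    harvest_awen: np.ndarray | None = None,
) -> LitterSeries:
    """Interpolate per-source AWEN inputs across the timeframe.

    ``anchors`` maps anchor labels to ``(turnover_awen, mortality_awen)``
    tuples of length-4 carbon vectors: ``"start"`` and ``"end"`` always;
    ``"before"`` and ``"after"`` when an event year is given.  Undisturbed
    cells interpolate linearly start→end.  Disturbed cells interpolate
    start→event using the start/before anchors and event+1→end using the
    after/end anchors; the event year additionally receives the harvest
    residues in the litter cohort.
    """
    years = np.arange(start_year, end_year)  # inputs drive steps start..end-1
    to_start, mort_start = (np.asarray(a, dtype=float) for a in anchors["start"])
    to_end, mort_end = (np.asarray(a, dtype=float) for a in anchors["end"])
    if event_year is None:
        lit = _interp_rows(start_year, end_year, to_start, to_end, years)
        dead = _interp_rows(start_year, end_year, mort_start, mort_end, years)
    else:
        if not start_year <= event_year < end_year:
            raise ValueError("event year outside timeframe")
        if "before" not in anchors or "after" not in anchors:
            raise ValueError("disturbed series needs 'before' and 'after' anchors")
        to_bef, mort_bef = (np.asarray(a, dtype=float) for a in anchors["before"])
        to_aft, mort_aft = (np.asarray(a, dtype=float) for a in anchors["after"])
        pre = years <= event_year
        post = ~pre
        lit = np.zeros((len(years), 4))
        dead = np.zeros((len(years), 4))
        lit[pre] = _interp_rows(start_year, event_year, to_start, to_bef, years[pre])
        dead[pre] = _interp_rows(start_year, event_year, mort_start, mort_bef, years[pre])
        lit[post] = _interp_rows(event_year + 1, end_year, to_aft, to_end, years[post])
        dead[post] = _interp_rows(event_year + 1, end_year, mort_aft, mort_end, years[post])
        if harvest_awen is not None:
            lit[years == event_year] += np.asarray(harvest_awen, dtype=float)
    series = LitterSeries(years, lit, dead)
    series.validate()
    return series
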