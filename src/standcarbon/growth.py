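"""Forward growth contract and the inverse-growth bisection search.

Stand development enters the carbon chain through external diameter and
dominant-height growth models whose parameter uncertainty is not accounted
for.  This module fixes their functional contract — a forward map
``(D, Hdom, SI, AGE, N, years) -> (D', Hdom')`` that is monotone and composes
over consecutive periods — and ships a documented default parametric family
per species used by the synthetic truth:

  Hdom' = Hdom + h1 * SI * (phi(AGE + y) - phi(AGE)),   phi(a) = 1 - exp(-lam*a)
  D'    = D * ((1 + AGE + y) / (1 + AGE))**c,
  c     = c0 * (SI / 14) * (n0 / (n0 + N))

so height increments are driven by site index and age alone, and the relative
diameter increment declines with both stand density and age.  The disturbance
pathway reconstructs the pre-event ("before") tree by forward growth from the
first epoch and the post-event ("after") tree by inverting growth from the
second epoch with a recursive interval-halving search.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "GrowthInputs",
    "GrowthModelSpec",
    "DEFAULT_GROWTH_SPECS",
    "grow_tree",
    "invert_growth",
    "GrowthInversionError",
]

#: convergence tolerance of the inverse search, in each variable's native
#: unit (cm for D, m for Hdom)
INVERSION_TOL = 1e-3


@dataclass(frozen=True)
class GrowthInputs:
    D: float      # mean diameter, cm
    Hdom: float   # dominant height, m
    SI: float     # site index, m at reference age
    AGE: float    # stand age, years
    N: float      # stems per hectare
    species: str = "spruce"

    def __post_init__(self):
        if self.AGE < 0:
            raise ValueError("AGE must be non-negative")


@dataclass(frozen=True)
class GrowthModelSpec:
    """Default parametric growth family; source tag marks provenance."""

    species: str
    h1: float = 1.6
    lam: float = 0.02
    c0: float = 0.9
    n0: float = 1000.0
    source: str = "synthetic-truth"

    def grow_arrays(self, d, hdom, si, age, n, years):
        """Elementwise forward growth on aligned arrays (or scalars)."""
        if np.any(np.asarray(years) < 0):
            raise ValueError("negative years: use invert_growth")
        phi = lambda a: 1.0 - np.exp(-self.lam * np.asarray(a, dtype=float))
        hdom2 = hdom + self.h1 * si * (phi(age + years) - phi(age))
        c = self.c0 * (si / 14.0) * (self.n0 / (self.n0 + n))
        d2 = d * ((1.0 + age + years) / (1.0 + age)) ** c
        return d2, hdom2

    def grow(self, x: GrowthInputs, years: float) -> tuple[float, float]:
        d, hdom = self.grow_arrays(x.D, x.Hdom, x.SI, x.AGE, x.N, years)
        return float(d), float(hdom)


DEFAULT_GROWTH_SPECS = {
    "spruce": GrowthModelSpec("spruce", h1=1.60, lam=0.020, c0=0.90),
    "pine": GrowthModelSpec("pine", h1=1.45, lam=0.018, c0=0.80),
    "birch": GrowthModelSpec("birch", h1=1.30, lam=0.025, c0=0.85),
}


def grow_tree(spec, x: GrowthInputs, years: float, height_model=None):
    """Forward growth over ``years``; AGE advances accordingly.

    Returns the grown ``GrowthInputs`` (same N); if ``height_model`` (a fitted
    mean-height area model) and epoch dummy are supplied via a
    ``(model, t)`` tuple, the mean height is also returned.
    """
    d, hdom = spec.grow(x, years)
    grown = replace(x, D=d, Hdom=hdom, AGE=x.AGE + years)
    if height_model is not None:
        model, t = height_model
        import pandas as pd

        h = float(model.predict(pd.DataFrame({"Hdom": [hdom]}), t)[0])
        return grown, max(h, 1.3)
    return grown


class GrowthInversionError(RuntimeError):
    pass


def _bisect(f, lo: float, hi: float, target: float, tol: float, max_iter: int = 200) -> float:
    """Solve f(x) = target for increasing f by recursive interval halving."""
    flo, fhi = f(lo), f(hi)
    if not (flo - tol <= target <= fhi + tol):
        raise GrowthInversionError(
            f"target {target:.4f} outside growable range [{flo:.4f}, {fhi:.4f}]")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        val = f(mid)
        if abs(val - target) < tol and hi - lo < tol:
            return mid
        if val < target:
            lo = mid
        else:
            hi = mid
    raise GrowthInversionError("inverse search did not converge")


def invert_growth(
    spec, target: GrowthInputs, years: float, tol: float = INVERSION_TOL
) -> GrowthInputs:
    """State ``years`` before ``target`` under the given growth spec.

    Finds x with AGE = target.AGE - years such that growing x forward by
    ``years`` reproduces the target's Hdom and D within ``tol`` in each
    variable's native unit.  Dominant height is inverted first (its increment
    depends only on SI and AGE), then diameter given the height trajectory —
    mirroring the dependency order of the forward models.  Stand density is
    held at the target's value.  A target below the minimum growable state
    raises :class:`GrowthInversionError`.
    """
    if years < 0:
        raise ValueError("years must be non-negative")
    if years == 0:
        return target
    age0 = max(target.AGE - years, 0.0)
    base = replace(target, AGE=age0)

    def grown_hdom(h0: float) -> float:
        return spec.grow(replace(base, Hdom=h0), years)[1]

    hdom0 = _bisect(grown_hdom, 0.0, target.Hdom + tol, target.Hdom, tol)

    def grown_d(d0: float) -> float:
        return spec.grow(replace(base, D=d0, Hdom=hdom0), years)[0]

    d0 = _bisect(grown_d, 1e-6, target.D + tol, target.D, tol)
    return replace(base, D=d0, Hdom=hdom0)


def invert_growth_arrays(
    spec, d, hdom, si, age_end, n, years, tol: float = INVERSION_TOL, max_iter: int = 80
):
    """Vectorised inverse growth by interval halving on aligned arrays.

    Solves for the (D0, Hdom0) at ``age_end - years`` whose forward growth
    matches the targets, holding N at the target value.  Targets below the
    minimum growable state converge to the lower bracket edge (zero), which
    callers should treat as a degenerate young/clearcut state.
    """
    d = np.asarray(d, dtype=float)
    hdom = np.asarray(hdom, dtype=float)
    si = np.asarray(si, dtype=float)
    years = np.asarray(years, dtype=float)
    age0 = np.maximum(np.asarray(age_end, dtype=float) - years, 0.0)

    lo, hi = np.zeros_like(hdom), hdom + tol
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        grown = spec.grow_arrays(d, mid, si, age0, n, years)[1]
        lo = np.where(grown < hdom, mid, lo)
        hi = np.where(grown < hdom, hi, mid)
    hdom0 = 0.5 * (lo + hi)

    lo, hi = np.full_like(d, 1e-6), d + tol
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        grown = spec.grow_arrays(mid, hdom0, si, age0, n, years)[0]
        lo = np.where(grown < d, mid, lo)
        hi = np.where(grown < d, hi, mid)
    d0 = 0.5 * (lo + hi)
    return d0, hdom0, age0
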