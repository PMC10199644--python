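"""Five-compartment linear soil carbon decomposition model.

Decomposing litter is tracked in four chemical compartments — acid-hydrolyzable
celluloses (A), water-soluble sugars (W), ethanol-soluble waxes (E) and
non-soluble lignin-like compounds (N) — plus humus (H), the terminal soil
organic carbon compartment.  Each litter compartment loses mass at a
climate-modulated first-order rate; the lost mass is split between transfers to
other litter compartments, humification into H, and CO2 emission.  Humus only
emits CO2.  Because the system is linear and the rates depend on climate alone,
carbon from distinct sources (turnover, mortality, harvest, legacy stocks) can
be traced through the shared system as independent cohorts whose sum equals a
combined run.

States are length-5 numpy vectors ordered (A, W, E, N, H) in Mg C ha^-1.
The continuous-time dynamics within a year are dx/dt = M x + u with constant
annual input u, advanced exactly with the matrix exponential.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm

from .constants import AWEN, COMPARTMENTS

__all__ = [
    "ClimateYear",
    "SoilParams",
    "DEFAULT_SOIL_PARAMS",
    "climate_modifier",
    "build_flow_matrix",
    "transition_operator",
    "annual_step",
    "spinup_equilibrium",
    "init_old_carbon",
    "ramp_operator",
    "carry_old_carbon",
    "sample_parameter_table",
    "params_from_vector",
]

_IDX = {c: i for i, c in enumerate(COMPARTMENTS)}


@dataclass(frozen=True)
class ClimateYear:
    """Annual climate forcing.

    precipitation : mm yr^-1
    temperature   : mean annual temperature, degC
    amplitude     : mean difference between monthly max and min temperature, degC
    """

    precipitation: float
    temperature: float
    amplitude: float

    def __post_init__(self):
        if self.precipitation < 0:
            raise ValueError("precipitation must be non-negative")


def _default_transfers() -> dict:
    # fraction of the decomposed outflow of `src` routed to `dst`
    return {
        ("A", "W"): 0.10,
        ("A", "E"): 0.01,
        ("W", "A"): 0.40,
        ("E", "A"): 0.25,
        ("E", "W"): 0.02,
        ("N", "A"): 0.10,
        ("N", "W"): 0.01,
    }


def _default_humification() -> dict:
    return {"A": 0.045, "W": 0.045, "E": 0.045, "N": 0.045}


@dataclass(frozen=True)
class SoilParams:
    """Structural parameters of the decomposition system.

    Rates are potential (reference-climate) first-order decomposition rates in
    yr^-1; the realised rate is the potential rate times the dimensionless
    climate modifier.  Transfer fractions route the decomposed outflow of a
    litter compartment; per source they must sum (with the humification
    fraction) to at most 1, the remainder being emitted as CO2.
    """

    decay_rates: dict = field(default_factory=lambda: {"A": 0.42, "W": 1.20, "E": 0.50, "N": 0.050})
    humus_rate: float = 0.0050
    transfers: dict = field(default_factory=_default_transfers)
    humification: dict = field(default_factory=_default_humification)
    temp_coef1: float = 0.09      # linear temperature response, degC^-1
    temp_coef2: float = -0.0013   # quadratic temperature response, degC^-2
    precip_coef: float = 1.2      # saturating precipitation response, m^-1

    def validate(self) -> None:
        for c in AWEN:
            out = sum(f for (s, _), f in self.transfers.items() if s == c)
            out += self.humification.get(c, 0.0)
            if out > 1.0 + 1e-12:
                raise ValueError(f"outflow fractions of {c} exceed 1 ({out:.4f})")
            if self.decay_rates[c] < 0:
                raise ValueError(f"negative decay rate for {c}")
        if any(f < 0 for f in self.transfers.values()):
            raise ValueError("negative transfer fraction")
        if self.humus_rate < 0:
            raise ValueError("negative humus rate")

    def to_vector(self) -> np.ndarray:
        """Flatten to the canonical parameter vector used for sampling."""
        v = [self.decay_rates[c] for c in AWEN]
        v.append(self.humus_rate)
        v += [self.transfers.get((s, d), 0.0) for s in AWEN for d in AWEN if s != d]
        v += [self.humification[c] for c in AWEN]
        v += [self.temp_coef1, self.temp_coef2, self.precip_coef]
        return np.asarray(v, dtype=float)


def params_from_vector(vec: np.ndarray, template: "SoilParams | None" = None) -> SoilParams:
    """Inverse of :meth:`SoilParams.to_vector`."""
    template = template or DEFAULT_SOIL_PARAMS
    vec = np.asarray(vec, dtype=float)
    rates = dict(zip(AWEN, vec[:4]))
    humus_rate = float(vec[4])
    pairs = [(s, d) for s in AWEN for d in AWEN if s != d]
    transfers = {p: float(f) for p, f in zip(pairs, vec[5:17]) if f != 0.0}
    hum = dict(zip(AWEN, vec[17:21].astype(float)))
    return replace(
        template,
        decay_rates=rates,
        humus_rate=humus_rate,
        transfers=transfers,
        humification=hum,
        temp_coef1=float(vec[21]),
        temp_coef2=float(vec[22]),
        precip_coef=float(vec[23]),
    )


DEFAULT_SOIL_PARAMS = SoilParams()


def climate_modifier(params: SoilParams, climate: ClimateYear) -> float:
    """Dimensionless multiplier on all decomposition rates.

    The temperature response exp(b1*T + b2*T^2) is averaged over an idealised
    seasonal cycle T_m = T + (amplitude/2)*sin(2*pi*m/12) sampled at the twelve
    months, capturing the convexity benefit of seasonal variation; the
    precipitation response saturates as 1 - exp(-g*P) with P in metres.
    """
    months = np.arange(1, 13)
    tm = climate.temperature + 0.5 * climate.amplitude * np.sin(2 * np.pi * months / 12.0)
    xi_t = float(np.mean(np.exp(params.temp_coef1 * tm + params.temp_coef2 * tm**2)))
    xi_p = 1.0 - np.exp(-params.precip_coef * climate.precipitation / 1000.0)
    return xi_t * float(xi_p)


def build_flow_matrix(params: SoilParams, climate: ClimateYear) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the 5x5 continuous-time rate matrix and the CO2 outflow rates.

    Returns ``(M, co2)`` such that dx/dt = M x + u and the instantaneous CO2
    emission rate is ``co2 @ x``.  Column i of M describes the fate of
    compartment i: the diagonal holds the negative total outflow rate, the
    off-diagonals the transfer rates into other compartments (humus receives
    the humification inflows and has no outflow other than its own CO2 decay).

    Raises ``ValueError`` if the resulting matrix is not strictly stable.
    """
    params.validate()
    xi = climate_modifier(params, climate)
    m = np.zeros((5, 5))
    co2 = np.zeros(5)
    for c in AWEN:
        i = _IDX[c]
        k = params.decay_rates[c] * xi
        m[i, i] = -k
        routed = 0.0
        for (s, d), f in params.transfers.items():
            if s == c:
                m[_IDX[d], i] += f * k
                routed += f
        ph = params.humification.get(c, 0.0)
        m[_IDX["H"], i] += ph * k
        routed += ph
        co2[i] = (1.0 - routed) * k
    kh = params.humus_rate * xi
    m[_IDX["H"], _IDX["H"]] = -kh
    co2[_IDX["H"]] = kh
    # zero eigenvalues (inert compartments, zero climate modifier) are fine;
    # only mass growth is unstable
    eig = np.linalg.eigvals(m)
    if np.any(eig.real > 1e-12):
        raise ValueError("unstable flow matrix (positive eigenvalue)")
    return m, co2


def transition_operator(matrix: np.ndarray, dt: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """One-step solution operators ``(P, R)`` of dx/dt = M x + u over ``dt``.

    ``x(dt) = P x(0) + R u`` with P = exp(M dt) and R = int_0^dt exp(M s) ds,
    both obtained from a single augmented matrix exponential (valid even for a
    singular M, e.g. when the climate modifier is zero).
    """
    aug = np.zeros((10, 10))
    aug[:5, :5] = matrix * dt
    aug[:5, 5:] = np.eye(5) * dt
    e = expm(aug)
    return e[:5, :5], e[:5, 5:]


def annual_step(
    state: np.ndarray,
    inflow: np.ndarray,
    matrix: np.ndarray | None = None,
    operator: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, float]:
    """Advance the soil state one year under constant within-year input.

    ``inflow`` is the AWEN(+H) carbon input over the year (Mg C ha^-1); pass a
    length-4 vector to mean AWEN-only input.  Returns the new state and the
    CO2 emitted during the year (by mass balance).
    """
    state = np.asarray(state, dtype=float)
    u = np.zeros(5)
    u[: len(np.atleast_1d(inflow))] = inflow
    if np.any(state < -1e-9) or np.any(u < -1e-12):
        raise ValueError("negative state or input")
    if operator is None:
        if matrix is None:
            raise ValueError("provide matrix or operator")
        operator = transition_operator(matrix)
    p, r = operator
    new = p @ state + r @ u
    if np.any(new < -1e-9):
        raise FloatingPointError("numerical failure: negative compartment")
    co2 = float(state.sum() + u.sum() - new.sum())
    return new, co2


def spinup_equilibrium(
    params: SoilParams,
    climate: ClimateYear,
    inflow: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 500_000,
) -> np.ndarray:
    """Steady state of the annual step under fixed climate and litter input.

    Computed in closed form as x* = (I - P)^-1 R u and verified against
    iterative stepping.  Slowly decaying compartments (humus) make the
    per-step increment a poor proxy for the remaining distance, so iteration
    continues until the increment falls below ``tol * 1e-3``, which bounds the
    geometric tail well below ``tol``; the two routes must then agree to
    within ``tol * 100`` or a ``RuntimeError`` is raised.
    """
    m, _ = build_flow_matrix(params, climate)
    p, r = transition_operator(m)
    u = np.zeros(5)
    u[: len(np.atleast_1d(inflow))] = inflow
    closed = np.linalg.solve(np.eye(5) - p, r @ u)
    x = np.zeros(5)
    increment_tol = tol * 1e-3
    for _ in range(max_iter):
        new = p @ x + r @ u
        if np.max(np.abs(new - x)) < increment_tol:
            x = new
            break
        x = new
    else:
        raise RuntimeError("spin-up did not converge")
    if np.max(np.abs(x - closed)) > 100 * tol:
        raise RuntimeError("iterative and closed-form equilibria disagree")
    return closed


def ramp_operator(p: np.ndarray, r: np.ndarray, n_years: int) -> np.ndarray:
    """Response matrix of an n-year linear input ramp.

    For inputs u_j = (j/n) * u applied in years j = 1..n, the state added by
    the ramp is ``ramp_operator(P, R, n) @ u`` (the legacy state itself decays
    as P^n x0).  n = 0 returns the zero matrix.
    """
    s = np.zeros((5, 5))
    acc = np.eye(5)  # P^(n-j) built backwards
    for j in range(n_years, 0, -1):
        s += (j / n_years) * (acc @ r)
        acc = p @ acc
    return s


def init_old_carbon(
    species: str,
    si: float,
    age: int,
    litter_2001: np.ndarray,
    params: SoilParams,
    climate_ref: ClimateYear,
    reference_table=None,
    reference_inflow: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage approximation of legacy ("old") soil carbon at the epoch start.

    Stage 1 establishes a long-term per-(species, site index) equilibrium
    state: looked up from ``reference_table`` (columns SP, SI, A, W, E, N, H)
    when available, otherwise spun up from ``reference_inflow``.  Stage 2
    assumes the current silvicultural cycle began with a clear cut ``age``
    years before the epoch start, with that equilibrium as the cycle-start
    state, and steps forward ``age`` years under the reference climate with the
    annual litter input ramped linearly from 0 to ``litter_2001``.

    Returns ``(old_litter, old_so)``: the resulting state split into its AWEN
    part (legacy litter cohort) and its humus part (legacy soil organic
    cohort), each as a full length-5 state vector.
    """
    eq = None
    if reference_table is not None:
        rows = reference_table[
            (reference_table["SP"] == species) & (np.isclose(reference_table["SI"], si))
        ]
        if len(rows):
            eq = rows.iloc[0][list(COMPARTMENTS)].to_numpy(dtype=float)
    if eq is None:
        if reference_inflow is None:
            raise KeyError(
                f"no long-term reference for ({species}, SI={si}) and no reference inflow"
            )
        eq = spinup_equilibrium(params, climate_ref, reference_inflow)
    m, _ = build_flow_matrix(params, climate_ref)
    p, r = transition_operator(m)
    age = max(int(age), 0)
    u = np.zeros(5)
    u[: len(np.atleast_1d(litter_2001))] = litter_2001
    state = np.linalg.matrix_power(p, age) @ eq + ramp_operator(p, r, age) @ u
    old_litter = state.copy()
    old_litter[_IDX["H"]] = 0.0
    old_so = np.zeros(5)
    old_so[_IDX["H"]] = state[_IDX["H"]]
    return old_litter, old_so


def carry_old_carbon(
    old_states: dict[str, np.ndarray],
    climate_series: list[ClimateYear],
    params: SoilParams,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Trace legacy cohorts through the timeframe with no new litter input.

    Returns the final states and the annual CO2 emission path (summed over
    cohorts).  Because the system is linear, adding these final states to a
    zero-initialised new-carbon run reproduces a combined-initialisation run.
    """
    states = {k: np.asarray(v, dtype=float).copy() for k, v in old_states.items()}
    co2 = np.zeros(len(climate_series))
    zero = np.zeros(4)
    for t, cl in enumerate(climate_series):
        op = transition_operator(build_flow_matrix(params, cl)[0])
        for key in states:
            states[key], emitted = annual_step(states[key], zero, operator=op)
            co2[t] += emitted
    return states, co2


def sample_parameter_table(
    params: SoilParams, n: int, seed: int, cv: float = 0.05
) -> np.ndarray:
    """Synthesise a seeded sample of full soil parameter vectors.

    Rates and fractions are perturbed multiplicatively (log-normal with
    coefficient of variation ``cv``); the climate-response coefficients
    additively with the same relative scale.  Rows that fail validation or
    stability are redrawn.  Stands in for an externally supplied posterior
    sample table; one row per draw in ``to_vector`` order.
    """
    rng = np.random.default_rng(seed)
    base = params.to_vector()
    sigma = np.sqrt(np.log1p(cv**2))
    rows = []
    ref = ClimateYear(700.0, 4.0, 20.0)
    while len(rows) < n:
        vec = base.copy()
        pos = base[:21] > 0
        vec[:21][pos] = base[:21][pos] * rng.lognormal(-0.5 * sigma**2, sigma, pos.sum())
        vec[21:] = base[21:] * (1.0 + cv * rng.standard_normal(3))
        try:
            candidate = params_from_vector(vec, params)
            build_flow_matrix(candidate, ref)
        except (ValueError, FloatingPointError):
            continue
        rows.append(vec)
    return np.asarray(rows)
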