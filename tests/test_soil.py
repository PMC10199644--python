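"""Soil decomposition model: flow structure, stepping, spin-up, cohorts."""

import numpy as np
import pytest

from standcarbon.constants import AWEN, COMPARTMENTS
from standcarbon.soil import (
    ClimateYear,
    SoilParams,
    annual_step,
    build_flow_matrix,
    carry_old_carbon,
    climate_modifier,
    init_old_carbon,
    params_from_vector,
    ramp_operator,
    sample_parameter_table,
    spinup_equilibrium,
    transition_operator,
)

IDX = {c: i for i, c in enumerate(COMPARTMENTS)}


class TestFlowMatrix:
    def test_zero_precipitation_stops_decomposition(self, soil_params):
        dry = ClimateYear(precipitation=0.0, temperature=4.0, amplitude=20.0)
        m, co2 = build_flow_matrix(soil_params, dry)
        assert np.allclose(m, 0.0) and np.allclose(co2, 0.0)

    def test_column_mass_audit(self, soil_params, boreal_climate):
        """Per compartment, total outflow = transfers out + CO2 emission."""
        m, co2 = build_flow_matrix(soil_params, boreal_climate)
        for c in AWEN:
            i = IDX[c]
            transfers_out = m[:, i].sum() - m[i, i]
            assert -m[i, i] == pytest.approx(transfers_out + co2[i], rel=1e-12)
        h = IDX["H"]
        assert np.all(m[:h, h] == 0.0)  # humus transfers to nothing
        assert -m[h, h] == pytest.approx(co2[h], rel=1e-12)

    def test_humus_is_absorbing(self, soil_params, boreal_climate):
        m, _ = build_flow_matrix(soil_params, boreal_climate)
        assert np.all(m[: IDX["H"], IDX["H"]] == 0.0)

    def test_matches_hand_built_two_compartment_reduction(self, boreal_climate):
        """A-and-humus-only parameters give the hand-derived 2x2 structure."""
        params = SoilParams(
            decay_rates={"A": 0.5, "W": 0.0, "E": 0.0, "N": 0.0},
            humus_rate=0.01,
            transfers={},
            humification={"A": 0.2, "W": 0.0, "E": 0.0, "N": 0.0},
        )
        m, co2 = build_flow_matrix(params, boreal_climate)
        xi = climate_modifier(params, boreal_climate)
        a, h = IDX["A"], IDX["H"]
        assert m[a, a] == pytest.approx(-0.5 * xi)
        assert m[h, a] == pytest.approx(0.2 * 0.5 * xi)
        assert co2[a] == pytest.approx(0.8 * 0.5 * xi)
        assert m[h, h] == pytest.approx(-0.01 * xi)
        assert co2[h] == pytest.approx(0.01 * xi)

    def test_mass_creating_parameters_rejected(self, boreal_climate):
        """Outflow fractions beyond 1 (mass creation) are invalid."""
        bad = SoilParams(transfers={("A", "W"): 0.9, ("A", "E"): 0.3},
                         humification={"A": 0.1, "W": 0.045, "E": 0.045, "N": 0.045})
        with pytest.raises(ValueError):
            build_flow_matrix(bad, boreal_climate)

    def test_vector_round_trip(self, soil_params):
        vec = soil_params.to_vector()
        back = params_from_vector(vec, soil_params)
        assert np.allclose(back.to_vector(), vec)


class TestAnnualStep:
    def test_zero_state_zero_input(self, soil_params, boreal_climate):
        m, _ = build_flow_matrix(soil_params, boreal_climate)
        state, co2 = annual_step(np.zeros(5), np.zeros(4), m)
        assert np.all(state == 0.0) and co2 == 0.0

    def test_linearity_enables_cohort_tracing(self, soil_params, boreal_climate, rng):
        m, _ = build_flow_matrix(soil_params, boreal_climate)
        op = transition_operator(m)
        x1, x2 = rng.uniform(0, 10, 5), rng.uniform(0, 10, 5)
        u1, u2 = rng.uniform(0, 2, 4), rng.uniform(0, 2, 4)
        joint, _ = annual_step(x1 + x2, u1 + u2, operator=op)
        s1, _ = annual_step(x1, u1, operator=op)
        s2, _ = annual_step(x2, u2, operator=op)
        assert np.allclose(joint, s1 + s2, rtol=1e-10, atol=1e-12)

    def test_agrees_with_explicit_euler_integration(self, soil_params, boreal_climate, rng):
        """Independent ODE oracle: forward Euler at dt = 1e-4 yr."""
        m, _ = build_flow_matrix(soil_params, boreal_climate)
        x0 = rng.uniform(0, 10, 5)
        u = np.concatenate([rng.uniform(0, 2, 4), [0.0]])
        stepped, _ = annual_step(x0, u[:4], m)
        dt = 1e-4
        x = x0.copy()
        for _ in range(int(1 / dt)):
            x = x + dt * (m @ x + u)
        assert np.allclose(stepped, x, rtol=1e-3)
        assert np.max(np.abs(stepped - x) / np.maximum(np.abs(stepped), 1e-12)) < 1e-3

    def test_mass_balance_every_year(self, soil_params, rng):
        """stocks + cumulative CO2 = initial stocks + cumulative input."""
        state = rng.uniform(0, 20, 5)
        total0 = state.sum()
        cum_in = cum_out = 0.0
        for _ in range(30):
            climate = ClimateYear(rng.uniform(300, 1200), rng.uniform(-2, 8),
                                  rng.uniform(15, 28))
            m, _ = build_flow_matrix(soil_params, climate)
            u = rng.uniform(0, 3, 4)
            state, co2 = annual_step(state, u, m)
            cum_in += u.sum()
            cum_out += co2
            balance = state.sum() + cum_out
            assert balance == pytest.approx(total0 + cum_in, rel=1e-9)


class TestSpinup:
    def test_zero_input_equilibrium_is_zero(self, soil_params, boreal_climate):
        assert np.allclose(spinup_equilibrium(soil_params, boreal_climate, np.zeros(4)), 0.0)

    def test_fixed_point_and_dual_method_agreement(self, soil_params, boreal_climate):
        u = np.array([1.2, 0.3, 0.15, 0.6])
        eq = spinup_equilibrium(soil_params, boreal_climate, u)
        m, _ = build_flow_matrix(soil_params, boreal_climate)
        stepped, _ = annual_step(eq, u, m)
        assert np.max(np.abs(stepped - eq)) < 1e-8
        # iterative verification happens inside spinup_equilibrium (<1e-6 guard);
        # re-check independently by long stepping
        x = np.zeros(5)
        op = transition_operator(m)
        for _ in range(20000):
            x, _ = annual_step(x, u, operator=op)
        assert np.max(np.abs(x - eq)) < 1e-6

    def test_linearity_in_input(self, soil_params, boreal_climate):
        u = np.array([1.0, 0.2, 0.1, 0.5])
        eq1 = spinup_equilibrium(soil_params, boreal_climate, u)
        eq2 = spinup_equilibrium(soil_params, boreal_climate, 2 * u)
        assert np.allclose(eq2, 2 * eq1, rtol=1e-9)


class TestOldCarbonInit:
    def test_reference_table_row_is_used_verbatim_at_cycle_start(
        self, soil_params, boreal_climate
    ):
        from standcarbon.pipeline import load_long_term_table

        table = load_long_term_table()
        old_litter, old_so = init_old_carbon(
            "spruce", 11, age=0, litter_2001=np.zeros(4), params=soil_params,
            climate_ref=boreal_climate, reference_table=table)
        assert old_litter[:4] == pytest.approx([7.10, 0.75, 0.69, 18.07])
        assert old_so[4] == pytest.approx(35.77)

    def test_missing_row_without_inflow_raises(self, soil_params, boreal_climate):
        from standcarbon.pipeline import load_long_term_table

        with pytest.raises(KeyError):
            init_old_carbon("spruce", 12.5, age=10, litter_2001=np.zeros(4),
                            params=soil_params, climate_ref=boreal_climate,
                            reference_table=load_long_term_table())

    def test_missing_row_spins_up_from_reference_inflow(self, soil_params, boreal_climate):
        u = np.array([1.0, 0.2, 0.1, 0.5])
        old_litter, old_so = init_old_carbon(
            "spruce", 12.5, age=0, litter_2001=np.zeros(4), params=soil_params,
            climate_ref=boreal_climate, reference_table=None, reference_inflow=u)
        eq = spinup_equilibrium(soil_params, boreal_climate, u)
        assert np.allclose(old_litter[:4], eq[:4])
        assert old_so[4] == pytest.approx(eq[4])

    def test_ramp_matches_direct_summation_oracle(self, soil_params, boreal_climate, rng):
        """The ramp operator equals explicit year-by-year stepping."""
        m, _ = build_flow_matrix(soil_params, boreal_climate)
        p, r = transition_operator(m)
        u = rng.uniform(0, 2, 4)
        u5 = np.concatenate([u, [0.0]])
        n_years = 23
        x = np.zeros(5)
        for j in range(1, n_years + 1):
            x, _ = annual_step(x, (j / n_years) * u, operator=(p, r))
        assert np.allclose(ramp_operator(p, r, n_years) @ u5, x, rtol=1e-10)


class TestCohortTracing:
    def test_zero_old_state_stays_zero(self, soil_params):
        climates = [ClimateYear(700, 4, 20)] * 15
        states, co2 = carry_old_carbon({"old": np.zeros(5)}, climates, soil_params)
        assert np.all(states["old"] == 0.0) and np.all(co2 == 0.0)

    def test_separated_cohorts_sum_to_combined_run(self, soil_params, rng):
        """Old carbon traced separately + new accumulation = combined run."""
        climates = [ClimateYear(rng.uniform(400, 1000), rng.uniform(0, 7),
                                rng.uniform(16, 26)) for _ in range(15)]
        old = rng.uniform(0, 30, 5)
        inputs = rng.uniform(0, 2, (15, 4))
        new_state = np.zeros(5)
        old_state = old.copy()
        combined = old.copy()
        for t, cl in enumerate(climates):
            op = transition_operator(build_flow_matrix(soil_params, cl)[0])
            new_state, _ = annual_step(new_state, inputs[t], operator=op)
            old_state, _ = annual_step(old_state, np.zeros(4), operator=op)
            combined, _ = annual_step(combined, inputs[t], operator=op)
        total = new_state + old_state
        assert np.max(np.abs(total - combined) / np.maximum(np.abs(combined), 1e-300)) < 1e-10

    def test_old_stocks_strictly_decrease_without_input(self, soil_params):
        climates = [ClimateYear(700, 4, 20)] * 10
        state = np.array([5.0, 0.5, 0.5, 15.0, 30.0])
        prev_total = state.sum()
        for cl in climates:
            op = transition_operator(build_flow_matrix(soil_params, cl)[0])
            state, _ = annual_step(state, np.zeros(4), operator=op)
            assert state.sum() < prev_total
            prev_total = state.sum()


def test_sampled_parameters_are_valid_and_reproducible(soil_params):
    a = sample_parameter_table(soil_params, 25, seed=3)
    b = sample_parameter_table(soil_params, 25, seed=3)
    assert np.array_equal(a, b)
    ref = ClimateYear(700, 4, 20)
    for row in a:
        build_flow_matrix(params_from_vector(row, soil_params), ref)  # no raise
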