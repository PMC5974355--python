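"""Adult energetics: unit costs, DEE, DFI, CPUE, scaling and sensitivity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ternergy import (
    ActivityCosts,
    EnergeticParams,
    activity_costs,
    adult_dfi,
    cpue,
    dee,
    flight_unit_cost,
    point_budget,
    population_dfi,
    sensitivity_oat,
    time_budget,
)


class TestFlightUnitCost:
    def test_midpoint_of_power_bounds(self):
        specific, whole = flight_unit_cost(31.8, 39.5, 0.39)
        assert specific == pytest.approx(35.65)
        assert whole == pytest.approx(0.8342, abs=2e-4)  # kJ·min⁻¹ whole bird

    def test_equal_bounds_pass_through(self):
        specific, _ = flight_unit_cost(30.0, 30.0, 0.39)
        assert specific == 30.0

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            flight_unit_cost(40.0, 31.8, 0.39)


class TestActivityCosts:
    def test_colony_cost_twice_bmr(self):
        c = activity_costs(EnergeticParams())
        assert c.colony == pytest.approx(2 * 6.73 * 0.39 * 0.06, rel=1e-9)  # 0.31496
        assert c.flying == pytest.approx(0.8342, abs=2e-4)
        assert c.diving == c.flying

    def test_linear_in_body_mass(self):
        c1 = activity_costs(EnergeticParams(), mass=0.39)
        c2 = activity_costs(EnergeticParams(), mass=0.78)
        assert c2.colony == pytest.approx(2 * c1.colony)
        assert c2.flying == pytest.approx(2 * c1.flying)

    def test_zero_bmr_zero_colony_cost(self):
        c = activity_costs(EnergeticParams(bmr_w_per_kg=0.0))
        assert c.colony == 0.0

    def test_table_rounded_preset(self):
        c = activity_costs(EnergeticParams(rounded_unit_costs=True))
        assert c.colony == pytest.approx(0.8 * 0.39)
        assert c.flying == pytest.approx(2.0 * 0.39)

    def test_flying_below_colony_rejected(self):
        with pytest.raises(ValueError, match="flying"):
            ActivityCosts(colony=1.0, flying=0.5, diving=0.5)


class TestDee:
    def test_printed_incubation_means_within_five_percent(self):
        budget = time_budget(np.full(3, 4.73), np.full(3, 1.52), np.full(3, 1.0))
        d = dee(budget, activity_costs(EnergeticParams()))
        assert d[0] == pytest.approx(668.0, rel=0.05)

    def test_zero_durations_zero_expenditure(self):
        budget = time_budget(np.array([4.0]), np.array([0.0]), np.array([0.0]))
        d = dee(budget, ActivityCosts(colony=0.0, flying=0.834, diving=0.834))
        assert d[0] == 0.0

    def test_single_activity_direct_arithmetic(self):
        # 60 min flying at 2.0 kJ·kg⁻¹·min⁻¹ on a 0.39 kg bird = 46.8 kJ
        budget = time_budget(np.array([1.0]), np.array([1.0]), np.array([0.0]))
        d = dee(budget, ActivityCosts(colony=0.0, flying=2.0 * 0.39, diving=2.0 * 0.39))
        assert d[0] == pytest.approx(46.8)

    def test_misaligned_cost_draws_rejected(self):
        budget = time_budget(np.full(5, 4.0), np.full(5, 1.0), np.full(5, 1.0))
        with pytest.raises(ValueError, match="aligned"):
            dee(budget, ActivityCosts(colony=np.ones(3), flying=np.ones(3), diving=np.ones(3)))


class TestAdultDfi:
    def test_printed_point_values(self):
        out = adult_dfi(np.array([667.9]), np.array([6.22]), np.array([0.77]))
        assert out[0] == pytest.approx(139.45, abs=0.01)

    def test_unit_energy_density_identity(self):
        d = np.array([500.0, 700.0])
        assert np.allclose(adult_dfi(d, np.ones(2), np.ones(2)), d)

    def test_nonpositive_cp_or_ea_rejected(self):
        with pytest.raises(ValueError):
            adult_dfi(np.array([500.0]), np.array([0.0]), np.array([0.77]))
        with pytest.raises(ValueError):
            adult_dfi(np.array([500.0]), np.array([6.22]), np.array([-0.1]))

    @given(
        d=st.floats(100.0, 1500.0),
        cp=st.floats(3.0, 9.0),
        ea=st.floats(0.3, 1.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_identity_dfi_cp_ea_equals_dee(self, d, cp, ea):
        out = adult_dfi(np.array([d]), np.array([cp]), np.array([ea]))
        assert out[0] * cp * ea == pytest.approx(d, rel=1e-12)


class TestCpueAndPopulation:
    @pytest.mark.parametrize(
        "food,minutes,expected",
        [(140.9, 432.0, 0.3261), (160.1, 614.0, 0.2607), (0.0, 400.0, 0.0)],
    )
    def test_ratio(self, food, minutes, expected):
        assert cpue(np.array([food]), np.array([minutes]))[0] == pytest.approx(
            expected, abs=5e-4
        )

    def test_zero_minutes_rejected(self):
        with pytest.raises(ValueError):
            cpue(np.array([100.0]), np.array([0.0]))

    @pytest.mark.parametrize(
        "pairs,per_capita,expected",
        [(15_000, 187.5, 2812.5), (0, 187.5, 0.0), (300_000, 1250.0, 375_000.0)],
    )
    def test_population_scaling(self, pairs, per_capita, expected):
        assert population_dfi(pairs, per_capita) == pytest.approx(expected)


class TestSensitivity:
    def test_prey_energy_elasticity_exactly_minus_one(self):
        table = sensitivity_oat(EnergeticParams(), 0.1, target="adult_dfi_incubation")
        row = table.set_index("input")
        assert row.loc["prey_energy_kj_per_g", "elasticity"] == pytest.approx(-1.0, abs=1e-12)
        assert row.loc["assimilation_efficiency", "elasticity"] == pytest.approx(
            -1.0, abs=1e-12
        )

    def test_body_mass_elasticity_unity_for_mass_specific_costs(self):
        table = sensitivity_oat(EnergeticParams(), 0.1, target="dee_incubation")
        row = table.set_index("input")
        assert row.loc["body_mass_kg", "elasticity"] == pytest.approx(1.0, abs=1e-12)

    def test_ranked_by_magnitude(self):
        table = sensitivity_oat(EnergeticParams(), 0.1)
        mags = table["elasticity"].abs().to_numpy()
        assert np.all(np.diff(mags) <= 1e-12)

    def test_unknown_target_rejected(self):
        with pytest.raises(ValueError, match="unknown target"):
            sensitivity_oat(EnergeticParams(), 0.1, target="gross_margin")

    def test_invalid_perturbation_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_oat(EnergeticParams(), 1.5)

    def test_perturb_then_revert_leaves_output_unchanged(self):
        p = EnergeticParams()
        base = point_budget(p)
        roundtrip = point_budget(p.replace(body_mass_kg=0.5).replace(body_mass_kg=0.39))
        assert base == roundtrip


class TestPointBudget:
    def test_central_values_reproduce_study_outputs(self):
        out = point_budget(EnergeticParams())
        assert out["dee_incubation"] == pytest.approx(668.0, rel=0.05)
        assert out["adult_dfi_incubation"] == pytest.approx(140.9, rel=0.05)
        assert out["chick_mei"] == pytest.approx(358.5125, rel=1e-6)
        assert out["chick_dfi"] == pytest.approx(74.85, abs=0.1)
        assert out["population_dfi"] == pytest.approx(2813, rel=0.05)

    def test_yaml_round_trip(self, tmp_path):
        p = EnergeticParams(breeding_pairs=20_000)
        path = tmp_path / "params.yaml"
        p.to_yaml(path)
        assert EnergeticParams.from_yaml(path) == p
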