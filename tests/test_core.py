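"""ODE engine: absorption, mass balance, reductions and kinetic properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbtk import (
    ExposureScenario,
    MetabolicPathway,
    SolverOptions,
    absorption_rate_constant,
    chemicals,
    ivive_vmax,
    mass_balance_report,
    metrics,
    run_to_steady_state,
    simulate,
)
from pbtk.core import SteadyStateError

from conftest import bateman


class TestAbsorptionRateConstant:
    @pytest.mark.parametrize(
        "half_life,expected",
        [(8.0, 0.0866433), (0.25, 2.7725887), (1e9, 6.93e-10)],
    )
    def test_values(self, half_life, expected):
        assert absorption_rate_constant(half_life) == pytest.approx(expected, rel=1e-3)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_half_life(self, bad):
        with pytest.raises(ValueError):
            absorption_rate_constant(bad)


class TestIviveVmax:
    def test_linear_in_rate_and_mass(self):
        base = ivive_vmax(0.5, 1820.0, basis="per_million_cells")
        assert ivive_vmax(1.0, 1820.0, basis="per_million_cells") == pytest.approx(2 * base)
        assert ivive_vmax(0.5, 910.0, basis="per_million_cells") == pytest.approx(base / 2)

    def test_hand_computed_product(self):
        # 0.5 µg/h per 10^6 cells x 99e6 cells/g x 1820 g liver
        assert ivive_vmax(0.5, 1820.0, basis="per_million_cells") == pytest.approx(
            0.5 * 99.0 * 1820.0
        )
        assert ivive_vmax(2.0, 1000.0, basis="per_mg_protein") == pytest.approx(
            2.0 * 32.0 * 1000.0
        )

    def test_undeclared_basis_is_an_error(self):
        with pytest.raises(ValueError, match="basis"):
            ivive_vmax(0.5, 1820.0, basis="per_flask")


class TestSimulate:
    def test_zero_dose_is_identically_zero(self, bpa_model):
        scenario = chemicals.oral_portions_scenario(0.0, 0.9, 0.25)
        res = simulate(**bpa_model, scenario=scenario)
        for name, series in res.concentrations.items():
            assert np.all(series == 0.0), name
        for name, series in res.ledgers.items():
            assert np.all(series == 0.0), name

    @pytest.mark.parametrize(
        "scenario_builder",
        [
            lambda: chemicals.oral_portions_scenario(50.0, 0.9, 0.25),
            lambda: chemicals.dermal_single_scenario(0.97, 0.6, 8.0),
            lambda: chemicals.dietary_scenario(20.0, 0.9, 0.25, duration_h=12.0),
            lambda: ExposureScenario(
                events=(
                    *chemicals.oral_portions_scenario(4.2, 0.9, 0.25).events,
                    *chemicals.dermal_single_scenario(0.97, 0.6, 8.0).events,
                ),
                n_days=2,
            ),
        ],
        ids=["oral-portions", "dermal-single", "dietary", "mixed-routes"],
    )
    def test_mass_balance_below_1e6(self, bpa_model, scenario_builder):
        res = simulate(**bpa_model, scenario=scenario_builder())
        assert mass_balance_report(res) < 1e-6

    def test_ledgers_non_decreasing_and_concentrations_non_negative(self, bpa_model):
        res = simulate(
            **bpa_model, scenario=chemicals.oral_portions_scenario(50.0, 0.9, 0.25)
        )
        for key in ("absorbed", "metabolized_glucuronide", "excreted_sulfate"):
            assert np.all(np.diff(res.ledgers[key]) >= -1e-9), key
        for name, series in res.concentrations.items():
            assert series.min() >= 0.0, name

    def test_tampered_ledger_is_detected(self, bpa_model):
        res = simulate(
            **bpa_model, scenario=chemicals.oral_portions_scenario(50.0, 0.9, 0.25)
        )
        total_in = res.ledgers["input_total"][-1]
        assert mass_balance_report(res) < 1e-6
        res.ledgers["metabolized_glucuronide"][-1] += 1.0
        assert mass_balance_report(res) == pytest.approx(1.0 / total_in, rel=0.01)

    def test_one_compartment_limit_matches_bateman(self, one_compartment):
        oc = one_compartment
        scenario = chemicals.single_dose_scenario(100.0, "oral", 1.0, 1.0, n_days=2)
        res = simulate(oc["profile"], oc["partitions"], oc["pathways"], scenario)
        ka = math.log(2.0) / 1.0
        ke = oc["clearance"] / oc["v_total"]
        expected = bateman(res.time, 100.0 * 70.0, oc["v_total"], ka, ke)
        mask = res.time > 0.05  # skip the initial transient of the lumped circuit
        err = np.abs(res.concentration("blood")[mask] - expected[mask])
        assert err.max() / expected.max() < 0.01

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(
        dose=st.floats(0.1, 100.0),
        half_life=st.floats(0.05, 6.0),
        extent=st.floats(0.05, 1.0),
        dermal=st.booleans(),
    )
    def test_mass_balance_property(self, bpa_model, dose, half_life, extent, dermal):
        """Conservation holds across randomly drawn dose events."""
        if dermal:
            scenario = chemicals.dermal_single_scenario(dose, extent, half_life)
        else:
            scenario = chemicals.oral_portions_scenario(dose, extent, half_life)
        res = simulate(**bpa_model, scenario=scenario)
        assert mass_balance_report(res) < 1e-6


class TestSteadyState:
    def test_constant_infusion_matches_dose_rate_over_clearance(self, bpa_model):
        clearance = sum(p.intrinsic_clearance for p in bpa_model["pathways"])
        scenario = chemicals.dietary_scenario(50.0, 0.9, 0.25, duration_h=24.0)
        res = run_to_steady_state(**bpa_model, daily_scenario=scenario)
        bw = bpa_model["profile"].body_weight_kg
        expected = 0.9 * 50.0 * bw / 24.0 / clearance
        assert metrics.steady_state_concentration(res) == pytest.approx(expected, rel=0.01)

    def test_daily_auc_doubles_with_dose_in_linear_regime(self, bpa_model):
        auc = {}
        for dose in (10.0, 20.0):
            res = run_to_steady_state(
                **bpa_model,
                daily_scenario=chemicals.oral_portions_scenario(dose, 0.9, 0.25),
            )
            auc[dose] = metrics.auc(res, "blood")
        assert auc[20.0] / auc[10.0] == pytest.approx(2.0, rel=0.01)

    def test_zero_dose_converges_on_day_one(self, bpa_model):
        res = run_to_steady_state(
            **bpa_model, daily_scenario=chemicals.oral_portions_scenario(0.0, 0.9, 0.25)
        )
        assert res.n_days_used == 1
        assert np.all(res.concentration("blood") == 0.0)

    def test_nonconvergence_raises(self, bpa_model):
        scenario = chemicals.oral_portions_scenario(50.0, 0.9, 0.25)
        with pytest.raises(SteadyStateError):
            run_to_steady_state(
                **bpa_model, daily_scenario=scenario, convergence_tol=1e-12, max_days=2
            )


@pytest.fixture(scope="module")
def coumarin_human(adult_profile):
    cfg = chemicals.load_chemical("coumarin_human")
    return {
        "profile": adult_profile,
        "partitions": chemicals.partitions_from_config(cfg),
        "pathways": chemicals.pathways_from_config(cfg),
    }


class TestKineticProperties:
    """Saturation and route/rate structure of the ODE core."""

    def test_route_invariant_liver_auc_at_equal_absorbed_dose(self, coumarin_human):
        aucs = []
        for route, hl in [("oral", 1.0 / 3.0), ("dermal", 0.5)]:
            res = simulate(
                **coumarin_human,
                scenario=chemicals.single_dose_scenario(100.0, route, 1.0, hl, n_days=4),
            )
            aucs.append(metrics.auc_to_infinity(res, "liver"))
        assert aucs[0] == pytest.approx(aucs[1], rel=0.01)

    def test_first_pass_lowers_oral_blood_auc(self, coumarin_human):
        res_oral = simulate(
            **coumarin_human,
            scenario=chemicals.single_dose_scenario(100.0, "oral", 1.0, 1 / 3, n_days=4),
        )
        res_dermal = simulate(
            **coumarin_human,
            scenario=chemicals.single_dose_scenario(100.0, "dermal", 1.0, 0.5, n_days=4),
        )
        assert metrics.auc_to_infinity(res_oral, "blood") < metrics.auc_to_infinity(
            res_dermal, "blood"
        )

    def test_slower_dermal_absorption_lowers_liver_cmax_not_auc(self, coumarin_human):
        fast = simulate(
            **coumarin_human,
            scenario=chemicals.single_dose_scenario(100.0, "dermal", 1.0, 0.5, n_days=4),
        )
        slow = simulate(
            **coumarin_human,
            scenario=chemicals.single_dose_scenario(100.0, "dermal", 1.0, 16.0, n_days=12),
        )
        assert metrics.cmax(slow, "liver") < metrics.cmax(fast, "liver")
        assert metrics.auc_to_infinity(slow, "liver") == pytest.approx(
            metrics.auc_to_infinity(fast, "liver"), rel=0.01
        )

    def test_saturation_increases_dose_normalised_auc(self, adult_profile):
        cfg = chemicals.load_chemical("coumarin_human")
        partitions = chemicals.partitions_from_config(cfg)
        pathway = MetabolicPathway("sat", vmax=50000.0, km=500.0, conjugate="conj")
        per_dose = []
        for dose in (10.0, 1000.0):
            res = simulate(
                adult_profile,
                partitions,
                [pathway],
                chemicals.single_dose_scenario(dose, "oral", 1.0, 0.5, n_days=6),
            )
            per_dose.append(metrics.auc_to_infinity(res, "blood") / dose)
        assert per_dose[1] > per_dose[0]
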