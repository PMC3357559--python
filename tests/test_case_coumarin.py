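"""Coumarin route comparison, rat batch simulation and metric identification."""

import numpy as np
import pandas as pd
import pytest

from pbtk import SolverOptions, chemicals, metrics, simulate
from pbtk.cases import coumarin
from pbtk.physiology import get_profile


@pytest.fixture(scope="module")
def human_table():
    return coumarin.run_human_comparison()


class TestHumanComparison:
    def test_liver_auc_is_route_invariant(self, human_table):
        aucs = human_table["auc_liver_ug_per_kg_h"]
        assert aucs.max() / aucs.min() == pytest.approx(1.0, rel=0.01)

    def test_liver_cmax_ordering(self, human_table):
        t = human_table.set_index("absorption_half_life_min")
        assert (
            t.at[20.0, "cmax_liver_ug_per_kg"]
            > t.at[30.0, "cmax_liver_ug_per_kg"]
            > t.at[960.0, "cmax_liver_ug_per_kg"]
        )

    def test_blood_auc_first_pass_asymmetry(self, human_table):
        dermal = human_table[human_table.route == "dermal"]["auc_blood_ug_per_kg_h"]
        oral = float(
            human_table[human_table.route == "oral"]["auc_blood_ug_per_kg_h"].iloc[0]
        )
        assert dermal.iloc[0] == pytest.approx(dermal.iloc[1], rel=0.01)
        assert (dermal > oral).all()

    def test_blood_cmax_depends_on_absorption_rate(self, human_table):
        t = human_table.set_index("absorption_half_life_min")
        assert t.at[30.0, "cmax_blood_ug_per_kg"] > t.at[20.0, "cmax_blood_ug_per_kg"]
        assert t.at[960.0, "cmax_blood_ug_per_kg"] < t.at[20.0, "cmax_blood_ug_per_kg"]

    def test_structure_holds_across_random_linear_fixtures(self, adult_profile):
        """Liver-AUC invariance and first-pass asymmetry are structural: they
        hold for any positive linear-regime Vmax/Km draw, not just defaults."""
        cfg = chemicals.load_chemical("coumarin_human")
        partitions = chemicals.partitions_from_config(cfg)
        rng = np.random.default_rng(7)
        opts = SolverOptions(rtol=1e-7, atol=1e-9, grid_step_h=0.02)
        for _ in range(5):
            cl = rng.uniform(30.0, 400.0)  # L/h
            km = rng.uniform(5e3, 5e4)  # µg/L, far above simulated levels
            pathway = chemicals.MetabolicPathway("p", vmax=cl * km, km=km, conjugate="c")
            res = {}
            for route, hl, days in [("oral", 1 / 3, 4), ("dermal", 0.5, 4)]:
                res[route] = simulate(
                    adult_profile,
                    partitions,
                    [pathway],
                    chemicals.single_dose_scenario(100.0, route, 1.0, hl, n_days=days),
                    opts,
                )
            auc_liver = {r: metrics.auc_to_infinity(res[r], "liver") for r in res}
            assert auc_liver["oral"] == pytest.approx(auc_liver["dermal"], rel=0.01)
            assert metrics.auc_to_infinity(res["oral"], "blood") < metrics.auc_to_infinity(
                res["dermal"], "blood"
            )


class TestRatBatch:
    def test_doubling_duration_doubles_auc_only(self, rat_model):
        studies = pd.DataFrame(
            {
                "study_id": ["a", "b"],
                "dose_mg_per_kg_day": [50.0, 50.0],
                "duration_weeks": [13.0, 26.0],
                "administration": ["gavage", "gavage"],
                "grade": [1, 1],
            }
        )
        out = coumarin.rat_batch(studies, rat_model).set_index("study_id")
        assert out.at["b", "auc_hep_ug_per_g_h"] / out.at[
            "a", "auc_hep_ug_per_g_h"
        ] == pytest.approx(2.0, rel=0.01)
        assert out.at["b", "cmax_hep_ug_per_g"] == pytest.approx(
            out.at["a", "cmax_hep_ug_per_g"], rel=0.01
        )

    def test_gavage_peaks_higher_than_dietary_at_equal_linear_dose(self, rat_model):
        gavage = rat_model.daily_metrics(0.5, "gavage")
        dietary = rat_model.daily_metrics(0.5, "dietary")
        assert gavage[0] > dietary[0]
        assert gavage[1] == pytest.approx(dietary[1], rel=0.02)

    def test_whole_study_accumulation_matches_brute_force(self, rat_model):
        """Daily-AUC x duration equals one long 28-day simulation."""
        profile = get_profile("rat", "adult")
        cfg = chemicals.load_chemical("coumarin_rat")
        scenario = chemicals.oral_portions_scenario(
            50.0 * 1000.0, 1.0, 1.0 / 3.0, times=(0.0,), n_days=28
        )
        res = simulate(
            profile,
            chemicals.partitions_from_config(cfg),
            chemicals.pathways_from_config(cfg),
            scenario,
            SolverOptions(rtol=1e-7, atol=1e-9, grid_step_h=0.02),
        )
        brute = metrics.auc(res, "liver") / 1000.0  # µg/g x h over 28 days
        daily = rat_model.daily_metrics(50.0, "gavage")[1]
        assert brute == pytest.approx(daily * 28.0, rel=0.01)

    def test_invalid_records_are_listed(self, rat_model):
        bad = pd.DataFrame(
            {
                "study_id": ["x", "y"],
                "dose_mg_per_kg_day": [0.0, 10.0],
                "duration_weeks": [4.0, 4.0],
                "administration": ["gavage", "injection"],
                "grade": [1, 9],
            }
        )
        with pytest.raises(coumarin.StudyValidationError) as err:
            coumarin.rat_batch(bad, rat_model)
        message = str(err.value)
        assert "row 0" in message and "row 1" in message


class TestAssociation:
    def test_perfectly_monotone_metric_gets_tau_one(self):
        values = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        grades = np.array([0, 1, 2, 3, 4])
        result = coumarin.grade_metric_association({"cmax_hep": values}, grades)
        assert result.correlations["cmax_hep"] == pytest.approx(1.0)
        assert result.violations["cmax_hep"] == 0

    def test_permutation_null_stays_below_half(self, rat_model):
        """With grades shuffled against metrics, |tau| rarely reaches 0.5."""
        rng = np.random.default_rng(11)
        values = np.exp(rng.uniform(np.log(0.6), np.log(200.0), size=31))
        grades = np.clip(np.round(rng.uniform(0, 4, size=31)).astype(int), 0, 4)
        taus = []
        for _ in range(1000):
            shuffled = rng.permutation(values)
            res = coumarin.grade_metric_association({"m": shuffled}, grades)
            taus.append(res.correlations["m"])
        assert np.mean(np.abs(taus) < 0.5) > 0.99

    def test_degenerate_grades_are_an_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            coumarin.grade_metric_association(
                {"m": [1.0, 2.0, 3.0, 4.0, 5.0]}, [2, 2, 2, 2, 2]
            )

    def test_too_few_records_is_an_error(self):
        with pytest.raises(ValueError, match="at least 5"):
            coumarin.grade_metric_association({"m": [1.0, 2.0]}, [0, 1])

    @pytest.mark.parametrize(
        "mechanism,expected",
        [("cmax_driven", "cmax_hep"), ("auc_driven", "auc_hep")],
    )
    def test_recovers_generating_mechanism(self, rat_model, mechanism, expected):
        from pbtk.synthetic import gen_tox_study_set

        study_set = gen_tox_study_set(mechanism, seed=5, rat_model=rat_model)
        batch = coumarin.rat_batch(study_set.records, rat_model)
        result = coumarin.grade_metric_association(
            {
                "cmax_hep": batch["cmax_hep_ug_per_g"],
                "auc_hep": batch["auc_hep_ug_per_g_h"],
            },
            batch["grade"].to_numpy(),
        )
        assert result.selected_metric == expected


class TestFullCase:
    def test_packaged_fixture_selects_cmax_and_clears_dermal_use(self, rat_model):
        report = coumarin.run_case(rat_model=rat_model)
        assert report.association.selected_metric == "cmax_hep"
        assert report.conclusion == "no concern"
        t = report.table3.set_index("absorption_half_life_min")
        assert t.at[30.0, "cmax_liver_ug_per_kg"] < t.at[20.0, "cmax_liver_ug_per_kg"]

    def test_auc_driven_set_suppresses_cmax_conclusion(self, rat_model):
        from pbtk.synthetic import gen_tox_study_set

        study_set = gen_tox_study_set("auc_driven", seed=5, rat_model=rat_model)
        report = coumarin.run_case(studies=study_set.records, rat_model=rat_model)
        assert report.association.selected_metric == "auc_hep"
        assert report.conclusion == "inconclusive"

    def test_empty_study_table_skips_association_with_warning(self):
        empty = pd.DataFrame(
            columns=[
                "study_id", "dose_mg_per_kg_day", "duration_weeks",
                "administration", "grade",
            ]
        )
        with pytest.warns(UserWarning, match="association stage skipped"):
            report = coumarin.run_case(studies=empty)
        assert report.association is None
        assert report.rat_metrics is None
        assert len(report.table3) == 3

    @pytest.mark.parametrize("scale", [0.5, 1.5])
    def test_selection_robust_to_rat_vmax_perturbation(self, scale):
        """Rank ordering, not absolute scale, drives the identification."""
        model = coumarin.RatModel(vmax_scale=scale)
        batch = coumarin.rat_batch(coumarin.load_packaged_studies(), model)
        result = coumarin.grade_metric_association(
            {
                "cmax_hep": batch["cmax_hep_ug_per_g"],
                "auc_hep": batch["auc_hep_ug_per_g_h"],
            },
            batch["grade"].to_numpy(),
        )
        assert result.selected_metric == "cmax_hep"
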