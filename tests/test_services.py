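"""Service/HR scale-up arithmetic and the 15-year resource plan."""

import numpy as np
import pytest

import mhplan
from mhplan import (
    CarePackage,
    CoverageTrajectory,
    PopulationTable,
    beds_required,
    bed_days_required,
    coverage_at,
    eligible_perinatal,
    eligible_population,
    fte_inpatient,
    fte_outpatient,
    run_scaleup,
    visits_required,
)
from mhplan.services import ConfigError, Provider, ServiceModel, StaffingParameters, Treatment
from conftest import spike_cases


class TestCoverage:
    def test_boundaries_agree_across_modes(self):
        for mode in ("linear", "exponential"):
            traj = CoverageTrajectory(0.01, 0.30, mode=mode)
            assert coverage_at(traj, 0) == pytest.approx(0.01)
            assert coverage_at(traj, 14) == pytest.approx(0.30)

    def test_exponential_midpoint_is_geometric_mean(self):
        traj = CoverageTrajectory(0.01, 0.30, mode="exponential")
        assert coverage_at(traj, 7) == pytest.approx(np.sqrt(0.01 * 0.30))

    def test_linear_dominates_exponential_midhorizon(self):
        lin = CoverageTrajectory(0.01, 0.30, mode="linear").series()
        exp = CoverageTrajectory(0.01, 0.30, mode="exponential").series()
        assert np.all(lin[1:-1] >= exp[1:-1])
        assert np.all(np.diff(lin) >= 0) and np.all(np.diff(exp) >= 0)

    def test_zero_baseline_exponential_rejected(self):
        with pytest.raises(ValueError):
            CoverageTrajectory(0.0, 0.3, mode="exponential")


class TestEligibility:
    def test_moderate_severe_share_arithmetic(self, cfg):
        parts = {"depression_only": spike_cases("depression_only", 1000.0, age=30)}
        out = eligible_population(parts, cfg.severity)
        assert out["depression_only"] == pytest.approx(280)

    def test_children_not_eligible(self, cfg):
        parts = {"ptsd_only": spike_cases("ptsd_only", 500.0, age=10)}
        assert eligible_population(parts, cfg.severity)["ptsd_only"] == 0.0

    def test_perinatal_product_of_proportions(self):
        counts = np.zeros(101)
        counts[20] = 200_000  # 100,000 women at female share 0.5
        pop = PopulationTable(counts, female_share=0.5)
        assert eligible_perinatal(pop) == pytest.approx(100_000 * 0.11 * 0.15 * 0.28)

    def test_perinatal_linear_in_fertility(self, fx):
        a = eligible_perinatal(fx.population, fertility_rate=0.11)
        b = eligible_perinatal(fx.population, fertility_rate=0.22)
        assert b == pytest.approx(2 * a)


def outpatient_pkg(visits_pp=4.0, prop=1.0):
    return CarePackage(
        "pkg", ("comorbid",), 0.3,
        {"outpatient": Treatment(prop, visits_per_person=visits_pp)},
    )


class TestResourceArithmetic:
    def test_zero_coverage_zero_visits(self):
        assert visits_required(1000, 0.0, outpatient_pkg()) == {"outpatient": 0.0}

    def test_visit_product(self):
        v = visits_required(1000, 0.5, outpatient_pkg(visits_pp=4.0))
        assert v["outpatient"] == pytest.approx(2000)

    def test_bed_days_product(self):
        pkg = CarePackage(
            "inp", ("comorbid",), 0.3,
            {"inpatient": Treatment(0.05, bed_days_per_person=14.0)},
        )
        assert bed_days_required(1000, 0.01, pkg) == pytest.approx(7.0)

    def test_ptsd_only_inpatient_rejected(self):
        pkg = CarePackage(
            "inp", ("ptsd_only",), 0.3,
            {"inpatient": Treatment(0.05, bed_days_per_person=14.0)},
        )
        with pytest.raises(ConfigError):
            bed_days_required(1000, 0.01, pkg, group="ptsd_only")

    def test_beds_formula(self):
        assert beds_required(365.0) == pytest.approx(1.15)
        assert beds_required(0.0) == 0.0
        assert round(beds_required(44_000)) in (139, 140)

    def test_fte_outpatient_arithmetic(self):
        staffing = StaffingParameters(
            providers={"nurse": Provider(240, {"outpatient": 10.0})},
            shares={"outpatient": {"nurse": 1.0}},
        )
        fte = fte_outpatient({"outpatient": 2400.0}, staffing)
        assert fte["nurse"] == pytest.approx(1.0)

    def test_fte_outpatient_zero_consult_rate_rejected(self):
        staffing = StaffingParameters(
            providers={"nurse": Provider(240, {})},
            shares={"outpatient": {"nurse": 1.0}},
        )
        with pytest.raises(ConfigError):
            fte_outpatient({"outpatient": 100.0}, staffing)

    def test_fte_inpatient_ward_staffing(self):
        staffing = StaffingParameters(
            providers={"nurse": Provider(230, {"outpatient": 10.0}, staff_per_ward=4.0)},
            shares={"outpatient": {"nurse": 1.0}},
        )
        assert fte_inpatient(25.0, staffing)["nurse"] == pytest.approx(4.0)
        assert fte_inpatient(0.0, staffing)["nurse"] == 0.0


@pytest.fixture(scope="module")
def service_model(cfg, fx):
    return mhplan.build_service_model(cfg, fx)


class TestScaleupPlan:
    def test_resources_nondecreasing(self, service_model):
        for mode in ("linear", "exponential"):
            plan = run_scaleup(service_model, mode=mode)
            for col in ("primary_care_visits", "ancillary_visits", "outpatient_visits",
                        "inpatient_days", "beds", "fte_total"):
                assert np.all(np.diff(plan[col]) >= -1e-9), (mode, col)

    def test_modes_agree_at_endpoints_only(self, service_model):
        lin = run_scaleup(service_model, "linear")
        exp = run_scaleup(service_model, "exponential")
        for col in ("primary_care_visits", "fte_total"):
            assert lin[col].iloc[0] == pytest.approx(exp[col].iloc[0])
            assert lin[col].iloc[-1] == pytest.approx(exp[col].iloc[-1])
            assert np.all(lin[col].iloc[1:-1].values >= exp[col].iloc[1:-1].values)

    def test_fte_additivity(self, service_model, cfg):
        plan = run_scaleup(service_model)
        parts = sum(plan[f"fte_{p}"] for p in cfg.staffing.providers)
        np.testing.assert_allclose(parts, plan["fte_total"], rtol=1e-12)

    def test_zero_coverage_all_zero(self, service_model, cfg, fx):
        from dataclasses import replace

        zero_pkgs = tuple(
            replace(p, coverage_target=0.0) for p in service_model.packages
        )
        model = replace(service_model, packages=zero_pkgs, baseline_coverage=0.0)
        plan = run_scaleup(model)
        assert plan["fte_total"].abs().max() == 0.0
        assert plan["inpatient_days"].abs().max() == 0.0

    def test_ptsd_only_generates_no_inpatient_demand(self, service_model):
        from dataclasses import replace

        model = replace(
            service_model,
            eligible_2015={"ptsd_only": service_model.eligible_2015["ptsd_only"]},
        )
        plan = run_scaleup(model)
        assert plan["inpatient_days"].abs().max() == 0.0

    def test_baseline_service_contacts_match_published(self, service_model):
        plan = run_scaleup(service_model)
        base = plan.iloc[0]
        assert base["primary_care_visits"] == pytest.approx(37_000, rel=0.10)
        assert base["ancillary_visits"] == pytest.approx(78_000, rel=0.10)
        assert base["outpatient_visits"] == pytest.approx(6_000, rel=0.10)
        assert base["inpatient_days"] == pytest.approx(1_000, rel=0.10)
        assert round(base["beds"]) == 3

    def test_final_year_service_contacts_match_published(self, service_model):
        plan = run_scaleup(service_model)
        final = plan.iloc[-1]
        assert final["primary_care_visits"] == pytest.approx(2e6, rel=0.15)
        assert final["ancillary_visits"] == pytest.approx(2e6, rel=0.15)
        assert final["outpatient_visits"] == pytest.approx(3e5, rel=0.15)
        assert final["inpatient_days"] == pytest.approx(44_000, rel=0.15)
        assert final["beds"] == pytest.approx(140, rel=0.15)

    def test_final_year_provider_mix_matches_published(self, service_model):
        # ~1600 workers: 570 nurses, 210 physicians, 90 psychiatrists,
        # 100 psychologists, 620 other non-specialists
        final = run_scaleup(service_model).iloc[-1]
        assert final["fte_total"] == pytest.approx(1600, rel=0.10)
        assert final["fte_nurse"] == pytest.approx(570, rel=0.15)
        assert final["fte_other_physician"] == pytest.approx(210, rel=0.15)
        assert final["fte_psychiatrist"] == pytest.approx(90, rel=0.15)
        assert final["fte_psychologist"] == pytest.approx(100, rel=0.15)
        other = final["fte_other_psychosocial"] + final["fte_other_provider"]
        assert other == pytest.approx(620, rel=0.15)

    def test_incomplete_configuration_rejected(self, cfg):
        with pytest.raises(ConfigError):
            ServiceModel(
                packages=(), staffing=cfg.staffing, eligible_2015={},
                population_2015=1e6,
            )
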