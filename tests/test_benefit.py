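"""Markov scenario engine: effectiveness, cohorts, averted burden, discounting."""

import copy

import numpy as np
import pytest

import mhplan
from mhplan import (
    CohortSpec,
    EffectSpec,
    HazardSet,
    InterventionPackage,
    RateSchedule,
    apply_effectiveness,
    averted_burden,
    combined_effectiveness,
    discount,
    run_cohort,
    run_scenario,
)

const = lambda v: RateSchedule(np.full(101, float(v)))


def toy_hazards(i=0.02, r=0.3, f=0.0, m=0.01):
    return HazardSet(const(i), const(r), const(f), const(m))


class TestCombinedEffectiveness:
    def test_single_package(self):
        pkgs = [InterventionPackage("a", efficacy=0.5)]
        assert combined_effectiveness(pkgs, 1.0) == pytest.approx(0.5)

    def test_two_packages_complement_product(self):
        pkgs = [InterventionPackage("a", 0.5), InterventionPackage("b", 0.5)]
        assert combined_effectiveness(pkgs, 1.0) == pytest.approx(0.75)

    def test_zero_efficacy_zero_effect(self):
        pkgs = [InterventionPackage("a", 0.0), InterventionPackage("b", 0.0)]
        assert combined_effectiveness(pkgs, 1.0) == 0.0

    def test_coverage_share_scales_effective_fraction(self):
        pkgs = [InterventionPackage("a", 0.5, coverage_share=0.5)]
        assert combined_effectiveness(pkgs, 0.5) == pytest.approx(0.125)


class TestApplyEffectiveness:
    def test_zero_effectiveness_is_identity(self):
        hz, dw = apply_effectiveness(toy_hazards(), 0.3, 0.0, EffectSpec(0.5, 0.5))
        assert dw == 0.3
        np.testing.assert_array_equal(hz.remission.values, toy_hazards().remission.values)

    def test_full_dw_reduction_boundary(self):
        _, dw = apply_effectiveness(toy_hazards(), 0.3, 1.0, EffectSpec(0.0, 1.0))
        assert dw == pytest.approx(0.0)

    def test_remission_uplift_arithmetic(self):
        hz, _ = apply_effectiveness(toy_hazards(r=1.40), 0.3, 0.4, EffectSpec(0.5, 0.0))
        assert hz.remission.values[0] == pytest.approx(1.68)


class TestRunCohort:
    def test_disease_free_cohort_accrues_nothing(self, benefit_setup):
        _, streams = benefit_setup
        stream = streams[0]
        from dataclasses import replace

        stream0 = replace(stream, hazards=replace(stream.hazards, incidence=const(0)))
        cohort = CohortSpec("15-29", 22.0, 1000.0, 0.0)
        _, ylds = run_cohort(cohort, stream0, np.zeros(15))
        assert np.all(ylds == 0)

    def test_identical_coverage_identical_tables(self, benefit_setup):
        _, streams = benefit_setup
        cohort = CohortSpec("30-44", 37.0, 1e5, 0.08)
        cov = np.full(15, 0.2)
        c1, y1 = run_cohort(cohort, streams[1], cov)
        c2, y2 = run_cohort(cohort, streams[1], cov.copy())
        np.testing.assert_array_equal(y1, y2)
        np.testing.assert_array_equal(c1, c2)

    def test_cohort_mass_conserved(self, benefit_setup):
        # alive + dead stays at the initial size throughout (closed cohort)
        _, streams = benefit_setup
        stream = streams[1]
        cohort = CohortSpec("45-59", 52.0, 5e4, 0.1)
        from mhplan.illness_death import StateVector, step_year
        from mhplan.benefit import combined_effectiveness as ce, apply_effectiveness as ae

        state = StateVector(cohort.size * 0.9, cohort.size * 0.1)
        cov = mhplan.CoverageTrajectory(0.01, 0.30).series()
        for t in range(15):
            eff = ce(stream.packages, cov[t])
            hz, _ = ae(stream.hazards, stream.dw, eff, stream.effects)
            state = step_year(state, *hz.at(cohort.mid_age + t))
            assert state.total == pytest.approx(cohort.size, rel=1e-10)

    def test_oldest_cohort_truncates_with_warning(self, benefit_setup):
        _, streams = benefit_setup
        cohort = CohortSpec("90+", 90.0, 1e4, 0.05)
        with pytest.warns(UserWarning):
            run_cohort(cohort, streams[0], np.zeros(15))


class TestScenarios:
    def test_partial_null_averts_nothing_vs_itself(self, scenario_results):
        null = scenario_results[("partial_null", "linear")]
        out = averted_burden(null, null)
        assert out["dalys_averted"] == 0.0
        assert out["percent_averted"] == 0.0

    def test_current_coverage_averts_small_positive(self, scenario_results):
        out = averted_burden(
            scenario_results[("current", "linear")],
            scenario_results[("partial_null", "linear")],
        )
        assert 0 < out["percent_averted"] < 5

    def test_averted_monotone_in_target_coverage(self, scenario_results):
        null = scenario_results[("partial_null", "linear")]
        pct = [
            averted_burden(scenario_results[(s, "linear")], null)["percent_averted"]
            for s in ("current", "target30", "target100")
        ]
        assert pct[0] < pct[1] < pct[2]

    def test_linear_scaleup_dominates_exponential(self, scenario_results):
        null = scenario_results[("partial_null", "linear")]
        for s in ("target30", "target100"):
            lin = averted_burden(scenario_results[(s, "linear")], null)["percent_averted"]
            exp = averted_burden(scenario_results[(s, "exponential")], null)["percent_averted"]
            assert lin >= exp

    def test_averted_monotone_in_efficacy(self, cfg, fx, benefit_setup):
        cohorts, streams = benefit_setup
        null = run_scenario(cohorts, streams, "partial_null")
        base = averted_burden(
            run_scenario(cohorts, streams, "target30"), null
        )["percent_averted"]
        weak_cfg = copy.deepcopy(cfg.benefit)
        for s in weak_cfg["streams"].values():
            s["effects"]["delta_dw"] *= 0.5
            s["effects"]["delta_remission"] *= 0.5
        cohorts_w, streams_w = mhplan.build_streams(fx, cfg.severity, weak_cfg)
        null_w = run_scenario(cohorts_w, streams_w, "partial_null")
        weak = averted_burden(
            run_scenario(cohorts_w, streams_w, "target30"), null_w
        )["percent_averted"]
        assert weak < base

    def test_deterministic_pure_function(self, benefit_setup):
        cohorts, streams = benefit_setup
        a = run_scenario(cohorts, streams, "target30")
        b = run_scenario(cohorts, streams, "target30")
        assert a.total == b.total

    def test_zero_efficacy_averts_exactly_zero(self, cfg, fx):
        b = copy.deepcopy(cfg.benefit)
        for s in b["streams"].values():
            for p in s["packages"]:
                p["efficacy"] = 0.0
        cohorts, streams = mhplan.build_streams(fx, cfg.severity, b)
        null = run_scenario(cohorts, streams, "partial_null")
        full = run_scenario(cohorts, streams, "target100")
        assert averted_burden(full, null)["dalys_averted"] == pytest.approx(0.0, abs=1e-6)


class TestDiscounting:
    def test_zero_rate_plain_sum(self):
        assert discount(np.ones(15), 0.0) == 15.0

    def test_annuity_closed_form(self):
        # sum of 1.03^-t for t = 0..14
        assert discount(np.ones(15), 0.03) == pytest.approx(12.296, abs=5e-4)

    def test_discounted_never_exceeds_undiscounted(self):
        series = np.linspace(0, 10, 15)
        assert discount(series, 0.03) <= series.sum()

    def test_discounting_shifts_percent_averted_modestly(self, cfg, fx):
        res = mhplan.run_benefit_scenarios(cfg, fx, scenarios=("partial_null", "target30"),
                                           modes=("linear",))
        resd = mhplan.run_benefit_scenarios(cfg, fx, scenarios=("partial_null", "target30"),
                                            modes=("linear",), discount_rate=0.03)
        delta = abs(
            res["scenarios"]["target30_linear"]["percent_averted"]
            - resd["scenarios"]["target30_linear"]["percent_averted"]
        )
        assert delta <= 5.0
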