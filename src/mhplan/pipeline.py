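"""Pipeline orchestration: synth → prevalence → burden → services → benefit.

Each stage reads its inputs either from the in-memory bundle produced by an
earlier stage in the same run or from the CSV/JSON files a previous run left
in the output directory, so single stages can be re-run against cached
inputs.  Every run writes a manifest (config hash, seed, package version,
stages executed) alongside its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import benefit as hb
from .burden import compute_ylds, propagate_uncertainty, yld_rate
from .config import RunConfig, load_config
from .fixture import SyriaFixture, build_streams, syria_fixture
from .services import (
    ServiceModel,
    eligible_perinatal,
    eligible_population,
    run_scaleup,
)
from .tables import read_age_table, write_age_table, PopulationTable, RateSchedule, CaseCounts
from .synthetic import PrevalenceCurve

log = logging.getLogger(__name__)

STAGES = ("synth", "prevalence", "burden", "services", "benefit")

CASE_GROUPS = ("ptsd", "depression", "ptsd_only", "depression_only", "comorbid", "combined")


def build_fixture(cfg: RunConfig, seed: int | None = None) -> SyriaFixture:
    f = cfg.fixture
    mort = f.get("mortality", {})
    return syria_fixture(
        seed=seed if seed is not None else cfg.seed,
        total_population=float(f.get("total_population", 17054263.6)),
        growth_rate=float(f.get("growth_rate", 0.025)),
        peak_age=float(f.get("peak_age", 25.0)),
        spread=float(f.get("spread", 15.0)),
        comorbid_rho=float(f.get("comorbid_rho", 0.50)),
        mortality_params={
            "makeham_a": float(mort.get("makeham_a", 0.002)),
            "gompertz_b": float(mort.get("gompertz_b", 5e-5)),
            "gompertz_theta": float(mort.get("gompertz_theta", 0.09)),
        },
    )


def build_service_model(cfg: RunConfig, fixture: SyriaFixture) -> ServiceModel:
    svc = cfg.services
    eligible = eligible_population(fixture.cases, cfg.severity)
    peri = svc.get("perinatal", {})
    eligible["perinatal"] = eligible_perinatal(
        fixture.population,
        fertility_rate=float(peri.get("fertility_rate", 0.11)),
        perinatal_depression_prev=float(peri.get("perinatal_depression_prev", 0.15)),
        moderate_severe_prop=cfg.severity["depression"].moderate_severe_prop,
    )
    return ServiceModel(
        packages=cfg.packages,
        staffing=cfg.staffing,
        eligible_2015=eligible,
        population_2015=fixture.population.total,
        baseline_coverage=float(svc.get("baseline_coverage", 0.01)),
        population_growth=float(svc.get("population_growth", 0.015)),
    )


def run_benefit_scenarios(
    cfg: RunConfig,
    fixture: SyriaFixture,
    scenarios: tuple[str, ...] = ("partial_null", "current", "target30", "target100"),
    modes: tuple[str, ...] = ("linear", "exponential"),
    discount_rate: float = 0.0,
) -> dict:
    """Run the Markov engine for every scenario × mode and summarise averted
    burden against the partial-null comparator."""
    cohorts, streams = build_streams(fixture, cfg.severity, cfg.benefit)
    comparator = hb.run_scenario(cohorts, streams, "partial_null",
                                 discount_rate=discount_rate)
    out: dict = {"discount_rate": discount_rate, "scenarios": {}}
    for mode in modes:
        for name in scenarios:
            res = hb.run_scenario(cohorts, streams, name, mode=mode,
                                  discount_rate=discount_rate)
            summary = hb.averted_burden(res, comparator)
            out["scenarios"][f"{name}_{mode}"] = {
                "total_dalys": res.total,
                "dalys_averted": summary["dalys_averted"],
                "percent_averted": summary["percent_averted"],
                "percent_by_stream": summary["percent_by_stream"],
            }
    return out


# ---------------------------------------------------------------------------
# Staged execution with file exchange
# ---------------------------------------------------------------------------

def _load_fixture_from(out_dir: Path, cfg: RunConfig) -> SyriaFixture:
    """Rehydrate the fixture bundle from a previous synth stage's CSVs."""
    pop = PopulationTable(read_age_table(out_dir / "population.csv"))
    mort = RateSchedule(read_age_table(out_dir / "mortality.csv"), name="all_cause_mortality")
    curves = {}
    for d, spec in (
        ("ptsd", 0.129),
        ("depression", 0.076),
    ):
        vals = read_age_table(out_dir / f"prevalence_{d}.csv")
        curves[d] = PrevalenceCurve(d, RateSchedule(vals, name=f"{d}_prevalence"), spec)
    fx = build_fixture(cfg)
    cases = {d: CaseCounts(d, curves[d].values * pop.counts) for d in curves}
    from .prevalence import comorbidity_partition
    cases.update(comorbidity_partition(cases["ptsd"], cases["depression"], fx.comorbidity))
    return SyriaFixture(pop, mort, curves, cases, fx.prevalence_specs, fx.comorbidity, cfg.seed)


def run_pipeline(
    config: RunConfig | str | Path | None = None,
    stages: tuple[str, ...] = STAGES,
    out_dir: str | Path = "mhplan_out",
    seed: int | None = None,
) -> dict:
    """Execute the requested stages in order; returns the report bundle."""
    cfg = config if isinstance(config, RunConfig) else load_config(config)
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stages {bad}; valid: {STAGES}")
    stages = tuple(s for s in STAGES if s in stages)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = seed if seed is not None else cfg.seed
    report: dict = {}
    fixture: SyriaFixture | None = None

    def need_fixture() -> SyriaFixture:
        nonlocal fixture
        if fixture is None:
            if (out / "population.csv").exists() and "synth" not in stages:
                fixture = _load_fixture_from(out, cfg)
            else:
                fixture = build_fixture(cfg, seed=seed)
        return fixture

    for stage in stages:
        log.info("running stage %s", stage)
        try:
            if stage == "synth":
                fx = need_fixture()
                write_age_table(out / "population.csv", fx.population.counts, "persons")
                write_age_table(out / "mortality.csv", fx.mortality.values, "hazard")
                for d, curve in fx.curves.items():
                    write_age_table(out / f"prevalence_{d}.csv", curve.values, "prevalence")
                report["synth"] = {"total_population": fx.population.total}
            elif stage == "prevalence":
                fx = need_fixture()
                totals = {}
                for g in CASE_GROUPS:
                    write_age_table(out / f"cases_{g}.csv", fx.cases[g].cases, "cases")
                    totals[g] = fx.cases[g].total
                report["prevalence"] = {"totals": totals}
                (out / "prevalence_summary.json").write_text(json.dumps(report["prevalence"], indent=2))
            elif stage == "burden":
                fx = need_fixture()
                summary = {}
                for d in ("ptsd", "depression"):
                    res = propagate_uncertainty(
                        fx.cases[d], cfg.severity[d], fx.prevalence_specs[d],
                        n_draws=2000, seed=seed,
                    )
                    _, std_rate = yld_rate(res, fx.population)
                    write_age_table(out / f"ylds_{d}.csv", res.ylds_by_age, "ylds")
                    summary[d] = {
                        "ylds": res.point,
                        "lower95": res.lower95,
                        "upper95": res.upper95,
                        "deterministic": res.deterministic,
                        "yld_rate_per_1000": std_rate,
                    }
                report["burden"] = summary
                (out / "burden_summary.json").write_text(json.dumps(summary, indent=2))
            elif stage == "services":
                fx = need_fixture()
                model = build_service_model(cfg, fx)
                plans = {}
                for mode in ("linear", "exponential"):
                    plan = run_scaleup(model, mode=mode)
                    plan.to_csv(out / f"service_plan_{mode}.csv", index=False)
                    plans[mode] = {
                        "baseline_fte_per_100k": float(plan["fte_per_100k"].iloc[0]),
                        "final_fte_per_100k": float(plan["fte_per_100k"].iloc[-1]),
                    }
                report["services"] = plans
            elif stage == "benefit":
                fx = need_fixture()
                result = run_benefit_scenarios(cfg, fx)
                report["benefit"] = result
                (out / "benefit_summary.json").write_text(json.dumps(result, indent=2))
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": seed,
        "stages": list(stages),
        "config_source": cfg.source,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg.raw, sort_keys=True).encode()
        ).hexdigest(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    report["manifest"] = manifest
    return report
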