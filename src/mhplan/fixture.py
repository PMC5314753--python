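"""The Syria-like synthetic study fixture.

Bundles every input the pipeline needs, generated by :mod:`mhplan.synthetic`
with defaults matching the study conditions: age-standardised prevalences of
12.9% (95% UI 6.9–22.9) for PTSD and 7.6% (5.1–10.9) for major depression,
50% of PTSD cases comorbid with depression, and a total population anchored
so that PTSD cases come to ≈2.2 million (2.2e6 / 0.129 ≈ 17.05 million
people; the case count is the analysis' lead figure and the published
depression count is not consistent with the same population total).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import benefit as hb
from .burden import SeverityModel, moderate_severe_dw
from .illness_death import (
    HazardSet,
    MortalityRisk,
    excess_mortality_from_rr,
    fit_incidence,
)
from .prevalence import ComorbiditySpec, comorbidity_partition, prevalent_cases
from .synthetic import (
    DEFAULT_SEED,
    ParameterSpec,
    PrevalenceCurve,
    make_mortality,
    make_population,
    make_prevalence_curve,
)
from .tables import CaseCounts, PopulationTable, RateSchedule

#: Total population chosen so 12.9% prevalence yields ≈2.2 million PTSD cases.
SYRIA_TOTAL_POPULATION = 2.2e6 / 0.129

PTSD_PREVALENCE = ParameterSpec("ptsd_prevalence", 0.129, 0.069, 0.229, kind="proportion")
DEPRESSION_PREVALENCE = ParameterSpec(
    "depression_prevalence", 0.076, 0.051, 0.109, kind="proportion"
)


@dataclass(frozen=True)
class SyriaFixture:
    population: PopulationTable
    mortality: RateSchedule
    curves: dict[str, PrevalenceCurve]
    cases: dict[str, CaseCounts]  # ptsd, depression, + comorbidity partition
    prevalence_specs: dict[str, ParameterSpec]
    comorbidity: ComorbiditySpec
    seed: int


def syria_fixture(
    seed: int = DEFAULT_SEED,
    total_population: float = SYRIA_TOTAL_POPULATION,
    growth_rate: float = 0.025,
    peak_age: float = 25.0,
    spread: float = 15.0,
    comorbid_rho: float = 0.50,
    mortality_params: dict | None = None,
) -> SyriaFixture:
    """Build the complete synthetic fixture; a pure function of its inputs."""
    mortality = make_mortality(**(mortality_params or {}))
    population = make_population(
        total_population,
        {"kind": "growth", "rate": growth_rate, "mortality": mortality},
        seed=seed,
    )
    curves = {
        "ptsd": make_prevalence_curve(
            "ptsd", PTSD_PREVALENCE.point, population, peak_age=peak_age, spread=spread
        ),
        "depression": make_prevalence_curve(
            "depression", DEPRESSION_PREVALENCE.point, population,
            peak_age=peak_age, spread=spread,
        ),
    }
    ptsd_cases = prevalent_cases(curves["ptsd"], population)
    dep_cases = prevalent_cases(curves["depression"], population)
    spec = ComorbiditySpec(comorbid_rho)
    cases = {"ptsd": ptsd_cases, "depression": dep_cases}
    cases.update(comorbidity_partition(ptsd_cases, dep_cases, spec))
    return SyriaFixture(
        population=population,
        mortality=mortality,
        curves=curves,
        cases=cases,
        prevalence_specs={"ptsd": PTSD_PREVALENCE, "depression": DEPRESSION_PREVALENCE},
        comorbidity=spec,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Benefit-model setup: disorder streams and multi-age cohorts
# ---------------------------------------------------------------------------

def build_streams(
    fixture: SyriaFixture,
    severity: dict[str, SeverityModel],
    benefit_cfg: dict,
) -> tuple[dict[str, list[hb.CohortSpec]], list[hb.DiseaseStream]]:
    """Construct the disorder streams and cohorts for the Markov engine.

    Two streams are modelled: PTSD (PTSD-only cases; remission 0.17/year,
    zero case fatality) and comorbid depression/PTSD (depression parameters:
    remission 1.40/year, mortality RR 1.9).  Depression-only cases ride in
    the comorbid stream by default (``include_depression_only``) so that all
    moderate–severe burden is covered; set it false to model the comorbid
    cases alone.

    Incidence for each stream is back-calculated from its age-specific
    prevalence so the untreated model reproduces the fixture's prevalence
    curves.
    """
    pop = fixture.population
    m = fixture.mortality
    streams_cfg = benefit_cfg["streams"]
    include_dep_only = benefit_cfg.get("include_depression_only", True)

    comorbid_cases = fixture.cases["comorbid"].cases.copy()
    if include_dep_only:
        comorbid_cases = comorbid_cases + fixture.cases["depression_only"].cases
    stream_cases = {
        "ptsd": fixture.cases["ptsd_only"].cases,
        "comorbid": comorbid_cases,
    }
    severity_for = {"ptsd": severity["ptsd"], "comorbid": severity["depression"]}

    cohorts: dict[str, list[hb.CohortSpec]] = {}
    streams: list[hb.DiseaseStream] = []
    for name in ("ptsd", "comorbid"):
        cfg = streams_cfg[name]
        prev_values = np.clip(stream_cases[name] / pop.counts, 0.0, 0.999)
        prev = RateSchedule(prev_values, name=f"{name}_prevalence")
        remission = RateSchedule(np.full(101, float(cfg["remission"])), name="remission")
        rr = float(cfg.get("mortality_rr", 1.0))
        if rr > 1.0:
            f = excess_mortality_from_rr(m, MortalityRisk(rr))
        else:
            f = RateSchedule(np.zeros(101), name="excess_mortality")
        incidence = fit_incidence(prev, remission, f, m)
        hazards = HazardSet(incidence, remission, f, m)
        sev = severity_for[name]
        effects = hb.EffectSpec(
            delta_remission=float(cfg["effects"]["delta_remission"]),
            delta_dw=float(cfg["effects"]["delta_dw"]),
        )
        packages = tuple(
            hb.InterventionPackage(p["name"], float(p["efficacy"]),
                                   float(p.get("coverage_share", 1.0)))
            for p in cfg["packages"]
        )
        streams.append(
            hb.DiseaseStream(
                name=name,
                hazards=hazards,
                dw=moderate_severe_dw(sev),
                moderate_severe_prop=sev.moderate_severe_prop,
                effects=effects,
                packages=packages,
            )
        )
        cohorts[name] = [
            hb.CohortSpec(
                label=label,
                mid_age=mid,
                size=pop.band(lo, hi),
                initial_prevalence=float(prev.at(mid)),
            )
            for label, lo, hi, mid in hb.AGE_BANDS
        ]
    return cohorts, streams
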