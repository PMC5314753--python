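"""Service and human-resource requirements for care-package scale-up.

Re-implements the resource arithmetic of WHO mhGAP-style costing: an
eligible population (moderate–severe cases aged 15+, plus a perinatal
depression group) receives packages of care at a coverage rate that scales
up from a baseline over a 15-year horizon; packages translate into visits
by treatment type (primary care, ancillary, outpatient) and inpatient
bed-days; bed-days become beds via an occupancy factor; visits and beds
become full-time-equivalent (FTE) staff by provider type through
consultation-rate and ward-staffing parameters.

PTSD-only cases receive the depression packages of care but never inpatient
treatment; comorbid depression/PTSD cases receive the full depression
packages including inpatient care.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .burden import SeverityModel
from .tables import CaseCounts, PopulationTable

VISIT_TYPES = ("primary_care", "ancillary", "outpatient")
TREATMENT_TYPES = VISIT_TYPES + ("inpatient",)

HORIZON_YEARS = 15  # t = 0 (baseline) .. 14 (target attained)


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Coverage trajectory
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoverageTrajectory:
    """Coverage scale-up from ``baseline`` at t=0 to ``target`` at t=14.

    ``linear`` interpolates affinely; ``exponential`` geometrically (a slow
    start with most of the scale-up concentrated in the final years).  Both
    modes agree exactly at the endpoints.
    """

    baseline: float = 0.01
    target: float = 0.30
    years: int = HORIZON_YEARS
    mode: str = "linear"

    def __post_init__(self):
        if not 0.0 <= self.baseline <= self.target <= 1.0:
            raise ValueError("require 0 <= baseline <= target <= 1")
        if self.mode not in ("linear", "exponential"):
            raise ValueError(f"unknown scale-up mode {self.mode!r}")
        if self.mode == "exponential" and self.baseline <= 0:
            raise ValueError("exponential scale-up undefined for baseline <= 0")

    def at(self, t: int) -> float:
        return coverage_at(self, t)

    def series(self) -> np.ndarray:
        return np.array([self.at(t) for t in range(self.years)])


def coverage_at(traj: CoverageTrajectory, t: int) -> float:
    """Coverage at year index t in 0..years-1."""
    T = traj.years - 1
    if not 0 <= t <= T:
        raise ValueError(f"year index {t} outside 0..{T}")
    if traj.baseline == traj.target:
        return traj.baseline
    if traj.mode == "linear":
        return traj.baseline + (traj.target - traj.baseline) * t / T
    return traj.baseline * (traj.target / traj.baseline) ** (t / T)


# ---------------------------------------------------------------------------
# Care packages and staffing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Treatment:
    """One treatment type inside a package of care.

    ``proportion`` of people in the package receive this treatment;
    visit-based types carry visits per person and minutes per visit,
    inpatient carries bed-days per person (``proportion`` then plays the
    role of the percentage use of inpatient care).
    """

    proportion: float
    visits_per_person: float = 0.0
    minutes_per_visit: float = 30.0
    bed_days_per_person: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.proportion <= 1.0:
            raise ValueError("treatment proportion must be in [0, 1]")
        if self.visits_per_person < 0 or self.bed_days_per_person < 0:
            raise ValueError("visits/bed-days per person must be >= 0")


@dataclass(frozen=True)
class CarePackage:
    name: str
    applies_to: tuple[str, ...]
    coverage_target: float
    treatments: dict[str, Treatment]
    inpatient_allowed: bool = True

    def __post_init__(self):
        if not 0.0 <= self.coverage_target <= 1.0:
            raise ValueError(f"{self.name}: coverage target must be in [0, 1]")
        unknown = set(self.treatments) - set(TREATMENT_TYPES)
        if unknown:
            raise ConfigError(f"{self.name}: unknown treatment types {sorted(unknown)}")
        if not self.inpatient_allowed and "inpatient" in self.treatments:
            raise ConfigError(f"{self.name}: inpatient treatment listed but not allowed")


@dataclass(frozen=True)
class Provider:
    days_per_year: float
    consults_per_day: dict[str, float]
    staff_per_ward: float = 0.0

    def __post_init__(self):
        if self.days_per_year <= 0:
            raise ValueError("days worked per year must be > 0")


@dataclass(frozen=True)
class StaffingParameters:
    """Provider workloads, treatment-type delivery shares and ward staffing."""

    providers: dict[str, Provider]
    shares: dict[str, dict[str, float]]  # treatment type -> provider -> share
    ward_size_beds: float = 25.0
    occupancy_factor: float = 1.15  # 1/0.86 ~ 86% occupancy

    def __post_init__(self):
        for ttype, shares in self.shares.items():
            if ttype not in VISIT_TYPES:
                raise ConfigError(f"shares given for unknown treatment type {ttype!r}")
            tot = sum(shares.values())
            if abs(tot - 1.0) > 1e-6:
                raise ConfigError(f"{ttype}: provider shares sum to {tot}, expected 1")
            for prov in shares:
                if prov not in self.providers:
                    raise ConfigError(f"{ttype}: unknown provider {prov!r}")


# ---------------------------------------------------------------------------
# Eligible populations
# ---------------------------------------------------------------------------

ADULT_AGE = 15


def eligible_population(
    partition: dict[str, CaseCounts],
    severity: dict[str, SeverityModel],
    min_age: int = ADULT_AGE,
) -> dict[str, float]:
    """Moderate–severe cases aged ``min_age``+ per group.

    PTSD-only cases use the PTSD (anxiety-proxy) moderate–severe share;
    depression-only and comorbid cases use the depression share.
    """
    model_for = {
        "ptsd_only": "ptsd",
        "depression_only": "depression",
        "comorbid": "depression",
    }
    out: dict[str, float] = {}
    for group, key in model_for.items():
        if group not in partition:
            continue
        if key not in severity:
            raise ConfigError(f"missing severity model {key!r} for group {group!r}")
        prop = severity[key].moderate_severe_prop
        out[group] = partition[group].band_total(min_age, 100) * prop
    return out


def eligible_perinatal(
    population: PopulationTable,
    fertility_rate: float = 0.11,
    perinatal_depression_prev: float = 0.15,
    moderate_severe_prop: float = 0.28,
) -> float:
    """Women aged 15–44 who give birth in the year and have moderate–severe
    perinatal depression: women_15_44 × fertility × prevalence × mod–sev share."""
    return (
        population.women(15, 44)
        * fertility_rate
        * perinatal_depression_prev
        * moderate_severe_prop
    )


# ---------------------------------------------------------------------------
# Resource arithmetic
# ---------------------------------------------------------------------------

def visits_required(
    eligible: float, coverage: float, pkg: CarePackage
) -> dict[str, float]:
    """Visits by treatment type: eligible × coverage × proportion × visits pp."""
    if eligible < 0 or coverage < 0:
        raise ValueError("eligible and coverage must be >= 0")
    treated = eligible * coverage
    return {
        ttype: treated * t.proportion * t.visits_per_person
        for ttype, t in pkg.treatments.items()
        if ttype in VISIT_TYPES
    }


def bed_days_required(
    eligible: float, coverage: float, pkg: CarePackage, group: str = "comorbid"
) -> float:
    """Inpatient bed-days: eligible × coverage × percentage use × bed-days pp.

    PTSD-only cases receive no inpatient care in any configuration.
    """
    if group == "ptsd_only":
        raise ConfigError("inpatient treatment requested for a PTSD-only group")
    if "inpatient" not in pkg.treatments:
        return 0.0
    if not pkg.inpatient_allowed:
        raise ConfigError(f"{pkg.name}: inpatient not allowed")
    t = pkg.treatments["inpatient"]
    return eligible * coverage * t.proportion * t.bed_days_per_person


def beds_required(bed_days: float, occupancy_factor: float = 1.15) -> float:
    """Beds = bed-days / 365 × occupancy factor (1.15 ≈ 86% occupancy).

    Returned unrounded; round to the nearest integer only in reports.
    """
    if bed_days < 0:
        raise ValueError("bed_days must be >= 0")
    return bed_days / 365.0 * occupancy_factor


def fte_outpatient(
    visits: dict[str, float], staffing: StaffingParameters
) -> dict[str, float]:
    """FTE per provider from community/outpatient visits.

    FTE_p = Σ_type visits_type × share_{p,type} / (consults_per_day_{p,type}
    × days_per_year_p).
    """
    fte = {p: 0.0 for p in staffing.providers}
    for ttype, n_visits in visits.items():
        if n_visits == 0:
            continue
        if ttype not in staffing.shares:
            raise ConfigError(f"no provider shares configured for {ttype!r}")
        for prov, share in staffing.shares[ttype].items():
            if share == 0:
                continue
            provider = staffing.providers[prov]
            cpd = provider.consults_per_day.get(ttype, 0.0)
            if cpd <= 0:
                raise ConfigError(
                    f"{prov}: zero consultations/day for {ttype} with nonzero share"
                )
            fte[prov] += n_visits * share / (cpd * provider.days_per_year)
    return fte


def fte_inpatient(beds: float, staffing: StaffingParameters) -> dict[str, float]:
    """FTE per provider for inpatient care: beds/ward-size × staff per ward."""
    if beds < 0:
        raise ValueError("beds must be >= 0")
    wards = beds / staffing.ward_size_beds
    return {p: wards * prov.staff_per_ward for p, prov in staffing.providers.items()}


# ---------------------------------------------------------------------------
# 15-year scale-up plan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ServiceModel:
    """Complete configuration for the 15-year resource scale-up."""

    packages: tuple[CarePackage, ...]
    staffing: StaffingParameters
    eligible_2015: dict[str, float]  # group -> persons at baseline
    population_2015: float
    baseline_coverage: float = 0.01
    population_growth: float = 0.015  # annual, applied to population and eligibles

    def __post_init__(self):
        missing = []
        if not self.packages:
            missing.append("packages")
        if not self.eligible_2015:
            missing.append("eligible_2015")
        if missing:
            raise ConfigError(f"incomplete service configuration: missing {missing}")

    def population_at(self, t: int) -> float:
        return self.population_2015 * (1.0 + self.population_growth) ** t


def run_scaleup(model: ServiceModel, mode: str = "linear") -> pd.DataFrame:
    """Yearly visits, bed-days, beds and FTE by provider over the horizon.

    Each package scales from the common baseline coverage to its own target
    (linearly or exponentially); the eligible populations grow with the
    projected population.  Quantities are unrounded; round in reports.
    """
    providers = list(model.staffing.providers)
    rows = []
    for t in range(HORIZON_YEARS):
        growth = (1.0 + model.population_growth) ** t
        visits = {v: 0.0 for v in VISIT_TYPES}
        bed_days = 0.0
        for pkg in model.packages:
            traj = CoverageTrajectory(
                baseline=model.baseline_coverage, target=pkg.coverage_target, mode=mode
            )
            cov = traj.at(t)
            for group in pkg.applies_to:
                eligible = model.eligible_2015.get(group, 0.0) * growth
                for ttype, n in visits_required(eligible, cov, pkg).items():
                    visits[ttype] += n
                if "inpatient" in pkg.treatments and group != "ptsd_only":
                    bed_days += bed_days_required(eligible, cov, pkg, group=group)
        beds = beds_required(bed_days, model.staffing.occupancy_factor)
        fte_out = fte_outpatient(visits, model.staffing)
        fte_in = fte_inpatient(beds, model.staffing)
        fte = {p: fte_out[p] + fte_in[p] for p in providers}
        total_fte = sum(fte.values())
        pop = model.population_at(t)
        row = {
            "year": 2015 + t,
            "t": t,
            **{f"{v}_visits": visits[v] for v in VISIT_TYPES},
            "inpatient_days": bed_days,
            "beds": beds,
            **{f"fte_{p}": fte[p] for p in providers},
            "fte_total": total_fte,
            "population": pop,
            "fte_per_100k": total_fte / pop * 1e5,
        }
        rows.append(row)
    return pd.DataFrame(rows)
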