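"""Multi-cohort Markov health-benefit analysis (avertable DALYs).

Six adult age cohorts (15–29, 30–44, 45–59, 60–69, 70–79, 80+), each
represented by its mid-age, are propagated for 15 years through the
three-state illness-death model under scenario-specific treatment coverage.
Treatment acts through intervention packages whose effectiveness at year t
is the package efficacy times its effective coverage; the packages combine
as 1 − Π(1 − c_k·e_k) and the combined effectiveness raises the remission
hazard and lowers the disability weight proportionally.

Scenarios: ``partial_null`` (all services removed — the no-treatment
comparator), ``current`` (constant 1% coverage), ``target30`` and
``target100`` (coverage ramped from 1% to 30% / 100%, linearly or
exponentially).  The DALY burden tracked is the YLD burden of
moderate–severe cases (case fatality for these disorders is too low for a
meaningful YLL component); burden averted is reported against the
partial-null comparator, optionally discounted at 3% per year.

Everything here is deterministic: results are pure functions of the
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import warnings

import numpy as np

from .illness_death import HazardSet, StateVector, step_year
from .services import CoverageTrajectory, HORIZON_YEARS

AGE_BANDS = (
    ("15-29", 15, 29, 22.0),
    ("30-44", 30, 44, 37.0),
    ("45-59", 45, 59, 52.0),
    ("60-69", 60, 69, 64.5),
    ("70-79", 70, 79, 74.5),
    ("80+", 80, 100, 85.0),
)


@dataclass(frozen=True)
class CohortSpec:
    label: str
    mid_age: float
    size: float
    initial_prevalence: float
    horizon: int = HORIZON_YEARS

    def __post_init__(self):
        if self.size < 0 or not 0 <= self.initial_prevalence < 1:
            raise ValueError("invalid cohort size or initial prevalence")


@dataclass(frozen=True)
class InterventionPackage:
    """A treatable intervention with overall efficacy and a coverage share.

    ``coverage_share`` (c_k) is the fraction of the covered population this
    package reaches; the scenario's scale-up coverage multiplies it.
    """

    name: str
    efficacy: float
    coverage_share: float = 1.0

    def __post_init__(self):
        if not 0 <= self.efficacy <= 1 or not 0 <= self.coverage_share <= 1:
            raise ValueError(f"{self.name}: efficacy and coverage share must be in [0, 1]")


@dataclass(frozen=True)
class EffectSpec:
    """Maximum proportional parameter changes at full combined effectiveness:
    remission is multiplied by (1 + delta_remission·eff) and the disability
    weight by (1 − delta_dw·eff)."""

    delta_remission: float
    delta_dw: float

    def __post_init__(self):
        if self.delta_remission < 0 or not 0 <= self.delta_dw <= 1:
            raise ValueError("require delta_remission >= 0 and delta_dw in [0, 1]")


def combined_effectiveness(
    packages: list[InterventionPackage] | tuple[InterventionPackage, ...],
    scaleup_coverage: float,
) -> float:
    """1 − Π_k (1 − c_k·s·e_k) with s the scenario scale-up coverage at t."""
    eff = 1.0
    for pkg in packages:
        e_k = pkg.coverage_share * scaleup_coverage * pkg.efficacy
        if e_k > 1.0:
            raise ValueError(f"{pkg.name}: effective fraction {e_k} exceeds 1")
        eff *= 1.0 - e_k
    return 1.0 - eff


def apply_effectiveness(
    hazards: HazardSet, dw: float, eff: float, effects: EffectSpec
) -> tuple[HazardSet, float]:
    """Adjust remission and disability weight for combined effectiveness
    ``eff``; eff = 0 is the identity."""
    if not 0.0 <= eff <= 1.0:
        raise ValueError("combined effectiveness must be in [0, 1]")
    new_dw = dw * (1.0 - effects.delta_dw * eff)
    if new_dw < 0:
        raise ValueError("adjusted disability weight below zero")
    new_remission = hazards.remission * (1.0 + effects.delta_remission * eff)
    return replace(hazards, remission=new_remission), new_dw


@dataclass(frozen=True)
class DiseaseStream:
    """One modelled disorder stream (PTSD, or comorbid depression/PTSD)."""

    name: str
    hazards: HazardSet
    dw: float  # mean DW among moderate-severe cases
    moderate_severe_prop: float
    effects: EffectSpec
    packages: tuple[InterventionPackage, ...]


def scenario_coverage(name: str, mode: str = "linear") -> np.ndarray:
    """Per-year scale-up coverage for the four named scenarios."""
    if name == "partial_null":
        return np.zeros(HORIZON_YEARS)
    if name == "current":
        return np.full(HORIZON_YEARS, 0.01)
    targets = {"target30": 0.30, "target100": 1.00}
    if name not in targets:
        raise ValueError(f"unknown scenario {name!r}")
    return CoverageTrajectory(baseline=0.01, target=targets[name], mode=mode).series()


def run_cohort(
    cohort: CohortSpec,
    stream: DiseaseStream,
    coverage: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Propagate one cohort under a coverage series.

    Returns per-year diseased counts C(t) and YLD(t) = C(t) × mod–sev share
    × adjusted DW, for t = 0..horizon-1 (year-start states).  Ages beyond
    100 are truncated to the terminal age with a warning.
    """
    if len(coverage) < cohort.horizon:
        raise ValueError("coverage series shorter than the cohort horizon")
    if cohort.mid_age + cohort.horizon > 100:
        warnings.warn(
            f"cohort {cohort.label}: ages beyond 100 truncated to the terminal age"
        )
    state = StateVector(
        cohort.size * (1 - cohort.initial_prevalence),
        cohort.size * cohort.initial_prevalence,
    )
    diseased = np.zeros(cohort.horizon)
    ylds = np.zeros(cohort.horizon)
    for t in range(cohort.horizon):
        eff = combined_effectiveness(stream.packages, coverage[t])
        adj_hazards, adj_dw = apply_effectiveness(
            stream.hazards, stream.dw, eff, stream.effects
        )
        diseased[t] = state.diseased
        ylds[t] = state.diseased * stream.moderate_severe_prop * adj_dw
        age = min(cohort.mid_age + t, 100.0)
        state = step_year(state, *adj_hazards.at(age))
    return diseased, ylds


@dataclass(frozen=True)
class ScenarioResult:
    scenario: str
    mode: str
    yld_by_year: dict[str, np.ndarray]  # disorder stream -> per-year YLDs (summed over cohorts)
    discount_rate: float = 0.0

    @property
    def yearly_total(self) -> np.ndarray:
        return sum(self.yld_by_year.values())

    @property
    def total(self) -> float:
        return discount(self.yearly_total, self.discount_rate)

    def stream_total(self, name: str) -> float:
        return discount(self.yld_by_year[name], self.discount_rate)


def run_scenario(
    cohorts: dict[str, list[CohortSpec]],
    streams: list[DiseaseStream] | tuple[DiseaseStream, ...],
    scenario: str,
    mode: str = "linear",
    discount_rate: float = 0.0,
) -> ScenarioResult:
    """Total per-year YLDs over all cohorts for each disorder stream.

    ``cohorts`` maps stream name → its cohort list (initial prevalences are
    disorder-specific even though the age bands are shared).
    """
    coverage = scenario_coverage(scenario, mode)
    by_stream: dict[str, np.ndarray] = {}
    for stream in streams:
        if stream.name not in cohorts:
            raise ValueError(f"missing cohorts for disorder stream {stream.name!r}")
        total = np.zeros(HORIZON_YEARS)
        for cohort in cohorts[stream.name]:
            _, ylds = run_cohort(cohort, stream, coverage)
            total += ylds
        by_stream[stream.name] = total
    return ScenarioResult(scenario, mode, by_stream, discount_rate)


def averted_burden(
    scenario: ScenarioResult, comparator: ScenarioResult
) -> dict[str, float]:
    """DALYs averted and percent averted relative to the comparator."""
    if set(scenario.yld_by_year) != set(comparator.yld_by_year):
        raise ValueError("scenario and comparator model different disorder streams")
    averted = comparator.total - scenario.total
    pct = 100.0 * averted / comparator.total if comparator.total > 0 else 0.0
    by_stream = {}
    for name in scenario.yld_by_year:
        c = comparator.stream_total(name)
        s = scenario.stream_total(name)
        by_stream[name] = 100.0 * (c - s) / c if c > 0 else 0.0
    return {"dalys_averted": averted, "percent_averted": pct,
            "percent_by_stream": by_stream}


def discount(series: np.ndarray, rate: float = 0.03) -> float:
    """Present value Σ_t value_t/(1+rate)^t, t = 0..len-1 (t=0 undiscounted)."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    series = np.asarray(series, dtype=float)
    t = np.arange(series.size)
    return float(np.sum(series / (1.0 + rate) ** t))
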