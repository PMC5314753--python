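"""YLD burden from prevalent cases, severity splits and disability weights.

YLDs for a disorder are prevalent cases × the severity-weighted disability
weight (DW): cases are split across severity classes (asymptomatic / mild /
moderate / severe), each class carries a DW on the 0 (perfect health) to 1
(death) scale, and the asymptomatic class contributes nothing.  PTSD uses
the anxiety-disorder severity model as a proxy, mirroring burden-of-disease
practice where PTSD is not assessed separately.

Uncertainty is propagated by Monte Carlo: seeded draws of the standardised
prevalence (beta) scale the case counts, seeded draws of each class DW
(beta, matching the published 95% intervals) enter the severity-weighted
mean, and the 2.5/97.5 percentiles of the resulting YLD totals form the
95% uncertainty interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .synthetic import ParameterSpec, draw_parameters
from .tables import CaseCounts, PopulationTable, RateSchedule

log = logging.getLogger(__name__)

#: GBD 2010 global age-standardised YLD rate per 1000 for major depression,
#: kept as a comparison constant for the conflict-affected estimates.
GLOBAL_DEPRESSION_YLD_RATE_PER_1000 = 9.2
#: Same for the anxiety-disorders group (the PTSD proxy).
GLOBAL_ANXIETY_YLD_RATE_PER_1000 = 3.9


@dataclass(frozen=True)
class SeverityClass:
    name: str
    proportion: float
    dw: float
    dw_lower95: float = None  # type: ignore[assignment]
    dw_upper95: float = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.dw_lower95 is None:
            object.__setattr__(self, "dw_lower95", self.dw)
        if self.dw_upper95 is None:
            object.__setattr__(self, "dw_upper95", self.dw)
        if not 0.0 <= self.dw <= 1.0:
            raise ValueError(f"{self.name}: disability weight must be in [0, 1]")
        if not self.dw_lower95 <= self.dw <= self.dw_upper95:
            raise ValueError(f"{self.name}: DW interval must bracket the point estimate")
        if self.proportion < 0:
            raise ValueError(f"{self.name}: class proportion must be >= 0")


@dataclass(frozen=True)
class SeverityModel:
    """Severity-class proportions and disability weights for one disorder.

    ``moderate_severe_prop`` is the share of prevalent cases eligible for
    treatment packages (moderate + severe classes) and must agree with the
    class proportions.
    """

    disorder: str
    classes: tuple[SeverityClass, ...]
    moderate_severe_prop: float

    def __post_init__(self):
        total = sum(c.proportion for c in self.classes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"{self.disorder}: severity proportions sum to {total}, expected 1"
            )
        modsev = sum(
            c.proportion for c in self.classes if c.name in ("moderate", "severe")
        )
        if abs(modsev - self.moderate_severe_prop) > 1e-6:
            raise ValueError(
                f"{self.disorder}: moderate_severe_prop {self.moderate_severe_prop} "
                f"!= moderate+severe class share {modsev}"
            )

    def class_named(self, name: str) -> SeverityClass:
        for c in self.classes:
            if c.name == name:
                return c
        raise KeyError(name)


def expected_dw(model: SeverityModel) -> float:
    """Severity-weighted mean disability weight Σ proportion × DW."""
    return sum(c.proportion * c.dw for c in model.classes)


def moderate_severe_dw(model: SeverityModel) -> float:
    """Mean DW among moderate and severe cases only (used where treatment
    packages are restricted to moderate–severe cases)."""
    classes = [c for c in model.classes if c.name in ("moderate", "severe")]
    weight = sum(c.proportion for c in classes)
    return sum(c.proportion * c.dw for c in classes) / weight


def combine_dws(dw1: float, dw2: float) -> float:
    """Multiplicative DW combination 1 − (1−dw1)(1−dw2) for comorbid health
    states.  Off by default in the pipeline; provided as an option."""
    return 1.0 - (1.0 - dw1) * (1.0 - dw2)


@dataclass(frozen=True)
class BurdenResult:
    disorder: str
    ylds_by_age: np.ndarray
    point: float
    lower95: float = None  # type: ignore[assignment]
    upper95: float = None  # type: ignore[assignment]
    deterministic: float = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.lower95 is None:
            object.__setattr__(self, "lower95", self.point)
        if self.upper95 is None:
            object.__setattr__(self, "upper95", self.point)
        if self.deterministic is None:
            object.__setattr__(self, "deterministic", self.point)
        if not self.lower95 <= self.point <= self.upper95:
            raise ValueError("require lower95 <= point <= upper95")
        if self.point < 0:
            raise ValueError("YLDs must be non-negative")


def compute_ylds(cases: CaseCounts, model: SeverityModel) -> BurdenResult:
    """Point-estimate YLDs: ylds_a = cases_a × E[DW]."""
    dw = expected_dw(model)
    by_age = cases.cases * dw
    total = float(by_age.sum())
    return BurdenResult(model.disorder, by_age, total)


def yld_rate(result: BurdenResult, standard: PopulationTable) -> tuple[RateSchedule, float]:
    """Per-1000 YLD rates by age plus the age-standardised summary.

    rate_a = 1000 × ylds_a / n_a; the summary is the population-weighted mean
    of the age-specific rates.
    """
    pop = standard.counts
    zero = (pop == 0) & (result.ylds_by_age > 0)
    if np.any(zero):
        raise ValueError(
            f"zero population at ages {np.nonzero(zero)[0].tolist()} with nonzero YLDs"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(pop > 0, 1000.0 * result.ylds_by_age / np.where(pop > 0, pop, 1.0), 0.0)
    sched = RateSchedule(rates, name=f"{result.disorder}_yld_rate_per_1000")
    standardised = float(standard.proportions @ rates)
    return sched, standardised


def propagate_uncertainty(
    cases: CaseCounts,
    model: SeverityModel,
    prevalence_spec: ParameterSpec,
    n_draws: int = 2000,
    seed: int = 0,
) -> BurdenResult:
    """Monte-Carlo YLD uncertainty interval.

    Each draw scales the case counts by (prevalence draw / prevalence point)
    and recomputes the severity-weighted DW from per-class DW draws; the UI
    is the empirical 2.5/97.5 percentile of the per-draw YLD totals and the
    reported point estimate is the draw mean (the deterministic product is
    kept alongside).
    """
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100")
    rng_seeds = np.random.SeedSequence(seed).spawn(len(model.classes) + 1)
    prev_draws = draw_parameters(
        prevalence_spec, n_draws, seed=rng_seeds[0].generate_state(1)[0] % 2**31
    )
    case_scale = prev_draws / prevalence_spec.point
    dw_draws = np.zeros(n_draws)
    for cls, ss in zip(model.classes, rng_seeds[1:]):
        if cls.dw == 0.0:
            continue
        spec = ParameterSpec(
            f"{model.disorder}_{cls.name}_dw", cls.dw, cls.dw_lower95, cls.dw_upper95,
            kind="proportion",
        )
        dw_draws += cls.proportion * draw_parameters(
            spec, n_draws, seed=ss.generate_state(1)[0] % 2**31
        )
    deterministic = cases.total * expected_dw(model)
    totals = cases.total * case_scale * dw_draws
    lower, upper = np.percentile(totals, [2.5, 97.5])
    point = float(totals.mean())
    # guard against float-epsilon inversions when the draws are degenerate
    lower, upper = min(lower, point), max(upper, point)
    log.info(
        "%s YLDs: MC mean %.0f (deterministic %.0f), 95%% UI %.0f–%.0f",
        model.disorder, point, deterministic, lower, upper,
    )
    by_age = cases.cases * expected_dw(model) * (point / deterministic if deterministic else 1.0)
    return BurdenResult(model.disorder, by_age, point, float(lower), float(upper),
                        deterministic=float(deterministic))
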