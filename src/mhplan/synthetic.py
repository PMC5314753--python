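"""Synthetic study inputs: population pyramid, mortality, prevalence, draws.

The real analysis drew its inputs from UN population statistics, GBD 2010
mortality, and a prior meta-regression of disorder prevalence in
conflict-affected populations.  None of those tables ship with this package;
this module generates structurally equivalent stand-ins so every downstream
stage runs offline:

* a young, growing population pyramid (quasi-stable age structure),
* a Gompertz–Makeham all-cause mortality hazard calibrated to a life
  expectancy at birth around 70 years,
* unimodal age-specific prevalence curves peaking in young adults that
  age-standardise *exactly* to a configured target, and
* seeded Monte-Carlo draws whose 2.5/97.5 percentiles reproduce stated
  95% uncertainty intervals (lognormal for rates, beta for proportions).

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .tables import AGES, N_AGES, PopulationTable, RateSchedule

DEFAULT_SEED = 20150101

Z95 = float(stats.norm.ppf(0.975))


# ---------------------------------------------------------------------------
# Mortality
# ---------------------------------------------------------------------------

def make_mortality(
    makeham_a: float = 0.002,
    gompertz_b: float = 5e-5,
    gompertz_theta: float = 0.09,
) -> RateSchedule:
    """Gompertz–Makeham all-cause mortality hazard h(a) = A + B·exp(θ·a).

    Defaults are calibrated so the implied period life expectancy at birth
    falls in the high 60s–low 70s, a plausible all-cause schedule for a
    middle-income population.  Hazards exceeding 2/year before age 100 are
    allowed but flagged as an implausible life table.
    """
    if makeham_a < 0 or gompertz_b <= 0 or gompertz_theta <= 0:
        raise ValueError("require A >= 0, B > 0, theta > 0")
    hazard = makeham_a + gompertz_b * np.exp(gompertz_theta * AGES)
    if np.any(hazard[:-1] > 2.0):
        warnings.warn("mortality hazard exceeds 2/year before age 100; implausible life table")
    return RateSchedule(hazard, name="all_cause_mortality")


def life_expectancy(mortality: RateSchedule) -> float:
    """Period life expectancy at birth from the hazard schedule.

    Survivorship l(a) = exp(-∫h); person-years per age approximated by the
    trapezoid of l at age boundaries, terminal age closed with 1/h(100).
    """
    h = mortality.values
    cum = np.concatenate([[0.0], np.cumsum(h)])
    l = np.exp(-cum)  # l[0..101] at exact ages 0..101
    years = 0.5 * (l[:-1] + l[1:])
    return float(years.sum() + l[-1] / h[-1])


# ---------------------------------------------------------------------------
# Population pyramid
# ---------------------------------------------------------------------------

def make_population(
    total: float,
    shape_params: dict | None = None,
    seed: int = DEFAULT_SEED,
    reference_year: int = 2015,
) -> PopulationTable:
    """Generate a population pyramid with the requested total.

    ``shape_params`` keys:

    kind
        ``"uniform"`` (equal counts per age) or ``"growth"`` (default): a
        quasi-stable pyramid n(a) ∝ exp(-g·a)·l(a) with growth rate ``rate``
        and survivorship l from ``mortality`` (defaults to
        :func:`make_mortality`).
    rate
        intrinsic growth rate per year (default 0.025 — a young pyramid).
    jitter
        multiplicative lognormal noise sd on the smooth shape (default 0);
        seeded, then renormalised so the total is preserved.
    """
    if total <= 0:
        raise ValueError("total population must be positive")
    p = dict(shape_params or {})
    kind = p.get("kind", "growth")
    if kind == "uniform":
        shape = np.ones(N_AGES)
    elif kind == "growth":
        rate = p.get("rate", 0.025)
        mortality = p.get("mortality") or make_mortality()
        cum = np.concatenate([[0.0], np.cumsum(mortality.values[:-1])])
        survivorship = np.exp(-cum)
        shape = np.exp(-rate * AGES) * survivorship
    else:
        raise ValueError(f"unknown pyramid kind {kind!r}")
    jitter = p.get("jitter", 0.0)
    if jitter:
        rng = np.random.default_rng(seed)
        shape = shape * rng.lognormal(0.0, jitter, size=N_AGES)
    counts = shape / shape.sum() * total
    return PopulationTable(counts, reference_year=reference_year)


# ---------------------------------------------------------------------------
# Prevalence curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrevalenceCurve:
    """Age-specific prevalence for one disorder, paired with the population
    it was standardised against."""

    disorder: str
    schedule: RateSchedule
    target_std_prev: float

    @property
    def values(self) -> np.ndarray:
        return self.schedule.values


def _gamma_shape(peak_age: float, spread: float) -> np.ndarray:
    """Unimodal base shape: gamma density parameterised by mode and sd."""
    var = spread**2
    theta = (-peak_age + np.sqrt(peak_age**2 + 4 * var)) / 2
    k = peak_age / theta + 1
    return stats.gamma.pdf(AGES, a=k, scale=theta)


def make_prevalence_curve(
    disorder: str,
    target_std_prev: float,
    population: PopulationTable,
    peak_age: float = 25.0,
    spread: float = 15.0,
    flat: bool = False,
) -> PrevalenceCurve:
    """Unimodal prevalence curve rescaled so its age-standardised summary
    against ``population`` equals ``target_std_prev`` exactly.

    The base shape is a gamma density with mode ``peak_age`` and standard
    deviation ``spread`` (prevalent cases concentrated in adolescents and
    young adults); ``flat=True`` returns the constant curve p_a = target.
    """
    if not 0.0 < target_std_prev < 1.0:
        raise ValueError("target age-standardised prevalence must be in (0, 1)")
    if flat:
        values = np.full(N_AGES, target_std_prev)
    else:
        base = _gamma_shape(peak_age, spread)
        std = float(population.proportions @ base)
        values = base * (target_std_prev / std)
        if np.any(values > 1.0):
            raise ValueError(
                "rescaled prevalence exceeds 1 at some age; widen the curve or lower the target"
            )
    return PrevalenceCurve(disorder, RateSchedule(values, name=f"{disorder}_prevalence"),
                           target_std_prev)


# ---------------------------------------------------------------------------
# Uncertainty draws
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterSpec:
    """A point estimate with a 95% uncertainty interval.

    ``kind`` selects the draw distribution: ``"rate"`` → lognormal (positive,
    unbounded), ``"proportion"`` → beta (bounded in [0, 1]); both are fitted
    so their 2.5/97.5 percentiles match the stated interval.
    """

    name: str
    point: float
    lower95: float
    upper95: float
    kind: str = "rate"

    def __post_init__(self):
        if not self.lower95 <= self.point <= self.upper95:
            raise ValueError(f"{self.name}: require lower95 <= point <= upper95")
        if self.kind not in ("rate", "proportion"):
            raise ValueError(f"{self.name}: kind must be 'rate' or 'proportion'")
        if self.kind == "proportion" and not (0 <= self.lower95 and self.upper95 <= 1):
            raise ValueError(f"{self.name}: proportion bounds must lie in [0, 1]")
        if self.lower95 < 0:
            raise ValueError(f"{self.name}: draws must be non-negative")


def _fit_beta(point: float, lower: float, upper: float) -> tuple[float, float]:
    # moment-based start, then match both interval endpoints exactly
    mean = point
    sd = max((upper - lower) / (2 * Z95), 1e-6)
    v = min(sd**2, mean * (1 - mean) * 0.99)
    nu = mean * (1 - mean) / v - 1
    x0 = np.log([max(mean * nu, 1e-3), max((1 - mean) * nu, 1e-3)])

    def resid(logab):
        a, b = np.exp(logab)
        q = stats.beta.ppf([0.025, 0.975], a, b)
        return np.log(q) - np.log([lower, upper])

    sol = optimize.least_squares(resid, x0, xtol=1e-12, ftol=1e-12)
    return tuple(np.exp(sol.x))


def draw_parameters(spec: ParameterSpec, n_draws: int, seed: int = DEFAULT_SEED) -> np.ndarray:
    """Seeded Monte-Carlo draws reproducing the spec's 95% interval.

    Degenerate intervals (lower = point = upper) return constant draws.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    if spec.upper95 == spec.lower95:
        return np.full(n_draws, spec.point)
    if spec.kind == "rate":
        if spec.lower95 <= 0:
            raise ValueError(f"{spec.name}: lognormal draws need lower95 > 0")
        sigma = (np.log(spec.upper95) - np.log(spec.lower95)) / (2 * Z95)
        mu = (np.log(spec.upper95) + np.log(spec.lower95)) / 2
        return rng.lognormal(mu, sigma, size=n_draws)
    a, b = _fit_beta(spec.point, spec.lower95, spec.upper95)
    return stats.beta.rvs(a, b, size=n_draws, random_state=rng)
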