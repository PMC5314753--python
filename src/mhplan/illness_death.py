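"""Three-state illness-death cohort solver (healthy / diseased / dead).

A closed cohort moves between states under four age-specific hazards:
incidence i (healthy→diseased), remission r (diseased→healthy), background
mortality m (both states→dead) and excess case mortality f (diseased→dead,
on top of m).  Within each one-year age step the hazards are held constant
and the linear system

    dS/dt = -(i+m)·S + r·C
    dC/dt =  i·S - (r+m+f)·C
    dD/dt =  m·S + (m+f)·C

is solved exactly with a matrix exponential, so competing risks are handled
consistently and total mass S+C+D is conserved to machine precision.

The inverse problem — back-calculating an internally consistent incidence
schedule from a target prevalence curve given remission and mortality — is
solved age by age with a bisection on i(a), clamping at zero (with a
diagnostic) where prevalence declines faster than remission plus mortality
can explain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import expm

from .tables import AGES, N_AGES, RateSchedule

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HazardSet:
    """Age-indexed transition hazards on the 0..100 grid, per person-year."""

    incidence: RateSchedule
    remission: RateSchedule
    excess_mortality: RateSchedule
    background_mortality: RateSchedule

    def __post_init__(self):
        for name in ("incidence", "remission", "excess_mortality", "background_mortality"):
            vals = getattr(self, name).values
            if np.any(vals < 0):
                raise ValueError(f"{name} hazards must be non-negative")

    def at(self, age: float) -> tuple[float, float, float, float]:
        """(i, r, f, m) at a possibly fractional age (linear interpolation,
        clamped at the terminal age)."""
        a = min(age, AGES[-1])
        return (
            self.incidence.at(a),
            self.remission.at(a),
            self.excess_mortality.at(a),
            self.background_mortality.at(a),
        )


@dataclass(frozen=True)
class StateVector:
    """Occupancy of the three states, in persons."""

    healthy: float
    diseased: float
    dead: float = 0.0

    def __post_init__(self):
        if min(self.healthy, self.diseased, self.dead) < -1e-9:
            raise ValueError("state occupancies must be non-negative")

    @property
    def alive(self) -> float:
        return self.healthy + self.diseased

    @property
    def total(self) -> float:
        return self.alive + self.dead

    @property
    def prevalence(self) -> float:
        if self.alive <= 0:
            raise ZeroDivisionError("cohort extinct: no survivors to take prevalence over")
        return self.diseased / self.alive


@dataclass(frozen=True)
class MortalityRisk:
    """Relative risk of all-cause mortality among cases (RR >= 1)."""

    rr: float

    def __post_init__(self):
        if self.rr < 1.0:
            raise ValueError("mortality RR < 1 (protective effects) not supported")


def excess_mortality_from_rr(
    background: RateSchedule, risk: MortalityRisk
) -> RateSchedule:
    """f(a) = m(a)·(RR − 1), so the total case hazard m+f equals RR·m."""
    return RateSchedule(background.values * (risk.rr - 1.0), name="excess_mortality")


def _transition_matrix(i: float, r: float, f: float, m: float, dt: float = 1.0) -> np.ndarray:
    if min(i, r, f, m) < 0:
        raise ValueError("hazards must be non-negative")
    gen = np.array(
        [
            [-(i + m), r, 0.0],
            [i, -(r + m + f), 0.0],
            [m, m + f, 0.0],
        ]
    )
    return expm(gen * dt)


def step_year(state: StateVector, i: float, r: float, f: float, m: float) -> StateVector:
    """Advance the cohort one year under constant within-year hazards."""
    vec = _transition_matrix(i, r, f, m) @ np.array(
        [state.healthy, state.diseased, state.dead]
    )
    return StateVector(*np.maximum(vec, 0.0))


def solve_forward(
    hazards: HazardSet, initial: StateVector, age_start: int, age_stop: int
) -> RateSchedule:
    """Propagate from ``age_start`` to ``age_stop`` and return prevalence
    among survivors at each age of the full 0..100 grid (zero outside the
    propagated range, the initial prevalence at ``age_start``)."""
    if not 0 <= age_start < age_stop <= 100:
        raise ValueError("require 0 <= age_start < age_stop <= 100")
    prev = np.zeros(N_AGES)
    state = initial
    prev[age_start] = state.prevalence
    for a in range(age_start, age_stop):
        state = step_year(state, *hazards.at(a))
        prev[a + 1] = state.prevalence
    return RateSchedule(prev, name="prevalence")


def fit_incidence(
    target_prevalence: RateSchedule,
    remission: RateSchedule,
    excess_mortality: RateSchedule,
    background_mortality: RateSchedule,
    age_start: int = 0,
    age_stop: int = 100,
    tol: float = 1e-8,
    max_iter: int = 200,
    i_max: float = 10.0,
) -> RateSchedule:
    """Back-calculate incidence i(a) consistent with a prevalence curve.

    Starting a unit cohort at the target prevalence at ``age_start``, each
    age's incidence is found by bisection on [0, i_max] such that one year
    of propagation lands exactly on the target prevalence at the next age.
    Where even i = 0 overshoots (prevalence falls faster than remission and
    mortality allow) the incidence is clamped at zero and the age logged.
    """
    p = target_prevalence.values
    if np.any((p < 0) | (p >= 1)):
        raise ValueError("target prevalence must lie in [0, 1)")
    incidence = np.zeros(N_AGES)
    clamped: list[int] = []
    state = StateVector(1.0 - p[age_start], p[age_start])
    for a in range(age_start, age_stop):
        r, fx, m = remission.values[a], excess_mortality.values[a], background_mortality.values[a]
        target = p[a + 1]

        def prev_after(i: float) -> float:
            return step_year(state, i, r, fx, m).prevalence

        lo, hi = 0.0, i_max
        if prev_after(0.0) >= target:
            incidence[a] = 0.0
            if prev_after(0.0) > target + tol:
                clamped.append(a)
        elif prev_after(i_max) < target:
            raise RuntimeError(
                f"fit_incidence: no incidence in [0, {i_max}] reaches prevalence "
                f"{target} at age {a + 1}"
            )
        else:
            for _ in range(max_iter):
                mid = 0.5 * (lo + hi)
                if prev_after(mid) < target:
                    lo = mid
                else:
                    hi = mid
                if hi - lo < tol:
                    break
            else:
                raise RuntimeError(f"fit_incidence: no convergence at age {a}")
            incidence[a] = 0.5 * (lo + hi)
        state = step_year(state, incidence[a], r, fx, m)
    if clamped:
        log.warning(
            "fit_incidence: incidence clamped at 0 at %d ages (prevalence declines "
            "faster than remission+mortality allow): %s",
            len(clamped), clamped[:10],
        )
    # hold the last fitted value on the terminal tail so the schedule is defined 0..100
    incidence[age_stop:] = incidence[age_stop - 1]
    return RateSchedule(incidence, name="incidence")
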