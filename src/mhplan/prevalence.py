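"""Prevalent cases and the PTSD/depression comorbidity partition.

Age-standardised prevalence inputs are turned into age-specific prevalent
cases (prevalence × population, age by age) and split into mutually
exclusive groups — PTSD only, depression only, comorbid — given the
proportion of PTSD cases that also meet criteria for depression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .synthetic import PrevalenceCurve
from .tables import CaseCounts, PopulationTable, RateSchedule

log = logging.getLogger(__name__)


def age_standardise(rates: RateSchedule, standard: PopulationTable) -> float:
    """Population-weighted mean rate: Σ_a (n_a/N)·rate_a."""
    return float(standard.proportions @ rates.values)


def prevalent_cases(curve: PrevalenceCurve, population: PopulationTable) -> CaseCounts:
    """cases_a = p_a × n_a."""
    return CaseCounts(curve.disorder, curve.values * population.counts)


@dataclass(frozen=True)
class ComorbiditySpec:
    """Proportion of PTSD cases comorbid with depression (scalar rho)."""

    rho: float = 0.50

    def __post_init__(self):
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("comorbidity proportion rho must be in [0, 1]")


def comorbidity_partition(
    ptsd: CaseCounts,
    depression: CaseCounts,
    spec: ComorbiditySpec = ComorbiditySpec(),
) -> dict[str, CaseCounts]:
    """Partition cases into {ptsd_only, depression_only, comorbid, combined}.

    Comorbid cases are rho × PTSD cases age by age, clamped at the depression
    case count where rho·PTSD would exceed it (logged); the combined total is
    PTSD + depression − comorbid, so ptsd_only + depression_only + comorbid
    = combined at every age.
    """
    comorbid = spec.rho * ptsd.cases
    excess = comorbid > depression.cases + 1e-9
    if np.any(excess):
        ages = np.nonzero(excess)[0]
        log.warning(
            "comorbid cases clamped at depression cases at %d ages (first: %d)",
            ages.size, ages[0],
        )
        comorbid = np.minimum(comorbid, depression.cases)
    combined = ptsd.cases + depression.cases - comorbid
    return {
        "ptsd_only": CaseCounts("ptsd_only", ptsd.cases - comorbid),
        "depression_only": CaseCounts("depression_only", depression.cases - comorbid),
        "comorbid": CaseCounts("comorbid", comorbid),
        "combined": CaseCounts("combined", combined),
    }
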