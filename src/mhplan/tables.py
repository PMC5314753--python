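"""Age-indexed containers shared across the pipeline.

Everything downstream works on a single-year age grid 0..100 (101 rows,
age 100 treated as a closed terminal age).  Two containers cover all
tabular exchange: :class:`PopulationTable` for person counts and
:class:`RateSchedule` for any age-indexed rate, hazard, proportion or
per-age quantity (prevalence, mortality, incidence, remission, YLDs).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

AGE_MIN = 0
AGE_MAX = 100
AGES = np.arange(AGE_MIN, AGE_MAX + 1)
N_AGES = AGES.size


class AgeGridError(ValueError):
    """Raised when a table does not cover the contiguous 0..100 age grid."""


def _as_grid(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (N_AGES,):
        raise AgeGridError(
            f"{name} must have {N_AGES} entries for ages {AGE_MIN}..{AGE_MAX}, "
            f"got shape {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise AgeGridError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class PopulationTable:
    """Person counts by single year of age, 0..100 inclusive.

    ``female_share`` is a scalar female proportion applied uniformly when a
    female slice is needed (the perinatal eligibility step); the model is
    otherwise sex-aggregated.
    """

    counts: np.ndarray
    reference_year: int = 2015
    female_share: float = 0.494

    def __post_init__(self):
        arr = _as_grid(self.counts, "population counts")
        if np.any(arr < 0):
            raise ValueError("population counts must be non-negative")
        if not 0.0 <= self.female_share <= 1.0:
            raise ValueError("female_share must be in [0, 1]")
        object.__setattr__(self, "counts", arr)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        """Age weights w_a = n_a / N used for age-standardisation."""
        return self.counts / self.total

    def band(self, lo: int, hi: int) -> float:
        """Total persons aged ``lo``..``hi`` inclusive."""
        if not (AGE_MIN <= lo <= hi <= AGE_MAX):
            raise ValueError(f"band [{lo}, {hi}] outside {AGE_MIN}..{AGE_MAX}")
        return float(self.counts[lo : hi + 1].sum())

    def women(self, lo: int, hi: int) -> float:
        return self.band(lo, hi) * self.female_share

    def scaled(self, factor: float) -> "PopulationTable":
        return replace(self, counts=self.counts * factor)


@dataclass(frozen=True)
class RateSchedule:
    """An age-indexed vector of rates/hazards/proportions on ages 0..100."""

    values: np.ndarray
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "values", _as_grid(self.values, self.name or "rates"))

    def at(self, age: float) -> float:
        """Value at (possibly fractional) age, linearly interpolated, clamped
        to the terminal age beyond 100."""
        return float(np.interp(age, AGES, self.values))

    def __mul__(self, factor: float) -> "RateSchedule":
        return RateSchedule(self.values * factor, name=self.name)

    __rmul__ = __mul__


@dataclass(frozen=True)
class CaseCounts:
    """Prevalent cases by age for one disorder/group."""

    label: str
    cases: np.ndarray

    def __post_init__(self):
        arr = _as_grid(self.cases, f"{self.label} cases")
        if np.any(arr < -1e-9):
            raise ValueError(f"{self.label} cases must be non-negative")
        object.__setattr__(self, "cases", np.maximum(arr, 0.0))

    @property
    def total(self) -> float:
        return float(self.cases.sum())

    def band_total(self, lo: int, hi: int) -> float:
        return float(self.cases[lo : hi + 1].sum())


# ---------------------------------------------------------------------------
# CSV exchange: headered (age, value) tables
# ---------------------------------------------------------------------------

def read_age_table(path, value_column: str | None = None) -> np.ndarray:
    """Read a headered CSV with columns (age, <value>) into a 0..100 vector.

    Enforces a contiguous single-year grid; duplicate or missing ages raise
    with the offending ages named.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise AgeGridError(f"{path}: expected columns (age, value)")
    age_col = df.columns[0]
    val_col = value_column or df.columns[1]
    ages = df[age_col].to_numpy()
    dup = pd.Series(ages)[pd.Series(ages).duplicated()].unique()
    if dup.size:
        raise AgeGridError(f"{path}: duplicate age {', '.join(str(int(a)) for a in dup)}")
    missing = sorted(set(AGES.tolist()) - set(int(a) for a in ages))
    extra = sorted(set(int(a) for a in ages) - set(AGES.tolist()))
    if missing or extra:
        raise AgeGridError(
            f"{path}: age grid must be contiguous 0..100 "
            f"(missing {missing[:5]}{'...' if len(missing) > 5 else ''}, extra {extra[:5]})"
        )
    order = np.argsort(ages)
    return df[val_col].to_numpy(dtype=float)[order]


def write_age_table(path, values, value_column: str = "value") -> None:
    pd.DataFrame({"age": AGES, value_column: _as_grid(values, value_column)}).to_csv(
        path, index=False
    )
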