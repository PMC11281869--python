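"""Smoking-behavior strata and cohort construction.

The evaluation populations are cohorts with *uniform* smoking behavior:
every individual shares the same start age, quit age and intensity, so that
differences between model profiles and screening scenarios are never
confounded by population composition.  Two canonical strata are bundled:

* ``heavy`` — started at 15, 30 cigarettes/day, never quit
  (75 pack-years accumulated by age 65, still smoking), and
* ``light`` — started at 15, 10 cigarettes/day, quit at 55
  (20 pack-years by 65, quit 10 years prior).

Other-cause death is fixed at a single age (default 100) for everyone, which
deliberately removes smoking-related competing mortality from scenario
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

CIGARETTES_PER_PACK = 20.0


class ConfigurationError(ValueError):
    """Raised when a population spec or model profile is invalid."""


@dataclass(frozen=True)
class SmokingHistory:
    """A deterministic lifetime smoking trajectory.

    Parameters
    ----------
    start_age : float
        Age (years) at smoking initiation.
    quit_age : float or None
        Age at cessation; ``None`` means never quits.
    cigarettes_per_day : float
        Constant intensity over the smoking period.
    """

    start_age: float
    quit_age: Optional[float]
    cigarettes_per_day: float

    def __post_init__(self) -> None:
        if self.cigarettes_per_day < 0:
            raise ConfigurationError("cigarettes_per_day must be >= 0")
        if self.quit_age is not None and not self.start_age < self.quit_age:
            raise ConfigurationError("start_age must be < quit_age")


#: Canonical strata used throughout the evaluation.
HEAVY = SmokingHistory(start_age=15.0, quit_age=None, cigarettes_per_day=30.0)
LIGHT = SmokingHistory(start_age=15.0, quit_age=55.0, cigarettes_per_day=10.0)
NEVER = SmokingHistory(start_age=0.0, quit_age=None, cigarettes_per_day=0.0)

SMOKING_LABELS = {"heavy": HEAVY, "light": LIGHT, "never": NEVER}


def resolve_smoking(smoking: Union[str, SmokingHistory]) -> SmokingHistory:
    """Map a canonical label ('heavy'/'light'/'never') or an explicit history."""
    if isinstance(smoking, SmokingHistory):
        return smoking
    try:
        return SMOKING_LABELS[smoking]
    except KeyError:
        raise ConfigurationError(
            f"unknown smoking label {smoking!r}; expected one of {sorted(SMOKING_LABELS)}"
        ) from None


def smoking_label(history: SmokingHistory) -> str:
    """Canonical label for a history, or 'custom' if it matches no bundled stratum."""
    for name, h in SMOKING_LABELS.items():
        if h == history:
            return name
    return "custom"


def pack_years(history: SmokingHistory, age) -> Union[float, np.ndarray]:
    """Cumulative pack-years smoked by ``age`` (20 cigarettes = 1 pack).

    Clamps at zero before the start age and is constant after the quit age,
    hence non-decreasing in age.  Accepts scalar or array ages.
    """
    age = np.asarray(age, dtype=float)
    end = age if history.quit_age is None else np.minimum(age, history.quit_age)
    years = np.clip(end - history.start_age, 0.0, None)
    out = years * history.cigarettes_per_day / CIGARETTES_PER_PACK
    return float(out) if out.ndim == 0 else out


def is_current_smoker(history: SmokingHistory, age) -> Union[bool, np.ndarray]:
    """Whether the person smokes at ``age`` (half-open period [start, quit))."""
    age = np.asarray(age, dtype=float)
    active = (age >= history.start_age) & (history.cigarettes_per_day > 0)
    if history.quit_age is not None:
        active &= age < history.quit_age
    return bool(active) if active.ndim == 0 else active


@dataclass(frozen=True)
class PopulationSpec:
    """One evaluated population: a sex stratum x a uniform smoking behavior.

    ``sex='both'`` is an exactly balanced 50/50 mix, assigned deterministically
    by index parity so scenario comparisons are free of compositional noise.
    """

    sex: str = "both"
    smoking: Union[str, SmokingHistory] = "heavy"
    n_individuals: int = 200_000
    other_cause_death_age: float = 100.0

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female", "both"):
            raise ConfigurationError(f"sex must be male/female/both, got {self.sex!r}")
        if int(self.n_individuals) < 1:
            raise ConfigurationError("n_individuals must be >= 1")
        if not self.other_cause_death_age > 65:
            raise ConfigurationError("other_cause_death_age must exceed 65")
        resolve_smoking(self.smoking)  # validate eagerly

    @property
    def smoking_history(self) -> SmokingHistory:
        return resolve_smoking(self.smoking)

    @property
    def smoking_name(self) -> str:
        return self.smoking if isinstance(self.smoking, str) else smoking_label(self.smoking)


def make_cohort(spec: PopulationSpec, seed: int) -> pd.DataFrame:
    """Instantiate a cohort of identically specified individuals.

    Returns a DataFrame with one row per individual (``id``, ``sex``) whose
    ``attrs`` carry the spec and the seed.  All randomness downstream is
    drawn from counter-based substreams reproducible from ``(seed, id)``
    (see :mod:`mclir._rng`), so the same ``(spec, seed)`` always yields a
    bit-identical cohort and life histories.
    """
    if not isinstance(spec, PopulationSpec):
        raise ConfigurationError("spec must be a PopulationSpec")
    seed = int(seed)
    if not 0 <= seed < 2**63:
        raise ConfigurationError("seed must be a non-negative integer")
    n = int(spec.n_individuals)
    ids = np.arange(n, dtype=np.int64)
    if spec.sex == "both":
        sex = np.where(ids % 2 == 0, "male", "female")
    else:
        sex = np.full(n, spec.sex, dtype=object)
    cohort = pd.DataFrame({"id": ids, "sex": sex})
    cohort.attrs["spec"] = spec
    cohort.attrs["seed"] = seed
    return cohort
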