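"""The four counterfactual one-time-screen scenarios under common random numbers.

A single CT screen at age 65 is compared across four worlds sharing identical
life histories and identical random draws:

========================  ===================  ==================
scenario                  test sensitivity     treatment of
                                               screen detections
========================  ===================  ==================
``NoScreen``              (no screen)          --
``RealSensRealTreat``     stage-specific       observed effectiveness
``RealSensPerfectTreat``  stage-specific       perfect (never die of LC)
``PerfectSensTreat``      100% in every stage  perfect
========================  ===================  ==================

Detection uses a single reserved uniform per individual compared against the
stage-specific sensitivity (inverse-CDF coupling), so the two realistic-
sensitivity scenarios detect *exactly* the same cancers and every detection
set is nested inside the perfect-sensitivity one for every seed.  Scenario
differences are therefore exact per-individual counterfactuals, not
asymptotic Monte-Carlo contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .natural_history import DEFAULT_SCREEN_AGE, simulate_life_histories
from .population import ConfigurationError, PopulationSpec, make_cohort
from .profiles import NaturalHistoryProfile

SCENARIO_NAMES = (
    "NoScreen",
    "RealSensRealTreat",
    "RealSensPerfectTreat",
    "PerfectSensTreat",
)

_MODES = {
    "NoScreen": (None, None),
    "RealSensRealTreat": ("realistic", "realistic"),
    "RealSensPerfectTreat": ("realistic", "perfect"),
    "PerfectSensTreat": ("perfect", "perfect"),
}

OUTCOME_COLUMNS = ["id", "detection_mode", "dx_age", "dx_stage", "lead_time", "lc_death_age"]


@dataclass(frozen=True)
class ScenarioSpec:
    """One scenario; the name fixes the sensitivity/treatment mode pair."""

    name: str
    screen_age: float = DEFAULT_SCREEN_AGE

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ConfigurationError(
                f"unknown scenario {self.name!r}; expected one of {SCENARIO_NAMES}"
            )
        if not 18.0 < self.screen_age:
            raise ConfigurationError("screen_age must be an adult age")

    @property
    def sensitivity_mode(self) -> Optional[str]:
        return _MODES[self.name][0]

    @property
    def treatment_mode(self) -> Optional[str]:
        return _MODES[self.name][1]


def _strata_sensitivities(
    life: pd.DataFrame, profile: NaturalHistoryProfile
) -> np.ndarray:
    """Per-row (n, 4) stage sensitivities with sex/smoking modifiers applied."""
    label = life.attrs["spec"].smoking_name
    s_m = np.asarray(profile.sensitivities_for("male", label))
    s_f = np.asarray(profile.sensitivities_for("female", label))
    female = (life["sex"].to_numpy() == "female")[:, None]
    return np.where(female, s_f, s_m)


def screen_result(
    life: pd.DataFrame,
    spec: ScenarioSpec,
    sensitivities: Union[np.ndarray, list, None] = None,
    profile: Optional[NaturalHistoryProfile] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Screen-detection flags and preclinical stages at the screen.

    A cancer is screen detected iff it is preclinical at the screen age
    (``onset < screen_age < clinical_age``) and the individual's reserved
    detection uniform falls below the sensitivity of its stage at the screen.
    Perfect mode uses sensitivity 1 for every stage.  The same uniform is used
    in every scenario, which is the nesting contract.
    """
    if spec.name == "NoScreen":
        n = len(life)
        return np.zeros(n, dtype=bool), life["screen_stage"].to_numpy()
    preclin = life["preclinical_at_screen"].to_numpy() & ~life["excluded"].to_numpy()
    stage = life["screen_stage"].to_numpy()
    if spec.sensitivity_mode == "perfect":
        return preclin.copy(), stage
    if sensitivities is None:
        if profile is None:
            raise ConfigurationError("realistic mode needs sensitivities or a profile")
        sens = _strata_sensitivities(life, profile)
    else:
        sens = np.asarray(sensitivities, dtype=float)
        if sens.ndim == 1:
            sens = np.tile(sens, (len(life), 1))
    safe = np.where(preclin, stage, 1)
    s_row = sens[np.arange(len(life)), safe - 1]
    detected = preclin & (life["detection_u"].to_numpy() < s_row)
    return detected, stage


def run_scenario(
    life: pd.DataFrame,
    spec: ScenarioSpec,
    profile: NaturalHistoryProfile,
) -> pd.DataFrame:
    """Realize one scenario for every (non-excluded) individual.

    Screen-detected cancers are diagnosed at the screen age in their
    preclinical stage; under realistic treatment their survival comes from the
    pre-drawn stage-at-detection draw on a reserved substream (shared across
    scenarios), under perfect treatment they never die of lung cancer.
    Everyone else follows the clinical course unchanged.
    """
    keep = ~life["excluded"].to_numpy()
    sub = life.loc[keep]
    n = len(sub)
    has_dx = (~sub["clinical_age"].isna()).to_numpy() & (
        sub["clinical_age"].to_numpy() < sub["other_cause_death_age"].to_numpy()
    )

    detected, _ = screen_result(life, spec, profile=profile)
    detected = detected[keep]

    mode = np.where(detected, "screen", np.where(has_dx, "clinical", "none"))
    dx_age = np.where(
        detected, spec.screen_age, np.where(has_dx, sub["clinical_age"], np.nan)
    )
    dx_stage = np.where(
        detected,
        sub["screen_stage"].to_numpy(),
        np.where(has_dx, sub["clinical_stage"].to_numpy(), 0),
    ).astype(int)
    lead = np.where(detected, sub["clinical_age"].to_numpy() - spec.screen_age, np.nan)

    clin_death = sub["clinical_death_age"].to_numpy()
    if spec.name == "NoScreen":
        lc_death = clin_death
    elif spec.treatment_mode == "perfect":
        lc_death = np.where(detected, np.nan, clin_death)
    else:
        lc_death = np.where(
            detected, sub["screen_death_age_realistic"].to_numpy(), clin_death
        )
    lc_death = np.where(has_dx | detected, lc_death, np.nan)

    out = pd.DataFrame(
        {
            "id": sub["id"].to_numpy(),
            "detection_mode": mode,
            "dx_age": dx_age,
            "dx_stage": dx_stage,
            "lead_time": lead,
            "lc_death_age": lc_death,
        }
    )
    out.attrs.update(life.attrs)
    out.attrs["scenario"] = spec.name
    out.attrs["screen_age"] = float(spec.screen_age)
    out.attrs["n_eligible"] = int(n)
    return out


def run_all_scenarios(
    cohort_or_spec: Union[pd.DataFrame, PopulationSpec],
    profile: NaturalHistoryProfile,
    seed: Optional[int] = None,
    screen_age: float = DEFAULT_SCREEN_AGE,
) -> Tuple[pd.DataFrame, Dict[str, pd.DataFrame]]:
    """Simulate the shared life histories and all four scenario outcomes.

    Accepts either a ready cohort frame (seed taken from its attrs) or a
    :class:`PopulationSpec` plus an explicit seed.  Deterministic given
    (profile, population spec, seed).
    """
    if isinstance(cohort_or_spec, PopulationSpec):
        if seed is None:
            raise ConfigurationError("seed is required when passing a PopulationSpec")
        cohort = make_cohort(cohort_or_spec, seed)
    else:
        cohort = cohort_or_spec
    life = simulate_life_histories(cohort, profile, screen_age=screen_age)
    outcomes = {
        name: run_scenario(life, ScenarioSpec(name, screen_age), profile)
        for name in SCENARIO_NAMES
    }
    return life, outcomes
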