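"""Model-profile definition, validation, and the five bundled profiles.

A *profile* is the complete parameterisation of one natural-history model:
onset hazard, sojourn-time distribution, stage dwell partition, stage-specific
screening sensitivities, stage-specific survival, and sex/smoking strata
modifiers.  Profiles are declarative YAML documents validated against a strict
schema (unknown keys rejected), so two profiles run on the same population and
seed differ only through their parameters.

Five profiles named ``*-like`` after the CISNET lung models are bundled.  They
carry each model's published stage-specific screening sensitivities; every
other parameter is an illustrative default (``calibration_status:
illustrative``) because the models' internal calibrations are not public.
"""

from __future__ import annotations

import importlib.resources
import json
from pathlib import Path
from typing import List, Literal, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .population import ConfigurationError

SCHEMA_VERSION = 1

STAGES = ("I", "II", "III", "IV")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class OnsetHazard(_Strict):
    """Tumor-onset hazard: a baseline age shape times a log-linear smoking dose
    response, ``h(a) = h0(a) * exp(b_py * packyears(a) + b_cur * current(a)) * m_sex``."""

    family: Literal["weibull", "constant"] = "weibull"
    shape: float = Field(default=1.0, gt=0)
    scale: float = Field(default=100.0, gt=0)  # years (weibull) -- ignored for constant
    rate: float = Field(default=0.0, ge=0)     # per-year baseline (constant family)
    beta_pack_years: float = Field(default=0.0, ge=0)  # log-hazard per pack-year
    beta_current_smoker: float = 0.0           # log-hazard while currently smoking
    sex_multiplier_female: float = Field(default=1.0, gt=0)


class SojournComponent(_Strict):
    family: Literal["exponential", "weibull", "lognormal", "fixed"]
    weight: float = Field(default=1.0, gt=0)
    mean: float = Field(default=2.0, gt=0)      # exponential mean / fixed value
    shape: float = Field(default=1.5, gt=0)     # weibull shape
    scale: float = Field(default=2.0, gt=0)     # weibull scale
    mu: float = 0.7                              # lognormal log-mean
    sigma: float = Field(default=0.5, gt=0)      # lognormal log-sd


class SojournDist(_Strict):
    """Preclinical sojourn-time distribution; a two-component mixture is the
    aggressiveness knob (short-sojourn aggressive + long-sojourn indolent)."""

    family: Literal["exponential", "weibull", "lognormal", "fixed", "mixture"]
    mean: float = Field(default=2.0, gt=0)
    shape: float = Field(default=1.5, gt=0)
    scale: float = Field(default=2.0, gt=0)
    mu: float = 0.7
    sigma: float = Field(default=0.5, gt=0)
    components: Optional[List[SojournComponent]] = None

    @model_validator(mode="after")
    def _check_mixture(self):
        if self.family == "mixture":
            if not self.components or len(self.components) != 2:
                raise ValueError("mixture sojourn_dist requires exactly 2 components")
        elif self.components is not None:
            raise ValueError("components only valid for family=mixture")
        return self


class StageDwell(_Strict):
    """Partition of preclinical progression into stage I-IV dwell times.

    ``fractions`` split a progression span into consecutive stage dwells.  The
    span defaults to the individual's sojourn time (so the fractions partition
    the sojourn exactly); setting ``progression_span`` to a fixed number of
    years decouples progression speed from sojourn length, making the clinical
    stage increase with sojourn time and leaving late-stage entries unreached
    for short sojourns.
    """

    fractions: List[float] = Field(min_length=4, max_length=4)
    mode: Literal["fixed", "dirichlet"] = "fixed"
    concentration: float = Field(default=50.0, gt=0)
    progression_span: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _check_fractions(self):
        if any(f < 0 for f in self.fractions):
            raise ValueError("stage dwell fractions must be non-negative")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("stage dwell fractions must sum to 1")
        return self


class Sensitivity(_Strict):
    by_stage: List[float] = Field(min_length=4, max_length=4)

    @model_validator(mode="after")
    def _check_probs(self):
        if any(not 0 <= s <= 1 for s in self.by_stage):
            raise ValueError("stage sensitivities must lie in [0, 1]")
        return self


class DeathTime(_Strict):
    """Time-to-lung-cancer-death distribution for non-cured cases, by stage."""

    family: Literal["exponential", "weibull", "fixed"] = "exponential"
    mean_by_stage: List[float] = Field(default=[5.0, 4.0, 2.5, 1.2], min_length=4, max_length=4)
    shape: float = Field(default=1.3, gt=0)  # weibull only; scale derived from mean

    @model_validator(mode="after")
    def _check_means(self):
        if any(m <= 0 for m in self.mean_by_stage):
            raise ValueError("death-time means must be positive")
        return self


class Survival(_Strict):
    cure_by_stage: List[float] = Field(min_length=4, max_length=4)
    cure_order_override: bool = False
    death_time: DeathTime = DeathTime()

    @model_validator(mode="after")
    def _check_cure(self):
        c = self.cure_by_stage
        if any(not 0 <= x <= 1 for x in c):
            raise ValueError("cure probabilities must lie in [0, 1]")
        if not self.cure_order_override and any(c[i] < c[i + 1] for i in range(3)):
            raise ValueError(
                "cure probabilities must be non-increasing across stages "
                "(set cure_order_override: true to allow)"
            )
        return self


class ScreenDetectionSurvival(_Strict):
    """How screen detection alters survival: via the stage shift alone, or with
    an additional within-stage cure-probability boost."""

    mode: Literal["stage_shift_only", "stage_shift_plus_cure_boost"] = "stage_shift_only"
    cure_boost: float = Field(default=1.0, ge=1.0)

    @model_validator(mode="after")
    def _check(self):
        if self.mode == "stage_shift_only" and self.cure_boost != 1.0:
            raise ValueError("cure_boost requires mode=stage_shift_plus_cure_boost")
        return self


class StratumModifier(_Strict):
    sojourn_scale: float = Field(default=1.0, gt=0)
    sensitivity_scale: float = Field(default=1.0, gt=0)  # capped at 1 after scaling
    cure_scale: float = Field(default=1.0, gt=0)         # capped at 1 after scaling


class Modifiers(_Strict):
    female: StratumModifier = StratumModifier()
    smoking: dict[str, StratumModifier] = {}


class NaturalHistoryProfile(_Strict):
    """Fully validated natural-history model profile."""

    schema_version: int = SCHEMA_VERSION
    profile_name: str
    calibration_status: Literal["illustrative", "calibrated"] = "illustrative"
    long_sojourn_tail: bool = False
    onset_hazard: OnsetHazard
    sojourn_dist: SojournDist
    stage_dwell: StageDwell
    sensitivity: Sensitivity
    survival: Survival
    screen_detection_survival: ScreenDetectionSurvival = ScreenDetectionSurvival()
    modifiers: Modifiers = Modifiers()

    @model_validator(mode="after")
    def _check_version(self):
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported schema_version {self.schema_version}; expected {SCHEMA_VERSION}"
            )
        return self

    # -- strata-resolved parameters ------------------------------------

    def sojourn_scale_for(self, sex: str, smoking: str) -> float:
        m = 1.0
        if sex == "female":
            m *= self.modifiers.female.sojourn_scale
        if smoking in self.modifiers.smoking:
            m *= self.modifiers.smoking[smoking].sojourn_scale
        return m

    def sensitivities_for(self, sex: str, smoking: str) -> List[float]:
        m = 1.0
        if sex == "female":
            m *= self.modifiers.female.sensitivity_scale
        if smoking in self.modifiers.smoking:
            m *= self.modifiers.smoking[smoking].sensitivity_scale
        return [min(1.0, s * m) for s in self.sensitivity.by_stage]

    def cure_for(self, sex: str, smoking: str) -> List[float]:
        m = 1.0
        if sex == "female":
            m *= self.modifiers.female.cure_scale
        if smoking in self.modifiers.smoking:
            m *= self.modifiers.smoking[smoking].cure_scale
        return [min(1.0, c * m) for c in self.survival.cure_by_stage]


def profile_from_dict(data: dict) -> NaturalHistoryProfile:
    """Validate a raw mapping into a profile, with field-level errors."""
    try:
        return NaturalHistoryProfile.model_validate(data)
    except ValidationError as exc:
        raise ConfigurationError(f"invalid model profile:\n{exc}") from exc


def load_profile(path: Union[str, Path]) -> NaturalHistoryProfile:
    """Load and validate a profile from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"profile file {path} is not a mapping")
    return profile_from_dict(data)


def dump_profile(profile: NaturalHistoryProfile, path: Union[str, Path]) -> None:
    """Write a profile back to YAML; round-trips field-for-field."""
    with open(path, "w") as fh:
        yaml.safe_dump(profile.model_dump(mode="json"), fh, sort_keys=False)


BUILTIN_NAMES = ("miscan-like", "uombcc-like", "lcos-like", "lcpm-like", "oncosim-like")


def _bundled_path(name: str):
    return importlib.resources.files("mclir").joinpath("profiles", f"{name}.yaml")


def builtin_profile(name: str) -> NaturalHistoryProfile:
    """Load one bundled illustrative profile by name."""
    if name not in BUILTIN_NAMES:
        raise ConfigurationError(f"unknown builtin profile {name!r}; have {BUILTIN_NAMES}")
    with importlib.resources.as_file(_bundled_path(name)) as p:
        return load_profile(p)


def builtin_profiles() -> List[NaturalHistoryProfile]:
    """The five bundled illustrative profiles (Table-2 sensitivities)."""
    return [builtin_profile(name) for name in BUILTIN_NAMES]


def resolve_profile(name_or_path: Union[str, Path]) -> NaturalHistoryProfile:
    """Accept either a bundled profile name or a path to a YAML file."""
    if isinstance(name_or_path, str) and name_or_path in BUILTIN_NAMES:
        return builtin_profile(name_or_path)
    return load_profile(name_or_path)


def json_schema() -> dict:
    """JSON schema for profile files (shipped for external validation)."""
    return NaturalHistoryProfile.model_json_schema()


def write_json_schema(path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(json_schema(), indent=2))
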