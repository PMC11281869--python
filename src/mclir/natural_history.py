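"""No-screening natural course of disease for every individual in a cohort.

The simulator draws, for each individual: a tumor onset age from a
smoking-dose-responsive hazard; a preclinical sojourn time (onset to clinical
diagnosis in the absence of screening); a stage I-IV progression schedule
within the preclinical window; and post-diagnosis survival (cure, or a
time to lung-cancer death).  Everything is continuous-time; other-cause death
censors all later events.

All draws are inverse-CDF transforms of per-purpose uniforms from
:mod:`mclir._rng`, which is what makes the screening scenarios in
:mod:`mclir.scenarios` exactly nested counterfactuals of the same life.
One uniform per individual is *reserved* for screen detection and never used
here.
"""

from __future__ import annotations

import math
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import cumulative_trapezoid
from scipy.special import ndtri

from ._rng import cohort_uniforms, purpose_stream
from .population import (
    ConfigurationError,
    PopulationSpec,
    SmokingHistory,
    is_current_smoker,
    pack_years,
)
from .profiles import NaturalHistoryProfile, OnsetHazard, SojournDist

DEFAULT_SCREEN_AGE = 65.0
_AGE_GRID_STEP = 0.05
_TINY = 1e-12


# ---------------------------------------------------------------------------
# onset
# ---------------------------------------------------------------------------

def cumulative_onset_hazard(
    hazard: OnsetHazard,
    history: SmokingHistory,
    sex: str,
    max_age: float = 100.0,
):
    """Cumulative onset hazard H(a) on a fine age grid.

    The hazard is ``h0(a) * exp(b_py * packyears(a) + b_cur * current(a))``
    times a sex multiplier; pack-years make it a time-varying hazard, so the
    cumulative hazard is integrated numerically (trapezoid on a 0.05-y grid,
    exact for the piecewise-linear exponent's piecewise-smooth integrand to
    well below Monte-Carlo resolution).
    """
    ages = np.arange(0.0, max_age + _AGE_GRID_STEP / 2, _AGE_GRID_STEP)
    if hazard.family == "constant":
        h0 = np.full_like(ages, hazard.rate)
    else:  # weibull baseline hazard
        k, s = hazard.shape, hazard.scale
        with np.errstate(divide="ignore"):
            h0 = (k / s) * (ages / s) ** (k - 1.0)
        if k < 1.0:
            h0[0] = h0[1]  # avoid the integrable singularity at age 0
    log_mult = hazard.beta_pack_years * pack_years(history, ages)
    log_mult = log_mult + hazard.beta_current_smoker * is_current_smoker(
        history, ages
    ).astype(float)
    h = h0 * np.exp(log_mult)
    if sex == "female":
        h = h * hazard.sex_multiplier_female
    H = np.concatenate([[0.0], cumulative_trapezoid(h, ages)])
    return ages, H


def onset_ages_from_uniforms(
    profile: NaturalHistoryProfile,
    history: SmokingHistory,
    sex: str,
    u: np.ndarray,
    max_age: float = 100.0,
) -> np.ndarray:
    """Invert the cumulative hazard: ``a = H^{-1}(-log(1-u))``; NaN = no tumor."""
    ages, H = cumulative_onset_hazard(profile.onset_hazard, history, sex, max_age)
    target = -np.log1p(-np.asarray(u, dtype=float))
    onset = np.interp(target, H, ages)
    onset[target > H[-1]] = np.nan
    return onset


def draw_onset_age(
    profile: NaturalHistoryProfile,
    smoking: SmokingHistory,
    sex: str,
    substream: np.random.Generator,
    n: int = 1,
    max_age: float = 100.0,
) -> np.ndarray:
    """Sample onset ages (NaN where no tumor develops in the lifetime)."""
    return onset_ages_from_uniforms(profile, smoking, sex, substream.random(n), max_age)


# ---------------------------------------------------------------------------
# sojourn time
# ---------------------------------------------------------------------------

def _component_ppf(comp, u: np.ndarray) -> np.ndarray:
    if comp.family == "exponential":
        return -comp.mean * np.log1p(-u)
    if comp.family == "weibull":
        return comp.scale * (-np.log1p(-u)) ** (1.0 / comp.shape)
    if comp.family == "lognormal":
        return np.exp(comp.mu + comp.sigma * ndtri(np.clip(u, _TINY, 1 - _TINY)))
    if comp.family == "fixed":
        return np.full_like(u, comp.mean)
    raise ConfigurationError(f"unsupported sojourn family {comp.family!r}")


def sojourn_cdf(dist: SojournDist, x) -> Union[float, np.ndarray]:
    """CDF of the (unscaled) sojourn distribution — the analytic oracle used
    when validating recovery of sojourn times from scenario differences."""
    x = np.asarray(x, dtype=float)
    if dist.family == "mixture":
        w = np.array([c.weight for c in dist.components], dtype=float)
        w = w / w.sum()
        vals = w[0] * sojourn_cdf(dist.components[0], x) + w[1] * sojourn_cdf(
            dist.components[1], x
        )
        return float(vals) if vals.ndim == 0 else vals
    if dist.family == "exponential":
        out = -np.expm1(-x / dist.mean)
    elif dist.family == "weibull":
        out = -np.expm1(-((x / dist.scale) ** dist.shape))
    elif dist.family == "lognormal":
        out = stats.norm.cdf((np.log(np.maximum(x, _TINY)) - dist.mu) / dist.sigma)
    elif dist.family == "fixed":
        out = (x >= dist.mean).astype(float)
    else:
        raise ConfigurationError(f"unsupported sojourn family {dist.family!r}")
    out = np.where(x <= 0, 0.0, out)
    return float(out) if out.ndim == 0 else out


def sojourn_from_uniforms(
    dist: SojournDist, u_component: np.ndarray, u: np.ndarray
) -> np.ndarray:
    """Inverse-CDF sojourn draw (before strata scaling); strictly positive."""
    u = np.asarray(u, dtype=float)
    if dist.family == "mixture":
        c0, c1 = dist.components
        w0 = c0.weight / (c0.weight + c1.weight)
        take0 = np.asarray(u_component) < w0
        out = np.where(take0, _component_ppf(c0, u), _component_ppf(c1, u))
    else:
        out = _component_ppf(dist, u)
    return np.maximum(out, _TINY)


def draw_sojourn_time(
    profile: NaturalHistoryProfile,
    sex: str,
    smoking: str,
    substream: np.random.Generator,
    n: int = 1,
) -> np.ndarray:
    """Sample sojourn times with sex/smoking scale modifiers applied."""
    base = sojourn_from_uniforms(profile.sojourn_dist, substream.random(n), substream.random(n))
    return base * profile.sojourn_scale_for(sex, smoking)


# ---------------------------------------------------------------------------
# stage trajectory
# ---------------------------------------------------------------------------

def dwell_fractions_from_uniforms(
    profile: NaturalHistoryProfile, u4: np.ndarray
) -> np.ndarray:
    """Per-individual stage dwell fractions, (n, 4).

    ``fixed`` mode repeats the profile fractions; ``dirichlet`` mode perturbs
    them with a Dirichlet(concentration * fractions) draw built from gamma
    inverse-CDFs so it stays on the per-purpose uniform streams.
    """
    f = np.asarray(profile.stage_dwell.fractions, dtype=float)
    n = u4.shape[0]
    if profile.stage_dwell.mode == "fixed":
        return np.tile(f, (n, 1))
    alpha = profile.stage_dwell.concentration * f
    g = np.zeros((n, 4))
    for k in range(4):
        if alpha[k] > 0:
            g[:, k] = stats.gamma.ppf(np.clip(u4[:, k], _TINY, 1 - _TINY), a=alpha[k])
    total = g.sum(axis=1)
    total[total == 0] = 1.0
    return g / total[:, None]


def stage_entry_offsets(
    sojourn_time: np.ndarray,
    fractions: np.ndarray,
    progression_span: Optional[float] = None,
) -> np.ndarray:
    """Offsets from onset to entry into stages II, III, IV, shape (n, 3).

    Dwell in stage k is ``fraction_k * span``.  When ``progression_span`` is
    None the span is the sojourn time itself (the fractions partition the
    preclinical window exactly); a fixed span decouples progression speed from
    sojourn length, so entries can lie beyond clinical detection (unreached).
    """
    sojourn_time = np.asarray(sojourn_time, dtype=float)
    fractions = np.atleast_2d(np.asarray(fractions, dtype=float))
    if np.any(fractions < 0):
        raise ConfigurationError("stage dwell fractions must be non-negative")
    span = sojourn_time if progression_span is None else progression_span
    cum = np.cumsum(fractions[:, :3], axis=1)
    return cum * np.asarray(span, dtype=float).reshape(-1, 1)


def stage_at(elapsed: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Stage occupied ``elapsed`` years after onset (half-open: entry at t
    means the new stage is occupied at t)."""
    elapsed = np.asarray(elapsed, dtype=float).reshape(-1, 1)
    return 1 + (offsets <= elapsed).sum(axis=1)


def clinical_stage_at_detection(
    sojourn_time: np.ndarray, offsets: np.ndarray
) -> np.ndarray:
    """Stage occupied at the instant of clinical detection (left limit, so a
    zero-dwell terminal stage is never the clinical stage)."""
    s = np.asarray(sojourn_time, dtype=float).reshape(-1, 1)
    return 1 + (offsets < s).sum(axis=1)


def draw_stage_trajectory(
    sojourn_time,
    stage_dwell_fractions,
    substream: Optional[np.random.Generator] = None,
    mode: str = "fixed",
    concentration: float = 50.0,
    progression_span: Optional[float] = None,
):
    """Convenience wrapper: (entry offsets, clinical stage) for given sojourns."""
    sojourn_time = np.atleast_1d(np.asarray(sojourn_time, dtype=float))
    f = np.asarray(stage_dwell_fractions, dtype=float)
    n = sojourn_time.shape[0]
    if mode == "dirichlet":
        if substream is None:
            raise ConfigurationError("dirichlet dwell mode requires a substream")
        g = substream.gamma(np.maximum(concentration * f, _TINY), size=(n, 4))
        fractions = g / g.sum(axis=1, keepdims=True)
    else:
        fractions = np.tile(f, (n, 1))
    offsets = stage_entry_offsets(sojourn_time, fractions, progression_span)
    return offsets, clinical_stage_at_detection(sojourn_time, offsets)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def _death_delay_from_uniforms(profile, stage: np.ndarray, u: np.ndarray) -> np.ndarray:
    dt = profile.survival.death_time
    means = np.asarray(dt.mean_by_stage, dtype=float)[np.asarray(stage, int) - 1]
    u = np.asarray(u, dtype=float)
    if dt.family == "exponential":
        return -means * np.log1p(-u)
    if dt.family == "weibull":
        scale = means / math.gamma(1.0 + 1.0 / dt.shape)
        return scale * (-np.log1p(-u)) ** (1.0 / dt.shape)
    if dt.family == "fixed":
        return means.copy()
    raise ConfigurationError(f"unsupported death-time family {dt.family!r}")


def survival_from_uniforms(
    profile: NaturalHistoryProfile,
    stage: np.ndarray,
    age_at_dx: np.ndarray,
    u_cure: np.ndarray,
    u_death: np.ndarray,
    sex_is_female: np.ndarray,
    smoking: str,
    other_cause_death_age: float,
    cure_boost: float = 1.0,
):
    """Cure flag and lung-cancer death age for diagnosed cancers.

    With probability ``cure_stage`` (strata-adjusted, optionally boosted for
    screen-detected cases) the cancer never causes death; otherwise a
    stage-specific delay is added to the diagnosis age.  Deaths at or after
    the other-cause death age are censored (returned as NaN).
    """
    stage = np.asarray(stage, dtype=int)
    cure_m = np.array([profile.cure_for("male", smoking)])
    cure_f = np.array([profile.cure_for("female", smoking)])
    cure = np.where(np.asarray(sex_is_female)[:, None], cure_f, cure_m)[
        np.arange(stage.shape[0]), stage - 1
    ]
    cure = np.minimum(1.0, cure * cure_boost)
    cured = np.asarray(u_cure, dtype=float) < cure
    death_age = np.asarray(age_at_dx, dtype=float) + _death_delay_from_uniforms(
        profile, stage, u_death
    )
    death_age = np.where(cured | (death_age >= other_cause_death_age), np.nan, death_age)
    return cured, death_age


def draw_clinical_survival(
    stage: int,
    age_at_dx: float,
    profile: NaturalHistoryProfile,
    sex: str,
    substream: np.random.Generator,
    smoking: str = "heavy",
    other_cause_death_age: float = 100.0,
    n: int = 1,
):
    """Scalar/batch wrapper over :func:`survival_from_uniforms`."""
    stage_arr = np.full(n, stage, dtype=int)
    return survival_from_uniforms(
        profile,
        stage_arr,
        np.full(n, age_at_dx, dtype=float),
        substream.random(n),
        substream.random(n),
        np.full(n, sex == "female"),
        smoking,
        other_cause_death_age,
    )


# ---------------------------------------------------------------------------
# full life histories
# ---------------------------------------------------------------------------

LIFE_COLUMNS = [
    "id", "sex", "excluded", "onset_age", "sojourn_time",
    "stage_entry_I", "stage_entry_II", "stage_entry_III", "stage_entry_IV",
    "clinical_age", "clinical_stage", "clinical_cured", "clinical_death_age",
    "preclinical_at_screen", "screen_stage",
    "screen_cured_realistic", "screen_death_age_realistic",
    "detection_u", "other_cause_death_age",
]


def simulate_life_histories(
    cohort: pd.DataFrame,
    profile: NaturalHistoryProfile,
    screen_age: float = DEFAULT_SCREEN_AGE,
) -> pd.DataFrame:
    """Simulate the no-screening natural course for a whole cohort.

    The returned frame holds, per individual, the full counterfactual clinical
    course *and* the screen-time quantities every scenario shares under the
    common-random-numbers contract: the preclinical stage at the screen age,
    the reserved detection uniform, and the realistic-treatment survival draw
    for a hypothetical screen detection (from its own reserved substreams, so
    treatment-mode toggles perturb nothing else).

    Individuals whose counterfactual clinical diagnosis falls before the
    screen age are flagged ``excluded`` (the evaluation conditions on no
    diagnosis before then) and carry zero weight in all metrics.
    """
    spec: PopulationSpec = cohort.attrs["spec"]
    seed: int = cohort.attrs["seed"]
    n = len(cohort)
    history = spec.smoking_history
    label = spec.smoking_name
    ocd = float(spec.other_cause_death_age)
    if not screen_age < ocd:
        raise ConfigurationError("screen_age must precede other_cause_death_age")

    sex = cohort["sex"].to_numpy()
    female = sex == "female"

    # Reserve the detection uniform first: its stream position never depends
    # on any natural-history switch.
    u_det = cohort_uniforms(seed, "detection", n)

    # onset (hazard grid differs by sex only; smoking is uniform in-cohort)
    u_onset = cohort_uniforms(seed, "onset", n)
    onset = np.full(n, np.nan)
    for sx in ("male", "female"):
        mask = sex == sx
        if mask.any():
            onset[mask] = onset_ages_from_uniforms(
                profile, history, sx, u_onset[mask], max_age=ocd
            )
    has_tumor = ~np.isnan(onset)

    # sojourn
    u_comp = cohort_uniforms(seed, "sojourn_component", n)
    u_soj = cohort_uniforms(seed, "sojourn", n)
    base_soj = sojourn_from_uniforms(profile.sojourn_dist, u_comp, u_soj)
    scale = np.where(
        female,
        profile.sojourn_scale_for("female", label),
        profile.sojourn_scale_for("male", label),
    )
    sojourn = np.where(has_tumor, base_soj * scale, np.nan)
    clinical_age = onset + sojourn

    # stage trajectory
    u4 = np.column_stack(
        [cohort_uniforms(seed, f"dwell_g{k}", n) for k in (1, 2, 3, 4)]
    )
    fractions = dwell_fractions_from_uniforms(profile, u4)
    offsets = stage_entry_offsets(
        np.where(has_tumor, sojourn, 1.0),
        fractions,
        profile.stage_dwell.progression_span,
    )
    clin_stage = clinical_stage_at_detection(np.where(has_tumor, sojourn, 1.0), offsets)
    clin_stage = np.where(has_tumor, clin_stage, 0).astype(int)

    entry_ages = onset[:, None] + np.column_stack([np.zeros(n), offsets])
    # unreached entries (at/after clinical detection) and post-censoring ages -> NaN
    reached = np.column_stack(
        [np.ones(n, bool), offsets < np.where(has_tumor, sojourn, np.nan)[:, None]]
    )
    entry_ages = np.where(reached & (entry_ages < ocd), entry_ages, np.nan)

    # clinical survival (only meaningful where a diagnosis occurs pre-censoring)
    dx_happens = has_tumor & (clinical_age < ocd)
    u_ccure = cohort_uniforms(seed, "clinical_cure", n)
    u_cdeath = cohort_uniforms(seed, "clinical_death", n)
    safe_stage = np.where(dx_happens, clin_stage, 1)
    clin_cured, clin_death = survival_from_uniforms(
        profile, safe_stage, np.where(dx_happens, clinical_age, 0.0),
        u_ccure, u_cdeath, female, label, ocd,
    )
    clin_cured = np.where(dx_happens, clin_cured, False)
    clin_death = np.where(dx_happens, clin_death, np.nan)

    # screen-time state
    preclin = has_tumor & (onset < screen_age) & (screen_age < clinical_age)
    elapsed = np.where(preclin, screen_age - onset, 0.0)
    scr_stage = stage_at(elapsed, offsets)
    scr_stage = np.where(preclin, scr_stage, 0).astype(int)

    # realistic-treatment survival for a screen detection (reserved substreams)
    boost = (
        profile.screen_detection_survival.cure_boost
        if profile.screen_detection_survival.mode == "stage_shift_plus_cure_boost"
        else 1.0
    )
    u_scure = cohort_uniforms(seed, "screen_cure", n)
    u_sdeath = cohort_uniforms(seed, "screen_death", n)
    scr_cured, scr_death = survival_from_uniforms(
        profile, np.where(preclin, scr_stage, 1), np.full(n, screen_age),
        u_scure, u_sdeath, female, label, ocd, cure_boost=boost,
    )
    scr_cured = np.where(preclin, scr_cured, False)
    scr_death = np.where(preclin, scr_death, np.nan)

    excluded = has_tumor & (clinical_age < screen_age)

    life = pd.DataFrame(
        {
            "id": cohort["id"].to_numpy(),
            "sex": sex,
            "excluded": excluded,
            "onset_age": onset,
            "sojourn_time": sojourn,
            "stage_entry_I": entry_ages[:, 0],
            "stage_entry_II": entry_ages[:, 1],
            "stage_entry_III": entry_ages[:, 2],
            "stage_entry_IV": entry_ages[:, 3],
            "clinical_age": clinical_age,
            "clinical_stage": clin_stage,
            "clinical_cured": clin_cured,
            "clinical_death_age": clin_death,
            "preclinical_at_screen": preclin,
            "screen_stage": scr_stage,
            "screen_cured_realistic": scr_cured,
            "screen_death_age_realistic": scr_death,
            "detection_u": u_det,
            "other_cause_death_age": np.full(n, ocd),
        }
    )
    life.attrs["spec"] = spec
    life.attrs["seed"] = seed
    life.attrs["profile_name"] = profile.profile_name
    life.attrs["screen_age"] = float(screen_age)
    return life
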