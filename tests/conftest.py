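"""Shared test helpers: quick profile construction, randomized profiles for
property sweeps, and a brute-force per-individual oracle for every window
metric (pure-Python tallies, independent of the pandas/numpy pipeline)."""

from __future__ import annotations

import copy
import math

import numpy as np

from mclir.profiles import NaturalHistoryProfile, profile_from_dict

BASE_PROFILE = {
    "profile_name": "test",
    "onset_hazard": {"family": "constant", "rate": 0.004},
    "sojourn_dist": {"family": "exponential", "mean": 2.0},
    "stage_dwell": {"fractions": [0.25, 0.25, 0.25, 0.25], "progression_span": 3.0},
    "sensitivity": {"by_stage": [0.4, 0.5, 0.7, 0.9]},
    "survival": {"cure_by_stage": [0.6, 0.4, 0.2, 0.05]},
}


def _deep_merge(base: dict, over: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in over.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def make_profile(**overrides) -> NaturalHistoryProfile:
    """BASE_PROFILE with nested overrides, validated."""
    return profile_from_dict(_deep_merge(BASE_PROFILE, overrides))


def random_profile(rng: np.random.Generator) -> NaturalHistoryProfile:
    """A random but well-posed profile for invariant sweeps."""
    soj_family = rng.choice(["exponential", "weibull", "lognormal", "mixture"])
    if soj_family == "mixture":
        sojourn = {
            "family": "mixture",
            "components": [
                {"family": "exponential", "mean": float(rng.uniform(0.5, 2.0)),
                 "weight": float(rng.uniform(0.3, 0.7))},
                {"family": "weibull", "shape": float(rng.uniform(1.0, 2.5)),
                 "scale": float(rng.uniform(2.0, 5.0)), "weight": 1.0},
            ],
        }
    elif soj_family == "weibull":
        sojourn = {"family": "weibull", "shape": float(rng.uniform(0.8, 2.5)),
                   "scale": float(rng.uniform(1.0, 4.0))}
    elif soj_family == "lognormal":
        sojourn = {"family": "lognormal", "mu": float(rng.uniform(0.0, 1.2)),
                   "sigma": float(rng.uniform(0.3, 1.0))}
    else:
        sojourn = {"family": "exponential", "mean": float(rng.uniform(0.8, 3.5))}

    fractions = rng.dirichlet([2.0, 2.0, 2.0, 2.0])
    cure = np.sort(rng.uniform(0.02, 0.85, size=4))[::-1]
    sens = rng.uniform(0.1, 1.0, size=4)
    mode = str(rng.choice(["fixed", "dirichlet"]))
    span = None if rng.random() < 0.4 else float(rng.uniform(1.0, 5.0))
    screen_mode = (
        {"mode": "stage_shift_plus_cure_boost", "cure_boost": float(rng.uniform(1.0, 2.0))}
        if rng.random() < 0.5
        else {"mode": "stage_shift_only"}
    )
    return make_profile(
        profile_name=f"random-{rng.integers(1 << 30)}",
        onset_hazard={"family": "constant", "rate": float(rng.uniform(0.002, 0.01))},
        sojourn_dist=sojourn,
        stage_dwell={"fractions": [float(f) for f in fractions], "mode": mode,
                     "concentration": float(rng.uniform(5, 100)),
                     "progression_span": span},
        sensitivity={"by_stage": [float(s) for s in sens]},
        survival={
            "cure_by_stage": [float(c) for c in cure],
            "death_time": {"family": str(rng.choice(["exponential", "weibull", "fixed"])),
                           "mean_by_stage": [float(m) for m in rng.uniform(0.5, 6.0, 4)]},
        },
        screen_detection_survival=screen_mode,
        modifiers={"female": {"sojourn_scale": float(rng.uniform(1.0, 1.5)),
                              "sensitivity_scale": float(rng.uniform(0.9, 1.1)),
                              "cure_scale": float(rng.uniform(0.9, 1.1))}},
    )


# ---------------------------------------------------------------------------
# brute-force oracle: per-individual fate tallies with plain Python arithmetic
# ---------------------------------------------------------------------------

def _in_window(x) -> bool:
    return x is not None and not math.isnan(x) and 65.0 <= x < 81.0


def oracle_window_counts(outcomes) -> dict:
    """Window tallies by looping rows one at a time (no vectorised code)."""
    clinical = 0
    screen = 0
    deaths = 0
    per_year_clinical = [0] * 16
    per_year_stage4 = [0] * 16
    for row in outcomes.itertuples(index=False):
        if row.detection_mode == "clinical" and _in_window(row.dx_age):
            clinical += 1
            year = int(math.floor(row.dx_age)) - 65
            per_year_clinical[year] += 1
            if int(row.dx_stage) == 4:
                per_year_stage4[year] += 1
        if row.detection_mode == "screen" and _in_window(row.dx_age):
            screen += 1
        if _in_window(row.lc_death_age):
            deaths += 1
    return {
        "clinical": clinical,
        "screen": screen,
        "deaths": deaths,
        "per_year_clinical": per_year_clinical,
        "per_year_stage4": per_year_stage4,
    }


def oracle_metrics(outcomes_by_scenario) -> dict:
    """All window metrics from brute-force tallies and plain arithmetic."""
    c = {name: oracle_window_counts(out) for name, out in outcomes_by_scenario.items()}
    ns, rr = c["NoScreen"], c["RealSensRealTreat"]
    rp, pp = c["RealSensPerfectTreat"], c["PerfectSensTreat"]
    rclir = (1 - rr["clinical"] / ns["clinical"]) * 100
    mclir = (1 - pp["clinical"] / ns["clinical"]) * 100
    rmor = (1 - rr["deaths"] / ns["deaths"]) * 100
    ismor = (1 - rp["deaths"] / ns["deaths"]) * 100
    mmor = (1 - pp["deaths"] / ns["deaths"]) * 100
    out = {
        "RCLIR": rclir, "MCLIR": mclir,
        "RMOR": rmor, "ISMOR": ismor, "MMOR": mmor,
        "inc_A": rclir, "inc_B": mclir - rclir, "inc_C": 100 - mclir,
        "mor_A": rmor, "mor_B": ismor - rmor, "mor_C": mmor - ismor,
        "mor_D": 100 - mmor,
        "counts": c,
    }
    curves = {}
    for name in ("RealSensRealTreat", "PerfectSensTreat"):
        curve = []
        for t in range(16):
            ref = ns["per_year_clinical"][t]
            num = c[name]["per_year_clinical"][t]
            curve.append(float("nan") if ref == 0 else (1 - num / ref) * 100)
        curves[name] = curve
    out["curves"] = curves
    return out
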