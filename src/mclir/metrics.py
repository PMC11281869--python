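"""MCLIR metric suite: everything derivable from the four-scenario comparison.

The quantities computed here are the evaluation framework itself:

* window reductions — RCLIR/MCLIR for clinical incidence, RMOR/ISMOR/MMOR for
  lung-cancer mortality, each a ``(1 - scenario/NoScreen) * 100%`` contrast of
  sums over ages 65-80;
* area decompositions — the window cancers (or deaths) partitioned into
  screen-detected-and-benefiting (A), detected-without-benefit (B),
  present-but-missed (C) and, for mortality, not-yet-detectable (D), under
  either the whole-window or the detectable-at-screen denominator;
* conditional proportions of screen-detected cases (A/(A+B), B/(A+B));
* per-year postscreening curves — incidence-reduction curves and the share of
  clinical detections occurring in stage IV;
* recovery of the sojourn-time distribution from the perfect-sensitivity
  scenario; and
* cross-profile median / model-range summaries.

All internal arithmetic is full precision; percentages are rounded to one
decimal (half away from zero) only at report serialisation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

WINDOW_START = 65
WINDOW_END = 80  # inclusive; bins are [A, A+1) for A = 65..80
N_YEARS = WINDOW_END - WINDOW_START + 1


class UndefinedMetricError(ZeroDivisionError):
    """A reduction metric was requested against a zero reference count."""


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (matching conventional printed percentages)."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return float("nan")
    q = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * q + 0.5) / q, x)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

@dataclass
class IncidenceMortalitySeries:
    """Per-age (65..80) event counts for one scenario.

    ``clinical_incidence`` and ``screen_detected`` are (16, 4) stage-split
    counts; ``lc_deaths`` are deaths occurring in each 1-year bin.
    ``window_deaths`` is the mortality window total under the configured
    counting basis (deaths occurring in-window, or deaths among cancers
    diagnosed in-window).
    """

    scenario: str
    cohort_n: int
    clinical_incidence: np.ndarray  # (16, 4) ints
    screen_detected: np.ndarray     # (16, 4) ints
    lc_deaths: np.ndarray           # (16,) ints
    window_deaths: int
    mortality_basis: str = "death_in_window"

    @property
    def ages(self) -> np.ndarray:
        return np.arange(WINDOW_START, WINDOW_END + 1)

    @property
    def window_clinical(self) -> int:
        return int(self.clinical_incidence.sum())

    def __post_init__(self) -> None:
        assert self.clinical_incidence.shape == (N_YEARS, 4)
        assert self.screen_detected.shape == (N_YEARS, 4)
        assert self.lc_deaths.shape == (N_YEARS,)
        if self.screen_detected[1:].any():
            raise ValueError("screen detections outside the screen-age bin")


def _bin_by_stage(ages: np.ndarray, stages: np.ndarray) -> np.ndarray:
    counts = np.zeros((N_YEARS, 4), dtype=int)
    in_win = (ages >= WINDOW_START) & (ages < WINDOW_END + 1)
    idx = np.floor(ages[in_win]).astype(int) - WINDOW_START
    stg = stages[in_win].astype(int) - 1
    np.add.at(counts, (idx, stg), 1)
    return counts


def aggregate_series(
    outcomes: pd.DataFrame,
    mortality_basis: str = "death_in_window",
) -> IncidenceMortalitySeries:
    """Bin one scenario's outcomes into the 65-80 evaluation window.

    Events are binned into 1-year intervals [A, A+1); diagnoses and deaths
    outside the window are excluded from window sums.  Clinical and screen
    detections are tallied separately by stage.
    """
    if mortality_basis not in ("death_in_window", "diagnosis_in_window"):
        raise ValueError(f"unknown mortality_basis {mortality_basis!r}")
    if len(outcomes) == 0:  # flagged zero series
        return IncidenceMortalitySeries(
            scenario=outcomes.attrs.get("scenario", ""),
            cohort_n=0,
            clinical_incidence=np.zeros((N_YEARS, 4), dtype=int),
            screen_detected=np.zeros((N_YEARS, 4), dtype=int),
            lc_deaths=np.zeros(N_YEARS, dtype=int),
            window_deaths=0,
            mortality_basis=mortality_basis,
        )
    mode = outcomes["detection_mode"].to_numpy()
    dx_age = outcomes["dx_age"].to_numpy(dtype=float)
    dx_stage = outcomes["dx_stage"].to_numpy()
    death = outcomes["lc_death_age"].to_numpy(dtype=float)

    clin = mode == "clinical"
    scr = mode == "screen"
    clinical_incidence = _bin_by_stage(dx_age[clin], dx_stage[clin])
    screen_detected = _bin_by_stage(dx_age[scr], dx_stage[scr])

    lc_deaths = np.zeros(N_YEARS, dtype=int)
    died = ~np.isnan(death)
    d_in = died & (death >= WINDOW_START) & (death < WINDOW_END + 1)
    np.add.at(lc_deaths, np.floor(death[d_in]).astype(int) - WINDOW_START, 1)

    if mortality_basis == "death_in_window":
        window_deaths = int(d_in.sum())
    else:
        dx_in = (dx_age >= WINDOW_START) & (dx_age < WINDOW_END + 1)
        window_deaths = int((died & dx_in).sum())

    return IncidenceMortalitySeries(
        scenario=outcomes.attrs.get("scenario", ""),
        cohort_n=int(outcomes.attrs.get("n_eligible", len(outcomes))),
        clinical_incidence=clinical_incidence,
        screen_detected=screen_detected,
        lc_deaths=lc_deaths,
        window_deaths=window_deaths,
        mortality_basis=mortality_basis,
    )


# ---------------------------------------------------------------------------
# window reduction metrics
# ---------------------------------------------------------------------------

def incidence_reduction(
    numerator: IncidenceMortalitySeries, reference: IncidenceMortalitySeries
) -> float:
    """Generic window clinical-incidence reduction, in percent.

    With the screened scenario as numerator and NoScreen as reference this is
    RCLIR (realistic sensitivity) or MCLIR (perfect sensitivity).
    """
    ref = reference.window_clinical
    if ref == 0:
        raise UndefinedMetricError("reference window clinical incidence is zero")
    return (1.0 - numerator.window_clinical / ref) * 100.0


def mortality_reduction(
    numerator: IncidenceMortalitySeries, reference: IncidenceMortalitySeries
) -> float:
    ref = reference.window_deaths
    if ref == 0:
        raise UndefinedMetricError("reference window lung-cancer deaths are zero")
    return (1.0 - numerator.window_deaths / ref) * 100.0


def mortality_reductions(
    noscreen: IncidenceMortalitySeries,
    realreal: IncidenceMortalitySeries,
    realperfect: IncidenceMortalitySeries,
    perfectperfect: IncidenceMortalitySeries,
) -> Tuple[float, float, float]:
    """(RMOR, ISMOR, MMOR): each screened scenario's window mortality vs NoScreen."""
    return (
        mortality_reduction(realreal, noscreen),
        mortality_reduction(realperfect, noscreen),
        mortality_reduction(perfectperfect, noscreen),
    )


# ---------------------------------------------------------------------------
# area decompositions
# ---------------------------------------------------------------------------

@dataclass
class AreaDecomposition:
    """Partition of window cancers (incidence) or deaths (mortality) into the
    screening-fate areas, as percentages of the whole window.

    Incidence: A (screen detected) + B (missed by imperfect sensitivity)
    + C (not yet detectable) = 100.  Mortality adds the treatment split:
    A (detected, death prevented) + B (detected, not prevented) + C (missed)
    + D (not yet detectable) = 100.
    """

    context: str  # "incidence" | "mortality"
    A: float
    B: float
    C: float
    D: Optional[float] = None
    denominator: str = "window_total"

    def __post_init__(self) -> None:
        if self.context not in ("incidence", "mortality"):
            raise ValueError("context must be incidence or mortality")
        if self.context == "mortality" and self.denominator == "window_total" and self.D is None:
            raise ValueError("mortality window decomposition requires area D")

    def detectable(self) -> "AreaDecomposition":
        """Rescale onto the cancers (deaths) detectable at the screen.

        Incidence: A and B shares of A+B; mortality: A, B and C shares of
        A+B+C (area D, the not-yet-detectable mass, is dropped from the
        denominator).
        """
        if self.denominator != "window_total":
            return self
        if self.context == "incidence":
            total = self.A + self.B
            if total == 0:
                raise UndefinedMetricError("no cancers detectable at the screen")
            return AreaDecomposition(
                self.context, 100 * self.A / total, 100 * self.B / total,
                0.0, None, denominator="detectable_at_screen",
            )
        total = self.A + self.B + self.C
        if total == 0:
            raise UndefinedMetricError("no deaths detectable at the screen")
        return AreaDecomposition(
            self.context, 100 * self.A / total, 100 * self.B / total,
            100 * self.C / total, None, denominator="detectable_at_screen",
        )


def area_decomposition(
    noscreen: IncidenceMortalitySeries,
    realreal: IncidenceMortalitySeries,
    realperfect: IncidenceMortalitySeries,
    perfectperfect: IncidenceMortalitySeries,
    context: str,
) -> AreaDecomposition:
    """Window-total area decomposition from the four scenario series.

    Incidence: A = RCLIR, B = MCLIR - RCLIR, C = 100 - MCLIR.
    Mortality:  A = RMOR, B = ISMOR - RMOR, C = MMOR - ISMOR, D = 100 - MMOR.
    """
    if context == "incidence":
        rclir = incidence_reduction(realreal, noscreen)
        mclir = incidence_reduction(perfectperfect, noscreen)
        return AreaDecomposition("incidence", rclir, mclir - rclir, 100.0 - mclir)
    if context == "mortality":
        rmor, ismor, mmor = mortality_reductions(
            noscreen, realreal, realperfect, perfectperfect
        )
        return AreaDecomposition(
            "mortality", rmor, ismor - rmor, mmor - ismor, 100.0 - mmor
        )
    raise ValueError(f"unknown context {context!r}")


def conditional_proportions(decomp: AreaDecomposition) -> Tuple[float, float]:
    """Screen-detected shares 100*A/(A+B) and 100*B/(A+B).

    For mortality this is the split of screen-detected deaths into prevented
    vs not prevented — the treatment-effectiveness signature of a model.
    """
    total = decomp.A + decomp.B
    if total == 0:
        raise UndefinedMetricError("A + B is zero; conditional shares undefined")
    return 100.0 * decomp.A / total, 100.0 * decomp.B / total


# ---------------------------------------------------------------------------
# postscreening curves
# ---------------------------------------------------------------------------

def reduction_curve(
    numerator: IncidenceMortalitySeries, reference: IncidenceMortalitySeries
) -> np.ndarray:
    """Per-year clinical-incidence reduction (%) by year postscreen (0..15).

    Years with zero reference incidence are returned as NaN (explicit missing
    marker) rather than dividing by zero.
    """
    num = numerator.clinical_incidence.sum(axis=1).astype(float)
    ref = reference.clinical_incidence.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        curve = (1.0 - num / ref) * 100.0
    curve[ref == 0] = np.nan
    return curve


def stage_iv_curve(
    outcomes_by_scenario: Dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Share (%) of clinical detections occurring in stage IV, per year postscreen.

    Three curves: NoScreen, realistic sensitivity (the two RealSens scenarios
    share clinical detections) and perfect sensitivity.  Years with no
    clinical detections are NaN.
    """
    picks = {
        "NoScreen": outcomes_by_scenario["NoScreen"],
        "RealisticSensitivity": outcomes_by_scenario["RealSensRealTreat"],
        "PerfectSensitivity": outcomes_by_scenario["PerfectSensTreat"],
    }
    data = {}
    for label, out in picks.items():
        series = aggregate_series(out)
        totals = series.clinical_incidence.sum(axis=1).astype(float)
        stage4 = series.clinical_incidence[:, 3].astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = 100.0 * stage4 / totals
        pct[totals == 0] = np.nan
        data[label] = pct
    return pd.DataFrame(data, index=pd.RangeIndex(N_YEARS, name="year_postscreen"))


# ---------------------------------------------------------------------------
# sojourn-time recovery
# ---------------------------------------------------------------------------

SOJOURN_BIN_KEYS = ("lt2", "from2to4", "from4to5", "ge5")


def estimate_sojourn_bins(
    life: pd.DataFrame,
    perfect_outcomes: pd.DataFrame,
    min_detections: int = 200,
) -> dict:
    """Recover the sojourn-time distribution from the perfect-sensitivity screen.

    Under perfect sensitivity every cancer preclinical at the screen is
    detected, and its lead time plus its elapsed preclinical time reconstruct
    the full sojourn.  Prevalent cancers are a length-biased sample of
    sojourns (long sojourns are more likely to straddle the screen age), so
    each case is reweighted by 1/sojourn — the classical renewal correction,
    exact under locally stationary onset — before binning.

    Returns percentages in the partition {<2y, [2,4)y, [4,5)y, >=5y} (summing
    to 100) plus the derived cumulative ``lt5`` share, the detection count,
    and a ``low_precision`` flag when detections are scarce.
    """
    scr = perfect_outcomes[perfect_outcomes["detection_mode"] == "screen"]
    screen_age = perfect_outcomes.attrs.get("screen_age", 65.0)
    merged = scr.merge(life[["id", "onset_age"]], on="id", how="left")
    elapsed = screen_age - merged["onset_age"].to_numpy(dtype=float)
    sojourn = elapsed + merged["lead_time"].to_numpy(dtype=float)
    n = len(sojourn)
    out = {k: float("nan") for k in SOJOURN_BIN_KEYS}
    out["lt5"] = float("nan")
    out["n_detections"] = int(n)
    out["effective_n"] = 0.0
    out["low_precision"] = bool(n < min_detections)
    if n == 0:
        return out
    w = 1.0 / np.maximum(sojourn, 1e-9)
    w = w / w.sum()
    out["effective_n"] = float(1.0 / np.sum(w**2))  # Kish, for MC standard errors
    edges = [(0.0, 2.0), (2.0, 4.0), (4.0, 5.0), (5.0, np.inf)]
    for key, (lo, hi) in zip(SOJOURN_BIN_KEYS, edges):
        out[key] = float(100.0 * w[(sojourn >= lo) & (sojourn < hi)].sum())
    out["lt5"] = out["lt2"] + out["from2to4"] + out["from4to5"]
    return out


# ---------------------------------------------------------------------------
# cross-profile summaries
# ---------------------------------------------------------------------------

def cross_profile_summary(values: Sequence[float]) -> Tuple[float, Tuple[float, float]]:
    """Median and model range (min, max) across profiles.

    The median uses the midpoint of the two central values for even counts.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("cross_profile_summary requires at least one value")
    return float(np.median(vals)), (min(vals), max(vals))


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

REPORT_SCHEMA_VERSION = 1


@dataclass
class MCLIRReport:
    """The complete metric suite for one profile x population run."""

    profile_name: str
    population: dict
    seed: int
    screen_age: float
    cohort: dict
    rclir: float
    mclir: float
    rmor: float
    ismor: float
    mmor: float
    incidence_areas: AreaDecomposition
    mortality_areas: AreaDecomposition
    conditional_incidence: Tuple[float, float]
    mortality_detectable_shares: Tuple[float, float, float]
    conditional_mortality: Tuple[float, float]
    reduction_curve_realistic: np.ndarray
    reduction_curve_perfect: np.ndarray
    stage_iv: pd.DataFrame
    sojourn_bins: dict
    window_sums: dict
    mortality_basis: str = "death_in_window"

    def to_dict(self, ndigits: Optional[int] = 1) -> dict:
        r = (lambda x: round_half_away(x, ndigits)) if ndigits is not None else float

        def rlist(a):
            return [None if (isinstance(v, float) and math.isnan(v)) else r(v) for v in a]

        inc = self.incidence_areas
        mor = self.mortality_areas
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "profile": self.profile_name,
            "population": self.population,
            "seed": int(self.seed),
            "screen_age": self.screen_age,
            "mortality_basis": self.mortality_basis,
            "cohort": self.cohort,
            "metrics": {
                "RCLIR": r(self.rclir), "MCLIR": r(self.mclir),
                "RMOR": r(self.rmor), "ISMOR": r(self.ismor), "MMOR": r(self.mmor),
            },
            "incidence_areas": {
                "A": r(inc.A), "B": r(inc.B), "C": r(inc.C),
                "detectable": dict(
                    zip(("A", "B"), map(r, self.conditional_incidence))
                ),
            },
            "mortality_areas": {
                "A": r(mor.A), "B": r(mor.B), "C": r(mor.C), "D": r(mor.D),
                "detectable": dict(
                    zip(("A", "B", "C"), map(r, self.mortality_detectable_shares))
                ),
                "screen_detected": dict(
                    zip(("A", "B"), map(r, self.conditional_mortality))
                ),
            },
            "curves": {
                "reduction_realistic": rlist(self.reduction_curve_realistic),
                "reduction_perfect": rlist(self.reduction_curve_perfect),
                "stage_iv": {
                    col: rlist(self.stage_iv[col].to_numpy())
                    for col in self.stage_iv.columns
                },
            },
            "sojourn_bins": {
                k: (r(v) if isinstance(v, float) else v)
                for k, v in self.sojourn_bins.items()
            },
            "window_sums": self.window_sums,
        }

    def to_json(self, ndigits: Optional[int] = 1) -> str:
        return json.dumps(self.to_dict(ndigits), indent=2, sort_keys=True)


def compute_report(
    life: pd.DataFrame,
    outcomes_by_scenario: Dict[str, pd.DataFrame],
    mortality_basis: str = "death_in_window",
) -> MCLIRReport:
    """Assemble the full MCLIR report from the four scenario outcome tables."""
    series = {
        name: aggregate_series(out, mortality_basis)
        for name, out in outcomes_by_scenario.items()
    }
    ns, rr = series["NoScreen"], series["RealSensRealTreat"]
    rp, pp = series["RealSensPerfectTreat"], series["PerfectSensTreat"]

    rclir = incidence_reduction(rr, ns)
    mclir = incidence_reduction(pp, ns)
    rmor, ismor, mmor = mortality_reductions(ns, rr, rp, pp)
    inc_areas = area_decomposition(ns, rr, rp, pp, "incidence")
    mor_areas = area_decomposition(ns, rr, rp, pp, "mortality")
    nan = float("nan")
    try:
        cond_inc = conditional_proportions(inc_areas)
    except UndefinedMetricError:
        cond_inc = (nan, nan)
    try:
        d = mor_areas.detectable()
        det_shares = (d.A, d.B, d.C)
    except UndefinedMetricError:
        det_shares = (nan, nan, nan)
    try:
        cond_mor = conditional_proportions(mor_areas)
    except UndefinedMetricError:
        cond_mor = (nan, nan)

    spec = life.attrs["spec"]
    n_total = len(life)
    cohort = {
        "n_simulated": int(n_total),
        "n_excluded_pre_screen_dx": int(life["excluded"].sum()),
        "n_eligible": int(n_total - life["excluded"].sum()),
        "n_preclinical_at_screen": int(
            (life["preclinical_at_screen"] & ~life["excluded"]).sum()
        ),
    }
    return MCLIRReport(
        profile_name=life.attrs.get("profile_name", ""),
        population={
            "sex": spec.sex,
            "smoking": spec.smoking_name,
            "n_individuals": int(spec.n_individuals),
            "other_cause_death_age": float(spec.other_cause_death_age),
        },
        seed=int(life.attrs.get("seed", -1)),
        screen_age=float(life.attrs.get("screen_age", 65.0)),
        cohort=cohort,
        rclir=rclir,
        mclir=mclir,
        rmor=rmor,
        ismor=ismor,
        mmor=mmor,
        incidence_areas=inc_areas,
        mortality_areas=mor_areas,
        conditional_incidence=cond_inc,
        mortality_detectable_shares=det_shares,
        conditional_mortality=cond_mor,
        reduction_curve_realistic=reduction_curve(rr, ns),
        reduction_curve_perfect=reduction_curve(pp, ns),
        stage_iv=stage_iv_curve(outcomes_by_scenario),
        sojourn_bins=estimate_sojourn_bins(life, outcomes_by_scenario["PerfectSensTreat"]),
        window_sums={
            name: {
                "clinical_incidence": s.window_clinical,
                "screen_detected": int(s.screen_detected.sum()),
                "lc_deaths": s.window_deaths,
            }
            for name, s in series.items()
        },
        mortality_basis=mortality_basis,
    )
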