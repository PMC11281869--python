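"""Natural-history component draws against closed-form oracles."""

import numpy as np
import pytest
from scipy import stats

from conftest import make_profile
from mclir.natural_history import (
    clinical_stage_at_detection,
    onset_ages_from_uniforms,
    simulate_life_histories,
    sojourn_cdf,
    sojourn_from_uniforms,
    stage_at,
    stage_entry_offsets,
    survival_from_uniforms,
)
from mclir.population import HEAVY, LIGHT, PopulationSpec, make_cohort
from mclir.profiles import profile_from_dict


def _uniforms(seed, n):
    return np.random.default_rng(seed).random(n)


# ---------------------------------------------------------------------------
# onset
# ---------------------------------------------------------------------------

def test_zero_hazard_yields_no_cancer():
    prof = make_profile(onset_hazard={"family": "constant", "rate": 0.0})
    onset = onset_ages_from_uniforms(prof, HEAVY, "male", _uniforms(0, 1000))
    assert np.isnan(onset).all()


def test_constant_hazard_onset_matches_exponential():
    """With a constant hazard and no smoking effect, onset ages are
    exponential; Kolmogorov-Smirnov at alpha=0.01, n=100,000."""
    lam = 0.02
    prof = make_profile(onset_hazard={"family": "constant", "rate": lam})
    onset = onset_ages_from_uniforms(prof, HEAVY, "male", _uniforms(1, 100_000), max_age=600.0)
    onset = onset[~np.isnan(onset)]
    assert len(onset) > 99_000
    res = stats.kstest(onset, stats.expon(scale=1 / lam).cdf)
    assert res.pvalue > 0.01


def test_heavier_smoking_raises_onset_probability():
    """A positive pack-year coefficient orders the strata: heavy smokers have
    a higher probability of onset by 65 than light smokers (3 SE, n=100,000)."""
    prof = make_profile(
        onset_hazard={"family": "weibull", "shape": 5.0, "scale": 160.0,
                      "beta_pack_years": 0.018, "beta_current_smoker": 0.2}
    )
    n = 100_000
    p_heavy = np.mean(onset_ages_from_uniforms(prof, HEAVY, "male", _uniforms(2, n)) <= 65)
    p_light = np.mean(onset_ages_from_uniforms(prof, LIGHT, "male", _uniforms(3, n)) <= 65)
    se = np.sqrt(p_heavy * (1 - p_heavy) / n + p_light * (1 - p_light) / n)
    assert p_heavy - p_light > 3 * se


def test_negative_hazard_parameters_rejected():
    with pytest.raises(Exception):
        make_profile(onset_hazard={"family": "weibull", "shape": -1.0})


# ---------------------------------------------------------------------------
# sojourn
# ---------------------------------------------------------------------------

def test_point_mass_sojourn():
    prof = make_profile(sojourn_dist={"family": "fixed", "mean": 1.0})
    draws = sojourn_from_uniforms(prof.sojourn_dist, _uniforms(4, 500), _uniforms(5, 500))
    np.testing.assert_allclose(draws, 1.0)


def test_exponential_sojourn_cdf():
    """P(sojourn < 2y) for an exponential(mean 2) is 1 - e^-1 (3 SE, n=100,000)."""
    prof = make_profile(sojourn_dist={"family": "exponential", "mean": 2.0})
    n = 100_000
    draws = sojourn_from_uniforms(prof.sojourn_dist, _uniforms(6, n), _uniforms(7, n))
    p = np.mean(draws < 2.0)
    target = 1 - np.exp(-1)
    assert abs(p - target) < 3 * np.sqrt(target * (1 - target) / n)
    assert (draws > 0).all()


def test_female_sojourn_scale_modifier():
    """A 1.5x female scale modifier scales the mean exactly under shared draws."""
    prof = make_profile(modifiers={"female": {"sojourn_scale": 1.5}})
    assert prof.sojourn_scale_for("female", "heavy") == 1.5
    u1, u2 = _uniforms(8, 50_000), _uniforms(9, 50_000)
    base = sojourn_from_uniforms(prof.sojourn_dist, u1, u2)
    male = base * prof.sojourn_scale_for("male", "heavy")
    female = base * prof.sojourn_scale_for("female", "heavy")
    assert female.mean() == pytest.approx(1.5 * male.mean())


def test_mixture_sojourn_matches_analytic_cdf():
    dist = make_profile(
        sojourn_dist={
            "family": "mixture",
            "components": [
                {"family": "exponential", "mean": 1.0, "weight": 0.6},
                {"family": "exponential", "mean": 4.0, "weight": 0.4},
            ],
        }
    ).sojourn_dist
    n = 200_000
    draws = sojourn_from_uniforms(dist, _uniforms(10, n), _uniforms(11, n))
    for x in (1.0, 2.0, 5.0):
        target = sojourn_cdf(dist, x)
        assert np.mean(draws < x) == pytest.approx(target, abs=3 * np.sqrt(target * (1 - target) / n))


# ---------------------------------------------------------------------------
# stage trajectory
# ---------------------------------------------------------------------------

def test_degenerate_partition_always_stage_one():
    offsets = stage_entry_offsets(np.array([1.0, 3.0, 7.5]), [1.0, 0.0, 0.0, 0.0])
    stages = clinical_stage_at_detection(np.array([1.0, 3.0, 7.5]), offsets)
    assert (stages == 1).all()


def test_equal_quarters_partition_arithmetic():
    """Sojourn 4y split in quarters: entries at offsets 1, 2, 3; detection in IV."""
    offsets = stage_entry_offsets(np.array([4.0]), [0.25, 0.25, 0.25, 0.25])
    np.testing.assert_allclose(offsets, [[1.0, 2.0, 3.0]])
    assert clinical_stage_at_detection(np.array([4.0]), offsets)[0] == 4


def test_stage_is_nondecreasing_step_function_of_time():
    offsets = stage_entry_offsets(np.array([4.0]), [0.25, 0.25, 0.25, 0.25])
    times = np.linspace(0, 4, 101)
    stages = [stage_at(np.array([t]), offsets)[0] for t in times]
    assert all(b >= a for a, b in zip(stages, stages[1:]))
    assert stage_at(np.array([1.0]), offsets)[0] == 2  # entry instant joins new stage


def test_clinical_stage_monotone_in_sojourn():
    """Same dwell-fraction draws, longer sojourn -> same or later clinical stage
    (both with sojourn-proportional dwells and with a fixed progression span)."""
    short, long = np.array([1.5]), np.array([4.5])
    f = [0.4, 0.2, 0.2, 0.2]
    for span in (None, 3.0):
        s_short = clinical_stage_at_detection(short, stage_entry_offsets(short, f, span))
        s_long = clinical_stage_at_detection(long, stage_entry_offsets(long, f, span))
        assert s_long[0] >= s_short[0]


def test_fixed_progression_span_leaves_late_entries_unreached():
    offsets = stage_entry_offsets(np.array([1.0]), [0.25, 0.25, 0.25, 0.25],
                                  progression_span=4.0)
    assert clinical_stage_at_detection(np.array([1.0]), offsets)[0] == 1


def test_negative_fraction_rejected():
    with pytest.raises(Exception):
        stage_entry_offsets(np.array([2.0]), [-0.1, 0.5, 0.3, 0.3])


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def test_certain_cure_and_degenerate_death_time():
    prof = make_profile(
        survival={"cure_by_stage": [1.0, 1.0, 1.0, 1.0]}
    )
    cured, death = survival_from_uniforms(
        prof, np.full(100, 2), np.full(100, 70.0), _uniforms(12, 100), _uniforms(13, 100),
        np.zeros(100, bool), "heavy", 100.0,
    )
    assert cured.all() and np.isnan(death).all()

    prof0 = make_profile(
        survival={"cure_by_stage": [0.0, 0.0, 0.0, 0.0],
                  "death_time": {"family": "fixed", "mean_by_stage": [2.0, 2.0, 2.0, 2.0]}}
    )
    cured, death = survival_from_uniforms(
        prof0, np.full(10, 3), np.full(10, 70.0), _uniforms(14, 10), _uniforms(15, 10),
        np.zeros(10, bool), "heavy", 100.0,
    )
    assert not cured.any()
    np.testing.assert_allclose(death, 72.0)


def test_empirical_cure_fraction_binomial():
    """Observed cure rate matches the configured probability (3 SE, n=100,000)."""
    prof = make_profile(survival={"cure_by_stage": [0.6, 0.37, 0.2, 0.05]})
    n = 100_000
    cured, _ = survival_from_uniforms(
        prof, np.full(n, 2), np.full(n, 70.0), _uniforms(16, n), _uniforms(17, n),
        np.zeros(n, bool), "heavy", 100.0,
    )
    c = 0.37
    assert abs(cured.mean() - c) < 3 * np.sqrt(c * (1 - c) / n)


# ---------------------------------------------------------------------------
# composed life histories
# ---------------------------------------------------------------------------

def _life(profile, n=20_000, seed=11, sex="male", smoking="heavy", ocd=100.0):
    spec = PopulationSpec(sex=sex, smoking=smoking, n_individuals=n,
                          other_cause_death_age=ocd)
    return simulate_life_histories(make_cohort(spec, seed), profile)


def test_life_history_identities():
    life = _life(make_profile(), n=30_000)
    has = ~life["onset_age"].isna()
    # clinical detection age = onset + sojourn
    np.testing.assert_allclose(
        life.loc[has, "clinical_age"],
        life.loc[has, "onset_age"] + life.loc[has, "sojourn_time"],
    )
    # no onset -> no events of any kind
    none = ~has
    assert life.loc[none, "clinical_death_age"].isna().all()
    assert not life.loc[none, "preclinical_at_screen"].any()
    # preclinical at the screen iff onset < 65 < clinical detection
    expected = has & (life["onset_age"] < 65) & (life["clinical_age"] > 65)
    np.testing.assert_array_equal(life["preclinical_at_screen"], expected)
    # exclusion flags exactly the pre-screen diagnoses
    np.testing.assert_array_equal(life["excluded"], has & (life["clinical_age"] < 65))


def test_fixed_sojourn_window_arithmetic():
    """With a point-mass 4y sojourn, onsets in (61, 65) are preclinical at the
    65 screen and onsets after 65 are untouched by screening."""
    prof = make_profile(sojourn_dist={"family": "fixed", "mean": 4.0})
    life = _life(prof, n=50_000)
    has = ~life["onset_age"].isna()
    in_band = has & (life["onset_age"] > 61) & (life["onset_age"] < 65)
    assert (life.loc[in_band, "preclinical_at_screen"]).all()
    post = has & (life["onset_age"] > 65)
    assert not life.loc[post, "preclinical_at_screen"].any()


def test_no_event_after_other_cause_death():
    life = _life(make_profile(), n=50_000, ocd=82.0)
    assert not (life["clinical_death_age"] >= 82.0).any()
    for col in ("stage_entry_I", "stage_entry_II", "stage_entry_III", "stage_entry_IV"):
        assert not (life[col] >= 82.0).any()


def test_clinical_sojourn_distribution_matches_configured_cdf():
    """Among clinically detected cancers, the sojourn distribution is the
    configured one (3 SE at n=200,000): detection does not bias the draw."""
    prof = make_profile(sojourn_dist={"family": "exponential", "mean": 2.0})
    life = _life(prof, n=200_000)
    soj = life.loc[~life["onset_age"].isna(), "sojourn_time"].to_numpy()
    for x in (1.0, 2.0, 4.0):
        target = sojourn_cdf(prof.sojourn_dist, x)
        se = np.sqrt(target * (1 - target) / len(soj))
        assert np.mean(soj < x) == pytest.approx(target, abs=3 * se)


def test_dirichlet_dwell_mode_runs_and_partitions():
    prof = make_profile(stage_dwell={"fractions": [0.4, 0.2, 0.2, 0.2],
                                     "mode": "dirichlet", "concentration": 30.0,
                                     "progression_span": None})
    life = _life(prof, n=5_000)
    has = ~life["onset_age"].isna()
    # with span = sojourn, entry into stage IV (when reached) precedes detection
    e4 = life.loc[has, "stage_entry_IV"]
    ok = e4.isna() | (e4 < life.loc[has, "clinical_age"] + 1e-9)
    assert ok.all()
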