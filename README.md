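# mclir

**Counterfactual evaluation of one-time lung cancer screening with a
natural-history microsimulator and the maximum clinical incidence reduction
(MCLIR) framework.**

`mclir` is for modelers and screening-policy analysts who want to separate
*what a CT screen actually achieves* from *what it could at most achieve* —
and to see how strongly those answers depend on natural-history assumptions
such as sojourn-time distributions, stage-specific test sensitivity, and the
survival benefit conferred by early detection.

## The problem

Microsimulation models of lung cancer screening can disagree substantially
about who benefits from screening, even when calibrated to the same trials.
The disagreement is driven by assumptions that are hard to observe directly:
how long tumors stay in the preclinical, screen-detectable phase (the
*sojourn time*), how likely a CT scan is to detect a tumor at each stage,
and how much detecting a tumor earlier improves survival. `mclir` makes
those assumptions explicit, swappable *model profiles* and quantifies their
consequences with a common set of counterfactual metrics.

## The framework

A cohort of individuals with a shared smoking history is simulated from a
natural-history profile: tumor onset from a smoking-dose-dependent hazard,
a random preclinical sojourn time partitioned into stage I–IV dwell periods,
clinical diagnosis at the end of the sojourn, and stage-dependent
cure/survival. A single CT screen is offered at age 65 and outcomes are
tallied over the window ages 65–80. Four scenarios are run on the **same
random draws** (common random numbers), so every difference between
scenarios is caused by the intervention, not by noise:

1. **NoScreen** — natural history only.
2. **RealSensRealTreat** — screen with realistic stage-specific sensitivity
   and realistic post-detection survival.
3. **RealSensPerfectTreat** — realistic sensitivity, but every
   screen-detected cancer is cured.
4. **PerfectSensTreat** — every preclinical cancer is detected and cured.

Writing `I_s` for window clinical incidence and `M_s` for window lung-cancer
mortality under scenario `s`, with `s = 0` the no-screening reference:

- `RCLIR = (1 − I_real/I_0) × 100` — realistic clinical incidence reduction;
- `MCLIR = (1 − I_perfect/I_0) × 100` — the *maximum* clinical incidence
  reduction, the upper bound a perfectly sensitive test could reach;
- `RMOR ≤ ISMOR ≤ MMOR` — the analogous mortality reductions under
  realistic/realistic, realistic/perfect, and perfect/perfect
  sensitivity/treatment.

These induce area decompositions of window cancers (A: screen-detected,
B: missed by imperfect sensitivity, C: not yet detectable) and of window
deaths (A: prevented, B: detected without benefit, C: missed,
D: not yet detectable), plus conditional shares such as
`100·A/(A+B)` — the fraction of screen-detected deaths actually prevented.
Because detection sets are exactly nested across scenarios, the inequalities
`MCLIR ≥ RCLIR` and `MMOR ≥ ISMOR ≥ RMOR` hold per-run, not just in
expectation. The perfect-sensitivity scenario also recovers the generating
sojourn-time distribution from the simulated lead times, with a `1/s`
length-bias correction for the oversampling of long sojourns among
prevalent cases.

Five illustrative built-in profiles
(`miscan-like`, `uombcc-like`, `lcos-like`, `lcpm-like`, `oncosim-like`)
span the published range of stage-specific CT sensitivities — from strongly
stage-graded (≈40% at stage I, ≈98% at stage IV) to nearly uniform (≈91% at
every stage) — and differ in sojourn-time shape and screen-detection
survival benefit. Cross-profile medians and model ranges summarize how much
of a conclusion is model-dependent.

## Worked example

```python
from mclir import PopulationSpec, builtin_profile, run_all_scenarios, compute_report

spec = PopulationSpec(sex="both", smoking="heavy", n_individuals=200_000)
life, outcomes = run_all_scenarios(spec, builtin_profile("miscan-like"), seed=42)
report = compute_report(life, outcomes)
print(report.to_json())
```

Selected output (200,000 heavy smokers — 30 cigarettes/day from age 15,
never quit, i.e. 75 pack-years at the age-65 screen):

```text
"metrics":  {"RCLIR": 6.5, "MCLIR": 9.2, "RMOR": 1.5, "ISMOR": 10.9, "MMOR": 15.0}
"mortality_areas": {"A": 1.5, "B": 9.4, "C": 4.1, "D": 85.0,
                    "screen_detected": {"A": 13.4, "B": 86.6}}
"sojourn_bins": {"lt2": 54.3, "from2to4": 23.0, "from4to5": 6.2, "ge5": 16.5}
```

Reading this: a single realistic screen removes 6.5% of the clinical
cancers that would otherwise be diagnosed in ages 65–80; a perfectly
sensitive screen could remove at most 9.2%, so better test sensitivity can
close a gap of only 2.7 points — 90.8% of window cancers are simply not yet
detectable at the screen. On mortality, the realistic screen prevents 1.5%
of window lung-cancer deaths while the ceiling is 15.0%; of the deaths the
screen *does* detect early, only 13.4% are prevented under this profile's
treatment-benefit assumption, so most of the headroom here lies in
treatment effectiveness, not in test sensitivity. The recovered sojourn
bins show 54.3% of preclinical phases last under two years under this
profile's mixture sojourn distribution.

The same analysis is available from a shell:

```bash
mclir run --profile miscan-like --population heavy --n 200000 --seed 42 --out runs/miscan
mclir run --profile oncosim-like --population heavy --n 200000 --seed 42 --out runs/oncosim
mclir compare runs/miscan runs/oncosim --out runs/cmp   # per-profile rows + median
mclir report runs/miscan --plots                        # postscreening curves
```

`compare` refuses to pool runs whose populations differ, and appends a
median row (with model ranges) to the sensitivity and
mortality-effectiveness tables — the cross-model summary that shows which
conclusions survive a change of natural-history assumptions.

## Layout

- `src/mclir/population.py` — smoking histories, pack-years, cohorts
- `src/mclir/profiles.py` + `profiles/*.yaml` — validated natural-history profiles
- `src/mclir/natural_history.py` — onset, sojourn, stage progression, survival
- `src/mclir/scenarios.py` — the four coupled counterfactual scenarios
- `src/mclir/metrics.py` — reductions, area decompositions, curves, summaries
- `src/mclir/cli.py` — `mclir run / compare / report`

See `docs/methods.md` for modeling assumptions, parameter choices, and
numerical conventions.
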