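# frailtysim

Deterministic system-dynamics projection of frailty in an ageing
population, with a health-service use and cost overlay and policy-scenario
experiments.

Frailty — the state of reduced physiological reserve that accumulates with
age — is routinely measured in English primary care with the electronic
Frailty Index (eFI: 36 deficits, score = deficits/36, categorised fit
< 0.12 ≤ mild < 0.24 ≤ moderate < 0.36 ≤ severe). As populations age, the
number of people living with frailty, and their use of GP and hospital
services, grows even when incidence rates stay constant. `frailtysim` is
for health-services researchers and analysts who want to project that
growth, attach contact volumes and costs to it, and quantify what
prevention, slowed progression or admission avoidance would save.

## Model

The 50+ population is split into 16 stocks: four age bands (50–64, 65–74,
75–84, 85+) × four eFI categories (fit, mild, moderate, severe). With
annual per-capita rates, one year's update of the stock vector *x* is the
affine map

    x(t+1) = M x(t) + e(t) · m

where *M* encodes forward frailty transitions (fit→mild→moderate→severe;
no recovery), age-band promotion, and age×frailty-specific mortality;
*e(t)* is the number of people turning 50 in year *t* and *m* the simplex
splitting them across frailty states. All flows are computed
simultaneously from start-of-year stocks; if a stratum's outflow rates sum
above 1 they are rescaled proportionally, so stocks stay non-negative for
any valid rate set. Band promotion can be a constant per-capita rate
(1/width by default) or a year-varying schedule emulating cohort waves.

On top of the population trajectory, per-person annual contact rates for
nine service categories (GP face-to-face / home visit / telephone /
e-consultation; outpatient, ED, elective, unplanned and critical-care
admissions) give contact volumes, and 2016/17 unit costs give constant-
price costs. Policy scenarios are multiplicative interventions on
transition rates or service rates, compared year-by-year against the
baseline.

Because the engine is exactly affine, `build_affine_map` doubles as an
independent oracle for the stepper, and bounded least squares
(`frailtysim.calibration`) can recover unpublished rates from aggregate
target series — both from synthetic truths and from the packaged
published projection tables (`frailtysim.england`).

## Worked example

```python
import frailtysim as fs

baseline = fs.calibrate_england_baseline()     # fit to packaged tables
outputs = fs.run_pipeline(baseline.initial, baseline.params_fn(),
                          baseline.entries, baseline.service_rates,
                          baseline.unit_costs, 2025, 2040)
stats = fs.summarize(outputs)
print(stats.population_growth_pct, stats.frail_growth_pct,
      stats.prevalence_pct[2025], stats.prevalence_pct[2040],
      stats.frail_cost_change_gbp_bn)
```

prints

```
3.9 12.6 70.2 76.1 10.0
```

— over 2025–2040 the 50+ population grows 3.9% while the number living
with frailty grows 12.6%; prevalence rises from 70.2% to 76.1% of the
50+ population; and the annual cost of services used by people living
with frailty ends £10.0bn higher (2016/17 prices). Running scenario A
(5% lower fit→mild incidence, `examples/policy_scenarios.py`) leaves the
2040 frail count 195,479 lower and saves £4.97bn over the 16 years.

The `examples/` directory has one short script per capability: baseline
projection, policy scenarios, synthetic parameter recovery, and the
packaged reference tables. A thin CLI wraps the same calls:
`frailtysim run|scenario|calibrate|report|fixtures --help`.

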