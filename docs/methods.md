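# Methods

## Model structure

The population aged 50+ is partitioned into 16 compartments ("stocks"):
four age bands (50–64, 65–74, 75–84, 85+) crossed with four eFI frailty
categories (fit, mild, moderate, severe; eFI cut-points 0.12 / 0.24 /
0.36). Time advances in discrete annual steps (forward Euler, dt = 1
year), matching the annual transition rates and annual output tables the
model is built around; dt is not configurable below one year because no
sub-annual rate information exists to drive it.

Per year, four flows act on each stratum, all computed simultaneously
from start-of-year stocks and applied together (avoiding any
order-of-application ambiguity):

* **frailty transition** — fit→mild, mild→moderate, moderate→severe at an
  annual per-capita rate per age band. Frailty never improves: reverse
  rates are structurally absent, reflecting both the observed rarity of
  recorded reversal and the eFI's inability to measure it reliably.
* **mortality** — an annual rate per (band, state).
* **ageing** — promotion to the next band at a per-capita rate; defaults
  are 1/width (1/15, 1/10, 1/10), the open-ended 85+ band only exits by
  death. The rate may be a year-varying schedule (see calibration) to
  emulate cohort waves — explicit counts of people turning 65/75/85.
* **entry** — people turning 50 join the youngest band, split across
  frailty states by an entry mix (configurable; not hard-coded all-fit,
  since measured prevalence in the early 50s is substantial).

If a stratum's per-capita outflow rates sum to s > 1, all its rates are
rescaled by 1/s. Because rates are stock-independent constants, the whole
step — capping included — is exactly affine, `x(t+1) = M x(t) + e(t) m`.
`build_affine_map` constructs (M, m) explicitly and is the independent
oracle for the stepper: `run()` must agree with iterated matrix
multiplication elementwise to 1e-9 relative, which the suite checks over
100 seeded rate sets.

**Year accounting.** `run(start, end)` stores start-of-year stocks for
every calendar year in [start, end] and a flow ledger for the steps
start..end−1; `run(y, y)` is the degenerate run holding only the initial
stocks. Annual incidence — defined as the fit→mild flow — is reported for
every stock year including `end`, computed as rate × start-of-year stock
(the identical arithmetic the ledger records for earlier years). A
2025–2040 horizon therefore has 16 stock years, 16 incidence years, and
horizon-years = 16 for per-annum averages. One modelling simplification
follows from the stepwise flows: an incidence definition that admits
fit→moderate jumps within a year cannot be represented; all incidence is
counted on the fit→mild edge.

**Invariants.** Conservation (total change = entrants − deaths, 1e-9
relative), non-negativity of all stocks and flows for any valid rate set,
and no-recovery are tested as properties. Monotone frailty ordering —
raising one transition rate never lowers downstream frail stocks — holds
whenever capping is inactive and is tested there; under capping a higher
transition rate also rescales the stratum's mortality and ageing, which
can break the ordering, so the property is only claimed for sub-unit
outflow sums.

## Service-use and cost overlay

Annual per-person contact rates, indexed (band, state, category) over
nine categories — GP face-to-face, home visit, telephone, e-consultation
(sector: primary care); outpatient, ED attendance, elective admission,
unplanned admission, critical care (sector: secondary & urgent care) —
are applied to start-of-year stocks; unit costs per contact (GBP,
2016/17 base) turn contacts into costs. Projections are reported in
constant base-year prices; the 3.5%-per-year inflation helper exists only
to harmonise unit costs quoted against other base years and round-trips
exactly. Aggregations (sector × fit/frail/total) are additive by
construction and linear in stocks, rates and unit costs; display rounds
contacts to 0.1 million and costs to 0.1 GBP m, with all arithmetic
unrounded underneath.

## Scenarios

Scenarios are multiplicative interventions: factors per (band, transition)
on population flows and per category on service rates, with the all-ones
spec reproducing the baseline bit-identically. Built-ins: **A**
(prevention) fit→mild × 0.95 everywhere; **B** (slowed progression)
mild→moderate × 0.90 and moderate→severe × 0.95 simultaneously; **C**
(admission avoidance) unplanned-admission rate × 0.975, population flows
untouched — admission prevention is treated as service-demand reduction
with no feedback into frailty dynamics. The phrase "x% reduction per
year" is ambiguous between a constant factor and a factor compounding
yearly; the default is constant (parallel with how A reads), and a
compounding mode (factor^(t+1) in year t) is provided without presenting
either as certain. Comparison reports give year-wise deltas
(baseline − scenario), cumulative saving, and per-annum saving
(cumulative / horizon-years). Two savings notions are exposed: net (all
strata) and frail-group (costs incurred by people living with frailty);
flow scenarios keep people alive and fit longer, so the frail-group
saving exceeds the net saving, and headline scenario savings are
conventionally quoted for the frail group.

## Calibration

`frailtysim.calibration` fits any named subset of rates, initial stocks,
entry counts or service rates — addressed as e.g.
`transition:65-74:fit_mild`, `initial:85+:severe`, `entries:2030` — by
bounded least squares (scipy trust-region reflective) on a weighted sum
of squared **relative** residuals, so person counts (millions) and costs
(GBP m) mix without rescaling. The contract is determinism given the
starting point and bound feasibility; convergence status, per-target
residuals and the Jacobian rank at the solution are always reported, so
flat directions (unidentifiable combinations) are flagged rather than
hidden. On noiseless engine-generated targets with per-stratum stock
series, all 12 transition rates are recovered to ≈1e-12 relative from
starting points 1.5× the truth, across 20 seeded problems. With only
aggregate targets (overall frail counts), rank deficiency appears and is
reported — which is exactly the behaviour the identifiability flag
exists for.

## The reference England baseline

The published projections print aggregates (incidence by band, contacts
and costs by sector × fit/frail, headline totals and scenario effects)
but none of the underlying rates. `frailtysim.england` recovers a
parameterisation consistent with those aggregates in three layers:

1. **Fit column, closed form.** Incidence is the fit→mild flow and
   nothing flows into the fit column except entrants, so given fit→mild
   rates the fit stocks are pinned exactly (stock = incidence / rate).
   The printed incidence series carry cohort waves (the 75–84 column
   falls then rises; 85+ wiggles twice) that a constant per-capita
   ageing chain provably cannot reproduce below ≈3–6% error; with a
   year-varying promotion schedule — the natural representation of
   population projections of people turning 65/75/85 — the promotion and
   entrant series that reproduce the incidence table exactly are read
   off the band-by-band balance equations in closed form. The fit→mild
   rates are chosen closest (relatively) to a literature-scale prior
   subject to the fit-column totals matching printed population − frail
   totals in 2025 and 2040. A consequence worth stating: the printed
   aggregates themselves force high fit→mild turnover in the younger
   bands (≈0.12–0.14/yr) and an entrant series above demographic
   estimates of people turning 50 (~1.1M/yr) — the entrants absorb all
   unmodelled inflow into the open cohort, so they are calibration
   quantities, not demographic estimates.
2. **Frail side, lever fit.** The initial frail stocks are scaled to the
   printed 2025 frail total exactly; eight composition-preserving levers
   (a mild↔moderate/severe shift, young/old mortality scales for mild
   and for moderate+severe, two progression-rate scales, and the entry
   fit share) are then fitted to four printed dynamics targets — the
   2040 frail and moderate+severe totals and the published frail-count
   effects of the prevention and progression scenarios — with weak
   priors holding the levers near literature-scale anchors where the
   targets leave them free. The achieved fit is < 0.001% on every
   target; it is one consistent parameterisation among many, and the
   fit diagnostics flag it as not individually identifiable.
3. **Service rates, one linear fit.** Given the frozen trajectory,
   contacts and costs are linear in the 144 per-stratum category rates,
   so a single bounded linear least squares (BVLS) fits them to the 128
   printed contact/cost cells plus constraints that the tables alone
   cannot supply: the unplanned-admission volume and unit cost implied
   by the published admission-avoidance arithmetic (2.48M admissions at
   a 2.5% reduction ⇒ 99.2M cumulative; GBP 4.2bn / 2.48M ⇒ ≈GBP 1694
   per admission), and the published scenario A/B frail-group contact
   reductions and savings, which are linear in the rates because the
   population-side scenario deltas are already fixed. Remaining unit
   costs are representative 2016/17 reference values. Every printed
   contact/cost cell is reproduced within 0.65%, and all scenario
   outputs within ≈1% of print.

Published aggregates are used here as calibration inputs, which is the
package's stated purpose where source rates are unpublished; the
acceptance tolerance (2% relative on the fitting targets) was fixed
before fitting and is not adjusted to outcomes.

## Synthetic data

Everything stochastic lives in `frailtysim.synthetic`: seeded uniform
draws within configurable ranges for transition rates (optionally
age-monotone), band-level mortality with a frailty gradient, a Dirichlet
entry mix, entrant counts, service rates graded frail ≫ fit, and
jittered unit costs. Defaults emulate a high-prevalence ageing
population: ~23.1M initial population with ~69% measured frailty,
600–800k entrants/year, and rate magnitudes that produce a mid-70s-%
prevalence plateau over a 16-year run — illustrative of the regime, not
estimates. `make_truth` runs the real engine on a generated world and
returns both the parameters and the observables, which is the
parameter-recovery harness. What the generator does **not** emulate:
individual-level GP records or eFI deficit codes, covariate structure
(sex, ethnicity, deprivation), measurement noise in observed series, or
cohort waves in ageing (it uses constant promotion rates). Passing
recovery tests therefore show the estimator is correct on data generated
by the model's own mechanism; they do not show the model fits real
cohorts.

The packaged reference tables ship as versioned CSV with SHA-256
integrity checks, exactly as printed — including a 65–74 incidence
column total computed before rounding (2 509 209 vs a rounded-sum
2 509 200) and one cost row whose printed operands differ from its
printed total by two display units; tests compare at printed precision
with slack only for these documented pre-rounding artefacts.

## Numerical choices and degenerate inputs

Outflow capping guarantees non-negativity for arbitrary valid rates; a
post-step clamp zeroes magnitudes below 1e-9 persons arising from
floating-point cancellation. Prevalence of an empty population raises
rather than returning a silent zero. Entry-mix weights freed during
calibration are renormalised to the simplex after each update. Display
rounding is half-up (ties away from zero) at 1 dp for percentages and
GBP bn, nearest million for per-annum savings; no intermediate rounding
anywhere. Config files are schema-validated YAML (`schema_version: 1`)
with every failing field listed; run outputs are written atomically with
a manifest of input hashes, package version and timestamp, and rerunning
with unchanged inputs reproduces every output byte-for-byte except the
manifest timestamp.

## Known limitations

Aggregate stocks only — no individual-level microsimulation, no
covariates beyond age × frailty, no frailty reversal, no continuous-time
solver. The costing covers publicly funded primary and secondary/urgent
health care only: social care, community care, informal and privately
funded care are out of scope. The reference baseline holds incidence,
progression, demographic trends and service provision constant over the
horizon, and its recovered rates are one consistent parameterisation of
the printed aggregates, not estimates of the unpublished source rates;
quantities the printed aggregates do not constrain (e.g. the split of
secondary-care contacts across categories beyond the pinned unplanned
volume) should not be interpreted. Scenario effects are first-order
service-demand arithmetic: no intervention costs, no cost-effectiveness,
no interaction between combined scenarios.
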