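# Methods

## Model

`polypillce` implements a Markov cohort cost-utility model comparing a
fixed-dose cardiovascular polypill (aspirin + atorvastatin + ramipril)
against the same monocomponents taken loosely, in a secondary-prevention
cohort with prior coronary heart disease (CHD) or stroke, from the payer
perspective of the Portuguese health service (2020 euros).

A hypothetical cohort of 1000 identical-mixture patients enters the model
in the stable secondary-prevention state, split 57.9% post-CHD / 42.1%
post-stroke. Each cycle, patients may suffer a recurrent cardiovascular
event — nonfatal CHD (→ acute CHD state), nonfatal stroke (→ acute
stroke state), or a fatal event (→ CV death) — or die of non-CV causes.
Acute states last exactly one cycle before the survivor returns to a
stable state. The first model year uses four 3-month cycles (the
high-risk window after an index event), annual cycles thereafter.

### State space

The drawn model has 4 health states, but chronic utility and follow-up
cost depend on which events a patient has survived. The engine therefore
expands each alive state by an event-history tag (post-CHD, post-stroke,
both), giving 11 states: 3 stable, 3 acute-CHD, 3 acute-stroke, CV death
and non-CV death. A nonfatal stroke in a post-CHD patient moves them to
acute-stroke(both); "both"-history patients take the lower of the two
chronic utilities (0.69, the stroke value) and the higher of the two
annual follow-up costs (the post-CHD value — higher-burden assumption,
overridable through the cost inputs).

### Transition probabilities

Base case: the SMART recurrent-event equation, a Cox model over the
cohort's mean risk-factor profile. The 10-year composite risk of a major
CV event is `risk10 = 1 − S0^exp(lp)` with S0 = 0.8107. The linear
predictor is evaluated at cohort means; binary covariates enter as
prevalence fractions (expected-value approximation appropriate for a
cohort — not micro — simulation). Coefficients are shipped as a data CSV
(`data/smart_coefficients.csv`) with per-term transforms (identity, log,
square, indicator, offset); lipid terms are converted to per-mg/dL so the
profile's native units apply directly. Risk is converted to the cycle
length assuming a constant rate: `p = 1 − (1 − risk10)^(len/10)`, and is
recomputed every cycle with age and years-since-first-event advanced by
elapsed model time (the minimal covariate dynamic consistent with rising
lifetime risk; other covariates stay at arm-adjusted baseline).

The composite probability is split into CHD vs stroke by
`chd_share_of_events` and into fatal vs nonfatal by per-type case-fatality
fractions; components re-sum to the composite exactly. Non-CV mortality
comes from a general-population life table (sex-blended annual qx at
floor(age), converted to cycle length). Within a cycle, non-CV death
takes its full probability and the event split is scaled by (1 − m),
keeping each transition row stochastic; alternatives differ at O(p·m).

Scenario route ("framingham"): a subsequent-CHD equation and a
primary-stroke equation scaled by the recurrent-vs-primary relative risk
(capped at 1). The two per-cycle probabilities are combined as competing
risks — P(any) = 1 − (1−p₁)(1−p₂), allocated proportionally — so the row
stays stochastic even where the equations saturate at extreme ages. The
shipped Framingham-style coefficient files are synthetic reconstructions
(marked as such in their filenames and headers): plausible functional
forms calibrated to realistic risks at the base profile, not
transcriptions of published equations.

### Treatment arms

The comparator sits at the baseline (Table-of-inputs) risk-factor values;
the intervention applies the published incremental deltas on top
(SBP −1.80 mm Hg, TC −5.28 mg/dL, HDL +4.01 mg/dL) and a higher annual
drug cost (€84.62 vs €63.44). Alternative-comparator scenarios derive
their deltas from the printed 2-year follow-up means (equipotent
alternatives: 2.6 / 23.4 / 2.4; usual care: −3.4 / 23.5 / 3.6 with the
comparator drug cost weighted by the mean 81.5% treatment coverage). No
adherence decay is modelled: effectiveness, not adherence, is the
modelled mechanism.

### Accounting

- Life-years: alive occupancy × cycle length; QALYs additionally weight
  by state utility (chronic CHD 0.84, chronic stroke 0.69, acute CHD
  0.76, acute stroke 0.63, death 0). Acute utilities apply for exactly
  one cycle.
- Drug cost accrues to all alive states pro-rated by cycle length.
  Annual follow-up cost accrues to stable states only: acute-event costs
  are all-inclusive for the acute cycle (they cover the episode and its
  first year of management), so paying follow-up during an acute cycle
  would double count.
- Acute and fatal event costs are charged once, at incidence, by type
  and fatality (€4560.1 / €3153.5 nonfatal/fatal CHD; €8653.3 / €6381.2
  nonfatal/fatal stroke). Death accrues nothing thereafter.
- Half-cycle correction: state-time accruals use the trapezoid of start-
  and end-of-cycle occupancy (exact for linear decay); incidence-based
  accruals are attributed at the transition and not corrected.
- Discounting: 4%/year applied after the first year; all cycles starting
  in year one share factor 1, later cycles use (1.04)^(−floor(t)). This
  follows the stated "yearly basis after the first year" literally; a
  fractional-exponent variant would differ by < 2% on year-one cycles.
- Event counts are undiscounted expected counts scaled to the cohort.

## Inputs the published table does not carry

Four epidemiology inputs live only in unpublished supplementary files and
are supplied as documented defaults (`synthetic_data.EPI_DEFAULTS`),
chosen once on domain grounds and exposed in the parameter file:
CHD share of composite events 0.579 (reuses the cohort history
weighting), case fatality 0.16 (CHD) and 0.18 (stroke) — literature-order
28-day values that keep fatal events a minority of events — recurrent- vs
primary-stroke relative risk 2.3, and years since first event 1.0 at
entry.

The life table is generated from a Gompertz hazard `qx = 1 − exp(−a·e^{b·age})`
(a = 2.8e-5, b = 0.0975, female hazard ratio 0.52, cap at 105), calibrated
so blended period life expectancy at birth is ≈ 81 years with a realistic
female advantage. Any national life-table CSV (`age,qx_male,qx_female`)
can be swapped in through the parameter file without code changes. The
generator reproduces the age-structure of real mortality but none of its
period effects (cohort trends, accident humps), so absolute LY totals are
indicative rather than reproductions of the published values.

Because these inputs (and the SMART coefficient transcription) differ
from the unpublished originals, the package reproduces the published
analysis *structurally* and *directionally* — positive incremental LY and
QALY at an ICUR far below €30 000/QALY, ICURs falling strictly with
horizon, dominance under the alternative comparators — rather than
digit-for-digit. The shipped base case lands at ICUR ≈ €1.8k/QALY vs the
published €1557, with prevented-event counts of the same order.

## Sensitivity analyses

One-way (OWSA): every scalar input swept alone to 0.8× / 1.2× base, all
else fixed; entries ranked by spread for tornado display. Excursions are
mechanical — a utility may exceed 1 at the high bound — and are
deliberately not re-validated, so the ±20% contract holds exactly.

Probabilistic (PSA): all uncertain inputs drawn jointly, standard error
20% of the mean by default (per-parameter overrides accepted):

| family    | inputs | notes |
|-----------|--------|-------|
| normal    | continuous population characteristics; treatment deltas; risk-equation coefficients | beta is ill-posed for unbounded mmHg/mg-dL deltas, so normal is used for them; the centring offset is calibration, never sampled |
| beta      | prevalences, history weights, case fatalities, CHD share, utilities, baseline survival | moment-matched (α = m(m(1−m)/v − 1)); infeasible variance falls back to a truncated normal with a logged warning |
| gamma     | all costs | shape m²/v, scale v/m |
| lognormal | recurrent-stroke relative risk | moment-matched on the log scale |

Draws are truncated to valid ranges (acute ≤ chronic utility, fractions
in [0,1], positives > 0). Each iteration uses a substream spawned from
the master seed, so an n-iteration run is a prefix of any longer run with
the same seed. The summary "mean ICUR" is the ratio of means
mean(Δcost)/mean(ΔQALY) — the conventional single average of a PSA
cloud — with the mean of per-draw ratios exported alongside.

## Numerical contracts checked by the test suite

- Occupancy conserves to 1 ± 1e−10 every cycle on every fixture.
- Four quarterly survival probabilities compose to the annual one to 1e−12.
- The trapezoidal correction is exact on linear occupancy decay (1e−12).
- A seeded 100 000-walker microsimulation through the same transition
  matrices matches cohort LY, QALY and event totals within 3 Monte-Carlo
  standard errors (run on the 2-year "tiny" fixture — baseline survival
  inflated to 0.45 — which exercises every transition type cheaply).
- With the SE scale at 0 the PSA collapses onto the deterministic run
  (1e−6).

Problem sizes used by the shipped analyses: cohort 1000, lifetime horizon
32 years (35 cycles), PSA 1000 iterations; these match the published
design, and the scenario grid re-runs the model at horizons 2/5/10/20.

## Known limitations

- No tunnel states: risk does not escalate with accumulated recurrent
  events (explicitly out of scope), and no incremental disutility for
  multiple events.
- No adherence modelling, copayments, societal perspective or budget
  impact.
- Cohort-mean (expected-value) evaluation of a nonlinear risk equation
  ignores within-cohort covariate dispersion; for the modest risks here
  the convexity bias is small but not zero.
- The Framingham-route coefficient files are synthetic stand-ins; that
  scenario demonstrates the two-equation machinery, not a published
  equation's output.
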