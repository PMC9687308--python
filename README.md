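# polypillce

Markov cohort cost-utility model of a fixed-dose cardiovascular polypill
(aspirin + atorvastatin + ramipril) versus the same monocomponents taken
loosely, for secondary prevention in patients with prior coronary heart
disease (CHD) or stroke. Built for health economists and modellers who
want a transparent, scriptable re-implementation of a published
polypill cost-utility analysis for the Portuguese payer setting —
with every input in one editable YAML file.

## The model in brief

A cohort of 1000 patients (57.9% post-CHD, 42.1% post-stroke) moves
through stable, acute-CHD, acute-stroke and death states in 3-month
cycles for the first year and annual cycles thereafter, over a 32-year
lifetime horizon. Recurrent-event risk comes from the SMART equation,

    risk₁₀ = 1 − S₀^exp(lp),   S₀ = 0.8107,

evaluated each cycle at the cohort's (arm-adjusted, age-advanced) mean
risk-factor profile and rescaled to the cycle length at constant rate.
The composite risk is split into CHD/stroke and fatal/nonfatal events;
non-CV mortality comes from a life table. Costs (drug, acute-event,
follow-up) and QALYs are accrued with half-cycle correction and
discounted at 4%/year after year one. The headline outputs are

    ICER = Δcost / ΔLY,   ICUR = Δcost / ΔQALY,   NMB = λ·ΔQALY − Δcost

for the polypill arm versus the monocomponent arm, plus one-way
(tornado) and probabilistic (CEAC, scatter) sensitivity analyses and a
scenario grid (horizons 2/5/10/20 years, a two-equation Framingham
route, alternative comparator cohorts). See `docs/methods.md` for the
full specification of states, accrual rules and distributions.

## Worked example

```python
from polypillce import MarkovCostUtility

model = MarkovCostUtility.from_yaml()   # packaged base case
results = model.fit()
print(results.summary())
```

prints (abridged):

```
Markov cohort cost-utility comparison (cohort of 1000, 32-year horizon, 4% discount)
                          polypill  monocomponents  incremental
Total cost (EUR)       10571601.42     10503165.39     68436.03
  drug cost              895846.38       668968.86    226877.52
  acute event cost      3577360.02      3774158.39   -196798.37
  follow-up cost        6098395.02      6060038.15     38356.87
Life-years (disc.)        10586.70        10544.91        41.79
QALYs (disc.)              8112.90         8075.41        37.48
Subsequent CHD events       482.24          506.99       -24.74
Recurrent strokes           342.30          359.86       -17.56
CV deaths                   166.99          175.56        -8.57

ICER: 1,638 EUR/LY gained
ICUR: 1,826 EUR/QALY gained
Dominance: none
NMB at 30,000 EUR/QALY: 1,056,082 EUR
```

Read: over the cohort's lifetime the polypill strategy costs €68k more
(drug spending up €227k, partly offset by €197k of acute events
avoided), prevents ~25 CHD events, ~18 strokes and ~9 CV deaths per
1000 patients, and buys 37.5 discounted QALYs — about €1.8k per QALY
gained, far below the €30 000/QALY willingness-to-pay threshold.

Uncertainty and scenarios hang off the results object:

```python
psa = results.run_psa(n_iter=1000, seed=1)
psa.prob_cost_effective(30_000)   # ≈ 0.73
psa.prob_cost_saving()            # ≈ 0.41
tornado = results.run_owsa()      # tornado['icur'][0] is the top driver
table = results.scenario_table()  # horizons, Framingham, alt. comparators
```

The same analyses are available from the shell:

```bash
polypillce run                 # deterministic base case + traces
polypillce psa -n 1000 --seed 1 --plot
polypillce owsa
polypillce scenarios
polypillce report --out results/
```

All inputs live in `src/polypillce/data/basecase_portugal.yaml`; point
`--config` at a copy to change the country prices, cohort profile, or
the life table (any `age,qx_male,qx_female` CSV).

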