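# stepmi

Handling missing daily step-count outcomes in randomized trials: wear-time
classification, day-substitution, interval-censored (Tobit) multiple
imputation by chained equations, MNAR delta-adjustment sensitivity analysis,
and a heteroscedastic-by-arm primary analysis pooled by Rubin's rules — with
a synthetic trial generator so the whole pipeline is testable end to end.

## What it does

Accelerometer trials measure steps in short epochs over 7-day windows at
several occasions. Days are classified by wear time (runs of zero-step
epochs of 60+ minutes count as non-wear): **observed** (wear >= 540 min),
**partial** (0 < wear < 540; the count is a right-censored lower bound) or
**missing** (wear 0). `stepmi` implements a decision framework over four
choices — substitute days from the following week, impute partials as
censored, assume MAR vs a delta-adjusted MNAR, include auxiliary variables
(BMI and daily weather) — packaged as five named scenarios (`plausible`,
`suspicious`, `plausible-no-aux`, `replace-days`, `dismissive`).

Imputation works on log daily counts, cycling Tobit regressions of each
(year, weekday) cell on the other days, analysis covariates and optional
auxiliaries, separately per arm. Completed datasets are week-averaged and
analysed with a bivariate linear model with arm-specific unstructured 2x2
residual covariance; the M fits are pooled with Rubin's rules
(Barnard-Rubin degrees of freedom) and reported as arm-vs-usual-care
contrasts at years 1 and 2.

## CLI

```bash
# synthetic trial with known truth (optionally epoch-level streams)
stepmi simulate --n 200 --seed 1 --out data/ [--epochs]

# epoch streams -> classified day records
stepmi classify --epochs data/epochs.csv --run-minutes 60 --cutoff 540 --out days.csv

# day-substitution from the following week
stepmi substitute --days data/days.csv --participants data/participants.csv \
    --strategy same-weekday --out subbed.csv --report report.csv

# chained Tobit imputation under a scenario's decisions
stepmi impute --days data/days.csv --participants data/participants.csv \
    --aux data/aux.csv --scenario plausible --m 20 --cycles 10 --seed 1 --out imp/

# MNAR delta-adjustment
stepmi adjust --imputed imp/ --delta 0.95 --statuses missing,partial --out adj/

# week-average, fit, pool, contrast
stepmi analyze --imputed imp/ --participants data/participants.csv --out results/

# or everything at once for a named scenario
stepmi run --data data/ --scenario suspicious --m 20 --cycles 10 --seed 1 --out results/
```

Small arms can exhaust the per-arm imputation designs; pass `--pool-arms`
to fit shared coefficients with arm indicators.

## Python API

```python
from stepmi import (SimConfig, simulate_trial, ImputationSpec,
                    get_scenario, run_scenario)

ds, truth = simulate_trial(SimConfig(n_participants=300, seed=1,
                                     mechanism="mcar", p_missing=0.2))
res = run_scenario(ds, get_scenario("plausible"),
                   ImputationSpec(m=20, cycles=10, seed=1, pool_arms=True))
print(res.contrasts)       # arm-vs-usual-care differences, years 1 and 2
print(res.pooled.table)    # Rubin-pooled fixed effects
```

## Layout

- `src/stepmi/accel.py` — epoch streams, non-wear detection, day classification
- `src/stepmi/substitution.py` — day-substitution and its report
- `src/stepmi/trial_data.py` — data model, CSV I/O, photoperiod
- `src/stepmi/imputation.py` — bounds, interval regression, chained imputation
- `src/stepmi/mnar.py` — delta-adjustment
- `src/stepmi/analysis.py` — week averages, primary fit, Rubin pooling, contrasts
- `src/stepmi/scenarios.py` — the five presets and the end-to-end runner
- `src/stepmi/simulate.py` — synthetic trial generator with known truth
- `src/stepmi/cli.py` — the `stepmi` command
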