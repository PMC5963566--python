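# harvestrisk

Harvest-risk stock assessment for a density-regulated marine-mammal stock.
The pipeline reconstructs total removals from sparse, era-heterogeneous
catch records (missing-year fills, underreporting, struck-and-lost
correction), maps life-history priors to a maximum per-capita growth rate
via the Euler–Lotka equation, fits generalized-logistic (Pella–Tomlinson)
dynamics to abundance surveys by sampling-importance-resampling, projects
the posterior five years forward under candidate catch levels, and advises
the largest quota that lets the stock increase with at least 70%
probability. Subsistence-demand arithmetic (hunters × per-hunter annual
walrus need) is included for comparing advice against community demand.

## Modules

| module | purpose |
|---|---|
| `harvestrisk.catch_history` | missing-year fills, loss schedule, removals reconstruction |
| `harvestrisk.demography` | Euler–Lotka growth multiplier from survival/maturity/birth-rate priors |
| `harvestrisk.dynamics` | generalized-logistic projection with removals; MSYL diagnostic |
| `harvestrisk.inference` | SIR fit of the dynamics to log-normally noisy surveys |
| `harvestrisk.risk_advice` | probability-of-increase curves, quota advice, subsistence demand |
| `harvestrisk.synthetic_data` | known-truth scenario generation for round-trip testing |
| `harvestrisk.io` / `harvestrisk.cli` | CSV/YAML formats and the `assess` command line |

## CLI

```bash
# generate a known-truth fixture scenario
assess simulate-scenario --config scenario.yaml --out-dir fixtures/

# full pipeline: reconstruct -> fit -> advise
assess run --catches fixtures/catches.csv --surveys fixtures/surveys.csv \
           --config assess.yaml --seed 42 --out-dir results/

# individual stages
assess reconstruct --catches catches.csv --start 1900 --end 2016 --out removals.csv
assess fit --removals removals.csv --surveys surveys.csv --draws 50000 \
           --resample 5000 --seed 42 --out posterior.csv
assess advise --posterior posterior.csv --criterion 0.70 --horizon 5 \
              --grid 0:200 --out advice.json
assess demand --hunters 60 --per-hunter 12 --quota 85
```

Input formats: catches CSV (`year,landed,documented,source`; empty `landed`
for undocumented years), surveys CSV (`year,estimate,cv`), YAML assessment
config (priors, loss schedule, projection spec; defaults encode the
standard constants: 5%/30% losses ramping linearly over 1960–1970,
uniform life-history priors, carrying capacity capped at 5000, 70%
criterion over a 5-year horizon).

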