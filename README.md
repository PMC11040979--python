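# t2dsim

Discrete-event state-transition microsimulation of type 2 diabetes (T2D)
incidence, prevalence and DALYs in a heterogeneous population stratified by
age, sex, region, province, education and income.

The model advances a synthetic population in annual cycles. Each year every
alive individual ages by one year, the modifiable risk factors (BMI class,
waist-circumference class, blood-pressure medication, history of high blood
glucose) move through calibrated *net* annual transition probabilities,
healthy adults aged 35+ face a Bernoulli T2D-onset draw at the annualised
concise-FINDRISC 10-year risk, and everyone faces a death draw — cause-deleted
mortality for the healthy, relative-risk-adjusted all-cause mortality for
people with T2D. Onset and death may fall in the same year; T2D is absorbing.

## Package layout

| module | role |
| --- | --- |
| `t2dsim.synthpop` | survey-like fixture generation and expansion to population marginals by weighted resampling |
| `t2dsim.dynamics` | age-smoothed prevalence curves, Nelder–Mead calibration of net transition matrices, multinomial application |
| `t2dsim.findrisc` | concise FINDRISC logistic risk and the 10-year → 1-year constant-hazard conversion |
| `t2dsim.mortality` | mortality and relative-risk tables, rate → probability conversion, cause attribution |
| `t2dsim.engine` | the annual-cycle simulation loop (seeded, byte-reproducible) |
| `t2dsim.burden` | incidence/prevalence/mortality rates per 100,000, YLL/YLD/DALY accounting, percent change |
| `t2dsim.inequality` | ridit-based RII and SII, ICC agreement, trend test |
| `t2dsim.uncertainty` | probabilistic sensitivity analysis with percentile uncertainty intervals |
| `t2dsim.interface` | YAML-configured end-to-end pipeline, run manifest |

Every input has a bundled synthetic default (demo marginals, Gompertz-like
mortality, relative-risk bands, age-prevalence curves), so the package runs
out of the box with no external data.

## CLI

```bash
t2dsim synthpop --seed 1 --scale 100 --out population.csv
t2dsim calibrate --out transitions.csv
t2dsim run --population population.csv --seed 1 --out outdir/
t2dsim burden --log outdir/events.csv --history outdir/history.csv --out burden.csv
t2dsim inequality --burden burden.csv --axis education --out inequality.csv
t2dsim pipeline --seed 1 --out demo/          # every stage + manifest.json
```

`--scale N` divides the national-scale marginals by `N` (default 100,
≈114k individuals, which runs end to end — including a 100-run PSA on a 1%
subsample — in a couple of minutes on one CPU).

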