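# flockvalue

Bio-economic modelling of smallholder sheep flocks: solve the stationary
(zero-growth) flock for a given set of demographic and price parameters,
value its annual physical output, and estimate the gross and net cost of
young-stock (lamb) mortality under mortality and fertility scenarios.

The flock has six compartments ({female, male} × {lamb 0–6 m, sub-adult
6–12 m, adult}). Breeding females anchor the flock; adult males are tied
to them by a fixed ratio. Adult offtake of each sex is solved in closed
form so that every compartment is constant year over year (or grows at a
chosen constant rate, with the inventory change valued as revenue). On
top of the solver, the analysis layer sweeps lamb mortality, computes
revenue per head / per ewe / per 100 kg feed dry matter, gross margins,
the cost of a mortality level relative to a lower one, marginal returns
per mortality step, a fertility sensitivity comparison, and
population-level extrapolations.

A calibrated baseline parameter fixture for Ethiopian mixed
crop-livestock sheep ships with the package
(`src/flockvalue/data/baseline_mcl_sheep.yaml`).

## Library quick start

```python
from flockvalue import (ScenarioSpec, cost_of_ysm, load_baseline_parameters,
                        sweep_ysm)

demo, prices = load_baseline_parameters()
sweep = sweep_ysm(demo, prices, ScenarioSpec())
print(sweep.at(0.20).metrics.per_head)        # USD per head and year
cost = cost_of_ysm(sweep, baseline_ysm=0.20, target_ysm=0.0)
print(cost.gross_cost_per_head, cost.net_cost_per_head)
```

## Command line

```sh
flockvalue params validate my_params.yaml
flockvalue run --out report/            # sweep, cost summary, report table
flockvalue run --mode growth --growth-rate 0.102 --out report_growth/
flockvalue synth --seed 7 --n 10 --out synth/   # random feasible parameter sets
```

`flockvalue run` writes `sweep.csv`, `cost_of_ysm.json`,
`flock_table.csv`/`.txt` (inventory / deaths / offtake / value blocks per
mortality scenario) and `parameters.csv`; add `--plot` for a
revenue-vs-mortality figure (requires matplotlib).

## Notes on conventions

* Class rates are interpreted as per-class risks by default; an
  engine-level `convention="hazard"` switch treats them as competing
  exponential hazards instead.
* All money is accounted in Birr and converted to USD once per statement
  (43 Birr/USD in the baseline fixture).
* Feed dry matter (2.6% of live weight per day) and manure output both
  scale with standing flock biomass.
* Stocks are fractional head (deterministic model); rounding to one
  decimal happens only in the report table.
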