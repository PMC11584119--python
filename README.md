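# duocea

A deterministic Markov cohort model of the cost-effectiveness of
DSI-guided management for patients with chronic liver disease suspected
of having esophageal varices.

## The problem

Patients at risk for large esophageal varices are conventionally screened
and surveilled by endoscopy (EGD): an initial detection endoscopy, then
repeat EGD every two years (no varices), yearly (small varices), or twice
yearly (large varices), plus twice-yearly labs/AFP and ultrasound HCC
surveillance. EGD is expensive and carries a small procedural mortality.

The DuO oral cholate challenge test produces a Disease Severity Index
(DSI, 0–50). A cutoff of 18.3 partitions patients into a stable-function,
low-risk stratum (DSI ≤ 18.3) and a poor-function, high-risk stratum
(DSI > 18.3), enabling three management decisions:

1. **avoid endoscopy** in the low-DSI stratum,
2. **reduce follow-up** (yearly labs, ultrasound every two years) in the
   low-DSI stratum,
3. **improve adherence** to management guidelines in the high-DSI
   stratum, reducing progression to decompensated cirrhosis (DC) by 35%.

This package asks: for a 100,000-patient cohort, at what DuO test price
is the DSI-guided strategy cost-saving or highly cost-effective relative
to standard of care, and how many DC cases, deaths, and QALYs does it
change?

## The model

An annual-cycle cohort model over health states
{no varices; small varices ± variceal hemorrhage (VH); large varices
untreated ± VH; large varices treated ± post-treatment bleeding; DC first
year; DC subsequent years; dead (liver / procedure / other)} × DSI
stratum. Cohort mass is conserved exactly; all arithmetic is
expected-value (no microsimulation). Annual costs (USD) and utility
weights (QALY/yr) per state, discounted at 3%/yr with year 1
undiscounted, give per-year ledgers; the incremental cost-effectiveness
ratio is ICER = ΔCost/ΔQALY against a $20,000/QALY threshold
("highly cost-effective" below 1×, or outright cost-saving). Total
discounted cost is affine in the test price, so break-even prices
(ΔCost = 0 at a given year) have an exact closed form. All uncertain
inputs are betaPERT(min, mode, max) distributed; see
[docs/methods.md](docs/methods.md) for every assumption and switch.

## Worked example

```python
from duocea import StrategyConfig, compare_strategies, default_parameters

p = default_parameters()                      # the published input tables
strategy = StrategyConfig.intervention(price=3250.0)   # all three decisions
result = compare_strategies(p, strategy, horizon=5)
print(result.frame)
```

prints (abridged; `examples/run_base_case.py`):

```
 year     delta_cost  delta_qalys      icer     classification  dc_averted  deaths_averted
    1   19,909,159.3         91.6 217,436.5 not cost-effective     1,724.3            -7.5
    2  -22,263,919.7        487.8       NaN        cost-saving     3,173.7           202.6
    3  -79,292,390.7      1,259.3       NaN        cost-saving     4,387.7           567.7
    5 -210,403,011.1      4,030.2       NaN        cost-saving     6,239.7         1,573.4
```

Reading: at a $3,250 test price the DSI-guided strategy costs ~$20M extra
in year 1 (every patient is tested), is already cost-saving from year 2,
and over five years averts 6,240 incident DC cases and 1,573 deaths,
gains 4,030 discounted QALYs, and saves $210M in direct medical costs.
Break-even pricing (`examples/break_even_pricing.py`) shows the combined
strategy is cost-neutral at $3,403 per test at two years and $4,054 at
five; the what-if sweep (`examples/price_what_if.py`) shows the time to a
highly cost-effective intervention stretching from 1 year at $1,000 to
9 years at $5,000.

Each script in `examples/` demonstrates one capability: the base case,
break-even pricing, the price sweep, tornado and probabilistic
sensitivity analysis, and parameter-file handling. The same analyses are
available from the shell:

```sh
duo-cea reproduce --out results/       # full report bundle
duo-cea breakeven --year 2 --decisions all
duo-cea sweep --prices 1000:5000:500
```

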