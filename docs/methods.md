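# Methods

## Model structure

The cohort is a continuous (expected-value) population of 100,000
patients with chronic liver disease suspected of having varices, tracked
over annual cycles as occupancy over 12 health states × 2 DSI strata:

| state | annual cost (USD) | utility (QALY/yr) |
|---|---|---|
| no varices | 145 | 0.92 |
| small varices, no VH | 155 | 0.79 |
| small varices, VH | 5,010 | 0.69 |
| large varices, untreated, no VH | 155* | 0.76 |
| large varices, untreated, VH | 5,010* | 0.69 |
| large varices, treated, stable | 1,110 | 0.83 |
| large varices, treated, bleeding | 5,010 | 0.69 |
| DC, first year | 25,595 | 0.69 |
| DC, subsequent years | 24,755 | 0.69 |
| dead (liver / procedure / other) | 0 | 0 |

\* No cost is published for untreated large varices (they exist only as
missed cases in the low-DSI stratum of the intervention arm, ~495
patients); we assign routine small-varices-level care without VH and the
VH-management cost with VH. The treated-large bleeding substate is costed
at the rebleeding figure ($5,010); a switch (`treated_event_cost`)
substitutes the treated-large maintenance cost ($1,110) — the difference
is negligible because the substate is identical in both arms.

Annual transition probabilities: progression to DC from no varices
(6.6%/2.0% for high/low DSI), small varices (11.9%/3.4%), untreated
large varices (13.5%), treated large varices (13.5% stratified, 13.7% in
the unstratified "overall" mode); death from any VH/bleeding substate,
from DC, and 12.9%/yr in each case; EGD procedural mortality 0.001% per
procedure, applied to expected procedure counts (schedule frequency ×
occupancy) and routed to a separate death cause. 2.5%/yr of the
surviving low-DSI stratum migrates across the cutoff, keeping its health
state; in the intervention arm migrating untreated large varices are
treated on arrival (annual retesting detects the stratum change).
Entering DC always means exactly one year in the first-year state, then
the subsequent-years state. Dead states are absorbing. With the
adherence decision active, every progression-to-DC probability in the
high-DSI stratum is multiplied by (1 − 0.35).

Background (all-cause) mortality is a structural assumption: the state
scheme lists it as an exit but no rate is published, so the default is
**zero** and it is excluded from reported mortality either way. A nonzero
`all_cause_mortality_annual` is accepted and routed to its own death
state.

### Competing exits

Where a state has both a death exit and a progression exit (the VH
substates, 12.9% + progression), the default combines them additively
(mutually exclusive annual probabilities; row sums validated ≤ 1). A
`competing_exits="sequential"` switch applies death first and scales
progression by survival; it changes the base-case outputs by < 0.1%.

### Variceal-hemorrhage dynamics

The published tables give initial VH prevalence per varices category
(small: 5% high-DSI / 0.1% low-DSI; untreated large: 15%; treated large:
2% post-treatment bleeding) and VH mortality, but no annual VH incidence.
Default (`vh_mixing="static"`): each cycle every varices category is
re-apportioned to its VH substate at the initial-split fraction, so VH
substates contribute excess mortality, cost, and disutility in constant
proportion — the only VH quantities the tables support without inventing
an incidence rate. The alternative (`"baseline_only"`) assigns VH status
once at baseline and lets it deplete through mortality; it moves all
headline outputs by well under 1%.

## Arms, schedules, and accrual

Expected test counts per patient-year by state (surveillance states
only; DC patients are managed through their state cost and receive no
scheduled testing):

* **SOC** (and the high-DSI intervention stratum): EGD 0.5 / 1 / 2 per
  year for no / small / large varices; labs + AFP 2/yr; ultrasound 2/yr.
* **Intervention, low-DSI stratum**: decision 1 removes all EGDs;
  decision 2 sets labs 1/yr and ultrasound 0.5/yr; the DuO test repeats
  yearly.

**Year one.** Every patient receives the arm's initial test. The initial
detection EGD is charged on top of the surveillance schedule (the
grade-keyed surveillance frequencies presuppose a detection endoscopy),
so a no-varices SOC patient incurs 1.5 expected EGDs in year 1. The
yearly DuO repeat, by contrast, is simply one test per year, so year 1's
single DuO is the initial one — it is not double-charged. A
`initial_test_mode="replace"` switch applies the max-of-schedule-and-one
convention to EGDs as well.

**Per-decision isolation.** When a decision is evaluated alone, only its
own schedule component is relaxed. The annual DuO repeat is charged to
the low-DSI stratum for decisions 1–2 and to the whole arm for decision
3 alone (the stratum whose management the DSI informs carries the test);
the initial whole-arm DuO is always charged.

**Accrual.** Care costs and QALYs accrue on the average of start- and
end-of-year occupancy (a half-cycle correction: transitions happen
throughout the year), while scheduled tests are charged on the
population present at the start of the cycle. This `accrual=
"midyear_care"` default was fixed by a sweep over the structural-switch
grid against the published headline results, which are incompatible with
fully start-of-year accounting (it delays cost-saving status by a year
and understates QALY gains by ~25%); `"start"` and `"midyear_all"`
remain available. Discounting is 3%/yr with factor (1+r)^−(t−1) (year 1
undiscounted); `discount_offset=0` switches to discounting from year 1.

## Economics

Comparisons are cumulative discounted deltas per year. Classification:
cost-saving (ΔCost ≤ 0); highly cost-effective (ICER < 1× the
$20,000/QALY threshold); cost-effective (< 3×, a package convention —
the source defines only the 1× band); otherwise not cost-effective.
Dominant or dominated configurations are labelled, never given a signed
ICER. Because the dynamics never depend on the test price, discounted
total cost is exactly affine in it and the break-even price is
−ΔCost(price 0) / (discounted DuO count); the solver re-evaluates the
solution (|residual| < $1 per cohort required) and a bisection
cross-check agrees to < $0.01.

## Uncertainty machinery (the synthetic-input generator)

The "data" of this analysis are parameter sets. Every uncertain input
carries a (min, mode, max) betaPERT distribution — the published
interval where one is printed, ±20% where footnoted, upper-only +20% for
labs and ultrasound; printed point values (e.g. the 6.6%/11.9% high-DSI
rates) stay points. Sampling uses the conventional λ = 4 shapes
1 + 4(mode−min)/(max−min) and 1 + 4(max−mode)/(max−min); mode = max
(utility 0.69 (0.44–0.69)) gives shape2 = 1 and is valid. Perturbed sets
resample every uncertain value independently and are deterministic under
a seed. What this emulates is parameter uncertainty exactly as the
published analysis frames it; what it does **not** emulate is sampling
variation in the underlying clinical studies, correlation between
inputs, or structural uncertainty, so passing sensitivity checks say
nothing about those.

One-way (tornado) analysis moves each parameter to its interval ends
with the rest at mode, ranks by swing in the years-to-highly-cost-
effective outcome (censored at horizon + 1 when never reached, ties
broken by name), and attributes variance by squared-swing shares — the
standard tornado heuristic; the attribution method behind the published
">80% from eight variables" statement is unstated, so that comparison is
reported, not asserted. Note the years outcome is a coarse integer: at
the base-case price most parameters cannot move it a whole year, so few
parameters carry all the share.

## Calibration and known limitations

All inputs are printed in the source tables, but four structural
components are not: VH incidence, all-cause mortality, year-one test
accounting, and per-decision schedules. With the defaults above, the
model reproduces the published qualitative findings exactly (highly
cost-effective within two years at $3,250; cost-saving within three
years; nine years to cost-effectiveness at $5,000) and the five-year
QALY gain, three- and five-year cost savings, and combined-strategy
break-even prices to within ~1–11%.

Three published figures cannot be recovered from the published inputs
under any switch setting, and are reported as computed rather than
tuned toward:

* the five-year **DC-averted / deaths-averted pair**: the published
  ratio (2,740/3,498 = 0.78) exceeds what a 12.9%/yr DC mortality can
  generate within five years (≤ ~0.42 of averted cases can have died);
  the printed stratum rates × the 35% reduction imply ~6,200 averted DC
  cases and ~1,570 downstream deaths, which is what this model reports;
* the **decision-3-alone break-even price** ($1,541 at two years), which
  implies adherence savings several times larger than the published DC
  costs allow;
* the near-equality of the three **per-decision break-even prices**,
  which no single consistent test-charging rule reproduces together with
  the combined-strategy price.

Other limitations: no varices-grade progression (no varices → small →
large) is modelled because no such rates are published, so surveillance
schedules never change after baseline; HCC appears only as a
surveillance cost; no age/sex structure; treated small varices under
NSBB are out of scope. Model runs take milliseconds (24 states, ≤ 10
cycles), so all analyses — including the 39-parameter tornado and the
probabilistic analysis — run in seconds on one CPU.
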