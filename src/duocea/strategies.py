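"""Management arms, testing schedules, and yearly cost/QALY accrual.

The two arms differ in how patients are tested and managed:

* **SOC** — universal initial endoscopy; surveillance EGD every two years
  (no varices), yearly (small varices) or twice yearly (large varices);
  standard labs + AFP and ultrasound HCC surveillance twice yearly.
* **Intervention** — universal initial DuO test; the high-DSI stratum
  (DSI > 18.3) follows the SOC schedule, the low-DSI stratum is managed
  according to three decisions: (1) avoid endoscopy, (2) reduce follow-up
  (labs yearly, ultrasound every two years), (3) improved adherence to
  guidelines in the high-DSI stratum (35% reduction in progression to
  decompensated cirrhosis).

Expected test counts are per patient-year by health state; patients in
decompensated cirrhosis are managed through their (large) annual state
cost and receive no scheduled surveillance testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .parameters import ModelOptions, ParameterSet
from .states import N_STATES, SURVEILLANCE, HealthState, Stratum

__all__ = [
    "StrategyConfig",
    "TestingSchedule",
    "YearlyLedger",
    "build_schedule",
    "effective_schedule",
    "state_costs",
    "state_utilities",
    "accrue_year",
    "ledgers_to_frame",
]

Arm = Literal["soc", "intervention"]


@dataclass(frozen=True)
class StrategyConfig:
    """One arm of the analysis plus its decision toggles and test price."""

    arm: Arm
    decision_avoid_egd: bool = False       # decision 1 (DSI <= 18.3)
    decision_reduce_followup: bool = False  # decision 2 (DSI <= 18.3)
    decision_adherence: bool = False       # decision 3 (DSI > 18.3)
    duo_price: float = 0.0

    def __post_init__(self) -> None:
        if self.duo_price < 0:
            raise ValueError("duo_price must be nonnegative")
        if self.arm == "soc" and any(
            (self.decision_avoid_egd, self.decision_reduce_followup, self.decision_adherence)
        ):
            raise ValueError("decision toggles are only meaningful in the intervention arm")

    @classmethod
    def soc(cls) -> "StrategyConfig":
        return cls(arm="soc")

    @classmethod
    def intervention(
        cls, decisions: tuple[int, ...] = (1, 2, 3), price: float = 3250.0
    ) -> "StrategyConfig":
        bad = set(decisions) - {1, 2, 3}
        if bad:
            raise ValueError(f"unknown decisions {sorted(bad)}")
        return cls(
            arm="intervention",
            decision_avoid_egd=1 in decisions,
            decision_reduce_followup=2 in decisions,
            decision_adherence=3 in decisions,
            duo_price=price,
        )

    @property
    def decisions(self) -> tuple[int, ...]:
        out = []
        if self.decision_avoid_egd:
            out.append(1)
        if self.decision_reduce_followup:
            out.append(2)
        if self.decision_adherence:
            out.append(3)
        return tuple(out)


@dataclass(frozen=True)
class TestingSchedule:
    """Expected annual test counts per patient, by health state."""

    egd: np.ndarray
    duo: np.ndarray
    labs: np.ndarray
    ultrasound: np.ndarray

    def __post_init__(self) -> None:
        for name in ("egd", "duo", "labs", "ultrasound"):
            arr = getattr(self, name)
            if arr.shape != (N_STATES,):
                raise ValueError(f"{name} schedule must have shape ({N_STATES},)")
            if np.any(arr < 0):
                raise ValueError(f"{name} schedule has negative counts")


def _soc_schedule() -> dict[str, np.ndarray]:
    egd = np.zeros(N_STATES)
    egd[HealthState.NO_VARICES] = 0.5
    egd[[HealthState.SMALL_VARICES_NO_VH, HealthState.SMALL_VARICES_VH]] = 1.0
    egd[
        [
            HealthState.LARGE_UNTREATED_NO_VH,
            HealthState.LARGE_UNTREATED_VH,
            HealthState.LARGE_TREATED_STABLE,
            HealthState.LARGE_TREATED_VH,
        ]
    ] = 2.0
    labs = np.zeros(N_STATES)
    labs[SURVEILLANCE] = 2.0
    ultrasound = np.zeros(N_STATES)
    ultrasound[SURVEILLANCE] = 2.0
    return {"egd": egd, "duo": np.zeros(N_STATES), "labs": labs, "ultrasound": ultrasound}


def build_schedule(
    strategy: StrategyConfig,
    stratum: Stratum,
    options: Optional[ModelOptions] = None,
) -> TestingSchedule:
    """Steady-state (years >= 2) testing schedule for one arm/stratum.

    The annual repeat DuO test is charged to the low-DSI stratum whenever
    a low-DSI decision (1 or 2) defines the intervention, and to the whole
    arm when the adherence decision is evaluated alone: the stratum whose
    management the DSI informs carries the test.
    """
    options = options or ModelOptions()
    parts = _soc_schedule()
    if strategy.arm == "intervention":
        d1, d2, d3 = (
            strategy.decision_avoid_egd,
            strategy.decision_reduce_followup,
            strategy.decision_adherence,
        )
        adherence_alone = d3 and not (d1 or d2)
        if stratum == Stratum.BELOW:
            if d1:
                parts["egd"] = np.zeros(N_STATES)
            if d2:
                parts["labs"] = np.where(parts["labs"] > 0, 1.0, 0.0)
                parts["ultrasound"] = np.where(parts["ultrasound"] > 0, 0.5, 0.0)
            duo = np.zeros(N_STATES)
            duo[SURVEILLANCE] = 1.0
            parts["duo"] = duo
        else:
            if adherence_alone or options.repeat_duo_above:
                duo = np.zeros(N_STATES)
                duo[SURVEILLANCE] = 1.0
                parts["duo"] = duo
    return TestingSchedule(**parts)


def effective_schedule(
    strategy: StrategyConfig,
    stratum: Stratum,
    year: int,
    options: Optional[ModelOptions] = None,
) -> TestingSchedule:
    """Schedule actually applied in ``year`` (1-based).

    Year 1 includes each arm's initial test: an EGD under SOC (and in any
    intervention stratum still screened endoscopically), and the initial
    DuO test for the whole intervention arm.  Under the default "add"
    convention the initial (detection) EGD is incurred on top of the
    surveillance EGD schedule, whose grade-specific frequencies presuppose
    a detection endoscopy; the yearly DuO repeat, by contrast, is simply
    one test per year, so year 1's single DuO is the initial one (the
    count is the maximum of schedule and initial test).  Under "replace"
    both modalities use the maximum convention.
    """
    options = options or ModelOptions()
    sched = build_schedule(strategy, stratum, options)
    if year != 1:
        return sched
    init_egd = np.zeros(N_STATES)
    init_duo = np.zeros(N_STATES)
    if strategy.arm == "soc":
        init_egd[SURVEILLANCE] = 1.0
    else:
        init_duo[SURVEILLANCE] = 1.0
        screened = stratum == Stratum.ABOVE or not strategy.decision_avoid_egd
        if screened:
            init_egd[SURVEILLANCE] = 1.0
    if options.initial_test_mode == "add":
        egd = sched.egd + init_egd
    else:
        egd = np.maximum(sched.egd, init_egd)
    duo = np.maximum(sched.duo, init_duo)
    return TestingSchedule(egd=egd, duo=duo, labs=sched.labs, ultrasound=sched.ultrasound)


# ---------------------------------------------------------------------------
# accrual
# ---------------------------------------------------------------------------

def state_costs(p: ParameterSet, options: Optional[ModelOptions] = None) -> np.ndarray:
    """Annual healthcare cost (USD) per health state."""
    options = options or p.options
    c = p.costs
    treated_event = (
        c.large_treated_rebleed.mode
        if options.treated_event_cost == "rebleed"
        else c.large_treated.mode
    )
    out = np.zeros(N_STATES)
    out[HealthState.NO_VARICES] = c.no_varices.mode
    out[HealthState.SMALL_VARICES_NO_VH] = c.small_varices_no_vh.mode
    out[HealthState.SMALL_VARICES_VH] = c.small_varices_vh.mode
    out[HealthState.LARGE_UNTREATED_NO_VH] = c.large_untreated_no_vh.mode
    out[HealthState.LARGE_UNTREATED_VH] = c.large_untreated_vh.mode
    out[HealthState.LARGE_TREATED_STABLE] = c.large_treated.mode
    out[HealthState.LARGE_TREATED_VH] = treated_event
    out[HealthState.DC_FIRST_YEAR] = c.dc_first_year.mode
    out[HealthState.DC_SUBSEQUENT] = c.dc_subsequent.mode
    return out


def state_utilities(p: ParameterSet) -> np.ndarray:
    """Annual QALY weight per health state."""
    u = p.utilities
    out = np.zeros(N_STATES)
    out[HealthState.NO_VARICES] = u.no_varices.mode
    out[HealthState.SMALL_VARICES_NO_VH] = u.small_no_vh.mode
    out[HealthState.SMALL_VARICES_VH] = u.small_vh.mode
    out[HealthState.LARGE_UNTREATED_NO_VH] = u.large_untreated_no_vh.mode
    out[HealthState.LARGE_UNTREATED_VH] = u.large_untreated_vh.mode
    out[HealthState.LARGE_TREATED_STABLE] = u.large_treated_no_event.mode
    out[HealthState.LARGE_TREATED_VH] = u.large_treated_event.mode
    out[HealthState.DC_FIRST_YEAR] = u.dc.mode
    out[HealthState.DC_SUBSEQUENT] = u.dc.mode
    return out


@dataclass
class YearlyLedger:
    """Costs, QALYs, and event counts accrued in one model year."""

    year: int
    healthcare_cost: float = 0.0
    diagnostic_cost: float = 0.0
    test_price_cost: float = 0.0
    qalys: float = 0.0
    discount_factor: float = 1.0
    duo_tests: float = 0.0
    egd_tests: float = 0.0
    incident_dc: float = 0.0
    deaths_liver: float = 0.0
    deaths_procedure: float = 0.0
    deaths_other: float = 0.0

    @property
    def total_cost(self) -> float:
        return self.healthcare_cost + self.diagnostic_cost + self.test_price_cost


def accrue_year(
    occupancy: np.ndarray,
    p: ParameterSet,
    strategy: StrategyConfig,
    year: int,
    options: Optional[ModelOptions] = None,
    diagnostics_occupancy: Optional[np.ndarray] = None,
) -> YearlyLedger:
    """Accrue one year's costs and QALYs.

    ``occupancy`` has shape (2 strata, n states) and drives care costs
    and QALYs; scheduled tests are charged on ``diagnostics_occupancy``
    when given (the cohort runner passes start-of-year occupancy there
    under the default mid-year care accrual), otherwise on ``occupancy``.
    Healthcare cost is occupancy times the state's annual cost;
    diagnostic cost is occupancy times expected test counts times unit
    costs; the DuO price is accounted separately so total cost stays
    affine in the price.  Event counts (incident DC, deaths) are filled
    in by the cohort runner.
    """
    options = options or p.options
    occupancy = np.asarray(occupancy, dtype=float)
    diag_occ_all = (
        occupancy
        if diagnostics_occupancy is None
        else np.asarray(diagnostics_occupancy, dtype=float)
    )
    costs = state_costs(p, options)
    utils = state_utilities(p)
    rate = p.economics.discount_rate
    ledger = YearlyLedger(
        year=year,
        discount_factor=(1.0 + rate) ** -(year - options.discount_offset),
    )
    for stratum in Stratum:
        occ = occupancy[stratum]
        diag_occ = diag_occ_all[stratum]
        sched = effective_schedule(strategy, stratum, year, options)
        ledger.healthcare_cost += float(occ @ costs)
        ledger.diagnostic_cost += float(
            diag_occ @ (
                sched.egd * p.costs.egd.mode
                + sched.labs * p.costs.standard_labs_afp.mode
                + sched.ultrasound * p.costs.ultrasound_hcc.mode
            )
        )
        duo_count = float(diag_occ @ sched.duo)
        ledger.duo_tests += duo_count
        ledger.egd_tests += float(diag_occ @ sched.egd)
        ledger.test_price_cost += duo_count * strategy.duo_price
        ledger.qalys += float(occ @ utils)
    return ledger


def ledgers_to_frame(ledgers: list[YearlyLedger]) -> pd.DataFrame:
    """Long-format per-year ledger table with discounted columns."""
    rows = []
    for led in ledgers:
        rows.append(
            {
                "year": led.year,
                "healthcare_cost": led.healthcare_cost,
                "diagnostic_cost": led.diagnostic_cost,
                "test_price_cost": led.test_price_cost,
                "total_cost": led.total_cost,
                "qalys": led.qalys,
                "discount_factor": led.discount_factor,
                "disc_healthcare_cost": led.healthcare_cost * led.discount_factor,
                "disc_diagnostic_cost": led.diagnostic_cost * led.discount_factor,
                "disc_test_price_cost": led.test_price_cost * led.discount_factor,
                "disc_total_cost": led.total_cost * led.discount_factor,
                "disc_qalys": led.qalys * led.discount_factor,
                "duo_tests": led.duo_tests,
                "egd_tests": led.egd_tests,
                "incident_dc": led.incident_dc,
                "deaths_liver": led.deaths_liver,
                "deaths_procedure": led.deaths_procedure,
                "deaths_other": led.deaths_other,
            }
        )
    return pd.DataFrame(rows)
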