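"""Deterministic cohort engine for the annual-cycle transition model.

The cohort is a continuous (expected-value) population: occupancy is a
nonnegative real array over (DSI stratum x health state), advanced one
year at a time by stratum-specific row-stochastic transition matrices,
with three extra flows handled outside the matrices:

* endoscopy-related procedure deaths, proportional to the expected number
  of EGDs performed on each state in the year;
* migration of the low-DSI stratum into the high-DSI stratum (disease
  progression across the 18.3 cutoff), preserving health state;
* re-apportioning of each varices category between its bleeding and
  non-bleeding substates (static-mixing VH model, switchable).

Total mass (alive plus dead) is conserved to 1e-6 relative tolerance at
every cycle; a violation raises rather than being clipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .parameters import ModelOptions, ParameterSet
from .states import ALIVE, N_STATES, N_STRATA, HealthState, Stratum
from .strategies import (
    StrategyConfig,
    YearlyLedger,
    accrue_year,
    effective_schedule,
    ledgers_to_frame,
)

__all__ = [
    "CohortState",
    "ConservationError",
    "initialize_cohort",
    "build_transition_matrix",
    "apply_vh_mixing",
    "step",
    "run_cohort",
    "RunResult",
    "run_strategy",
    "trajectory_to_frame",
]

_CONSERVATION_RTOL = 1e-6


class ConservationError(RuntimeError):
    """Cohort mass was not conserved by a cycle update."""


@dataclass(frozen=True)
class CohortState:
    """Occupancy and cumulative event counters at one annual cycle."""

    occupancy: np.ndarray  # shape (N_STRATA, N_STATES)
    year_index: int = 0
    cumulative_incident_dc: float = 0.0
    cumulative_deaths_liver: float = 0.0
    cumulative_deaths_procedure: float = 0.0
    cumulative_deaths_other: float = 0.0

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.shape != (N_STRATA, N_STATES):
            raise ValueError(f"occupancy must have shape ({N_STRATA}, {N_STATES})")
        if np.any(occ < -1e-9):
            raise ValueError("occupancy must be nonnegative")
        object.__setattr__(self, "occupancy", occ)

    @property
    def total(self) -> float:
        return float(self.occupancy.sum())

    @property
    def alive(self) -> float:
        return float(self.occupancy[:, ALIVE].sum())

    @property
    def cumulative_deaths_modelled(self) -> float:
        """Liver- plus procedure-related deaths (the reported causes)."""
        return self.cumulative_deaths_liver + self.cumulative_deaths_procedure


def initialize_cohort(p: ParameterSet, strategy: StrategyConfig) -> CohortState:
    """Split the cohort by DSI stratum, varices category, VH status, and
    treatment status.

    The SOC arm detects every large varices case by universal endoscopy
    and treats it; the intervention arm treats per the stratum treated
    fractions (all high-DSI cases, none of the low-DSI cases, whose large
    varices go unscreened and therefore untreated under decision 1).
    """
    pop = p.population
    n = float(pop.cohort_size)
    frac_above = pop.fraction_dsi_above.mode
    occ = np.zeros((N_STRATA, N_STATES))
    for stratum in Stratum:
        if stratum == Stratum.ABOVE:
            n_stratum = n * frac_above
            dist = pop.varices_above
            small_vh = pop.small_vh_above.mode
            treated = 1.0 if strategy.arm == "soc" else pop.treated_fraction_above
        else:
            n_stratum = n * (1.0 - frac_above)
            dist = pop.varices_below
            small_vh = pop.small_vh_below.mode
            treated = 1.0 if strategy.arm == "soc" else pop.treated_fraction_below
        n_no, n_small, n_large = n_stratum * dist.as_array()
        occ[stratum, HealthState.NO_VARICES] = n_no
        occ[stratum, HealthState.SMALL_VARICES_VH] = n_small * small_vh
        occ[stratum, HealthState.SMALL_VARICES_NO_VH] = n_small * (1.0 - small_vh)
        n_treated = n_large * treated
        n_untreated = n_large - n_treated
        event = pop.large_treated_event.mode
        occ[stratum, HealthState.LARGE_TREATED_VH] = n_treated * event
        occ[stratum, HealthState.LARGE_TREATED_STABLE] = n_treated * (1.0 - event)
        vh = pop.large_untreated_vh.mode
        occ[stratum, HealthState.LARGE_UNTREATED_VH] = n_untreated * vh
        occ[stratum, HealthState.LARGE_UNTREATED_NO_VH] = n_untreated * (1.0 - vh)
    return CohortState(occupancy=occ)


def _exit_row(
    exits: dict[int, float],
    stay: int,
    death_states: Sequence[int],
    mode: str,
    all_cause: float,
) -> np.ndarray:
    """One transition-matrix row from a dict of exit probabilities.

    "additive" treats the listed exits as mutually exclusive annual
    probabilities (their sum must stay below 1); "sequential" applies
    death exits first and scales the remaining exits by survival.
    """
    row = np.zeros(N_STATES)
    exits = dict(exits)
    if mode == "sequential":
        p_death = sum(q for s, q in exits.items() if s in set(death_states))
        for s in list(exits):
            if s not in set(death_states):
                exits[s] = exits[s] * (1.0 - p_death)
    if all_cause > 0.0:
        for s in list(exits):
            exits[s] = exits[s] * (1.0 - all_cause)
        exits[HealthState.DEAD_OTHER] = exits.get(HealthState.DEAD_OTHER, 0.0) + all_cause
    total = sum(exits.values())
    if total > 1.0 + 1e-12:
        raise ValueError(f"exit probabilities sum to {total:.6f} > 1")
    for s, q in exits.items():
        row[s] += q
    row[stay] += 1.0 - total
    return row


def build_transition_matrix(
    p: ParameterSet,
    stratum: Stratum,
    strategy: StrategyConfig,
    options: Optional[ModelOptions] = None,
) -> np.ndarray:
    """Row-stochastic annual transition matrix for one (stratum, arm).

    When the adherence decision is active, every progression-to-DC
    probability in the high-DSI stratum is multiplied by
    ``1 - dc_reduction_on_adherence``.  Cross-stratum migration is not part
    of the matrix (it is an inter-stratum flow applied by :func:`step`).
    """
    options = options or p.options
    t = p.transitions
    adherence = (
        strategy.arm == "intervention"
        and strategy.decision_adherence
        and stratum == Stratum.ABOVE
    )
    mult = 1.0 - t.dc_reduction_on_adherence.mode if adherence else 1.0
    if stratum == Stratum.ABOVE:
        q_nv = t.no_varices_to_dc_above.mode
        q_sv = t.small_varices_to_dc_above.mode
    else:
        q_nv = t.no_varices_to_dc_below.mode
        q_sv = t.small_varices_to_dc_below.mode
    q_lt = (
        t.large_treated_to_dc_overall.mode
        if options.large_treated_rate == "overall"
        else t.large_treated_to_dc_above.mode
    )
    q_lu = t.large_untreated_to_dc.mode
    q_nv, q_sv, q_lt, q_lu = (q * mult for q in (q_nv, q_sv, q_lt, q_lu))
    d_vh = t.vh_to_death.mode
    d_post = t.post_treatment_vh_to_death.mode
    d_dc = t.dc_to_death.mode
    m = t.all_cause_mortality_annual
    mode = options.competing_exits
    DC, DL = HealthState.DC_FIRST_YEAR, HealthState.DEAD_LIVER
    deaths = (HealthState.DEAD_LIVER, HealthState.DEAD_PROCEDURE, HealthState.DEAD_OTHER)

    M = np.zeros((N_STATES, N_STATES))
    M[HealthState.NO_VARICES] = _exit_row({DC: q_nv}, HealthState.NO_VARICES, deaths, mode, m)
    M[HealthState.SMALL_VARICES_NO_VH] = _exit_row(
        {DC: q_sv}, HealthState.SMALL_VARICES_NO_VH, deaths, mode, m
    )
    M[HealthState.SMALL_VARICES_VH] = _exit_row(
        {DL: d_vh, DC: q_sv}, HealthState.SMALL_VARICES_VH, deaths, mode, m
    )
    M[HealthState.LARGE_UNTREATED_NO_VH] = _exit_row(
        {DC: q_lu}, HealthState.LARGE_UNTREATED_NO_VH, deaths, mode, m
    )
    M[HealthState.LARGE_UNTREATED_VH] = _exit_row(
        {DL: d_vh, DC: q_lu}, HealthState.LARGE_UNTREATED_VH, deaths, mode, m
    )
    M[HealthState.LARGE_TREATED_STABLE] = _exit_row(
        {DC: q_lt}, HealthState.LARGE_TREATED_STABLE, deaths, mode, m
    )
    M[HealthState.LARGE_TREATED_VH] = _exit_row(
        {DL: d_post, DC: q_lt}, HealthState.LARGE_TREATED_VH, deaths, mode, m
    )
    # everyone entering DC spends exactly one year in the first-year state:
    # survivors (the remainder) move on to the subsequent-years state
    M[HealthState.DC_FIRST_YEAR] = _exit_row(
        {DL: d_dc}, HealthState.DC_SUBSEQUENT, deaths, mode, m
    )
    M[HealthState.DC_SUBSEQUENT] = _exit_row(
        {DL: d_dc}, HealthState.DC_SUBSEQUENT, deaths, mode, m
    )
    for s in deaths:
        M[s, s] = 1.0
    rowsums = M.sum(axis=1)
    if not np.allclose(rowsums, 1.0, atol=1e-12):
        raise ValueError(f"transition matrix rows do not sum to 1: {rowsums}")
    if np.any(M < 0):
        raise ValueError("transition matrix has negative entries")
    return M


def apply_vh_mixing(
    occ: np.ndarray, p: ParameterSet, options: Optional[ModelOptions] = None
) -> np.ndarray:
    """Re-apportion each varices category between its VH and non-VH
    substates at the initial-split fractions (static-mixing VH model).

    Idempotent; a no-op under ``vh_mixing='baseline_only'``.
    """
    options = options or p.options
    occ = np.array(occ, dtype=float)
    if options.vh_mixing == "baseline_only":
        return occ
    pop = p.population
    for stratum in Stratum:
        small_vh = (
            pop.small_vh_above.mode if stratum == Stratum.ABOVE else pop.small_vh_below.mode
        )
        pairs = [
            (HealthState.SMALL_VARICES_NO_VH, HealthState.SMALL_VARICES_VH, small_vh),
            (
                HealthState.LARGE_UNTREATED_NO_VH,
                HealthState.LARGE_UNTREATED_VH,
                pop.large_untreated_vh.mode,
            ),
            (
                HealthState.LARGE_TREATED_STABLE,
                HealthState.LARGE_TREATED_VH,
                pop.large_treated_event.mode,
            ),
        ]
        for quiet, bleeding, frac in pairs:
            total = occ[stratum, quiet] + occ[stratum, bleeding]
            occ[stratum, quiet] = total * (1.0 - frac)
            occ[stratum, bleeding] = total * frac
    return occ


def step(
    c: CohortState,
    matrices: tuple[np.ndarray, np.ndarray],
    p: ParameterSet,
    strategy: StrategyConfig,
    options: Optional[ModelOptions] = None,
) -> CohortState:
    """Advance the cohort one annual cycle.

    Order of operations: VH substate mixing, expected procedure deaths
    from the year's EGD schedule, the stratum transition matrices, then
    low-to-high DSI migration (migrating untreated large varices are
    treated on arrival in the intervention arm, where annual retesting
    detects the stratum change).
    """
    options = options or p.options
    year = c.year_index + 1
    occ = apply_vh_mixing(c.occupancy, p, options)
    total_before = occ.sum()

    # expected EGD-related deaths, proportional to procedures performed
    p_egd = p.transitions.egd_to_death_per_procedure.mode
    deaths_procedure = 0.0
    for stratum in Stratum:
        sched = effective_schedule(strategy, stratum, year, options)
        dead = occ[stratum] * sched.egd * p_egd
        occ[stratum] -= dead
        occ[stratum, HealthState.DEAD_PROCEDURE] += float(dead.sum())
        deaths_procedure += float(dead.sum())

    dead_before = occ[:, [HealthState.DEAD_LIVER, HealthState.DEAD_OTHER]].sum(axis=0)
    new = np.empty_like(occ)
    for stratum in Stratum:
        new[stratum] = occ[stratum] @ matrices[stratum]
    incident_dc = float(new[:, HealthState.DC_FIRST_YEAR].sum())

    mu = p.transitions.below_to_above_migration.mode
    migrants = new[Stratum.BELOW, ALIVE] * mu
    new[Stratum.BELOW, ALIVE] -= migrants
    if strategy.arm == "intervention" and p.population.treated_fraction_above > 0:
        # newly high-DSI patients with untreated large varices are detected
        # and treated from the next cycle onward
        treat = p.population.treated_fraction_above
        moved_nvh = migrants[HealthState.LARGE_UNTREATED_NO_VH] * treat
        moved_vh = migrants[HealthState.LARGE_UNTREATED_VH] * treat
        migrants[HealthState.LARGE_UNTREATED_NO_VH] -= moved_nvh
        migrants[HealthState.LARGE_UNTREATED_VH] -= moved_vh
        migrants[HealthState.LARGE_TREATED_STABLE] += moved_nvh
        migrants[HealthState.LARGE_TREATED_VH] += moved_vh
    new[Stratum.ABOVE, ALIVE] += migrants

    if not np.isclose(new.sum(), total_before, rtol=_CONSERVATION_RTOL):
        raise ConservationError(
            f"cohort mass changed from {total_before:.6f} to {new.sum():.6f} in year {year}"
        )

    dead_after = new[:, [HealthState.DEAD_LIVER, HealthState.DEAD_OTHER]].sum(axis=0)
    return CohortState(
        occupancy=new,
        year_index=year,
        cumulative_incident_dc=c.cumulative_incident_dc + incident_dc,
        cumulative_deaths_liver=c.cumulative_deaths_liver
        + float(dead_after[0] - dead_before[0]),
        cumulative_deaths_procedure=c.cumulative_deaths_procedure + deaths_procedure,
        cumulative_deaths_other=c.cumulative_deaths_other
        + float(dead_after[1] - dead_before[1]),
    )


def run_cohort(
    p: ParameterSet,
    strategy: StrategyConfig,
    horizon: Optional[int] = None,
    options: Optional[ModelOptions] = None,
) -> list[CohortState]:
    """Deterministic trajectory of ``horizon + 1`` states (including the
    initial state)."""
    options = options or p.options
    horizon = p.economics.horizon if horizon is None else horizon
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    matrices = tuple(
        build_transition_matrix(p, stratum, strategy, options) for stratum in Stratum
    )
    states = [initialize_cohort(p, strategy)]
    for _ in range(horizon):
        states.append(step(states[-1], matrices, p, strategy, options))
    return states


@dataclass(frozen=True)
class RunResult:
    """Trajectory plus per-year ledgers for one strategy."""

    strategy: StrategyConfig
    trajectory: list[CohortState]
    ledgers: list[YearlyLedger]

    @property
    def frame(self) -> pd.DataFrame:
        return ledgers_to_frame(self.ledgers)

    @property
    def final(self) -> CohortState:
        return self.trajectory[-1]


def run_strategy(
    p: ParameterSet,
    strategy: StrategyConfig,
    horizon: Optional[int] = None,
    options: Optional[ModelOptions] = None,
) -> RunResult:
    """Run one arm and accrue its yearly ledgers.

    Care costs and QALYs accrue, by default, on the average of (VH-mixed)
    start- and end-of-year occupancy — a half-cycle correction reflecting
    that transitions happen throughout the year — while scheduled tests
    are charged on the population present at the start of the cycle.  The
    ``accrual`` option switches to fully start-of-year or fully mid-year
    accounting.
    """
    options = options or p.options
    horizon = p.economics.horizon if horizon is None else horizon
    trajectory = run_cohort(p, strategy, horizon, options)
    ledgers = []
    for year in range(1, horizon + 1):
        occ_start = apply_vh_mixing(trajectory[year - 1].occupancy, p, options)
        if options.accrual == "start":
            care_occ, diag_occ = occ_start, occ_start
        else:
            occ_end = apply_vh_mixing(trajectory[year].occupancy, p, options)
            mid = 0.5 * (occ_start + occ_end)
            care_occ = mid
            diag_occ = mid if options.accrual == "midyear_all" else occ_start
        led = accrue_year(
            care_occ, p, strategy, year, options, diagnostics_occupancy=diag_occ
        )
        prev, cur = trajectory[year - 1], trajectory[year]
        led.incident_dc = cur.cumulative_incident_dc - prev.cumulative_incident_dc
        led.deaths_liver = cur.cumulative_deaths_liver - prev.cumulative_deaths_liver
        led.deaths_procedure = (
            cur.cumulative_deaths_procedure - prev.cumulative_deaths_procedure
        )
        led.deaths_other = cur.cumulative_deaths_other - prev.cumulative_deaths_other
        ledgers.append(led)
    return RunResult(strategy=strategy, trajectory=trajectory, ledgers=ledgers)


def trajectory_to_frame(
    result: RunResult, arm_label: Optional[str] = None
) -> pd.DataFrame:
    """Long-format occupancy table (year, arm, stratum, state, occupancy)."""
    label = arm_label or result.strategy.arm
    rows = []
    for state_obj in result.trajectory:
        for stratum in Stratum:
            for hs in HealthState:
                rows.append(
                    {
                        "year": state_obj.year_index,
                        "arm": label,
                        "stratum": stratum.name.lower(),
                        "state": hs.name,
                        "occupancy": state_obj.occupancy[stratum, hs],
                    }
                )
    return pd.DataFrame(rows)


def export_trajectory(result: RunResult, path: Union[str, Path]) -> None:
    trajectory_to_frame(result).to_csv(path, index=False)
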