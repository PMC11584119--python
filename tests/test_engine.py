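"""Cohort initialization, transition matrices, stepping, and conservation."""

import numpy as np
import pytest

from conftest import freeze_dynamics
from duocea.engine import (
    CohortState,
    build_transition_matrix,
    initialize_cohort,
    run_cohort,
    run_strategy,
    step,
    trajectory_to_frame,
)
from duocea.parameters import ModelOptions, UncertainValue, set_uncertain
from duocea.states import ALIVE, N_STATES, HealthState, Stratum
from duocea.strategies import StrategyConfig

SOC = StrategyConfig.soc()
INT_ALL = StrategyConfig.intervention(price=3250.0)


# -- initialization ---------------------------------------------------------

def test_initial_stratum_split(params):
    """100,000 patients split 51% / 49% across the DSI cutoff."""
    c = initialize_cohort(params, INT_ALL)
    assert c.occupancy[Stratum.ABOVE].sum() == pytest.approx(51_000)
    assert c.occupancy[Stratum.BELOW].sum() == pytest.approx(49_000)
    assert c.total == pytest.approx(100_000)


def test_initial_large_varices_above(params):
    """High-DSI stratum holds 51,000 x 19% = 9,690 large varices, all treated."""
    c = initialize_cohort(params, INT_ALL)
    large = c.occupancy[
        Stratum.ABOVE,
        [
            HealthState.LARGE_UNTREATED_NO_VH,
            HealthState.LARGE_UNTREATED_VH,
            HealthState.LARGE_TREATED_STABLE,
            HealthState.LARGE_TREATED_VH,
        ],
    ]
    assert large.sum() == pytest.approx(9_690)
    assert large[0] == large[1] == 0.0  # all treated above the cutoff
    assert large[3] == pytest.approx(9_690 * 0.02)  # post-treatment bleeding split


def test_soc_treats_low_dsi_large_varices_but_intervention_does_not(params):
    soc = initialize_cohort(params, SOC)
    inter = initialize_cohort(params, INT_ALL)
    untreated = [HealthState.LARGE_UNTREATED_NO_VH, HealthState.LARGE_UNTREATED_VH]
    assert soc.occupancy[Stratum.BELOW, untreated].sum() == 0.0
    assert inter.occupancy[Stratum.BELOW, untreated].sum() == pytest.approx(
        49_000 * (0.01 / 0.99)
    )


def test_degenerate_fraction_above_empties_other_stratum(params):
    p = set_uncertain(params, "population.fraction_dsi_above", UncertainValue.point(1.0))
    c = initialize_cohort(p, SOC)
    assert c.occupancy[Stratum.BELOW].sum() == 0.0
    assert c.occupancy[Stratum.ABOVE].sum() == pytest.approx(100_000)


# -- transition matrices ----------------------------------------------------

@pytest.mark.parametrize("stratum", list(Stratum))
@pytest.mark.parametrize("strategy", [SOC, INT_ALL], ids=["soc", "intervention"])
def test_matrix_rows_stochastic_and_dead_absorbing(params, stratum, strategy):
    M = build_transition_matrix(params, stratum, strategy)
    assert np.allclose(M.sum(axis=1), 1.0, atol=1e-12)
    assert np.all(M >= 0) and np.all(M <= 1)
    for dead in (HealthState.DEAD_LIVER, HealthState.DEAD_PROCEDURE, HealthState.DEAD_OTHER):
        assert M[dead, dead] == 1.0


def test_adherence_reduces_high_dsi_progression(params):
    """With the adherence decision, no-varices progression above the cutoff
    is 6.6% x (1 - 35%) = 4.29%/yr."""
    M = build_transition_matrix(params, Stratum.ABOVE, INT_ALL)
    assert M[HealthState.NO_VARICES, HealthState.DC_FIRST_YEAR] == pytest.approx(0.0429)
    # low-DSI stratum and SOC arm keep the raw rates
    M_soc = build_transition_matrix(params, Stratum.ABOVE, SOC)
    assert M_soc[HealthState.NO_VARICES, HealthState.DC_FIRST_YEAR] == pytest.approx(0.066)


def test_dc_first_year_empties_every_cycle(params):
    M = build_transition_matrix(params, Stratum.ABOVE, SOC)
    row = M[HealthState.DC_FIRST_YEAR]
    assert row[HealthState.DC_FIRST_YEAR] == 0.0
    assert row[HealthState.DEAD_LIVER] == pytest.approx(0.129)
    assert row[HealthState.DC_SUBSEQUENT] == pytest.approx(0.871)


# -- stepping ---------------------------------------------------------------

def _single_patient(state, stratum=Stratum.ABOVE):
    occ = np.zeros((2, N_STATES))
    occ[stratum, state] = 1.0
    return CohortState(occupancy=occ)


def test_single_dc_patient_death_flow(params):
    """One patient in established DC contributes 0.129 expected liver
    deaths in one cycle."""
    c = _single_patient(HealthState.DC_SUBSEQUENT)
    matrices = tuple(build_transition_matrix(params, s, SOC) for s in Stratum)
    nxt = step(c, matrices, params, SOC)
    assert nxt.cumulative_deaths_liver == pytest.approx(0.129)
    assert nxt.occupancy[Stratum.ABOVE, HealthState.DC_SUBSEQUENT] == pytest.approx(0.871)


def test_frozen_dynamics_leave_cohort_unchanged(params):
    p = freeze_dynamics(params)
    c = initialize_cohort(p, SOC)
    matrices = tuple(build_transition_matrix(p, s, SOC) for s in Stratum)
    nxt = step(c, matrices, p, SOC)
    assert nxt.year_index == 1
    assert np.allclose(nxt.occupancy, c.occupancy)


@pytest.mark.parametrize("strategy", [SOC, INT_ALL], ids=["soc", "intervention"])
def test_mass_conservation_over_horizon(params, strategy):
    """Alive plus dead occupancy equals the initial cohort every year."""
    for state in run_cohort(params, strategy, 10):
        assert state.total == pytest.approx(100_000, rel=1e-6)


def test_matrix_power_oracle_equivalence(params):
    """With migration, procedure deaths, and VH re-mixing switched off the
    engine is a pure Markov chain: occupancy after t years must equal the
    initial occupancy times the t-th matrix power, per stratum."""
    p = set_uncertain(
        params, "transitions.below_to_above_migration", UncertainValue.point(0.0)
    )
    p = set_uncertain(
        p, "transitions.egd_to_death_per_procedure", UncertainValue.point(0.0)
    )
    options = ModelOptions(vh_mixing="baseline_only")
    traj = run_cohort(p, SOC, 6, options)
    occ0 = traj[0].occupancy
    for stratum in Stratum:
        M = build_transition_matrix(p, stratum, SOC, options)
        for t, state in enumerate(traj):
            expected = occ0[stratum] @ np.linalg.matrix_power(M, t)
            assert np.allclose(state.occupancy[stratum], expected, atol=1e-8)


def test_three_state_chain_hand_computed():
    """Brute-force two-year arithmetic on the DC death chain: starting in
    first-year DC with 12.9%/yr mortality, dead mass is 0.129 then
    0.129 + 0.871 x 0.129 = 0.241359."""
    from duocea.parameters import default_parameters

    p = default_parameters()
    matrices = tuple(build_transition_matrix(p, s, SOC) for s in Stratum)
    c = _single_patient(HealthState.DC_FIRST_YEAR)
    y1 = step(c, matrices, p, SOC)
    assert y1.cumulative_deaths_liver == pytest.approx(0.129)
    y2 = step(y1, matrices, p, SOC)
    assert y2.cumulative_deaths_liver == pytest.approx(0.241359)
    assert y2.occupancy[Stratum.ABOVE, HealthState.DC_SUBSEQUENT] == pytest.approx(0.758641)


def test_incident_dc_counter_nondecreasing(params):
    traj = run_cohort(params, INT_ALL, 10)
    cumulative = [s.cumulative_incident_dc for s in traj]
    assert all(b >= a for a, b in zip(cumulative, cumulative[1:]))


def test_horizon_zero_returns_initial_state_only(params):
    traj = run_cohort(params, SOC, 0)
    assert len(traj) == 1 and traj[0].year_index == 0


def test_stronger_adherence_never_increases_high_dsi_dc(params):
    """Cumulative incident DC is monotone nonincreasing in the adherence
    effect size."""
    totals = []
    for reduction in (0.0, 0.20, 0.35, 0.50):
        p = set_uncertain(
            params,
            "transitions.dc_reduction_on_adherence",
            UncertainValue.point(reduction),
        )
        totals.append(run_cohort(p, INT_ALL, 8)[-1].cumulative_incident_dc)
    assert all(b <= a + 1e-9 for a, b in zip(totals, totals[1:]))


def test_migration_moves_low_to_high_stratum(params):
    """2.5%/yr of the surviving low-DSI stratum crosses the cutoff."""
    traj = run_cohort(params, SOC, 1)
    below0 = traj[0].occupancy[Stratum.BELOW, ALIVE].sum()
    below1 = traj[1].occupancy[Stratum.BELOW, ALIVE].sum()
    # migration removed 2.5% of the post-transition survivors
    assert below1 < below0 * 0.98


def test_null_equivalence_of_arms(params):
    """With identical treatment policies and a free test, both arms incur
    identical costs, QALYs, and dynamics (only the DuO count differs)."""
    pop = params.population.model_copy(update={"treated_fraction_below": 1.0})
    p = params.model_copy(update={"population": pop})
    inert = StrategyConfig(arm="intervention", duo_price=0.0)
    soc_run = run_strategy(p, SOC, 6)
    int_run = run_strategy(p, inert, 6)
    fs, fi = soc_run.frame, int_run.frame
    for col in ("healthcare_cost", "diagnostic_cost", "qalys", "incident_dc",
                "deaths_liver", "deaths_procedure", "total_cost"):
        assert np.allclose(fs[col], fi[col]), col
    for a, b in zip(soc_run.trajectory, int_run.trajectory):
        assert np.allclose(a.occupancy, b.occupancy)


def test_trajectory_export_long_format(params):
    result = run_strategy(params, SOC, 2)
    frame = trajectory_to_frame(result)
    assert len(frame) == 3 * 2 * N_STATES
    assert set(frame.columns) == {"year", "arm", "stratum", "state", "occupancy"}
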