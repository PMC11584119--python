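"""Parameter defaults, validation, betaPERT sampling, and file round-trips."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from duocea.parameters import (
    ParameterValidationError,
    UncertainValue,
    betapert_sample,
    default_parameters,
    iter_uncertain,
    packaged_base_case_path,
    perturbed_parameter_sets,
    read_parameters,
    set_uncertain,
    write_parameters,
)


def _get(p, dotted):
    obj = p
    for part in dotted.split("."):
        obj = getattr(obj, part)
    return obj


# every printed table cell, as (path, expected)
PRINTED_DEFAULTS = [
    ("population.cohort_size", 100_000),
    ("population.fraction_dsi_above.mode", 0.51),
    ("population.fraction_dsi_above.minimum", 0.30),
    ("population.fraction_dsi_above.maximum", 0.70),
    ("population.varices_overall.no_varices", 0.66),
    ("population.varices_overall.small_varices", 0.24),
    ("population.varices_overall.large_varices", 0.10),
    ("population.varices_above.no_varices", 0.48),
    ("population.varices_above.small_varices", 0.33),
    ("population.varices_above.large_varices", 0.19),
    ("population.small_vh_above.mode", 0.05),
    ("population.small_vh_below.mode", 0.001),
    ("population.large_untreated_vh.mode", 0.15),
    ("population.large_treated_event.mode", 0.02),
    ("population.treated_fraction_above", 1.0),
    ("population.treated_fraction_below", 0.0),
    ("performance.dsi_cutoff", 18.3),
    ("performance.sensitivity_small", 0.709),
    ("performance.sensitivity_large", 0.934),
    ("transitions.no_varices_to_dc_overall.mode", 0.040),
    ("transitions.no_varices_to_dc_above.mode", 0.066),
    ("transitions.no_varices_to_dc_below.mode", 0.020),
    ("transitions.small_varices_to_dc_overall.mode", 0.083),
    ("transitions.small_varices_to_dc_above.mode", 0.119),
    ("transitions.small_varices_to_dc_below.mode", 0.034),
    ("transitions.below_to_above_migration.mode", 0.025),
    ("transitions.below_to_above_migration.minimum", 0.020),
    ("transitions.below_to_above_migration.maximum", 0.030),
    ("transitions.large_untreated_to_dc.mode", 0.135),
    ("transitions.large_treated_to_dc_overall.mode", 0.137),
    ("transitions.large_treated_to_dc_above.mode", 0.135),
    ("transitions.vh_to_death.mode", 0.129),
    ("transitions.post_treatment_vh_to_death.mode", 0.129),
    ("transitions.rebleed_to_death.mode", 0.129),
    ("transitions.dc_to_death.mode", 0.129),
    ("transitions.egd_to_death_per_procedure.mode", 0.00001),
    ("transitions.dc_reduction_on_adherence.mode", 0.35),
    ("transitions.dc_reduction_on_adherence.minimum", 0.20),
    ("transitions.dc_reduction_on_adherence.maximum", 0.50),
    ("transitions.all_cause_mortality_annual", 0.0),
    ("costs.no_varices.mode", 145.0),
    ("costs.small_varices_no_vh.mode", 155.0),
    ("costs.small_varices_vh.mode", 5010.0),
    ("costs.large_treated.mode", 1110.0),
    ("costs.large_treated.minimum", 585.0),
    ("costs.large_treated.maximum", 1332.0),
    ("costs.large_treated_rebleed.mode", 5010.0),
    ("costs.dc_first_year.mode", 25595.0),
    ("costs.dc_first_year.minimum", 16430.0),
    ("costs.dc_first_year.maximum", 30714.0),
    ("costs.dc_subsequent.mode", 24755.0),
    ("costs.dc_subsequent.minimum", 4690.0),
    ("costs.dc_subsequent.maximum", 29706.0),
    ("costs.egd.mode", 2642.0),
    ("costs.egd.minimum", 1882.0),
    ("costs.egd.maximum", 3641.0),
    ("costs.standard_labs_afp.mode", 475.0),
    ("costs.ultrasound_hcc.mode", 745.0),
    ("costs.duo_test_price", 3250.0),
    ("utilities.no_varices.mode", 0.92),
    ("utilities.no_varices.minimum", 0.72),
    ("utilities.no_varices.maximum", 1.00),
    ("utilities.small_no_vh.mode", 0.79),
    ("utilities.small_vh.mode", 0.69),
    ("utilities.small_vh.minimum", 0.44),
    ("utilities.small_vh.maximum", 0.69),
    ("utilities.large_treated_no_event.mode", 0.83),
    ("utilities.large_treated_event.mode", 0.69),
    ("utilities.large_untreated_no_vh.mode", 0.76),
    ("utilities.dc.mode", 0.69),
    ("economics.discount_rate", 0.03),
    ("economics.ce_threshold", 20_000.0),
]


@pytest.mark.parametrize("path,expected", PRINTED_DEFAULTS, ids=[p for p, _ in PRINTED_DEFAULTS])
def test_default_parameters_match_printed_tables(path, expected):
    assert _get(default_parameters(), path) == pytest.approx(expected)


def test_pm20_uncertainty_interval_derivation(params):
    """A +/-20% interval around the $145 no-varices cost is (116, 145, 174)."""
    uv = params.costs.no_varices
    assert (uv.minimum, uv.mode, uv.maximum) == (116.0, 145.0, pytest.approx(174.0))


def test_upper_only_uncertainty_interval(params):
    """Labs and ultrasound carry an upper-only +20% interval."""
    labs = params.costs.standard_labs_afp
    assert (labs.minimum, labs.mode, labs.maximum) == (475.0, 475.0, 570.0)
    us = params.costs.ultrasound_hcc
    assert (us.minimum, us.mode, us.maximum) == (745.0, 745.0, 894.0)


def test_low_dsi_varices_distribution_is_renormalized(params):
    """The printed 84/14/1 column sums to 0.99 and must be rescaled."""
    dist = params.population.varices_below
    assert dist.as_array().sum() == pytest.approx(1.0, abs=1e-12)
    assert dist.no_varices == pytest.approx(0.84 / 0.99)


def test_mode_equal_to_maximum_is_valid():
    """Utility 0.69 (0.44-0.69) has mode == max and must validate."""
    uv = UncertainValue(minimum=0.44, mode=0.69, maximum=0.69)
    assert uv.pert_mean == pytest.approx((0.44 + 4 * 0.69 + 0.69) / 6)


def test_unordered_uncertain_value_rejected():
    with pytest.raises(ValueError, match="minimum <= mode <= maximum"):
        UncertainValue(minimum=0.5, mode=0.4, maximum=0.6)


# -- betaPERT ---------------------------------------------------------------

def test_betapert_degenerate_yields_constant():
    v = UncertainValue(minimum=0.5, mode=0.5, maximum=0.5)
    assert np.all(betapert_sample(v, 100, seed=1) == 0.5)


def test_betapert_mean_matches_closed_form():
    """Empirical mean of 1e5 draws within 3 standard errors of
    (min + 4 mode + max) / 6, including the mode == max edge case."""
    for v in (
        UncertainValue(minimum=0.20, mode=0.35, maximum=0.50),
        UncertainValue(minimum=0.44, mode=0.69, maximum=0.69),
    ):
        draws = betapert_sample(v, 100_000, seed=7)
        se = draws.std(ddof=1) / math.sqrt(len(draws))
        assert abs(draws.mean() - v.pert_mean) < 3 * se


def test_betapert_support_and_determinism():
    v = UncertainValue(minimum=1882.0, mode=2642.0, maximum=3641.0)
    a = betapert_sample(v, 10_000, seed=11)
    b = betapert_sample(v, 10_000, seed=11)
    assert np.array_equal(a, b)
    assert a.min() >= v.minimum and a.max() <= v.maximum


@settings(derandomize=True, max_examples=50)
@given(
    a=st.floats(0, 1, allow_nan=False),
    dm=st.floats(0, 1, allow_nan=False),
    db=st.floats(0.01, 1, allow_nan=False),
)
def test_betapert_support_property(a, dm, db):
    """Every draw lies inside [min, max] for arbitrary valid shapes."""
    v = UncertainValue(minimum=a, mode=a + dm, maximum=a + dm + db)
    draws = betapert_sample(v, 500, seed=3)
    assert np.all((draws >= v.minimum) & (draws <= v.maximum))


# -- perturbation -----------------------------------------------------------

def test_perturbed_sets_are_reproducible_and_in_support(params):
    sets_a = perturbed_parameter_sets(params, 3, seed=42)
    sets_b = perturbed_parameter_sets(params, 3, seed=42)
    assert sets_a == sets_b
    for drawn in sets_a:
        for (path, uv), (_, base) in zip(iter_uncertain(drawn), iter_uncertain(params)):
            assert uv.is_degenerate
            assert base.minimum <= uv.mode <= base.maximum, path
        # point parameters untouched
        assert drawn.transitions.all_cause_mortality_annual == 0.0
        assert drawn.costs.duo_test_price == params.costs.duo_test_price


def test_perturbing_degenerate_set_is_identity(params):
    from conftest import make_degenerate

    p = make_degenerate(params)
    (only,) = perturbed_parameter_sets(p, 1, seed=0)
    assert only.transitions == p.transitions
    assert only.costs == p.costs
    assert only.utilities == p.utilities


# -- file I/O ---------------------------------------------------------------

def test_round_trip_is_identity(params, tmp_path):
    path = tmp_path / "params.yaml"
    write_parameters(params, path)
    assert read_parameters(path) == params


def test_packaged_base_case_equals_defaults():
    assert read_parameters(packaged_base_case_path()) == default_parameters()


def test_out_of_range_probability_names_field(params, tmp_path):
    data = params.model_dump()
    data["transitions"]["dc_to_death"]["maximum"] = 1.3
    data["transitions"]["dc_to_death"]["mode"] = 1.3
    path = tmp_path / "bad.yaml"
    import yaml

    path.write_text(yaml.safe_dump(data))
    with pytest.raises(ParameterValidationError, match="dc_to_death"):
        read_parameters(path)


def test_missing_field_rejected_without_silent_default(params, tmp_path):
    data = params.model_dump()
    del data["utilities"]["dc"]
    path = tmp_path / "missing.yaml"
    import yaml

    path.write_text(yaml.safe_dump(data))
    with pytest.raises(ParameterValidationError, match="utilities.dc"):
        read_parameters(path)


def test_unknown_key_rejected(params, tmp_path):
    data = params.model_dump()
    data["costs"]["mystery_fee"] = 1.0
    path = tmp_path / "unknown.yaml"
    import yaml

    path.write_text(yaml.safe_dump(data))
    with pytest.raises(ParameterValidationError, match="mystery_fee"):
        read_parameters(path)


def test_set_uncertain_rejects_unknown_path(params):
    with pytest.raises(ParameterValidationError):
        set_uncertain(params, "costs.nonexistent", UncertainValue.point(1.0))
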