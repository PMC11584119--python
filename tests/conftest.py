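import pytest

from duocea.parameters import (
    UncertainValue,
    default_parameters,
    iter_uncertain,
    set_uncertain,
)


@pytest.fixture
def params():
    return default_parameters()


def make_degenerate(p):
    """All uncertain values collapsed to their modes."""
    for path, uv in list(iter_uncertain(p)):
        p = set_uncertain(p, path, UncertainValue.point(uv.mode))
    return p


def freeze_dynamics(p):
    """No transitions, no migration, no procedure deaths: a static cohort."""
    for path in (
        "transitions.no_varices_to_dc_above",
        "transitions.no_varices_to_dc_below",
        "transitions.small_varices_to_dc_above",
        "transitions.small_varices_to_dc_below",
        "transitions.large_untreated_to_dc",
        "transitions.large_treated_to_dc_above",
        "transitions.large_treated_to_dc_overall",
        "transitions.vh_to_death",
        "transitions.post_treatment_vh_to_death",
        "transitions.rebleed_to_death",
        "transitions.dc_to_death",
        "transitions.egd_to_death_per_procedure",
        "transitions.below_to_above_migration",
    ):
        p = set_uncertain(p, path, UncertainValue.point(0.0))
    return p
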