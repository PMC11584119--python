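"""Model parameters: validated inputs, betaPERT uncertainty, and file I/O.

Every quantity the model consumes lives in a single :class:`ParameterSet`:
the population structure of the 100,000-patient cohort, DuO test
performance, annual health-state transition probabilities, annual costs
(USD), annual utility weights (QALY/yr), and the economic settings
(discount rate, willingness-to-pay threshold, horizon).

Uncertain quantities are three-point :class:`UncertainValue` objects
(minimum, mode, maximum) interpreted as betaPERT distributions; the model
itself always runs on the mode, and the uncertainty machinery resamples
the three-point objects into degenerate (point) ones.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterator, Literal, Sequence, Union

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

logger = logging.getLogger(__name__)

__all__ = [
    "UncertainValue",
    "VaricesDistribution",
    "PopulationInputs",
    "TestPerformance",
    "TransitionParameters",
    "CostParameters",
    "UtilityParameters",
    "EconomicSettings",
    "ModelOptions",
    "ParameterSet",
    "ParameterValidationError",
    "default_parameters",
    "betapert_sample",
    "read_parameters",
    "write_parameters",
    "perturbed_parameter_sets",
    "iter_uncertain",
    "set_uncertain",
]


class ParameterValidationError(ValueError):
    """A parameter file or parameter object violates the schema."""


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class UncertainValue(_StrictModel):
    """Three-point (minimum, mode, maximum) uncertain quantity.

    Interpreted as a betaPERT distribution when perturbed.  A degenerate
    value (minimum == mode == maximum) represents a point parameter or a
    realized draw.  ``mode == maximum`` (or ``mode == minimum``) is valid;
    the corresponding PERT shape parameter is then 1.
    """

    minimum: float
    mode: float
    maximum: float

    @model_validator(mode="before")
    @classmethod
    def _coerce_instance(cls, data):
        # allow passing a plain UncertainValue where a constrained
        # subclass (probability, cost) is declared
        if isinstance(data, UncertainValue):
            return {"minimum": data.minimum, "mode": data.mode, "maximum": data.maximum}
        return data

    @model_validator(mode="after")
    def _check_order(self) -> "UncertainValue":
        if not (self.minimum <= self.mode <= self.maximum):
            raise ValueError(
                f"requires minimum <= mode <= maximum, got "
                f"({self.minimum}, {self.mode}, {self.maximum})"
            )
        return self

    # -- constructors -------------------------------------------------
    @classmethod
    def point(cls, x: float) -> "UncertainValue":
        return cls(minimum=x, mode=x, maximum=x)

    @classmethod
    def pm20(cls, x: float) -> "UncertainValue":
        """Symmetric +/-20% uncertainty interval around the mode."""
        lo, hi = sorted((0.8 * x, 1.2 * x))
        return cls(minimum=lo, mode=x, maximum=hi)

    @classmethod
    def upper20(cls, x: float) -> "UncertainValue":
        """Upper-only +20% uncertainty interval (minimum = mode)."""
        return cls(minimum=x, mode=x, maximum=1.2 * x)

    @property
    def is_degenerate(self) -> bool:
        return self.minimum == self.maximum

    @property
    def pert_mean(self) -> float:
        """Closed-form betaPERT mean, (min + 4*mode + max) / 6."""
        return (self.minimum + 4.0 * self.mode + self.maximum) / 6.0


class _ProbabilityUV(UncertainValue):
    @model_validator(mode="after")
    def _check_unit_interval(self) -> "_ProbabilityUV":
        if not (0.0 <= self.minimum and self.maximum <= 1.0):
            raise ValueError(
                f"probability bounds must lie in [0, 1], got "
                f"({self.minimum}, {self.mode}, {self.maximum})"
            )
        return self


class _NonNegativeUV(UncertainValue):
    @model_validator(mode="after")
    def _check_nonnegative(self) -> "_NonNegativeUV":
        if self.minimum < 0.0:
            raise ValueError(f"must be nonnegative, got minimum {self.minimum}")
        return self


class VaricesDistribution(_StrictModel):
    """Proportions of a stratum across the three varices categories.

    Renormalized at validation time when the printed values sum to
    slightly off 1 (the low-DSI column prints 84/14/1 = 0.99); sums
    further than 2% from 1 are rejected.
    """

    no_varices: float = Field(ge=0.0, le=1.0)
    small_varices: float = Field(ge=0.0, le=1.0)
    large_varices: float = Field(ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _renormalize(self) -> "VaricesDistribution":
        total = self.no_varices + self.small_varices + self.large_varices
        if abs(total - 1.0) > 0.02:
            raise ValueError(f"varices distribution sums to {total:.4f}, not 1")
        if total != 1.0:
            logger.info(
                "renormalizing varices distribution (printed sum %.4f)", total
            )
            object.__setattr__(self, "no_varices", self.no_varices / total)
            object.__setattr__(self, "small_varices", self.small_varices / total)
            object.__setattr__(self, "large_varices", self.large_varices / total)
        return self

    def as_array(self) -> np.ndarray:
        return np.array([self.no_varices, self.small_varices, self.large_varices])


class PopulationInputs(_StrictModel):
    cohort_size: int = Field(gt=0)
    fraction_dsi_above: _ProbabilityUV
    varices_overall: VaricesDistribution
    varices_above: VaricesDistribution
    varices_below: VaricesDistribution
    #: initial (and, under static mixing, standing) VH fractions
    small_vh_above: _ProbabilityUV
    small_vh_below: _ProbabilityUV
    large_untreated_vh: _ProbabilityUV
    large_treated_event: _ProbabilityUV
    #: fraction of large varices on prophylactic treatment per DSI stratum
    #: (the intervention arm's response to diagnosis; the SOC arm treats all
    #: endoscopically detected large varices regardless of stratum)
    treated_fraction_above: float = Field(ge=0.0, le=1.0)
    treated_fraction_below: float = Field(ge=0.0, le=1.0)


class TestPerformance(_StrictModel):
    """DuO test characteristics. Sensitivities are carried but not used by
    the cohort dynamics: the stratum-specific varices distributions already
    embed the test's classification behaviour."""

    dsi_cutoff: float = Field(gt=0.0, lt=50.0)
    sensitivity_small: float = Field(ge=0.0, le=1.0)
    sensitivity_large: float = Field(ge=0.0, le=1.0)


class TransitionParameters(_StrictModel):
    """Annual transition probabilities of the health-state model."""

    no_varices_to_dc_overall: _ProbabilityUV
    no_varices_to_dc_above: _ProbabilityUV
    no_varices_to_dc_below: _ProbabilityUV
    small_varices_to_dc_overall: _ProbabilityUV
    small_varices_to_dc_above: _ProbabilityUV
    small_varices_to_dc_below: _ProbabilityUV
    below_to_above_migration: _ProbabilityUV
    large_untreated_to_dc: _ProbabilityUV
    large_treated_to_dc_overall: _ProbabilityUV
    large_treated_to_dc_above: _ProbabilityUV
    vh_to_death: _ProbabilityUV
    post_treatment_vh_to_death: _ProbabilityUV
    rebleed_to_death: _ProbabilityUV
    dc_to_death: _ProbabilityUV
    egd_to_death_per_procedure: _ProbabilityUV
    #: relative reduction in all progression-to-DC probabilities in the
    #: high-DSI stratum when the adherence decision is active
    dc_reduction_on_adherence: _ProbabilityUV
    #: background mortality; no value is supplied by the source tables, so
    #: the default model excludes it (a structural assumption, logged at load)
    all_cause_mortality_annual: float = Field(ge=0.0, le=1.0, default=0.0)


class CostParameters(_StrictModel):
    """Annual healthcare costs and per-event diagnostic costs, USD."""

    no_varices: _NonNegativeUV
    small_varices_no_vh: _NonNegativeUV
    small_varices_vh: _NonNegativeUV
    large_treated: _NonNegativeUV
    large_treated_rebleed: _NonNegativeUV
    #: no cost is printed for untreated large varices; modelled as routine
    #: (small-varices level) care without VH and VH-management cost with VH
    large_untreated_no_vh: _NonNegativeUV
    large_untreated_vh: _NonNegativeUV
    dc_first_year: _NonNegativeUV
    dc_subsequent: _NonNegativeUV
    egd: _NonNegativeUV
    standard_labs_afp: _NonNegativeUV
    ultrasound_hcc: _NonNegativeUV
    #: the free variable of the analysis; excluded from sensitivity analyses
    duo_test_price: float = Field(ge=0.0)


class UtilityParameters(_StrictModel):
    """Annual QALY weights per health state."""

    no_varices: _ProbabilityUV
    small_no_vh: _ProbabilityUV
    small_vh: _ProbabilityUV
    large_treated_no_event: _ProbabilityUV
    large_treated_event: _ProbabilityUV
    large_untreated_no_vh: _ProbabilityUV
    large_untreated_vh: _ProbabilityUV
    dc: _ProbabilityUV


class EconomicSettings(_StrictModel):
    discount_rate: float = Field(ge=0.0)
    ce_threshold: float = Field(gt=0.0)
    horizon: int = Field(ge=1)


class ModelOptions(_StrictModel):
    """Structural switches left open by the source tables.

    Defaults are the package's fixed reconstruction; each is documented in
    the methods note.
    """

    #: "static": varices categories are re-apportioned to their VH substate
    #: at the initial-split fraction every cycle; "baseline_only": VH status
    #: is assigned at baseline and evolves only through mortality
    vh_mixing: Literal["static", "baseline_only"] = "static"
    #: discount factor is (1+r)^-(t - offset); offset 1 leaves year 1
    #: undiscounted
    discount_offset: int = 1
    #: "add": year 1 incurs the initial test on top of the steady schedule;
    #: "replace": year 1 count is max(steady schedule, one initial test)
    initial_test_mode: Literal["add", "replace"] = "add"
    #: how simultaneous exit probabilities from a state combine: "additive"
    #: (independent exits, row sums checked) or "sequential" (death first,
    #: progression applies to survivors)
    competing_exits: Literal["additive", "sequential"] = "additive"
    #: which printed treated-large progression rate to use: the
    #: stratum-specific 13.5% or the overall 13.7%
    large_treated_rate: Literal["stratified", "overall"] = "stratified"
    #: annual cost of the treated-large event substate: the rebleeding
    #: management cost or the treated-large maintenance cost
    treated_event_cost: Literal["rebleed", "treated"] = "rebleed"
    #: repeat DuO testing in the high-DSI stratum of the intervention arm
    repeat_duo_above: bool = False
    #: occupancy used when accruing a year's costs and QALYs:
    #: "midyear_care" (default) accrues care costs and QALYs on the average
    #: of start- and end-of-year occupancy (a half-cycle correction) while
    #: charging scheduled tests on the population present at the start of
    #: the cycle; "midyear_all" half-cycle-corrects everything; "start"
    #: accrues everything on start-of-year occupancy
    accrual: Literal["midyear_care", "midyear_all", "start"] = "midyear_care"


class Meta(_StrictModel):
    description: str = ""


class ParameterSet(_StrictModel):
    """Complete, validated input set for one model run."""

    meta: Meta = Field(default_factory=Meta)
    population: PopulationInputs
    performance: TestPerformance
    transitions: TransitionParameters
    costs: CostParameters
    utilities: UtilityParameters
    economics: EconomicSettings
    options: ModelOptions = Field(default_factory=ModelOptions)


def default_parameters() -> ParameterSet:
    """The printed base case: population structure, transition rates,
    costs, utilities, and economic settings, with their printed or
    footnoted (+/-20%, or upper-only +20%) uncertainty intervals."""
    uv = UncertainValue
    return ParameterSet(
        meta=Meta(
            description=(
                "Base case: 100,000 patients with chronic liver disease "
                "suspected of having esophageal varices; DuO test at $3,250."
            )
        ),
        population=PopulationInputs(
            cohort_size=100_000,
            fraction_dsi_above=uv(minimum=0.30, mode=0.51, maximum=0.70),
            varices_overall=VaricesDistribution(
                no_varices=0.66, small_varices=0.24, large_varices=0.10
            ),
            varices_above=VaricesDistribution(
                no_varices=0.48, small_varices=0.33, large_varices=0.19
            ),
            varices_below=VaricesDistribution(
                no_varices=0.84, small_varices=0.14, large_varices=0.01
            ),
            small_vh_above=uv.pm20(0.05),
            small_vh_below=uv.pm20(0.001),
            large_untreated_vh=uv.pm20(0.15),
            large_treated_event=uv.pm20(0.02),
            treated_fraction_above=1.0,
            treated_fraction_below=0.0,
        ),
        performance=TestPerformance(
            dsi_cutoff=18.3, sensitivity_small=0.709, sensitivity_large=0.934
        ),
        transitions=TransitionParameters(
            no_varices_to_dc_overall=uv.pm20(0.040),
            no_varices_to_dc_above=uv.point(0.066),
            no_varices_to_dc_below=uv.pm20(0.020),
            small_varices_to_dc_overall=uv.pm20(0.083),
            small_varices_to_dc_above=uv.point(0.119),
            small_varices_to_dc_below=uv.pm20(0.034),
            below_to_above_migration=uv(minimum=0.020, mode=0.025, maximum=0.030),
            large_untreated_to_dc=uv.pm20(0.135),
            large_treated_to_dc_overall=uv.pm20(0.137),
            large_treated_to_dc_above=uv.pm20(0.135),
            vh_to_death=uv.pm20(0.129),
            post_treatment_vh_to_death=uv.pm20(0.129),
            rebleed_to_death=uv.pm20(0.129),
            dc_to_death=uv.pm20(0.129),
            egd_to_death_per_procedure=uv.pm20(0.00001),
            dc_reduction_on_adherence=uv(minimum=0.20, mode=0.35, maximum=0.50),
            all_cause_mortality_annual=0.0,
        ),
        costs=CostParameters(
            no_varices=uv.pm20(145.0),
            small_varices_no_vh=uv.pm20(155.0),
            small_varices_vh=uv.pm20(5010.0),
            large_treated=uv(minimum=585.0, mode=1110.0, maximum=1332.0),
            large_treated_rebleed=uv.pm20(5010.0),
            large_untreated_no_vh=uv.pm20(155.0),
            large_untreated_vh=uv.pm20(5010.0),
            dc_first_year=uv(minimum=16430.0, mode=25595.0, maximum=30714.0),
            dc_subsequent=uv(minimum=4690.0, mode=24755.0, maximum=29706.0),
            egd=uv(minimum=1882.0, mode=2642.0, maximum=3641.0),
            standard_labs_afp=uv.upper20(475.0),
            ultrasound_hcc=uv.upper20(745.0),
            duo_test_price=3250.0,
        ),
        utilities=UtilityParameters(
            no_varices=uv(minimum=0.72, mode=0.92, maximum=1.00),
            small_no_vh=uv(minimum=0.77, mode=0.79, maximum=0.81),
            small_vh=uv(minimum=0.44, mode=0.69, maximum=0.69),
            large_treated_no_event=uv(minimum=0.79, mode=0.83, maximum=0.87),
            large_treated_event=uv(minimum=0.44, mode=0.69, maximum=0.69),
            large_untreated_no_vh=uv(minimum=0.70, mode=0.76, maximum=0.79),
            large_untreated_vh=uv(minimum=0.44, mode=0.69, maximum=0.69),
            dc=uv(minimum=0.44, mode=0.69, maximum=0.69),
        ),
        economics=EconomicSettings(discount_rate=0.03, ce_threshold=20_000.0, horizon=10),
    )


# ---------------------------------------------------------------------------
# betaPERT sampling
# ---------------------------------------------------------------------------

def betapert_sample(
    v: UncertainValue,
    n: int,
    seed: Union[int, np.random.Generator],
) -> np.ndarray:
    """Draw ``n`` betaPERT (lambda = 4) samples from ``v``.

    shape1 = 1 + 4 (mode - min) / (max - min),
    shape2 = 1 + 4 (max - mode) / (max - min),
    scaled to [min, max].  A degenerate value yields the constant.
    """
    if not isinstance(v, UncertainValue):
        v = UncertainValue.model_validate(v)
    if n < 1:
        raise ParameterValidationError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a, m, b = v.minimum, v.mode, v.maximum
    if a == b:
        return np.full(n, m, dtype=float)
    span = b - a
    shape1 = 1.0 + 4.0 * (m - a) / span
    shape2 = 1.0 + 4.0 * (b - m) / span
    return a + span * rng.beta(shape1, shape2, size=n)


# ---------------------------------------------------------------------------
# traversal of uncertain leaves
# ---------------------------------------------------------------------------

def iter_uncertain(p: ParameterSet) -> Iterator[tuple[str, UncertainValue]]:
    """Yield ``(dotted_path, value)`` for every UncertainValue in ``p``
    in a stable (declaration) order."""
    for section_name in ("population", "transitions", "costs", "utilities"):
        section = getattr(p, section_name)
        for field_name in type(section).model_fields:
            value = getattr(section, field_name)
            if isinstance(value, UncertainValue):
                yield f"{section_name}.{field_name}", value


def set_uncertain(p: ParameterSet, path: str, value: UncertainValue) -> ParameterSet:
    """Return a copy of ``p`` with the UncertainValue at ``path`` replaced."""
    section_name, field_name = path.split(".", 1)
    data = p.model_dump()
    if field_name not in data[section_name]:
        raise ParameterValidationError(f"unknown parameter path {path!r}")
    data[section_name][field_name] = value.model_dump()
    return ParameterSet.model_validate(data)


def perturbed_parameter_sets(
    p: ParameterSet, n: int, seed: int
) -> list[ParameterSet]:
    """``n`` parameter sets with every UncertainValue independently
    resampled from its betaPERT distribution (each becomes a degenerate
    value at the draw); point parameters are untouched.  Deterministic
    under ``seed``."""
    if n < 1:
        raise ParameterValidationError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    paths = [path for path, _ in iter_uncertain(p)]
    draws = {
        path: betapert_sample(dict(iter_uncertain(p))[path], n, rng)
        for path in paths
    }
    out = []
    for i in range(n):
        data = p.model_dump()
        for path in paths:
            section_name, field_name = path.split(".", 1)
            x = float(draws[path][i])
            data[section_name][field_name] = {
                "minimum": x, "mode": x, "maximum": x
            }
        out.append(ParameterSet.model_validate(data))
    return out


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_parameters(p: ParameterSet, path: Union[str, Path]) -> None:
    """Write ``p`` as a YAML parameter file (lossless round-trip)."""
    with open(path, "w") as fh:
        yaml.safe_dump(p.model_dump(), fh, sort_keys=False)


def _format_loc(loc: Sequence) -> str:
    return ".".join(str(part) for part in loc)


def read_parameters(path: Union[str, Path]) -> ParameterSet:
    """Read and validate a YAML parameter file.

    Unknown keys, out-of-range values, and missing fields are rejected with
    the offending field path; there are no silent defaults for table values.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParameterValidationError(f"{path}: not a mapping")
    try:
        return ParameterSet.model_validate(data)
    except Exception as exc:  # pydantic ValidationError
        details = []
        for err in getattr(exc, "errors", lambda: [])():
            details.append(f"{_format_loc(err['loc'])}: {err['msg']}")
        raise ParameterValidationError(
            f"{path}: invalid parameter file\n  " + "\n  ".join(details or [str(exc)])
        ) from exc


def packaged_base_case_path() -> Path:
    """Path of the parameter file shipped with the package."""
    return Path(__file__).parent / "data" / "paper_base_case.yaml"
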