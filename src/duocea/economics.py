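"""Discounting, ICER comparison, break-even pricing, and what-if sweeps.

Comparisons are cumulative: for each year *t* the discounted costs and
QALYs accrued through year *t* are differenced between the intervention
and SOC arms.  The incremental cost-effectiveness ratio (ICER) is
delta-cost over delta-QALY; an arm that saves money outright is
"cost-saving" and its ICER is not reported.  "Highly cost-effective"
means cost-saving or ICER below one times the willingness-to-pay
threshold ($20,000/QALY in the base case).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import RunResult, run_strategy
from .parameters import ModelOptions, ParameterSet
from .strategies import StrategyConfig

__all__ = [
    "discount_stream",
    "ComparisonResult",
    "compare",
    "compare_strategies",
    "years_to_highly_cost_effective",
    "BreakEvenResult",
    "break_even_price",
    "price_sweep",
    "classify",
]

COST_SAVING = "cost-saving"
HIGHLY_CE = "highly cost-effective"
COST_EFFECTIVE = "cost-effective"
NOT_CE = "not cost-effective"


def discount_stream(
    values: Sequence[float], rate: float, offset: int = 1
) -> np.ndarray:
    """Discount a per-year stream; year t is scaled by (1+rate)^-(t-offset),
    so with the default offset year 1 is undiscounted."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    values = np.asarray(values, dtype=float)
    t = np.arange(1, len(values) + 1)
    return values * (1.0 + rate) ** -(t - offset)


def classify(dcost: float, dqaly: float, threshold: float) -> str:
    """Cost-effectiveness class of a (delta-cost, delta-QALY) pair."""
    if dcost <= 0.0:
        return COST_SAVING
    if dqaly <= 0.0:
        return NOT_CE
    icer = dcost / dqaly
    if icer < threshold:
        return HIGHLY_CE
    if icer < 3.0 * threshold:
        return COST_EFFECTIVE
    return NOT_CE


@dataclass(frozen=True)
class ComparisonResult:
    """Per-year cumulative comparison of an intervention/SOC pair.

    All yearly arrays are cumulative through that year; costs and QALYs
    are discounted.  ``icer[t]`` is NaN where the delta-QALY is
    nonpositive or the intervention is dominant (cost-saving).
    """

    years: np.ndarray
    delta_cost: np.ndarray
    delta_qalys: np.ndarray
    icer: np.ndarray
    classification: list[str]
    dc_averted: np.ndarray
    deaths_averted: np.ndarray
    ce_threshold: float

    def at_year(self, year: int) -> dict:
        i = int(year) - 1
        if not (0 <= i < len(self.years)):
            raise ValueError(f"year {year} outside horizon {len(self.years)}")
        return {
            "year": int(self.years[i]),
            "delta_cost": float(self.delta_cost[i]),
            "delta_qalys": float(self.delta_qalys[i]),
            "icer": float(self.icer[i]),
            "classification": self.classification[i],
            "dc_averted": float(self.dc_averted[i]),
            "deaths_averted": float(self.deaths_averted[i]),
        }

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "delta_cost": self.delta_cost,
                "delta_qalys": self.delta_qalys,
                "icer": self.icer,
                "classification": self.classification,
                "dc_averted": self.dc_averted,
                "deaths_averted": self.deaths_averted,
            }
        )


def compare(
    intervention: RunResult, soc: RunResult, p: ParameterSet
) -> ComparisonResult:
    """Cumulative discounted deltas (intervention minus SOC) per year.

    Deaths averted count liver- and procedure-related deaths only; the
    background all-cause exit is excluded from reported mortality.
    """
    fi, fs = intervention.frame, soc.frame
    if len(fi) != len(fs):
        raise ValueError(f"horizon mismatch: {len(fi)} vs {len(fs)} ledger years")
    dcost = (fi["disc_total_cost"] - fs["disc_total_cost"]).cumsum().to_numpy()
    dqaly = (fi["disc_qalys"] - fs["disc_qalys"]).cumsum().to_numpy()
    dc_averted = (fs["incident_dc"] - fi["incident_dc"]).cumsum().to_numpy()
    deaths_averted = (
        (fs["deaths_liver"] + fs["deaths_procedure"])
        - (fi["deaths_liver"] + fi["deaths_procedure"])
    ).cumsum().to_numpy()
    icer = np.full(len(dcost), np.nan)
    classification = []
    for i in range(len(dcost)):
        cls = classify(dcost[i], dqaly[i], p.economics.ce_threshold)
        classification.append(cls)
        if dcost[i] > 0 and dqaly[i] > 0:
            icer[i] = dcost[i] / dqaly[i]
    return ComparisonResult(
        years=np.arange(1, len(dcost) + 1),
        delta_cost=dcost,
        delta_qalys=dqaly,
        icer=icer,
        classification=classification,
        dc_averted=dc_averted,
        deaths_averted=deaths_averted,
        ce_threshold=p.economics.ce_threshold,
    )


def compare_strategies(
    p: ParameterSet,
    intervention: StrategyConfig,
    horizon: Optional[int] = None,
    options: Optional[ModelOptions] = None,
) -> ComparisonResult:
    """Run both arms and compare them."""
    options = options or p.options
    soc = run_strategy(p, StrategyConfig.soc(), horizon, options)
    inter = run_strategy(p, intervention, horizon, options)
    return compare(inter, soc, p)


def years_to_highly_cost_effective(result: ComparisonResult) -> Optional[int]:
    """Smallest year at which the intervention is cost-saving or highly
    cost-effective; None if never within the horizon."""
    for i, cls in enumerate(result.classification):
        if cls in (COST_SAVING, HIGHLY_CE):
            return int(result.years[i])
    return None


@dataclass(frozen=True)
class BreakEvenResult:
    """Price at which the intervention is cost-neutral at a given year."""

    year: int
    price: float
    converged: bool
    residual: float  # cumulative discounted delta-cost at the solution, USD

    @property
    def price_rounded(self) -> int:
        return int(round(self.price))


def _delta_cost_at(
    p: ParameterSet,
    strategy: StrategyConfig,
    price: float,
    year: int,
    soc: RunResult,
    options: ModelOptions,
) -> tuple[float, RunResult]:
    from dataclasses import replace

    inter = run_strategy(p, replace(strategy, duo_price=price), year, options)
    result = compare(inter, soc, p)
    return float(result.delta_cost[year - 1]), inter


def break_even_price(
    p: ParameterSet,
    strategy: StrategyConfig,
    year: int,
    options: Optional[ModelOptions] = None,
) -> BreakEvenResult:
    """Solve cumulative discounted delta-cost(year; price) = 0 for the
    DuO test price.

    Total cost is affine in price (the dynamics never depend on it), so
    the closed form ``price* = -delta_cost(0) / discounted_test_count``
    is exact; the solution is re-evaluated and must land within $1 of
    cost neutrality for the whole cohort.
    """
    options = options or p.options
    if year < 1:
        raise ValueError("break-even year must be >= 1")
    soc = run_strategy(p, StrategyConfig.soc(), year, options)
    dc0, inter0 = _delta_cost_at(p, strategy, 0.0, year, soc, options)
    frame = inter0.frame
    slope = float(
        (frame["duo_tests"] * frame["discount_factor"]).iloc[:year].sum()
    )
    if slope <= 0.0:
        return BreakEvenResult(year=year, price=math.nan, converged=False, residual=dc0)
    price = -dc0 / slope
    if price < 0.0:
        # intervention dearer than SOC even with a free test
        return BreakEvenResult(year=year, price=price, converged=False, residual=dc0)
    residual, _ = _delta_cost_at(p, strategy, price, year, soc, options)
    converged = abs(residual) < 1.0
    return BreakEvenResult(year=year, price=price, converged=converged, residual=residual)


def break_even_price_bisection(
    p: ParameterSet,
    strategy: StrategyConfig,
    year: int,
    options: Optional[ModelOptions] = None,
    lo: float = 0.0,
    hi: float = 50_000.0,
    tol: float = 1e-4,
) -> BreakEvenResult:
    """Bisection solve of the same root; cross-check for the closed form."""
    options = options or p.options
    soc = run_strategy(p, StrategyConfig.soc(), year, options)
    f_lo, _ = _delta_cost_at(p, strategy, lo, year, soc, options)
    f_hi, _ = _delta_cost_at(p, strategy, hi, year, soc, options)
    if f_lo > 0 or f_hi < 0:
        return BreakEvenResult(year=year, price=math.nan, converged=False, residual=f_lo)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        f_mid, _ = _delta_cost_at(p, strategy, mid, year, soc, options)
        if f_mid <= 0:
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
    price = 0.5 * (lo + hi)
    residual, _ = _delta_cost_at(p, strategy, price, year, soc, options)
    return BreakEvenResult(year=year, price=price, converged=True, residual=residual)


def price_sweep(
    p: ParameterSet,
    prices: Sequence[float],
    strategy: Optional[StrategyConfig] = None,
    horizon: Optional[int] = None,
    options: Optional[ModelOptions] = None,
) -> pd.DataFrame:
    """What-if analysis: years to a highly cost-effective intervention as
    a function of the DuO test price.  Output is sorted by price; years
    beyond the horizon are reported as missing."""
    from dataclasses import replace

    if len(prices) == 0:
        raise ValueError("prices must be nonempty")
    options = options or p.options
    horizon = p.economics.horizon if horizon is None else horizon
    strategy = strategy or StrategyConfig.intervention()
    soc = run_strategy(p, StrategyConfig.soc(), horizon, options)
    rows = []
    for price in sorted(float(x) for x in prices):
        inter = run_strategy(p, replace(strategy, duo_price=price), horizon, options)
        years = years_to_highly_cost_effective(compare(inter, soc, p))
        rows.append({"price": price, "years_to_highly_cost_effective": years})
    return pd.DataFrame(rows)
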