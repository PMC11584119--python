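"""One-way (tornado) and probabilistic sensitivity analysis.

The one-way analysis moves each uncertain parameter to its minimum and
maximum (all others at mode) and records the swing in the outcome —
by default the number of years for the intervention to become highly
cost-effective.  Variance attribution uses squared-swing shares, the
standard tornado heuristic.  The probabilistic analysis re-runs the
comparison on betaPERT-resampled parameter sets.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np
import pandas as pd

from .economics import compare_strategies, years_to_highly_cost_effective
from .parameters import (
    ModelOptions,
    ParameterSet,
    UncertainValue,
    iter_uncertain,
    perturbed_parameter_sets,
    set_uncertain,
)
from .strategies import StrategyConfig

__all__ = ["one_way_sensitivity", "probabilistic_sa"]


def _default_outcome(
    p: ParameterSet, strategy: StrategyConfig, options: ModelOptions
) -> float:
    """Years to a highly cost-effective intervention, censored at
    horizon + 1 when never reached (so extremes still register swing)."""
    result = compare_strategies(p, strategy, options=options)
    years = years_to_highly_cost_effective(result)
    return float(years) if years is not None else float(p.economics.horizon + 1)


def one_way_sensitivity(
    p: ParameterSet,
    strategy: Optional[StrategyConfig] = None,
    options: Optional[ModelOptions] = None,
    outcome: Optional[Callable[[ParameterSet, StrategyConfig, ModelOptions], float]] = None,
) -> pd.DataFrame:
    """Tornado analysis over every non-degenerate uncertain parameter.

    The DuO test price is a decision variable, not an uncertain one, and
    is excluded by construction.  Returns a frame ranked by swing
    (ties broken by parameter name) with columns: parameter, low, base,
    high, swing, share, cumulative_share.
    """
    strategy = strategy or StrategyConfig.intervention()
    options = options or p.options
    outcome = outcome or _default_outcome
    base = outcome(p, strategy, options)
    rows = []
    for path, uv in iter_uncertain(p):
        if uv.is_degenerate:
            continue
        low = outcome(
            set_uncertain(p, path, UncertainValue.point(uv.minimum)), strategy, options
        )
        high = outcome(
            set_uncertain(p, path, UncertainValue.point(uv.maximum)), strategy, options
        )
        rows.append(
            {
                "parameter": path,
                "low": low,
                "base": base,
                "high": high,
                "swing": abs(high - low),
            }
        )
    if not rows:
        raise ValueError("no non-degenerate uncertain parameters to vary")
    frame = pd.DataFrame(rows).sort_values(
        ["swing", "parameter"], ascending=[False, True], kind="mergesort"
    )
    total = float((frame["swing"] ** 2).sum())
    frame["share"] = (frame["swing"] ** 2 / total) if total > 0 else 0.0
    frame["cumulative_share"] = frame["share"].cumsum()
    return frame.reset_index(drop=True)


def probabilistic_sa(
    p: ParameterSet,
    strategy: Optional[StrategyConfig] = None,
    n: int = 1000,
    seed: int = 0,
    horizon: Optional[int] = None,
    options: Optional[ModelOptions] = None,
) -> tuple[pd.DataFrame, dict]:
    """Probabilistic sensitivity analysis over ``n`` betaPERT draws.

    Returns the per-draw outcomes (delta-cost, delta-QALYs, ICER, years)
    at the horizon, plus a summary dict with means and 2.5/97.5
    percentiles.  Deterministic under ``seed``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    strategy = strategy or StrategyConfig.intervention()
    options = options or p.options
    horizon = p.economics.horizon if horizon is None else horizon
    rows = []
    for draw in perturbed_parameter_sets(p, n, seed):
        result = compare_strategies(draw, strategy, horizon, options)
        at_end = result.at_year(horizon)
        years = years_to_highly_cost_effective(result)
        rows.append(
            {
                "delta_cost": at_end["delta_cost"],
                "delta_qalys": at_end["delta_qalys"],
                "icer": at_end["icer"],
                "years_to_highly_cost_effective": (
                    float(years) if years is not None else np.nan
                ),
            }
        )
    draws = pd.DataFrame(rows)
    summary = {}
    for col in draws.columns:
        vals = draws[col].dropna().to_numpy()
        summary[col] = {
            "mean": float(np.mean(vals)) if len(vals) else float("nan"),
            "p2.5": float(np.percentile(vals, 2.5)) if len(vals) else float("nan"),
            "p97.5": float(np.percentile(vals, 97.5)) if len(vals) else float("nan"),
            "n_defined": int(len(vals)),
        }
    return draws, summary
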