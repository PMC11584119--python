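"""Run orchestration and report bundles reproducing the headline tables.

:func:`reproduce_tables` runs the full analysis from one parameter file:
the base case (DC averted, deaths averted, QALYs gained, cost saved at
years 2/3/5), break-even prices (all decisions and each decision alone,
at years 2 and 5), the what-if price sweep, and the tornado table.  Each
table is written as CSV next to a formatted text summary whose numbers
are taken verbatim from the CSV cells, plus a JSON run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from . import __version__
from .economics import (
    break_even_price,
    compare,
    price_sweep,
    years_to_highly_cost_effective,
)
from .engine import run_strategy
from .parameters import ModelOptions, ParameterSet, read_parameters
from .strategies import StrategyConfig
from .uncertainty import one_way_sensitivity

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "base_case_table", "breakeven_table", "reproduce_tables"]

_DECISION_LABELS = {
    (1, 2, 3): "all_decisions",
    (1,): "decision_1_avoid_egd",
    (2,): "decision_2_reduce_followup",
    (3,): "decision_3_adherence",
}


@dataclass(frozen=True)
class RunManifest:
    """Provenance of a report bundle: identical manifests (up to the
    timestamp) imply identical outputs."""

    parameters_sha256: str
    strategy: dict
    seed: int
    horizon: int
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def write(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")


def parameters_hash(p: ParameterSet) -> str:
    canonical = yaml.safe_dump(p.model_dump(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _log_assumptions(p: ParameterSet, options: ModelOptions) -> None:
    logger.info("VH substate model: %s mixing", options.vh_mixing)
    logger.info(
        "discounting: (1+r)^-(t-%d), year 1 %s",
        options.discount_offset,
        "undiscounted" if options.discount_offset == 1 else "discounted",
    )
    logger.info("year-1 initial test convention: %s", options.initial_test_mode)
    logger.info("competing exits combined: %s", options.competing_exits)
    logger.info(
        "all-cause mortality: %.4f/yr (excluded from reported deaths)",
        p.transitions.all_cause_mortality_annual,
    )


def base_case_table(
    p: ParameterSet,
    strategy: Optional[StrategyConfig] = None,
    years: Sequence[int] = (2, 3, 5),
    options: Optional[ModelOptions] = None,
) -> pd.DataFrame:
    """Headline outcomes of one intervention configuration vs SOC."""
    options = options or p.options
    strategy = strategy or StrategyConfig.intervention(price=p.costs.duo_test_price)
    horizon = max(max(years), p.economics.horizon)
    soc = run_strategy(p, StrategyConfig.soc(), horizon, options)
    inter = run_strategy(p, strategy, horizon, options)
    result = compare(inter, soc, p)
    rows = []
    for year in years:
        at = result.at_year(year)
        rows.append(
            {
                "year": year,
                "dc_averted": at["dc_averted"],
                "deaths_averted": at["deaths_averted"],
                "qalys_gained": at["delta_qalys"],
                "cost_saved_usd": -at["delta_cost"],
                "classification": at["classification"],
            }
        )
    return pd.DataFrame(rows)


def breakeven_table(
    p: ParameterSet,
    years: Sequence[int] = (2, 5),
    options: Optional[ModelOptions] = None,
) -> pd.DataFrame:
    """Break-even DuO prices for all decisions combined and each decision
    alone, at the requested years."""
    options = options or p.options
    rows = []
    for decisions, label in _DECISION_LABELS.items():
        strategy = StrategyConfig.intervention(decisions=decisions, price=0.0)
        for year in years:
            res = break_even_price(p, strategy, year, options)
            rows.append(
                {
                    "configuration": label,
                    "year": year,
                    "break_even_price_usd": res.price_rounded,
                    "converged": res.converged,
                    "residual_usd": res.residual,
                }
            )
    return pd.DataFrame(rows)


def _summary_text(
    base: pd.DataFrame, brk: pd.DataFrame, sweep: pd.DataFrame, tornado: pd.DataFrame
) -> str:
    lines = ["DSI-guided management vs standard of care", "=" * 42, ""]
    lines.append("Base case (all three decisions):")
    for _, row in base.iterrows():
        lines.append(
            f"  year {int(row['year'])}: DC averted {row['dc_averted']:.0f}, "
            f"deaths averted {row['deaths_averted']:.0f}, "
            f"QALYs gained {row['qalys_gained']:.0f}, "
            f"cost saved ${row['cost_saved_usd'] / 1e6:.1f}M "
            f"({row['classification']})"
        )
    lines.append("")
    lines.append("Break-even DuO prices (cost-neutral vs SOC):")
    for _, row in brk.iterrows():
        lines.append(
            f"  {row['configuration']}, year {int(row['year'])}: "
            f"${row['break_even_price_usd']:,}"
        )
    lines.append("")
    lines.append("What-if price sweep (years to highly cost-effective):")
    for _, row in sweep.iterrows():
        years = row["years_to_highly_cost_effective"]
        label = f"{int(years)}" if pd.notna(years) else "beyond horizon"
        lines.append(f"  ${row['price']:,.0f}: {label} years")
    lines.append("")
    lines.append("Top one-way sensitivity drivers (squared-swing share):")
    for _, row in tornado.head(8).iterrows():
        lines.append(
            f"  {row['parameter']}: swing {row['swing']:.1f} years, "
            f"share {row['share']:.2f}"
        )
    return "\n".join(lines) + "\n"


def reproduce_tables(
    params: Union[ParameterSet, str, Path],
    out_dir: Union[str, Path],
    seed: int = 0,
    sweep_prices: Sequence[float] = (1000, 1500, 2000, 2500, 3000, 3500, 4000, 4500, 5000),
    options: Optional[ModelOptions] = None,
) -> dict[str, Path]:
    """Run the full analysis and write the report bundle.

    Deterministic for a given parameter file and seed.  Any stage failure
    aborts with the stage name.
    """
    p = params if isinstance(params, ParameterSet) else read_parameters(params)
    options = options or p.options
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _log_assumptions(p, options)

    stage = "base_case"
    try:
        base = base_case_table(p, options=options)
        base.to_csv(out / "base_case.csv", index=False)
        stage = "breakeven"
        brk = breakeven_table(p, options=options)
        brk.to_csv(out / "breakeven.csv", index=False)
        stage = "sweep"
        sweep = price_sweep(
            p,
            sweep_prices,
            StrategyConfig.intervention(price=0.0),
            options=options,
        )
        sweep.to_csv(out / "sweep.csv", index=False)
        stage = "tornado"
        tornado = one_way_sensitivity(p, options=options)
        tornado.to_csv(out / "tornado.csv", index=False)
        stage = "summary"
        (out / "summary.txt").write_text(_summary_text(base, brk, sweep, tornado))
        stage = "manifest"
        strategy = StrategyConfig.intervention(price=p.costs.duo_test_price)
        RunManifest(
            parameters_sha256=parameters_hash(p),
            strategy=strategy.__dict__,
            seed=seed,
            horizon=p.economics.horizon,
        ).write(out / "manifest.json")
    except Exception as exc:
        raise RuntimeError(f"report stage {stage!r} failed: {exc}") from exc

    return {
        "base_case": out / "base_case.csv",
        "breakeven": out / "breakeven.csv",
        "sweep": out / "sweep.csv",
        "tornado": out / "tornado.csv",
        "summary": out / "summary.txt",
        "manifest": out / "manifest.json",
    }
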