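"""Result tables and display formatting.

All model arithmetic runs at full precision; this module owns the display
conventions of the study's result tables — 2-decimal USD, integer-percent
itemized shares, and effect proportions reported to two decimal places (the
precision at which they enter the model's parameter table) shown as
percentages with one decimal.  Rendering is deterministic: the same inputs
produce byte-identical text.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .costing import CostLedger, itemize
from .parameters import ParameterTable
from .tree import DecisionTree, IncrementalResult, incremental, rollback

__all__ = [
    "diagnosed_proportion",
    "format_percent",
    "effect_summary",
    "basecase_report",
    "render_basecase",
    "cost_summary_table",
    "itemized_cost_table",
    "render_frame",
]


def diagnosed_proportion(n_severe: int, n_enrolled: int) -> float:
    """Diagnosed-severe proportion rounded to the model's 2-decimal precision."""
    if n_enrolled <= 0:
        raise ValueError("n_enrolled must be positive")
    return round(n_severe / n_enrolled, 2)


def format_percent(proportion: float, decimals: int = 1) -> str:
    """Format a proportion as a percent string, e.g. 0.16 -> '16.0%'."""
    return f"{100 * proportion:.{decimals}f}%"


def effect_summary(counts: Mapping[str, Mapping[str, int]]) -> dict:
    """Per-arm diagnosed-severe proportions and their difference.

    ``counts`` maps arm -> {'severe': k, 'enrolled': n}.  The difference is
    reported in percentage points at the model's display precision.
    """
    out: dict = {"arms": {}}
    props = {}
    for arm, c in counts.items():
        p = diagnosed_proportion(c["severe"], c["enrolled"])
        props[arm] = p
        out["arms"][arm] = {
            "severe": int(c["severe"]),
            "enrolled": int(c["enrolled"]),
            "proportion": p,
            "display": format_percent(p),
        }
    if {"intervention", "control"} <= props.keys():
        diff = round(props["intervention"] - props["control"], 2)
        out["difference_pp"] = round(100 * diff)
        out["difference_display"] = f"{round(100 * diff)} percentage points"
    return out


def basecase_report(tree: DecisionTree, params: ParameterTable) -> dict:
    """Per-strategy expected cost/effect at base values plus the incremental result."""
    outcomes = rollback(tree, params.base_values())
    res: IncrementalResult = incremental(outcomes["control"], outcomes["intervention"])
    return {
        "effect_definition": tree.effect_definition,
        "strategies": {
            name: {"expected_cost": float(c), "expected_effect": float(e)}
            for name, (c, e) in outcomes.items()
        },
        "incremental": {
            "comparator": "intervention",
            "reference": "control",
            "delta_cost": res.delta_cost,
            "delta_effect": res.delta_effect,
            "icer": res.icer,
            "status": res.status,
        },
    }


def render_basecase(report: dict) -> str:
    """Fixed-width text rendering of a base-case report."""
    lines = [f"Base case (effect = {report['effect_definition']})", ""]
    lines.append(f"{'strategy':<16}{'E[cost] USD':>14}{'E[effect]':>12}")
    for name, o in report["strategies"].items():
        lines.append(f"{name:<16}{o['expected_cost']:>14.4f}{o['expected_effect']:>12.4f}")
    inc = report["incremental"]
    lines.append("")
    lines.append(f"delta cost   : {inc['delta_cost']:.4f} USD per child")
    lines.append(f"delta effect : {inc['delta_effect']:.4f} cases per child")
    if inc["status"] == "icer":
        lines.append(f"ICER         : {inc['icer']:.2f} USD per extra diagnosed severe case")
    else:
        lines.append(f"ICER         : {inc['status']}")
    return "\n".join(lines) + "\n"


def cost_summary_table(ledgers: Mapping[tuple[str, str], CostLedger]) -> pd.DataFrame:
    """Total and average cost per diagnosed case, by arm and diagnosis class.

    Cells with no diagnosed case show a 'no cases' marker instead of an
    average — never a silent zero.
    """
    rows = []
    for (arm, cls), ledger in sorted(ledgers.items()):
        rows.append(
            {
                "arm": arm,
                "diagnosis_class": cls,
                "n_diagnosed": ledger.n_cases,
                "total_usd": round(ledger.total, 2),
                "average_usd": round(ledger.average(), 2) if ledger.n_cases else "no cases",
            }
        )
    return pd.DataFrame(
        rows, columns=["arm", "diagnosis_class", "n_diagnosed", "total_usd", "average_usd"]
    )


def itemized_cost_table(ledger: CostLedger) -> pd.DataFrame:
    """Itemized ledger with 2-decimal totals and integer-percent shares."""
    df = itemize(ledger)
    df["total_usd"] = df["total_usd"].round(2)
    return df


def render_frame(df: pd.DataFrame) -> str:
    """Deterministic plain-text table rendering."""
    return df.to_string(index=False) + "\n"
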