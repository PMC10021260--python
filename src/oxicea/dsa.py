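"""One-way deterministic sensitivity analysis (tornado diagram data).

Each uncertain parameter is set in turn to the low and high end of its
deterministic range (the min/max columns of the parameter table, the 95%-CI
style bounds of the trial estimates) while all other parameters stay at
base, and the ICER is recomputed.  Ends where one strategy dominates are
reported as dominance statuses, never coerced to numbers; the bar spread is
then undefined and such entries sort after all finite-spread entries.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .parameters import ParameterSpec, ParameterTable
from .tree import DecisionTree, incremental, rollback

__all__ = ["TornadoEntry", "one_way", "tornado", "tornado_frame", "base_case_icer"]


def _icer_at(tree: DecisionTree, values: dict[str, float]):
    """ICER (or dominance status string) of intervention vs control."""
    out = rollback(tree, values)
    res = incremental(out["control"], out["intervention"])
    return res.icer if res.status == "icer" else res.status


@dataclass(frozen=True)
class TornadoEntry:
    """One tornado bar: ICER (or status) at each end of a parameter's range."""

    parameter: str
    icer_at_min: float | str
    icer_at_max: float | str

    @property
    def spread(self) -> float | None:
        """|ICER(max) − ICER(min)| when both ends are ratios, else None."""
        if isinstance(self.icer_at_min, str) or isinstance(self.icer_at_max, str):
            return None
        return abs(self.icer_at_max - self.icer_at_min)


def base_case_icer(tree: DecisionTree, params: ParameterTable):
    """ICER with every parameter at its base value."""
    return _icer_at(tree, params.base_values())


def one_way(tree: DecisionTree, params: ParameterTable, param: ParameterSpec) -> TornadoEntry:
    """Recompute the ICER with one parameter at its min and at its max.

    All other parameters stay at base.  Dominance at an end is propagated as
    a status string.
    """
    if param.name not in tree.parameters():
        raise KeyError(f"parameter {param.name!r} does not appear in the model")
    base = params.base_values()
    low = dict(base, **{param.name: param.min})
    high = dict(base, **{param.name: param.max})
    return TornadoEntry(param.name, _icer_at(tree, low), _icer_at(tree, high))


def tornado(tree: DecisionTree, params: ParameterTable) -> list[TornadoEntry]:
    """One-way entries for every varying parameter, widest bar first.

    Parameters with min == max are skipped (their bar has zero width by
    construction).  Entries with a defined spread sort by spread descending;
    entries with a dominance end sort after them; ties break on the
    parameter name, making the ordering a pure function of the inputs.
    """
    entries = [
        one_way(tree, params, spec)
        for spec in params
        if spec.name in tree.parameters() and spec.min < spec.max
    ]
    entries.sort(
        key=lambda e: (e.spread is None, -(e.spread if e.spread is not None else 0.0), e.parameter)
    )
    return entries


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    """Tornado entries as a frame: ``parameter,icer_at_min,icer_at_max,spread``."""
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "icer_at_min": e.icer_at_min,
                "icer_at_max": e.icer_at_max,
                "spread": e.spread,
            }
            for e in entries
        ],
        columns=["parameter", "icer_at_min", "icer_at_max", "spread"],
    )
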