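"""Probabilistic sensitivity analysis: Monte Carlo over all model inputs.

Every uncertain parameter is replaced by its fitted distribution (gamma for
costs, beta for proportions, method-of-moments fit to base value and SD) and
drawn jointly; each joint draw is rolled back through the decision tree to
give an incremental point (ΔC, ΔE) on the cost-effectiveness plane.
Decision uncertainty is summarized through cost-effectiveness acceptability
curves: at willingness-to-pay λ, the probability that each strategy has the
highest net monetary benefit NMB = λ·E − C.  For the two-strategy model the
intervention is preferred in a draw iff λ·ΔE − ΔC > 0, so the CEAC crosses
one half at the median of the per-draw ratio ΔC/ΔE (among ΔE > 0 draws).

Draws are independent across parameters, except that parameters in a shared
draw group take one common draw — by default the two specificities, since
the combined strategy's specificity is assumed equal to that of IMCI alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .parameters import ParameterTable
from .tree import DecisionTree, rollback

__all__ = [
    "PSAConfig",
    "PSAResult",
    "CrossoverResult",
    "run_psa",
    "ceac",
    "crossover_wtp",
    "psa_summary",
]

#: The combined strategy's specificity is assumed equal to IMCI's, so the two
#: rows share a single Monte Carlo draw by default.
DEFAULT_SHARED_GROUPS: tuple[frozenset[str], ...] = (
    frozenset({"spec_intervention", "spec_control"}),
)


def default_wtp_grid() -> np.ndarray:
    """0–100 USD per diagnosed severe case, 1-USD steps."""
    return np.arange(0.0, 101.0)


@dataclass
class PSAConfig:
    """Monte Carlo settings: iteration count, seed, WTP grid, shared draws."""

    iterations: int = 10_000
    seed: int = 0
    wtp_grid: np.ndarray = field(default_factory=default_wtp_grid)
    shared_draw_groups: Sequence[frozenset[str]] = DEFAULT_SHARED_GROUPS

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        grid = np.asarray(self.wtp_grid, dtype=float)
        if grid.size and (np.any(np.diff(grid) <= 0) or grid[0] < 0):
            raise ValueError("wtp_grid must be strictly increasing and non-negative")
        self.wtp_grid = grid


@dataclass(frozen=True)
class PSAResult:
    """Per-draw parameter assignments and rolled-back outcomes.

    ``draws`` has one row per iteration: sampled parameter values, per-
    strategy cost/effect, and the incremental ΔC, ΔE of the intervention
    versus the control strategy.
    """

    draws: pd.DataFrame
    strategy_names: tuple[str, ...]
    config: PSAConfig

    def __len__(self) -> int:
        return len(self.draws)

    @property
    def delta_cost(self) -> np.ndarray:
        return self.draws["delta_cost"].to_numpy()

    @property
    def delta_effect(self) -> np.ndarray:
        return self.draws["delta_effect"].to_numpy()


def _sample_parameters(params: ParameterTable, config: PSAConfig, rng) -> dict[str, np.ndarray]:
    """One vector of draws per parameter, honoring shared draw groups.

    Draw order is fixed: parameters in table order, a full iteration vector
    each; a shared group is drawn once, at its first member's position, from
    that member's fitted distribution.
    """
    group_of: dict[str, frozenset[str]] = {}
    for group in config.shared_draw_groups:
        for name in group:
            if name in group_of:
                raise ValueError(f"parameter {name!r} appears in two shared draw groups")
            group_of[name] = group

    n = config.iterations
    values: dict[str, np.ndarray] = {}
    group_draws: dict[frozenset[str], np.ndarray] = {}
    for spec in params:
        group = group_of.get(spec.name)
        if group is not None and group in group_draws:
            values[spec.name] = group_draws[group]
            continue
        if spec.is_fixed:
            draw = np.full(n, spec.base)
        else:
            draw = spec.distribution_params().sample(rng, size=n)
        values[spec.name] = draw
        if group is not None:
            group_draws[group] = draw
    return values


def run_psa(tree: DecisionTree, params: ParameterTable, config: PSAConfig) -> PSAResult:
    """Sample all parameters and roll each joint draw back through the tree.

    Reproducible: the same seed gives a bit-identical draw table.  Fixed
    parameters contribute their base value in every draw.  Distribution
    fitting happens before any sampling, so an infeasible parameter (e.g. a
    beta SD exceeding its variance bound) fails fast.
    """
    for spec in params:
        if not spec.is_fixed:
            spec.distribution_params()  # validate before sampling
    rng = np.random.default_rng(config.seed)
    values = _sample_parameters(params, config, rng)
    outcomes = rollback(tree, values)

    table: dict[str, np.ndarray] = dict(values)
    for name, (cost, effect) in outcomes.items():
        table[f"cost_{name}"] = np.broadcast_to(cost, (config.iterations,)).copy()
        table[f"effect_{name}"] = np.broadcast_to(effect, (config.iterations,)).copy()
    names = tuple(name for name, _ in tree.strategies)
    ref, comp = names[1], names[0]  # control is the reference strategy
    table["delta_cost"] = table[f"cost_{comp}"] - table[f"cost_{ref}"]
    table["delta_effect"] = table[f"effect_{comp}"] - table[f"effect_{ref}"]
    draws = pd.DataFrame(table)
    draws.index.name = "iteration"
    return PSAResult(draws=draws, strategy_names=names, config=config)


def ceac(result: PSAResult, wtp_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves over a WTP grid.

    At each λ the intervention's probability is the fraction of draws in
    which it has strictly the higher net monetary benefit; exact NMB ties
    are split equally.  Columns: ``wtp, p_intervention, p_control``;
    probabilities sum to one at every grid point.
    """
    grid = np.asarray(result.config.wtp_grid if wtp_grid is None else wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("WTP grid is empty")
    if len(result) == 0:
        raise ValueError("no PSA draws")
    d_nmb = grid[:, None] * result.delta_effect[None, :] - result.delta_cost[None, :]
    p_int = (d_nmb > 0).mean(axis=1) + 0.5 * (d_nmb == 0).mean(axis=1)
    return pd.DataFrame(
        {"wtp": grid, "p_intervention": p_int, "p_control": 1.0 - p_int}
    )


@dataclass(frozen=True)
class CrossoverResult:
    """WTP at which the strategies swap rank on the acceptability curves.

    ``grid_wtp`` is the smallest grid λ at which the intervention's
    probability of highest net monetary benefit is at least the control's;
    ``interpolated_wtp`` linearly interpolates the 0.5 crossing between the
    bracketing grid points.  Both are ``None`` when no crossing lies on the
    grid (``in_range`` False).
    """

    grid_wtp: float | None
    interpolated_wtp: float | None

    @property
    def in_range(self) -> bool:
        return self.grid_wtp is not None


def crossover_wtp(ceac_points: pd.DataFrame) -> CrossoverResult:
    """Detect the CEAC rank-order swap on a computed grid."""
    p = ceac_points["p_intervention"].to_numpy()
    wtp = ceac_points["wtp"].to_numpy()
    above = p >= 0.5
    if not above.any() or above[0]:
        return CrossoverResult(
            grid_wtp=float(wtp[0]) if above.any() else None,
            interpolated_wtp=float(wtp[0]) if above.any() else None,
        )
    i = int(np.argmax(above))
    p0, p1 = p[i - 1], p[i]
    if p1 == p0:  # degenerate: flat at 0.5
        interp = float(wtp[i])
    else:
        interp = float(wtp[i - 1] + (0.5 - p0) / (p1 - p0) * (wtp[i] - wtp[i - 1]))
    return CrossoverResult(grid_wtp=float(wtp[i]), interpolated_wtp=interp)


def psa_summary(result: PSAResult) -> dict:
    """Distributional summary of the incremental cloud and per-draw ICERs.

    Ratio statistics use only draws with ΔE ≠ 0; their excluded complement
    is counted, never silently dropped.  Percentiles are 2.5/50/97.5.
    """
    if len(result) == 0:
        raise ValueError("no PSA draws")
    dc, de = result.delta_cost, result.delta_effect
    nonzero = de != 0
    icers = dc[nonzero] / de[nonzero]

    def stats(x: np.ndarray) -> dict:
        return {
            "mean": float(np.mean(x)),
            "p2.5": float(np.percentile(x, 2.5)),
            "median": float(np.median(x)),
            "p97.5": float(np.percentile(x, 97.5)),
            "min": float(np.min(x)),
            "max": float(np.max(x)),
        }

    out = {
        "n_draws": int(len(result)),
        "n_zero_delta_effect": int((~nonzero).sum()),
        "delta_cost": stats(dc),
        "delta_effect": stats(de),
    }
    out["icer"] = stats(icers) if icers.size else None
    return out
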