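"""Probabilistic decision tree for the two-strategy diagnostic comparison.

Each strategy (pulse oximetry + IMCI versus IMCI alone) is a chance tree
over a child presenting with suspected pneumonia: the child is diagnosed
severe with the arm's diagnosed-severe proportion, and the diagnosis is then
true or false according to the arm's sensitivity (after a severe diagnosis)
or specificity (after a non-severe diagnosis).  Terminal payoffs carry the
arm's average cost for the diagnosis class and an effect indicator for a
detected severe case.  Pathways are mutually exclusive; rolling back the
tree gives expected cost and expected effect per child, and the incremental
comparison gives the ICER in USD per extra diagnosed severe case.

Branch probability expressions are restricted to a parameter or its
complement (``p`` / ``1 - p``), which lets chance-node normalization be
checked exactly, for any valid parameter assignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

import numpy as np

__all__ = [
    "ProbExpr",
    "TerminalPayoff",
    "Node",
    "DecisionTree",
    "IncrementalResult",
    "build_model",
    "rollback",
    "incremental",
    "EFFECT_DEFINITIONS",
]

EFFECT_DEFINITIONS = ("true_positive", "any_severe_diagnosis")


@dataclass(frozen=True)
class ProbExpr:
    """Branch probability: a named parameter or its complement ``1 - p``."""

    param: str
    complement: bool = False

    def evaluate(self, assignment: Mapping[str, float | np.ndarray]):
        try:
            p = assignment[self.param]
        except KeyError:
            raise KeyError(f"missing parameter {self.param!r} in assignment") from None
        return 1.0 - p if self.complement else p

    def __str__(self) -> str:
        return f"1 - {self.param}" if self.complement else self.param


@dataclass(frozen=True)
class TerminalPayoff:
    """Leaf payoff: a cost parameter reference and a 0/1 effect indicator."""

    cost_param: str
    effect: int

    def __post_init__(self) -> None:
        if self.effect not in (0, 1):
            raise ValueError(f"effect indicator must be 0 or 1, got {self.effect}")


@dataclass(frozen=True)
class Node:
    """Chance or terminal node.

    Chance nodes carry ``branches`` — (probability expression, child) pairs
    whose expressions must be structurally complementary so probabilities sum
    to one for every valid assignment.  Terminal nodes carry a payoff.
    """

    kind: Literal["chance", "terminal"]
    label: str
    branches: tuple[tuple[ProbExpr, "Node"], ...] = ()
    payoff: TerminalPayoff | None = None

    def __post_init__(self) -> None:
        if self.kind == "terminal":
            if self.payoff is None or self.branches:
                raise ValueError(f"{self.label}: terminal nodes carry a payoff, no branches")
        elif self.kind == "chance":
            if self.payoff is not None or not self.branches:
                raise ValueError(f"{self.label}: chance nodes carry branches, no payoff")
            exprs = [e for e, _ in self.branches]
            if (
                len(exprs) != 2
                or exprs[0].param != exprs[1].param
                or exprs[0].complement == exprs[1].complement
            ):
                raise ValueError(
                    f"{self.label}: chance-node branches must be a complementary "
                    f"pair (p, 1 - p) over one parameter"
                )
        else:
            raise ValueError(f"unknown node kind {self.kind!r}")

    def leaves(self) -> list[tuple[tuple[ProbExpr, ...], TerminalPayoff]]:
        """All root-to-leaf paths as (probability-expression sequence, payoff)."""
        if self.kind == "terminal":
            assert self.payoff is not None
            return [((), self.payoff)]
        out = []
        for expr, child in self.branches:
            for path, payoff in child.leaves():
                out.append(((expr, *path), payoff))
        return out

    def parameters(self) -> set[str]:
        if self.kind == "terminal":
            assert self.payoff is not None
            return {self.payoff.cost_param}
        names: set[str] = set()
        for expr, child in self.branches:
            names.add(expr.param)
            names |= child.parameters()
        return names


@dataclass(frozen=True)
class DecisionTree:
    """Strategy-labelled chance trees sharing one parameter namespace."""

    strategies: tuple[tuple[str, Node], ...]
    effect_definition: str = "true_positive"

    @property
    def strategy_names(self) -> list[str]:
        return [name for name, _ in self.strategies]

    def root(self, strategy: str) -> Node:
        for name, node in self.strategies:
            if name == strategy:
                return node
        raise KeyError(f"unknown strategy {strategy!r}")

    def parameters(self) -> set[str]:
        names: set[str] = set()
        for _, node in self.strategies:
            names |= node.parameters()
        return names

    # -- JSON serialization --------------------------------------------------

    def to_dict(self) -> dict:
        def node_dict(node: Node) -> dict:
            if node.kind == "terminal":
                return {
                    "kind": "terminal",
                    "label": node.label,
                    "payoff": {"cost": node.payoff.cost_param, "effect": node.payoff.effect},
                }
            return {
                "kind": "chance",
                "label": node.label,
                "branches": [
                    {"probability": str(expr), "param": expr.param,
                     "complement": expr.complement, "child": node_dict(child)}
                    for expr, child in node.branches
                ],
            }

        return {
            "effect_definition": self.effect_definition,
            "strategies": {name: node_dict(node) for name, node in self.strategies},
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "DecisionTree":
        def parse(d: Mapping) -> Node:
            if d["kind"] == "terminal":
                return Node(
                    "terminal",
                    d["label"],
                    payoff=TerminalPayoff(d["payoff"]["cost"], int(d["payoff"]["effect"])),
                )
            return Node(
                "chance",
                d["label"],
                branches=tuple(
                    (ProbExpr(b["param"], bool(b["complement"])), parse(b["child"]))
                    for b in d["branches"]
                ),
            )

        return cls(
            strategies=tuple((name, parse(nd)) for name, nd in doc["strategies"].items()),
            effect_definition=doc.get("effect_definition", "true_positive"),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "DecisionTree":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _arm_tree(arm: str, effect_definition: str) -> Node:
    """Four-terminal chance tree for one diagnostic strategy."""
    p, sens, spec = f"p_severe_{arm}", f"sens_{arm}", f"spec_{arm}"
    c_sev, c_non = f"cost_severe_{arm}", f"cost_nonsevere_{arm}"
    fp_effect = 1 if effect_definition == "any_severe_diagnosis" else 0
    severe_dx = Node(
        "chance",
        f"{arm}: diagnosed severe",
        branches=(
            (ProbExpr(sens), Node("terminal", f"{arm}: true positive",
                                  payoff=TerminalPayoff(c_sev, 1))),
            (ProbExpr(sens, complement=True),
             Node("terminal", f"{arm}: false positive",
                  payoff=TerminalPayoff(c_sev, fp_effect))),
        ),
    )
    nonsevere_dx = Node(
        "chance",
        f"{arm}: diagnosed non-severe",
        branches=(
            (ProbExpr(spec), Node("terminal", f"{arm}: true negative",
                                  payoff=TerminalPayoff(c_non, 0))),
            (ProbExpr(spec, complement=True),
             Node("terminal", f"{arm}: false negative",
                  payoff=TerminalPayoff(c_non, 0))),
        ),
    )
    return Node(
        "chance",
        f"{arm}: diagnosis",
        branches=((ProbExpr(p), severe_dx), (ProbExpr(p, complement=True), nonsevere_dx)),
    )


def build_model(params, effect_definition: str = "true_positive") -> DecisionTree:
    """Build the canonical two-strategy diagnosis tree from a parameter table.

    Per strategy: a chance node splits diagnosed severe (arm's
    diagnosed-severe proportion) from diagnosed non-severe; a severe
    diagnosis is a true positive with the arm's sensitivity, a non-severe
    diagnosis a true negative with the arm's specificity.  Severe-diagnosis
    leaves pay the arm's severe-case average cost, non-severe leaves the
    non-severe average.  The effect indicator is 1 on true positives only
    (default), or on every severe diagnosis when ``effect_definition`` is
    ``"any_severe_diagnosis"``.

    Raises
    ------
    KeyError
        Naming the first referenced parameter absent from ``params``.
    """
    if effect_definition not in EFFECT_DEFINITIONS:
        raise ValueError(
            f"effect_definition must be one of {EFFECT_DEFINITIONS}, "
            f"got {effect_definition!r}"
        )
    tree = DecisionTree(
        strategies=(
            ("intervention", _arm_tree("intervention", effect_definition)),
            ("control", _arm_tree("control", effect_definition)),
        ),
        effect_definition=effect_definition,
    )
    available = set(params.names) if hasattr(params, "names") else set(params)
    for name in sorted(tree.parameters()):
        if name not in available:
            raise KeyError(f"model references parameter {name!r} absent from the table")
    return tree


def _expect(node: Node, assignment: Mapping[str, float | np.ndarray]):
    """Recursive expectation (cost, effect) of a subtree under an assignment."""
    if node.kind == "terminal":
        payoff = node.payoff
        cost = assignment[payoff.cost_param]
        if np.any(np.asarray(cost) < 0):
            raise ValueError(f"{node.label}: cost payoff evaluates negative")
        return cost, float(payoff.effect)
    cost = effect = 0.0
    for expr, child in node.branches:
        p = expr.evaluate(assignment)
        arr = np.asarray(p)
        if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
            raise ValueError(
                f"{node.label}: branch probability {expr} evaluates outside [0, 1]"
            )
        c, e = _expect(child, assignment)
        cost = cost + p * c
        effect = effect + p * e
    return cost, effect


def rollback(
    tree: DecisionTree, assignment: Mapping[str, float | np.ndarray]
) -> dict[str, tuple[float, float]]:
    """Expected (cost, effect) per strategy under a parameter assignment.

    Values may be scalars or equally-shaped arrays (one entry per Monte
    Carlo draw); the expectation is computed element-wise.
    """
    return {name: _expect(node, assignment) for name, node in tree.strategies}


@dataclass(frozen=True)
class IncrementalResult:
    """Incremental comparison of a strategy against a reference.

    ``status`` is ``"icer"`` when the ratio is meaningful, ``"dominant"``
    (comparator cheaper and more effective), ``"dominated"`` (costlier and
    less effective), or ``"equal_effect"`` (no effect difference, so no
    ratio).  ``icer`` is USD per extra diagnosed severe case, ``None``
    whenever the ratio is not meaningful.
    """

    delta_cost: float
    delta_effect: float
    icer: float | None
    status: Literal["icer", "dominant", "dominated", "equal_effect"]

    def describe(self) -> str:
        if self.status == "icer":
            return f"{self.icer:.2f} USD per extra diagnosed severe case"
        return self.status


def incremental(
    ref: tuple[float, float], comp: tuple[float, float]
) -> IncrementalResult:
    """Incremental cost, effect, and ICER of ``comp`` versus ``ref``.

    Both arguments are (expected cost, expected effect) pairs from the same
    rollback; the comparator is the strategy under evaluation.
    """
    delta_cost = comp[0] - ref[0]
    delta_effect = comp[1] - ref[1]
    if delta_effect == 0:
        return IncrementalResult(delta_cost, delta_effect, None, "equal_effect")
    if delta_cost < 0 and delta_effect > 0:
        return IncrementalResult(delta_cost, delta_effect, None, "dominant")
    if delta_cost > 0 and delta_effect < 0:
        return IncrementalResult(delta_cost, delta_effect, None, "dominated")
    return IncrementalResult(delta_cost, delta_effect, delta_cost / delta_effect, "icer")
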