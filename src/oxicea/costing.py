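"""Micro-costing engine for the two-arm pneumonia diagnosis trial.

Totals itemized provider and patient costs per arm and diagnosis class,
annuitizes capital equipment (the pulse oximeter), and computes average cost
per diagnosed case.  All arithmetic is carried at full precision; display
rounding (2-decimal USD, integer percent shares) happens only in reporting.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "UnitCost",
    "CapitalItem",
    "CostLedger",
    "annuitize",
    "average_cost",
    "itemize",
    "patient_level_totals",
    "load_unit_costs",
    "default_unit_costs",
    "etb_to_usd",
    "personnel_cost_per_consultation",
    "ETB_PER_USD",
    "QUANTITY_ITEMS",
]

#: Official average 2018 exchange rate used to express all costs in USD.
ETB_PER_USD = 27.4220

#: Mapping from per-child quantity fields to unit-cost item names.
QUANTITY_ITEMS = {
    "km": "transport",
    "hospital_days": "hospital_stay",
    "oxygen_m3": "oxygen",
    "drug_doses": "drugs",
    "iv_fluids": "iv_fluids",
    "iv_cannulae": "iv_cannula",
    "consultations": "consultation",
}

#: Items a child can only accrue after a severe-pneumonia diagnosis
#: (oxygen therapy and hospital admission follow referral).
SEVERE_ONLY_QUANTITIES = ("hospital_days", "oxygen_m3", "iv_fluids", "iv_cannulae")


def etb_to_usd(amount_etb: float) -> float:
    """Convert Ethiopian Birr to 2018 USD at the fixed study exchange rate."""
    return amount_etb / ETB_PER_USD


@dataclass(frozen=True)
class UnitCost:
    """Per-unit 2018 USD cost of one resource item.

    ``arm`` distinguishes items whose unit cost differs between trial arms
    (personnel time, training); ``"shared"`` items cost the same in both.
    """

    item: str
    perspective: str  # provider | patient
    category: str  # capital | recurrent | patient_expense
    unit: str  # per_device | per_child | per_km | per_day | per_m3 | per_session
    usd: float
    arm: str = "shared"

    def __post_init__(self) -> None:
        if self.usd < 0:
            raise ValueError(f"{self.item}: unit cost must be >= 0, got {self.usd}")
        if self.category == "capital" and self.perspective != "provider":
            raise ValueError(f"{self.item}: capital items carry the provider perspective")


@dataclass(frozen=True)
class CapitalItem:
    """A capital purchase to be annuitized over its useful life.

    Defaults reflect the study's costing of the pulse oximeter: a two-year
    product life, a 7% annual interest rate, and an 8-month cost-accrual
    horizon.
    """

    price: float
    lifetime_years: int = 2
    annual_rate: float = 0.07
    quantity: int = 1
    horizon_months: float = 8.0

    def __post_init__(self) -> None:
        if self.lifetime_years < 1:
            raise ValueError("lifetime_years must be >= 1")
        if not 0 <= self.annual_rate < 1:
            raise ValueError("annual_rate must lie in [0, 1)")
        if self.quantity < 0:
            raise ValueError("quantity must be >= 0")
        if self.price < 0:
            raise ValueError("price must be >= 0")


def annuitize(item: CapitalItem) -> tuple[float, float]:
    """Equivalent annual cost of a capital item, and its pro-rated horizon cost.

    The annual equivalent is ``price / AF`` with annuity factor
    ``AF = (1 - (1+r)^-n) / r`` (``AF = n`` at r = 0).  The horizon cost
    pro-rates the annual equivalent over ``horizon_months`` and multiplies by
    ``quantity``.

    Returns
    -------
    (annual, horizon_total)
        Annual equivalent USD per unit, and total USD accrued over the
        horizon for all units.
    """
    n, r = item.lifetime_years, item.annual_rate
    if r == 0:
        factor = float(n)
    else:
        # -expm1(-n log1p(r)) / r == (1 - (1+r)^-n) / r, stable as r -> 0
        factor = -math.expm1(-n * math.log1p(r)) / r
    annual = item.price / factor
    horizon_total = annual * item.quantity * item.horizon_months / 12.0
    return annual, horizon_total


def average_cost(total: float, n_cases: int) -> float:
    """Average cost per diagnosed case: exact quotient ``total / n_cases``.

    Raises
    ------
    ZeroDivisionError
        If ``n_cases`` is zero — an average over no cases is undefined and is
        never silently reported as zero.
    """
    if n_cases == 0:
        raise ZeroDivisionError("average cost undefined: no diagnosed cases")
    if n_cases < 0:
        raise ValueError(f"n_cases must be >= 0, got {n_cases}")
    return total / n_cases


@dataclass
class CostLedger:
    """Itemized cost totals for one arm and diagnosis class."""

    arm: str
    diagnosis_class: str  # severe | non_severe
    entries: dict[str, float] = field(default_factory=dict)
    n_cases: int = 0

    def __post_init__(self) -> None:
        for item, v in self.entries.items():
            if v < 0:
                raise ValueError(f"ledger entry {item!r} must be >= 0, got {v}")
        if self.n_cases < 0:
            raise ValueError("n_cases must be >= 0")

    def add(self, item: str, usd: float) -> None:
        if usd < 0:
            raise ValueError(f"cannot add negative cost for {item!r}")
        self.entries[item] = self.entries.get(item, 0.0) + usd

    @property
    def total(self) -> float:
        return sum(self.entries.values())

    def average(self) -> float:
        return average_cost(self.total, self.n_cases)


def itemize(ledger: CostLedger) -> pd.DataFrame:
    """Item totals with integer-percent shares of the ledger grand total.

    Returns a frame with columns ``item, total_usd, share_pct`` plus a final
    ``total`` row.  Shares are rounded to integer percent, so they sum to
    100 +/- rounding slack; totals are conserved exactly.
    """
    if not ledger.entries:
        raise ValueError(
            f"empty ledger ({ledger.arm}/{ledger.diagnosis_class}): nothing to itemize"
        )
    grand = ledger.total
    rows = [
        {
            "item": item,
            "total_usd": usd,
            "share_pct": round(100 * usd / grand) if grand > 0 else 0,
        }
        for item, usd in ledger.entries.items()
    ]
    rows.append({"item": "total", "total_usd": grand, "share_pct": 100})
    return pd.DataFrame(rows, columns=["item", "total_usd", "share_pct"])


class UnitCostTable:
    """Unit costs indexed by ``(item, arm)`` with shared-arm fallback."""

    def __init__(self, costs: Iterable[UnitCost]):
        self._costs = list(costs)
        self._index: dict[tuple[str, str], UnitCost] = {}
        for c in self._costs:
            key = (c.item, c.arm)
            if key in self._index:
                raise ValueError(f"duplicate unit cost for {key}")
            self._index[key] = c

    def __iter__(self):
        return iter(self._costs)

    def __len__(self) -> int:
        return len(self._costs)

    def lookup(self, item: str, arm: str) -> UnitCost:
        for key in ((item, arm), (item, "shared")):
            if key in self._index:
                return self._index[key]
        raise KeyError(f"no unit cost for item {item!r} in arm {arm!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [vars(c) for c in self._costs],
            columns=["item", "perspective", "category", "unit", "usd", "arm"],
        )


def load_unit_costs(path: str | Path) -> UnitCostTable:
    """Load a unit-cost table (CSV: ``item,perspective,category,unit,usd,arm``)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"unit-cost table not found: {path}")
    df = pd.read_csv(path)
    required = ["item", "perspective", "category", "unit", "usd"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if "arm" not in df.columns:
        df = df.assign(arm="shared")
    return UnitCostTable(
        UnitCost(
            item=str(r["item"]),
            perspective=str(r["perspective"]),
            category=str(r["category"]),
            unit=str(r["unit"]),
            usd=float(r["usd"]),
            arm=str(r["arm"]),
        )
        for _, r in df.iterrows()
    )


def default_unit_costs() -> UnitCostTable:
    """The packaged unit-cost table of the diagnosis study (2018 USD)."""
    ref = importlib.resources.files("oxicea").joinpath("data/unit_costs.csv")
    with importlib.resources.as_file(ref) as p:
        return load_unit_costs(p)


def personnel_cost_per_consultation(
    annual_salary: float,
    annual_duty_fee: float,
    time_fraction: float,
    consultations_per_year: float,
) -> float:
    """Allocate a share of health-worker pay to one diagnostic consultation.

    ``time_fraction`` is the fraction of total working time spent on
    childhood-pneumonia diagnosis; the allocated pay is spread over the
    worker's annual consultation volume.
    """
    if not 0 <= time_fraction <= 1:
        raise ValueError("time_fraction must lie in [0, 1]")
    if consultations_per_year <= 0:
        raise ValueError("consultations_per_year must be > 0")
    return (annual_salary + annual_duty_fee) * time_fraction / consultations_per_year


def patient_level_totals(
    records: pd.DataFrame,
    unit_costs: UnitCostTable,
    fixed_costs: Mapping[str, Mapping[str, float]] | None = None,
) -> dict[tuple[str, str], CostLedger]:
    """Accumulate per-item cost totals from patient-level quantity records.

    Each record row carries non-negative quantities (km travelled, hospital
    days, oxygen m3, drug doses, IV fluids, IV cannulae, consultations); each
    is multiplied by its unit cost and accumulated into the ledger for the
    child's ``(arm, diagnosis)`` cell.  Consultations additionally accrue the
    arm-specific provider personnel cost.  ``fixed_costs`` maps arm ->
    {item -> USD} for costs incurred once per arm (training, capital
    equipment, batteries); following the study's itemization these are
    charged to the arm's severe ledger.

    Raises
    ------
    KeyError
        Naming the item, when a quantity column or fixed-cost item has no
        unit cost and is not itself a fixed total.
    """
    ledgers: dict[tuple[str, str], CostLedger] = {}
    for arm in ("intervention", "control"):
        for cls in ("severe", "non_severe"):
            ledgers[(arm, cls)] = CostLedger(arm=arm, diagnosis_class=cls)

    if len(records):
        quantity_cols = [c for c in records.columns if c in QUANTITY_ITEMS]
        unknown = set(records.columns) - set(QUANTITY_ITEMS) - {
            "cluster_id",
            "arm",
            "child_id",
            "diagnosis",
        }
        if unknown:
            raise KeyError(f"unknown item column(s) in records: {sorted(unknown)}")
        if (records[quantity_cols] < 0).any().any():
            raise ValueError("record quantities must be non-negative")
        grouped = records.groupby(["arm", "diagnosis"], sort=False)
        for (arm, cls), grp in grouped:
            ledger = ledgers[(arm, cls)]
            ledger.n_cases += len(grp)
            for col in quantity_cols:
                item = QUANTITY_ITEMS[col]
                qty = float(grp[col].sum())
                if qty == 0:
                    continue
                ledger.add(item, qty * unit_costs.lookup(item, arm).usd)
            n_consult = float(grp["consultations"].sum()) if "consultations" in grp else 0.0
            if n_consult:
                ledger.add("personnel", n_consult * unit_costs.lookup("personnel", arm).usd)

    if fixed_costs:
        for arm, items in fixed_costs.items():
            ledger = ledgers[(arm, "severe")]
            for item, usd in items.items():
                ledger.add(item, float(usd))

    return ledgers
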