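"""Synthetic patient-level data for the two-arm diagnostic trial.

Emulates the structure the costing analysis consumes: a cluster-randomized
trial across 24 health centres (12 per arm), each enrolling children with
suspected pneumonia; each child is diagnosed severe with an arm-specific
probability and accrues itemized resource quantities (consultations, drug
doses, IV fluids and cannulae, hospital days, oxygen volume, kilometres
travelled) whose means are calibrated so that expected per-case itemized
costs match the study's printed cost tables.  Arm-level fixed provider
costs (pulse oximeter capital, batteries, training, and personnel time not
tied to a costed consultation) are carried separately and charged to the
arm's severe ledger, mirroring the study's itemization.

The generator preserves the only structure the downstream analysis uses —
diagnosis-class labels and mean itemized costs per arm — and does not model
within-cluster cost correlation by default (an optional lognormal cluster
effect is available for robustness experiments).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .costing import (
    CostLedger,
    UnitCostTable,
    average_cost,
    default_unit_costs,
    patient_level_totals,
)

__all__ = [
    "SynthConfig",
    "default_config",
    "generate",
    "recover_parameters",
    "estimates_to_parameter_table",
    "TrialEstimates",
    "TABLE_SEVERE_ITEMIZED",
    "TRIAL_COUNTS",
]

#: Printed itemized severe-pneumonia cost totals per arm (2018 USD), the
#: calibration targets for the generator's expected ledgers.
TABLE_SEVERE_ITEMIZED: dict[str, dict[str, float]] = {
    "intervention": {
        "pulse_oximeter": 191.0,
        "batteries": 1.0,
        "training": 27.0,
        "personnel": 135.0,
        "oxygen": 743.0,
        "consultation": 59.0,
        "drugs_supplies": 1221.0,
        "transport": 559.0,
        "hospital_stay": 873.0,
    },
    "control": {
        "training": 3.0,
        "personnel": 15.0,
        "oxygen": 171.0,
        "consultation": 14.0,
        "drugs_supplies": 181.0,
        "transport": 139.0,
        "hospital_stay": 89.0,
    },
}

#: Trial enrolment and diagnosed-severe counts per arm.
TRIAL_COUNTS = {
    "intervention": {"enrolled": 928, "severe": 148},
    "control": {"enrolled": 876, "severe": 34},
}

#: Class-average cost per diagnosed non-severe case (total / n diagnosed).
NONSEVERE_AVERAGE = {
    "intervention": 2794.45 / 780,
    "control": 1800.17 / 842,
}

QUANTITY_COLUMNS = (
    "consultations",
    "drug_doses",
    "iv_fluids",
    "iv_cannulae",
    "hospital_days",
    "oxygen_m3",
    "km",
)

#: Items only accrued after a severe diagnosis (hospital referral pathway).
SEVERE_ONLY = ("iv_fluids", "iv_cannulae", "hospital_days", "oxygen_m3")

#: Assumed mean counts of IV fluids / cannulae per severe case and of drug
#: doses per non-severe case; the itemized tables print only the pooled
#: drugs-and-supplies line, so the split within it is an assumption.
IV_MEAN_SEVERE = 2.0
DRUG_DOSES_NONSEVERE = {"intervention": 1.5, "control": 1.0}


def _severe_quantity_means(arm: str, unit_costs: UnitCostTable) -> dict[str, float]:
    """Item-quantity means per severe case implied by the itemized totals."""
    items = TABLE_SEVERE_ITEMIZED[arm]
    n = TRIAL_COUNTS[arm]["severe"]
    u = lambda item: unit_costs.lookup(item, arm).usd
    drugs_usd = items["drugs_supplies"] / n - IV_MEAN_SEVERE * (u("iv_fluids") + u("iv_cannula"))
    return {
        "consultations": items["consultation"] / n / u("consultation"),
        "oxygen_m3": items["oxygen"] / n / u("oxygen"),
        "km": items["transport"] / n / u("transport"),
        "hospital_days": items["hospital_stay"] / n / u("hospital_stay"),
        "iv_fluids": IV_MEAN_SEVERE,
        "iv_cannulae": IV_MEAN_SEVERE,
        "drug_doses": drugs_usd / u("drugs"),
    }


def _nonsevere_quantity_means(arm: str, unit_costs: UnitCostTable) -> dict[str, float]:
    """Item means per non-severe case consistent with the class average cost.

    One consultation per child (fee plus arm personnel cost), an assumed
    mean drug-dose count, and the kilometre mean absorbing the remainder.
    """
    u = lambda item: unit_costs.lookup(item, arm).usd
    consult = 1.0
    drugs = DRUG_DOSES_NONSEVERE[arm]
    remainder = (
        NONSEVERE_AVERAGE[arm]
        - consult * (u("consultation") + u("personnel"))
        - drugs * u("drugs")
    )
    if remainder < 0:
        raise ValueError(f"{arm}: non-severe item means over-allocate the class average")
    means = {q: 0.0 for q in SEVERE_ONLY}
    means.update(consultations=consult, drug_doses=drugs, km=remainder / u("transport"))
    return means


def _fixed_costs(unit_costs: UnitCostTable) -> dict[str, dict[str, float]]:
    """Arm-level fixed provider costs charged once to the severe ledger.

    Personnel cost beyond the per-consultation allocation (supervision and
    time not tied to a costed visit) is carried here so that expected
    ledgers reproduce the printed itemization.
    """
    out: dict[str, dict[str, float]] = {}
    for arm, items in TABLE_SEVERE_ITEMIZED.items():
        sev = _severe_quantity_means(arm, unit_costs)
        n_sev = TRIAL_COUNTS[arm]["severe"]
        per_consult = unit_costs.lookup("personnel", arm).usd
        variable_personnel_severe = n_sev * sev["consultations"] * per_consult
        fixed = {
            k: v
            for k, v in items.items()
            if k in ("pulse_oximeter", "batteries", "training")
        }
        fixed["personnel"] = max(0.0, items["personnel"] - variable_personnel_severe)
        out[arm] = fixed
    return out


@dataclass
class SynthConfig:
    """Generator settings; defaults reproduce the trial's study conditions.

    ``cluster_size_mean`` is per arm (enrolment / 12 clusters);
    ``cluster_size_dispersion`` is the negative-binomial dispersion (larger
    = closer to Poisson).  ``quantities`` maps (arm, class) to item-quantity
    means; ``dispersion`` selects stochastic draws (Poisson counts, gamma
    continuous quantities) or point masses at the means.
    ``cluster_sigma`` switches on a multiplicative lognormal cluster effect
    on quantity means (0 = off, the default: the analysis consumes arm
    aggregates only).
    """

    seed: int = 0
    n_clusters: int = 24
    cluster_size_mean: Mapping[str, float] = field(
        default_factory=lambda: {
            arm: TRIAL_COUNTS[arm]["enrolled"] / 12 for arm in TRIAL_COUNTS
        }
    )
    cluster_size_dispersion: float = 8.0
    p_severe: Mapping[str, float] = field(
        default_factory=lambda: {
            arm: TRIAL_COUNTS[arm]["severe"] / TRIAL_COUNTS[arm]["enrolled"]
            for arm in TRIAL_COUNTS
        }
    )
    quantities: Mapping[tuple[str, str], Mapping[str, float]] | None = None
    fixed_costs: Mapping[str, Mapping[str, float]] | None = None
    dispersion: Literal["stochastic", "point"] = "stochastic"
    gamma_cv: float = 0.5  # coefficient of variation of continuous quantities
    cluster_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.n_clusters < 2 or self.n_clusters % 2:
            raise ValueError("n_clusters must be an even count >= 2 (balanced arms)")
        for arm, p in self.p_severe.items():
            if not 0 <= p <= 1:
                raise ValueError(f"p_severe[{arm!r}] must lie in [0, 1]")
        for arm, m in self.cluster_size_mean.items():
            if not (math.isfinite(m) and m > 0):
                raise ValueError(f"cluster_size_mean[{arm!r}] must be positive")
        if self.cluster_size_dispersion <= 0 or self.gamma_cv <= 0:
            raise ValueError("dispersion parameters must be positive")
        if self.cluster_sigma < 0:
            raise ValueError("cluster_sigma must be >= 0")
        if self.quantities is not None:
            for key, means in self.quantities.items():
                for item, m in means.items():
                    if not (math.isfinite(m) and m >= 0):
                        raise ValueError(f"quantity mean {key}/{item} must be >= 0")


def default_config(seed: int = 0, unit_costs: UnitCostTable | None = None, **overrides) -> SynthConfig:
    """Study-condition defaults with calibrated item-quantity means."""
    uc = unit_costs or default_unit_costs()
    quantities = {}
    for arm in ("intervention", "control"):
        quantities[(arm, "severe")] = _severe_quantity_means(arm, uc)
        quantities[(arm, "non_severe")] = _nonsevere_quantity_means(arm, uc)
    return SynthConfig(
        seed=seed, quantities=quantities, fixed_costs=_fixed_costs(uc), **overrides
    )


def _draw_quantities(
    rng: np.random.Generator, means: Mapping[str, float], n: int, mode: str, cv: float
) -> dict[str, np.ndarray]:
    """Quantities for ``n`` children of one (arm, class, cluster) cell.

    Counts (consultations, doses, IV items, hospital days) are Poisson;
    consultations are shifted (1 + Poisson) so every diagnosed child has at
    least one visit.  Continuous quantities (km, oxygen volume) are gamma
    with the stated mean and coefficient of variation — non-negative and
    right-skewed, as travel distances and oxygen use are.
    """
    out: dict[str, np.ndarray] = {}
    for col in QUANTITY_COLUMNS:
        mu = float(means.get(col, 0.0))
        if mode == "point" or mu == 0.0:
            out[col] = np.full(n, mu)
        elif col == "consultations":
            out[col] = 1.0 + rng.poisson(max(mu - 1.0, 0.0), size=n)
        elif col in ("km", "oxygen_m3"):
            shape = 1.0 / cv**2
            out[col] = rng.gamma(shape, mu / shape, size=n)
        else:
            out[col] = rng.poisson(mu, size=n).astype(float)
    return out


def generate(config: SynthConfig) -> pd.DataFrame:
    """Generate one synthetic trial as a patient-level record table.

    One row per child: ``cluster_id, arm, child_id, diagnosis`` plus the
    itemized quantity columns.  Reproducible under ``config.seed``; arm
    allocation is exactly balanced (clusters alternate arms); severe-only
    quantities are zero for non-severe children by construction.
    """
    cfg = config if config.quantities is not None else default_config(seed=config.seed)
    rng = np.random.default_rng(cfg.seed)
    k = cfg.cluster_size_dispersion
    frames = []
    child_counter = 0
    for cluster_id in range(cfg.n_clusters):
        arm = "intervention" if cluster_id % 2 == 0 else "control"
        m = cfg.cluster_size_mean[arm]
        if cfg.dispersion == "point":
            size = max(1, round(m))
        else:
            size = max(1, int(rng.negative_binomial(k, k / (k + m))))
        severe = rng.random(size) < cfg.p_severe[arm]
        cluster_scale = (
            rng.lognormal(-0.5 * cfg.cluster_sigma**2, cfg.cluster_sigma)
            if cfg.cluster_sigma > 0
            else 1.0
        )
        for cls, mask in (("severe", severe), ("non_severe", ~severe)):
            n = int(mask.sum())
            if n == 0:
                continue
            means = {
                item: mu * cluster_scale for item, mu in cfg.quantities[(arm, cls)].items()
            }
            qty = _draw_quantities(rng, means, n, cfg.dispersion, cfg.gamma_cv)
            frames.append(
                pd.DataFrame(
                    {
                        "cluster_id": cluster_id,
                        "arm": arm,
                        "child_id": child_counter + np.flatnonzero(mask),
                        "diagnosis": cls,
                        **qty,
                    }
                )
            )
        child_counter += size
    records = pd.concat(frames, ignore_index=True).sort_values("child_id", kind="stable")
    return records.reset_index(drop=True)


@dataclass(frozen=True)
class TrialEstimates:
    """Arm-level estimates recovered from patient-level records.

    ``p_severe`` and its binomial SE per arm; per (arm, class) the ledger
    average cost per diagnosed case (including any arm fixed costs charged
    to the severe class), the variable-only average, and its empirical SE.
    Cells with no diagnosed case are flagged in ``empty_cells`` and excluded.
    """

    p_severe: dict[str, float]
    p_severe_se: dict[str, float]
    n_enrolled: dict[str, int]
    average_cost: dict[tuple[str, str], float]
    variable_average: dict[tuple[str, str], float]
    cost_se: dict[tuple[str, str], float]
    empty_cells: list[tuple[str, str]]
    ledgers: dict[tuple[str, str], CostLedger]


def recover_parameters(
    records: pd.DataFrame,
    unit_costs: UnitCostTable | None = None,
    fixed_costs: Mapping[str, Mapping[str, float]] | None = None,
) -> TrialEstimates:
    """Apply the trial's estimators to a record table.

    Diagnosed-severe proportion per arm = severe / enrolled (binomial SE);
    average cost per diagnosed case via the costing ledgers, with
    ``fixed_costs`` charged once per arm to the severe class.  The
    variable-only per-child cost gives the empirical standard error.
    """
    uc = unit_costs or default_unit_costs()
    ledgers = patient_level_totals(records, uc, fixed_costs=fixed_costs)

    p_severe, p_se, n_enrolled = {}, {}, {}
    for arm, grp in records.groupby("arm"):
        n = len(grp)
        p = float((grp["diagnosis"] == "severe").mean())
        p_severe[arm] = p
        p_se[arm] = math.sqrt(p * (1 - p) / n) if n else float("nan")
        n_enrolled[arm] = n

    per_child = records.copy()
    per_child["variable_cost"] = 0.0
    for col, item in (
        ("km", "transport"),
        ("hospital_days", "hospital_stay"),
        ("oxygen_m3", "oxygen"),
        ("drug_doses", "drugs"),
        ("iv_fluids", "iv_fluids"),
        ("iv_cannulae", "iv_cannula"),
        ("consultations", "consultation"),
    ):
        if col in per_child.columns:
            rates = per_child["arm"].map(lambda a, item=item: uc.lookup(item, a).usd)
            per_child["variable_cost"] += per_child[col] * rates
    personnel = per_child["arm"].map(lambda a: uc.lookup("personnel", a).usd)
    if "consultations" in per_child.columns:
        per_child["variable_cost"] += per_child["consultations"] * personnel

    avg, var_avg, se, empty = {}, {}, {}, []
    for key, ledger in ledgers.items():
        if ledger.n_cases == 0:
            empty.append(key)
            continue
        avg[key] = ledger.average()
        cell = per_child[
            (per_child["arm"] == key[0])
            & (per_child["diagnosis"] == ("severe" if key[1] == "severe" else "non_severe"))
        ]["variable_cost"]
        var_avg[key] = float(cell.mean())
        se[key] = float(cell.std(ddof=1) / math.sqrt(len(cell))) if len(cell) > 1 else 0.0

    return TrialEstimates(
        p_severe=p_severe,
        p_severe_se=p_se,
        n_enrolled=n_enrolled,
        average_cost=avg,
        variable_average=var_avg,
        cost_se=se,
        empty_cells=empty,
        ledgers=ledgers,
    )


def estimates_to_parameter_table(est: TrialEstimates, fallback=None) -> "ParameterTable":
    """Build a model parameter table from recovered trial estimates.

    Cost and diagnosed-severe-proportion rows are re-estimated from the
    records (base = estimate, sd = standard error, min/max = normal-
    approximation 95% bounds truncated to the parameter's support);
    sensitivity and specificity are not estimable from the trial (no
    reference-standard diagnosis) and are taken from ``fallback`` — by
    default the packaged literature-based table.
    """
    from .parameters import ParameterSpec, ParameterTable, default_parameters

    fallback = fallback or default_parameters()
    class_key = {"severe": "severe", "non_severe": "nonsevere"}
    specs = []
    for (arm, cls), mean in est.average_cost.items():
        se = max(est.cost_se[(arm, cls)], 1e-6)
        specs.append(
            ParameterSpec(
                name=f"cost_{class_key[cls]}_{arm}",
                role="cost",
                arm=arm,
                base=mean,
                min=max(0.0, mean - 1.96 * se),
                max=mean + 1.96 * se,
                sd=se,
                distribution="gamma",
                source="synthetic trial estimate",
            )
        )
    for arm, p in est.p_severe.items():
        se = max(est.p_severe_se[arm], 1e-6)
        specs.append(
            ParameterSpec(
                name=f"p_severe_{arm}",
                role="probability",
                arm=arm,
                base=p,
                min=max(0.0, p - 1.96 * se),
                max=min(1.0, p + 1.96 * se),
                sd=se,
                distribution="beta",
                source="synthetic trial estimate",
            )
        )
    have = {s.name for s in specs}
    specs.extend(s for s in fallback if s.name not in have)
    return ParameterTable(specs)
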