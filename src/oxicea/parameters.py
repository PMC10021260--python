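"""Model input parameters and their uncertainty distributions.

Every input to the cost-effectiveness model — per-arm average costs of a
severe / non-severe pneumonia diagnosis, per-arm proportions diagnosed
severe, and per-arm diagnostic sensitivity and specificity — is described by
a :class:`ParameterSpec`: a base (point-estimate) value, a deterministic
sensitivity range ``[min, max]``, a standard deviation, and a distribution
family used in probabilistic sensitivity analysis.  Costs are modelled as
gamma random variables and proportions as beta random variables; both are
parameterized from ``(base, sd)`` by the method of moments.

The packaged default table (``data/parameters.csv``) holds the ten inputs of
the pulse-oximetry / IMCI severe-pneumonia diagnosis model, in 2018 USD.
"""

from __future__ import annotations

import importlib.resources
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

__all__ = [
    "ParameterSpec",
    "DistributionParams",
    "ParameterTable",
    "ParameterValidationError",
    "load_parameters",
    "default_parameters",
    "gamma_from_mean_sd",
    "beta_from_mean_sd",
]

PARAMETER_COLUMNS = ["name", "role", "arm", "base", "min", "max", "sd", "distribution", "source"]

Role = Literal["cost", "probability"]
Arm = Literal["intervention", "control", "shared"]
Family = Literal["gamma", "beta", "fixed"]


class ParameterValidationError(ValueError):
    """A parameter row violates the table schema or a model invariant."""


@dataclass(frozen=True)
class ParameterSpec:
    """One model input with its point estimate and uncertainty description.

    Parameters
    ----------
    name
        Identifier used in probability and payoff expressions.
    role
        ``"cost"`` (USD) or ``"probability"`` (proportion in [0, 1]).
    arm
        Which trial arm the parameter belongs to, or ``"shared"``.
    base, min, max
        Point estimate and deterministic-sensitivity bounds, same units.
    sd
        Standard deviation driving the PSA distribution.
    distribution
        ``"gamma"`` for costs, ``"beta"`` for probabilities, or ``"fixed"``
        for a degenerate (non-sampled) parameter.
    source
        Free-text provenance note.
    """

    name: str
    role: Role
    arm: Arm
    base: float
    min: float
    max: float
    sd: float
    distribution: Family
    source: str = ""

    def __post_init__(self) -> None:
        if self.role not in ("cost", "probability"):
            raise ParameterValidationError(f"{self.name}: unknown role {self.role!r}")
        if self.arm not in ("intervention", "control", "shared"):
            raise ParameterValidationError(f"{self.name}: unknown arm {self.arm!r}")
        if self.distribution not in ("gamma", "beta", "fixed"):
            raise ParameterValidationError(
                f"{self.name}: unknown distribution {self.distribution!r}"
            )
        for fname in ("base", "min", "max", "sd"):
            v = getattr(self, fname)
            if not math.isfinite(v):
                raise ParameterValidationError(f"{self.name}: non-finite {fname} ({v!r})")
        if not (self.min <= self.base <= self.max):
            raise ParameterValidationError(
                f"{self.name}: base {self.base} outside [min, max] = "
                f"[{self.min}, {self.max}]"
            )
        if self.sd < 0:
            raise ParameterValidationError(f"{self.name}: sd must be >= 0, got {self.sd}")
        if self.sd == 0 and self.distribution != "fixed":
            raise ParameterValidationError(
                f"{self.name}: sd = 0 requires distribution = fixed"
            )
        if self.role == "probability":
            if not (0 <= self.min and self.max <= 1):
                raise ParameterValidationError(
                    f"{self.name}: probability bounds must lie in [0, 1]"
                )
            if self.distribution not in ("beta", "fixed"):
                raise ParameterValidationError(
                    f"{self.name}: probability parameters use beta or fixed distributions"
                )
        else:  # cost
            if self.base < 0 or self.min < 0:
                raise ParameterValidationError(f"{self.name}: costs must be non-negative")
            if self.distribution not in ("gamma", "fixed"):
                raise ParameterValidationError(
                    f"{self.name}: cost parameters use gamma or fixed distributions"
                )

    @property
    def is_fixed(self) -> bool:
        return self.distribution == "fixed"

    def distribution_params(self) -> "DistributionParams | None":
        """Method-of-moments distribution for PSA; ``None`` when fixed."""
        if self.is_fixed:
            return None
        if self.distribution == "gamma":
            return gamma_from_mean_sd(self.base, self.sd)
        return beta_from_mean_sd(self.base, self.sd)


@dataclass(frozen=True)
class DistributionParams:
    """Fitted sampling distribution: gamma(shape, scale) or beta(alpha, beta).

    ``shape_a``/``shape_b`` are the gamma shape and scale, or the beta alpha
    and beta.  The implied mean and SD reproduce the fitting inputs.
    """

    family: Literal["gamma", "beta"]
    shape_a: float
    shape_b: float

    def __post_init__(self) -> None:
        if self.shape_a <= 0 or self.shape_b <= 0:
            raise ValueError(
                f"{self.family} parameters must be positive, got "
                f"({self.shape_a}, {self.shape_b})"
            )

    @property
    def mean(self) -> float:
        if self.family == "gamma":
            return self.shape_a * self.shape_b
        return self.shape_a / (self.shape_a + self.shape_b)

    @property
    def sd(self) -> float:
        if self.family == "gamma":
            return math.sqrt(self.shape_a) * self.shape_b
        a, b = self.shape_a, self.shape_b
        return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))

    def sample(self, rng, size=None):
        """Draw from the fitted distribution with a numpy Generator."""
        if self.family == "gamma":
            return rng.gamma(self.shape_a, self.shape_b, size=size)
        return rng.beta(self.shape_a, self.shape_b, size=size)


def gamma_from_mean_sd(mean: float, sd: float) -> DistributionParams:
    """Fit a gamma distribution to a mean and SD by the method of moments.

    shape = (mean/sd)^2 and scale = sd^2/mean, so that shape*scale = mean and
    sqrt(shape)*scale = sd exactly.

    Raises
    ------
    ValueError
        If ``mean`` or ``sd`` is not strictly positive.
    """
    if mean <= 0 or sd <= 0:
        raise ValueError(f"gamma fit requires mean > 0 and sd > 0, got ({mean}, {sd})")
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return DistributionParams("gamma", shape, scale)


def beta_from_mean_sd(mean: float, sd: float) -> DistributionParams:
    """Fit a beta distribution to a mean and SD by the method of moments.

    With nu = mean(1-mean)/sd^2 - 1, alpha = mean*nu and beta = (1-mean)*nu.
    Requires 0 < mean < 1 and 0 < sd^2 < mean(1-mean); otherwise no beta
    distribution has those moments.
    """
    if not 0 < mean < 1:
        raise ValueError(f"beta fit requires 0 < mean < 1, got {mean}")
    if sd <= 0:
        raise ValueError(f"beta fit requires sd > 0, got {sd}")
    var = sd**2
    bound = mean * (1 - mean)
    if var >= bound:
        raise ValueError(
            f"no beta distribution has mean {mean} and sd {sd}: "
            f"variance {var:.6g} >= mean(1-mean) = {bound:.6g}"
        )
    nu = bound / var - 1
    return DistributionParams("beta", mean * nu, (1 - mean) * nu)


class ParameterTable:
    """Ordered, name-indexed collection of :class:`ParameterSpec`."""

    def __init__(self, specs: Iterable[ParameterSpec]):
        self._specs: list[ParameterSpec] = list(specs)
        self._by_name: dict[str, ParameterSpec] = {}
        for s in self._specs:
            if s.name in self._by_name:
                raise ParameterValidationError(f"duplicate parameter name {s.name!r}")
            self._by_name[s.name] = s

    def __iter__(self):
        return iter(self._specs)

    def __len__(self) -> int:
        return len(self._specs)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> ParameterSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown parameter {name!r}") from None

    @property
    def names(self) -> list[str]:
        return [s.name for s in self._specs]

    def base_values(self) -> dict[str, float]:
        """Point-estimate assignment usable by the decision-tree rollback."""
        return {s.name: s.base for s in self._specs}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) | {} for s in self._specs], columns=PARAMETER_COLUMNS)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _specs_from_frame(df: pd.DataFrame, origin: str) -> ParameterTable:
    missing = [c for c in PARAMETER_COLUMNS if c not in df.columns and c != "source"]
    if missing:
        raise ParameterValidationError(f"{origin}: missing column(s) {missing}")
    if "source" not in df.columns:
        df = df.assign(source="")
    specs = []
    for idx, row in df.iterrows():
        try:
            numeric = {c: float(row[c]) for c in ("base", "min", "max", "sd")}
        except (TypeError, ValueError) as exc:
            raise ParameterValidationError(
                f"{origin}, row {idx} ({row.get('name', '?')}): non-numeric value ({exc})"
            ) from None
        try:
            specs.append(
                ParameterSpec(
                    name=str(row["name"]),
                    role=str(row["role"]),
                    arm=str(row["arm"]),
                    distribution=str(row["distribution"]),
                    source=str(row["source"]),
                    **numeric,
                )
            )
        except ParameterValidationError as exc:
            raise ParameterValidationError(f"{origin}, row {idx}: {exc}") from None
    return ParameterTable(specs)


def load_parameters(path: str | Path) -> ParameterTable:
    """Load and validate a parameter table from CSV or JSON.

    The CSV header is ``name,role,arm,base,min,max,sd,distribution,source``;
    the JSON form is a list of objects with the same keys.

    Raises
    ------
    ParameterValidationError
        Naming the offending row and rule on any schema or invariant failure.
    FileNotFoundError
        If the file does not exist.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"parameter table not found: {path}")
    if path.suffix.lower() == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path)
    return _specs_from_frame(df, str(path))


def default_parameters() -> ParameterTable:
    """The packaged ten-parameter input table of the diagnosis model."""
    ref = importlib.resources.files("oxicea").joinpath("data/parameters.csv")
    with importlib.resources.as_file(ref) as p:
        return load_parameters(p)
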