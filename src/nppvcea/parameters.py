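"""Model inputs: uncertainty distributions, estimation helpers and the
default parameter set.

Every model input (state costs in ¥ per patient per year, state utilities on
the 0-1 EQ-5D scale, annual transition probabilities) is carried as a
:class:`DistributionSpec`: a base value, a standard error, the shape
parameters of its sampling distribution (gamma for costs, beta for
probabilities and utilities, fitted by the method of moments) and the bounds
used by one-way sensitivity analysis.

The module also houses the two deterministic mappings the model relies on:

* a published linear mapping from the COPD Assessment Test (CAT, 0-40) and
  age to EQ-5D-3L utility,
      utility = 1.26848 - 0.02159 * CAT - 0.00188 * age
* the standard conversion between an event rate and the probability of at
  least one event over a period, tp_t = 1 - exp(-r * t).

A default parameter file transcribing the trial-derived inputs of the home
noninvasive-ventilation evaluation ships with the package
(``data/default_parameters.json``) and is returned by
:func:`load_default_parameters`.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Literal

import numpy as np

from .errors import ConfigurationError, InfeasibleMomentsError, ModelError
from .states import (
    ALIVE_STATES,
    ARM_BOTH,
    ARMS,
    STATE_INDEX,
    STATE_ORDER,
    HealthState,
)

__all__ = [
    "DistributionSpec",
    "ParameterRecord",
    "ParameterSet",
    "ModelConfig",
    "cat_to_utility",
    "rate_to_probability",
    "probability_to_rate",
    "fit_gamma_moments",
    "fit_beta_moments",
    "annualize_device_cost",
    "load_default_parameters",
    "load_parameters",
]

# Coefficients of the published CAT -> EQ-5D-3L mapping (Taiwanese COPD
# derivation sample; intercept, CAT slope, age slope).
UTILITY_INTERCEPT = 1.26848
UTILITY_CAT_SLOPE = -0.02159
UTILITY_AGE_SLOPE = -0.00188


def cat_to_utility(cat: float, age: float) -> float:
    """Map a CAT score and age to an EQ-5D-3L utility.

    The mapping is linear and is applied unclamped; a warning (not an
    error) is emitted if the result falls outside [0, 1].

    Parameters
    ----------
    cat : CAT score, 0-40.
    age : age in years.
    """
    if not 0 <= cat <= 40:
        raise ValueError(f"CAT score must be in [0, 40], got {cat}")
    u = UTILITY_INTERCEPT + UTILITY_CAT_SLOPE * cat + UTILITY_AGE_SLOPE * age
    if not 0.0 <= u <= 1.0:
        warnings.warn(
            f"mapped utility {u:.5f} outside [0, 1] (cat={cat}, age={age})",
            stacklevel=2,
        )
    return u


def rate_to_probability(rate: float, t: float = 1.0) -> float:
    """Probability of at least one event in time ``t`` at constant ``rate``."""
    if rate < 0:
        raise ValueError(f"rate must be non-negative, got {rate}")
    if t <= 0:
        raise ValueError(f"time must be positive, got {t}")
    return -math.expm1(-rate * t)


def probability_to_rate(p: float, t: float = 1.0) -> float:
    """Constant event rate implying probability ``p`` over time ``t``."""
    if not 0 <= p < 1:
        raise ValueError(f"probability must be in [0, 1), got {p}")
    if t <= 0:
        raise ValueError(f"time must be positive, got {t}")
    return -math.log1p(-p) / t


def fit_gamma_moments(mean: float, se: float) -> tuple[float, float]:
    """Gamma (shape, scale) matching a mean and standard error exactly.

    shape = (mean/se)^2, scale = se^2/mean.
    """
    if mean <= 0 or se <= 0:
        raise ValueError(f"gamma moments require mean > 0 and se > 0, got {mean}, {se}")
    return (mean / se) ** 2, se**2 / mean


def fit_beta_moments(mean: float, se: float) -> tuple[float, float]:
    """Beta (alpha, beta) matching a mean and standard error exactly.

    alpha + beta = mean(1-mean)/se^2 - 1, alpha = mean * (alpha + beta).
    """
    if not 0 < mean < 1:
        raise ValueError(f"beta moments require 0 < mean < 1, got {mean}")
    if se <= 0 or se**2 >= mean * (1 - mean):
        raise InfeasibleMomentsError(
            f"se^2 must lie in (0, mean(1-mean)): mean={mean}, se={se}"
        )
    total = mean * (1 - mean) / se**2 - 1
    return mean * total, (1 - mean) * total


def annualize_device_cost(
    purchase_price: float, lifespan_years: float, discount_rate: float
) -> float:
    """Equivalent annual cost of a device by the annuity method.

    price * r / (1 - (1+r)^-L); at r = 0 this degrades to straight-line
    price / L.
    """
    if purchase_price < 0:
        raise ValueError(f"purchase price must be >= 0, got {purchase_price}")
    if lifespan_years < 1:
        raise ValueError(f"device lifespan must be >= 1 year, got {lifespan_years}")
    if not 0 <= discount_rate <= 1:
        raise ValueError(f"discount rate must be in [0, 1], got {discount_rate}")
    if discount_rate == 0:
        return purchase_price / lifespan_years
    return (
        purchase_price
        * discount_rate
        / (1 - (1 + discount_rate) ** (-lifespan_years))
    )


DistKind = Literal["gamma", "beta", "fixed", "residual"]


@dataclass(frozen=True)
class DistributionSpec:
    """A parameter's base value, uncertainty and sampling distribution.

    ``kind`` is ``gamma`` (costs), ``beta`` (probabilities/utilities),
    ``fixed`` (no sampling) or ``residual`` (a transition-matrix diagonal,
    recomputed as 1 minus the row's off-diagonal entries and never sampled).
    ``low``/``high`` are the deterministic sensitivity-analysis bounds.
    For gamma, ``beta_param`` is the scale.
    """

    kind: DistKind
    base: float
    se: float | None = None
    alpha: float | None = None
    beta_param: float | None = None
    low: float | None = None
    high: float | None = None

    def __post_init__(self) -> None:
        if self.kind in ("gamma", "beta") and (self.alpha is None or self.beta_param is None):
            if self.se is None:
                raise ConfigurationError(
                    f"{self.kind} spec needs either shapes or an se (base={self.base})"
                )
            fit = fit_gamma_moments if self.kind == "gamma" else fit_beta_moments
            a, b = fit(self.base, self.se)
            object.__setattr__(self, "alpha", a)
            object.__setattr__(self, "beta_param", b)
        if self.low is not None and self.high is not None and not (
            self.low <= self.base <= self.high
        ):
            raise ConfigurationError(
                f"bounds must bracket base value: {self.low} <= {self.base} <= {self.high}"
            )

    @property
    def mean(self) -> float:
        """Mean implied by the stored shapes (base value for fixed kinds)."""
        if self.kind == "gamma":
            return self.alpha * self.beta_param
        if self.kind == "beta":
            return self.alpha / (self.alpha + self.beta_param)
        return self.base

    def sample(self, rng: np.random.Generator) -> float:
        """Draw one value; fixed and residual kinds return the base value."""
        if self.kind == "gamma":
            return float(rng.gamma(self.alpha, self.beta_param))
        if self.kind == "beta":
            return float(rng.beta(self.alpha, self.beta_param))
        return self.base

    def with_base(self, value: float) -> "DistributionSpec":
        """Copy with the base value replaced (shapes and bounds dropped)."""
        return DistributionSpec(kind="fixed", base=value)


@dataclass(frozen=True)
class ParameterRecord:
    """One named model input.

    ``category`` is ``cost`` (¥/patient/year, ``state`` is the state the cost
    accrues in), ``utility`` (``state`` is the state) or ``transition``
    (``name`` is ``"<from>-><to>"`` and ``state`` the from-state). ``arm`` is
    ``iot``, ``standard`` or ``both`` for inputs shared by the arms.
    """

    name: str
    category: Literal["cost", "utility", "transition"]
    arm: str
    state: HealthState
    spec: DistributionSpec

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.category, self.arm, f"{self.state.value}:{self.name}")

    @property
    def label(self) -> str:
        """Human-readable label used in sensitivity-analysis output."""
        if self.category == "cost":
            return f"{self.name} cost, {self.state.value}, {self.arm}"
        if self.category == "utility":
            return f"utility, {self.state.value}"
        return f"transition {self.name}, {self.arm}"


@dataclass
class ModelConfig:
    """Run-level settings of the cohort model.

    Defaults reproduce the published analysis: an 8-year horizon of annual
    cycles, 5% annual discounting, a willingness-to-pay threshold of
    ¥70,100/QALY (2019 Chinese per-capita GDP), annual background mortality
    0.0087, the whole cohort starting in the stable state, and a half-cycle
    correction (see docs/methods.md for the accrual convention).
    """

    horizon_cycles: int = 8
    cycle_length: float = 1.0
    discount_rate: float = 0.05
    wtp: float = 70_100.0
    natural_mortality: float = 0.0087
    initial_distribution: tuple[float, float, float, float] = (1.0, 0.0, 0.0, 0.0)
    half_cycle_correction: bool = True

    def __post_init__(self) -> None:
        if self.horizon_cycles < 1:
            raise ConfigurationError(f"horizon_cycles must be >= 1, got {self.horizon_cycles}")
        if not 0 <= self.discount_rate <= 1:
            raise ConfigurationError(f"discount_rate must be in [0, 1], got {self.discount_rate}")
        if self.cycle_length <= 0:
            raise ConfigurationError(f"cycle_length must be > 0, got {self.cycle_length}")
        if not 0 <= self.natural_mortality < 1:
            raise ConfigurationError(
                f"natural_mortality must be in [0, 1), got {self.natural_mortality}"
            )
        init = np.asarray(self.initial_distribution, dtype=float)
        if init.shape != (4,) or np.any(init < 0) or abs(init.sum() - 1) > 1e-9:
            raise ConfigurationError(
                f"initial_distribution must be a length-4 simplex, got {self.initial_distribution}"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        if "initial_distribution" in d:
            d = dict(d, initial_distribution=tuple(d["initial_distribution"]))
        return cls(**d)

    def to_dict(self) -> dict:
        return {
            "horizon_cycles": self.horizon_cycles,
            "cycle_length": self.cycle_length,
            "discount_rate": self.discount_rate,
            "wtp": self.wtp,
            "natural_mortality": self.natural_mortality,
            "initial_distribution": list(self.initial_distribution),
            "half_cycle_correction": self.half_cycle_correction,
        }


class ParameterSet:
    """The full collection of model inputs for both strategies."""

    def __init__(self, records: Iterable[ParameterRecord]):
        self.records: list[ParameterRecord] = list(records)
        keys = [r.key for r in self.records]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ConfigurationError(f"duplicate parameter records: {dupes}")

    # -- accessors ---------------------------------------------------------

    def cost_records(self, arm: str) -> list[ParameterRecord]:
        return [
            r
            for r in self.records
            if r.category == "cost" and r.arm in (arm, ARM_BOTH)
        ]

    def state_cost(self, arm: str, state: HealthState) -> float:
        """Total annual cost of occupying ``state`` under ``arm`` (base case)."""
        return sum(r.spec.base for r in self.cost_records(arm) if r.state == state)

    def utility_record(self, state: HealthState) -> ParameterRecord:
        for r in self.records:
            if r.category == "utility" and r.state == state:
                return r
        raise KeyError(f"no utility record for state {state}")

    def utilities(self) -> np.ndarray:
        u = np.zeros(4)
        for s in ALIVE_STATES:
            u[STATE_INDEX[s]] = self.utility_record(s).spec.base
        return u

    def transition_record(self, arm: str, frm: HealthState, to: HealthState) -> ParameterRecord:
        name = f"{frm.value}->{to.value}"
        for r in self.records:
            if r.category == "transition" and r.name == name and r.arm in (arm, ARM_BOTH):
                return r
        raise KeyError(f"no transition record {name} for arm {arm}")

    def transition_matrix(self, arm: str, base_overrides: dict | None = None) -> np.ndarray:
        """Assemble the 4x4 annual transition matrix for ``arm``.

        Diagonals are the residual 1 minus the row's off-diagonal entries;
        the death row is absorbing. ``base_overrides`` maps
        ``(from, to) -> value`` and is used by sampling / sensitivity code.
        """
        overrides = base_overrides or {}
        m = np.zeros((4, 4))
        m[3, 3] = 1.0
        for frm in ALIVE_STATES:
            i = STATE_INDEX[frm]
            off = 0.0
            for to in STATE_ORDER:
                if to == frm:
                    continue
                rec = self.transition_record(arm, frm, to)
                val = overrides.get((frm, to), rec.spec.base)
                m[i, STATE_INDEX[to]] = val
                off += val
            resid = 1.0 - off
            if resid < -1e-9:
                raise ModelError(
                    f"negative residual diagonal for {arm}/{frm.value}: {resid:.3g}"
                )
            m[i, i] = max(resid, 0.0)
        return m

    def replaced(self, record: ParameterRecord, new_base: float) -> "ParameterSet":
        """New ParameterSet with one record's base value replaced."""
        out = []
        for r in self.records:
            if r is record:
                out.append(replace(r, spec=r.spec.with_base(new_base)))
            else:
                out.append(r)
        return ParameterSet(out)

    # -- serialization -----------------------------------------------------

    def to_records_json(self) -> list[dict]:
        out = []
        for r in self.records:
            s = r.spec
            out.append(
                {
                    "name": r.name,
                    "category": r.category,
                    "arm": r.arm,
                    "state": r.state.value,
                    "kind": s.kind,
                    "base": s.base,
                    "se": s.se,
                    "alpha": s.alpha,
                    "beta": s.beta_param,
                    "low": s.low,
                    "high": s.high,
                }
            )
        return out

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"parameters": self.to_records_json()}, fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_records_json(cls, records: list[dict]) -> "ParameterSet":
        out = []
        for d in records:
            try:
                spec = DistributionSpec(
                    kind=d["kind"],
                    base=d["base"],
                    se=d.get("se"),
                    alpha=d.get("alpha"),
                    beta_param=d.get("beta"),
                    low=d.get("low"),
                    high=d.get("high"),
                )
                out.append(
                    ParameterRecord(
                        name=d["name"],
                        category=d["category"],
                        arm=d["arm"],
                        state=HealthState(d["state"]),
                        spec=spec,
                    )
                )
            except KeyError as exc:
                raise ConfigurationError(f"parameter record missing field {exc}") from exc
        return cls(out)

    @classmethod
    def from_json(cls, path) -> "ParameterSet":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        if "parameters" not in doc:
            raise ConfigurationError("parameter file missing top-level 'parameters' list")
        return cls.from_records_json(doc["parameters"])

    # -- integrity ---------------------------------------------------------

    def validate(self) -> None:
        """Check structural invariants (row sums, bounds, value ranges)."""
        for r in self.records:
            s = r.spec
            if r.category == "cost" and s.base < 0:
                raise ConfigurationError(f"negative cost base for {r.label}")
            if r.category == "utility" and not 0 <= s.base <= 1:
                raise ConfigurationError(f"utility base outside [0,1] for {r.label}")
        for arm in ARMS:
            m = self.transition_matrix(arm)
            if not np.allclose(m.sum(axis=1), 1.0, atol=1e-4):
                raise ModelError(f"transition rows for {arm} do not sum to 1")


def load_parameters(path=None) -> ParameterSet:
    """Load a parameter file, or the shipped default when ``path`` is None."""
    if path is None:
        return load_default_parameters()
    return ParameterSet.from_json(path)


def load_default_parameters() -> ParameterSet:
    """The default parameter set (trial-derived costs, utilities, transitions)."""
    ref = resources.files("nppvcea").joinpath("data/default_parameters.json")
    with resources.as_file(ref) as path:
        return ParameterSet.from_json(path)
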