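"""Cohort Markov engine: propagate state occupancy and accrue discounted
costs and QALYs for one management strategy.

The cohort starts from ``config.initial_distribution`` and is propagated
through the arm's annual transition matrix for ``horizon_cycles`` cycles,
giving occupancy vectors at trace points t = 0..H. Accrual follows one of
two conventions:

* ``half_cycle_correction=True`` (default): trapezoidal weights over the
  trace points — 1/2 at t = 0 and t = H, 1 in between — with each point
  discounted at (1 + r)^(-t). This is the convention that reproduces the
  published base-case totals exactly.
* ``half_cycle_correction=False``: full weight on trace points t = 0..H-1
  (state occupied during cycle t accrues that cycle's cost/utility),
  discounted at (1 + r)^(-t); cycle 0 is undiscounted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ModelError
from .parameters import ModelConfig, ParameterSet
from .states import ARMS, STATE_INDEX, STATE_ORDER, HealthState

__all__ = ["ArmModel", "CohortTrace", "run_cohort", "discount_factor", "build_arm_models"]


def discount_factor(t: float, rate: float) -> float:
    """(1 + rate)^(-t); equals 1 at t = 0 for every rate."""
    if t < 0:
        raise ValueError(f"cycle index must be >= 0, got {t}")
    return (1.0 + rate) ** (-t)


def _validate_matrix(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.shape != (4, 4):
        raise ModelError(f"transition matrix must be 4x4, got shape {m.shape}")
    if np.any(m < -1e-12) or np.any(m > 1 + 1e-12):
        raise ModelError("transition probabilities must lie in [0, 1]")
    sums = m.sum(axis=1)
    bad = np.where(np.abs(sums - 1) > 1e-9)[0]
    if bad.size:
        rows = ", ".join(f"{STATE_ORDER[i].value} (sum={sums[i]:.6g})" for i in bad)
        raise ModelError(f"transition matrix rows do not sum to 1: {rows}")
    if not np.allclose(m[3], [0, 0, 0, 1], atol=1e-12):
        raise ModelError("death row must be absorbing (0, 0, 0, 1)")
    return np.clip(m, 0.0, 1.0)


@dataclass
class ArmModel:
    """One strategy's transition matrix, per-state annual costs and utilities."""

    arm: str
    matrix: np.ndarray  # 4x4, row-stochastic, death absorbing
    state_costs: np.ndarray  # ¥ per patient per year, death = 0
    state_utilities: np.ndarray  # 0-1 scale, death = 0

    def __post_init__(self) -> None:
        self.matrix = _validate_matrix(self.matrix)
        self.state_costs = np.asarray(self.state_costs, dtype=float)
        self.state_utilities = np.asarray(self.state_utilities, dtype=float)
        if self.state_costs.shape != (4,) or self.state_utilities.shape != (4,):
            raise ModelError("state_costs and state_utilities must have length 4")
        didx = STATE_INDEX[HealthState.DEATH]
        if self.state_costs[didx] != 0 or self.state_utilities[didx] != 0:
            raise ModelError("death state must carry zero cost and zero utility")
        if np.any(self.state_costs < 0):
            raise ModelError("alive-state costs must be non-negative")


@dataclass
class CohortTrace:
    """State occupancy and cost/QALY accrual per cycle, with totals.

    ``occupancy`` has shape (horizon+1, 4): trace points t = 0..H.
    Accrual arrays have length horizon+1; entries are already weighted by
    the accrual convention, so totals are plain sums.
    """

    arm: str
    occupancy: np.ndarray
    cost_undiscounted: np.ndarray
    cost_discounted: np.ndarray
    qaly_undiscounted: np.ndarray
    qaly_discounted: np.ndarray

    @property
    def total_cost(self) -> float:
        return float(self.cost_discounted.sum())

    @property
    def total_qalys(self) -> float:
        return float(self.qaly_discounted.sum())

    @property
    def total_cost_undiscounted(self) -> float:
        return float(self.cost_undiscounted.sum())

    @property
    def total_qalys_undiscounted(self) -> float:
        return float(self.qaly_undiscounted.sum())

    def to_frame(self) -> pd.DataFrame:
        """One row per trace point, plus a totals row."""
        n = self.occupancy.shape[0]
        df = pd.DataFrame(
            {
                "cycle": np.arange(n),
                **{
                    f"occ_{s.value}": self.occupancy[:, i]
                    for i, s in enumerate(STATE_ORDER)
                },
                "cost_undiscounted": self.cost_undiscounted,
                "cost_discounted": self.cost_discounted,
                "qaly_undiscounted": self.qaly_undiscounted,
                "qaly_discounted": self.qaly_discounted,
            }
        )
        totals = {c: np.nan for c in df.columns}
        totals.update(
            cycle=-1,
            cost_undiscounted=self.total_cost_undiscounted,
            cost_discounted=self.total_cost,
            qaly_undiscounted=self.total_qalys_undiscounted,
            qaly_discounted=self.total_qalys,
        )
        return pd.concat([df, pd.DataFrame([totals])], ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_cohort(model: ArmModel, config: ModelConfig) -> CohortTrace:
    """Run the cohort simulation for one arm and accrue discounted totals."""
    horizon = config.horizon_cycles
    occ = np.empty((horizon + 1, 4))
    occ[0] = np.asarray(config.initial_distribution, dtype=float)
    for t in range(horizon):
        occ[t + 1] = occ[t] @ model.matrix

    weights = np.ones(horizon + 1)
    if config.half_cycle_correction:
        weights[0] = weights[-1] = 0.5
    else:
        weights[-1] = 0.0
    disc = (1.0 + config.discount_rate) ** (-np.arange(horizon + 1, dtype=float))

    cost_per_point = occ @ model.state_costs * config.cycle_length
    qaly_per_point = occ @ model.state_utilities * config.cycle_length
    return CohortTrace(
        arm=model.arm,
        occupancy=occ,
        cost_undiscounted=weights * cost_per_point,
        cost_discounted=weights * disc * cost_per_point,
        qaly_undiscounted=weights * qaly_per_point,
        qaly_discounted=weights * disc * qaly_per_point,
    )


def build_arm_models(
    params: ParameterSet,
    cost_overrides: dict | None = None,
    utility_overrides: dict | None = None,
    transition_overrides: dict | None = None,
) -> dict[str, ArmModel]:
    """Assemble both arms' :class:`ArmModel` from a parameter set.

    The override mappings allow sampling and sensitivity code to substitute
    values without rebuilding the parameter set: ``cost_overrides`` maps a
    cost record's ``key`` to a value, ``utility_overrides`` maps a state to
    a utility, and ``transition_overrides`` maps ``(arm, from, to)`` to a
    probability (``arm`` may be ``"both"`` for shared rows).
    """
    cost_overrides = cost_overrides or {}
    utility_overrides = utility_overrides or {}
    transition_overrides = transition_overrides or {}

    utilities = np.zeros(4)
    for s in STATE_ORDER[:3]:
        utilities[STATE_INDEX[s]] = utility_overrides.get(
            s, params.utility_record(s).spec.base
        )

    models = {}
    for arm in ARMS:
        costs = np.zeros(4)
        for rec in params.cost_records(arm):
            costs[STATE_INDEX[rec.state]] += cost_overrides.get(rec.key, rec.spec.base)
        trans = {
            (frm, to): v
            for (a, frm, to), v in transition_overrides.items()
            if a in (arm, "both")
        }
        matrix = params.transition_matrix(arm, base_overrides=trans)
        models[arm] = ArmModel(
            arm=arm, matrix=matrix, state_costs=costs, state_utilities=utilities
        )
    return models
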