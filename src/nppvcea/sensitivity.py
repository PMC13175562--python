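"""Deterministic and probabilistic sensitivity analysis.

One-way sensitivity analysis (OWSA) re-runs the base-case comparison twice
per parameter — at its stored lower and upper bound, everything else held at
base — and ranks parameters by the spread of the resulting ICERs for a
tornado chart. Transition probabilities are excluded (they are correlated
through the residual diagonals); the discount rate is varied 0-8% and the
IoT service items jointly by ±10%.

Probabilistic sensitivity analysis (PSA) redraws every gamma/beta parameter
from its method-of-moments distribution per Monte-Carlo iteration, rebuilds
both arms, and summarises the cost-effectiveness plane: the probability of
a positive incremental net monetary benefit at the willingness-to-pay
threshold, the probability of dominance, and the cost-effectiveness
acceptability curve (CEAC) over a WTP grid. Transition rows stay coherent
by sampling off-diagonals and taking the diagonal as the residual,
rejecting draws with a negative residual; the serious-state row is shared
by the arms and drawn once per iteration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cea import ArmTotals, compare
from .errors import ConfigurationError, EstimationError
from .markov import build_arm_models, run_cohort
from .parameters import ModelConfig, ParameterRecord, ParameterSet
from .states import ALIVE_STATES, ARM_IOT, ARMS, HealthState, STATE_ORDER

__all__ = [
    "OWSAEntry",
    "run_owsa",
    "PSAResult",
    "run_psa",
    "compute_ceac",
    "plot_tornado",
    "plot_psa_scatter",
    "plot_ceac",
]

log = logging.getLogger(__name__)

#: Names of the fixed IoT service-cost items varied jointly in OWSA.
IOT_SERVICE_ITEMS = ("equipment_maintenance", "telephone_contact", "home_visits")


def _icer_ratio(params: ParameterSet, config: ModelConfig) -> float:
    """Raw ΔC/ΔE ratio of IoT vs standard (signed; used for tornado spans)."""
    models = build_arm_models(params)
    traces = {arm: run_cohort(models[arm], config) for arm in ARMS}
    d_cost = traces["iot"].total_cost - traces["standard"].total_cost
    d_eff = traces["iot"].total_qalys - traces["standard"].total_qalys
    return d_cost / d_eff


@dataclass(frozen=True)
class OWSAEntry:
    """Tornado-chart row: ICER at a parameter's lower and upper bound."""

    name: str
    low: float
    high: float
    icer_low: float
    icer_high: float

    @property
    def range(self) -> float:
        return abs(self.icer_high - self.icer_low)


def run_owsa(
    params: ParameterSet,
    config: ModelConfig,
    discount_rate_bounds: tuple[float, float] = (0.0, 0.08),
    mortality_relative_bounds: tuple[float, float] = (0.9, 1.1),
    iot_items_relative_bounds: tuple[float, float] = (0.9, 1.1),
) -> list[OWSAEntry]:
    """One-way sensitivity analysis, sorted by descending ICER range.

    Each cost and utility parameter is set to its stored lower/upper bound in
    turn; the discount rate is varied over ``discount_rate_bounds``, the
    background mortality and the three IoT service items over relative
    bounds (±10% by default, the IoT items jointly as a single entry).
    """
    entries: list[OWSAEntry] = []

    def icer_with(new_params: ParameterSet, new_config: ModelConfig) -> float:
        return _icer_ratio(new_params, new_config)

    for rec in params.records:
        if rec.category == "transition":
            continue  # correlated through residual diagonals; excluded
        if rec.category == "utility" and rec.spec.kind == "fixed":
            continue  # death utility anchored at 0
        if rec.category == "cost" and rec.name in IOT_SERVICE_ITEMS:
            continue  # handled jointly below
        spec = rec.spec
        if spec.low is None or spec.high is None:
            raise ConfigurationError(f"parameter '{rec.label}' has no OWSA bounds")
        entries.append(
            OWSAEntry(
                name=rec.label,
                low=spec.low,
                high=spec.high,
                icer_low=icer_with(params.replaced(rec, spec.low), config),
                icer_high=icer_with(params.replaced(rec, spec.high), config),
            )
        )

    # IoT service items, varied jointly (a single "cost of IoT" entry).
    iot_total = sum(
        r.spec.base
        for r in params.records
        if r.category == "cost" and r.name in IOT_SERVICE_ITEMS
    )
    if iot_total > 0:
        icers = []
        for factor in iot_items_relative_bounds:
            scaled = params
            for rec in list(scaled.records):
                if rec.category == "cost" and rec.name in IOT_SERVICE_ITEMS:
                    scaled = scaled.replaced(rec, rec.spec.base * factor)
            icers.append(icer_with(scaled, config))
        entries.append(
            OWSAEntry(
                name="IoT service items (joint)",
                low=iot_total * iot_items_relative_bounds[0],
                high=iot_total * iot_items_relative_bounds[1],
                icer_low=icers[0],
                icer_high=icers[1],
            )
        )

    # Discount rate.
    lo, hi = discount_rate_bounds
    entries.append(
        OWSAEntry(
            name="discount rate",
            low=lo,
            high=hi,
            icer_low=icer_with(params, replace(config, discount_rate=lo)),
            icer_high=icer_with(params, replace(config, discount_rate=hi)),
        )
    )

    # Background mortality (the fixed stable/nonserious -> death entries).
    mort_recs = [
        r
        for r in params.records
        if r.category == "transition"
        and r.name.endswith("->death")
        and r.spec.kind == "fixed"
    ]
    if mort_recs:
        base_m = mort_recs[0].spec.base
        icers = []
        for factor in mortality_relative_bounds:
            scaled = params
            for rec in list(scaled.records):
                if rec in mort_recs or (
                    rec.category == "transition"
                    and rec.name.endswith("->death")
                    and rec.spec.kind == "fixed"
                ):
                    scaled = scaled.replaced(rec, rec.spec.base * factor)
            icers.append(icer_with(scaled, config))
        entries.append(
            OWSAEntry(
                name="natural mortality",
                low=base_m * mortality_relative_bounds[0],
                high=base_m * mortality_relative_bounds[1],
                icer_low=icers[0],
                icer_high=icers[1],
            )
        )

    entries.sort(key=lambda e: e.range, reverse=True)
    return entries


def owsa_frame(entries: list[OWSAEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.name,
                "low_input": e.low,
                "high_input": e.high,
                "icer_at_low": e.icer_low,
                "icer_at_high": e.icer_high,
                "range": e.range,
            }
            for e in entries
        ]
    )


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class PSAResult:
    """Monte-Carlo samples plus summary probabilities.

    ``samples`` has one row per iteration with per-arm totals, increments
    and incremental NMB at ``wtp``; ``draws`` (optional) holds the sampled
    parameter values, one column per sampled parameter.
    """

    samples: pd.DataFrame
    wtp: float
    n_row_rejections: int
    draws: pd.DataFrame | None = None

    @property
    def p_cost_effective(self) -> float:
        return float((self.samples["inc_nmb"] > 0).mean())

    @property
    def p_dominant(self) -> float:
        s = self.samples
        return float(((s["delta_cost"] < 0) & (s["delta_effect"] > 0)).mean())

    def summary(self) -> dict:
        return {
            "n_iterations": int(len(self.samples)),
            "wtp": self.wtp,
            "p_cost_effective": self.p_cost_effective,
            "p_dominant": self.p_dominant,
            "mean_delta_cost": float(self.samples["delta_cost"].mean()),
            "mean_delta_effect": float(self.samples["delta_effect"].mean()),
            "n_row_rejections": self.n_row_rejections,
        }


def _sampled_records(params: ParameterSet) -> list[ParameterRecord]:
    return [r for r in params.records if r.spec.kind in ("gamma", "beta")]


def _draw_transitions(
    params: ParameterSet, rng: np.random.Generator
) -> tuple[dict, dict, int]:
    """Draw coherent transition rows for both arms.

    Returns (overrides for build_arm_models, named draws, rejection count).
    Off-diagonal beta entries are sampled, fixed entries kept at base, and
    each row's diagonal must be a non-negative residual; rows sharing
    parameters across arms (the serious state) are drawn once.
    """
    rejections = 0
    # group off-diagonal records by (arm, from-state) row
    rows: dict[tuple[str, HealthState], list[ParameterRecord]] = {}
    for r in params.records:
        if r.category != "transition":
            continue
        frm = r.state
        to = HealthState(r.name.split("->")[1])
        if to == frm:
            continue  # residual diagonal, never sampled
        rows.setdefault((r.arm, frm), []).append(r)

    overrides: dict = {}
    named: dict = {}
    for (arm, frm), recs in rows.items():
        for _ in range(1000):
            vals = {}
            for r in recs:
                to = HealthState(r.name.split("->")[1])
                vals[to] = r.spec.sample(rng)
            if 1.0 - sum(vals.values()) >= 0.0:
                break
            rejections += 1
        else:  # pragma: no cover - requires pathological shapes
            raise EstimationError(
                f"could not draw a coherent transition row for {arm}/{frm.value}"
            )
        by_dest = {HealthState(r.name.split("->")[1]): r for r in recs}
        for to, v in vals.items():
            overrides[(arm, frm, to)] = v
            if by_dest[to].spec.kind == "beta":
                named[f"tp_{arm}_{frm.value}->{to.value}"] = v
    return overrides, named, rejections


def run_psa(
    params: ParameterSet,
    config: ModelConfig,
    n_iterations: int = 1000,
    seed: int | None = None,
    wtp: float | None = None,
    collect_draws: bool = False,
    fixed_cost_items: str = "exclude",
) -> PSAResult:
    """Monte-Carlo probabilistic sensitivity analysis.

    Per iteration, every gamma (cost) and beta (utility, transition)
    parameter is redrawn from its stored shapes, both arms are re-run and
    the increments recorded. Deterministic given ``seed``.

    ``fixed_cost_items`` controls cost items that carry no uncertainty
    distribution (the IoT service items). The default ``"exclude"``
    mirrors the published probabilistic model, whose sampled cost totals
    comprised only the distribution-carrying parameters; ``"base"``
    instead keeps fixed items at their base value in every iteration (so a
    fully fixed parameter set reproduces the base case exactly). Fixed
    transition entries (background mortality) are always held at base.
    """
    if n_iterations < 1:
        raise ConfigurationError(f"n_iterations must be >= 1, got {n_iterations}")
    if fixed_cost_items not in ("exclude", "base"):
        raise ConfigurationError(
            f"fixed_cost_items must be 'exclude' or 'base', got {fixed_cost_items!r}"
        )
    wtp = config.wtp if wtp is None else wtp
    rng = np.random.default_rng(seed)

    cost_recs = [r for r in params.records if r.category == "cost"]
    util_recs = {
        s: params.utility_record(s)
        for s in ALIVE_STATES
    }

    rows = []
    draw_rows: list[dict] = []
    total_rejections = 0
    for i in range(n_iterations):
        named: dict = {}
        cost_overrides = {}
        for r in cost_recs:
            if r.spec.kind == "fixed" and fixed_cost_items == "exclude":
                cost_overrides[r.key] = 0.0
                continue
            v = r.spec.sample(rng)
            cost_overrides[r.key] = v
            if r.spec.kind != "fixed":
                named[f"cost_{r.arm}_{r.state.value}_{r.name}"] = v
        utility_overrides = {}
        for s, r in util_recs.items():
            v = r.spec.sample(rng)
            utility_overrides[s] = v
            if r.spec.kind != "fixed":
                named[f"utility_{s.value}"] = v
        trans_overrides, trans_named, rej = _draw_transitions(params, rng)
        named.update(trans_named)
        total_rejections += rej

        models = build_arm_models(
            params,
            cost_overrides=cost_overrides,
            utility_overrides=utility_overrides,
            transition_overrides=trans_overrides,
        )
        traces = {arm: run_cohort(models[arm], config) for arm in ARMS}
        d_cost = traces["iot"].total_cost - traces["standard"].total_cost
        d_eff = traces["iot"].total_qalys - traces["standard"].total_qalys
        if not (np.isfinite(d_cost) and np.isfinite(d_eff)):  # pragma: no cover
            raise EstimationError(f"non-finite PSA draw at iteration {i}")
        rows.append(
            {
                "iteration": i,
                "cost_iot": traces["iot"].total_cost,
                "cost_standard": traces["standard"].total_cost,
                "qalys_iot": traces["iot"].total_qalys,
                "qalys_standard": traces["standard"].total_qalys,
                "delta_cost": d_cost,
                "delta_effect": d_eff,
                "inc_nmb": wtp * d_eff - d_cost,
            }
        )
        if collect_draws:
            draw_rows.append(named)

    if total_rejections > 0.01 * n_iterations:
        warnings.warn(
            f"{total_rejections} transition-row rejections over "
            f"{n_iterations} iterations (>1%)",
            stacklevel=2,
        )
    return PSAResult(
        samples=pd.DataFrame(rows),
        wtp=wtp,
        n_row_rejections=total_rejections,
        draws=pd.DataFrame(draw_rows) if collect_draws else None,
    )


def default_wtp_grid() -> np.ndarray:
    """WTP grid for the acceptability curve: ¥0-150,000 in ¥2,500 steps."""
    return np.arange(0.0, 150_000.0 + 1, 2_500.0)


def compute_ceac(samples: pd.DataFrame, wtp_grid=None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve from PSA samples.

    For each threshold λ on the grid, the probability that the intervention
    is cost-effective is the fraction of iterations with λ·ΔE − ΔC > 0. At
    λ = 0 this is P(ΔC < 0); as λ → ∞ it converges to P(ΔE > 0).
    """
    if len(samples) == 0:
        raise EstimationError("CEAC requires a nonempty sample set")
    grid = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    if np.any(grid < 0):
        raise ConfigurationError("WTP grid values must be >= 0")
    d_eff = samples["delta_effect"].to_numpy()
    d_cost = samples["delta_cost"].to_numpy()
    prob = [(lam * d_eff - d_cost > 0).mean() for lam in grid]
    return pd.DataFrame({"wtp": grid, "probability": prob})


# ---------------------------------------------------------------------------
# Plots (optional; matplotlib imported lazily)
# ---------------------------------------------------------------------------


def plot_tornado(entries: list[OWSAEntry], base_icer: float, path) -> None:
    """Horizontal tornado chart of OWSA ICER ranges (largest on top)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    shown = entries[: min(len(entries), 15)][::-1]
    fig, ax = plt.subplots(figsize=(8, 0.45 * len(shown) + 1.5))
    for y, e in enumerate(shown):
        lo, hi = sorted((e.icer_low, e.icer_high))
        ax.barh(y, hi - lo, left=lo, height=0.6, color="#4878a8")
    ax.axvline(base_icer, color="k", lw=1, ls="--", label="base-case ICER")
    ax.set_yticks(range(len(shown)))
    ax.set_yticklabels([e.name for e in shown], fontsize=8)
    ax.set_xlabel("ICER (¥/QALY)")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_psa_scatter(samples: pd.DataFrame, wtp: float, path) -> None:
    """Cost-effectiveness plane scatter with the WTP threshold line."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(samples["delta_effect"], samples["delta_cost"], s=6, alpha=0.4)
    xs = np.array(ax.get_xlim())
    ax.plot(xs, wtp * xs, "k:", lw=1, label=f"WTP = ¥{wtp:,.0f}/QALY")
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("incremental QALYs")
    ax.set_ylabel("incremental cost (¥)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(ceac: pd.DataFrame, wtp: float, path) -> None:
    """Acceptability curve: P(cost-effective) against the WTP threshold."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ceac["wtp"], ceac["probability"])
    ax.axvline(wtp, color="k", ls="--", lw=1, label=f"WTP = ¥{wtp:,.0f}/QALY")
    ax.set_xlabel("willingness to pay (¥/QALY)")
    ax.set_ylabel("P(IoT management cost-effective)")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
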