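"""Re-estimation of model parameters from patient-level follow-up data.

Transition probabilities: consecutive classified follow-up periods (the
first period is usable only when it is serious or death, since medication
adjustment is unobservable there) yield transition counts per arm and
from-state. Counts are converted to rates over the person-time at risk and
then to annual probabilities via tp = 1 - exp(-r). Death from the stable
and nonserious states is overridden by the background (natural) mortality
from the model config; the serious-state row is pooled across arms, as in
the source trial; diagonals are residuals.

State utilities: per-observation utilities from the CAT-and-age mapping
(age advanced to the end of the period), averaged per state pooled across
arms; the sample standard error feeds a beta fit.

State costs: per-observation itemized costs annualized by period length;
the stratum mean and standard error feed a gamma fit. Items with zero
variance become fixed-kind specs; fixed service items supplied by the
caller (e.g. the IoT management items) are passed through unchanged.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict

import numpy as np

from .errors import DataError, EstimationError
from .parameters import (
    DistributionSpec,
    ModelConfig,
    ParameterRecord,
    ParameterSet,
    cat_to_utility,
    rate_to_probability,
)
from .states import (
    ALIVE_STATES,
    ARM_BOTH,
    ARMS,
    STATE_ORDER,
    HealthState,
)
from .synthetic_trial import TrialDataset, classify_state

__all__ = [
    "estimate_transitions",
    "estimate_state_utilities",
    "estimate_state_costs",
    "estimate_parameters",
    "default_iot_service_items",
]

log = logging.getLogger(__name__)


def _bounds(mean: float, se: float) -> tuple[float, float]:
    # 95% CI bounds for one-way sensitivity analysis
    return mean - 1.96 * se, mean + 1.96 * se


def _classified_periods(ds: TrialDataset):
    """Per patient: list of (period, classified state or None)."""
    grouped = ds.grouped_observations()
    return [
        (p, [(o, classify_state(o)) for o in grouped.get(p.patient_id, [])])
        for p in ds.patients
    ]


def estimate_transitions(
    ds: TrialDataset, config: ModelConfig, strict: bool = False
) -> list[ParameterRecord]:
    """Annual transition-probability records estimated from a dataset.

    Consecutive classified period pairs are counted per arm and from-state
    (unknown-state periods are skipped); the serious-state row is pooled
    across arms and emitted with arm='both'. Within each period-length
    stratum the per-period transition fraction is converted to a rate by
    r = -ln(1 - p)/t; stratum rates are averaged weighted by person-time
    and the pooled rate converted to an annual probability, so the
    procedure inverts the generator's Markov mode exactly in expectation.
    Standard errors come from the binomial variance of each stratum
    fraction propagated through the two conversions. With ``strict`` a
    from-state with zero person-time raises; otherwise it yields a
    degenerate hold-or-die row (diagonal 1 - natural mortality) with a
    warning.
    """
    # per (arm, frm): {period_length_months: {"n": pairs, "to": {state: count}}}
    strata: dict = defaultdict(lambda: defaultdict(lambda: {"n": 0, "to": defaultdict(int)}))

    for patient, rows in _classified_periods(ds):
        for (_, s_prev), (o_next, s_next) in zip(rows, rows[1:]):
            if s_prev is None or s_next is None:
                continue
            if s_prev == HealthState.DEATH:
                raise DataError(
                    f"patient {patient.patient_id}: transition out of death"
                )
            arm = ARM_BOTH if s_prev == HealthState.SERIOUS else patient.arm
            cell = strata[(arm, s_prev)][o_next.period_length_months]
            cell["n"] += 1
            cell["to"][s_next] += 1

    def _annual_estimate(key, to) -> tuple[float, float] | None:
        """Pooled annual probability and SE for one off-diagonal, or None."""
        rates, variances, weights = [], [], []
        for months, cell in strata[key].items():
            t = months / 12.0
            n = cell["n"]
            k = cell["to"][to]
            p_hat = min(k / n, (n - 0.5) / n)  # cap to keep the rate finite
            rates.append(-np.log1p(-p_hat) / t)
            # delta method: var(r) = var(p) / (t (1-p))^2
            variances.append(p_hat * (1 - p_hat) / n / (t * (1 - p_hat)) ** 2)
            weights.append(n * t)
        w = np.asarray(weights) / sum(weights)
        r_bar = float(w @ np.asarray(rates))
        var_r = float(w**2 @ np.asarray(variances))
        p_annual = rate_to_probability(r_bar, 1.0)
        se_annual = float(np.exp(-r_bar) * np.sqrt(var_r))
        return p_annual, se_annual

    records: list[ParameterRecord] = []
    for frm in ALIVE_STATES:
        row_arms = [ARM_BOTH] if frm == HealthState.SERIOUS else list(ARMS)
        for arm in row_arms:
            key = (arm, frm)
            observed = sum(cell["n"] for cell in strata[key].values())
            if observed == 0:
                msg = f"no person-time observed for state '{frm.value}' in arm '{arm}'"
                if strict:
                    raise EstimationError(msg)
                warnings.warn(msg + "; emitting a degenerate row", stacklevel=2)
            annual: dict[HealthState, DistributionSpec] = {}
            for to in STATE_ORDER:
                if to == frm:
                    continue
                if to == HealthState.DEATH and frm != HealthState.SERIOUS:
                    # background mortality overrides the trial data
                    annual[to] = DistributionSpec(
                        "fixed", config.natural_mortality
                    )
                    continue
                total_events = sum(c["to"][to] for c in strata[key].values())
                if observed == 0 or total_events == 0:
                    # a serious row with no observed deaths still carries the
                    # background hazard rather than implying immortality
                    fallback = (
                        config.natural_mortality if to == HealthState.DEATH else 0.0
                    )
                    annual[to] = DistributionSpec("fixed", fallback)
                    continue
                p, se = _annual_estimate(key, to)
                try:
                    spec = DistributionSpec(
                        "beta", p, se=se, low=max(_bounds(p, se)[0], 0.0),
                        high=min(_bounds(p, se)[1], 1.0),
                    )
                except Exception:
                    spec = DistributionSpec("fixed", p)
                annual[to] = spec

            off = sum(s.base for s in annual.values())
            if off > 1 + 1e-9:
                raise EstimationError(
                    f"off-diagonal annual probabilities for {arm}/{frm.value} "
                    f"sum to {off:.4f} > 1"
                )
            annual[frm] = DistributionSpec("residual", max(1.0 - off, 0.0))
            for to, spec in annual.items():
                records.append(
                    ParameterRecord(
                        name=f"{frm.value}->{to.value}",
                        category="transition",
                        arm=arm,
                        state=frm,
                        spec=spec,
                    )
                )
    return records


def _age_at(obs, age_at_entry: float) -> float:
    """Age at the end of the observation's period."""
    end_months = {1: 3.0, 2: 6.0, 3: 12.0}.get(
        obs.period_index, obs.period_index * obs.period_length_months
    )
    return age_at_entry + end_months / 12.0


def estimate_state_utilities(ds: TrialDataset) -> list[ParameterRecord]:
    """Per-state utility records (pooled across arms) from CAT scores."""
    ages = {p.patient_id: p.age_at_entry for p in ds.patients}
    values: dict[HealthState, list[float]] = defaultdict(list)
    for o in ds.observations:
        s = classify_state(o)
        if s is None or s == HealthState.DEATH:
            continue
        values[s].append(cat_to_utility(o.cat_score, _age_at(o, ages[o.patient_id])))

    records = []
    for s in ALIVE_STATES:
        v = values[s]
        if len(v) < 2:
            raise EstimationError(
                f"state '{s.value}' observed {len(v)} time(s); need >= 2 for a utility"
            )
        mean = float(np.mean(v))
        se = float(np.std(v, ddof=1) / np.sqrt(len(v)))
        # infeasible moments (e.g. zero variance) surface as an error
        spec = DistributionSpec(
            "beta", mean, se=se,
            low=max(_bounds(mean, se)[0], 0.0), high=min(_bounds(mean, se)[1], 1.0),
        )
        records.append(ParameterRecord("utility", "utility", ARM_BOTH, s, spec))
    records.append(
        ParameterRecord(
            "utility", "utility", ARM_BOTH, HealthState.DEATH, DistributionSpec("fixed", 0.0)
        )
    )
    return records


def estimate_state_costs(
    ds: TrialDataset, fixed_items: list[ParameterRecord] | None = None
) -> list[ParameterRecord]:
    """Per-arm, per-state itemized annual-cost records.

    Each observation's item cost is annualized by its period length; the
    stratum mean and standard error are fitted to a gamma. A stratum absent
    in one arm falls back to pooling across arms (logged). ``fixed_items``
    are appended unchanged.
    """
    arms = {p.patient_id: p.arm for p in ds.patients}
    # annualized draws per (arm, state, item)
    values: dict = defaultdict(list)
    for o in ds.observations:
        s = classify_state(o)
        if s in (None, HealthState.DEATH):
            continue
        for item, cost in o.itemized_costs.items():
            if cost < 0:
                raise DataError(
                    f"negative cost for patient {o.patient_id}, item '{item}'"
                )
            values[(arms[o.patient_id], s, item)].append(
                cost * 12.0 / o.period_length_months
            )

    items_per_state: dict = defaultdict(set)
    for (arm, s, item) in values:
        items_per_state[s].add(item)

    records = []
    for s in ALIVE_STATES:
        for item in sorted(items_per_state[s]):
            for arm in ARMS:
                v = values[(arm, s, item)]
                if not v:
                    pooled = values[(ARMS[0], s, item)] + values[(ARMS[1], s, item)]
                    if not pooled:
                        raise EstimationError(
                            f"no cost observations for item '{item}' in state '{s.value}'"
                        )
                    log.warning(
                        "no '%s' cost observations for arm '%s' in state '%s'; "
                        "pooling across arms", item, arm, s.value,
                    )
                    v = pooled
                mean = float(np.mean(v))
                if len(v) < 2 or np.std(v, ddof=1) == 0:
                    spec = DistributionSpec("fixed", mean)
                else:
                    se = float(np.std(v, ddof=1) / np.sqrt(len(v)))
                    spec = DistributionSpec(
                        "gamma", mean, se=se,
                        low=max(_bounds(mean, se)[0], 0.0), high=_bounds(mean, se)[1],
                    )
                records.append(ParameterRecord(item, "cost", arm, s, spec))
    records.extend(fixed_items or [])
    return records


def default_iot_service_items() -> list[ParameterRecord]:
    """The three fixed IoT management cost items (¥/patient/year), attached
    to the IoT arm's stable and nonserious states."""
    items = [
        ("equipment_maintenance", 100.00),
        ("telephone_contact", 293.00),
        ("home_visits", 2379.00),
    ]
    out = []
    for state in (HealthState.STABLE, HealthState.NONSERIOUS):
        for name, base in items:
            out.append(
                ParameterRecord(
                    name, "cost", "iot", state,
                    DistributionSpec("fixed", base, low=0.9 * base, high=1.1 * base),
                )
            )
    return out


def estimate_parameters(
    ds: TrialDataset,
    config: ModelConfig,
    fixed_cost_items: list[ParameterRecord] | None = None,
    strict: bool = False,
) -> ParameterSet:
    """Full parameter set (costs, utilities, transitions) from a dataset.

    ``fixed_cost_items`` defaults to the three IoT service items.
    """
    if fixed_cost_items is None:
        fixed_cost_items = default_iot_service_items()
    records = (
        estimate_state_costs(ds, fixed_items=fixed_cost_items)
        + estimate_state_utilities(ds)
        + estimate_transitions(ds, config, strict=strict)
    )
    return ParameterSet(records)
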