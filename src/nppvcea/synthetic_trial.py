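"""Synthetic two-arm follow-up data with the structure of the home-NPPV
trial that feeds the estimation stage.

The emulated design: two management arms (IoT-based, n=58; standard, n=67),
follow-up visits at 3, 6 and 12 months (three periods of 3, 3 and 6
months), and per period a CAT score, a hospitalization flag, a
medication-adjustment flag and itemized costs. In the first period the
medication-adjustment flag is unobservable (baseline medication is
unknown), so stable and nonserious periods cannot be told apart there —
the generator always emits it as unknown, forcing downstream estimation to
exercise the exclusion rule.

Health-state classification of one observation follows the trial's rules:
death, else hospitalized → serious exacerbation, else medication adjusted →
nonserious exacerbation, else stable; an unknown adjustment flag leaves the
state unknown.

Two latent-state mechanisms are available: a first-order Markov chain
over per-arm annual transition matrices (the default, using the shipped
base-case matrices, so parameter-recovery tests can get back the matrix
that generated the data), or independent per-period draws from configured
occupancy probabilities (for classification and goodness-of-fit testing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .parameters import probability_to_rate, rate_to_probability
from .states import ARM_IOT, ARM_STANDARD, STATE_INDEX, STATE_ORDER, HealthState

__all__ = [
    "PatientRecord",
    "FollowUpObservation",
    "TrialDataset",
    "GeneratorConfig",
    "generate_trial",
    "classify_state",
    "write_dataset",
    "read_dataset",
    "PERIODS",
]

#: (period_index, length in months); follow-up at months 3, 6 and 12.
PERIODS: tuple[tuple[int, int], ...] = ((1, 3), (2, 3), (3, 6))


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    arm: str
    age_at_entry: float
    sex: str  # 'male' | 'female'


@dataclass(frozen=True)
class FollowUpObservation:
    """One follow-up period for one patient.

    ``medication_adjusted`` is ``None`` when unobservable (period 1).
    ``itemized_costs`` maps item name to ¥ accrued over the period.
    """

    patient_id: str
    period_index: int
    period_length_months: float
    cat_score: int
    hospitalized: bool
    medication_adjusted: bool | None
    died: bool
    itemized_costs: dict[str, float] = field(default_factory=dict)


@dataclass
class TrialDataset:
    patients: list[PatientRecord]
    observations: list[FollowUpObservation]
    generator_config: "GeneratorConfig | None" = None

    def __eq__(self, other) -> bool:
        # generator_config is not persisted by the CSV round-trip
        return (
            isinstance(other, TrialDataset)
            and self.patients == other.patients
            and self.observations == other.observations
        )

    def grouped_observations(self) -> dict[str, list[FollowUpObservation]]:
        """Observations per patient, ordered by period, in one pass."""
        by_patient: dict[str, list[FollowUpObservation]] = {}
        for o in self.observations:
            by_patient.setdefault(o.patient_id, []).append(o)
        for obs in by_patient.values():
            obs.sort(key=lambda o: o.period_index)
        return by_patient

    def observations_for(self, patient_id: str) -> list[FollowUpObservation]:
        return self.grouped_observations().get(patient_id, [])

    def validate(self) -> None:
        ids = {p.patient_id for p in self.patients}
        if len(ids) != len(self.patients):
            raise DataError("duplicate patient_id in patients table")
        seen: set[tuple[str, int]] = set()
        for o in self.observations:
            if o.patient_id not in ids:
                raise DataError(f"observation references unknown patient_id {o.patient_id}")
            key = (o.patient_id, o.period_index)
            if key in seen:
                raise DataError(f"duplicate observation for {key}")
            seen.add(key)
        for pid, obs in self.grouped_observations().items():
            for prev in obs[:-1]:
                if prev.died:
                    raise DataError(f"patient {pid} has observations after death")


def classify_state(obs: FollowUpObservation) -> HealthState | None:
    """Health state of one follow-up period, or None when unidentifiable.

    died → death; hospitalized → serious; medication adjusted → nonserious;
    adjustment known absent → stable; adjustment unknown (period 1) → None.
    Unknown periods are excluded from transition counting downstream.
    """
    if obs.died:
        return HealthState.DEATH
    if obs.hospitalized:
        return HealthState.SERIOUS
    if obs.medication_adjusted is True:
        return HealthState.NONSERIOUS
    if obs.medication_adjusted is False:
        return HealthState.STABLE
    return None


# ---------------------------------------------------------------------------
# Generator configuration
# ---------------------------------------------------------------------------

# Per-state CAT means invert the utility mapping at the trial's mean age, so
# estimated state utilities land near the published values; SD in CAT points.
DEFAULT_CAT_MEANS = {
    HealthState.STABLE: 24.0,
    HealthState.NONSERIOUS: 25.0,
    HealthState.SERIOUS: 28.0,
}
DEFAULT_CAT_SD = 4.0

# Per-arm/state itemized annual cost (mean, per-observation SD) in ¥. Means
# follow the trial's cost table; SDs are set so stratum standard errors come
# out at the order the trial reports (SE ~ SD/sqrt(n) with n of a few dozen).
DEFAULT_COSTS = {
    (ARM_IOT, HealthState.STABLE): {"treatment": (8913.18, 2200.0)},
    (ARM_STANDARD, HealthState.STABLE): {"treatment": (8828.47, 2300.0)},
    (ARM_IOT, HealthState.NONSERIOUS): {"treatment": (10792.54, 3300.0)},
    (ARM_STANDARD, HealthState.NONSERIOUS): {"treatment": (10157.65, 3100.0)},
    (ARM_IOT, HealthState.SERIOUS): {"hospitalization": (29675.74, 16000.0)},
    (ARM_STANDARD, HealthState.SERIOUS): {"hospitalization": (29918.20, 18000.0)},
}

# Per-arm latent-state occupancy for independent per-period draws, echoing
# the first trial year's state mix (IoT: fewer serious periods).
DEFAULT_OCCUPANCY = {
    ARM_IOT: {
        HealthState.STABLE: 0.50,
        HealthState.NONSERIOUS: 0.29,
        HealthState.SERIOUS: 0.19,
        HealthState.DEATH: 0.02,
    },
    ARM_STANDARD: {
        HealthState.STABLE: 0.44,
        HealthState.NONSERIOUS: 0.19,
        HealthState.SERIOUS: 0.34,
        HealthState.DEATH: 0.03,
    },
}


def _default_transition_matrices() -> dict[str, np.ndarray]:
    """Per-arm annual matrices of the shipped base-case parameter set."""
    from .parameters import load_default_parameters

    ps = load_default_parameters()
    return {arm: ps.transition_matrix(arm) for arm in (ARM_IOT, ARM_STANDARD)}


@dataclass
class GeneratorConfig:
    """Settings for :func:`generate_trial`.

    When ``transition_matrices`` is set (a per-arm 4x4 annual matrix — the
    default uses the shipped base-case matrices, so the generated cohort
    follows the trial's published dynamics), latent states follow a Markov
    chain whose per-period matrices are derived by the rate conversion
    tp = 1 - exp(-r t). With ``transition_matrices=None`` each period's
    state is instead drawn independently from ``occupancy``; that mode is
    useful for stress-testing classification and occupancy frequencies but
    produces period-to-period churn whose implied annual transition rates
    need not be feasible as probabilities.
    """

    arm_sizes: dict[str, int] = field(
        default_factory=lambda: {ARM_IOT: 58, ARM_STANDARD: 67}
    )
    age_mean: float = 70.18
    age_sd: float = 6.5
    age_range: tuple[float, float] = (40.0, 80.0)
    male_fraction: float = 0.84
    occupancy: dict[str, dict[HealthState, float]] = field(
        default_factory=lambda: {
            a: dict(v) for a, v in DEFAULT_OCCUPANCY.items()
        }
    )
    cat_means: dict[HealthState, float] = field(
        default_factory=lambda: dict(DEFAULT_CAT_MEANS)
    )
    cat_sd: float = DEFAULT_CAT_SD
    costs: dict[tuple[str, HealthState], dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_COSTS.items()
        }
    )
    transition_matrices: dict[str, np.ndarray] | None = field(
        default_factory=lambda: _default_transition_matrices()
    )
    initial_state_probs: dict[HealthState, float] = field(
        default_factory=lambda: {HealthState.STABLE: 1.0}
    )
    random_seed: int = 0

    def validate(self) -> None:
        for arm, n in self.arm_sizes.items():
            if n < 1:
                raise ConfigurationError(f"arm_sizes[{arm!r}] must be >= 1, got {n}")
        if self.age_sd < 0:
            raise ConfigurationError(f"age_sd must be >= 0, got {self.age_sd}")
        if not 0 <= self.male_fraction <= 1:
            raise ConfigurationError(
                f"male_fraction must be in [0, 1], got {self.male_fraction}"
            )
        if self.cat_sd < 0:
            raise ConfigurationError(f"cat_sd must be >= 0, got {self.cat_sd}")
        for arm, probs in self.occupancy.items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"occupancy[{arm!r}] must sum to 1, got {total}"
                )
            if any(p < 0 for p in probs.values()):
                raise ConfigurationError(f"occupancy[{arm!r}] has negative entries")
        for key, items in self.costs.items():
            for item, (mean, sd) in items.items():
                if mean < 0 or sd < 0:
                    raise ConfigurationError(
                        f"costs[{key}][{item!r}] mean/sd must be >= 0"
                    )
        total = sum(self.initial_state_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"initial_state_probs must sum to 1, got {total}")


def _period_matrix(annual: np.ndarray, months: float) -> np.ndarray:
    """Annual transition matrix rescaled to a period of ``months`` months.

    Off-diagonals go probability → rate → period probability; diagonals are
    the residual.
    """
    t = months / 12.0
    m = np.zeros((4, 4))
    m[3, 3] = 1.0
    for i in range(3):
        off = 0.0
        for j in range(4):
            if j == i:
                continue
            p = rate_to_probability(probability_to_rate(annual[i, j]), t)
            m[i, j] = p
            off += p
        if off > 1:
            raise ConfigurationError(
                f"annual matrix row {STATE_ORDER[i].value} too aggressive for a "
                f"{months}-month period"
            )
        m[i, i] = 1.0 - off
    return m


def _trunc_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    """Truncated-normal draw by rejection (cheap for mild truncation)."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(rng.normal(mean, sd), lo, hi))  # pragma: no cover


def _draw_cat(rng: np.random.Generator, mean: float, sd: float) -> int:
    """Integer CAT score from a normal truncated to [0, 40]."""
    return int(round(_trunc_normal(rng, mean, sd, 0.0, 40.0)))


def _draw_costs(
    rng: np.random.Generator,
    items: dict[str, tuple[float, float]],
    months: float,
) -> dict[str, float]:
    """Itemized period costs: gamma draws of annual rates scaled to the period."""
    out = {}
    for item, (mean, sd) in items.items():
        if mean == 0:
            out[item] = 0.0
        elif sd == 0:
            out[item] = mean * months / 12.0
        else:
            shape = (mean / sd) ** 2
            scale = sd**2 / mean
            out[item] = float(rng.gamma(shape, scale)) * months / 12.0
    return out


def generate_trial(config: GeneratorConfig) -> TrialDataset:
    """Generate a synthetic two-arm follow-up dataset.

    Deterministic given ``config.random_seed``. Hospitalization marks
    exactly the serious periods and medication adjustment exactly the
    nonserious ones (emitted as unknown in period 1); patients who die emit
    a terminal observation and nothing afterwards.
    """
    config.validate()
    rng = np.random.default_rng(config.random_seed)

    patients: list[PatientRecord] = []
    observations: list[FollowUpObservation] = []

    for arm, n in config.arm_sizes.items():
        period_matrices = None
        if config.transition_matrices is not None:
            annual = np.asarray(config.transition_matrices[arm], dtype=float)
            period_matrices = {
                months: _period_matrix(annual, months) for _, months in PERIODS
            }
        occ_probs = None
        if period_matrices is None:
            occ = config.occupancy[arm]
            occ_probs = np.array([occ.get(s, 0.0) for s in STATE_ORDER])

        for k in range(n):
            pid = f"{arm}-{k + 1:03d}"
            lo, hi = config.age_range
            age = _trunc_normal(rng, config.age_mean, config.age_sd, lo, hi)
            sex = "male" if rng.uniform() < config.male_fraction else "female"
            patients.append(PatientRecord(pid, arm, round(age, 1), sex))

            state = None
            if period_matrices is not None:
                init = np.array(
                    [config.initial_state_probs.get(s, 0.0) for s in STATE_ORDER]
                )
                state = STATE_ORDER[rng.choice(4, p=init)]
            for period_index, months in PERIODS:
                if period_matrices is not None:
                    state = STATE_ORDER[
                        rng.choice(4, p=period_matrices[months][STATE_INDEX[state]])
                    ]
                else:
                    state = STATE_ORDER[rng.choice(4, p=occ_probs)]
                if state == HealthState.DEATH:
                    observations.append(
                        FollowUpObservation(
                            patient_id=pid,
                            period_index=period_index,
                            period_length_months=months,
                            cat_score=0,
                            hospitalized=False,
                            medication_adjusted=None if period_index == 1 else False,
                            died=True,
                            itemized_costs={},
                        )
                    )
                    break
                observations.append(
                    FollowUpObservation(
                        patient_id=pid,
                        period_index=period_index,
                        period_length_months=months,
                        cat_score=_draw_cat(
                            rng, config.cat_means[state], config.cat_sd
                        ),
                        hospitalized=state == HealthState.SERIOUS,
                        medication_adjusted=(
                            None
                            if period_index == 1
                            else state == HealthState.NONSERIOUS
                        ),
                        died=False,
                        itemized_costs=_draw_costs(
                            rng, config.costs.get((arm, state), {}), months
                        ),
                    )
                )

    ds = TrialDataset(patients=patients, observations=observations, generator_config=config)
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

PATIENT_COLUMNS = ["patient_id", "arm", "age", "sex"]
OBS_BASE_COLUMNS = [
    "patient_id",
    "period_index",
    "period_length_months",
    "cat_score",
    "hospitalized",
    "medication_adjusted",
    "died",
]


def write_dataset(ds: TrialDataset, path) -> None:
    """Write ``patients.csv`` and ``observations.csv`` under directory ``path``.

    Booleans are 0/1; an unknown medication-adjustment flag is an empty
    field; cost items become ``cost_<item>`` columns.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {"patient_id": p.patient_id, "arm": p.arm, "age": p.age_at_entry, "sex": p.sex}
            for p in ds.patients
        ],
        columns=PATIENT_COLUMNS,
    ).to_csv(path / "patients.csv", index=False)

    items = sorted({k for o in ds.observations for k in o.itemized_costs})
    rows = []
    for o in ds.observations:
        row = {
            "patient_id": o.patient_id,
            "period_index": o.period_index,
            "period_length_months": o.period_length_months,
            "cat_score": o.cat_score,
            "hospitalized": int(o.hospitalized),
            "medication_adjusted": (
                "" if o.medication_adjusted is None else int(o.medication_adjusted)
            ),
            "died": int(o.died),
        }
        for item in items:
            row[f"cost_{item}"] = o.itemized_costs.get(item, "")
        rows.append(row)
    pd.DataFrame(rows, columns=OBS_BASE_COLUMNS + [f"cost_{i}" for i in items]).to_csv(
        path / "observations.csv", index=False
    )


def _require_columns(df: pd.DataFrame, required: list[str], fname: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{fname} is missing required column(s): {', '.join(missing)}")


def read_dataset(path) -> TrialDataset:
    """Read a dataset written by :func:`write_dataset`; the inverse round-trips."""
    path = Path(path)
    try:
        pat = pd.read_csv(path / "patients.csv", dtype={"patient_id": str})
        obs = pd.read_csv(
            path / "observations.csv", dtype={"patient_id": str}, keep_default_na=False
        )
    except pd.errors.ParserError as exc:
        raise DataError(f"malformed CSV under {path}: {exc}") from exc
    _require_columns(pat, PATIENT_COLUMNS, "patients.csv")
    _require_columns(obs, OBS_BASE_COLUMNS, "observations.csv")

    patients = [
        PatientRecord(
            patient_id=str(r.patient_id),
            arm=str(r.arm),
            age_at_entry=float(r.age),
            sex=str(r.sex),
        )
        for r in pat.itertuples()
    ]
    cost_cols = [c for c in obs.columns if c.startswith("cost_")]
    observations = []
    for idx, r in enumerate(obs.itertuples(), start=2):  # header is line 1
        try:
            med_raw = str(getattr(r, "medication_adjusted"))
            med = None if med_raw == "" else bool(int(med_raw))
            costs = {}
            for c in cost_cols:
                v = getattr(r, c)
                if str(v) != "":
                    costs[c[len("cost_"):]] = float(v)
            observations.append(
                FollowUpObservation(
                    patient_id=str(r.patient_id),
                    period_index=int(r.period_index),
                    period_length_months=float(r.period_length_months),
                    cat_score=int(r.cat_score),
                    hospitalized=bool(int(r.hospitalized)),
                    medication_adjusted=med,
                    died=bool(int(r.died)),
                    itemized_costs=costs,
                )
            )
        except (TypeError, ValueError) as exc:
            raise DataError(f"observations.csv line {idx}: {exc}") from exc
    ds = TrialDataset(patients=patients, observations=observations)
    ds.validate()
    return ds
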