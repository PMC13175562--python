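"""Estimation-stage tests: recovery of generating transition matrices,
utility and cost calibration recovery, the first-period exclusion rule,
and degenerate-data behaviour."""

import warnings

import numpy as np
import pytest

from nppvcea import (
    DataError,
    EstimationError,
    GeneratorConfig,
    HealthState,
    InfeasibleMomentsError,
    ModelConfig,
    PatientRecord,
    TrialDataset,
    cat_to_utility,
    estimate_parameters,
    estimate_state_costs,
    estimate_state_utilities,
    estimate_transitions,
    generate_trial,
    load_default_parameters,
)
from nppvcea.parameters import ParameterSet
from nppvcea.states import ALIVE_STATES, STATE_INDEX

from test_synthetic_trial import obs


def stable_only_dataset(n=6):
    patients = [PatientRecord(f"p{i}", "iot" if i % 2 else "standard", 70.0, "male")
                for i in range(n)]
    observations = []
    for i, p in enumerate(patients):
        observations += [
            obs(patient_id=p.patient_id, period_index=2, period_length_months=3,
                cat_score=20 + i % 5),
            obs(patient_id=p.patient_id, period_index=3, period_length_months=6,
                cat_score=22 + i % 5),
        ]
    return TrialDataset(patients=patients, observations=observations)


class TestTransitionRecovery:
    def test_recovers_generating_matrix(self, default_params, config):
        # moderate n here; the full 5,000-per-arm check runs in the
        # acceptance suite
        gc = GeneratorConfig(
            arm_sizes={"iot": 1500, "standard": 1500}, random_seed=101
        )
        ds = generate_trial(gc)
        est = ParameterSet(estimate_transitions(ds, config))
        for arm in ("iot", "standard"):
            truth = default_params.transition_matrix(arm)
            for frm in ALIVE_STATES:
                for to in ALIVE_STATES:
                    if to == frm:
                        continue
                    rec = est.transition_record(arm, frm, to)
                    se = rec.spec.se or 0.0
                    assert rec.spec.base == pytest.approx(
                        truth[STATE_INDEX[frm], STATE_INDEX[to]],
                        abs=max(2 * se, 0.02),
                    )

    def test_natural_mortality_overrides_data(self, config):
        ds = generate_trial(GeneratorConfig(random_seed=2))
        est = ParameterSet(estimate_transitions(ds, config))
        for arm in ("iot", "standard"):
            for frm in (HealthState.STABLE, HealthState.NONSERIOUS):
                rec = est.transition_record(arm, frm, HealthState.DEATH)
                assert rec.spec.base == config.natural_mortality
                assert rec.spec.kind == "fixed"

    def test_serious_row_pooled_across_arms(self, config):
        ds = generate_trial(GeneratorConfig(random_seed=2))
        records = estimate_transitions(ds, config)
        serious = [r for r in records if r.state is HealthState.SERIOUS]
        assert serious and all(r.arm == "both" for r in serious)

    def test_rows_sum_to_one_with_absorbing_death(self, config):
        ds = generate_trial(GeneratorConfig(random_seed=13))
        est = ParameterSet(estimate_transitions(ds, config))
        for arm in ("iot", "standard"):
            m = est.transition_matrix(arm)
            np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-9)
            np.testing.assert_allclose(m[3], [0, 0, 0, 1])

    def test_all_stable_data_gives_degenerate_rows(self, config):
        ds = stable_only_dataset()
        with pytest.warns(UserWarning, match="person-time"):
            est = ParameterSet(estimate_transitions(ds, config))
        for arm in ("iot", "standard"):
            m = est.transition_matrix(arm)
            i = STATE_INDEX[HealthState.STABLE]
            assert m[i, i] == pytest.approx(1 - config.natural_mortality)
            assert m[i, STATE_INDEX[HealthState.NONSERIOUS]] == 0.0
            assert m[i, STATE_INDEX[HealthState.SERIOUS]] == 0.0

    def test_strict_mode_raises_on_missing_state(self, config):
        ds = stable_only_dataset()
        with pytest.raises(EstimationError, match="serious"):
            estimate_transitions(ds, config, strict=True)

    def test_first_period_exclusion(self, config):
        # a hospitalized (serious) first period IS usable for transition
        # counting, while an unknown first period is skipped: the only
        # serious -> stable events here occur out of period 1
        patients = [PatientRecord(f"p{i}", "iot", 70.0, "male") for i in range(40)]
        observations = []
        for i, p in enumerate(patients):
            to_stable = i < 4  # 4 of 40 leave the serious state after period 1
            observations += [
                obs(patient_id=p.patient_id, period_index=1,
                    medication_adjusted=None, hospitalized=True),
                obs(patient_id=p.patient_id, period_index=2,
                    hospitalized=not to_stable,
                    medication_adjusted=False),
                obs(patient_id=p.patient_id, period_index=3,
                    hospitalized=not to_stable,
                    medication_adjusted=False),
            ]
        ds = TrialDataset(patients=patients, observations=observations)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = ParameterSet(estimate_transitions(ds, config))
        rec = est.transition_record("both", HealthState.SERIOUS, HealthState.STABLE)
        # without the period-1 pairs there would be no serious->stable events
        assert rec.spec.base > 0


class TestUtilityEstimation:
    def test_calibrated_recovery_of_state_utilities(self):
        # independent-draw mode with deterministic ages: the expected age at
        # any observation is age_mean + mean period end (0.25, 0.5, 1.0 y),
        # so CAT means are chosen to land on the published state utilities
        targets = {
            HealthState.STABLE: 0.6195,
            HealthState.NONSERIOUS: 0.5960,
            HealthState.SERIOUS: 0.5319,
        }
        age_mean = 70.18
        mean_age_at_obs = age_mean + (0.25 + 0.5 + 1.0) / 3
        cat_means = {
            s: (1.26848 - 0.00188 * mean_age_at_obs - u) / 0.02159
            for s, u in targets.items()
        }
        occ = {
            HealthState.STABLE: 0.45,
            HealthState.NONSERIOUS: 0.30,
            HealthState.SERIOUS: 0.25,
            HealthState.DEATH: 0.0,
        }
        cfg = GeneratorConfig(
            arm_sizes={"iot": 1500, "standard": 1500},
            age_mean=age_mean,
            age_sd=0.0,
            occupancy={"iot": occ, "standard": occ},
            cat_means=cat_means,
            transition_matrices=None,
            random_seed=77,
        )
        ds = generate_trial(cfg)
        est = {r.state: r.spec for r in estimate_state_utilities(ds)}
        for s, target in targets.items():
            spec = est[s]
            assert spec.base == pytest.approx(target, abs=2 * spec.se)

    def test_death_utility_fixed_zero(self):
        ds = generate_trial(GeneratorConfig(random_seed=3))
        est = {r.state: r.spec for r in estimate_state_utilities(ds)}
        assert est[HealthState.DEATH].kind == "fixed"
        assert est[HealthState.DEATH].base == 0.0

    def test_zero_variance_surfaces_infeasible_moments(self):
        # identical CAT scores and identical ages at observation: the state
        # utility has zero SE, which the beta fit cannot represent
        patients = [PatientRecord("p1", "iot", 70.0, "male"),
                    PatientRecord("p2", "standard", 70.0, "male")]
        observations = [obs(patient_id=p.patient_id, period_index=2, cat_score=20)
                        for p in patients]
        ds = TrialDataset(patients=patients, observations=observations)
        with pytest.raises(InfeasibleMomentsError):
            estimate_state_utilities(ds)

    def test_rarely_observed_state_raises(self, config):
        ds = stable_only_dataset(n=2)
        # nonserious/serious never observed
        with pytest.raises(EstimationError, match="observed"):
            estimate_state_utilities(ds)

    def test_age_advances_with_follow_up(self):
        # identical CAT, different periods -> later periods give lower utility
        p = PatientRecord("p", "iot", 70.0, "male")
        o1 = obs(patient_id="p", period_index=2)
        o3 = obs(patient_id="p", period_index=3)
        ds = TrialDataset(patients=[p], observations=[o1, o3])
        from nppvcea.estimation import _age_at

        assert _age_at(o3, 70.0) > _age_at(o1, 70.0)
        assert _age_at(o1, 70.0) == pytest.approx(70.5)


class TestCostEstimation:
    def test_calibrated_recovery_of_cost_means(self):
        from nppvcea.synthetic_trial import DEFAULT_COSTS

        gc = GeneratorConfig(arm_sizes={"iot": 1200, "standard": 1200}, random_seed=8)
        ds = generate_trial(gc)
        records = estimate_state_costs(ds)
        for rec in records:
            truth = DEFAULT_COSTS.get((rec.arm, rec.state), {}).get(rec.name)
            if truth is None:
                continue
            mean, _ = truth
            se = rec.spec.se or 0.0
            assert rec.spec.base == pytest.approx(mean, abs=max(2 * se, 0.02 * mean))

    def test_annualization_scales_by_period_length(self):
        p = PatientRecord("p", "iot", 70.0, "male")
        # ¥100 over 3 months and ¥200 over 6 months both mean ¥400/year
        observations = [
            obs(patient_id="p", period_index=2, period_length_months=3,
                itemized_costs={"treatment": 100.0}),
            obs(patient_id="p", period_index=3, period_length_months=6,
                itemized_costs={"treatment": 200.0}),
        ]
        ds = TrialDataset(patients=[p], observations=observations)
        records = estimate_state_costs(ds, fixed_items=[])
        rec = next(r for r in records if r.arm == "iot" and r.name == "treatment")
        assert rec.spec.base == pytest.approx(400.0)
        assert rec.spec.kind == "fixed"  # zero variance -> fixed spec

    def test_negative_cost_names_patient(self):
        p = PatientRecord("bad-patient", "iot", 70.0, "male")
        ds = TrialDataset(
            patients=[p],
            observations=[obs(patient_id="bad-patient",
                              itemized_costs={"treatment": -5.0})],
        )
        with pytest.raises(DataError, match="bad-patient"):
            estimate_state_costs(ds)

    def test_missing_stratum_pools_across_arms(self, caplog):
        # serious observed only in the standard arm -> IoT falls back to pool
        patients = [PatientRecord("s1", "standard", 70.0, "male"),
                    PatientRecord("s2", "standard", 71.0, "male"),
                    PatientRecord("i1", "iot", 69.0, "male")]
        observations = [
            obs(patient_id="s1", period_index=2, hospitalized=True,
                itemized_costs={"hospitalization": 7000.0}),
            obs(patient_id="s2", period_index=2, hospitalized=True,
                itemized_costs={"hospitalization": 8000.0}),
            obs(patient_id="i1", period_index=2, medication_adjusted=True,
                itemized_costs={"treatment": 2500.0}),
        ]
        ds = TrialDataset(patients=patients, observations=observations)
        import logging

        with caplog.at_level(logging.WARNING, logger="nppvcea.estimation"):
            records = estimate_state_costs(ds, fixed_items=[])
        assert any("pooling" in m for m in caplog.messages)
        iot_hosp = next(
            r for r in records
            if r.arm == "iot" and r.state is HealthState.SERIOUS
        )
        assert iot_hosp.spec.base == pytest.approx(30_000.0)  # pooled, annualized


class TestFullPipeline:
    def test_estimated_parameters_form_valid_model(self, config):
        ds = generate_trial(GeneratorConfig(random_seed=21))
        params = estimate_parameters(ds, config)
        params.validate()
        # IoT service items pass through as fixed records
        items = [r for r in params.records
                 if r.category == "cost" and r.spec.kind == "fixed"]
        assert {r.name for r in items} == {
            "equipment_maintenance", "telephone_contact", "home_visits"
        }
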