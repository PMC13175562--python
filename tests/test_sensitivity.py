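"""Sensitivity-analysis tests: OWSA collapse and ordering behaviour, PSA
determinism and degenerate modes, parameter-mean convergence, and the CEAC
limit identities."""

import numpy as np
import pandas as pd
import pytest

from nppvcea import (
    EstimationError,
    ModelConfig,
    ParameterSet,
    compute_ceac,
    run_owsa,
    run_psa,
)
from nppvcea.markov import build_arm_models, run_cohort
from nppvcea.sensitivity import default_wtp_grid, owsa_frame


def collapsed_params(params: ParameterSet) -> ParameterSet:
    """All OWSA bounds collapsed onto the base value."""
    records = []
    for d in params.to_records_json():
        if d["low"] is not None:
            d = dict(d, low=d["base"], high=d["base"])
        records.append(d)
    return ParameterSet.from_records_json(records)


def all_fixed_params(params: ParameterSet) -> ParameterSet:
    """Every distribution replaced by a fixed spec at its base value."""
    records = []
    for d in params.to_records_json():
        if d["kind"] in ("gamma", "beta"):
            d = dict(d, kind="fixed", se=None, alpha=None, beta=None)
        records.append(d)
    return ParameterSet.from_records_json(records)


def base_increments(params, config):
    models = build_arm_models(params)
    traces = {arm: run_cohort(models[arm], config) for arm in models}
    return (
        traces["iot"].total_cost - traces["standard"].total_cost,
        traces["iot"].total_qalys - traces["standard"].total_qalys,
    )


class TestOWSA:
    def test_collapsed_bounds_reproduce_base_icer(self, default_params, config):
        d_cost, d_eff = base_increments(default_params, config)
        base_icer = d_cost / d_eff
        entries = run_owsa(
            collapsed_params(default_params),
            config,
            discount_rate_bounds=(config.discount_rate, config.discount_rate),
            mortality_relative_bounds=(1.0, 1.0),
            iot_items_relative_bounds=(1.0, 1.0),
        )
        for e in entries:
            assert e.icer_low == pytest.approx(base_icer, rel=1e-12)
            assert e.icer_high == pytest.approx(base_icer, rel=1e-12)
            assert e.range == 0.0

    def test_sorted_by_descending_range(self, default_params, config):
        entries = run_owsa(default_params, config)
        ranges = [e.range for e in entries]
        assert ranges == sorted(ranges, reverse=True)

    def test_discount_rate_entry_finite_at_zero_and_eight_percent(
        self, default_params, config
    ):
        entries = run_owsa(default_params, config)
        disc = next(e for e in entries if e.name == "discount rate")
        assert disc.low == 0.0 and disc.high == 0.08
        assert np.isfinite(disc.icer_low) and np.isfinite(disc.icer_high)

    def test_transitions_excluded(self, default_params, config):
        entries = run_owsa(default_params, config)
        assert not any(e.name.startswith("transition") for e in entries)

    def test_frame_export(self, default_params, config):
        df = owsa_frame(run_owsa(default_params, config))
        assert list(df.columns) == [
            "parameter", "low_input", "high_input",
            "icer_at_low", "icer_at_high", "range",
        ]
        assert len(df) > 10


class TestPSA:
    def test_seed_determinism(self, default_params, config):
        a = run_psa(default_params, config, n_iterations=50, seed=123)
        b = run_psa(default_params, config, n_iterations=50, seed=123)
        pd.testing.assert_frame_equal(a.samples, b.samples)

    def test_all_fixed_reproduces_base_case(self, default_params, config):
        d_cost, d_eff = base_increments(default_params, config)
        res = run_psa(
            all_fixed_params(default_params), config, n_iterations=10, seed=0,
            fixed_cost_items="base",
        )
        np.testing.assert_allclose(res.samples["delta_cost"], d_cost, rtol=1e-12)
        np.testing.assert_allclose(res.samples["delta_effect"], d_eff, rtol=1e-12)

    def test_draw_validity(self, default_params, config):
        res = run_psa(
            default_params, config, n_iterations=100, seed=5, collect_draws=True
        )
        draws = res.draws
        for col in draws.columns:
            if col.startswith("cost_"):
                assert (draws[col] >= 0).all()
            else:  # utilities and transition probabilities
                assert draws[col].between(0, 1).all()

    def test_parameter_means_converge_to_base(self, default_params, config):
        # Unconstrained parameters (costs, utilities) converge to their base
        # values. Transition entries are sampled subject to the row-coherence
        # rejection rule, which truncates the joint distribution, so their
        # accepted-draw means are compared against an independent rejection
        # sampler for the same rows rather than against the raw base value.
        res = run_psa(
            default_params, config, n_iterations=10_000, seed=31, collect_draws=True
        )
        free, rows = {}, {}
        for rec in default_params.records:
            if rec.spec.kind == "gamma":
                free[f"cost_{rec.arm}_{rec.state.value}_{rec.name}"] = rec.spec.base
            elif rec.spec.kind == "beta" and rec.category == "utility":
                free[f"utility_{rec.state.value}"] = rec.spec.base
            elif rec.category == "transition":
                to = rec.name.split("->")[1]
                if to != rec.state.value:  # off-diagonal entries only
                    rows.setdefault((rec.arm, rec.state.value), []).append(rec)

        trans_names = {
            f"tp_{rec.arm}_{rec.name}"
            for recs in rows.values()
            for rec in recs
            if rec.spec.kind == "beta"
        }
        assert set(free) | trans_names == set(res.draws.columns)

        for name, base in free.items():
            col = res.draws[name]
            se = col.std(ddof=1) / np.sqrt(len(col))
            assert abs(col.mean() - base) < 3 * se, name

        # independent oracle: redraw each row with the same rejection rule
        oracle_rng = np.random.default_rng(987)
        n_oracle = 20_000
        for (arm, frm), recs in rows.items():
            betas = [r for r in recs if r.spec.kind == "beta"]
            if not betas:
                continue
            fixed_sum = sum(r.spec.base for r in recs if r.spec.kind != "beta")
            draws = np.column_stack(
                [oracle_rng.beta(r.spec.alpha, r.spec.beta_param, n_oracle)
                 for r in betas]
            )
            accepted = draws[draws.sum(axis=1) + fixed_sum <= 1.0]
            for j, rec in enumerate(betas):
                col = res.draws[f"tp_{rec.arm}_{rec.name}"]
                se = np.sqrt(
                    col.var(ddof=1) / len(col)
                    + accepted[:, j].var(ddof=1) / len(accepted)
                )
                assert abs(col.mean() - accepted[:, j].mean()) < 3 * se, rec.name

    def test_rejection_warning_when_rows_often_incoherent(self, default_params, config):
        with pytest.warns(UserWarning, match="rejections"):
            run_psa(default_params, config, n_iterations=500, seed=2)

    def test_iteration_count_validated(self, default_params, config):
        from nppvcea import ConfigurationError

        with pytest.raises(ConfigurationError):
            run_psa(default_params, config, n_iterations=0)


class TestCEAC:
    def make_samples(self, d_cost, d_eff):
        return pd.DataFrame(
            {"delta_cost": d_cost, "delta_effect": d_eff,
             "inc_nmb": np.zeros(len(d_cost))}
        )

    def test_all_dominant_gives_probability_one_everywhere(self):
        s = self.make_samples([-10.0, -5.0], [0.1, 0.2])
        ceac = compute_ceac(s, [0, 1000, 1e6])
        assert (ceac["probability"] == 1.0).all()

    def test_lambda_zero_limit_is_p_cheaper(self, default_params, config):
        res = run_psa(default_params, config, n_iterations=400, seed=9)
        ceac = compute_ceac(res.samples, [0.0])
        p_cheaper = (res.samples["delta_cost"] < 0).mean()
        assert ceac["probability"].iloc[0] == pytest.approx(p_cheaper)

    def test_large_lambda_limit_is_p_more_effective(self, default_params, config):
        res = run_psa(default_params, config, n_iterations=400, seed=9)
        ceac = compute_ceac(res.samples, [1e12])
        p_more = (res.samples["delta_effect"] > 0).mean()
        assert ceac["probability"].iloc[0] == pytest.approx(p_more)

    def test_matches_psa_summary_at_wtp(self, default_params, config):
        res = run_psa(default_params, config, n_iterations=300, seed=17)
        ceac = compute_ceac(res.samples, [config.wtp])
        assert ceac["probability"].iloc[0] == pytest.approx(res.p_cost_effective)

    def test_default_grid_brackets_threshold(self):
        grid = default_wtp_grid()
        assert grid[0] == 0.0
        assert grid[-1] == 150_000.0
        assert 70_100.0 < grid[-1]

    def test_empty_samples_rejected(self):
        with pytest.raises(EstimationError):
            compute_ceac(pd.DataFrame({"delta_cost": [], "delta_effect": []}))
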