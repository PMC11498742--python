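"""Method-pair dispatch, likelihood evaluation, and gradient assembly."""

import numpy as np
import pandas as pd
import pytest

from eqsens import ValidationError
from eqsens.fixtures import as_dataset, build_fixture, generate_synthetic_data
from eqsens.io import build_dataset
from eqsens.model import derive, parse_model
from eqsens.objective import (
    OK,
    TAILORED_INAPPLICABLE,
    MethodPair,
    finite_difference_gradient,
    negative_log_likelihood,
    objective_gradient,
    simulate_condition,
)


class TestMethodPair:
    @pytest.mark.parametrize("name", [
        "int_int_fsa", "int_int_asa", "int_lin_fsa",
        "int_lin_asa", "newton_lin_fsa", "newton_lin_asa",
    ])
    def test_admissible_pairs_construct(self, name):
        pair = MethodPair.from_name(name)
        assert pair.name == name

    @pytest.mark.parametrize("sens", ["fsa_integration", "asa_integration"])
    def test_newton_with_integrated_sensitivities_rejected(self, sens):
        with pytest.raises(ValidationError):
            MethodPair("newton", sens)

    def test_unknown_names_rejected(self):
        with pytest.raises(ValidationError):
            MethodPair.from_name("newton_int_fsa")
        with pytest.raises(ValidationError):
            MethodPair("bisection", "fsa_tailored")

    def test_exactly_six_pairs(self):
        assert len(MethodPair.all_pairs()) == 6


class TestSimulateCondition:
    def test_posteq_only_gives_steady_outputs(self, decay2, config):
        fx, d = decay2
        rows = pd.DataFrame({
            "observableId": ["obs_x1", "obs_x2"],
            "simulationConditionId": "c1",
            "preequilibrationConditionId": None,
            "time": [np.inf, np.inf],
            "measurement": [0.5, 0.25],
        })
        res = simulate_condition(
            fx.model, d, fx.true_theta, fx.conditions["c1"], rows,
            MethodPair("integration", "fsa_tailored"), config,
        )
        assert res.ok
        assert res.y_steady["obs_x1"] == pytest.approx(0.5, rel=1e-7)
        assert res.y_steady["obs_x2"] == pytest.approx(0.25, rel=1e-7)

    def test_preeq_equals_posteq_for_same_input(self, cascade_preeq, config):
        """With u^e = u and no dynamic rows, the pre-equilibration steady state
        equals the post-equilibration one."""
        fx, d = cascade_preeq
        m = fx.model
        from eqsens.model import Condition

        cond = Condition("same", {"u": 2.0}, preeq_condition_id="samepre")
        pre = Condition("samepre", {"u": 2.0})
        rows = pd.DataFrame({
            "observableId": ["obs_x3"],
            "simulationConditionId": "same",
            "preequilibrationConditionId": "samepre",
            "time": [np.inf],
            "measurement": [0.0],
        })
        res = simulate_condition(
            m, d, fx.true_theta, cond, rows,
            MethodPair("integration", "fsa_tailored"), config, preeq_condition=pre,
        )
        assert res.ok
        assert np.allclose(res.x_preeq_star, res.x_star_post, rtol=1e-6)

    def test_drift_fails_in_posteq_phase(self, no_steady_state, config):
        fx, d = no_steady_state
        rows = pd.DataFrame({
            "observableId": ["obs_x"],
            "simulationConditionId": "c1",
            "preequilibrationConditionId": None,
            "time": [np.inf],
            "measurement": [1.0],
        })
        res = simulate_condition(
            fx.model, d, fx.true_theta, fx.conditions["c1"], rows,
            MethodPair("integration", "fsa_tailored"), config,
        )
        assert res.status == "no_steady_state" and res.phase == "posteq"


class TestNegativeLogLikelihood:
    def test_single_unit_residual(self, decay2, config):
        fx, d = decay2
        # one steady row with measurement = y* + sigma (sigma = 0.1, so
        # residual/sigma = 1): J = log(2 pi 0.01)/2 + 1/2
        rows = pd.DataFrame({
            "observableId": ["obs_x2"],
            "simulationConditionId": "c1",
            "preequilibrationConditionId": None,
            "time": [np.inf],
            "measurement": [0.25 + 0.1],
        })
        res = simulate_condition(
            fx.model, d, fx.true_theta, fx.conditions["c1"], rows,
            MethodPair("integration", "fsa_tailored"), config,
        )
        nll = negative_log_likelihood([res])
        assert nll == pytest.approx(0.5 * np.log(2 * np.pi * 0.01) + 0.5, rel=1e-6)

    def test_zero_residuals_reduce_to_normalization(self, decay2, config):
        fx, d = decay2
        rows = pd.DataFrame({
            "observableId": ["obs_x1", "obs_x2"],
            "simulationConditionId": "c1",
            "preequilibrationConditionId": None,
            "time": [np.inf, np.inf],
            "measurement": [0.5, 0.25],
        })
        res = simulate_condition(
            fx.model, d, fx.true_theta, fx.conditions["c1"], rows,
            MethodPair("integration", "fsa_tailored"), config,
        )
        # m rows with zero residual: (m/2) log(2 pi sigma^2)
        assert negative_log_likelihood([res]) == pytest.approx(
            np.log(2 * np.pi * 0.01), rel=1e-5
        )

    def test_failed_simulation_propagates(self, no_steady_state, config):
        from eqsens import SimulationError

        fx, d = no_steady_state
        rows = pd.DataFrame({
            "observableId": ["obs_x"],
            "simulationConditionId": "c1",
            "preequilibrationConditionId": None,
            "time": [np.inf],
            "measurement": [1.0],
        })
        res = simulate_condition(
            fx.model, d, fx.true_theta, fx.conditions["c1"], rows,
            MethodPair("integration", "fsa_tailored"), config,
        )
        with pytest.raises(SimulationError):
            negative_log_likelihood([res])


class TestObjectiveGradient:
    def test_objective_identical_across_pairs(self, decay2, decay2_dataset, config, all_pairs):
        fx, d = decay2
        theta = fx.true_theta * 1.4
        values = []
        for pair in all_pairs:
            r = objective_gradient(fx.model, d, theta, decay2_dataset, pair, config)
            assert r.ok
            values.append(r.objective_value)
        assert np.allclose(values, values[0], rtol=1e-8)

    def test_zero_residual_dataset_has_zero_gradient(self, decay2, config, all_pairs):
        fx, d = decay2
        syn = generate_synthetic_data(fx, noise_sd=0.0, seed=0)
        data = as_dataset(fx, syn)
        for pair in all_pairs:
            r = objective_gradient(fx.model, d, fx.true_theta, data, pair, config)
            assert r.ok
            assert np.max(np.abs(r.gradient)) < 1e-5

    def test_cross_pair_gradient_agreement(self, decay2, decay2_dataset, config):
        fx, d = decay2
        theta = fx.true_theta * 0.6
        a = objective_gradient(
            fx.model, d, theta, decay2_dataset,
            MethodPair("integration", "fsa_integration"), config,
        )
        b = objective_gradient(
            fx.model, d, theta, decay2_dataset,
            MethodPair("newton", "asa_tailored"), config,
        )
        assert a.ok and b.ok
        rel = np.linalg.norm(a.gradient - b.gradient) / np.linalg.norm(a.gradient)
        assert rel < 1e-4

    def test_matches_finite_differences(self, scalar_relax, config, all_pairs):
        fx, d = scalar_relax
        syn = generate_synthetic_data(fx, noise_sd=0.05, seed=2)
        data = as_dataset(fx, syn)
        theta = np.array([0.7, 1.8, 0.15])
        fd = finite_difference_gradient(fx.model, d, theta, data, config)
        for pair in all_pairs:
            r = objective_gradient(fx.model, d, theta, data, pair, config)
            assert r.ok
            rel = np.linalg.norm(r.gradient - fd) / np.linalg.norm(fd)
            assert rel < 1e-4

    def test_log_scale_gradient_is_chain_rule_of_linear(self, config):
        """The same model declared with lin vs log10 scales yields gradients
        related by theta * ln 10."""
        doc = {
            "name": "m",
            "states": [{"name": "x", "init": "0"}],
            "parameters": [
                {"name": "theta", "lower": 1e-3, "upper": 1e3, "scale": "SCALE"},
                {"name": "k", "lower": 1e-3, "upper": 1e3, "scale": "SCALE"},
            ],
            "inputs": [],
            "rates": {"x": "theta - k*x"},
            "observables": [{"name": "obs_x", "formula": "x", "noise_formula": "0.1"}],
        }
        import copy, json

        def model_with(scale):
            d2 = copy.deepcopy(doc)
            for p in d2["parameters"]:
                p["scale"] = scale
            return parse_model(d2)

        m_log, m_lin = model_with("log10"), model_with("lin")
        rows = pd.DataFrame({
            "observableId": ["obs_x"],
            "simulationConditionId": ["c1"],
            "preequilibrationConditionId": [None],
            "time": [np.inf],
            "measurement": [1.3],
        })
        from eqsens.model import Condition

        theta = np.array([1.0, 2.0])
        pair = MethodPair("integration", "asa_tailored")
        grads = {}
        for tag, m in (("log", m_log), ("lin", m_lin)):
            data = build_dataset(m, {"c1": Condition("c1", {})}, rows)
            r = objective_gradient(m, derive(m), theta, data, pair, config)
            assert r.ok
            grads[tag] = r.gradient
        assert np.allclose(grads["log"], theta * np.log(10.0) * grads["lin"], rtol=1e-10)

    def test_tailored_pairs_flag_conserved_models(self, reversible_pair, config):
        fx, d = reversible_pair
        syn = generate_synthetic_data(fx, noise_sd=0.05, seed=3)
        data = as_dataset(fx, syn)
        for name in ("int_lin_fsa", "int_lin_asa", "newton_lin_fsa", "newton_lin_asa"):
            r = objective_gradient(
                fx.model, d, fx.true_theta, data, MethodPair.from_name(name), config
            )
            assert r.status == TAILORED_INAPPLICABLE
        for name in ("int_int_fsa", "int_int_asa"):
            r = objective_gradient(
                fx.model, d, fx.true_theta, data, MethodPair.from_name(name), config
            )
            assert r.status == OK

    def test_combined_preeq_and_posteq_condition(self, cascade_preeq, config, all_pairs):
        """Pre- and post-equilibration in the same condition: every pair
        agrees with the FD oracle."""
        fx, d = cascade_preeq
        syn = generate_synthetic_data(fx, noise_sd=0.05, seed=4)
        data = as_dataset(fx, syn)
        assert np.isinf(data.measurements["time"]).any()
        assert data.measurements["preequilibrationConditionId"].notna().all()
        theta = fx.true_theta * 1.3
        fd = finite_difference_gradient(fx.model, d, theta, data, config)
        for pair in all_pairs:
            r = objective_gradient(fx.model, d, theta, data, pair, config)
            assert r.ok
            assert np.linalg.norm(r.gradient - fd) / np.linalg.norm(fd) < 1e-4

    def test_timings_are_decomposed(self, decay2, decay2_dataset, config):
        fx, d = decay2
        r = objective_gradient(
            fx.model, d, fx.true_theta, decay2_dataset,
            MethodPair("integration", "asa_integration"), config,
        )
        t = r.timings
        assert t["total"] >= t["equilibration"] + t["dynamic"] - 1e-9
        assert t["equilibration"] >= 0 and t["dynamic"] >= 0
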