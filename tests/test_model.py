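"""Model parsing, symbolic derivatives, conservation detection and reduction."""

import numpy as np
import pytest
import sympy as sp

from eqsens import SchemaError, ValidationError
from eqsens.model import (
    ConservationLaw,
    derive,
    detect_conservation,
    parse_model,
    reduce_model,
)
from eqsens.forward import integrate_states
from eqsens.steady_state import EquilibrationConfig

DECAY2_DOC = {
    "name": "decay2",
    "states": [{"name": "x1", "init": "0"}, {"name": "x2", "init": "0"}],
    "parameters": [
        {"name": "k1", "lower": 1e-3, "upper": 1e3, "scale": "log10"},
        {"name": "k2", "lower": 1e-3, "upper": 1e3, "scale": "log10"},
        {"name": "k3", "lower": 1e-3, "upper": 1e3, "scale": "log10"},
    ],
    "inputs": ["u"],
    "rates": {"x1": "k1*u - k2*x1", "x2": "k2*x1 - k3*x2"},
    "observables": [{"name": "obs_x2", "formula": "x2", "noise_formula": "0.1"}],
}

REVERSIBLE_DOC = {
    "name": "rev",
    "states": [{"name": "x1", "init": "a"}, {"name": "x2", "init": "b"}],
    "parameters": [
        {"name": "k1", "lower": 1e-2, "upper": 1e2, "scale": "log10"},
        {"name": "k2", "lower": 1e-2, "upper": 1e2, "scale": "log10"},
        {"name": "a", "lower": 1e-2, "upper": 1e1, "scale": "log10"},
        {"name": "b", "lower": 1e-2, "upper": 1e1, "scale": "log10"},
    ],
    "inputs": [],
    "rates": {"x1": "-k1*x1 + k2*x2", "x2": "k1*x1 - k2*x2"},
    "observables": [{"name": "obs_x1", "formula": "x1", "noise_formula": "0.1"}],
}


class TestParseModel:
    def test_counts_from_document(self):
        m = parse_model(DECAY2_DOC)
        assert m.n_x == 2 and m.n_theta == 3 and m.n_u == 1 and m.n_y == 1

    def test_undeclared_symbol_named_in_error(self):
        doc = {**DECAY2_DOC, "rates": {"x1": "k9*u - k2*x1", "x2": "k2*x1 - k3*x2"}}
        with pytest.raises(SchemaError, match="k9"):
            parse_model(doc)

    def test_empty_states_rejected(self):
        with pytest.raises(ValidationError):
            parse_model({**DECAY2_DOC, "states": []})

    def test_nonpositive_log_bound_rejected(self):
        doc = {
            **DECAY2_DOC,
            "parameters": [
                {"name": "k1", "lower": 0.0, "upper": 1e3, "scale": "log10"},
                {"name": "k2", "lower": 1e-3, "upper": 1e3, "scale": "log10"},
                {"name": "k3", "lower": 1e-3, "upper": 1e3, "scale": "log10"},
            ],
        }
        with pytest.raises(ValidationError):
            parse_model(doc)

    def test_missing_rate_rejected(self):
        doc = {**DECAY2_DOC, "rates": {"x1": "k1*u - k2*x1"}}
        with pytest.raises(SchemaError, match="x2"):
            parse_model(doc)

    def test_noise_must_be_positive(self):
        doc = {
            **DECAY2_DOC,
            "observables": [
                {"name": "obs", "formula": "x2", "noise_formula": "k1 - k1"}
            ],
        }
        with pytest.raises(ValidationError):
            parse_model(doc)


class TestDerive:
    def test_decay2_jacobian(self):
        m = parse_model(DECAY2_DOC)
        d = derive(m)
        theta = np.array([1.0, 2.0, 4.0])
        J = d.jac(np.array([0.3, 0.7]), theta, np.array([1.0]))
        assert np.allclose(J, [[-2.0, 0.0], [2.0, -4.0]])

    def test_decay2_dfdp_k1_column(self):
        m = parse_model(DECAY2_DOC)
        d = derive(m)
        dfdp = d.dfdp(np.array([0.3, 0.7]), np.array([1.0, 2.0, 4.0]), np.array([2.5]))
        assert np.allclose(dfdp[:, 0], [2.5, 0.0])  # df/dk1 = (u, 0)

    def test_parameter_noise_gives_unit_dsigmadp_row(self):
        doc = {
            "name": "m",
            "states": [{"name": "x", "init": "0"}],
            "parameters": [
                {"name": "k", "lower": 0.1, "upper": 10, "scale": "log10"},
                {"name": "s", "lower": 0.01, "upper": 10, "scale": "log10"},
            ],
            "inputs": [],
            "rates": {"x": "k - x"},
            "observables": [{"name": "obs", "formula": "x", "noise_formula": "s"}],
        }
        d = derive(parse_model(doc))
        assert np.allclose(d.dsigmadp(np.array([1.0, 0.5])), [[0.0, 1.0]])

    @pytest.mark.parametrize("doc", [DECAY2_DOC, REVERSIBLE_DOC])
    def test_derivatives_match_finite_differences(self, doc):
        """Every symbolic derivative entry agrees with a central difference of
        the underlying expression to relative error < 1e-6."""
        m = parse_model(doc)
        d = derive(m)
        rng = np.random.default_rng(3)
        x = rng.uniform(0.2, 2.0, m.n_x)
        theta = m.sample_theta(rng)
        u = rng.uniform(0.5, 2.0, m.n_u)
        h = 1e-6

        def fd(fun, args, wrt, k):
            args_p = [a.copy() for a in args]
            args_m = [a.copy() for a in args]
            step = h * max(1.0, abs(args[wrt][k]))
            args_p[wrt][k] += step
            args_m[wrt][k] -= step
            return (fun(*args_p) - fun(*args_m)) / (2 * step)

        for k in range(m.n_x):
            got = d.jac(x, theta, u)[:, k]
            want = fd(m.f, [x, theta, u], 0, k)
            assert np.allclose(got, want, rtol=1e-6, atol=1e-8)
        for k in range(m.n_theta):
            assert np.allclose(
                d.dfdp(x, theta, u)[:, k], fd(m.f, [x, theta, u], 1, k),
                rtol=1e-6, atol=1e-8,
            )
            assert np.allclose(
                d.dx0dp(theta, u)[:, k], fd(m.x0, [theta, u], 0, k),
                rtol=1e-6, atol=1e-8,
            )
            assert np.allclose(
                d.dhdp(x, theta, u)[:, k], fd(m.h, [x, theta, u], 1, k),
                rtol=1e-6, atol=1e-8,
            )

    def test_non_differentiable_rate_rejected(self):
        doc = {
            **DECAY2_DOC,
            "rates": {"x1": "k1*Abs(u) - k2*x1", "x2": "k2*floor(x1) - k3*x2"},
        }
        with pytest.raises((ValidationError, SchemaError)):
            derive(parse_model(doc))


class TestDetectConservation:
    def test_reversible_pair_has_sum_law(self):
        m = parse_model(REVERSIBLE_DOC)
        laws = detect_conservation(m, seed=1)
        assert len(laws) == 1
        c = laws[0].coefficients
        # proportional to (1, 1)
        assert np.allclose(c / c[0], [1.0, 1.0], atol=1e-8)

    def test_decay2_has_no_laws(self):
        m = parse_model(DECAY2_DOC)
        assert detect_conservation(m, seed=1) == []

    def test_frozen_state_is_conserved(self):
        doc = {
            "name": "frozen",
            "states": [{"name": "x", "init": "1"}],
            "parameters": [{"name": "k", "lower": 0.1, "upper": 10}],
            "inputs": [],
            "rates": {"x": "0"},
            "observables": [{"name": "obs", "formula": "x", "noise_formula": "1"}],
        }
        laws = detect_conservation(parse_model(doc), seed=1)
        assert len(laws) == 1
        assert np.allclose(np.abs(laws[0].coefficients), [1.0])

    def test_pure_drift_is_not_conserved(self):
        # dx/dt = k has zero Jacobian but c.f = k != 0: no conservation law
        doc = {
            "name": "drift",
            "states": [{"name": "x", "init": "0"}],
            "parameters": [{"name": "k", "lower": 0.1, "upper": 10}],
            "inputs": [],
            "rates": {"x": "k"},
            "observables": [{"name": "obs", "formula": "x", "noise_formula": "1"}],
        }
        assert detect_conservation(parse_model(doc), seed=1) == []


class TestReduceModel:
    def test_closed_form_steady_state_of_reduced_model(self):
        """Eliminating x2 by the (1,1) law gives dx1/dt = -k1 x1 + k2 (T - x1)
        with steady state x1* = k2 T / (k1 + k2)."""
        m = parse_model(REVERSIBLE_DOC)
        law = ConservationLaw(
            coefficients=np.array([1.0, 1.0]), total_name="T", eliminated_state=1
        )
        red = reduce_model(m, [law])
        assert red.state_names == ["x1"]
        k1, k2, a, b = 1.3, 0.7, 1.0, 2.0
        theta = np.array([k1, k2, a, b])
        x1 = 0.4
        f = red.f(np.array([x1]), theta, np.array([]))
        assert np.isclose(f[0], -k1 * x1 + k2 * ((a + b) - x1))
        x1_star = k2 * (a + b) / (k1 + k2)
        assert np.allclose(red.f(np.array([x1_star]), theta, np.array([])), 0.0)

    def test_symmetric_rates_give_half_total(self):
        m = parse_model(REVERSIBLE_DOC)
        law = ConservationLaw(np.array([1.0, 1.0]), "T", eliminated_state=1)
        red = reduce_model(m, [law])
        theta = np.array([2.0, 2.0, 1.0, 1.0])  # k1 = k2, T = 2
        assert np.allclose(red.f(np.array([1.0]), theta, np.array([])), 0.0)

    def test_empty_laws_is_identity(self):
        m = parse_model(DECAY2_DOC)
        assert reduce_model(m, []) is m

    def test_zero_coefficient_for_eliminated_state_rejected(self):
        m = parse_model(REVERSIBLE_DOC)
        law = ConservationLaw(np.array([1.0, 0.0]), "T", eliminated_state=1)
        with pytest.raises(ValidationError):
            reduce_model(m, [law])

    def test_reduction_preserves_retained_dynamics(self):
        """Trajectories of the retained state match between full and reduced
        models for consistent initial values."""
        m = parse_model(REVERSIBLE_DOC)
        laws = detect_conservation(m, seed=5)
        red = reduce_model(m, laws)
        d_full, d_red = derive(m), derive(red)
        cfg = EquilibrationConfig()
        theta = np.array([1.0, 2.0, 1.5, 0.5])
        t_grid = [0.2, 0.5, 1.0, 2.0]
        full_states, _ = integrate_states(
            m, d_full, theta, np.array([]), m.x0(theta, np.array([])), t_grid, cfg
        )
        red_states, _ = integrate_states(
            red, d_red, theta, np.array([]), red.x0(theta, np.array([])), t_grid, cfg
        )
        kept = [m.state_names.index(s) for s in red.state_names]
        assert np.allclose(full_states[:, kept], red_states, rtol=1e-6, atol=1e-8)

    def test_reduced_jacobian_is_full_rank(self):
        m = parse_model(REVERSIBLE_DOC)
        red = reduce_model(m, detect_conservation(m, seed=5))
        d = derive(red)
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.uniform(0.1, 3.0, red.n_x)
            theta = red.sample_theta(rng)
            svals = np.linalg.svd(d.jac(x, theta, np.array([])), compute_uv=False)
            assert svals.min() > 1e-8 * svals.max()


class TestParameterScales:
    def test_roundtrip_and_gradient_factor(self):
        m = parse_model(DECAY2_DOC)
        theta = np.array([0.01, 1.0, 100.0])
        scaled = m.theta_to_scaled(theta)
        assert np.allclose(scaled, [-2.0, 0.0, 2.0])
        assert np.allclose(m.theta_from_scaled(scaled), theta)
        grad = np.array([1.0, 1.0, 1.0])
        assert np.allclose(
            m.grad_to_scaled(theta, grad), theta * np.log(10.0)
        )
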