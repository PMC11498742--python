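"""Forward sensitivity analysis (FSA).

State sensitivities s_k = dx/dtheta_k obey the linear ODE system obtained by
differentiating the model equations,

    ds_k/dt = (df/dx) s_k + df/dtheta_k,   s_k(t0) = dx0/dtheta_k,

which is integrated *coupled* with the states in one stiff solver call.
At a steady state the left-hand side vanishes, so the sensitivities satisfy
the linear algebraic system

    (df/dx) S = -df/dtheta             (tailored method)

which replaces equilibration-phase sensitivity integration by a single LU
factorization reused for all n_theta right-hand sides. The tailored solve
requires a full-rank Jacobian; a condition estimate above ``cond_limit``
raises TailoredMethodInapplicable instead of returning garbage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import scipy.linalg
from scipy.integrate import solve_ivp

from .errors import SimulationError, TailoredMethodInapplicable
from .steady_state import (
    CONVERGED,
    NEGATIVE_STATE,
    NO_STEADY_STATE,
    NUMERICAL_ERROR,
    DenseTrajectory,
    EquilibrationConfig,
    SteadyStateResult,
    solve_window,
    wrms,
)

__all__ = [
    "SensitivityMatrix",
    "TrajectoryWithSens",
    "integrate_states",
    "integrate_with_fsa",
    "steady_state_sensitivities",
    "equilibrate_with_fsa_by_integration",
]


@dataclass
class SensitivityMatrix:
    """State sensitivities dx/dtheta (n_x x n_theta) at one time point or at
    the steady state (``at_time == "steady_state"``)."""

    values: np.ndarray
    at_time: Union[float, str]


@dataclass
class TrajectoryWithSens:
    """States, sensitivities, outputs and output sensitivities on a time grid."""

    times: np.ndarray  # (n_t,)
    states: np.ndarray  # (n_t, n_x)
    sens: np.ndarray  # (n_t, n_x, n_theta)
    outputs: np.ndarray  # (n_t, n_y)
    output_sens: np.ndarray  # (n_t, n_y, n_theta)


def _check_solution(sol, phase: str):
    if sol.status == -1 or not np.all(np.isfinite(sol.y)):
        raise SimulationError(NUMERICAL_ERROR, phase)


def integrate_states(
    model,
    deriv,
    theta,
    u,
    x0,
    t_grid: Sequence[float],
    config: EquilibrationConfig,
    dense: bool = False,
    phase: str = "dynamic",
):
    """Plain state integration over [0, max(t_grid)].

    Returns ``(states_at_grid, DenseTrajectory or None)``. Raises
    SimulationError with the given phase label on integrator failure.
    """
    theta = np.asarray(theta, dtype=float)
    u = np.asarray(u, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    t_grid = np.asarray(sorted(t_grid), dtype=float)
    if t_grid.size == 0:
        return np.zeros((0, model.n_x)), DenseTrajectory(x_const=x0) if dense else None
    t_end = float(t_grid[-1])
    if t_end == 0.0:
        states = np.tile(x0, (t_grid.size, 1))
        return states, DenseTrajectory(x_const=x0) if dense else None

    try:
        sol = solve_window(
            lambda t, x: model.f(x, theta, u),
            (0.0, t_end),
            x0,
            config,
            jac=lambda t, x: deriv.jac(x, theta, u),
            t_eval=t_grid,
            dense_output=dense,
        )
    except Exception as exc:
        raise SimulationError(NUMERICAL_ERROR, phase, str(exc)) from exc
    _check_solution(sol, phase)
    states = sol.y.T.copy()
    traj = DenseTrajectory(sol=sol.sol, t0=0.0, t_end=t_end) if dense else None
    return states, traj


def integrate_with_fsa(
    model,
    deriv,
    theta,
    u,
    x0,
    s0,
    t_grid: Sequence[float],
    config: EquilibrationConfig,
) -> TrajectoryWithSens:
    """Integrate the augmented state + sensitivity system over a time grid.

    ``s0`` is the initial sensitivity matrix: dx0/dtheta for a plain start,
    or the equilibrated steady-state sensitivities when the dynamic phase
    starts from a pre-equilibrated state. Output sensitivities are assembled
    as dy/dtheta = (dh/dx) S + dh/dtheta at every grid time.
    """
    theta = np.asarray(theta, dtype=float)
    u = np.asarray(u, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    s0 = np.asarray(s0, dtype=float).reshape(model.n_x, model.n_theta)
    t_grid = np.asarray(sorted(t_grid), dtype=float)
    n_x, n_th = model.n_x, model.n_theta

    def assemble(times, states, sens):
        n_t = len(times)
        outputs = np.empty((n_t, model.n_y))
        output_sens = np.empty((n_t, model.n_y, n_th))
        for j in range(n_t):
            x = states[j]
            outputs[j] = model.h(x, theta, u)
            output_sens[j] = deriv.dhdx(x, theta, u) @ sens[j] + deriv.dhdp(x, theta, u)
        return TrajectoryWithSens(
            times=np.asarray(times, float),
            states=np.asarray(states, float),
            sens=np.asarray(sens, float),
            outputs=outputs,
            output_sens=output_sens,
        )

    if t_grid.size == 0:
        return assemble(t_grid, np.zeros((0, n_x)), np.zeros((0, n_x, n_th)))
    t_end = float(t_grid[-1])
    if t_end == 0.0:
        states = np.tile(x0, (t_grid.size, 1))
        sens = np.tile(s0, (t_grid.size, 1, 1))
        return assemble(t_grid, states, sens)

    def rhs(t, z):
        x = z[:n_x]
        S = z[n_x:].reshape(n_x, n_th)
        J = deriv.jac(x, theta, u)
        return np.concatenate(
            [model.f(x, theta, u), (J @ S + deriv.dfdp(x, theta, u)).ravel()]
        )

    z0 = np.concatenate([x0, s0.ravel()])
    try:
        sol = solve_window(rhs, (0.0, t_end), z0, config, t_eval=t_grid)
    except Exception as exc:
        raise SimulationError(NUMERICAL_ERROR, "dynamic", str(exc)) from exc
    _check_solution(sol, "dynamic")
    states = sol.y[:n_x].T.copy()
    sens = sol.y[n_x:].T.reshape(len(t_grid), n_x, n_th).copy()
    return assemble(t_grid, states, sens)


def steady_state_sensitivities(
    deriv, theta, u, x_star, cond_limit: float = 1e12
) -> SensitivityMatrix:
    """Tailored steady-state sensitivities: solve (df/dx) S = -df/dtheta.

    One dense LU factorization serves all n_theta right-hand sides. Raises
    TailoredMethodInapplicable for a rank-deficient or ill-conditioned
    Jacobian (the caller falls back to integration).
    """
    theta = np.asarray(theta, dtype=float)
    u = np.asarray(u, dtype=float)
    x_star = np.asarray(x_star, dtype=float)
    J = deriv.jac(x_star, theta, u)
    if not np.all(np.isfinite(J)):
        raise TailoredMethodInapplicable("non-finite Jacobian at the steady state")
    cond = np.linalg.cond(J)
    if not np.isfinite(cond) or cond > cond_limit:
        raise TailoredMethodInapplicable(
            f"Jacobian condition number {cond:.3g} exceeds {cond_limit:.3g} "
            "(rank-deficient steady-state system; conserved quantities present?)"
        )
    try:
        lu, piv = scipy.linalg.lu_factor(J)
        S = scipy.linalg.lu_solve((lu, piv), -deriv.dfdp(x_star, theta, u))
    except (scipy.linalg.LinAlgError, ValueError) as exc:
        raise TailoredMethodInapplicable(str(exc)) from exc
    return SensitivityMatrix(values=S, at_time="steady_state")


def equilibrate_with_fsa_by_integration(
    model,
    deriv,
    theta,
    u,
    x_init,
    s_init,
    config: EquilibrationConfig,
    phase: str = "posteq",
):
    """Equilibrate the coupled state + sensitivity system by integration.

    Stops at the first accepted point where the *state* WRMS criterion is
    met (optionally also requiring sensitivity WRMS below 1 when
    ``config.sens_wrms`` is set). Returns
    ``(SteadyStateResult, SensitivityMatrix)``.
    """
    import time as _time

    t_start = _time.perf_counter()
    theta = np.asarray(theta, dtype=float)
    u = np.asarray(u, dtype=float)
    x_init = np.asarray(x_init, dtype=float)
    s_init = np.asarray(s_init, dtype=float).reshape(model.n_x, model.n_theta)
    n_x, n_th = model.n_x, model.n_theta

    def elapsed():
        return _time.perf_counter() - t_start

    def error_measure(x, S):
        e = wrms(model.f(x, theta, u), x, config.rtol, config.atol)
        if config.sens_wrms and np.isfinite(e):
            J = deriv.jac(x, theta, u)
            sdot = J @ S + deriv.dfdp(x, theta, u)
            for k in range(n_th):
                ek = wrms(sdot[:, k], S[:, k], config.rtol, config.atol)
                e = max(e, ek)
        return e

    e0 = error_measure(x_init, s_init)
    if not np.isfinite(e0):
        res = SteadyStateResult(
            x_star=x_init, status=NUMERICAL_ERROR, wrms_final=np.inf,
            iterations_or_steps=0, method="integration",
            equilibration_time_elapsed=elapsed(),
        )
        return res, SensitivityMatrix(values=s_init, at_time="steady_state")
    if e0 < 1.0:
        res = SteadyStateResult(
            x_star=x_init, status=CONVERGED, wrms_final=e0,
            iterations_or_steps=0, method="integration",
            equilibration_time_elapsed=elapsed(),
            trajectory=DenseTrajectory(x_const=x_init), t_end=0.0,
        )
        return res, SensitivityMatrix(values=s_init, at_time="steady_state")

    def rhs(t, z):
        x = z[:n_x]
        S = z[n_x:].reshape(n_x, n_th)
        J = deriv.jac(x, theta, u)
        return np.concatenate(
            [model.f(x, theta, u), (J @ S + deriv.dfdp(x, theta, u)).ravel()]
        )

    def converged_event(t, z):
        e = error_measure(z[:n_x], z[n_x:].reshape(n_x, n_th))
        return (e - 1.0) if np.isfinite(e) else 1.0

    converged_event.terminal = True
    converged_event.direction = -1

    z0 = np.concatenate([x_init, s_init.ravel()])
    try:
        sol = solve_ivp(
            rhs,
            (0.0, config.max_time),
            z0,
            method=config.equilibration_solver,
            rtol=config.int_rtol,
            atol=config.int_atol,
            events=[converged_event],
        )
    except Exception:
        res = SteadyStateResult(
            x_star=x_init, status=NUMERICAL_ERROR, wrms_final=np.inf,
            iterations_or_steps=0, method="integration",
            equilibration_time_elapsed=elapsed(),
        )
        return res, SensitivityMatrix(values=s_init, at_time="steady_state")

    n_steps = len(sol.t)
    if sol.status == -1 or not np.all(np.isfinite(sol.y)):
        res = SteadyStateResult(
            x_star=x_init, status=NUMERICAL_ERROR, wrms_final=np.inf,
            iterations_or_steps=n_steps, method="integration",
            equilibration_time_elapsed=elapsed(),
        )
        return res, SensitivityMatrix(values=s_init, at_time="steady_state")

    negative = config.check_negative_trajectory and bool(
        np.min(sol.y[:n_x]) < -config.effective_neg_tol
    )
    if sol.status == 1 and len(sol.t_events[0]):
        t_end = float(sol.t_events[0][0])
        z_star = np.asarray(sol.y_events[0][0], dtype=float)
        status = CONVERGED
    else:
        t_end = float(sol.t[-1])
        z_star = np.asarray(sol.y[:, -1], dtype=float)
        status = NO_STEADY_STATE
    x_star = z_star[:n_x]
    S_star = z_star[n_x:].reshape(n_x, n_th)
    if negative or x_star.min() < -config.effective_neg_tol:
        status = NEGATIVE_STATE
    e_final = wrms(model.f(x_star, theta, u), x_star, config.rtol, config.atol)
    res = SteadyStateResult(
        x_star=x_star, status=status, wrms_final=e_final,
        iterations_or_steps=n_steps, method="integration",
        equilibration_time_elapsed=elapsed(), t_end=t_end,
    )
    return res, SensitivityMatrix(values=S_star, at_time="steady_state")
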