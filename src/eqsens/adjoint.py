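"""Adjoint sensitivity analysis (ASA).

The adjoint state p(t) obeys the backward linear ODE

    dp/dt = -(df/dx)^T p,

with p = 0 beyond the last measurement time and a jump

    p(t_j^-) = p(t_j^+) + sum_i (dh_i/dx)^T (ybar_ij - y_i(t_j)) / sigma_ij^2

at every measurement time. The gradient contribution of the dynamic window is
the quadrature integral(p^T df/dtheta_k dt), carried as n_theta extra backward
ODE components in one augmented solve (no post-hoc interpolation quadrature).

At a steady state with stable, full-rank Jacobian the equilibration-window
quadrature collapses to a linear solve: with

    (df/dx)^T p_integral = -p_boundary

the window contributes -p_integral^T df/dtheta (tailored method). The sign
convention is fixed by exact agreement with the finite-difference oracle on
scalar closed-form problems. For pre-equilibration p_boundary is p(t0) from
the dynamic backward pass (and the dx0/dtheta term vanishes because the
adjoint has decayed at the far end of the window); for post-equilibration
p_boundary is the steady-state residual adjoint and the adjoint handed to the
dynamic pass is zero (infinite-horizon decay).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.linalg

from .errors import SimulationError, TailoredMethodInapplicable
from .steady_state import (
    NUMERICAL_ERROR,
    DenseTrajectory,
    EquilibrationConfig,
    solve_window,
)

__all__ = [
    "AdjointSolution",
    "SteadyStateAdjoint",
    "backward_adjoint",
    "preeq_adjoint_contribution",
    "posteq_adjoint_contribution",
    "posteq_adjoint_by_integration",
]


@dataclass
class AdjointSolution:
    """Adjoint state at the window start and the accumulated quadrature
    integral(p^T df/dtheta dt) over the window."""

    p_t0: np.ndarray  # (n_x,)
    quadrature: np.ndarray  # (n_theta,)
    status: str = "ok"


@dataclass
class SteadyStateAdjoint:
    """Solution of the steady-state linear adjoint system.

    Invariant: (df/dx)^T p_integral + p_boundary = 0 to solver precision.
    """

    p_boundary: np.ndarray
    p_integral: np.ndarray


def backward_adjoint(
    deriv,
    theta,
    u,
    trajectory: DenseTrajectory,
    t_start: float,
    t_end: float,
    jumps: Optional[Sequence[tuple]] = None,
    p_terminal: Optional[np.ndarray] = None,
    config: Optional[EquilibrationConfig] = None,
    phase: str = "adjoint",
) -> AdjointSolution:
    """Integrate the adjoint + quadrature system backward over [t_start, t_end].

    ``trajectory`` supplies the forward states by dense interpolation.
    ``jumps`` is a list of (time, vector) residual jumps applied to p while
    sweeping from t_end down to t_start; a jump exactly at t_start is applied
    after the sweep (so p_t0 includes it). ``p_terminal`` is the adjoint value
    beyond t_end (zero by default; the chained value from a post-equilibration
    window otherwise).
    """
    config = config or EquilibrationConfig()
    theta = np.asarray(theta, dtype=float)
    u = np.asarray(u, dtype=float)
    n_x = deriv.jac_expr.shape[0]
    n_th = deriv.dfdp_expr.shape[1]

    p = (
        np.zeros(n_x)
        if p_terminal is None
        else np.asarray(p_terminal, dtype=float).copy()
    )
    q = np.zeros(n_th)

    jump_map: dict[float, np.ndarray] = {}
    for t_j, vec in jumps or []:
        t_j = float(t_j)
        if not (t_start <= t_j <= t_end):
            raise ValueError(f"jump time {t_j} outside [{t_start}, {t_end}]")
        jump_map[t_j] = jump_map.get(t_j, np.zeros(n_x)) + np.asarray(vec, dtype=float)

    # The adjoint + quadrature system is linear and homogeneous in its
    # boundary data. Normalize to unit magnitude so the integrator's absolute
    # tolerance is meaningful regardless of residual size, and scale back at
    # the end. Zero boundary data short-circuits to the exact zero solution.
    scale = max(
        float(np.max(np.abs(p))) if p.size else 0.0,
        max((float(np.max(np.abs(v))) for v in jump_map.values()), default=0.0),
    )
    if scale == 0.0:
        return AdjointSolution(p_t0=np.zeros(n_x), quadrature=np.zeros(n_th))
    p = p / scale
    jump_map = {t: v / scale for t, v in jump_map.items()}

    def rhs(t, z):
        x = trajectory(t)
        J = deriv.jac(x, theta, u)
        pp = z[:n_x]
        return np.concatenate([-(J.T @ pp), -(deriv.dfdp(x, theta, u).T @ pp)])

    def jac(t, z):
        x = trajectory(t)
        J = deriv.jac(x, theta, u)
        out = np.zeros((n_x + n_th, n_x + n_th))
        out[:n_x, :n_x] = -J.T
        out[n_x:, :n_x] = -deriv.dfdp(x, theta, u).T
        return out

    # The quadrature components integrate p^T df/dtheta and can reach
    # magnitudes ~ |df/dtheta| * window while starting at zero; give them an
    # absolute tolerance proportional to that natural scale so the error
    # control does not demand absurd accuracy at their zero crossing.
    window = max(float(t_end) - float(t_start), 1.0)
    x_end = trajectory(t_end)
    q_rate = float(np.max(np.abs(deriv.dfdp(x_end, theta, u)))) or 1.0
    atol_vec = np.full(n_x + n_th, config.int_atol)
    atol_vec[n_x:] = config.int_atol * max(1.0, q_rate * window)

    def sweep(t_from, t_to, p, q):
        if t_from <= t_to:
            return p, q
        z0 = np.concatenate([p, q])
        try:
            sol = solve_window(
                rhs, (t_from, t_to), z0, config, jac=jac, atol=atol_vec
            )
        except Exception as exc:
            raise SimulationError(NUMERICAL_ERROR, phase, str(exc)) from exc
        if sol is None or sol.status != 0 or not np.all(np.isfinite(sol.y)):
            raise SimulationError(NUMERICAL_ERROR, phase)
        z = sol.y[:, -1]
        return z[:n_x].copy(), z[n_x:].copy()

    cur_t = float(t_end)
    if cur_t in jump_map:
        p = p + jump_map.pop(cur_t)
    for t_j in sorted(jump_map, reverse=True):
        p, q = sweep(cur_t, t_j, p, q)
        cur_t = t_j
        if t_j > t_start:
            p = p + jump_map[t_j]
    p, q = sweep(cur_t, float(t_start), p, q)
    if float(t_start) in jump_map and float(t_start) < float(t_end):
        p = p + jump_map[float(t_start)]  # boundary jump at the window start
    return AdjointSolution(p_t0=p * scale, quadrature=q * scale)


def _steady_state_adjoint_solve(
    deriv, theta, u, x_star, p_boundary, cond_limit: float
) -> tuple[np.ndarray, SteadyStateAdjoint]:
    """Shared tailored solve: (df/dx)^T p_integral = -p_boundary, and the
    gradient increment -p_integral^T df/dtheta at the steady state."""
    theta = np.asarray(theta, dtype=float)
    u = np.asarray(u, dtype=float)
    x_star = np.asarray(x_star, dtype=float)
    p_boundary = np.asarray(p_boundary, dtype=float)
    J = deriv.jac(x_star, theta, u)
    if not np.all(np.isfinite(J)):
        raise TailoredMethodInapplicable("non-finite Jacobian at the steady state")
    cond = np.linalg.cond(J)
    if not np.isfinite(cond) or cond > cond_limit:
        raise TailoredMethodInapplicable(
            f"Jacobian condition number {cond:.3g} exceeds {cond_limit:.3g}"
        )
    try:
        p_integral = scipy.linalg.solve(J.T, -p_boundary)
    except (scipy.linalg.LinAlgError, ValueError) as exc:
        raise TailoredMethodInapplicable(str(exc)) from exc
    increment = -(deriv.dfdp(x_star, theta, u).T @ p_integral)
    return increment, SteadyStateAdjoint(p_boundary=p_boundary, p_integral=p_integral)


def preeq_adjoint_contribution(
    deriv, theta, u_e, x_star_pre, p_t0, cond_limit: float = 1e12
):
    """Tailored pre-equilibration gradient increment.

    Solves (df/dx)^T p_integral = -p(t0) at the pre-equilibration steady
    state under input u^e and returns
    ``(-p_integral^T df/dtheta, SteadyStateAdjoint)``. The adjoint is at
    steady state (p = 0) at the far end of the window, so no dx0/dtheta term
    remains.
    """
    return _steady_state_adjoint_solve(deriv, theta, u_e, x_star_pre, p_t0, cond_limit)


def posteq_adjoint_contribution(
    deriv, theta, u, x_star, p_ss, cond_limit: float = 1e12
):
    """Tailored post-equilibration gradient increment.

    ``p_ss`` is the steady-state residual adjoint
    sum_i (dh_i/dx)^T (ybar_i* - y_i*) / sigma_i*^2. Returns
    ``(-p_integral^T df/dtheta, SteadyStateAdjoint)``; the adjoint handed to
    the dynamic backward pass is zero (it decays over the infinite
    equilibration horizon for a stable Jacobian).
    """
    return _steady_state_adjoint_solve(deriv, theta, u, x_star, p_ss, cond_limit)


def posteq_adjoint_by_integration(
    deriv,
    theta,
    u,
    trajectory: DenseTrajectory,
    t_window: float,
    p_ss,
    config: EquilibrationConfig,
):
    """Post-equilibration gradient increment by backward integration.

    Integrates the adjoint + quadrature system backward over the stored
    equilibration window (local time [0, t_window]) starting from
    p(t_window) = p_ss. Returns ``(increment, p_at_window_start)`` where the
    increment is minus the quadrature and ``p_at_window_start`` is chained
    into the dynamic backward pass as its terminal adjoint value.
    """
    p_ss = np.asarray(p_ss, dtype=float)
    if t_window <= 0:
        return np.zeros(deriv.dfdp_expr.shape[1]), p_ss.copy()
    adj = backward_adjoint(
        deriv,
        theta,
        u,
        trajectory,
        t_start=0.0,
        t_end=float(t_window),
        jumps=None,
        p_terminal=p_ss,
        config=config,
        phase="posteq",
    )
    return -adj.quadrature, adj.p_t0
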