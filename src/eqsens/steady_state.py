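"""Steady-state computation by numerical integration or damped Newton iteration.

The steady state x*(theta, u) is the long-time limit of the initial value
problem. Two methods are provided:

- **integration**: run a stiff (BDF) integrator until the weighted root mean
  square of the state time derivatives,

      wrms = sqrt( (1/n_x) * sum_i (xdot_i * w_i)^2 ),
      w_i  = 1 / (rtol * |x_i| + atol),

  drops below 1. This is robust for asymptotically stable systems but can be
  slow.

- **newton**: damped Newton iteration on f(x) = 0,

      x_{l+1} = x_l - gamma * (df/dx)^{-1} f(x_l),

  where the damping factor gamma grows after steps that reduce the WRMS error
  and shrinks (with the step rejected) otherwise. Fast when it converges, but
  sensitive to the initial guess and may return negative states.

Failures are reported as structured statuses (no exceptions): no steady state
within the horizon, Newton non-convergence, numerical errors, or negative
state variables beyond a small tolerance.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "EquilibrationConfig",
    "SteadyStateResult",
    "DenseTrajectory",
    "wrms",
    "equilibrate_by_integration",
    "equilibrate_by_newton",
    "CONVERGED",
    "NO_STEADY_STATE",
    "NEWTON_NONCONVERGED",
    "NUMERICAL_ERROR",
    "NEGATIVE_STATE",
]

CONVERGED = "converged"
NO_STEADY_STATE = "no_steady_state"
NEWTON_NONCONVERGED = "newton_nonconverged"
NUMERICAL_ERROR = "numerical_error"
NEGATIVE_STATE = "negative_state"


@dataclass
class EquilibrationConfig:
    """Tolerances and iteration controls for equilibration.

    ``rtol``/``atol`` enter the WRMS convergence criterion; ``int_rtol``/
    ``int_atol`` control the local error of every integrator call (dynamic,
    equilibration, sensitivity, adjoint). The WRMS tolerances are kept well
    below 1/max_time so that models with unbounded drift (dx/dt = k) run into
    the horizon cap instead of spuriously satisfying the relative criterion.

    The gamma_* fields define the Newton damping schedule: start at
    ``gamma_init``, multiply by ``gamma_up`` (capped at 1) after an accepted
    step, divide by ``gamma_down`` after a rejected one, give up below
    ``gamma_min``.
    """

    rtol: float = 1e-11
    atol: float = 1e-11
    int_rtol: float = 1e-8
    int_atol: float = 1e-10
    max_time: float = 1e10
    max_steps: int = 1_000_000
    newton_max_iters: int = 100
    gamma_init: float = 1.0
    gamma_min: float = 1e-10
    gamma_up: float = 2.0
    gamma_down: float = 4.0
    neg_tol: Optional[float] = None
    check_negative_trajectory: bool = True
    sens_wrms: bool = False  # strict mode: also gate on sensitivity WRMS
    solver: str = "LSODA"  # finite-window solve_ivp method (falls back to BDF)
    equilibration_solver: str = "BDF"  # long-horizon equilibration solves
    cond_limit: float = 1e12  # condition-number cap for steady-state linear solves
    fd_step: float = 1e-4  # central-difference step on optimization scale

    def __post_init__(self):
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("rtol and atol must be positive")
        if self.int_rtol <= 0 or self.int_atol <= 0:
            raise ValueError("integration tolerances must be positive")
        if not (0 < self.gamma_min <= self.gamma_init <= 1):
            raise ValueError("need 0 < gamma_min <= gamma_init <= 1")
        if self.gamma_up <= 1 or self.gamma_down <= 1:
            raise ValueError("gamma adaptation factors must exceed 1")

    @property
    def effective_neg_tol(self) -> float:
        return self.atol if self.neg_tol is None else self.neg_tol


class DenseTrajectory:
    """Dense forward solution on [t0, t_end] (constant for a zero-length window).

    Evaluation clips to the covered interval, so adjoint passes can query the
    exact window endpoints without extrapolating.
    """

    def __init__(self, sol=None, t0: float = 0.0, t_end: float = 0.0, x_const=None):
        self.sol = sol
        self.t0 = float(t0)
        self.t_end = float(t_end)
        self.x_const = None if x_const is None else np.asarray(x_const, dtype=float)

    def __call__(self, t: float) -> np.ndarray:
        if self.sol is None:
            return self.x_const
        t = min(max(float(t), self.t0), self.t_end)
        return np.asarray(self.sol(t), dtype=float).ravel()


@dataclass
class SteadyStateResult:
    """Outcome of one equilibration attempt."""

    x_star: np.ndarray
    status: str
    wrms_final: float
    iterations_or_steps: int
    method: str
    equilibration_time_elapsed: float
    trajectory: Optional[DenseTrajectory] = None
    t_end: float = 0.0

    @property
    def converged(self) -> bool:
        return self.status == CONVERGED


def solve_window(rhs, t_span, z0, config: EquilibrationConfig, **kwargs):
    """solve_ivp over a finite window with the configured method, retrying
    with BDF when the primary (LSODA) attempt fails. Raises the original
    exception / returns the failed solution only if BDF fails as well."""
    atol = kwargs.pop("atol", config.int_atol)
    try:
        sol = solve_ivp(
            rhs, t_span, z0, method=config.solver,
            rtol=config.int_rtol, atol=atol, **kwargs,
        )
        if sol.status != -1 and np.all(np.isfinite(sol.y)):
            return sol
    except Exception:
        if config.solver == "BDF":
            raise
        sol = None
    if config.solver == "BDF":
        return sol
    return solve_ivp(
        rhs, t_span, z0, method="BDF",
        rtol=config.int_rtol, atol=atol, **kwargs,
    )


def wrms(xdot, x, rtol: float, atol: float) -> float:
    """Weighted root mean square of the state time derivatives.

    Values below 1 declare the state a steady state at tolerances
    (rtol, atol). Returns +inf for non-finite input (numerical-error signal).
    """
    xdot = np.asarray(xdot, dtype=float)
    x = np.asarray(x, dtype=float)
    if xdot.size == 0 or xdot.shape != x.shape:
        raise ValueError("xdot and x must be nonempty vectors of equal length")
    if not (np.all(np.isfinite(xdot)) and np.all(np.isfinite(x))):
        return np.inf
    w = 1.0 / (rtol * np.abs(x) + atol)
    return float(np.sqrt(np.mean((xdot * w) ** 2)))


def equilibrate_by_integration(
    model,
    deriv,
    theta,
    u,
    x_init,
    config: EquilibrationConfig,
    keep_trajectory: bool = False,
) -> SteadyStateResult:
    """Integrate dx/dt = f until the WRMS criterion fires.

    The criterion is evaluated continuously via a terminal integrator event,
    so the first crossing below 1 stops the run. Status semantics:
    ``no_steady_state`` when the horizon or step cap is exhausted first,
    ``negative_state`` when an accepted state dips below -neg_tol,
    ``numerical_error`` on integrator failure.
    """
    t_start = time.perf_counter()
    theta = np.asarray(theta, dtype=float)
    u = np.asarray(u, dtype=float)
    x_init = np.asarray(x_init, dtype=float)

    def elapsed():
        return time.perf_counter() - t_start

    xdot0 = model.f(x_init, theta, u)
    e0 = wrms(xdot0, x_init, config.rtol, config.atol)
    if not np.isfinite(e0):
        return SteadyStateResult(
            x_star=x_init, status=NUMERICAL_ERROR, wrms_final=np.inf,
            iterations_or_steps=0, method="integration",
            equilibration_time_elapsed=elapsed(),
        )
    if e0 < 1.0:
        # convergence is checked before any work: starting at a steady state
        # is a no-op with a zero-length (constant) trajectory
        traj = DenseTrajectory(x_const=x_init) if keep_trajectory else None
        return SteadyStateResult(
            x_star=x_init, status=CONVERGED, wrms_final=e0,
            iterations_or_steps=0, method="integration",
            equilibration_time_elapsed=elapsed(), trajectory=traj, t_end=0.0,
        )

    def rhs(t, x):
        return model.f(x, theta, u)

    def jac(t, x):
        return deriv.jac(x, theta, u)

    def converged_event(t, x):
        e = wrms(model.f(x, theta, u), x, config.rtol, config.atol)
        return (e - 1.0) if np.isfinite(e) else 1.0

    converged_event.terminal = True
    converged_event.direction = -1

    try:
        sol = solve_ivp(
            rhs,
            (0.0, config.max_time),
            x_init,
            method=config.equilibration_solver,
            jac=jac,
            rtol=config.int_rtol,
            atol=config.int_atol,
            events=[converged_event],
            dense_output=keep_trajectory,
        )
    except Exception:
        return SteadyStateResult(
            x_star=x_init, status=NUMERICAL_ERROR, wrms_final=np.inf,
            iterations_or_steps=0, method="integration",
            equilibration_time_elapsed=elapsed(),
        )

    n_steps = len(sol.t)
    if sol.status == -1 or not np.all(np.isfinite(sol.y)):
        return SteadyStateResult(
            x_star=x_init, status=NUMERICAL_ERROR, wrms_final=np.inf,
            iterations_or_steps=n_steps, method="integration",
            equilibration_time_elapsed=elapsed(),
        )

    negative = config.check_negative_trajectory and bool(
        np.min(sol.y) < -config.effective_neg_tol
    )

    if sol.status == 1 and len(sol.t_events[0]):
        t_end = float(sol.t_events[0][0])
        x_star = np.asarray(sol.y_events[0][0], dtype=float)
        e_final = wrms(model.f(x_star, theta, u), x_star, config.rtol, config.atol)
        status = CONVERGED
    else:
        t_end = float(sol.t[-1])
        x_star = np.asarray(sol.y[:, -1], dtype=float)
        e_final = wrms(model.f(x_star, theta, u), x_star, config.rtol, config.atol)
        status = NO_STEADY_STATE

    if negative or x_star.min() < -config.effective_neg_tol:
        status = NEGATIVE_STATE
    if status != NEGATIVE_STATE and n_steps > config.max_steps:
        status = NO_STEADY_STATE

    traj = None
    if keep_trajectory and sol.sol is not None:
        traj = DenseTrajectory(sol=sol.sol, t0=0.0, t_end=t_end)
    return SteadyStateResult(
        x_star=x_star, status=status, wrms_final=e_final,
        iterations_or_steps=n_steps, method="integration",
        equilibration_time_elapsed=elapsed(), trajectory=traj, t_end=t_end,
    )


def equilibrate_by_newton(
    model,
    deriv,
    theta,
    u,
    x_init,
    config: EquilibrationConfig,
) -> SteadyStateResult:
    """Damped Newton iteration on f(x) = 0 with WRMS-based step control.

    A trial step is accepted iff it reduces the WRMS error; on acceptance
    gamma grows (capped at 1), on rejection the step is retried from the same
    iterate with gamma reduced. Status ``newton_nonconverged`` when gamma
    underflows or the iteration cap is hit, ``numerical_error`` on a singular
    or ill-conditioned Jacobian solve or non-finite values, ``negative_state``
    when the accepted solution has entries below -neg_tol.
    """
    t_start = time.perf_counter()
    theta = np.asarray(theta, dtype=float)
    u = np.asarray(u, dtype=float)
    x = np.asarray(x_init, dtype=float).copy()

    def elapsed():
        return time.perf_counter() - t_start

    def result(status, e, iters):
        final_status = status
        if status == CONVERGED and x.min() < -config.effective_neg_tol:
            final_status = NEGATIVE_STATE
        return SteadyStateResult(
            x_star=x, status=final_status, wrms_final=e,
            iterations_or_steps=iters, method="newton",
            equilibration_time_elapsed=elapsed(),
        )

    fx = model.f(x, theta, u)
    e = wrms(fx, x, config.rtol, config.atol)
    if not np.isfinite(e):
        return result(NUMERICAL_ERROR, np.inf, 0)
    if e < 1.0:
        return result(CONVERGED, e, 0)

    gamma = config.gamma_init
    iters = 0
    while iters < config.newton_max_iters:
        J = deriv.jac(x, theta, u)
        if not np.all(np.isfinite(J)):
            return result(NUMERICAL_ERROR, e, iters)
        try:
            cond = np.linalg.cond(J)
            if not np.isfinite(cond) or cond > config.cond_limit:
                return result(NUMERICAL_ERROR, e, iters)
            step = np.linalg.solve(J, fx)
        except np.linalg.LinAlgError:
            return result(NUMERICAL_ERROR, e, iters)

        accepted = False
        while not accepted:
            x_new = x - gamma * step
            if not np.all(np.isfinite(x_new)):
                return result(NUMERICAL_ERROR, e, iters)
            f_new = model.f(x_new, theta, u)
            e_new = wrms(f_new, x_new, config.rtol, config.atol)
            if e_new < e:  # error reduced: accept and re-grow gamma
                x, fx, e = x_new, f_new, e_new
                gamma = min(1.0, gamma * config.gamma_up)
                accepted = True
            else:  # reject, damp, retry from the same iterate
                gamma /= config.gamma_down
                if gamma < config.gamma_min:
                    return result(NEWTON_NONCONVERGED, e, iters)
        iters += 1
        if e < 1.0:
            return result(CONVERGED, e, iters)
    return result(NEWTON_NONCONVERGED, e, iters)
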