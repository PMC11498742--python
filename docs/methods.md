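# Methods

## Model class and assumptions

`eqsens` works with ODE models `dx/dt = f(x, θ, u)`, `x(t₀) = x₀(θ, u)` whose
right-hand side is Lipschitz in `x` and smooth in `θ`, observed through
`y = h(x, θ, u)` with independent Gaussian noise of standard deviation
`σ(θ)` per observable (noise formulas may depend on parameters only). The
negative log-likelihood sums `½[log(2πσ²) + ((ȳ − y)/σ)²]` over dynamic
measurement rows and steady-state rows (`time = inf`) alike. Its θ-gradient
therefore carries, for every row, a noise term
`(1/σ)(1 − r²/σ²) ∂σ/∂θ` and a residual term `−(r/σ²) ∂y/∂θ` — the noise
term includes the `1/σ · ∂σ/∂θ` normalization derivative for steady-state
rows as well, since the steady-state objective carries the same `log(2πσ²)`
normalization; this is verified against the finite-difference oracle on a
fixture with a fitted noise parameter.

Steady states are assumed asymptotically stable attractors of the flow;
oscillatory and chaotic systems are out of scope, as are events and
discontinuous inputs (expressions containing step-like atoms are rejected
at differentiation time with a pointer to `Piecewise` smooth modeling).

All model expressions are stored symbolically and every derivative the
machinery needs (`∂f/∂x`, `∂f/∂θ`, `∂x₀/∂θ`, `∂h/∂x`, `∂h/∂θ`, `∂σ/∂θ`) is
produced by exact sympy differentiation and compiled to numpy callables —
no numeric differencing enters the computational paths.

## Steady-state computation

**Integration.** A stiff BDF integrator runs on `[0, max_time]` with a
terminal event on the weighted root-mean-square criterion

```
wrms(ẋ, x) = sqrt( (1/n_x) Σᵢ (ẋᵢ wᵢ)² ) < 1,   wᵢ = 1 / (rtol·|xᵢ| + atol),
```

where the absolute value in the weight keeps it positive for transiently
negative states. The criterion is evaluated on the continuous solution, so
the run stops at the first crossing. Convergence is checked once at the
initial state before any work, so starting at a fixed point is a no-op.

Defaults: `rtol = atol = 1e-11`, `max_time = 1e10`, `max_steps = 1e6`. The
WRMS tolerances are deliberately below `1/max_time`: for a model with
constant drift (`dx/dt = k`, `x = kt`) the relative weight shrinks as the
state grows and the criterion would be met spuriously at `t ≈ 1/rtol`;
keeping `1/rtol > max_time` guarantees such models terminate with the
`no_steady_state` status instead.

**Damped Newton.** Iterates `x ← x − γ (∂f/∂x)⁻¹ f(x)` with the WRMS value
as the error measure: a trial step is accepted only if it reduces the
error, upon which `γ ← min(1, 2γ)`; otherwise the step is rejected and
retried with `γ ← γ/4`. The schedule (`γ₀ = 1`, growth 2, backoff 4,
`γ_min = 1e-10`, 100 iterations) is config-exposed; aggressive re-growth
with strong backoff mirrors common damped-Newton practice. A singular or
ill-conditioned Jacobian solve (condition estimate above `1e12`) or a
non-finite iterate yields `numerical_error`; `γ` underflow or the iteration
cap yields `newton_nonconverged`.

**Failure taxonomy.** Both methods report structured statuses rather than
exceptions: `converged`, `no_steady_state`, `newton_nonconverged`,
`numerical_error`, and `negative_state`. The negative-state check covers
all accepted integrator states and the final steady state (configurable);
its tolerance `neg_tol` defaults to the WRMS `atol`, so integrator-level
undershoots below zero do not count as failures while genuinely negative
Newton solutions do.

## Sensitivities at steady state

**Forward (FSA).** The sensitivity ODEs
`ṡₖ = (∂f/∂x)sₖ + ∂f/∂θₖ, sₖ(t₀) = ∂x₀/∂θₖ` are integrated coupled with the
states in one solver call. At a steady state they reduce to the linear
system `(∂f/∂x) S = −∂f/∂θ`, solved with one dense LU factorization for all
right-hand sides (the *tailored* method). The equilibration stopping rule
gates on the state WRMS only; a strict mode additionally requiring
sensitivity WRMS below 1 is available behind `sens_wrms` (off by default —
the fixtures' sensitivities converge on the same timescale as the states,
and the tailored cross-checks bound the residual slack).

**Adjoint (ASA).** The adjoint ODE `ṗ = −(∂f/∂x)ᵀp` is integrated backward
from the last measurement time with jumps
`Σᵢ (∂hᵢ/∂x)ᵀ rᵢⱼ/σᵢⱼ²` at each measurement time, while the gradient
quadrature `∫ pᵀ ∂f/∂θ dt` is carried as extra backward ODE components in
the same augmented solve. Forward states are supplied to the backward pass
by dense interpolation of the stored forward solution (the models this
package targets are small; no checkpointing scheme is needed). For the
equilibration windows:

- *post-equilibration*: the window quadrature reduces to
  `−p_integralᵀ ∂f/∂θ` with `(∂f/∂x)ᵀ p_integral = −p_ss`, where `p_ss` is
  the steady-state residual adjoint; the adjoint handed to the dynamic
  backward pass is zero, because for a stable Jacobian the steady-state
  adjoint decays over the infinite equilibration horizon. The
  integration-based variant integrates backward over the stored
  equilibration window starting from `p(t″) = p_ss` and chains the decayed
  `p(t_nt)` into the dynamic pass — the two routes agree to the stopping
  slack, which the test suite asserts.
- *pre-equilibration*: after the dynamic backward pass delivers `p(t₀)`,
  the pre-equilibration window contributes `−p_integralᵀ ∂f/∂θ` evaluated
  under the pre-equilibration input, with
  `(∂f/∂x)ᵀ p_integral = −p(t₀)`; the `∂x₀/∂θ` boundary term vanishes
  because the adjoint is at steady state (zero) at the far end of the
  window. When pre- and post-equilibration occur in the same condition the
  contributions chain: posteq window → dynamic window → preeq window.

The sign convention of the tailored contributions (`−p_integralᵀ∂f/∂θ` with
the linear system as above) is pinned by exact agreement with the
finite-difference oracle on scalar problems with closed-form gradients.

Both tailored solves require a full-rank steady-state Jacobian. Gradient
dispatch performs an up-front structural check — conserved-quantity
detection, cached per model — and reports `tailored_method_inapplicable`
for all four tailored pairs on models with conserved totals; runtime
condition estimates above `1e12` trigger the same status for non-structural
rank deficiency instead of returning garbage.

## Conserved quantities and model reduction

A conservation law is a vector `c` with `cᵀf(x, θ, u) = 0` everywhere,
equivalently `c` in the common left null space of the Jacobian. Detection
is numeric (the model dialect stores general rate expressions, not a
stoichiometric matrix): Jacobians at ≥ `2n_x + 2` random probe points
(states and inputs log-uniform around one, θ uniform on its declared scale
within bounds) are stacked and SVD-thresholded at `1e-10` relative; each
candidate is normalized so the largest-magnitude coefficient is one and
verified by the residual `|cᵀf|` at all probes, which rejects
constant-but-nonzero drift directions (`dx/dt = k`). With multiple
conservation laws the orthonormal null-space basis may mix directions whose
individual residuals differ; the fixtures here carry at most one law.

Reduction substitutes, per law, the state with the largest coefficient
(ties to the lowest index, keeping the substitution well-conditioned) by
`(T − Σ other weighted states)/c_elim`. The conserved total `T` is
substituted symbolically as `cᵀx₀(θ, u)` — rather than materialized as a
new parameter — so the parameter vector, bounds, and gradient dimensions
are unchanged and any θ-dependence of the total flows through the chain
rule exactly. Passing a numeric reference state instead freezes `T` to a
constant. Reduction preserves the dynamics of the retained states and
restores a full-rank Jacobian, both asserted by tests.

## Numerical choices

- **Solvers.** Long-horizon equilibration uses BDF; finite-window solves
  (dynamic phase, backward adjoint sweeps) use LSODA and retry with BDF on
  failure. Defaults `int_rtol = 1e-8`, `int_atol = 1e-10` for every
  integrator call.
- **Backward-pass scaling.** The adjoint + quadrature system is linear and
  homogeneous in its boundary data, so the boundary adjoint and all jumps
  are normalized to unit magnitude before integration and the results
  scaled back. The quadrature components additionally receive an absolute
  tolerance proportional to `max|∂f/∂θ| × window length`; without these two
  measures the error control demands absurd accuracy at the quadrature's
  zero crossing and the solver can abort at the first step for large
  residuals.
- **Finite-difference oracle.** Central differences with step `1e-4` on the
  optimization scale, simulated at integration tolerances tightened to
  `1e-10/1e-12` regardless of the run configuration, keeping the
  differencing noise near `1e-7` relative — two orders below the `1e-4`
  agreement bands it arbitrates.
- **Gradient scale.** Gradients are assembled in linear parameter space and
  converted at the boundary (`∂J/∂log₁₀θ = θ ln10 ∂J/∂θ`), keeping the
  sensitivity formulas literal.
- **Degenerate inputs.** Zero-length equilibration windows (start at the
  fixed point) yield constant trajectories and exact zero quadratures; a
  measurement at `t₀` is applied as an adjoint jump after the backward
  sweep, so it reaches the initial-state gradient term.

## Benchmark harness

The harness mirrors a method-comparison study design at desk scale: `n`
parameter vectors sampled uniformly on each parameter's declared scale
(log-uniform for log10 parameters), every method pair evaluated per vector,
failures tabulated by category (a vector fails as soon as any of its
conditions' phases fails), and gradients of mutually successful samples
compared pairwise. Because gradient entries are signed and the comparison
is done on log-transformed data, the Pearson correlation is computed on
`log₁₀|g|` with entries below `1e-12` excluded, sign mismatches counted
separately, and an untransformed correlation reported alongside; maximum
and median deviations are elementwise relative deviations with floor
`1e-12`. Timings are split into equilibration, dynamic, and overhead; they
are diagnostic output only and never asserted by tests.

## Fixtures and synthetic data

Five built-in models (n_x ≤ 3) with closed-form steady states cover all
code paths: a driven two-state decay chain (`decay2`), a scalar relaxation
with fitted noise parameter (`scalar_relax`), a reversible isomerization
with conserved total and θ-dependent initial values (`reversible_pair`), a
three-state cascade whose pre-equilibration input differs from the
dynamic-phase input (`cascade_preeq`), and a pure drift model with no
steady state (`no_steady_state`). Rate-constant bounds span six decades
(log10 in `[1e-3, 1e3]`), the ranges typical of kinetic parameter
estimation; generating parameters are of order one. The synthetic-data
generator simulates the fixture and adds i.i.d. Gaussian noise
(reproducible per seed); with zero noise it emits exact model outputs.

These fixtures are linear in the states, so Newton converges in one
iteration wherever its linear solve is regular — passing tests demonstrate
the correctness of the machinery (equality of the six gradient routes,
failure classification, conservation handling), not the robustness
differences between methods that only nonlinear, ill-conditioned real-world
models expose. Wall-clock comparisons on these fixtures likewise indicate
only the expected ordering (tailored ≪ integrated equilibration cost), not
transferable speedup magnitudes.

Problem sizes used by the shipped evaluation: gradient agreement over four
fixtures × 10 parameter draws × six pairs against the FD oracle; failure
rates over 100 draws (decay2) and 20 draws (drift fixture); parameter
recovery from 20 data points (noise sd 0.01, measurement grid log-spaced
over `[0.1, 10]` so both relaxation rates are resolved) with 10 multi-start
runs of scipy's `trust-constr` (a trust-region method, the family commonly
used for kinetic model calibration) on log10 coordinates.

## Known limitations

- Conservation detection validates candidate directions individually;
  models with several interacting conservation laws may need the candidate
  basis rotated before the residual check.
- Steady-state logic presumes asymptotic stability; marginally stable or
  oscillatory systems will either time out (`no_steady_state`) or pass the
  WRMS gate spuriously near a slow manifold.
- The noise model is additive Gaussian with parameter-only σ; per-row noise
  overrides and non-Gaussian likelihoods are not supported.
- The data layer accepts only the PEtab column subset documented in `io`;
  full PEtab problems (SBML models, observable/noise parameter columns) are
  rejected with a message rather than partially interpreted.
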