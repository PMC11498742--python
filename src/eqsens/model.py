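"""Symbolic ODE model container, exact derivatives, and conserved-quantity removal.

A model is the initial value problem

    dx/dt = f(x, theta, u),    x(t0) = x0(theta, u),

with states ``x`` (e.g. species abundances), unknown parameters ``theta``
(e.g. rate constants), and known inputs ``u`` encoding experimental
conditions (stimuli, medium composition, ...). Observations are
``y = h(x, theta, u)`` with Gaussian noise of standard deviation
``sigma(theta)`` per observable.

All expressions are held symbolically (sympy) so that every derivative the
sensitivity machinery needs — the Jacobian df/dx, df/dtheta, dx0/dtheta,
dh/dx, dh/dtheta, dsigma/dtheta — is produced by exact differentiation,
never by numeric differencing.

Linear combinations of states with identically zero time derivative
(conserved moieties) make the Jacobian rank-deficient, which rules out
Newton's method and the tailored steady-state sensitivity solves. They are
detected numerically from the common left null space of Jacobian evaluations
at random probe points and removed by substituting one state per law.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import sympy as sp
import yaml
from sympy.parsing.sympy_parser import parse_expr

from .errors import SchemaError, ValidationError

__all__ = [
    "Parameter",
    "Observable",
    "Condition",
    "ConservationLaw",
    "OdeModel",
    "DerivativeSet",
    "parse_model",
    "derive",
    "detect_conservation",
    "reduce_model",
]

SCALE_LIN = "lin"
SCALE_LOG10 = "log10"
_SCALES = (SCALE_LIN, SCALE_LOG10)

#: functions usable inside model expressions
_FUNCTIONS = {
    name: getattr(sp, name)
    for name in (
        "exp",
        "log",
        "sqrt",
        "sin",
        "cos",
        "tan",
        "sinh",
        "cosh",
        "tanh",
        "Abs",
        "Min",
        "Max",
        "Piecewise",
    )
}

#: atoms whose exact derivative is a distribution / undefined — rejected by derive()
_NON_DIFFERENTIABLE = (sp.Heaviside, sp.DiracDelta, sp.floor, sp.ceiling, sp.sign)


def _parse_expression(text, symbols: Mapping[str, sp.Symbol], context: str = "") -> sp.Expr:
    """Parse ``text`` against a closed symbol table; unknown names are an error."""
    try:
        expr = parse_expr(
            str(text), local_dict={**_FUNCTIONS, **symbols}, evaluate=True
        )
    except (SyntaxError, TypeError, ValueError) as exc:
        raise SchemaError(f"cannot parse expression {text!r}{context}: {exc}") from exc
    expr = sp.sympify(expr)
    declared = set(symbols.values())
    unknown = sorted(str(s) for s in expr.free_symbols - declared)
    if unknown:
        raise SchemaError(
            f"undeclared symbol(s) {', '.join(unknown)} in expression {text!r}{context}"
        )
    return expr


def _compile(groups: Sequence[Sequence[sp.Symbol]], exprs) -> callable:
    """Compile expressions into a numpy function of grouped vector arguments.

    ``groups`` is e.g. ``(x_syms, p_syms, u_syms)``; the returned callable takes
    one 1-d array per group. Column vectors are returned raveled, matrices with
    their symbolic shape.
    """
    is_vector = not isinstance(exprs, sp.MatrixBase)  # lists compile to 1-d output
    mat = exprs if isinstance(exprs, sp.MatrixBase) else sp.Matrix(exprs)
    shape = mat.shape
    flat_syms = [s for g in groups for s in g]
    fn = sp.lambdify(flat_syms, mat, modules="numpy")
    n_per_group = [len(g) for g in groups]

    def call(*args):
        if len(args) != len(n_per_group):
            raise TypeError(
                f"expected {len(n_per_group)} argument groups, got {len(args)}"
            )
        vals: list[float] = []
        for arr, n in zip(args, n_per_group):
            a = np.asarray(arr, dtype=float).ravel()
            if a.size != n:
                raise ValueError(f"argument of length {a.size}, expected {n}")
            vals.extend(a.tolist())
        out = np.asarray(fn(*vals), dtype=float)
        return out.ravel() if is_vector else out.reshape(shape)

    return call


@dataclass(frozen=True)
class Parameter:
    """An unknown model parameter with box bounds on linear scale.

    ``scale`` selects the coordinate used for sampling and optimization
    (``lin`` or ``log10``); model expressions always see the linear value.
    """

    name: str
    lower: float
    upper: float
    scale: str = SCALE_LIN

    def __post_init__(self):
        if self.scale not in _SCALES:
            raise ValidationError(
                f"parameter {self.name!r}: scale must be one of {_SCALES}, got {self.scale!r}"
            )
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise ValidationError(f"parameter {self.name!r}: bounds must be finite")
        if self.lower > self.upper:
            raise ValidationError(
                f"parameter {self.name!r}: lower bound exceeds upper bound"
            )
        if self.scale == SCALE_LOG10 and self.lower <= 0:
            raise ValidationError(
                f"parameter {self.name!r}: log10 scale requires positive bounds"
            )


@dataclass(frozen=True)
class Observable:
    """Observation map entry: ``y = formula(x, theta, u)`` with noise sd
    ``noise_formula(theta)``."""

    name: str
    formula: sp.Expr
    noise_formula: sp.Expr


@dataclass
class Condition:
    """One experimental condition: values for every declared input, plus an
    optional reference to the condition providing the pre-equilibration input
    vector u^e."""

    condition_id: str
    input_values: dict
    preeq_condition_id: Optional[str] = None


@dataclass
class ConservationLaw:
    """A linear combination c of states with c.f identically zero.

    ``total_name`` labels the conserved total c.x0(theta, u);
    ``eliminated_state`` is the index of the state removed by reduce_model.
    """

    coefficients: np.ndarray
    total_name: str
    eliminated_state: int


class OdeModel:
    """Validated ODE model with compiled numeric evaluators.

    Evaluators (all take/return 1-d float arrays):

    - ``f(x, theta, u)``       right-hand side, length n_x
    - ``x0(theta, u)``         initial state, length n_x
    - ``h(x, theta, u)``       observables, length n_y
    - ``sigma(theta)``         noise standard deviations, length n_y
    """

    def __init__(
        self,
        name: str,
        state_names: Sequence[str],
        init_exprs: Sequence[sp.Expr],
        parameters: Sequence[Parameter],
        input_names: Sequence[str],
        rhs_exprs: Sequence[sp.Expr],
        observables: Sequence[Observable],
    ):
        if len(state_names) < 1:
            raise ValidationError("model must declare at least one state")
        if len(parameters) < 1:
            raise ValidationError("model must declare at least one parameter")
        if len(observables) < 1:
            raise ValidationError("model must declare at least one observable")
        if len(init_exprs) != len(state_names) or len(rhs_exprs) != len(state_names):
            raise ValidationError("init/rhs expression count must match state count")

        names = (
            list(state_names)
            + [p.name for p in parameters]
            + list(input_names)
        )
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise SchemaError(f"duplicate identifier(s): {sorted(dupes)}")

        self.name = name
        self.state_names = list(state_names)
        self.parameters = list(parameters)
        self.parameter_names = [p.name for p in parameters]
        self.input_names = list(input_names)
        self.rhs_exprs = [sp.sympify(e) for e in rhs_exprs]
        self.init_exprs = [sp.sympify(e) for e in init_exprs]
        self.observables = list(observables)
        self.observable_names = [o.name for o in observables]

        self.x_syms = [sp.Symbol(s) for s in self.state_names]
        self.p_syms = [sp.Symbol(s) for s in self.parameter_names]
        self.u_syms = [sp.Symbol(s) for s in self.input_names]

        self.lower = np.array([p.lower for p in parameters], dtype=float)
        self.upper = np.array([p.upper for p in parameters], dtype=float)
        self.scales = [p.scale for p in parameters]

        self._check_closure()

        xpu = (self.x_syms, self.p_syms, self.u_syms)
        pu = (self.p_syms, self.u_syms)
        self.f = _compile(xpu, self.rhs_exprs)
        self.x0 = _compile(pu, self.init_exprs)
        self.h = _compile(xpu, [o.formula for o in self.observables])
        self.sigma = _compile((self.p_syms,), [o.noise_formula for o in self.observables])

        # filled lazily by objective-side applicability checks
        self._conservation_cache = None

        self._validate_sigma_positive()

    # -- shape accessors ---------------------------------------------------
    @property
    def n_x(self) -> int:
        return len(self.state_names)

    @property
    def n_theta(self) -> int:
        return len(self.parameter_names)

    @property
    def n_u(self) -> int:
        return len(self.input_names)

    @property
    def n_y(self) -> int:
        return len(self.observables)

    # -- validation --------------------------------------------------------
    def _check_closure(self):
        allowed_xpu = set(self.x_syms) | set(self.p_syms) | set(self.u_syms)
        allowed_pu = set(self.p_syms) | set(self.u_syms)
        allowed_p = set(self.p_syms)
        for label, exprs, allowed in (
            ("rate", self.rhs_exprs, allowed_xpu),
            ("init", self.init_exprs, allowed_pu),
            ("observable", [o.formula for o in self.observables], allowed_xpu),
            ("noise", [o.noise_formula for o in self.observables], allowed_p),
        ):
            for expr in exprs:
                extra = sorted(str(s) for s in expr.free_symbols - allowed)
                if extra:
                    raise SchemaError(
                        f"undeclared or disallowed symbol(s) {', '.join(extra)} "
                        f"in {label} expression {expr}"
                    )

    def _validate_sigma_positive(self, n_samples: int = 16, seed: int = 0):
        """Noise sds must be positive anywhere inside the bounds (checked by
        sampling; noise formulas depend on theta only)."""
        rng = np.random.default_rng(seed)
        for _ in range(n_samples):
            theta = self.sample_theta(rng)
            sig = self.sigma(theta)
            if not np.all(np.isfinite(sig)) or np.any(sig <= 0):
                raise ValidationError(
                    f"noise formula evaluates non-positive at theta={theta}"
                )

    # -- parameter-scale helpers -------------------------------------------
    def theta_to_scaled(self, theta: np.ndarray) -> np.ndarray:
        """Linear-scale theta -> optimization-scale coordinates."""
        theta = np.asarray(theta, dtype=float)
        out = theta.copy()
        for k, scale in enumerate(self.scales):
            if scale == SCALE_LOG10:
                out[k] = np.log10(theta[k])
        return out

    def theta_from_scaled(self, scaled: np.ndarray) -> np.ndarray:
        """Optimization-scale coordinates -> linear-scale theta."""
        scaled = np.asarray(scaled, dtype=float)
        out = scaled.copy()
        for k, scale in enumerate(self.scales):
            if scale == SCALE_LOG10:
                out[k] = 10.0 ** scaled[k]
        return out

    def grad_to_scaled(self, theta: np.ndarray, grad: np.ndarray) -> np.ndarray:
        """Chain rule dJ/d(log10 theta_k) = theta_k * ln(10) * dJ/dtheta_k."""
        theta = np.asarray(theta, dtype=float)
        grad = np.asarray(grad, dtype=float)
        factor = np.ones_like(grad)
        for k, scale in enumerate(self.scales):
            if scale == SCALE_LOG10:
                factor[k] = theta[k] * np.log(10.0)
        return grad * factor

    def sample_theta(self, rng: np.random.Generator) -> np.ndarray:
        """One parameter vector drawn uniformly on each parameter's declared
        scale, returned on linear scale."""
        out = np.empty(self.n_theta)
        for k, (lo, hi, scale) in enumerate(zip(self.lower, self.upper, self.scales)):
            if scale == SCALE_LOG10:
                out[k] = 10.0 ** rng.uniform(np.log10(lo), np.log10(hi))
            else:
                out[k] = rng.uniform(lo, hi)
        return out

    def condition_inputs(self, condition: Condition) -> np.ndarray:
        """Ordered input vector u for a condition; every declared input must
        be assigned."""
        missing = [n for n in self.input_names if n not in condition.input_values]
        if missing:
            raise ValidationError(
                f"condition {condition.condition_id!r} misses input(s) {missing}"
            )
        return np.array(
            [float(condition.input_values[n]) for n in self.input_names], dtype=float
        )

    def __repr__(self):
        return (
            f"OdeModel({self.name!r}, n_x={self.n_x}, n_theta={self.n_theta}, "
            f"n_u={self.n_u}, n_y={self.n_y})"
        )


@dataclass
class DerivativeSet:
    """All first-order symbolic derivatives of a model, with compiled evaluators.

    Shapes: jac (n_x, n_x), dfdp (n_x, n_theta), dx0dp (n_x, n_theta),
    dhdx (n_y, n_x), dhdp (n_y, n_theta), dsigmadp (n_y, n_theta).
    """

    jac_expr: sp.Matrix
    dfdp_expr: sp.Matrix
    dx0dp_expr: sp.Matrix
    dhdx_expr: sp.Matrix
    dhdp_expr: sp.Matrix
    dsigmadp_expr: sp.Matrix
    jac: callable = field(repr=False, default=None)
    dfdp: callable = field(repr=False, default=None)
    dx0dp: callable = field(repr=False, default=None)
    dhdx: callable = field(repr=False, default=None)
    dhdp: callable = field(repr=False, default=None)
    dsigmadp: callable = field(repr=False, default=None)


def derive(model: OdeModel) -> DerivativeSet:
    """Exact symbolic differentiation of f, x0, h, sigma.

    Raises ValidationError for expressions containing non-differentiable
    atoms (step functions etc.) — rewrite them as Piecewise with smooth
    branches instead.
    """
    all_exprs = (
        model.rhs_exprs
        + model.init_exprs
        + [o.formula for o in model.observables]
        + [o.noise_formula for o in model.observables]
    )
    for expr in all_exprs:
        if any(expr.has(a) for a in _NON_DIFFERENTIABLE):
            raise ValidationError(
                f"expression {expr} contains a non-differentiable function; "
                "model it with Piecewise smooth branches instead"
            )

    F = sp.Matrix(model.rhs_exprs)
    X0 = sp.Matrix(model.init_exprs)
    H = sp.Matrix([o.formula for o in model.observables])
    SIG = sp.Matrix([o.noise_formula for o in model.observables])

    jac_expr = F.jacobian(model.x_syms)
    dfdp_expr = F.jacobian(model.p_syms)
    dx0dp_expr = X0.jacobian(model.p_syms)
    dhdx_expr = H.jacobian(model.x_syms)
    dhdp_expr = H.jacobian(model.p_syms)
    dsigmadp_expr = SIG.jacobian(model.p_syms)

    xpu = (model.x_syms, model.p_syms, model.u_syms)
    pu = (model.p_syms, model.u_syms)
    return DerivativeSet(
        jac_expr=jac_expr,
        dfdp_expr=dfdp_expr,
        dx0dp_expr=dx0dp_expr,
        dhdx_expr=dhdx_expr,
        dhdp_expr=dhdp_expr,
        dsigmadp_expr=dsigmadp_expr,
        jac=_compile(xpu, jac_expr),
        dfdp=_compile(xpu, dfdp_expr),
        dx0dp=_compile(pu, dx0dp_expr),
        dhdx=_compile(xpu, dhdx_expr),
        dhdp=_compile(xpu, dhdp_expr),
        dsigmadp=_compile((model.p_syms,), dsigmadp_expr),
    )


def parse_model(document) -> OdeModel:
    """Build a validated OdeModel from the YAML model dialect.

    ``document`` may be a YAML string or an already-loaded mapping with keys
    ``states`` (name, init), ``parameters`` (name, lower, upper, scale),
    ``inputs``, ``rates`` (state -> expression), ``observables``
    (name, formula, noise_formula).
    """
    if isinstance(document, (str, bytes)):
        doc = yaml.safe_load(document)
    else:
        doc = dict(document)
    if not isinstance(doc, dict):
        raise SchemaError("model document must be a mapping")

    name = str(doc.get("name", "model"))

    states_doc = doc.get("states") or []
    if not states_doc:
        raise ValidationError("model must declare at least one state")
    state_names = []
    init_texts = []
    for entry in states_doc:
        if "name" not in entry:
            raise SchemaError("every state needs a 'name'")
        state_names.append(str(entry["name"]))
        init_texts.append(entry.get("init", 0))

    params_doc = doc.get("parameters") or []
    if not params_doc:
        raise ValidationError("model must declare at least one parameter")
    parameters = [
        Parameter(
            name=str(entry["name"]),
            lower=float(entry["lower"]),
            upper=float(entry["upper"]),
            scale=str(entry.get("scale", SCALE_LIN)),
        )
        for entry in params_doc
    ]

    input_names = [str(n) for n in (doc.get("inputs") or [])]

    symbols = {
        n: sp.Symbol(n)
        for n in state_names + [p.name for p in parameters] + input_names
    }

    rates_doc = doc.get("rates") or {}
    missing = [s for s in state_names if s not in rates_doc]
    if missing:
        raise SchemaError(f"missing rate expression for state(s): {missing}")
    extra = [s for s in rates_doc if s not in state_names]
    if extra:
        raise SchemaError(f"rate expression(s) for undeclared state(s): {extra}")
    rhs_exprs = [
        _parse_expression(rates_doc[s], symbols, context=f" (rate of {s})")
        for s in state_names
    ]
    init_exprs = [
        _parse_expression(t, symbols, context=f" (init of {s})")
        for s, t in zip(state_names, init_texts)
    ]

    obs_doc = doc.get("observables") or []
    if not obs_doc:
        raise ValidationError("model must declare at least one observable")
    observables = []
    for entry in obs_doc:
        observables.append(
            Observable(
                name=str(entry["name"]),
                formula=_parse_expression(
                    entry["formula"], symbols, context=f" (observable {entry['name']})"
                ),
                noise_formula=_parse_expression(
                    entry.get("noise_formula", 1.0),
                    symbols,
                    context=f" (noise of {entry['name']})",
                ),
            )
        )

    return OdeModel(
        name=name,
        state_names=state_names,
        init_exprs=init_exprs,
        parameters=parameters,
        input_names=input_names,
        rhs_exprs=rhs_exprs,
        observables=observables,
    )


def detect_conservation(
    model: OdeModel,
    n_probes: Optional[int] = None,
    seed: int = 0,
    deriv: Optional[DerivativeSet] = None,
    svd_rtol: float = 1e-10,
    residual_tol: float = 1e-8,
) -> list[ConservationLaw]:
    """Numerically find conserved linear combinations of states.

    A vector c is a conservation law iff c.f(x, theta, u) = 0 for all x,
    theta, u — equivalently c lies in the common left null space of the
    Jacobian at all points. We stack Jacobian evaluations at random probe
    points (states and inputs log-uniform around 1, theta uniform on its
    declared scale inside the bounds), take the SVD null space at relative
    threshold ``svd_rtol``, and keep candidates whose residual |c.f| is
    below ``residual_tol`` relative to |c|.|f| at every probe. The residual
    check rejects directions with constant-but-nonzero drift (e.g. dx/dt = k).
    """
    n_probes = n_probes if n_probes is not None else max(2 * model.n_x + 2, 5)
    if n_probes < model.n_x:
        raise ValidationError("n_probes must be at least the number of states")
    deriv = deriv if deriv is not None else derive(model)
    rng = np.random.default_rng(seed)

    probes = []
    for _ in range(n_probes):
        x = 10.0 ** rng.uniform(-1.0, 1.0, size=model.n_x)
        theta = model.sample_theta(rng)
        u = 10.0 ** rng.uniform(-0.5, 0.5, size=model.n_u)
        probes.append((x, theta, u))

    stacked = np.vstack([deriv.jac(x, th, u).T for (x, th, u) in probes])
    _, svals, vt = np.linalg.svd(stacked, full_matrices=False)
    smax = svals.max() if svals.size and svals.max() > 0 else 1.0
    candidates = [vt[i] for i in range(len(svals)) if svals[i] <= svd_rtol * smax]

    laws: list[ConservationLaw] = []
    existing = set(
        model.state_names + model.parameter_names + model.input_names
    )
    for c in candidates:
        elim = int(np.argmax(np.abs(c)))
        c = c / c[elim]  # normalize so the eliminated state's coefficient is 1
        ok = True
        for x, th, u in probes:
            fvec = model.f(x, th, u)
            denom = float(np.abs(c) @ np.abs(fvec))
            if abs(float(c @ fvec)) > residual_tol * max(denom, 1e-30):
                ok = False
                break
        if not ok:
            continue
        total_name = f"{model.state_names[elim]}_total"
        while total_name in existing:
            total_name += "_"
        existing.add(total_name)
        laws.append(
            ConservationLaw(
                coefficients=np.asarray(c, dtype=float),
                total_name=total_name,
                eliminated_state=elim,
            )
        )
    return laws


def _nice_number(v: float) -> sp.Expr:
    """Snap a floating coefficient to a nearby rational when one exists."""
    r = sp.nsimplify(v, rational=True, tolerance=1e-9)
    if abs(float(r) - v) <= 1e-9 * max(1.0, abs(v)):
        return r
    return sp.Float(v)


def reduce_model(
    model: OdeModel,
    laws: Sequence[ConservationLaw],
    reference_state: Optional[np.ndarray] = None,
) -> OdeModel:
    """Remove one state per conservation law so the Jacobian becomes full rank.

    Each eliminated state is replaced in every expression by
    ``(total - sum of the other weighted states) / its coefficient``, where
    the conserved total is the symbolic combination c.x0(theta, u) (or the
    numeric constant c.reference_state when a reference state vector is
    given). Dynamics of the retained states are unchanged.
    """
    if not laws:
        return model
    elim_indices = [law.eliminated_state for law in laws]
    if len(set(elim_indices)) != len(elim_indices):
        raise ValidationError("eliminated states of the laws must be distinct")
    for law in laws:
        if law.coefficients[law.eliminated_state] == 0:
            raise ValidationError(
                "zero coefficient for the eliminated state "
                f"({model.state_names[law.eliminated_state]})"
            )

    subs = {}
    for law in laws:
        c = law.coefficients
        e = law.eliminated_state
        if reference_state is not None:
            total_expr = sp.Float(float(np.dot(c, np.asarray(reference_state, float))))
        else:
            total_expr = sp.Add(
                *[_nice_number(c[j]) * model.init_exprs[j] for j in range(model.n_x)]
            )
        others = sp.Add(
            *[
                _nice_number(c[j]) * model.x_syms[j]
                for j in range(model.n_x)
                if j != e and c[j] != 0
            ]
        )
        subs[model.x_syms[e]] = (total_expr - others) / _nice_number(c[e])

    keep = [i for i in range(model.n_x) if i not in elim_indices]
    new_states = [model.state_names[i] for i in keep]
    new_rhs = [sp.simplify(model.rhs_exprs[i].subs(subs)) for i in keep]
    new_init = [model.init_exprs[i] for i in keep]
    new_obs = [
        Observable(o.name, sp.simplify(o.formula.subs(subs)), o.noise_formula)
        for o in model.observables
    ]
    return OdeModel(
        name=model.name + "_reduced",
        state_names=new_states,
        init_exprs=new_init,
        parameters=model.parameters,
        input_names=model.input_names,
        rhs_exprs=new_rhs,
        observables=new_obs,
    )
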