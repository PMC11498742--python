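"""Built-in fixture models with closed-form steady states, and a synthetic
measurement generator.

The fixtures are deliberately small (n_x <= 3) linear reaction chains whose
steady states and steady-state sensitivities are known in closed form, so
every method pair can be validated without any external model download:

- ``decay2``          two-state linear chain driven by an input, post-eq data
- ``scalar_relax``    scalar relaxation dx/dt = theta - k x with a fitted
                      noise parameter (exercises the dsigma/dtheta terms)
- ``reversible_pair`` reversible isomerization with a conserved total and
                      theta-dependent initial values (exercises conservation
                      detection/reduction and the rank-deficiency paths)
- ``cascade_preeq``   three-state cascade whose pre-equilibration input
                      differs from the dynamic-phase input
- ``no_steady_state`` pure drift dx/dt = k (exercises the failure paths)

Default parameter bounds span six decades on log10 scale (1e-3..1e3 for rate
constants), matching the log-uniform sampling ranges typical of kinetic
parameter estimation; data-generating values are of order one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import Dataset, build_dataset
from .model import Condition, OdeModel, derive, parse_model
from .objective import MethodPair, simulate_condition
from .steady_state import EquilibrationConfig

__all__ = [
    "FixtureSpec",
    "SyntheticDataset",
    "FIXTURE_NAMES",
    "build_fixture",
    "generate_synthetic_data",
    "default_times",
    "as_dataset",
]

FIXTURE_NAMES = (
    "decay2",
    "scalar_relax",
    "reversible_pair",
    "cascade_preeq",
    "no_steady_state",
)


@dataclass
class FixtureSpec:
    """A fixture model plus its generating parameters and closed forms.

    ``closed_form_steady_state(theta, u) -> x*`` and
    ``closed_form_sensitivities(theta, u) -> dx*/dtheta`` are None where no
    closed form exists (e.g. the drift fixture has no steady state).
    """

    name: str
    model: OdeModel
    true_theta: np.ndarray
    conditions: dict
    default_times: np.ndarray
    closed_form_steady_state: Optional[Callable] = None
    closed_form_sensitivities: Optional[Callable] = None


@dataclass
class SyntheticDataset:
    """Measurement rows generated from a fixture: exact model outputs plus
    i.i.d. Gaussian noise of standard deviation ``noise_sd``."""

    measurements: pd.DataFrame
    noise_sd: float
    seed: int


def _decay2() -> FixtureSpec:
    doc = {
        "name": "decay2",
        "states": [{"name": "x1", "init": "0"}, {"name": "x2", "init": "0"}],
        "parameters": [
            {"name": "k1", "lower": 1e-3, "upper": 1e3, "scale": "log10"},
            {"name": "k2", "lower": 1e-3, "upper": 1e3, "scale": "log10"},
            {"name": "k3", "lower": 1e-3, "upper": 1e3, "scale": "log10"},
        ],
        "inputs": ["u"],
        "rates": {"x1": "k1*u - k2*x1", "x2": "k2*x1 - k3*x2"},
        "observables": [
            {"name": "obs_x1", "formula": "x1", "noise_formula": "0.1"},
            {"name": "obs_x2", "formula": "x2", "noise_formula": "0.1"},
        ],
    }

    def x_star(theta, u):
        k1, k2, k3 = theta
        uu = float(np.atleast_1d(u)[0])
        return np.array([k1 * uu / k2, k1 * uu / k3])

    def sens(theta, u):
        k1, k2, k3 = theta
        uu = float(np.atleast_1d(u)[0])
        return np.array(
            [
                [uu / k2, -k1 * uu / k2**2, 0.0],
                [uu / k3, 0.0, -k1 * uu / k3**2],
            ]
        )

    return FixtureSpec(
        name="decay2",
        model=parse_model(doc),
        true_theta=np.array([1.0, 2.0, 4.0]),
        conditions={"c1": Condition("c1", {"u": 1.0})},
        default_times=np.array([0.5, 1.0, 2.0, 4.0, 8.0]),
        closed_form_steady_state=x_star,
        closed_form_sensitivities=sens,
    )


def _scalar_relax() -> FixtureSpec:
    doc = {
        "name": "scalar_relax",
        "states": [{"name": "x", "init": "0"}],
        "parameters": [
            {"name": "theta", "lower": 1e-3, "upper": 1e3, "scale": "log10"},
            {"name": "k", "lower": 1e-3, "upper": 1e3, "scale": "log10"},
            {"name": "s", "lower": 1e-2, "upper": 1e1, "scale": "log10"},
        ],
        "inputs": [],
        "rates": {"x": "theta - k*x"},
        "observables": [{"name": "obs_x", "formula": "x", "noise_formula": "s"}],
    }

    def x_star(theta, u=None):
        th, k, _ = theta
        return np.array([th / k])

    def sens(theta, u=None):
        th, k, _ = theta
        return np.array([[1.0 / k, -th / k**2, 0.0]])

    return FixtureSpec(
        name="scalar_relax",
        model=parse_model(doc),
        true_theta=np.array([1.0, 2.0, 0.1]),
        conditions={"c1": Condition("c1", {})},
        default_times=np.array([0.25, 0.5, 1.0, 2.0]),
        closed_form_steady_state=x_star,
        closed_form_sensitivities=sens,
    )


def _reversible_pair() -> FixtureSpec:
    doc = {
        "name": "reversible_pair",
        "states": [{"name": "x1", "init": "a"}, {"name": "x2", "init": "b"}],
        "parameters": [
            {"name": "k1", "lower": 1e-2, "upper": 1e2, "scale": "log10"},
            {"name": "k2", "lower": 1e-2, "upper": 1e2, "scale": "log10"},
            {"name": "a", "lower": 1e-2, "upper": 1e1, "scale": "log10"},
            {"name": "b", "lower": 1e-2, "upper": 1e1, "scale": "log10"},
        ],
        "inputs": [],
        "rates": {"x1": "-k1*x1 + k2*x2", "x2": "k1*x1 - k2*x2"},
        "observables": [
            {"name": "obs_x1", "formula": "x1", "noise_formula": "0.1"}
        ],
    }

    def x_star(theta, u=None):
        k1, k2, a, b = theta
        total = a + b
        return np.array([k2 * total / (k1 + k2), k1 * total / (k1 + k2)])

    def sens(theta, u=None):
        k1, k2, a, b = theta
        total = a + b
        denom = (k1 + k2) ** 2
        return np.array(
            [
                [-k2 * total / denom, k1 * total / denom, k2 / (k1 + k2), k2 / (k1 + k2)],
                [k2 * total / denom, -k1 * total / denom, k1 / (k1 + k2), k1 / (k1 + k2)],
            ]
        )

    return FixtureSpec(
        name="reversible_pair",
        model=parse_model(doc),
        true_theta=np.array([1.0, 2.0, 1.0, 1.0]),
        conditions={"c1": Condition("c1", {})},
        default_times=np.array([0.25, 0.5, 1.0, 2.0]),
        closed_form_steady_state=x_star,
        closed_form_sensitivities=sens,
    )


def _cascade_preeq() -> FixtureSpec:
    doc = {
        "name": "cascade_preeq",
        "states": [
            {"name": "x1", "init": "0"},
            {"name": "x2", "init": "0"},
            {"name": "x3", "init": "0"},
        ],
        "parameters": [
            {"name": "k0", "lower": 1e-3, "upper": 1e3, "scale": "log10"},
            {"name": "k1", "lower": 1e-3, "upper": 1e3, "scale": "log10"},
            {"name": "k2", "lower": 1e-3, "upper": 1e3, "scale": "log10"},
            {"name": "k3", "lower": 1e-3, "upper": 1e3, "scale": "log10"},
        ],
        "inputs": ["u"],
        "rates": {
            "x1": "k0*u - k1*x1",
            "x2": "k1*x1 - k2*x2",
            "x3": "k2*x2 - k3*x3",
        },
        "observables": [
            {"name": "obs_x2", "formula": "x2", "noise_formula": "0.1"},
            {"name": "obs_x3", "formula": "x3", "noise_formula": "0.1"},
        ],
    }

    def x_star(theta, u):
        k0, k1, k2, k3 = theta
        uu = float(np.atleast_1d(u)[0])
        return np.array([k0 * uu / k1, k0 * uu / k2, k0 * uu / k3])

    def sens(theta, u):
        k0, k1, k2, k3 = theta
        uu = float(np.atleast_1d(u)[0])
        return np.array(
            [
                [uu / k1, -k0 * uu / k1**2, 0.0, 0.0],
                [uu / k2, 0.0, -k0 * uu / k2**2, 0.0],
                [uu / k3, 0.0, 0.0, -k0 * uu / k3**2],
            ]
        )

    # the pre-equilibration input differs from the dynamic-phase input, so the
    # pre-equilibration steady state genuinely differs from the attractor
    conditions = {
        "pre": Condition("pre", {"u": 0.5}),
        "main": Condition("main", {"u": 2.0}, preeq_condition_id="pre"),
    }
    return FixtureSpec(
        name="cascade_preeq",
        model=parse_model(doc),
        true_theta=np.array([1.0, 1.0, 2.0, 4.0]),
        conditions=conditions,
        default_times=np.array([0.5, 1.0, 2.0, 4.0]),
        closed_form_steady_state=x_star,
        closed_form_sensitivities=sens,
    )


def _no_steady_state() -> FixtureSpec:
    doc = {
        "name": "no_steady_state",
        "states": [{"name": "x", "init": "0"}],
        "parameters": [
            {"name": "k", "lower": 1e-3, "upper": 1e3, "scale": "log10"}
        ],
        "inputs": [],
        "rates": {"x": "k"},
        "observables": [{"name": "obs_x", "formula": "x", "noise_formula": "0.1"}],
    }
    return FixtureSpec(
        name="no_steady_state",
        model=parse_model(doc),
        true_theta=np.array([1.0]),
        conditions={"c1": Condition("c1", {})},
        default_times=np.array([1.0, 2.0]),
    )


_BUILDERS = {
    "decay2": _decay2,
    "scalar_relax": _scalar_relax,
    "reversible_pair": _reversible_pair,
    "cascade_preeq": _cascade_preeq,
    "no_steady_state": _no_steady_state,
}


def build_fixture(name: str) -> FixtureSpec:
    """Return the named fixture; unknown names list the available ones."""
    if name not in _BUILDERS:
        raise ValidationError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    return _BUILDERS[name]()


def default_times(fixture: FixtureSpec) -> np.ndarray:
    return np.asarray(fixture.default_times, dtype=float)


def generate_synthetic_data(
    fixture: FixtureSpec,
    theta: Optional[np.ndarray] = None,
    conditions: Optional[dict] = None,
    times: Optional[Sequence[float]] = None,
    noise_sd: float = 0.02,
    seed: int = 0,
    include_steady_state_rows: bool = True,
    config: Optional[EquilibrationConfig] = None,
) -> SyntheticDataset:
    """Simulate the fixture at ``theta`` and emit a noisy measurement table.

    With ``noise_sd = 0`` the values are exact model outputs. Steady-state
    rows (``time = inf``) are appended per observable when requested.
    Simulation failures propagate (the drift fixture cannot generate
    steady-state rows).
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be nonnegative")
    theta = np.asarray(
        fixture.true_theta if theta is None else theta, dtype=float
    )
    conditions = conditions if conditions is not None else fixture.conditions
    times = np.asarray(
        fixture.default_times if times is None else times, dtype=float
    )
    if np.any(~np.isfinite(times)) or np.any(np.diff(times) < 0):
        raise ValidationError("times must be finite and sorted")
    config = config or EquilibrationConfig()
    model = fixture.model
    deriv = derive(model)
    rng = np.random.default_rng(seed)
    pair = MethodPair("integration", "fsa_tailored")

    # conditions referenced as someone's pre-equilibration get no rows of
    # their own; they only supply u^e
    preeq_targets = {
        c.preeq_condition_id for c in conditions.values() if c.preeq_condition_id
    }
    rows = []
    for cid, cond in conditions.items():
        if cid in preeq_targets:
            continue
        probe = []
        for obs in model.observable_names:
            for t in times:
                probe.append((obs, t))
            if include_steady_state_rows:
                probe.append((obs, np.inf))
        slice_df = pd.DataFrame(
            {
                "observableId": [o for o, _ in probe],
                "simulationConditionId": cid,
                "preequilibrationConditionId": cond.preeq_condition_id,
                "time": [t for _, t in probe],
                "measurement": 0.0,
            }
        )
        preeq = (
            conditions[cond.preeq_condition_id]
            if cond.preeq_condition_id
            else None
        )
        res = simulate_condition(
            model, deriv, theta, cond, slice_df, pair, config,
            preeq_condition=preeq,
        )
        if not res.ok:
            raise ValidationError(
                f"synthetic data generation failed: {res.status} during "
                f"{res.phase} for condition {cid!r}"
            )
        values = res.rows["y_sim"].to_numpy(float)
        if noise_sd > 0:
            values = values + rng.normal(0.0, noise_sd, size=values.shape)
        slice_df = slice_df.copy()
        slice_df["measurement"] = values
        rows.append(slice_df)

    measurements = pd.concat(rows, ignore_index=True)
    return SyntheticDataset(measurements=measurements, noise_sd=noise_sd, seed=seed)


def as_dataset(fixture: FixtureSpec, synthetic: SyntheticDataset) -> Dataset:
    """Assemble a validated Dataset from fixture conditions and generated
    measurements."""
    return build_dataset(fixture.model, dict(fixture.conditions), synthetic.measurements)
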