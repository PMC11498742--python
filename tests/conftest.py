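"""Shared fixtures: built-in models with their derivative sets, default
numerical configuration, and small synthetic datasets."""

import numpy as np
import pytest

from eqsens import EquilibrationConfig, MethodPair
from eqsens.fixtures import as_dataset, build_fixture, generate_synthetic_data
from eqsens.io import build_dataset
from eqsens.model import derive, detect_conservation, reduce_model


@pytest.fixture(scope="session")
def config():
    return EquilibrationConfig()


@pytest.fixture(scope="session")
def decay2():
    fx = build_fixture("decay2")
    return fx, derive(fx.model)


@pytest.fixture(scope="session")
def scalar_relax():
    fx = build_fixture("scalar_relax")
    return fx, derive(fx.model)


@pytest.fixture(scope="session")
def reversible_pair():
    fx = build_fixture("reversible_pair")
    return fx, derive(fx.model)


@pytest.fixture(scope="session")
def cascade_preeq():
    fx = build_fixture("cascade_preeq")
    return fx, derive(fx.model)


@pytest.fixture(scope="session")
def no_steady_state():
    fx = build_fixture("no_steady_state")
    return fx, derive(fx.model)


@pytest.fixture(scope="session")
def reversible_reduced(reversible_pair):
    fx, _ = reversible_pair
    laws = detect_conservation(fx.model, seed=7)
    red = reduce_model(fx.model, laws)
    return fx, red, derive(red)


@pytest.fixture(scope="session")
def decay2_dataset(decay2):
    fx, _ = decay2
    syn = generate_synthetic_data(fx, noise_sd=0.05, seed=11)
    return as_dataset(fx, syn)


@pytest.fixture(scope="session")
def all_pairs():
    return MethodPair.all_pairs()


def dataset_for(fx, model=None, noise_sd=0.05, seed=11, **kwargs):
    """Synthetic dataset helper; pass a reduced model to validate against it."""
    syn = generate_synthetic_data(fx, noise_sd=noise_sd, seed=seed, **kwargs)
    if model is None:
        return as_dataset(fx, syn)
    return build_dataset(model, dict(fx.conditions), syn.measurements)
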