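"""Shared fixtures: small generating models and simulated datasets.

Expensive fits are session-scoped so several tests can share them.
"""

import numpy as np
import pytest

import irtqol as q


def make_grm_items(rng, n_items, n_cats, n_factors=1, pattern=None,
                   slope_range=(0.8, 1.8), spread=1.8):
    """Random valid graded items: positive slopes, decreasing intercepts."""
    items = []
    for j in range(n_items):
        K = n_cats if np.isscalar(n_cats) else n_cats[j]
        slopes = np.zeros(n_factors)
        free = np.arange(n_factors) if pattern is None else np.nonzero(pattern[j])[0]
        slopes[free] = rng.uniform(*slope_range, free.size)
        raw = np.sort(rng.uniform(-spread, spread, K - 1))[::-1]
        d = raw - 0.3 * np.arange(K - 1)  # guarantee strict decrease
        items.append(q.ItemParameters(slopes, d))
    return items


def frozen_model(structure, items, n_persons=0, quad=None):
    """Wrap known parameters as a FittedModel (no estimation involved)."""
    if quad is None:
        quad = q.default_quadrature(q.integral_dimension(structure))
    return q.FittedModel(
        structure=structure, items=items,
        general_corr=np.eye(structure.n_general), loglik=0.0,
        n_params=0, n_persons=n_persons, converged=True, iterations=0,
        quadrature=quad)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def uni_setup():
    """Known unidimensional model + simulated data (N=600, 5 items, K=3)."""
    rng = np.random.default_rng(101)
    s = q.build_structure("unidimensional", 5)
    items = make_grm_items(rng, 5, 3)
    spec = q.SimulationSpec(s, items, 600, missing_rate=0.05, seed=42)
    data = q.simulate(spec)
    return spec, data


@pytest.fixture(scope="session")
def uni_fit(uni_setup):
    spec, data = uni_setup
    model = q.fit_em(data, spec.structure, seed=1)
    return spec, data, model


@pytest.fixture(scope="session")
def bifactor_toy():
    """6-item, 2-cluster bifactor generating model (3 full dimensions)."""
    rng = np.random.default_rng(77)
    s = q.build_structure("bifactor", 6, ["a", "a", "a", "b", "b", "b"])
    items = []
    for j in range(6):
        slopes = np.zeros(3)
        slopes[0] = rng.uniform(1.0, 1.8)
        slopes[1 if j < 3 else 2] = rng.uniform(0.6, 1.1)
        items.append(q.ItemParameters(
            slopes, np.sort(rng.uniform(-1.5, 1.5, 2))[::-1] - [0, 0.3]))
    spec = q.SimulationSpec(s, items, 400, seed=7)
    data = q.simulate(spec)
    return spec, data


@pytest.fixture(scope="session")
def hads_fit():
    """HADS-preset data (N=800) with its bifactor fit."""
    spec = q.preset("hads", n_persons=800, seed=5)
    data = q.simulate(spec)
    model = q.fit_em(data, spec.structure, seed=1)
    return spec, data, model
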