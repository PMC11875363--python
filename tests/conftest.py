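"""Shared fixtures: small, fast simulation states reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from turbisim import BackboneTree, BoundaryState, SimParams, simulate


def small_params(**kw) -> SimParams:
    """A scaled-down configuration for fast structural tests."""
    base = dict(t_max=250, t_B=170, tau=250, B=16.0, seed=7)
    base.update(kw)
    return SimParams(**base)


@pytest.fixture(scope="session")
def small_run():
    """One short default-physics run shared by structural tests."""
    return simulate(small_params())


@pytest.fixture(scope="session")
def small_run_pair():
    """Two runs with the same seed, for determinism checks."""
    p = small_params(seed=11)
    return simulate(p), simulate(p)


@pytest.fixture()
def chain_tree():
    """Straight 5-node chain at rest spacing r0 = 1, far from any wall."""
    n = 5
    pos = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
    parents = np.concatenate([[-1], np.arange(n - 1)])
    return BackboneTree(pos, parents, np.zeros(n, dtype=np.int64))


@pytest.fixture()
def far_boundary():
    return BoundaryState(b=1000.0, b_max=1000.0)


def random_tree(rng: np.random.Generator, n: int) -> BackboneTree:
    """Random tree with nodes scattered loosely in the plane."""
    pos = rng.uniform(-5, 5, size=(n, 2))
    parents = np.concatenate([[-1], [rng.integers(0, k) for k in range(1, n)]])
    births = rng.integers(0, 50, size=n)
    births[0] = 0
    return BackboneTree(pos, np.asarray(parents), births)
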