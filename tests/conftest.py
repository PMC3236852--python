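"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library's fast paths: truth tables
are evaluated gene-by-gene from the definition, and stationary distributions
are obtained by long-run power iteration, so agreement with the package is
evidence rather than tautology.
"""

import numpy as np
import pytest

from bnfault.networks import BooleanNetwork, index_to_state, state_to_index


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def brute_force_next_index(net: BooleanNetwork, idx: int) -> int:
    """Next-state index computed directly from the update-rule definition."""
    state = index_to_state(idx, net.n)
    nxt = []
    for i in range(net.n):
        row = 0
        for g in net.predictors[i]:
            row = 2 * row + state[g]
        nxt.append(net.tables[i][row])
    return state_to_index(nxt)


def power_iteration_ssd(P: np.ndarray, steps: int = 100_000) -> np.ndarray:
    """Stationary vector by repeated squaring of the chain (long-run limit)."""
    pi = np.full(P.shape[0], 1.0 / P.shape[0])
    # squaring reaches 2**k steps in k multiplications
    Pk = P.copy()
    n_applied = 1
    while n_applied < steps:
        Pk = Pk @ Pk
        Pk /= Pk.sum(axis=1, keepdims=True)  # renormalise drift
        n_applied *= 2
    return pi @ Pk


def random_distribution(rng: np.random.Generator, m: int) -> np.ndarray:
    x = rng.random(m) + 1e-6
    return x / x.sum()
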