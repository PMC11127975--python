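"""Shared fixtures and brute-force oracles for the test suite.

The oracles here are deliberately naive (exhaustive enumeration, direct
counting) and independent of the library's computation paths.
"""

import itertools

import numpy as np
import pytest

from graphdyn.dynamics import BinaryDynamics, log_likelihood


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def all_binary_arrays(N, T):
    """Every {0,1}^(N x T) array, enumerated column-major in time."""
    for bits in itertools.product((0, 1), repeat=N * T):
        yield np.array(bits, dtype=np.int8).reshape(N, T)


def joint_table(prior, dyn, T, init=0.5):
    """Exhaustive joint P(g, x) over all graphs and trajectories.

    Returns (graphs, prior probs, likelihood matrix with rows P(x | g))
    including the initial-condition factor, suitable for
    discrete_joint_info. Only usable when N*T is tiny.
    """
    graphs = list(prior.support())
    pg = np.exp2([prior.log_prob(g) for g in graphs])
    N = graphs[0].N
    rows = []
    for g in graphs:
        row = [
            2.0 ** log_likelihood(dyn, g, x, include_initial=True, init=init)
            for x in all_binary_arrays(N, T)
        ]
        rows.append(row)
    return graphs, pg, np.array(rows)


def constant_dynamics(alpha, beta):
    """Dynamics with neighbor-independent activation/deactivation rates."""
    return BinaryDynamics.from_rates(
        lambda n, m: np.full_like(np.asarray(n, dtype=float), alpha),
        lambda n, m: np.full_like(np.asarray(n, dtype=float), beta),
    )
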