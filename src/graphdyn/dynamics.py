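"""Binary Markov chains on graphs.

A process X = (X_1, ..., X_T) of binary vertex states evolves by synchronous
updates: at each step every vertex flips according to an activation
probability alpha(n, m) (inactive -> active) or deactivation probability
beta(n, m) (active -> inactive), where m and n are its numbers of active and
inactive neighbors (n + m = k_i). Three named rules are built in:

=========  =======================================  ==================
model      alpha(n, m)                              beta(n, m)
=========  =======================================  ==================
glauber    sigma(2 J (m - n))                       sigma(2 J (n - m))
sis        1 - (1 - eps) (1 - q)^m,  q = clip(λ/β)  β (recovery)
cowan      sigma(a (ν m - μ))                       β (recovery)
=========  =======================================  ==================

with sigma the logistic function. Defaults: β = 0.5 (SIS, Cowan), a = 7,
μ = 1 (Cowan), eps = 1e-3 (SIS spontaneous activation). The Glauber rule is
ferromagnetic by default (alignment with neighbors favored); the opposite
sign convention is available via ``ferromagnetic=False``.

Multiedges contribute to neighbor counts with their multiplicity and a
self-loop feeds a vertex's own state back with multiplicity 2 (consistent
with the degree identity k_i = sum_{j!=i} M_ij + 2 M_ii).

All log-probabilities are in bits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.special import expit

from ._util import as_rng

__all__ = [
    "BinaryDynamics",
    "TimeSeries",
    "neighbor_counts",
    "simulate",
    "log_likelihood",
    "true_transition_matrix",
    "transition_log_prob_terms",
    "stacked_log_likelihood",
]


@dataclass(frozen=True)
class BinaryDynamics:
    """Activation/deactivation rule pair with named parameters.

    ``activation`` and ``deactivation`` are vectorized maps from
    (inactive-neighbor count n, active-neighbor count m) to probabilities.
    """

    name: str
    params: dict = field(default_factory=dict)
    _alpha: Callable = None
    _beta: Callable = None

    def activation(self, n, m):
        return self._alpha(np.asarray(n, dtype=float), np.asarray(m, dtype=float))

    def deactivation(self, n, m):
        return self._beta(np.asarray(n, dtype=float), np.asarray(m, dtype=float))

    def local_rates(self, n, m):
        """(alpha, beta) at the given neighbor counts."""
        return self.activation(n, m), self.deactivation(n, m)

    @property
    def coupling(self) -> float:
        return self.params[self.params["coupling_name"]]

    def with_coupling(self, value: float) -> "BinaryDynamics":
        """Same model with the sweep-axis coupling parameter replaced."""
        kw = {k: v for k, v in self.params.items() if k != "coupling_name"}
        if self.name == "sis":
            kw.pop("q", None)  # re-derived from lam/recovery
        kw[self.params["coupling_name"]] = value
        factory = {"glauber": BinaryDynamics.glauber,
                   "sis": BinaryDynamics.sis,
                   "cowan": BinaryDynamics.cowan}[self.name]
        return factory(**kw)

    # -- factories ----------------------------------------------------------

    @staticmethod
    def glauber(J: float = 1.0, ferromagnetic: bool = True) -> "BinaryDynamics":
        if J < 0:
            raise ValueError("J must be non-negative")
        s = 1.0 if ferromagnetic else -1.0
        return BinaryDynamics(
            "glauber",
            {"J": J, "ferromagnetic": ferromagnetic, "coupling_name": "J"},
            _alpha=lambda n, m: expit(2.0 * J * s * (m - n)),
            _beta=lambda n, m: expit(2.0 * J * s * (n - m)),
        )

    @staticmethod
    def sis(
        lam: Optional[float] = None,
        q: Optional[float] = None,
        recovery: float = 0.5,
        eps: float = 1e-3,
    ) -> "BinaryDynamics":
        """SIS epidemics; the per-contact infection probability is
        q = clip(lam / recovery, 0, 1) unless ``q`` is given directly."""
        if not 0 < recovery <= 1:
            raise ValueError("recovery must lie in (0, 1]")
        if not 0 <= eps < 1:
            raise ValueError("eps must lie in [0, 1)")
        if q is None:
            if lam is None:
                raise ValueError("provide lam or q")
            q = min(1.0, max(0.0, lam / recovery))
        elif not 0 <= q <= 1:
            raise ValueError("q must lie in [0, 1]")
        lam = q * recovery if lam is None else lam
        qv, ev, bv = float(q), float(eps), float(recovery)
        return BinaryDynamics(
            "sis",
            {"lam": lam, "q": qv, "recovery": bv, "eps": ev, "coupling_name": "lam"},
            # algebraically 1 - (1-eps)(1-q)^m, arranged so alpha(., 0) == eps
            _alpha=lambda n, m: ev + (1.0 - ev) * (1.0 - (1.0 - qv) ** m),
            _beta=lambda n, m: np.full_like(np.asarray(m, dtype=float), bv),
        )

    @staticmethod
    def cowan(
        nu: float = 1.0, a: float = 7.0, mu: float = 1.0, recovery: float = 0.5
    ) -> "BinaryDynamics":
        if nu < 0 or a <= 0:
            raise ValueError("nu must be >= 0 and a > 0")
        if not 0 < recovery <= 1:
            raise ValueError("recovery must lie in (0, 1]")
        return BinaryDynamics(
            "cowan",
            {"nu": nu, "a": a, "mu": mu, "recovery": recovery, "coupling_name": "nu"},
            _alpha=lambda n, m: expit(a * (nu * m - mu)),
            _beta=lambda n, m: np.full_like(np.asarray(m, dtype=float), recovery),
        )

    @staticmethod
    def from_rates(alpha: Callable, beta: Callable, name: str = "custom"):
        """Arbitrary (n, m) -> probability rule pair (used mostly in tests)."""
        return BinaryDynamics(
            name, {"coupling_name": "none", "none": float("nan")},
            _alpha=lambda n, m: np.broadcast_arrays(
                np.asarray(alpha(n, m), dtype=float), n)[0],
            _beta=lambda n, m: np.broadcast_arrays(
                np.asarray(beta(n, m), dtype=float), n)[0],
        )


@dataclass
class TimeSeries:
    """Binary states X[i, t] for i in [0, N), t in [0, T), with a past split tau."""

    states: np.ndarray
    tau: Optional[int] = None

    def __post_init__(self):
        x = np.asarray(self.states)
        if x.ndim != 2:
            raise ValueError("states must be an N x T array")
        if not np.isin(x, (0, 1)).all():
            raise ValueError("states must be binary")
        self.states = x.astype(np.int8)
        if self.tau is not None and not (1 <= self.tau < self.T):
            raise ValueError("tau must satisfy 1 <= tau < T")

    @property
    def N(self) -> int:
        return self.states.shape[0]

    @property
    def T(self) -> int:
        return self.states.shape[1]

    @property
    def past(self) -> np.ndarray:
        if self.tau is None:
            raise ValueError("no past/future split set")
        return self.states[:, : self.tau]

    @property
    def future(self) -> np.ndarray:
        if self.tau is None:
            raise ValueError("no past/future split set")
        return self.states[:, self.tau :]

    def prefix(self, length: int) -> "TimeSeries":
        return TimeSeries(self.states[:, :length])

    def to_csv(self, path, metadata: Optional[dict] = None):
        """Rows = time, columns = vertices; optional JSON sidecar ``path + '.json'``."""
        np.savetxt(path, self.states.T, fmt="%d", delimiter=",")
        if metadata is not None:
            with open(str(path) + ".json", "w") as fh:
                json.dump(metadata, fh, indent=1)

    @classmethod
    def from_csv(cls, path, tau: Optional[int] = None) -> "TimeSeries":
        data = np.loadtxt(path, delimiter=",", dtype=np.int64, ndmin=2)
        return cls(data.T, tau=tau)


def _adjacency(g) -> np.ndarray:
    return g if isinstance(g, np.ndarray) else g.adjacency_matrix()


def neighbor_counts(g, x_t):
    """(n, m): inactive and active neighbor counts for one state vector."""
    A = _adjacency(g)
    x_t = np.asarray(x_t)
    if x_t.shape[0] != A.shape[0]:
        raise ValueError("state vector length does not match vertex count")
    m = A @ x_t
    n = A.sum(axis=1) - m
    return n, m


def simulate(dyn: BinaryDynamics, g, T: int, rng, init=0.5) -> TimeSeries:
    """Simulate T synchronous steps; X_1 ~ iid Bernoulli(init), independent of g.

    ``init`` may be a scalar probability, a length-N probability vector, or an
    explicit binary initial state vector (detected by dtype/values).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = as_rng(rng)
    A = _adjacency(g)
    N = A.shape[0]
    k = A.sum(axis=1)
    x = np.empty((N, T), dtype=np.int8)
    init_arr = np.asarray(init, dtype=float)
    if init_arr.ndim == 1 and np.isin(init_arr, (0.0, 1.0)).all():
        x[:, 0] = init_arr.astype(np.int8)
    else:
        x[:, 0] = rng.random(N) < init_arr
    for t in range(T - 1):
        cur = x[:, t]
        m = A @ cur
        n = k - m
        p_active = np.where(
            cur == 0, dyn.activation(n, m), 1.0 - dyn.deactivation(n, m)
        )
        x[:, t + 1] = rng.random(N) < p_active
    return TimeSeries(x)


def transition_log_prob_terms(dyn: BinaryDynamics, g, x) -> np.ndarray:
    """Per-(vertex, transition) log2-probabilities, shape (N, T-1).

    Entry (i, t) is the log-probability of the realized transition
    X[i, t] -> X[i, t+1] given the neighbor counts at time t.
    """
    A = _adjacency(g)
    s = x.states if isinstance(x, TimeSeries) else np.asarray(x)
    if s.shape[0] != A.shape[0]:
        raise ValueError("time series / graph vertex-count mismatch")
    m = A @ s
    n = A.sum(axis=1)[:, None] - m
    alpha = dyn.activation(n, m)
    beta = dyn.deactivation(n, m)
    p_active = np.where(s == 0, alpha, 1.0 - beta)  # P(next state = 1)
    nxt = s[:, 1:]
    p = np.where(nxt == 1, p_active[:, :-1], 1.0 - p_active[:, :-1])
    with np.errstate(divide="ignore"):
        return np.log2(p)


def log_likelihood(
    dyn: BinaryDynamics, g, x, *, include_initial: bool = False, init=0.5
) -> float:
    """log2 P(X = x | G = g) in bits, summed over vertices and transitions.

    The initial-condition term log2 P(X_1) is excluded by default (it is
    independent of g, so it cancels in every mutual-information quantity);
    set ``include_initial=True`` to add it for an iid Bernoulli(init) law.
    A realized zero-probability transition yields -inf.
    """
    total = float(transition_log_prob_terms(dyn, g, x).sum())
    if include_initial:
        s = x.states if isinstance(x, TimeSeries) else np.asarray(x)
        p1 = np.broadcast_to(np.asarray(init, dtype=float), (s.shape[0],))
        p = np.where(s[:, 0] == 1, p1, 1.0 - p1)
        with np.errstate(divide="ignore"):
            total += float(np.log2(p).sum())
    return total


def true_transition_matrix(dyn: BinaryDynamics, g, x) -> np.ndarray:
    """P*[i, t]: probability that vertex i is active at t+1 given the state at t."""
    A = _adjacency(g)
    s = x.states if isinstance(x, TimeSeries) else np.asarray(x)
    m = A @ s
    n = A.sum(axis=1)[:, None] - m
    return np.where(s == 0, dyn.activation(n, m), 1.0 - dyn.deactivation(n, m))


def stacked_log_likelihood(dyn: BinaryDynamics, A_stack: np.ndarray, x) -> np.ndarray:
    """log2 P(x | g) for every graph in a stacked adjacency array (S, N, N).

    Returns per-graph totals, shape (S,); used to evaluate the evidence by
    summation over an enumerated support without a Python-level graph loop.
    """
    s = x.states if isinstance(x, TimeSeries) else np.asarray(x)
    sf = s.astype(float)
    m = A_stack @ sf  # (S, N, T)
    k = A_stack.sum(axis=2)  # (S, N)
    n = k[:, :, None] - m
    alpha = dyn.activation(n, m)
    beta = dyn.deactivation(n, m)
    p_active = np.where(sf[None, :, :] == 0, alpha, 1.0 - beta)
    nxt = sf[None, :, 1:]
    p = np.where(nxt == 1, p_active[:, :, :-1], 1.0 - p_active[:, :, :-1])
    with np.errstate(divide="ignore"):
        return np.log2(p).sum(axis=(1, 2))


def per_step_stacked_log_likelihood(
    dyn: BinaryDynamics, A_stack: np.ndarray, x
) -> np.ndarray:
    """Per-transition log2-likelihood summed over vertices, shape (S, T-1).

    Cumulative sums of this array give the likelihood of every prefix of x,
    which lets T-sweeps reuse one set of samples across all T values.
    """
    s = x.states if isinstance(x, TimeSeries) else np.asarray(x)
    sf = s.astype(float)
    m = A_stack @ sf
    k = A_stack.sum(axis=2)
    n = k[:, :, None] - m
    alpha = dyn.activation(n, m)
    beta = dyn.deactivation(n, m)
    p_active = np.where(sf[None, :, :] == 0, alpha, 1.0 - beta)
    nxt = sf[None, :, 1:]
    p = np.where(nxt == 1, p_active[:, :, :-1], 1.0 - p_active[:, :, :-1])
    with np.errstate(divide="ignore"):
        return np.log2(p).sum(axis=1)
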