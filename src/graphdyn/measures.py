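"""Entropies, mutual information and uncertainty coefficients.

The central object is the pair (graph prior P(G), dynamics likelihood
P(X|G)). Their mutual information I(X;G) = H(X) - H(X|G) = H(G) - H(G|X)
measures how much the time series and the structure determine each other,
and its normalized versions

* predictability      U(X|G) = I(X;G) / H(X)
* reconstructability  U(G|X) = I(X;G) / H(G)

quantify the fraction of dynamical (resp. structural) uncertainty removed
by knowing the other variable. All quantities are in bits.

Three computation routes are provided:

* :func:`discrete_joint_info` — exact summation over any finite joint table
  (also the brute-force oracle for everything else);
* :func:`exact_joint_measures` — exact evaluation for a dynamics on an
  enumerable graph support by exhaustive trajectory enumeration;
* :func:`exact_mc_mi` — the enumeration-based Monte Carlo estimator:
  I(X;G) ~ (1/M) sum_m [log P(x^(m)|g^(m)) - log P(x^(m))], with the
  evidence P(x) computed by summing the likelihood over the whole support.

The initial condition X_1 is independent of G, so its entropy contributes
identically to H(X) and H(X|G) and cancels in I; estimators drop the term
from likelihoods and add it back analytically to the reported entropies.

:func:`duality_scan` detects parameter intervals where predictability and
reconstructability move in opposite directions (the duality criterion
dU(G|X)/dθ · dU(X|G)/dθ < 0, applied to finite differences).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._util import as_rng, entropy_bits, log2sumexp, xlog2x
from .dynamics import (
    BinaryDynamics,
    per_step_stacked_log_likelihood,
    simulate,
    stacked_log_likelihood,
)

__all__ = [
    "binary_entropy",
    "MeasureSet",
    "PastMeasureSet",
    "ToyFiniteModel",
    "discrete_joint_info",
    "toy_closed_forms",
    "evidence_log_prob",
    "exact_mc_mi",
    "mc_mi_profile",
    "past_conditional_measures",
    "exact_joint_measures",
    "markov_chain_entropy",
    "DualityScan",
    "duality_scan",
]


def binary_entropy(p) -> float:
    """H(p) = -p log2 p - (1-p) log2(1-p), with 0 log 0 := 0."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must lie in [0, 1]")
    out = -(xlog2x(p) + xlog2x(1.0 - p))
    return float(out) if out.ndim == 0 else out


@dataclass
class MeasureSet:
    """Entropies (bits), mutual information and uncertainty coefficients.

    ``se`` maps field names to standard errors (zero for exact routes).
    """

    H_X: float
    H_G: float
    H_X_given_G: float
    H_G_given_X: float
    I: float
    U_X_given_G: float
    U_G_given_X: float
    entropy_rate_estimate: float = float("nan")
    se: dict = field(default_factory=dict)
    n_samples: Optional[int] = None

    def as_dict(self) -> dict:
        d = {
            "H_X": self.H_X,
            "H_G": self.H_G,
            "H_X_given_G": self.H_X_given_G,
            "H_G_given_X": self.H_G_given_X,
            "I": self.I,
            "U_X_given_G": self.U_X_given_G,
            "U_G_given_X": self.U_G_given_X,
            "entropy_rate_estimate": self.entropy_rate_estimate,
        }
        for k, v in self.se.items():
            d[f"se_{k}"] = v
        return d


@dataclass
class PastMeasureSet:
    """Past-conditioned variants: I(X_future; G | X_past) and partial coefficients."""

    tau: int
    I_cond: float
    H_future_given_past: float
    H_G_given_past: float
    U_future_given_G_past: float
    U_G_given_future_past: float
    se: dict = field(default_factory=dict)
    n_samples: Optional[int] = None

    def as_dict(self) -> dict:
        d = {
            "tau": self.tau,
            "I_cond": self.I_cond,
            "H_future_given_past": self.H_future_given_past,
            "H_G_given_past": self.H_G_given_past,
            "U_future_given_G_past": self.U_future_given_G_past,
            "U_G_given_future_past": self.U_G_given_future_past,
        }
        for k, v in self.se.items():
            d[f"se_{k}"] = v
        return d


# ---------------------------------------------------------------------------
# Finite tables (the brute-force oracle)
# ---------------------------------------------------------------------------


def discrete_joint_info(prior_probs, likelihood, *, atol: float = 1e-9) -> MeasureSet:
    """Exact measures for a finite prior table and likelihood matrix P(X|G).

    ``prior_probs`` has one entry per graph; ``likelihood`` rows are the
    outcome distributions of each graph. Everything is computed by direct
    summation over the joint support.
    """
    pg = np.asarray(prior_probs, dtype=float)
    lik = np.asarray(likelihood, dtype=float)
    if abs(pg.sum() - 1.0) > atol:
        raise ValueError("prior does not sum to 1")
    if np.any(np.abs(lik.sum(axis=1) - 1.0) > atol):
        raise ValueError("likelihood rows do not sum to 1")
    px = pg @ lik
    H_X = entropy_bits(px)
    H_G = entropy_bits(pg)
    H_XgG = float(-np.sum(pg[:, None] * xlog2x(lik)))
    I = H_X - H_XgG
    H_GgX = H_G - I
    U_xg = I / H_X if H_X > 0 else 0.0
    U_gx = I / H_G if H_G > 0 else 0.0
    return MeasureSet(H_X, H_G, H_XgG, H_GgX, I, U_xg, U_gx,
                      se={k: 0.0 for k in ("I", "H_X", "H_X_given_G",
                                           "U_X_given_G", "U_G_given_X")})


@dataclass(frozen=True)
class ToyFiniteModel:
    """Two graphs, three outcomes: P(g1)=p; g1 emits x1/x2 with prob r/(1-r),
    g2 emits x2/x3 with prob s/(1-s)."""

    p: float
    r: float
    s: float

    def __post_init__(self):
        for v in (self.p, self.r, self.s):
            if not 0 <= v <= 1:
                raise ValueError("p, r, s must lie in [0, 1]")

    def tables(self):
        prior = np.array([self.p, 1.0 - self.p])
        lik = np.array(
            [[self.r, 1.0 - self.r, 0.0], [0.0, self.s, 1.0 - self.s]]
        )
        return prior, lik


def toy_closed_forms(model: ToyFiniteModel) -> MeasureSet:
    """Closed-form measures for the two-graph/three-outcome model.

    For s = 0 the time series identifies the graph, so U(G|X) = 1 for any p
    and r, and U(X|G) = H(p) / (H(p) + p H(r)). For s = 1,
    U(X|G) = 1 - p H(r) / H(pr) and U(G|X) = (H(pr) - p H(r)) / H(p).
    Other s values delegate to exact summation.
    """
    p, r, s = model.p, model.r, model.s
    if s == 0.0:
        H_G = binary_entropy(p)
        H_X = binary_entropy(p) + p * binary_entropy(r)
        I = H_G
        U_xg = I / H_X if H_X > 0 else 0.0
        return MeasureSet(H_X, H_G, H_X - I, 0.0, I, U_xg, 1.0 if H_G > 0 else 0.0,
                          se={"I": 0.0})
    if s == 1.0:
        H_G = binary_entropy(p)
        H_X = binary_entropy(p * r)
        H_XgG = p * binary_entropy(r)
        I = H_X - H_XgG
        U_xg = 1.0 - H_XgG / H_X if H_X > 0 else 0.0
        U_gx = I / H_G if H_G > 0 else 0.0
        return MeasureSet(H_X, H_G, H_XgG, H_G - I, I, U_xg, U_gx, se={"I": 0.0})
    prior, lik = model.tables()
    return discrete_joint_info(prior, lik)


# ---------------------------------------------------------------------------
# Dynamics on enumerable graph ensembles
# ---------------------------------------------------------------------------


def _enumerated_prior(prior, support_cap):
    graphs = list(prior.support(cap=support_cap))
    logp = np.array([prior.log_prob(g) for g in graphs])
    A = np.stack([g.adjacency_matrix() for g in graphs]).astype(float)
    return graphs, logp, A


def _prior_entropy(logp: np.ndarray) -> float:
    p = np.exp2(logp)
    return float(-np.sum(p * logp))


def evidence_log_prob(x, prior, dyn: BinaryDynamics, *, support_cap: int = 10**6) -> float:
    """log2 P(X = x) = log2 sum_g P(g) P(x|g) over the enumerated support.

    The initial-condition factor is excluded, matching
    :func:`graphdyn.dynamics.log_likelihood`'s default.
    """
    _, logp, A = _enumerated_prior(prior, support_cap)
    return float(log2sumexp(logp + stacked_log_likelihood(dyn, A, x)))


def _assemble_measures(r, hx, hxg, H_G, T, init_entropy) -> MeasureSet:
    """Build a MeasureSet from per-sample log-ratio and entropy terms."""
    M = len(r)
    I = float(np.mean(r))
    H_X = float(np.mean(hx)) + init_entropy
    H_XgG = float(np.mean(hxg)) + init_entropy
    se_I = float(np.std(r, ddof=1) / math.sqrt(M)) if M > 1 else float("nan")
    se_hx = float(np.std(hx, ddof=1) / math.sqrt(M)) if M > 1 else float("nan")
    se_hxg = float(np.std(hxg, ddof=1) / math.sqrt(M)) if M > 1 else float("nan")
    U_xg = I / H_X if H_X > 0 else 0.0
    # delta method for the ratio of correlated sample means
    infl = (np.asarray(r) - U_xg * (np.asarray(hx) + init_entropy)) / H_X
    se_uxg = float(np.std(infl, ddof=1) / math.sqrt(M)) if M > 1 else float("nan")
    U_gx = I / H_G if H_G > 0 else 0.0
    se_ugx = se_I / H_G if H_G > 0 else 0.0
    return MeasureSet(
        H_X, H_G, H_XgG, H_G - I, I, U_xg, U_gx,
        entropy_rate_estimate=H_X / T,
        se={"I": se_I, "H_X": se_hx, "H_X_given_G": se_hxg,
            "U_X_given_G": se_uxg, "U_G_given_X": se_ugx, "H_G_given_X": se_I},
        n_samples=M,
    )


def exact_mc_mi(
    prior,
    dyn: BinaryDynamics,
    T: int,
    M: int,
    rng,
    *,
    init: float = 0.5,
    support_cap: int = 10**6,
) -> MeasureSet:
    """Monte Carlo mutual-information estimate with an exactly enumerated evidence.

    Samples M (graph, time-series) pairs from the generative model and
    averages log2 P(x|g) - log2 P(x); the evidence is a full sum over the
    support, so the only error is Monte Carlo (SE = sample SD / sqrt(M)).
    """
    if M < 2:
        raise ValueError("M must be >= 2 to report a standard error")
    rng = as_rng(rng)
    graphs, logp, A = _enumerated_prior(prior, support_cap)
    probs = np.exp2(logp)
    probs = probs / probs.sum()
    idx = rng.choice(len(graphs), size=M, p=probs)
    r = np.empty(M)
    hx = np.empty(M)
    hxg = np.empty(M)
    for m in range(M):
        x = simulate(dyn, A[idx[m]], T, rng, init=init)
        ll_all = stacked_log_likelihood(dyn, A, x)
        evid = float(log2sumexp(logp + ll_all))
        r[m] = ll_all[idx[m]] - evid
        hx[m] = -evid
        hxg[m] = -ll_all[idx[m]]
    N = A.shape[1]
    H_G = _prior_entropy(logp)
    return _assemble_measures(r, hx, hxg, H_G, T, N * binary_entropy(init))


def mc_mi_profile(
    prior,
    dyn: BinaryDynamics,
    T_grid: Sequence[int],
    M: int,
    rng,
    *,
    init: float = 0.5,
    support_cap: int = 10**6,
    tau_mode: Optional[str] = None,
):
    """Measures over a grid of process lengths, reusing one set of samples.

    Each of the M outer draws simulates once at max(T_grid); every T in the
    grid is then evaluated on the prefix of that trajectory (variance of
    successive differences is reduced by the shared randomness).

    ``tau_mode``: None (no past split), "one" (tau = 1) or "half"
    (tau = T // 2); past-conditioned measures are returned alongside.
    Returns (list of MeasureSet, list of PastMeasureSet or None).
    """
    rng = as_rng(rng)
    T_grid = sorted(int(t) for t in T_grid)
    Tmax = T_grid[-1]
    graphs, logp, A = _enumerated_prior(prior, support_cap)
    probs = np.exp2(logp)
    probs = probs / probs.sum()
    idx = rng.choice(len(graphs), size=M, p=probs)
    S = len(graphs)
    # cumulative per-prefix log-likelihoods for every support graph
    cum = np.zeros((M, S, Tmax))  # cum[m, s, t] = log2 P(x_{1..t+1} | g_s)
    for m in range(M):
        x = simulate(dyn, A[idx[m]], Tmax, rng, init=init)
        steps = per_step_stacked_log_likelihood(dyn, A, x)  # (S, Tmax-1)
        cum[m, :, 1:] = np.cumsum(steps, axis=1)
    N = A.shape[1]
    H_G = _prior_entropy(logp)
    H1 = N * binary_entropy(init)

    def measures_at(T):
        ll = cum[:, :, T - 1]  # (M, S)
        evid = log2sumexp(logp[None, :] + ll, axis=1)
        own = ll[np.arange(M), idx]
        return own - evid, -evid, -own

    results = []
    past_results = [] if tau_mode else None
    for T in T_grid:
        r, hx, hxg = measures_at(T)
        results.append(_assemble_measures(r, hx, hxg, H_G, T, H1))
        if tau_mode:
            tau = 1 if tau_mode == "one" else max(1, T // 2)
            if tau >= T:
                tau = T - 1
            if tau < 1:
                past_results.append(None)
                continue
            r_p, hx_p, _ = measures_at(tau)
            past_results.append(
                _past_from_samples(r, hx, r_p, hx_p, H_G, tau, H1)
            )
    return results, past_results


def _past_from_samples(r, hx, r_p, hx_p, H_G, tau, init_entropy) -> PastMeasureSet:
    M = len(r)
    d = np.asarray(r) - np.asarray(r_p)
    I_cond = float(np.mean(d))
    se_Ic = float(np.std(d, ddof=1) / math.sqrt(M)) if M > 1 else float("nan")
    H_X = float(np.mean(hx)) + init_entropy
    H_past = float(np.mean(hx_p)) + init_entropy
    H_fut = H_X - H_past
    I_past = float(np.mean(r_p))
    H_G_past = H_G - I_past
    U_f = I_cond / H_fut if H_fut > 0 else 0.0
    U_g = I_cond / H_G_past if H_G_past > 0 else 0.0
    return PastMeasureSet(
        tau, I_cond, H_fut, H_G_past, U_f, U_g,
        se={"I_cond": se_Ic,
            "U_future_given_G_past": se_Ic / H_fut if H_fut > 0 else 0.0,
            "U_G_given_future_past": se_Ic / H_G_past if H_G_past > 0 else 0.0},
        n_samples=M,
    )


def past_conditional_measures(
    prior,
    dyn: BinaryDynamics,
    T: int,
    tau: int,
    M: int,
    rng,
    *,
    init: float = 0.5,
    support_cap: int = 10**6,
) -> PastMeasureSet:
    """I(X_future; G | X_past) = I(X;G) - I(X_past;G) and partial coefficients.

    Both mutual informations are estimated from the same M samples (the
    past is the first ``tau`` steps of each simulated trajectory), so the
    X_1-independence identity I_cond = I at tau = 1 holds sample by sample.
    """
    if not 1 <= tau < T:
        raise ValueError("tau must satisfy 1 <= tau < T")
    rng = as_rng(rng)
    graphs, logp, A = _enumerated_prior(prior, support_cap)
    probs = np.exp2(logp)
    probs = probs / probs.sum()
    idx = rng.choice(len(graphs), size=M, p=probs)
    r = np.empty(M)
    hx = np.empty(M)
    r_p = np.empty(M)
    hx_p = np.empty(M)
    for m in range(M):
        x = simulate(dyn, A[idx[m]], T, rng, init=init)
        steps = per_step_stacked_log_likelihood(dyn, A, x)
        ll_T = steps.sum(axis=1)
        ll_tau = steps[:, : tau - 1].sum(axis=1) if tau > 1 else np.zeros(len(graphs))
        evid_T = float(log2sumexp(logp + ll_T))
        evid_tau = float(log2sumexp(logp + ll_tau))
        r[m] = ll_T[idx[m]] - evid_T
        r_p[m] = ll_tau[idx[m]] - evid_tau
        hx[m] = -evid_T
        hx_p[m] = -evid_tau
    N = A.shape[1]
    H_G = _prior_entropy(logp)
    return _past_from_samples(r, hx, r_p, hx_p, H_G, tau, N * binary_entropy(init))


# ---------------------------------------------------------------------------
# Exact evaluation by trajectory enumeration
# ---------------------------------------------------------------------------


def _state_table(N: int) -> np.ndarray:
    return (np.arange(2**N)[:, None] >> np.arange(N)) & 1


def _step_matrix(dyn: BinaryDynamics, A: np.ndarray) -> np.ndarray:
    """2^N x 2^N one-step transition matrix of the chain on one graph."""
    N = A.shape[0]
    table = _state_table(N).astype(float)  # (S, N)
    k = A.sum(axis=1)
    m = table @ A.T
    n = k[None, :] - m
    alpha = dyn.activation(n, m)
    beta = dyn.deactivation(n, m)
    p_act = np.where(table == 0, alpha, 1.0 - beta)  # (S, N)
    S = 2**N
    P = np.ones((S, S))
    tgt = _state_table(N)
    for i in range(N):
        P *= np.where(tgt[None, :, i] == 1, p_act[:, i, None], 1.0 - p_act[:, i, None])
    return P


def markov_chain_entropy(
    dyn: BinaryDynamics, g, T: int, *, init: float = 0.5
) -> float:
    """H(X | G = g) in bits via the chain rule H(X_1) + sum_t H(X_{t+1}|X_t).

    Cheap (no trajectory enumeration); serves as an independent cross-check
    of the exhaustive route.
    """
    A = g if isinstance(g, np.ndarray) else g.adjacency_matrix()
    N = A.shape[0]
    P = _step_matrix(dyn, A.astype(float))
    table = _state_table(N)
    p1 = np.prod(np.where(table == 1, init, 1.0 - init), axis=1)
    h = entropy_bits(p1)
    dist = p1.copy()
    row_h = -np.sum(xlog2x(P), axis=1)
    for _ in range(T - 1):
        h += float(dist @ row_h)
        dist = dist @ P
    return float(h)


def exact_joint_measures(
    prior,
    dyn: BinaryDynamics,
    T: int,
    *,
    init: float = 0.5,
    support_cap: int = 10**6,
    max_elements: float = 6e7,
) -> MeasureSet:
    """Exact measures by enumerating every trajectory of length T.

    Feasible only for tiny systems: the work scales as 2^{N(T-1)} times the
    support size (``max_elements`` guards the largest intermediate array).
    """
    graphs, logp, _ = _enumerated_prior(prior, support_cap)
    pg = np.exp2(logp)
    pg = pg / pg.sum()
    Gn = len(graphs)
    N = graphs[0].N
    S = 2**N
    need = (S ** max(T - 1, 0)) * Gn
    if need > max_elements:
        raise ValueError(
            f"trajectory enumeration needs {need:.2e} array elements "
            f"(cap {max_elements:.2e}); reduce T or N"
        )
    steps = np.stack([_step_matrix(dyn, g.adjacency_matrix().astype(float))
                      for g in graphs])  # (Gn, S, S)
    M2 = np.transpose(steps, (1, 2, 0))  # [s, s', g]
    table = _state_table(N)
    p1 = np.prod(np.where(table == 1, init, 1.0 - init), axis=1)
    H_X = entropy_bits(p1)
    H_XgG = H_X
    for s1 in range(S):
        if p1[s1] == 0:
            continue
        L = np.ones((1, Gn))
        prev = np.array([s1])
        for _ in range(T - 1):
            L = (L[:, None, :] * M2[prev]).reshape(-1, Gn)
            prev = np.tile(np.arange(S), len(prev))
        mix = L @ pg
        H_X += p1[s1] * float(-np.sum(xlog2x(mix)))
        H_XgG += p1[s1] * float(-np.sum(pg[None, :] * xlog2x(L)))
    H_G = _prior_entropy(logp)
    I = H_X - H_XgG
    U_xg = I / H_X if H_X > 0 else 0.0
    U_gx = I / H_G if H_G > 0 else 0.0
    return MeasureSet(
        H_X, H_G, H_XgG, H_G - I, I, U_xg, U_gx,
        entropy_rate_estimate=H_X / T,
        se={k: 0.0 for k in ("I", "U_X_given_G", "U_G_given_X")},
    )


# ---------------------------------------------------------------------------
# Duality detection
# ---------------------------------------------------------------------------


@dataclass
class DualityScan:
    """Result of scanning two uncertainty-coefficient curves along a parameter."""

    theta: np.ndarray
    U_X_given_G: np.ndarray
    U_G_given_X: np.ndarray
    dual_intervals: list  # [(theta_lo, theta_hi), ...] maximal flagged runs
    segment_flags: np.ndarray  # per consecutive pair of grid points

    @property
    def has_duality(self) -> bool:
        return len(self.dual_intervals) > 0


def duality_scan(
    theta,
    U_X_given_G,
    U_G_given_X,
    *,
    se_X=None,
    se_G=None,
    z: float = 1.0,
) -> DualityScan:
    """Flag maximal intervals where the two coefficients move in opposite
    directions (finite-difference version of the duality criterion).

    A segment between consecutive grid points is dual when both slopes are
    significant (|slope| > z * SE of the slope; exact curves with zero SE
    only need a nonzero slope) and of opposite sign.
    """
    theta = np.asarray(theta, dtype=float)
    if len(theta) < 3:
        raise ValueError("grid must contain at least 3 points")
    if np.any(np.diff(theta) <= 0):
        raise ValueError("grid must be sorted strictly increasing")
    u1 = np.asarray(U_X_given_G, dtype=float)
    u2 = np.asarray(U_G_given_X, dtype=float)
    se_X = np.zeros_like(u1) if se_X is None else np.asarray(se_X, dtype=float)
    se_G = np.zeros_like(u2) if se_G is None else np.asarray(se_G, dtype=float)
    dth = np.diff(theta)
    s1 = np.diff(u1) / dth
    s2 = np.diff(u2) / dth
    e1 = np.sqrt(se_X[:-1] ** 2 + se_X[1:] ** 2) / dth
    e2 = np.sqrt(se_G[:-1] ** 2 + se_G[1:] ** 2) / dth
    sig = (np.abs(s1) > z * e1) & (np.abs(s2) > z * e2)
    flags = sig & (s1 * s2 < 0)
    intervals = []
    i = 0
    while i < len(flags):
        if flags[i]:
            j = i
            while j + 1 < len(flags) and flags[j + 1]:
                j += 1
            intervals.append((float(theta[i]), float(theta[j + 1])))
            i = j + 1
        else:
            i += 1
    return DualityScan(theta, u1, u2, intervals, flags)
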