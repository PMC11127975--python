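"""Baseline reconstruction scorers and graph-free predictors.

Reconstruction is cast as binary classification of vertex pairs: a scorer
turns a time series into a score matrix S whose entry S_ij should correlate
with the presence of edge (i, j); accuracy is the AUC of the ROC curve.
Three scorers are provided: Pearson correlation, a lag-1 Granger
variance-ratio, and plug-in transfer entropy.

Prediction is cast as learning next-state activation probabilities without
the graph: a logistic regression or a one-hidden-layer perceptron maps the
full state X_t to per-vertex probabilities through a logistic link, trained
by gradient descent on the cross-entropy of realized transitions. The mean
absolute error against the true transition probabilities P* measures how
much predictive information the graph carried.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from ._util import as_rng, xlog2x
from .dynamics import TimeSeries
from .graphs import SimpleGraph

__all__ = [
    "ScoreMatrix",
    "correlation_scores",
    "granger_scores",
    "transfer_entropy_scores",
    "auc_roc",
    "PredictorModel",
    "train_predictor",
    "predict",
    "mae",
]


@dataclass
class ScoreMatrix:
    """Pairwise edge scores; ``higher_is_edge`` records the ranking direction."""

    S: np.ndarray
    method: str
    symmetric: bool
    higher_is_edge: bool = True

    def ranking_scores(self) -> np.ndarray:
        """Symmetrized, direction-normalized scores for AUC evaluation.

        Asymmetric scorers are reduced to undirected scores by the maximum
        of the two directions; decreasing-with-edge scores (the Granger
        variance ratio) are flipped to 1 - S.
        """
        S = self.S if self.higher_is_edge else 1.0 - self.S
        if not self.symmetric:
            S = np.maximum(S, S.T)
        return S


def _states(x) -> np.ndarray:
    return x.states if isinstance(x, TimeSeries) else np.asarray(x)


def correlation_scores(x) -> ScoreMatrix:
    """Pearson correlation of vertex time series (symmetric).

    Constant series have undefined correlation; their scores are set to 0.
    """
    s = _states(x).astype(float)
    if s.shape[1] < 2:
        raise ValueError("need T >= 2")
    sd = s.std(axis=1)
    constant = sd == 0
    sd_safe = np.where(constant, 1.0, sd)
    z = (s - s.mean(axis=1, keepdims=True)) / sd_safe[:, None]
    C = (z @ z.T) / s.shape[1]
    C[constant, :] = 0.0
    C[:, constant] = 0.0
    np.fill_diagonal(C, 0.0)
    return ScoreMatrix(C, "correlation", symmetric=True)


def granger_scores(x) -> ScoreMatrix:
    """Lag-1 linear Granger score S_ij = Sigma_ij / Sigma_i.

    Sigma_i is the residual variance of the autoregression of vertex i on
    its own past; Sigma_ij additionally includes vertex j's past. The ratio
    is <= 1 and *decreases* with edge strength, so ``higher_is_edge`` is
    False and AUC evaluation consumes 1 - S. Least squares is solved with
    the minimum-norm pseudo-inverse, which also covers singular designs.
    """
    s = _states(x).astype(float)
    N, T = s.shape
    if T < 3:
        raise ValueError("need T >= 3")
    past = s[:, :-1]
    ones = np.ones(T - 1)
    S = np.ones((N, N))
    for i in range(N):
        y = s[i, 1:]
        X_own = np.column_stack([ones, past[i]])
        resid = y - X_own @ np.linalg.lstsq(X_own, y, rcond=None)[0]
        sigma_i = float(resid @ resid) / (T - 1)
        for j in range(N):
            if j == i:
                continue
            X_both = np.column_stack([ones, past[i], past[j]])
            r2 = y - X_both @ np.linalg.lstsq(X_both, y, rcond=None)[0]
            sigma_ij = float(r2 @ r2) / (T - 1)
            S[i, j] = sigma_ij / sigma_i if sigma_i > 0 else 1.0
    np.fill_diagonal(S, 1.0)
    return ScoreMatrix(S, "granger", symmetric=False, higher_is_edge=False)


def transfer_entropy_scores(x) -> ScoreMatrix:
    """Plug-in transfer entropy T_{X_j -> X_i} (bits), pooled over time.

    T = H(X_i,t | X_i,t-1) - H(X_i,t | X_i,t-1, X_j,t-1) with conditional
    entropies from maximum-likelihood estimates of the pooled transition
    tables; empty bins follow the 0 log 0 convention.
    """
    s = _states(x).astype(np.int64)
    N, T = s.shape
    if T < 3:
        raise ValueError("need T >= 3")
    D = T - 1
    prev = s[:, :-1]
    nxt = s[:, 1:]
    S = np.zeros((N, N))
    # H(X_i,t | X_i,t-1) per vertex
    h_self = np.empty(N)
    for i in range(N):
        joint = np.zeros((2, 2))
        np.add.at(joint, (prev[i], nxt[i]), 1.0)
        joint /= D
        h_self[i] = _cond_entropy(joint)
    for i in range(N):
        for j in range(N):
            if i == j:
                continue
            joint = np.zeros((2, 2, 2))
            np.add.at(joint, (prev[i], prev[j], nxt[i]), 1.0)
            joint /= D
            h_pair = _cond_entropy(joint.reshape(4, 2))
            S[i, j] = h_self[i] - h_pair
    return ScoreMatrix(S, "transfer_entropy", symmetric=False)


def _cond_entropy(joint: np.ndarray) -> float:
    """H(Y | Z) in bits from a joint table with Z as leading axis."""
    pz = joint.sum(axis=1)
    return float(-np.sum(xlog2x(joint)) + np.sum(xlog2x(pz)))


def auc_roc(scores: ScoreMatrix, g: SimpleGraph) -> float:
    """Probability that the scorer ranks an edge above a non-edge.

    Rank-based (Mann-Whitney) AUC over the off-diagonal unordered pairs,
    with average ranks for ties.
    """
    S = scores.ranking_scores()
    iu = np.triu_indices(g.N, k=1)
    y = g.adjacency_matrix()[iu].astype(int)
    vals = S[iu]
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one edge and one non-edge")
    return float(roc_auc_score(y, vals))


# ---------------------------------------------------------------------------
# Graph-free predictors
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    epochs: int = 500
    step_size: float = 0.05
    hidden: int = 32
    seed: int = 0
    outer_relu: bool = False  # "paper-literal" MLP head (restricts output to [1/2, 1))


@dataclass
class PredictorModel:
    """Graph-free next-state predictor with a logistic output link."""

    kind: str  # "logistic" | "mlp"
    weights: dict
    config: TrainConfig
    loss_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def N(self) -> int:
        key = "A" if self.kind == "logistic" else "W1"
        return self.weights[key].shape[-1]

    def logits(self, X: np.ndarray) -> np.ndarray:
        """f(X_t) for a batch of states, shape (D, N) -> (D, N)."""
        w = self.weights
        if self.kind == "logistic":
            return X @ w["A"].T + w["b"]
        h = np.maximum(X @ w["W1"].T + w["b1"], 0.0)
        f = h @ w["W2"].T + w["b2"]
        if self.config.outer_relu:
            f = np.maximum(f, 0.0)
        return f


def _stack_transitions(series: Sequence[TimeSeries]):
    xs, ys = [], []
    for ts in series:
        s = _states(ts).astype(float)
        xs.append(s[:, :-1].T)
        ys.append(s[:, 1:].T)
    return np.vstack(xs), np.vstack(ys)


def train_predictor(
    kind: str, series: Sequence[TimeSeries], config: Optional[TrainConfig] = None
) -> PredictorModel:
    """Fit a logistic or MLP predictor of P(X_{i,t+1} = 1 | X_t) by
    full-batch gradient descent on the cross-entropy of realized transitions.

    Training pools the transitions of all provided series (the intended use
    concatenates series generated on different graphs, so the model cannot
    rely on any single structure). Returns the model with its loss trace;
    training aborts with an error if the loss becomes non-finite.
    """
    config = config or TrainConfig()
    X, Y = _stack_transitions(series)
    D, N = X.shape
    rng = as_rng(config.seed)
    if kind == "logistic":
        w = {"A": rng.normal(0, 0.01, (N, N)), "b": np.zeros(N)}
    elif kind == "mlp":
        h = config.hidden
        w = {
            "W1": rng.normal(0, math.sqrt(2.0 / N), (h, N)),
            "b1": np.zeros(h),
            "W2": rng.normal(0, math.sqrt(2.0 / h), (N, h)),
            "b2": np.zeros(N),
        }
    else:
        raise ValueError("kind must be 'logistic' or 'mlp'")
    model = PredictorModel(kind, w, config)
    trace = []
    lr = config.step_size
    for _ in range(config.epochs):
        if kind == "logistic":
            P = expit(X @ w["A"].T + w["b"])
            G = (P - Y) / D  # d(mean CE)/d logits
            w["A"] -= lr * (G.T @ X)
            w["b"] -= lr * G.sum(axis=0)
        else:
            Z1 = X @ w["W1"].T + w["b1"]
            H1 = np.maximum(Z1, 0.0)
            F = H1 @ w["W2"].T + w["b2"]
            Fo = np.maximum(F, 0.0) if config.outer_relu else F
            P = expit(Fo)
            G = (P - Y) / D
            if config.outer_relu:
                G = G * (F > 0)
            gW2 = G.T @ H1
            gH1 = (G @ w["W2"]) * (Z1 > 0)
            w["W2"] -= lr * gW2
            w["b2"] -= lr * G.sum(axis=0)
            w["W1"] -= lr * (gH1.T @ X)
            w["b1"] -= lr * gH1.sum(axis=0)
        eps = 1e-12
        loss = float(-np.mean(Y * np.log(P + eps) + (1 - Y) * np.log(1 - P + eps)))
        if not math.isfinite(loss):
            raise RuntimeError(f"training diverged (loss={loss}); config={config}")
        trace.append(loss)
    model.loss_trace = np.asarray(trace)
    return model


def predict(model: PredictorModel, x) -> np.ndarray:
    """Predicted activation probabilities P_hat[i, t] for every time step of x."""
    s = _states(x).astype(float)
    if s.shape[0] != model.N:
        raise ValueError("model/time-series vertex-count mismatch")
    return expit(model.logits(s.T)).T


def mae(P_star: np.ndarray, P_hat: np.ndarray) -> float:
    """Mean absolute error (1/NT) sum |P*_it - P_hat_it|."""
    P_star = np.asarray(P_star, dtype=float)
    P_hat = np.asarray(P_hat, dtype=float)
    if P_star.shape != P_hat.shape:
        raise ValueError("shape mismatch")
    return float(np.mean(np.abs(P_star - P_hat)))
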