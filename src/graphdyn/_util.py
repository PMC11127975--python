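"""Shared numerical helpers (base-2 log-space arithmetic, RNG coercion)."""

from __future__ import annotations

import math

import numpy as np

LN2 = math.log(2.0)


def as_rng(seed_or_rng) -> np.random.Generator:
    """Coerce an int seed, None, or an existing Generator into a Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def log2sumexp(a, axis=None):
    """log2(sum(2**a)) computed stably; tolerates -inf entries."""
    a = np.asarray(a, dtype=float)
    m = np.max(a, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    out = np.log2(np.sum(np.exp2(a - m), axis=axis)) + np.squeeze(m, axis=axis)
    return out


def xlog2x(p):
    """p * log2(p) with the 0*log(0) := 0 convention."""
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(p)
    mask = p > 0
    out[mask] = p[mask] * np.log2(p[mask])
    return out


def entropy_bits(p, axis=None):
    """Shannon entropy of a (possibly unnormalized-checked elsewhere) pmf, in bits."""
    return -np.sum(xlog2x(p), axis=axis)


def log2_comb(n: int, k: int) -> float:
    """log2 of the binomial coefficient, overflow-free."""
    if k < 0 or k > n:
        return -math.inf
    return (
        math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
    ) / LN2


def log2_factorial(n: int) -> float:
    return math.lgamma(n + 1) / LN2


def log2_double_factorial_even(m: int) -> float:
    """log2 of (2m)!! = 2^m * m!."""
    return m + math.lgamma(m + 1) / LN2
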