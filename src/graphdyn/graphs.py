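"""Random-graph ensembles (priors) over which dynamics evolve.

Two ensembles are provided, each with exact log-probability (in bits),
seeded sampling, and exhaustive support enumeration for small systems:

* :class:`ErdosRenyiPrior` — uniform over all simple graphs with ``N``
  vertices and exactly ``E`` edges.
* :class:`ConfigurationModelPrior` — the stub-matching law over loopy
  multigraphs with a fixed degree sequence ``k``; the probability of a
  multigraph ``g`` is ``(2E)!! / (2E)! * prod_i k_i! / (prod_{i<j} M_ij!
  prod_i (2 M_ii)!!)`` where ``M_ij`` counts parallel edges and ``M_ii``
  self-loops (each self-loop contributes 2 to the degree).

Vertices are 0-based. All probabilities are base-2 logarithms (bits).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from ._util import (
    as_rng,
    log2_comb,
    log2_double_factorial_even,
    log2_factorial,
)

__all__ = [
    "SimpleGraph",
    "LoopyMultigraph",
    "ErdosRenyiPrior",
    "ConfigurationModelPrior",
    "make_degree_sequence",
    "read_edge_list",
    "write_edge_list",
    "read_degree_sequence",
    "degrees_from_edge_list_file",
]


class OutOfSupportError(ValueError):
    """Raised when a graph cannot belong to a prior's support at all."""


def _norm_edge(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i <= j else (j, i)


@dataclass(frozen=True)
class SimpleGraph:
    """Undirected simple graph: ``N`` vertices, a frozenset of (i, j) pairs, i < j."""

    N: int
    edges: frozenset

    def __post_init__(self):
        object.__setattr__(
            self, "edges", frozenset(_norm_edge(i, j) for (i, j) in self.edges)
        )
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop ({i},{j}) in a simple graph")
            if not (0 <= i < self.N and 0 <= j < self.N):
                raise ValueError(f"edge ({i},{j}) outside [0,{self.N})")

    @property
    def edge_count(self) -> int:
        return len(self.edges)

    def adjacency_matrix(self) -> np.ndarray:
        A = np.zeros((self.N, self.N), dtype=np.int64)
        for i, j in self.edges:
            A[i, j] += 1
            A[j, i] += 1
        return A

    def degrees(self) -> np.ndarray:
        return self.adjacency_matrix().sum(axis=1)

    def has_edge(self, i: int, j: int) -> bool:
        return _norm_edge(i, j) in self.edges


@dataclass(frozen=True)
class LoopyMultigraph:
    """Loopy multigraph: multiplicities ``M_ij`` for unordered pairs, i ≤ j.

    The degree identity is ``k_i = sum_{j != i} M_ij + 2 M_ii``: a self-loop
    uses two stubs of its vertex.
    """

    N: int
    multiedges: tuple  # sorted tuple of ((i, j), count), i <= j, count >= 1

    @classmethod
    def from_dict(cls, N: int, counts: dict) -> "LoopyMultigraph":
        items = []
        for (i, j), c in counts.items():
            if c < 0:
                raise ValueError("negative multiplicity")
            if c == 0:
                continue
            if not (0 <= i < N and 0 <= j < N):
                raise ValueError(f"pair ({i},{j}) outside [0,{N})")
            items.append((_norm_edge(i, j), int(c)))
        merged: dict = {}
        for e, c in items:
            merged[e] = merged.get(e, 0) + c
        return cls(N, tuple(sorted(merged.items())))

    @classmethod
    def from_edge_instances(cls, N: int, instances) -> "LoopyMultigraph":
        counts: dict = {}
        for i, j in instances:
            e = _norm_edge(i, j)
            counts[e] = counts.get(e, 0) + 1
        return cls.from_dict(N, counts)

    def counts(self) -> dict:
        return dict(self.multiedges)

    def edge_instances(self) -> list:
        out = []
        for (i, j), c in self.multiedges:
            out.extend([(i, j)] * c)
        return out

    @property
    def edge_count(self) -> int:
        return sum(c for _, c in self.multiedges)

    def adjacency_matrix(self) -> np.ndarray:
        """Matrix whose row sums are the degrees: A_ij = M_ij, A_ii = 2 M_ii."""
        A = np.zeros((self.N, self.N), dtype=np.int64)
        for (i, j), c in self.multiedges:
            if i == j:
                A[i, i] += 2 * c
            else:
                A[i, j] += c
                A[j, i] += c
        return A

    def degrees(self) -> np.ndarray:
        return self.adjacency_matrix().sum(axis=1)


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ErdosRenyiPrior:
    """Uniform ensemble over simple graphs with fixed vertex and edge counts."""

    N: int
    E: int

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be positive")
        if not (0 <= self.E <= self.max_edges):
            raise ValueError(
                f"E={self.E} outside [0, {self.max_edges}] for N={self.N}"
            )

    @property
    def max_edges(self) -> int:
        return self.N * (self.N - 1) // 2

    def support_size(self) -> int:
        return math.comb(self.max_edges, self.E)

    def entropy(self) -> float:
        """H(G) in bits: log2 of the support size."""
        return log2_comb(self.max_edges, self.E)

    def log_prob(self, g: SimpleGraph) -> float:
        """-log2 C(C(N,2), E) for in-support graphs, -inf otherwise."""
        if not isinstance(g, SimpleGraph) or g.N != self.N:
            raise OutOfSupportError("graph/prior vertex-count mismatch")
        if g.edge_count != self.E:
            return -math.inf
        return -self.entropy()

    def sample(self, rng) -> SimpleGraph:
        rng = as_rng(rng)
        pairs = list(itertools.combinations(range(self.N), 2))
        idx = rng.choice(len(pairs), size=self.E, replace=False)
        return SimpleGraph(self.N, frozenset(pairs[i] for i in idx))

    def support(self, cap: int = 10**6):
        """Yield every graph of the ensemble once; refuse if larger than ``cap``."""
        size = self.support_size()
        if size > cap:
            raise ValueError(
                f"support size {size} exceeds cap {cap}; "
                "use sampling-based estimators instead"
            )
        pairs = list(itertools.combinations(range(self.N), 2))
        for combo in itertools.combinations(pairs, self.E):
            yield SimpleGraph(self.N, frozenset(combo))


@dataclass(frozen=True)
class ConfigurationModelPrior:
    """Stub-matching ensemble of loopy multigraphs with a fixed degree sequence."""

    degrees: tuple

    def __post_init__(self):
        k = tuple(int(d) for d in self.degrees)
        object.__setattr__(self, "degrees", k)
        if any(d < 0 for d in k):
            raise ValueError("degrees must be non-negative")
        if sum(k) % 2 != 0:
            raise ValueError("degree sum must be even")

    @property
    def N(self) -> int:
        return len(self.degrees)

    @property
    def E(self) -> int:
        return sum(self.degrees) // 2

    def log_prob(self, g: LoopyMultigraph) -> float:
        if not isinstance(g, LoopyMultigraph) or g.N != self.N:
            raise OutOfSupportError("graph/prior vertex-count mismatch")
        if tuple(g.degrees()) != self.degrees:
            return -math.inf
        E = self.E
        lp = log2_double_factorial_even(E) - log2_factorial(2 * E)
        lp += sum(log2_factorial(k) for k in self.degrees)
        for (i, j), c in g.multiedges:
            if i == j:
                lp -= log2_double_factorial_even(c)
            else:
                lp -= log2_factorial(c)
        return lp

    def sample(self, rng) -> LoopyMultigraph:
        """Uniform stub matching: pair a random permutation of half-edges."""
        rng = as_rng(rng)
        stubs = np.repeat(np.arange(self.N), self.degrees)
        perm = rng.permutation(stubs)
        instances = [(int(perm[2 * e]), int(perm[2 * e + 1])) for e in range(self.E)]
        return LoopyMultigraph.from_edge_instances(self.N, instances)

    def support(self, cap: int = 10**6):
        """Enumerate distinct multigraphs by exhausting all stub matchings."""
        n_matchings = _double_factorial_odd(2 * self.E - 1)
        if n_matchings > cap:
            raise ValueError(
                f"{n_matchings} stub matchings exceed cap {cap}"
            )
        stubs = []
        for v, k in enumerate(self.degrees):
            stubs.extend([v] * k)
        seen = set()
        for matching in _all_matchings(tuple(stubs)):
            g = LoopyMultigraph.from_edge_instances(self.N, matching)
            if g.multiedges not in seen:
                seen.add(g.multiedges)
                yield g

    def entropy(self, cap: int = 10**6) -> float:
        """H(G) in bits by exhaustive enumeration (small supports only)."""
        h = 0.0
        for g in self.support(cap=cap):
            lp = self.log_prob(g)
            h -= math.exp2(lp) * lp
        return h


def _double_factorial_odd(n: int) -> int:
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


def _all_matchings(stubs: tuple):
    """All perfect matchings of an even-length stub list (first-element anchored)."""
    if not stubs:
        yield []
        return
    a = stubs[0]
    rest = stubs[1:]
    for pos in range(len(rest)):
        b = rest[pos]
        remainder = rest[:pos] + rest[pos + 1 :]
        for tail in _all_matchings(remainder):
            yield [(a, b)] + tail


# ---------------------------------------------------------------------------
# Degree sequences
# ---------------------------------------------------------------------------


def make_degree_sequence(
    N: int,
    E: int,
    *,
    p: float = 5.0 / 6.0,
    rng=None,
    tolerance: float = 0.05,
    max_retries: int = 1000,
) -> tuple:
    """Draw a geometric degree sequence conditioned to sum to exactly 2E.

    Degrees are i.i.d. geometric, rho(k) = (1 - p) p^k for k >= 0 (mean
    p/(1-p), so p = 5/6 gives mean degree 5). Sequences are redrawn until
    the sum lies within ``tolerance * 2E`` of the target, then repaired by
    unit increments/decrements on random entries.
    """
    rng = as_rng(rng)
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    target = 2 * E
    tol = max(2, int(round(tolerance * target)))
    for _ in range(max_retries):
        k = rng.geometric(1.0 - p, size=N) - 1
        if abs(int(k.sum()) - target) <= tol:
            break
    else:
        raise RuntimeError(
            f"could not reach degree sum near {target} in {max_retries} draws"
        )
    k = k.astype(np.int64)
    while k.sum() < target:
        k[rng.integers(N)] += 1
    while k.sum() > target:
        i = rng.integers(N)
        if k[i] > 0:
            k[i] -= 1
    return tuple(int(d) for d in k)


# ---------------------------------------------------------------------------
# Edge-list / degree-sequence files
# ---------------------------------------------------------------------------


def _parse_edge_lines(path, index_base: int):
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"malformed edge line: {line!r}")
            i, j = int(parts[0]) - index_base, int(parts[1]) - index_base
            if i < 0 or j < 0:
                raise ValueError(f"negative vertex after 0-basing: {line!r}")
            yield i, j


def read_edge_list(path, *, index_base: int = 0, multigraph: bool = False, N=None):
    """Read a whitespace-separated edge list ('i j' per line, '#' comments).

    Duplicate lines collapse for simple graphs and accumulate multiplicity
    for multigraphs; ``index_base=1`` accepts 1-based files.
    """
    instances = list(_parse_edge_lines(path, index_base))
    n = max((max(i, j) for i, j in instances), default=-1) + 1
    if N is not None:
        n = max(n, N)
    if multigraph:
        return LoopyMultigraph.from_edge_instances(n, instances)
    return SimpleGraph(n, frozenset(_norm_edge(i, j) for i, j in instances))


def write_edge_list(graph, path, *, index_base: int = 0):
    with open(path, "w") as fh:
        fh.write(f"# N={graph.N}\n")
        if isinstance(graph, LoopyMultigraph):
            items = graph.edge_instances()
        else:
            items = sorted(graph.edges)
        for i, j in items:
            fh.write(f"{i + index_base} {j + index_base}\n")


def read_degree_sequence(path) -> tuple:
    """One integer per line; '#' comments allowed."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.append(int(line))
    return tuple(out)


def degrees_from_edge_list_file(path, *, index_base: int = 0, N=None) -> tuple:
    """Degree sequence of an edge-list file (multiplicities accumulate)."""
    g = read_edge_list(path, index_base=index_base, multigraph=True, N=N)
    return tuple(int(d) for d in g.degrees())
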