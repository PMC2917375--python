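"""Rate matrices and transition/equilibrium probabilities.

The presence/absence of each hyperedge evolves as a continuous-time Markov
chain.  Under the *independent-edge* model each edge toggles with constant
rates (insertion λ, deletion μ).  Under the *neighbor-dependent* model both
rates are weighted by the neighborhood component ν — the fraction of an
edge's neighbors present in the current network.  The *hybrid* model mixes
the two with a weight δ ∈ [0,1] (the neighbor-dependence probability):

    rate(x -> y flipping edge i) = [(1-δ) + δ·ν_x(i)] · q,  q = λ or μ.

δ=0 recovers the independent-edge model exactly; δ=1 the neighbor-dependent
model.  The joint chain over the m alterable edges has 2^m states; dense
generators are built up to m=14, beyond which callers should use the
pseudo-likelihood decomposition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from scipy.linalg import expm
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .hypernet import EdgeMask, InputError, ReferenceNetwork

__all__ = [
    "EvolutionParams",
    "NetworkGenerator",
    "CapacityError",
    "ReducibleChainError",
    "MAX_DENSE_EDGES",
    "hybrid_scale",
    "edge_rate_matrix",
    "edge_transition",
    "full_generator",
    "transition_probabilities",
    "equilibrium",
]

#: largest alterable-edge count for which a dense 2^m generator is built
MAX_DENSE_EDGES = 14


class CapacityError(ValueError):
    """State space too large for dense matrix work."""


class ReducibleChainError(ValueError):
    """The chain is not irreducible; no unique equilibrium exists."""


@dataclass(frozen=True)
class EvolutionParams:
    """Hybrid-model parameters: insertion rate λ, deletion rate μ, weight δ."""

    lam: float
    mu: float
    delta: float = 0.0

    def __post_init__(self):
        if not (self.lam > 0 and self.mu > 0):
            raise InputError(f"rates must be positive, got lam={self.lam}, mu={self.mu}")
        if not 0.0 <= self.delta <= 1.0:
            raise InputError(f"delta must be in [0,1], got {self.delta}")

    def astuple(self) -> Tuple[float, float, float]:
        return (self.lam, self.mu, self.delta)


def hybrid_scale(nu: float, delta: float) -> float:
    """Rate multiplier (1-δ) + δ·ν mixing the two models."""
    if not 0.0 <= nu <= 1.0:
        raise InputError(f"nu must be in [0,1], got {nu}")
    if not 0.0 <= delta <= 1.0:
        raise InputError(f"delta must be in [0,1], got {delta}")
    return (1.0 - delta) + delta * nu


def edge_rate_matrix(
    params: EvolutionParams, nu: float, nu_del: float | None = None
) -> np.ndarray:
    """2x2 generator for one hyperedge over states {absent, present}.

    ``nu`` scales the insertion rate; ``nu_del`` (defaulting to ``nu``) the
    deletion rate — they differ when ν is evaluated on the source state of
    each move, whose presence count includes the edge itself only for
    deletions.
    """
    if nu_del is None:
        nu_del = nu
    a = hybrid_scale(nu, params.delta) * params.lam  # absent -> present
    b = hybrid_scale(nu_del, params.delta) * params.mu  # present -> absent
    return np.array([[-a, a], [b, -b]], dtype=float)


def edge_transition(a: float, b: float, t: float) -> np.ndarray:
    """Closed-form 2-state CTMC transition matrix for rates a (0->1), b (1->0)."""
    if t < 0:
        raise InputError(f"branch length must be >= 0, got {t}")
    s = a + b
    if s == 0.0 or t == 0.0:
        return np.eye(2)
    e = math.exp(-s * t)
    return np.array(
        [
            [(b + a * e) / s, (a - a * e) / s],
            [(b - b * e) / s, (a + b * e) / s],
        ]
    )


@dataclass(frozen=True)
class NetworkGenerator:
    """Dense 2^m x 2^m generator over the joint alterable-edge states.

    State indexing: bit k of the index is the state of ``alterable[k]``; the
    least-significant bit is the lowest alterable edge index.  Core and
    prohibited edges are excluded from the index and re-inserted (1/0) when
    the neighborhood component is evaluated.
    """

    matrix: np.ndarray = field(repr=False)
    alterable: Tuple[int, ...]
    M: int
    core: frozenset

    @property
    def m(self) -> int:
        return len(self.alterable)

    @property
    def size(self) -> int:
        return self.matrix.shape[0]

    def index_of(self, bits: np.ndarray) -> int:
        """Joint-state index of a full M-bit state (mask bits ignored)."""
        idx = 0
        for k, i in enumerate(self.alterable):
            if bits[i]:
                idx |= 1 << k
        return idx

    def bits_of(self, index: int) -> np.ndarray:
        """Full M-bit state for a joint-state index (core=1, prohibited=0)."""
        bits = np.zeros(self.M, dtype=np.int8)
        for i in self.core:
            bits[i] = 1
        for k, i in enumerate(self.alterable):
            bits[i] = (index >> k) & 1
        return bits


def full_generator(
    ref: ReferenceNetwork,
    params: EvolutionParams,
    mask: EdgeMask | None = None,
    nu_scope: str = "network",
) -> NetworkGenerator:
    """Joint generator of the hybrid model over all alterable edges.

    Rates between states differing at exactly one alterable edge follow the
    hybrid rule with ν evaluated on the source state (full M-bit vector with
    the mask re-applied); all other off-diagonal rates are zero.
    """
    mask = mask or EdgeMask()
    alterable = mask.alterable(ref.M)
    m = len(alterable)
    if m > MAX_DENSE_EDGES:
        raise CapacityError(
            f"{m} alterable edges -> 2^{m} states exceeds the dense limit "
            f"(m <= {MAX_DENSE_EDGES}); use the pseudo-likelihood decomposition"
        )
    lam, mu, delta = params.astuple()

    # integer bitmask arithmetic over the full M-edge universe
    core_bits = 0
    for i in mask.core:
        core_bits |= 1 << i
    nbr_bits = [0] * ref.M
    for i in range(ref.M):
        for j in ref.neighbor_map[i]:
            nbr_bits[i] |= 1 << j
    ref_nbr_count = [len(ref.neighbor_map[i]) for i in range(ref.M)]

    if nu_scope not in ("network", "reference"):
        raise InputError(f"unknown neighborhood scope {nu_scope!r}")
    size = 1 << m
    Q = np.zeros((size, size))
    if ref.M <= 63:
        # vectorized path: states as uint64 bitmasks over the full edge set
        x = np.arange(size, dtype=np.uint64)
        full = np.full(size, core_bits, dtype=np.uint64)
        for k, i in enumerate(alterable):
            full |= ((x >> np.uint64(k)) & np.uint64(1)) << np.uint64(i)
        n_present = np.bitwise_count(full).astype(float)
        rows = np.arange(size)
        for k, i in enumerate(alterable):
            present = ((full >> np.uint64(i)) & np.uint64(1)).astype(bool)
            num = np.bitwise_count(full & np.uint64(nbr_bits[i])).astype(float)
            if nu_scope == "network":
                nu = np.divide(num, n_present, out=np.zeros(size), where=n_present > 0)
            else:
                d = ref_nbr_count[i]
                nu = num / d if d > 0 else np.zeros(size)
            q = np.where(present, mu, lam)
            Q[rows, x.astype(np.intp) ^ (1 << k)] = ((1.0 - delta) + delta * nu) * q
    else:
        for xi in range(size):
            full_i = core_bits
            for k, i in enumerate(alterable):
                if (xi >> k) & 1:
                    full_i |= 1 << i
            n_present = full_i.bit_count()
            for k, i in enumerate(alterable):
                present = (full_i >> i) & 1
                num = (nbr_bits[i] & full_i).bit_count()
                if nu_scope == "network":
                    nu = num / n_present if n_present > 0 else 0.0
                else:
                    nu = num / ref_nbr_count[i] if ref_nbr_count[i] > 0 else 0.0
                q = mu if present else lam
                Q[xi, xi ^ (1 << k)] = ((1.0 - delta) + delta * nu) * q
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return NetworkGenerator(Q, alterable, ref.M, frozenset(mask.core))


def _matrix_of(generator) -> np.ndarray:
    return generator.matrix if isinstance(generator, NetworkGenerator) else np.asarray(generator)


def transition_probabilities(generator, t: float) -> np.ndarray:
    """Stochastic matrix exp(Q·t); identity at t=0."""
    if t < 0:
        raise InputError(f"branch length must be >= 0, got {t}")
    Q = _matrix_of(generator)
    if t == 0.0:
        return np.eye(Q.shape[0])
    P = expm(Q * t)
    # exp of a generator is stochastic up to roundoff; clip tiny negatives
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


def equilibrium(generator) -> np.ndarray:
    """Stationary distribution π solving πQ = 0, Σπ = 1.

    Raises :class:`ReducibleChainError` when the chain is reducible (e.g.
    δ=1 with the empty network absorbing), naming the closed class.
    """
    Q = _matrix_of(generator)
    n = Q.shape[0]
    if n == 1:
        return np.ones(1)
    adj = csr_matrix((Q > 0).astype(np.int8))
    n_comp, labels = connected_components(adj, directed=True, connection="strong")
    if n_comp > 1:
        # a closed class has no positive rate leaving it
        closed = []
        for c in range(n_comp):
            members = np.flatnonzero(labels == c)
            outside = np.flatnonzero(labels != c)
            if not outside.size or not np.any(Q[np.ix_(members, outside)] > 0):
                closed.append(members)
        desc = "; ".join(
            "states {" + ", ".join(map(str, mem[:8])) + ("...}" if mem.size > 8 else "}")
            for mem in closed
        )
        raise ReducibleChainError(
            f"chain is reducible ({n_comp} communicating classes); "
            f"absorbing class(es): {desc}"
        )
    A = Q.T.copy()
    A[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    pi = np.linalg.solve(A, b)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    resid = np.abs(pi @ Q).max()
    if resid > 1e-8:
        raise ReducibleChainError(f"equilibrium solve failed, ||piQ||_inf = {resid:.3g}")
    return pi
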