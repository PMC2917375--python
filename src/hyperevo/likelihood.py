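"""Exact and pseudo-likelihoods of network evolution, and model comparison.

The exact pairwise likelihood of evolving network x into network y over a
branch of length t is the (x, y) entry of exp(Qt) for the joint generator
over the alterable edges, conditioned on the starting network x (no root
prior).  This is dense-matrix work and is limited to small systems, so a
composite *pseudo-likelihood* is provided for larger ones: the alterable
edges are partitioned greedily into sub-networks of at most N hyperedges by
descending neighbor count, and the exact likelihoods of the blocks are
multiplied.  Within a block the neighborhood component is, by default,
restricted to the block (neighbors outside it are invisible — the border
effect); a global-scope variant freezes the out-of-block edges at the
ancestor state instead.

Tree likelihoods come in two forms: conditioned on a full assignment of
internal states (a sum of branch terms plus a root prior), or integrated
over internal states by Felsenstein pruning over the joint state space.

Log-probabilities of impossible transitions are ``-inf``, which propagates
correctly through sums and comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import chi2

from .evomodel import (
    CapacityError,
    EvolutionParams,
    equilibrium,
    full_generator,
    transition_probabilities,
)
from .hypernet import (
    EdgeMask,
    InputError,
    ReferenceNetwork,
    as_state,
    validate_state,
)
from .phylo import Phylogeny

__all__ = [
    "MAX_PRUNING_EDGES",
    "SubnetworkPartition",
    "pairwise_loglik_exact",
    "decompose_subnetworks",
    "pseudo_loglik",
    "PseudoLikelihood",
    "tree_loglik_given_internals",
    "tree_loglik_pruning",
    "model_fit_lrt",
]

#: cap on alterable edges for full pruning tables (2^m likelihood vectors)
MAX_PRUNING_EDGES = 10

NEG_INF = float("-inf")


def _safe_log(p: float) -> float:
    return math.log(p) if p > 0.0 else NEG_INF


@dataclass(frozen=True)
class SubnetworkPartition:
    """Ordered disjoint blocks of alterable edge indices, each of size <= N."""

    blocks: Tuple[Tuple[int, ...], ...]
    N: int

    def __iter__(self):
        return iter(self.blocks)

    def __len__(self):
        return len(self.blocks)


def pairwise_loglik_exact(
    ref: ReferenceNetwork,
    params: EvolutionParams,
    x: np.ndarray,
    y: np.ndarray,
    t: float,
    mask: EdgeMask | None = None,
    nu_scope: str = "network",
) -> float:
    """log P(y | x, t) under the hybrid model, by matrix exponentiation."""
    mask = mask or EdgeMask()
    x = as_state(x, ref.M)
    y = as_state(y, ref.M)
    validate_state(x, mask)
    validate_state(y, mask)
    gen = full_generator(ref, params, mask, nu_scope)
    P = transition_probabilities(gen, t)
    return _safe_log(float(P[gen.index_of(x), gen.index_of(y)]))


def decompose_subnetworks(
    ref: ReferenceNetwork, mask: EdgeMask | None = None, N: int = 1
) -> SubnetworkPartition:
    """Greedy neighborhood partition of the alterable edges into blocks <= N.

    A block grows by repeatedly (a) seeding with the pooled edge of highest
    remaining-neighbor count (ties to the lowest index) and (b) adding the
    seed's top pooled neighbors ranked the same way, up to the block cap;
    neighbor counts are recomputed among the remaining pool after every
    round, and a new block starts when the current one reaches N.  With
    N >= m this yields a single block covering all alterable edges; with
    N = 1, singleton blocks in seed-selection order.
    """
    if N < 1:
        raise InputError(f"block size cap must be >= 1, got {N}")
    mask = mask or EdgeMask()
    pool = set(mask.alterable(ref.M))
    blocks: List[Tuple[int, ...]] = []
    while pool:
        block: List[int] = []
        while pool and len(block) < N:
            counts = {i: len(ref.neighbor_map[i] & pool) for i in pool}
            seed = min(pool, key=lambda i: (-counts[i], i))
            block.append(seed)
            pool.discard(seed)
            room = N - len(block)
            if room > 0:
                nbrs = sorted(
                    ref.neighbor_map[seed] & pool, key=lambda j: (-counts[j], j)
                )[:room]
                block.extend(nbrs)
                pool.difference_update(nbrs)
        blocks.append(tuple(sorted(block)))
    return SubnetworkPartition(tuple(blocks), N)


def _block_generator(
    ref: ReferenceNetwork,
    params: EvolutionParams,
    block: Sequence[int],
    anchor_bits: np.ndarray,
) -> Tuple[np.ndarray, Tuple[int, ...]]:
    """2^b generator over block edges with ν evaluated on block + anchor.

    Out-of-block edges are frozen at the anchor state: for block scope the
    anchor is the core edges alone (out-of-block alterable edges invisible —
    the border effect), for global scope the ancestor's full network.  ν
    uses the whole-network neighbor relation and presence count over the
    anchored state.
    """
    block = tuple(sorted(block))
    b = len(block)
    lam, mu, delta = params.astuple()
    frozen = 0
    for i in range(ref.M):
        if i not in block and anchor_bits[i]:
            frozen |= 1 << i
    nbr_bits = [0] * ref.M
    for i in block:
        for j in ref.neighbor_map[i]:
            nbr_bits[i] |= 1 << j
    size = 1 << b
    Q = np.zeros((size, size))
    for x in range(size):
        full = frozen
        for k, i in enumerate(block):
            if (x >> k) & 1:
                full |= 1 << i
        n_present = full.bit_count()
        for k, i in enumerate(block):
            present = (full >> i) & 1
            num = (nbr_bits[i] & full).bit_count()
            nu = num / n_present if n_present > 0 else 0.0
            q = mu if present else lam
            Q[x, x ^ (1 << k)] = ((1.0 - delta) + delta * nu) * q
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q, block


def _sub_index(bits: np.ndarray, block: Sequence[int]) -> int:
    idx = 0
    for k, i in enumerate(block):
        if bits[i]:
            idx |= 1 << k
    return idx


class PseudoLikelihood:
    """Composite-likelihood evaluator over a fixed sub-network partition.

    Precomputes the partition and block sub-references once; caches per-block
    transition matrices keyed by (params, t) so repeated evaluations at the
    same parameters (e.g. within an MCMC iteration) are cheap.
    """

    def __init__(
        self,
        ref: ReferenceNetwork,
        mask: EdgeMask | None = None,
        N: int = 1,
        nu_scope: str = "block",
    ):
        if nu_scope not in ("block", "global"):
            raise InputError(f"nu_scope must be 'block' or 'global', got {nu_scope!r}")
        self.ref = ref
        self.mask = mask or EdgeMask()
        self.N = N
        self.nu_scope = nu_scope
        self.partition = decompose_subnetworks(ref, self.mask, N)
        # block-scope anchor: core edges present, everything else absent
        self._core_anchor = np.zeros(ref.M, dtype=np.int8)
        for i in self.mask.core:
            self._core_anchor[i] = 1
        # per-params LRU: params_key -> {"gen": [...], "P": {t: [...]}, "pi": [...]}
        self._cache: Dict[tuple, dict] = {}
        self._max_cached_params = 4

    def _entry(self, params: EvolutionParams) -> dict:
        key = params.astuple()
        if key not in self._cache:
            if len(self._cache) >= self._max_cached_params:
                oldest = next(iter(self._cache))
                del self._cache[oldest]
            self._cache[key] = {
                "gen": [
                    _block_generator(self.ref, params, blk, self._core_anchor)[0]
                    for blk in self.partition
                ],
                "P": {},
                "pi": None,
            }
        else:
            self._cache[key] = self._cache.pop(key)  # move to MRU position
        return self._cache[key]

    def _block_generators(self, params: EvolutionParams, anchor: Optional[np.ndarray]):
        if self.nu_scope == "global":
            # anchor-dependent; not cached across anchors
            return [
                _block_generator(self.ref, params, blk, anchor)[0]
                for blk in self.partition
            ]
        return self._entry(params)["gen"]

    def _block_transitions(
        self, params: EvolutionParams, t: float, anchor: Optional[np.ndarray]
    ):
        if self.nu_scope == "global":
            return [
                transition_probabilities(Q, t)
                for Q in self._block_generators(params, anchor)
            ]
        entry = self._entry(params)
        if t not in entry["P"]:
            entry["P"][t] = [
                transition_probabilities(Q, t) for Q in entry["gen"]
            ]
        return entry["P"][t]

    def branch_loglik(
        self, params: EvolutionParams, x: np.ndarray, y: np.ndarray, t: float
    ) -> float:
        """Sum of block-restricted exact log-likelihoods for one branch."""
        x = as_state(x, self.ref.M)
        y = as_state(y, self.ref.M)
        validate_state(x, self.mask)
        validate_state(y, self.mask)
        total = 0.0
        mats = self._block_transitions(params, t, x)
        for blk, P in zip(self.partition, mats):
            total += _safe_log(float(P[_sub_index(x, blk), _sub_index(y, blk)]))
        return total

    def root_logprior(self, params: EvolutionParams, bits: np.ndarray) -> float:
        """Pseudo-equilibrium root prior: product of block equilibria."""
        if self.nu_scope == "global":
            pis = [equilibrium(Q) for Q in self._block_generators(params, bits)]
        else:
            entry = self._entry(params)
            if entry["pi"] is None:
                entry["pi"] = [equilibrium(Q) for Q in entry["gen"]]
            pis = entry["pi"]
        total = 0.0
        for blk, pi in zip(self.partition, pis):
            total += _safe_log(float(pi[_sub_index(bits, blk)]))
        return total

    def tree_loglik(self, tree: Phylogeny, params: EvolutionParams) -> float:
        total = self.root_logprior(params, tree.root.state)
        for node in tree.preorder():
            for child in node.children:
                total += self.branch_loglik(params, node.state, child.state, child.length)
                if total == NEG_INF:
                    return NEG_INF
        return total


def pseudo_loglik(
    ref: ReferenceNetwork,
    params: EvolutionParams,
    x: np.ndarray,
    y: np.ndarray,
    t: float,
    mask: EdgeMask | None = None,
    N: int = 1,
    nu_scope: str = "block",
) -> float:
    """Composite log-likelihood of x -> y over t via sub-network blocks."""
    ev = PseudoLikelihood(ref, mask, N, nu_scope)
    return ev.branch_loglik(params, x, y, t)


def _check_assigned(tree: Phylogeny) -> None:
    for node in tree.postorder():
        if node.state is None:
            raise InputError(f"node {node.label!r} has no network state assigned")


def tree_loglik_given_internals(
    tree: Phylogeny,
    ref: ReferenceNetwork,
    params: EvolutionParams,
    mask: EdgeMask | None = None,
    method: str = "exact",
    N: int | None = None,
    nu_scope: str = "block",
    evaluator: Optional[PseudoLikelihood] = None,
) -> float:
    """log P(tree | full state assignment) = log π(root) + Σ branch terms."""
    _check_assigned(tree)
    mask = mask or EdgeMask()
    if method == "exact":
        gen = full_generator(ref, params, mask)
        pi = equilibrium(gen)
        total = _safe_log(float(pi[gen.index_of(tree.root.state)]))
        for node in tree.preorder():
            for child in node.children:
                total += pairwise_loglik_exact(
                    ref, params, node.state, child.state, child.length, mask
                )
                if total == NEG_INF:
                    return NEG_INF
        return total
    if method == "pseudo":
        if evaluator is None:
            if N is None:
                raise InputError("pseudo method requires a block size cap N")
            evaluator = PseudoLikelihood(ref, mask, N, nu_scope)
        return evaluator.tree_loglik(tree, params)
    raise InputError(f"unknown likelihood method {method!r}")


def tree_loglik_pruning(
    tree: Phylogeny,
    ref: ReferenceNetwork,
    params: EvolutionParams,
    mask: EdgeMask | None = None,
) -> float:
    """Tree log-likelihood integrating over internal states (Felsenstein).

    Works over the joint 2^m state space of the alterable edges with exact
    transition matrices per branch; the root is closed with the equilibrium
    distribution.  Partial-likelihood vectors are max-rescaled to avoid
    underflow.
    """
    mask = mask or EdgeMask()
    m = len(mask.alterable(ref.M))
    if m > MAX_PRUNING_EDGES:
        raise CapacityError(
            f"{m} alterable edges exceeds the pruning cap (m <= {MAX_PRUNING_EDGES})"
        )
    gen = full_generator(ref, params, mask)
    size = gen.size
    P_cache: Dict[float, np.ndarray] = {}

    def P_of(t: float) -> np.ndarray:
        if t not in P_cache:
            P_cache[t] = transition_probabilities(gen, t)
        return P_cache[t]

    def prune(node) -> Tuple[np.ndarray, float]:
        if node.is_leaf:
            if node.state is None:
                raise InputError(f"leaf {node.label!r} has no observed state")
            validate_state(node.state, mask)
            vec = np.zeros(size)
            vec[gen.index_of(node.state)] = 1.0
            return vec, 0.0
        vec = np.ones(size)
        logscale = 0.0
        for child in node.children:
            cv, cs = prune(child)
            vec = vec * (P_of(child.length) @ cv)
            logscale += cs
        s = vec.max()
        if s <= 0.0:
            return vec, NEG_INF
        return vec / s, logscale + math.log(s)

    vec, logscale = prune(tree.root)
    if logscale == NEG_INF:
        return NEG_INF
    pi = equilibrium(gen)
    return _safe_log(float(pi @ vec)) + logscale


def model_fit_lrt(
    loglik_null: float, loglik_alt: float, df: int, tol: float = 1e-6
) -> Tuple[float, float]:
    """Likelihood-ratio test: statistic 2(ℓ_alt − ℓ_null), chi-square p-value."""
    if df < 1:
        raise InputError(f"degrees of freedom must be >= 1, got {df}")
    stat = 2.0 * (loglik_alt - loglik_null)
    if stat < -tol:
        raise InputError(
            f"alternative log-likelihood below null by {-stat / 2:.3g}: "
            "models are mis-specified or mis-ordered"
        )
    stat = max(stat, 0.0)
    p = float(chi2.sf(stat, df))
    return stat, p
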