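"""Hypergraph representation of metabolic networks.

A metabolic network is modelled as a directed hypergraph: each reaction is a
hyperedge connecting an arbitrary set of substrate metabolites to an arbitrary
set of product metabolites.  Evolution acts by gaining or losing hyperedges
from a fixed *reference network* — the universe of all allowed reactions for
the system — so any observed network is a presence bit vector of length M over
the reference edges.  Two hyperedges are neighbors when they share at least
one metabolite; this neighbor relation drives the neighbor-dependent rate
model.

Reversible reactions are encoded as two hyperedges, one per direction.

States are plain ``numpy`` 0/1 vectors of length M (int8 internally).  Edges
observed present in every taxon are *core* (never deleted), edges absent from
every taxon are *prohibited* (never inserted); everything else is *alterable*
and is what the Markov chain acts on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Sequence, Tuple

import numpy as np

__all__ = [
    "InputError",
    "Reaction",
    "ReferenceNetwork",
    "EdgeMask",
    "build_reference",
    "neighborhood_component",
    "classify_edges",
    "hamming_events",
    "degree_distribution",
    "as_state",
    "validate_state",
]


class InputError(ValueError):
    """Invalid user input (malformed reaction table, state, index...)."""


@dataclass(frozen=True)
class Reaction:
    """A reaction hyperedge: substrates -> products.

    Either side may be empty (exchange/boundary reactions) but not both.
    Metabolite identity is exact string match; ids are assumed pre-normalized.
    """

    id: str
    substrates: frozenset
    products: frozenset

    def __post_init__(self):
        object.__setattr__(self, "substrates", frozenset(self.substrates))
        object.__setattr__(self, "products", frozenset(self.products))
        if not (self.substrates | self.products):
            raise InputError(f"reaction {self.id!r} touches no metabolite")

    @property
    def metabolites(self) -> frozenset:
        return self.substrates | self.products


@dataclass(frozen=True)
class ReferenceNetwork:
    """The universe of M labelled hyperedges with the neighbor relation.

    ``neighbor_map[i]`` is the set of edge indices sharing at least one
    metabolite with edge i (symmetric, irreflexive).  Edge indices 0..M-1
    follow the input reaction order and are stable for the object's lifetime.
    """

    reactions: Tuple[Reaction, ...]
    metabolites: frozenset
    neighbor_map: Tuple[frozenset, ...]
    # derived index arrays for fast presence counting; not part of identity
    _neighbor_idx: tuple = field(repr=False, compare=False, default=())

    @property
    def M(self) -> int:
        return len(self.reactions)

    @property
    def reaction_ids(self) -> Tuple[str, ...]:
        return tuple(r.id for r in self.reactions)

    def index_of(self, reaction_id: str) -> int:
        try:
            return self.reaction_ids.index(reaction_id)
        except ValueError:
            raise InputError(f"unknown reaction id {reaction_id!r}") from None

    def neighbor_idx(self, i: int) -> np.ndarray:
        return self._neighbor_idx[i]

    @property
    def neighbor_counts(self) -> np.ndarray:
        return np.array([len(s) for s in self.neighbor_map], dtype=int)

    def incidence_matrix(self) -> Tuple[np.ndarray, Tuple[str, ...]]:
        """0/1 matrix (metabolites x edges) plus the metabolite row order."""
        mets = tuple(sorted(self.metabolites))
        A = np.zeros((len(mets), self.M), dtype=np.int8)
        row = {m: k for k, m in enumerate(mets)}
        for i, r in enumerate(self.reactions):
            for m in r.metabolites:
                A[row[m], i] = 1
        return A, mets


@dataclass(frozen=True)
class EdgeMask:
    """Edges pinned present (core) or absent (prohibited) during evolution."""

    core: frozenset = frozenset()
    prohibited: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "core", frozenset(self.core))
        object.__setattr__(self, "prohibited", frozenset(self.prohibited))
        if self.core & self.prohibited:
            raise InputError(
                f"edges both core and prohibited: {sorted(self.core & self.prohibited)}"
            )

    def alterable(self, M: int) -> Tuple[int, ...]:
        """Sorted indices of edges the chain may toggle."""
        fixed = self.core | self.prohibited
        bad = [i for i in fixed if not 0 <= i < M]
        if bad:
            raise InputError(f"mask indices out of range for M={M}: {sorted(bad)}")
        return tuple(i for i in range(M) if i not in fixed)


def as_state(bits: Iterable, M: int | None = None) -> np.ndarray:
    """Coerce to a validated int8 presence vector."""
    arr = np.asarray(list(bits) if not isinstance(bits, np.ndarray) else bits)
    arr = arr.astype(np.int8)
    if arr.ndim != 1:
        raise InputError("network state must be a 1-D 0/1 vector")
    if not np.isin(arr, (0, 1)).all():
        raise InputError("network state entries must be 0 or 1")
    if M is not None and arr.size != M:
        raise InputError(f"state length {arr.size} != M={M}")
    return arr


def validate_state(bits: np.ndarray, mask: EdgeMask) -> None:
    """Raise unless the state honors the core/prohibited pins."""
    for i in mask.core:
        if bits[i] != 1:
            raise InputError(f"core edge {i} absent from state")
    for i in mask.prohibited:
        if bits[i] != 0:
            raise InputError(f"prohibited edge {i} present in state")


def build_reference(reactions: Sequence[Reaction]) -> ReferenceNetwork:
    """Build the reference network and its metabolite-sharing neighbor map.

    Two hyperedges are neighbors iff their metabolite sets intersect.  The
    relation is symmetric and irreflexive by construction.
    """
    reactions = tuple(reactions)
    if not reactions:
        raise InputError("reaction list is empty")
    ids = [r.id for r in reactions]
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise InputError(f"duplicate reaction ids: {dupes}")

    # bucket edges by metabolite, then union buckets per edge
    by_met: Dict[str, list] = {}
    for i, r in enumerate(reactions):
        for m in r.metabolites:
            by_met.setdefault(m, []).append(i)
    nbr = [set() for _ in reactions]
    for members in by_met.values():
        for i in members:
            nbr[i].update(members)
    for i in range(len(reactions)):
        nbr[i].discard(i)

    neighbor_map = tuple(frozenset(s) for s in nbr)
    idx = tuple(np.array(sorted(s), dtype=np.intp) for s in neighbor_map)
    metabolites = frozenset(by_met)
    return ReferenceNetwork(reactions, metabolites, neighbor_map, idx)


def neighborhood_component(
    ref: ReferenceNetwork,
    bits: np.ndarray,
    i: int,
    scope: str = "network",
) -> float:
    """Fraction weighting edge i's toggle rate by its present neighbors.

    Default ``scope="network"``: (# neighbors of i present) / (# hyperedges
    present in the current network), and 0 when the network is empty.  The
    alternative ``scope="reference"`` normalizes by the neighbor count of i in
    the reference network instead.
    """
    if not 0 <= i < ref.M:
        raise InputError(f"edge index {i} out of range for M={ref.M}")
    nbr = ref.neighbor_idx(i)
    num = int(bits[nbr].sum()) if nbr.size else 0
    if scope == "network":
        denom = int(np.sum(bits != 0))
        return num / denom if denom > 0 else 0.0
    if scope == "reference":
        denom = len(nbr)
        return num / denom if denom > 0 else 0.0
    raise InputError(f"unknown neighborhood scope {scope!r}")


def classify_edges(leaf_states: Sequence[np.ndarray]) -> EdgeMask:
    """Core = present in every leaf; prohibited = absent from every leaf."""
    states = [as_state(s) for s in leaf_states]
    if not states:
        raise InputError("classify_edges needs at least one leaf state")
    lengths = {s.size for s in states}
    if len(lengths) != 1:
        raise InputError(f"leaf states have mixed lengths: {sorted(lengths)}")
    X = np.vstack(states)
    core = frozenset(np.flatnonzero(X.all(axis=0)).tolist())
    prohibited = frozenset(np.flatnonzero(~X.any(axis=0)).tolist())
    return EdgeMask(core=core, prohibited=prohibited)


def hamming_events(x: np.ndarray, y: np.ndarray) -> Tuple[int, int]:
    """(insertions, deletions) turning state x into state y."""
    x = as_state(x)
    y = as_state(y)
    if x.size != y.size:
        raise InputError(f"state length mismatch: {x.size} vs {y.size}")
    ins = int(np.sum((x == 0) & (y == 1)))
    dele = int(np.sum((x == 1) & (y == 0)))
    return ins, dele


def degree_distribution(ref: ReferenceNetwork, bits: np.ndarray) -> Dict[str, int]:
    """Per-metabolite count of present incident hyperedges."""
    bits = as_state(bits, ref.M)
    deg = {m: 0 for m in sorted(ref.metabolites)}
    for i in np.flatnonzero(bits):
        for m in ref.reactions[int(i)].metabolites:
            deg[m] += 1
    return deg
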