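"""Deterministic toy and random hypergraph systems plus simulated leaf data.

Every generator here is a pure function of its arguments (including the
seed), so the rest of the package is fully testable without any database
download.  The fixed toy system mirrors the scale of a small textbook
metabolic map — 13 metabolites and 10 hyperedges — with three subset
networks on a three-leaf phylogeny; its wiring is a synthetic stand-in
frozen for reproducibility, not an extraction from any real pathway.
Random systems emulate KEGG-pathway-sized universes (tens of reactions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .evomodel import (
    MAX_DENSE_EDGES,
    EvolutionParams,
    equilibrium,
    full_generator,
)
from .hypernet import (
    EdgeMask,
    InputError,
    Reaction,
    ReferenceNetwork,
    build_reference,
)
from .likelihood import PseudoLikelihood
from .phylo import Phylogeny, read_newick
from .simulator import evolve_ctmc

__all__ = ["ToySystem", "make_toy_system", "random_system", "simulate_leaf_data"]


@dataclass(frozen=True)
class ToySystem:
    """Frozen 13-metabolite, 10-hyperedge system with a 3-leaf phylogeny."""

    ref: ReferenceNetwork
    states: Dict[str, np.ndarray]  # H1, H2, H3 leaf networks
    newick: str

    def tree(self) -> Phylogeny:
        t = read_newick(self.newick)
        t.set_leaf_states(self.states)
        return t


#: synthetic toy wiring (frozen): reaction id -> (substrates, products)
_TOY_REACTIONS: Tuple[Tuple[str, Tuple[str, ...], Tuple[str, ...]], ...] = (
    ("1", ("A", "B"), ("C",)),
    ("2", ("C",), ("D",)),
    ("3", ("C",), ("E",)),
    ("4", ("D", "E"), ("F",)),
    ("5", ("F",), ("G",)),
    ("6", ("G", "H"), ("I",)),
    ("7", ("I",), ("J",)),
    ("8", ("J", "K"), ("L",)),
    ("9", ("L",), ("M",)),
    ("10", ("M",), ("H",)),
)

_TOY_STATES: Dict[str, Tuple[str, ...]] = {
    "H1": ("1", "2", "3", "4", "5", "6", "7", "8"),
    "H2": ("1", "2", "3", "4", "5", "6", "9", "10"),
    "H3": ("1", "2", "3", "5", "6", "7", "9"),
}

_TOY_NEWICK = "((H1:0.3,H2:0.3):0.2,H3:0.5);"


def make_toy_system() -> ToySystem:
    """The fixed toy system: 13 metabolites A–M, hyperedges labelled 1–10.

    Deterministic across versions; the three leaf networks are subsets of
    the reference hyperedges and the tree has the 3-leaf cherry shape
    ((H1,H2),H3) with fixed branch lengths.
    """
    reactions = [Reaction(rid, frozenset(s), frozenset(p)) for rid, s, p in _TOY_REACTIONS]
    ref = build_reference(reactions)
    states = {}
    for name, present in _TOY_STATES.items():
        bits = np.zeros(ref.M, dtype=np.int8)
        for rid in present:
            bits[ref.index_of(rid)] = 1
        states[name] = bits
    return ToySystem(ref, states, _TOY_NEWICK)


def random_system(
    n_metabolites: int,
    n_edges: int,
    max_arity: int = 4,
    seed: int = 0,
) -> ReferenceNetwork:
    """Reproducible random hypergraph with every metabolite used at least once.

    ``max_arity`` caps the number of participating metabolites per reaction
    (substrates plus products, minimum 2: at least one per side).
    """
    if max_arity < 2:
        raise InputError("max_arity must be >= 2 (one substrate and one product)")
    if n_metabolites < 2 or n_edges < 1:
        raise InputError("need at least 2 metabolites and 1 edge")
    if n_edges * max_arity < n_metabolites:
        raise InputError(
            f"{n_edges} edges of arity <= {max_arity} cannot cover "
            f"{n_metabolites} metabolites"
        )
    rng = np.random.default_rng(seed)
    mets = [f"m{k:03d}" for k in range(n_metabolites)]
    # deal every metabolite into some reaction first, then fill randomly
    assignment: List[List[str]] = [[] for _ in range(n_edges)]
    order = rng.permutation(n_metabolites)
    for pos, k in enumerate(order):
        assignment[pos % n_edges].append(mets[int(k)])
    reactions = []
    for e, seeded in enumerate(assignment):
        arity = int(rng.integers(2, max_arity + 1))
        members = list(seeded[:max_arity])
        others = [m for m in mets if m not in members]
        extra = max(0, arity - len(members))
        if extra and others:
            members += [
                mets[int(i)]
                for i in rng.choice(
                    [mets.index(o) for o in others],
                    size=min(extra, len(others)),
                    replace=False,
                )
            ]
        if len(members) < 2:
            pool = [m for m in mets if m not in members]
            members.append(pool[int(rng.integers(len(pool)))])
        cut = int(rng.integers(1, len(members)))
        reactions.append(
            Reaction(f"R{e + 1:03d}", frozenset(members[:cut]), frozenset(members[cut:]))
        )
    return build_reference(reactions)


def sample_root_state(
    ref: ReferenceNetwork,
    params: EvolutionParams,
    mask: EdgeMask,
    rng: np.random.Generator,
    block_cap: int = 10,
) -> np.ndarray:
    """Draw a root network from the (pseudo-)equilibrium distribution.

    Exact joint equilibrium when the alterable count allows a dense
    generator; otherwise a product over sub-network blocks of block
    equilibria.
    """
    alterable = mask.alterable(ref.M)
    bits = np.zeros(ref.M, dtype=np.int8)
    for i in mask.core:
        bits[i] = 1
    if len(alterable) <= MAX_DENSE_EDGES:
        gen = full_generator(ref, params, mask)
        pi = equilibrium(gen)
        idx = int(rng.choice(pi.size, p=pi))
        return gen.bits_of(idx)
    ev = PseudoLikelihood(ref, mask, N=block_cap)
    for Q, blk in zip(ev._block_generators(params, None), ev.partition):
        pi = equilibrium(Q)
        idx = int(rng.choice(pi.size, p=pi))
        for k, i in enumerate(blk):
            bits[i] = (idx >> k) & 1
    return bits


def simulate_leaf_data(
    tree: Phylogeny,
    ref: ReferenceNetwork,
    params: EvolutionParams,
    mask: EdgeMask | None = None,
    seed: int = 0,
) -> Tuple[Dict[str, np.ndarray], Dict[str, np.ndarray], Dict[Tuple[str, str], list]]:
    """Simulate networks down the tree; return (leaf states, truth, event log).

    The root is drawn from the equilibrium distribution and each branch is
    evolved with the continuous-time simulator over its length.  ``truth``
    holds the simulated states of every node (internal nodes included) and
    the event log maps (parent, child) to the branch's Gillespie events.
    """
    mask = mask or EdgeMask()
    rng = np.random.default_rng(seed)
    root_bits = sample_root_state(ref, params, mask, rng)
    truth: Dict[str, np.ndarray] = {}
    events: Dict[Tuple[str, str], list] = {}

    def descend(node, bits: np.ndarray) -> None:
        truth[node.label] = bits.copy()
        for child in node.children:
            res = evolve_ctmc(ref, bits, params, mask, child.length, rng)
            events[(node.label, child.label)] = res.events
            descend(child, res.end_state)

    descend(tree.root, root_bits)
    leaves = {l.label: truth[l.label] for l in tree.leaves}
    return leaves, truth, events
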