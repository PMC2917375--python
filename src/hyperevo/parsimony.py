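"""Fitch small-parsimony baseline for ancestral reaction states.

Each reaction (hyperedge) is treated as an independent binary character on
the rooted binary tree.  The two-pass Fitch procedure computes a
minimum-change ancestral assignment: the bottom-up pass builds candidate
state sets (intersection where possible, otherwise union, counting one
change per union), and the top-down pass assigns states, preferring the
parent's state when admissible.  The root is the only node whose choice can
be genuinely unforced; an ambiguous root set {0,1} resolves in favor of
presence and is flagged.

The minimum change count is invariant under the tie-break; only the
assignment differs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np

from .hypernet import InputError
from .phylo import Phylogeny

__all__ = ["FitchResult", "fitch_ancestral"]


@dataclass
class FitchResult:
    """Ancestral assignments, per-edge minimum change counts, ambiguity flags."""

    states: Dict[str, np.ndarray]  # internal node label -> 0/1 vector
    changes: np.ndarray  # per-edge minimum number of state changes
    ambiguous: Dict[str, np.ndarray]  # node label -> bool vector (unforced ties)

    @property
    def root_ambiguous(self) -> np.ndarray:
        """Edges whose root state parsimony could not resolve."""
        return next(iter(self.ambiguous.values()))  # populated for every internal


def fitch_ancestral(
    tree: Phylogeny, leaf_states: Dict[str, np.ndarray] | None = None
) -> FitchResult:
    """Run Fitch parsimony per reaction over the tree.

    ``leaf_states`` may be omitted when leaves already carry states.  All
    leaf vectors must be binary and of equal length.
    """
    work = tree.copy()
    if leaf_states is not None:
        work.set_leaf_states(leaf_states)
    leaves = work.leaves
    if any(l.state is None for l in leaves):
        raise InputError("every leaf needs an observed state")
    M = leaves[0].state.size
    for l in leaves:
        if l.state.size != M:
            raise InputError("leaf states have mixed lengths")
        if not np.isin(l.state, (0, 1)).all():
            raise InputError(f"leaf {l.label!r} has non-binary entries")

    # candidate sets as 2-bit masks: 1 -> {0}, 2 -> {1}, 3 -> {0,1}
    sets: Dict[str, np.ndarray] = {}
    changes = np.zeros(M, dtype=int)
    for node in work.postorder():
        if node.is_leaf:
            sets[node.label] = np.where(node.state == 1, 2, 1).astype(np.int8)
            continue
        a, b = (sets[c.label] for c in node.children)
        inter = a & b
        union = a | b
        empty = inter == 0
        changes += empty.astype(int)
        sets[node.label] = np.where(empty, union, inter).astype(np.int8)

    states: Dict[str, np.ndarray] = {}
    ambiguous: Dict[str, np.ndarray] = {}
    for node in work.preorder():
        if node.is_leaf:
            continue
        s = sets[node.label]
        if node.parent is None:
            # unforced {0,1} sets resolve to presence and are flagged
            assign = np.where(s == 1, 0, 1).astype(np.int8)
            amb = s == 3
        else:
            p = states[node.parent.label]
            p_mask = np.where(p == 1, 2, 1).astype(np.int8)
            take_parent = (s & p_mask) != 0
            own = np.where(s == 1, 0, 1).astype(np.int8)  # {0}->0, {1} or {0,1}->1
            assign = np.where(take_parent, p, own).astype(np.int8)
            # a {0,1} set always admits the parent state, so no unforced choice
            amb = np.zeros(M, dtype=bool)
        states[node.label] = assign
        ambiguous[node.label] = amb

    # keyed in preorder so the root's flags come first
    ordered_states = {
        n.label: states[n.label] for n in work.preorder() if not n.is_leaf
    }
    ordered_amb = {
        n.label: ambiguous[n.label] for n in work.preorder() if not n.is_leaf
    }
    return FitchResult(ordered_states, changes, ordered_amb)
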