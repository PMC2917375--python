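"""Rooted binary phylogeny with per-node network states.

The tree topology and branch lengths come from sequence analysis and are
treated as fixed, known inputs; only the network states at internal nodes are
latent.  Newick parsing/writing is delegated to dendropy and converted to a
small mutable node structure so samplers can attach and update presence
vectors in place.

Branch lengths are mandatory (the model has no default time scale) and
polytomies are rejected: every internal node, including the root, must have
exactly two children.
"""

from __future__ import annotations

from typing import Dict, Iterator, List, Optional

import dendropy
import numpy as np

from .hypernet import InputError

__all__ = ["Node", "Phylogeny", "read_newick"]


class Node:
    __slots__ = ("label", "length", "parent", "children", "state")

    def __init__(self, label: str, length: Optional[float] = None):
        self.label = label
        self.length = length  # branch length to parent; None at root
        self.parent: Optional["Node"] = None
        self.children: List["Node"] = []
        self.state: Optional[np.ndarray] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):
        kind = "leaf" if self.is_leaf else "internal"
        return f"<Node {self.label!r} ({kind}, t={self.length})>"


class Phylogeny:
    """Rooted binary tree; leaves carry observed states, internals latent ones."""

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    def _validate(self) -> None:
        seen = set()
        for node in self.postorder():
            if node.label in seen:
                raise InputError(f"duplicate node label {node.label!r}")
            seen.add(node.label)
            if node.children and len(node.children) != 2:
                raise InputError(
                    f"node {node.label!r} has {len(node.children)} children; "
                    "the tree must be strictly binary"
                )
            if node is not self.root:
                if node.length is None:
                    raise InputError(f"missing branch length above {node.label!r}")
                if node.length < 0:
                    raise InputError(f"negative branch length above {node.label!r}")

    # traversals -----------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        def walk(n: Node) -> Iterator[Node]:
            for c in n.children:
                yield from walk(c)
            yield n

        yield from walk(self.root)

    def preorder(self) -> Iterator[Node]:
        def walk(n: Node) -> Iterator[Node]:
            yield n
            for c in n.children:
                yield from walk(c)

        yield from walk(self.root)

    @property
    def leaves(self) -> List[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def internals(self) -> List[Node]:
        return [n for n in self.postorder() if not n.is_leaf]

    def node(self, label: str) -> Node:
        for n in self.postorder():
            if n.label == label:
                return n
        raise InputError(f"no node labelled {label!r}")

    # states ---------------------------------------------------------------
    def set_leaf_states(self, states: Dict[str, np.ndarray]) -> None:
        for leaf in self.leaves:
            if leaf.label not in states:
                raise InputError(f"no state provided for leaf {leaf.label!r}")
            leaf.state = np.asarray(states[leaf.label], dtype=np.int8).copy()

    def leaf_states(self) -> Dict[str, np.ndarray]:
        return {l.label: l.state for l in self.leaves}

    def copy(self) -> "Phylogeny":
        def clone(n: Node) -> Node:
            c = Node(n.label, n.length)
            c.state = None if n.state is None else n.state.copy()
            for ch in n.children:
                cc = clone(ch)
                cc.parent = c
                c.children.append(cc)
            return c

        return Phylogeny(clone(self.root))

    # newick ---------------------------------------------------------------
    def newick(self) -> str:
        def fmt(n: Node) -> str:
            if n.is_leaf:
                body = n.label
            else:
                body = "(" + ",".join(fmt(c) for c in n.children) + ")"
                if not n.label.startswith("_"):
                    body += n.label
            if n.length is not None:
                body += f":{n.length:g}"
            return body

        return fmt(self.root) + ";"


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Branch lengths are required on every non-root edge; polytomies and
    unlabelled duplicate structures are rejected.  Internal nodes without a
    label get deterministic ``_in`` labels in preorder.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=False
        )
    except Exception as e:  # dendropy raises several parse error types
        raise InputError(f"newick parse error: {e}") from None

    counter = [0]

    def convert(dnode) -> Node:
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        else:
            label = f"_i{counter[0]}"
            counter[0] += 1
        node = Node(label, dnode.edge.length)
        for dchild in dnode.child_nodes():
            child = convert(dchild)
            child.parent = node
            node.children.append(child)
        return node

    root = convert(dtree.seed_node)
    root.length = None  # ignore any root edge length
    tree = Phylogeny(root)
    for node in tree.postorder():
        if node is not tree.root and node.length is None:
            raise InputError(
                f"missing branch length above {node.label!r}: branch lengths are required"
            )
    return tree
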