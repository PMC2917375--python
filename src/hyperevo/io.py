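"""File formats: reaction tables, presence/absence matrices, run metadata.

Reaction table: TSV with header ``reaction_id  substrates  products``,
metabolite ids separated by ``|`` (empty field = empty side).  Presence
matrix: TSV with reaction_id rows and taxon columns, entries strictly 0/1
(the model has no missing-data mechanism).  Newick handling lives in
:mod:`hyperevo.phylo`; it is re-exported here for convenience.
"""

from __future__ import annotations

import hashlib
import json
from typing import Dict, Sequence

import numpy as np
import pandas as pd

from .hypernet import (
    EdgeMask,
    InputError,
    Reaction,
    ReferenceNetwork,
    build_reference,
    validate_state,
)
from .phylo import Phylogeny, read_newick  # noqa: F401  (re-export)

__all__ = [
    "read_reactions",
    "write_reactions",
    "read_presence_matrix",
    "write_presence_matrix",
    "read_newick",
    "config_hash",
    "rle_encode_bits",
    "rle_decode_bits",
]


def read_reactions(path) -> ReferenceNetwork:
    """Load a reaction TSV and build the reference network."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"reaction_id", "substrates", "products"}
    if not required.issubset(df.columns):
        raise InputError(
            f"reaction table must have columns {sorted(required)}, got {list(df.columns)}"
        )
    reactions = []
    for _, row in df.iterrows():
        subs = frozenset(m for m in str(row["substrates"]).split("|") if m)
        prods = frozenset(m for m in str(row["products"]).split("|") if m)
        reactions.append(Reaction(str(row["reaction_id"]), subs, prods))
    return build_reference(reactions)


def write_reactions(ref: ReferenceNetwork, path) -> None:
    rows = [
        {
            "reaction_id": r.id,
            "substrates": "|".join(sorted(r.substrates)),
            "products": "|".join(sorted(r.products)),
        }
        for r in ref.reactions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_presence_matrix(
    path, ref: ReferenceNetwork, mask: EdgeMask | None = None
) -> Dict[str, np.ndarray]:
    """Load a taxon -> presence-vector map, validated against the reference.

    Rows are reaction ids (first column), columns are taxa.  Every reference
    reaction must appear exactly once; entries must be 0 or 1.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise InputError("presence matrix needs a reaction_id column and >=1 taxon")
    id_col = df.columns[0]
    seen = list(df[id_col])
    unknown = [r for r in seen if r not in ref.reaction_ids]
    if unknown:
        raise InputError(f"unknown reaction id(s) in presence matrix: {unknown[:5]}")
    missing = [r for r in ref.reaction_ids if r not in seen]
    if missing:
        raise InputError(f"presence matrix missing reaction(s): {missing[:5]}")
    if len(set(seen)) != len(seen):
        raise InputError("duplicate reaction rows in presence matrix")
    order = [seen.index(r) for r in ref.reaction_ids]
    states: Dict[str, np.ndarray] = {}
    for taxon in df.columns[1:]:
        col = df[taxon].to_numpy()[order]
        bits = np.zeros(ref.M, dtype=np.int8)
        for i, v in enumerate(col):
            if v not in ("0", "1"):
                raise InputError(
                    f"non-binary entry {v!r} at reaction {ref.reaction_ids[i]!r}, "
                    f"taxon {taxon!r}"
                )
            bits[i] = int(v)
        if mask is not None:
            validate_state(bits, mask)
        states[taxon] = bits
    return states


def write_presence_matrix(
    states: Dict[str, np.ndarray], ref: ReferenceNetwork, path
) -> None:
    df = pd.DataFrame(
        {taxon: bits.astype(int) for taxon, bits in states.items()},
        index=list(ref.reaction_ids),
    )
    df.index.name = "reaction_id"
    df.to_csv(path, sep="\t")


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable run configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def rle_encode_bits(bits: Sequence[int]) -> str:
    """Run-length encode a 0/1 vector, e.g. 0011101 -> '0x2,1x3,0x1,1x1'."""
    bits = list(int(b) for b in bits)
    if not bits:
        return ""
    runs = []
    cur, count = bits[0], 1
    for b in bits[1:]:
        if b == cur:
            count += 1
        else:
            runs.append(f"{cur}x{count}")
            cur, count = b, 1
    runs.append(f"{cur}x{count}")
    return ",".join(runs)


def rle_decode_bits(text: str) -> np.ndarray:
    if not text:
        return np.zeros(0, dtype=np.int8)
    out = []
    for run in text.split(","):
        val, count = run.split("x")
        out.extend([int(val)] * int(count))
    return np.array(out, dtype=np.int8)
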