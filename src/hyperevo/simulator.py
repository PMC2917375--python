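"""Forward simulation of network evolution under the hybrid model.

Two simulators are provided.  ``evolve_jump_chain`` is the discrete embedded
chain: at each step per-edge toggle rates are computed from the hybrid rule,
one edge is chosen with probability proportional to its rate and flipped.
``evolve_ctmc`` is the continuous-time (Gillespie) counterpart with
exponential waiting times, used to generate leaf data that respects branch
lengths.  Core edges are never deleted and prohibited edges never inserted.

At δ=1 the empty network is absorbing (every ν is 0); simulations entering an
absorbing state stop early and flag it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .evomodel import EvolutionParams
from .hypernet import (
    EdgeMask,
    InputError,
    ReferenceNetwork,
    as_state,
    degree_distribution,
    validate_state,
)

__all__ = [
    "Trajectory",
    "CtmcResult",
    "TrajectorySummary",
    "toggle_rates",
    "evolve_jump_chain",
    "evolve_ctmc",
    "summarize_trajectory",
]


@dataclass
class Trajectory:
    """Jump-chain output: the visited states and an absorbing-state flag."""

    states: List[np.ndarray]
    absorbed: bool = False
    seed: Optional[int] = None


@dataclass
class CtmcResult:
    """Gillespie output: end state plus the (time, edge, kind) event list."""

    end_state: np.ndarray
    events: List[Tuple[float, int, str]]
    absorbed: bool = False
    seed: Optional[int] = None


def toggle_rates(
    ref: ReferenceNetwork,
    bits: np.ndarray,
    params: EvolutionParams,
    mask: EdgeMask,
    nu_scope: str = "network",
) -> np.ndarray:
    """Hybrid-model toggle rate for every edge (0 for core/prohibited).

    ν for edge i is evaluated on the current network: the denominator counts
    all present hyperedges, so it includes i itself when i is present.
    """
    lam, mu, delta = params.astuple()
    rates = np.zeros(ref.M)
    n_present = int(bits.sum())
    for i in mask.alterable(ref.M):
        nbr = ref.neighbor_idx(i)
        num = int(bits[nbr].sum()) if nbr.size else 0
        if nu_scope == "network":
            nu = num / n_present if n_present > 0 else 0.0
        elif nu_scope == "reference":
            nu = num / len(nbr) if len(nbr) > 0 else 0.0
        else:
            raise InputError(f"unknown neighborhood scope {nu_scope!r}")
        q = mu if bits[i] else lam
        rates[i] = ((1.0 - delta) + delta * nu) * q
    return rates


def evolve_jump_chain(
    ref: ReferenceNetwork,
    state0: np.ndarray,
    params: EvolutionParams,
    mask: EdgeMask | None = None,
    n_steps: int = 0,
    rng_seed: int | np.random.Generator = 0,
    nu_scope: str = "network",
) -> Trajectory:
    """Run the embedded jump chain for ``n_steps`` toggles."""
    mask = mask or EdgeMask()
    bits = as_state(state0, ref.M).copy()
    validate_state(bits, mask)
    if n_steps < 0:
        raise InputError("n_steps must be >= 0")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    states = [bits.copy()]
    absorbed = False
    for _ in range(n_steps):
        rates = toggle_rates(ref, bits, params, mask, nu_scope)
        total = rates.sum()
        if total <= 0.0:
            absorbed = True
            warnings.warn(
                "all toggle rates are zero (absorbing state); simulation stopped early"
            )
            break
        i = int(rng.choice(ref.M, p=rates / total))
        bits[i] ^= 1
        validate_state(bits, mask)
        states.append(bits.copy())
    seed = rng_seed if isinstance(rng_seed, int) else None
    return Trajectory(states, absorbed=absorbed, seed=seed)


def evolve_ctmc(
    ref: ReferenceNetwork,
    state0: np.ndarray,
    params: EvolutionParams,
    mask: EdgeMask | None = None,
    total_time: float = 0.0,
    rng_seed: int | np.random.Generator = 0,
    nu_scope: str = "network",
) -> CtmcResult:
    """Gillespie simulation over ``[0, total_time]``.

    Waiting times are exponential with the current total toggle rate,
    recomputed after every event; events are (time, edge index, 'insert' or
    'delete').
    """
    mask = mask or EdgeMask()
    bits = as_state(state0, ref.M).copy()
    validate_state(bits, mask)
    if total_time < 0:
        raise InputError("total_time must be >= 0")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    t = 0.0
    events: List[Tuple[float, int, str]] = []
    absorbed = False
    while True:
        rates = toggle_rates(ref, bits, params, mask, nu_scope)
        total = rates.sum()
        if total <= 0.0:
            absorbed = True
            if t < total_time:
                warnings.warn(
                    "all toggle rates are zero (absorbing state); no further events"
                )
            break
        t += rng.exponential(1.0 / total)
        if t >= total_time:
            break
        i = int(rng.choice(ref.M, p=rates / total))
        kind = "delete" if bits[i] else "insert"
        bits[i] ^= 1
        validate_state(bits, mask)
        events.append((t, i, kind))
    seed = rng_seed if isinstance(rng_seed, int) else None
    return CtmcResult(bits, events, absorbed=absorbed, seed=seed)


@dataclass
class TrajectorySummary:
    insertions: np.ndarray  # per-edge insertion counts
    deletions: np.ndarray  # per-edge deletion counts
    toggles: np.ndarray  # per-edge total toggles
    degree_samples: List[Dict[str, int]] = field(default_factory=list)


def summarize_trajectory(
    trajectory: Trajectory,
    ref: ReferenceNetwork,
    thin: int = 10,
    burn_in: int = 0,
) -> TrajectorySummary:
    """Per-edge event tallies plus thinned node-degree distributions.

    Degree distributions are sampled at every ``thin``-th state after
    ``burn_in`` (indices into the trajectory's state list).
    """
    states = trajectory.states
    if not states:
        raise InputError("empty trajectory")
    ins = np.zeros(ref.M, dtype=int)
    dele = np.zeros(ref.M, dtype=int)
    for a, b in zip(states, states[1:]):
        flips = np.flatnonzero(a != b)
        for i in flips:
            if b[i]:
                ins[i] += 1
            else:
                dele[i] += 1
    degs = [
        degree_distribution(ref, states[k])
        for k in range(burn_in, len(states), max(thin, 1))
    ]
    return TrajectorySummary(ins, dele, ins + dele, degs)
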