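"""Gibbs sampling of ancestral networks and Bayesian parameter estimation.

Internal-node networks are sampled one hyperedge at a time, conditioning on
the edge's state in the node's three neighbors (parent and two children) —
the analogue for networks of the Holmes–Bruno sampler for sequences.  For
edge i at an internal node, a 2x2 rate matrix is built from the hybrid model
with the neighborhood component evaluated on the node's current network (all
other edges frozen); the conditional over {absent, present} is the
normalized product of the parent transition (or the edge equilibrium at the
root) and the two child transitions over the connecting branch lengths.

Parameters (λ, μ, δ) are updated by a Metropolis–Hastings step nested in the
outer Gibbs loop.  Proposals are data-driven independence proposals: rates
are drawn from gamma distributions whose shape is one plus the number of
matching events on the currently imputed tree and whose scale is the inverse
of the branch-length-weighted count of allowed events; the neighbor
dependence δ is drawn from a beta distribution whose shapes are the average
present-neighbor count in the leaf networks and the average neighbor count
in the reference network.  The acceptance ratio uses the sub-network
pseudo-likelihood of the tree under a uniform prior.

Chain output includes thinned parameter and internal-state draws, the MH
acceptance fraction, effective sample sizes (initial-positive-sequence
estimator), and per-branch / per-edge insertion–deletion event counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from scipy.stats import gamma as gamma_dist

from .evomodel import EvolutionParams, edge_transition, hybrid_scale
from .hypernet import (
    EdgeMask,
    InputError,
    ReferenceNetwork,
    hamming_events,
    validate_state,
)
from .likelihood import NEG_INF, PseudoLikelihood
from .parsimony import fitch_ancestral
from .phylo import Node, Phylogeny

__all__ = [
    "EventProportions",
    "GammaProposal",
    "BetaProposal",
    "RatesProposal",
    "DeltaProposal",
    "ChainConfig",
    "ChainRecord",
    "node_conditional",
    "gibbs_sweep_internals",
    "event_proportions",
    "propose_rates",
    "propose_delta",
    "mh_update_params",
    "run_estimation",
    "ancestral_presence",
    "chain_diagnostics",
    "autocorrelation",
    "effective_sample_size",
]


# --------------------------------------------------------------------------
# node conditionals and the Gibbs sweep


def _nu_pair(
    ref: ReferenceNetwork, bits: np.ndarray, i: int, scope: str = "network"
) -> Tuple[float, float]:
    """Neighborhood component for edge i with its own bit forced 0 resp. 1.

    The numerator (present neighbors) excludes i by irreflexivity, so only
    the denominator (present hyperedges) changes with i's own state.
    """
    nbr = ref.neighbor_idx(i)
    num = int(bits[nbr].sum()) if nbr.size else 0
    if scope == "reference":
        nu = num / len(nbr) if len(nbr) else 0.0
        return nu, nu
    base = int(bits.sum()) - int(bits[i])
    nu0 = num / base if base > 0 else 0.0
    nu1 = num / (base + 1)
    return nu0, nu1


def node_conditional(
    node: Node,
    ref: ReferenceNetwork,
    params: EvolutionParams,
    mask: EdgeMask,
    i: int,
    pi_mode: str = "root",
    nu_scope: str = "network",
) -> float:
    """P(edge i present at this internal node | its three neighbors).

    Core/prohibited edges return their forced state with probability 1.
    ``pi_mode="root"`` multiplies the edge equilibrium only at the root
    (elsewhere the parent transition carries the prior); ``"always"``
    multiplies it at every node.
    """
    if node.is_leaf:
        raise InputError(f"node {node.label!r} is a leaf; its state is observed")
    if i in mask.core:
        return 1.0
    if i in mask.prohibited:
        return 0.0
    bits = node.state
    nu0, nu1 = _nu_pair(ref, bits, i, nu_scope)
    a = hybrid_scale(nu0, params.delta) * params.lam  # 0 -> 1
    b = hybrid_scale(nu1, params.delta) * params.mu  # 1 -> 0

    if node.parent is None:
        if a + b <= 0.0:
            return float(bits[i])  # frozen edge: keep current state
        w = np.array([b, a]) / (a + b)
    else:
        P = edge_transition(a, b, node.length)
        w = P[int(node.parent.state[i]), :].copy()
        if pi_mode == "always" and a + b > 0.0:
            w *= np.array([b, a]) / (a + b)
    for child in node.children:
        P = edge_transition(a, b, child.length)
        w = w * P[:, int(child.state[i])]
    total = w.sum()
    if total <= 0.0:
        return float(bits[i])
    return float(w[1] / total)


def gibbs_sweep_internals(
    tree: Phylogeny,
    ref: ReferenceNetwork,
    params: EvolutionParams,
    mask: EdgeMask,
    rng: np.random.Generator,
    pi_mode: str = "root",
    nu_scope: str = "network",
) -> Phylogeny:
    """One systematic scan: internal nodes in post-order, edges in index order.

    Each edge is redrawn from its full conditional; the neighborhood
    component is recomputed after every flip because the node's state vector
    is updated in place.  Leaves are never touched and masks are asserted.
    """
    alterable = mask.alterable(ref.M)
    for node in tree.postorder():
        if node.is_leaf:
            continue
        for i in alterable:
            p1 = node_conditional(node, ref, params, mask, i, pi_mode, nu_scope)
            node.state[i] = 1 if rng.random() < p1 else 0
        validate_state(node.state, mask)
    return tree


# --------------------------------------------------------------------------
# event proportions and parameter proposals


@dataclass(frozen=True)
class EventProportions:
    """Observed and allowed insertion/deletion events on one branch.

    Proportions are counts divided by the number of alterable hyperedges.
    Allowed insertions: edges absent in the parent and not prohibited;
    allowed deletions: edges present in the parent and not core.
    """

    parent: str
    child: str
    t: float
    insertions: int
    deletions: int
    allowed_insertions: int
    allowed_deletions: int
    m_alterable: int

    @property
    def pI(self) -> float:
        return self.insertions / self.m_alterable

    @property
    def pD(self) -> float:
        return self.deletions / self.m_alterable

    @property
    def aI(self) -> float:
        return self.allowed_insertions / self.m_alterable

    @property
    def aD(self) -> float:
        return self.allowed_deletions / self.m_alterable


def event_proportions(tree: Phylogeny, mask: EdgeMask) -> List[EventProportions]:
    """Per parent->child event and allowed-event tallies, preorder."""
    first = tree.root.state
    if first is None:
        raise InputError("all node states must be assigned")
    M = first.size
    alterable = mask.alterable(M)
    m = len(alterable)
    if m == 0:
        raise InputError("no alterable edges")
    out: List[EventProportions] = []
    for node in tree.preorder():
        for child in node.children:
            if node.state is None or child.state is None:
                raise InputError("all node states must be assigned")
            ins, dele = hamming_events(node.state, child.state)
            absent = sum(1 for i in alterable if node.state[i] == 0)
            present = m - absent
            out.append(
                EventProportions(
                    node.label, child.label, child.length, ins, dele, absent, present, m
                )
            )
    return out


@dataclass(frozen=True)
class GammaProposal:
    shape: float
    scale: float

    def __post_init__(self):
        if not (self.shape > 0 and self.scale > 0):
            raise InputError("gamma proposal parameters must be positive")

    def draw(self, rng: np.random.Generator) -> float:
        return float(rng.gamma(self.shape, self.scale))

    def logpdf(self, x: float) -> float:
        return float(gamma_dist.logpdf(x, a=self.shape, scale=self.scale))


@dataclass(frozen=True)
class BetaProposal:
    a: float
    b: float

    def __post_init__(self):
        if not (self.a > 0 and self.b > 0):
            raise InputError("beta proposal shapes must be positive")

    def draw(self, rng: np.random.Generator) -> float:
        return float(rng.beta(self.a, self.b))

    def logpdf(self, x: float) -> float:
        return float(beta_dist.logpdf(x, self.a, self.b))


@dataclass
class RatesProposal:
    lam: float
    mu: float
    insertion: GammaProposal
    deletion: GammaProposal

    def logpdf(self, lam: float, mu: float) -> float:
        return self.insertion.logpdf(lam) + self.deletion.logpdf(mu)


@dataclass
class DeltaProposal:
    delta: float
    proposal: BetaProposal
    degenerate: bool = False

    def logpdf(self, delta: float) -> float:
        return self.proposal.logpdf(delta)


#: exposure guard against a zero scale when no events are allowed anywhere
RATE_PROPOSAL_EPS = 1e-6


def propose_rates(
    tree: Phylogeny,
    mask: EdgeMask,
    rng: np.random.Generator,
    eps: float = RATE_PROPOSAL_EPS,
) -> RatesProposal:
    """Draw (λ', μ') from event-count-conjugate gamma proposals.

    Shape = 1 + total matching events over all branches (so with no events
    the proposal reduces to an exponential); scale = 1/(ε + branch-length-
    weighted allowed events), making the proposal mean track the naive rate
    estimate events/exposure.
    """
    props = event_proportions(tree, mask)
    n_ins = sum(p.insertions for p in props)
    n_del = sum(p.deletions for p in props)
    expo_ins = sum(p.allowed_insertions * p.t for p in props)
    expo_del = sum(p.allowed_deletions * p.t for p in props)
    g_ins = GammaProposal(1.0 + n_ins, 1.0 / (eps + expo_ins))
    g_del = GammaProposal(1.0 + n_del, 1.0 / (eps + expo_del))
    return RatesProposal(g_ins.draw(rng), g_del.draw(rng), g_ins, g_del)


def propose_delta(
    leaf_states: Sequence[np.ndarray],
    ref: ReferenceNetwork,
    rng: np.random.Generator,
) -> DeltaProposal:
    """Draw δ' from Beta(a, b) with neighbor-count-informed shapes.

    a = mean over leaves of the average number of present neighbors per
    present edge; b = average neighbor count per edge in the reference
    network.  Degenerate shapes fall back to a uniform Beta(1,1) proposal.
    """
    if not leaf_states:
        raise InputError("at least one leaf state is required")
    leaf_means = []
    for bits in leaf_states:
        present = np.flatnonzero(bits)
        if present.size == 0:
            leaf_means.append(0.0)
            continue
        counts = [int(bits[ref.neighbor_idx(int(i))].sum()) for i in present]
        leaf_means.append(float(np.mean(counts)))
    a = float(np.mean(leaf_means))
    b = float(np.mean(ref.neighbor_counts))
    if a <= 0.0 or b <= 0.0:
        warnings.warn(
            "degenerate neighbor statistics (a or b = 0); using uniform Beta(1,1)"
        )
        prop = BetaProposal(1.0, 1.0)
        return DeltaProposal(prop.draw(rng), prop, degenerate=True)
    prop = BetaProposal(a, b)
    return DeltaProposal(prop.draw(rng), prop)


# --------------------------------------------------------------------------
# Metropolis–Hastings parameter update


@dataclass(frozen=True)
class ChainConfig:
    """Run configuration for the outer estimation loop."""

    iterations: int = 60_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 0
    subnetwork_cap: int = 5
    rate_max: float = 100.0
    initial: Optional[EvolutionParams] = None
    init_internals: str = "fitch"  # or "random"
    nu_scope: str = "block"  # pseudo-likelihood neighborhood scope
    pi_mode: str = "root"

    def __post_init__(self):
        if not self.burn_in < self.iterations:
            raise InputError("burn_in must be < iterations")
        if self.thin < 1:
            raise InputError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


def mh_update_params(
    tree: Phylogeny,
    ref: ReferenceNetwork,
    mask: EdgeMask,
    params: EvolutionParams,
    config: ChainConfig,
    rng: np.random.Generator,
    evaluator: Optional[PseudoLikelihood] = None,
    current_loglik: Optional[float] = None,
) -> Tuple[EvolutionParams, bool, float]:
    """One MH sweep on the parameters against the pseudo tree likelihood.

    The rate pair (λ, μ) and the dependence probability δ are updated in two
    separate Metropolis-within-Gibbs moves: the rates jointly from their
    event-count gamma proposals, then δ from its beta proposal.  All are
    independence proposals whose hyper-parameters depend on the imputed tree
    only, so forward and reverse densities come from the same distributions.
    (Updating the rates as a pair matters: each proposal is centred on the
    event counts the currently imputed history implies, and accepting λ and
    μ one at a time lets that self-referential centring drift the pair up an
    identifiability ridge, whereas the joint move ties them to the
    likelihood.)  The prior is uniform: δ on [0,1], rates on (0, rate_max].
    Returns (params after the sweep, fraction of component moves accepted,
    log-likelihood of the returned params).
    """
    if evaluator is None:
        evaluator = PseudoLikelihood(ref, mask, config.subnetwork_cap, config.nu_scope)
    if current_loglik is None:
        current_loglik = evaluator.tree_loglik(tree, params)
    accepted = 0

    # move 1: rates given delta
    rp = propose_rates(tree, mask, rng)
    if 0.0 < rp.lam <= config.rate_max and 0.0 < rp.mu <= config.rate_max:
        proposed = EvolutionParams(rp.lam, rp.mu, params.delta)
        prop_loglik = evaluator.tree_loglik(tree, proposed)
        if prop_loglik > NEG_INF:
            log_ratio = (prop_loglik - current_loglik) + (
                rp.logpdf(params.lam, params.mu) - rp.logpdf(proposed.lam, proposed.mu)
            )
            if math.log(rng.random()) < min(0.0, log_ratio):
                params, current_loglik = proposed, prop_loglik
                accepted += 1

    # move 2: delta given rates
    dp = propose_delta(list(tree.leaf_states().values()), ref, rng)
    proposed = EvolutionParams(params.lam, params.mu, dp.delta)
    prop_loglik = evaluator.tree_loglik(tree, proposed)
    if prop_loglik > NEG_INF:
        log_ratio = (prop_loglik - current_loglik) + (
            dp.logpdf(params.delta) - dp.logpdf(proposed.delta)
        )
        if math.log(rng.random()) < min(0.0, log_ratio):
            params, current_loglik = proposed, prop_loglik
            accepted += 1

    return params, accepted / 2.0, current_loglik


# --------------------------------------------------------------------------
# outer loop


@dataclass
class ChainRecord:
    """Thinned MCMC draws plus diagnostics and event summaries."""

    lam: np.ndarray
    mu: np.ndarray
    delta: np.ndarray
    internal_draws: np.ndarray  # (n_draws, n_internal, M) uint8
    internal_labels: Tuple[str, ...]
    reaction_ids: Tuple[str, ...]
    mask: EdgeMask
    acceptance: float
    branch_events: pd.DataFrame  # mean ins/del per branch over retained draws
    edge_events: pd.DataFrame  # mean ins/del per edge over retained draws
    config: ChainConfig
    iterations_run: int
    interrupted: bool = False
    ess: Dict[str, float] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.lam.size


def _init_internals(
    tree: Phylogeny,
    ref: ReferenceNetwork,
    mask: EdgeMask,
    how: str,
    rng: np.random.Generator,
) -> None:
    if how == "fitch":
        fit = fitch_ancestral(tree)
        for node in tree.internals:
            node.state = fit.states[node.label].copy()
    elif how == "random":
        for node in tree.internals:
            node.state = rng.integers(0, 2, size=ref.M).astype(np.int8)
    else:
        raise InputError(f"unknown internal-state initialization {how!r}")
    for node in tree.internals:
        for i in mask.core:
            node.state[i] = 1
        for i in mask.prohibited:
            node.state[i] = 0
        validate_state(node.state, mask)


def run_estimation(
    tree: Phylogeny,
    ref: ReferenceNetwork,
    mask: EdgeMask,
    config: ChainConfig,
) -> ChainRecord:
    """Nested Gibbs loop: sweep internal networks, then MH-update parameters.

    Deterministic given ``config.seed``.  A KeyboardInterrupt returns the
    draws collected so far with ``interrupted=True`` so a run can be resumed
    from its last retained state.
    """
    for leaf in tree.leaves:
        if leaf.state is None:
            raise InputError(f"leaf {leaf.label!r} has no observed state")
        validate_state(leaf.state, mask)
    rng = np.random.default_rng(config.seed)
    work = tree.copy()
    _init_internals(work, ref, mask, config.init_internals, rng)
    params = config.initial or EvolutionParams(1.0, 1.0, 0.5)
    if params.delta in (0.0, 1.0):
        # boundary delta has zero proposal density and would freeze the chain
        params = EvolutionParams(
            params.lam, params.mu, min(max(params.delta, 1e-3), 1.0 - 1e-3)
        )
    evaluator = PseudoLikelihood(ref, mask, config.subnetwork_cap, config.nu_scope)

    internal_labels = tuple(n.label for n in work.internals)
    branch_pairs = [
        (n.label, c.label) for n in work.preorder() for c in n.children
    ]
    leaf_bits = {l.label: l.state for l in work.leaves}

    lam_draws: List[float] = []
    mu_draws: List[float] = []
    delta_draws: List[float] = []
    state_draws: List[np.ndarray] = []
    accepted = 0
    branch_ins = np.zeros(len(branch_pairs))
    branch_del = np.zeros(len(branch_pairs))
    edge_ins = np.zeros(ref.M)
    edge_del = np.zeros(ref.M)
    interrupted = False
    it = 0
    try:
        for it in range(1, config.iterations + 1):
            gibbs_sweep_internals(
                work, ref, params, mask, rng, config.pi_mode
            )
            params, acc, _ = mh_update_params(
                work, ref, mask, params, config, rng, evaluator
            )
            accepted += acc
            if it > config.burn_in and (it - config.burn_in) % config.thin == 0:
                lam_draws.append(params.lam)
                mu_draws.append(params.mu)
                delta_draws.append(params.delta)
                snap = np.vstack([work.node(l).state for l in internal_labels])
                state_draws.append(snap.astype(np.uint8))
                states = {**leaf_bits, **{l: snap[k] for k, l in enumerate(internal_labels)}}
                for b, (pl, cl) in enumerate(branch_pairs):
                    ins, dele = hamming_events(states[pl], states[cl])
                    branch_ins[b] += ins
                    branch_del[b] += dele
                    edge_ins += (states[pl] == 0) & (states[cl] == 1)
                    edge_del += (states[pl] == 1) & (states[cl] == 0)
    except KeyboardInterrupt:
        interrupted = True

    n = max(len(lam_draws), 1)
    branch_df = pd.DataFrame(
        {
            "parent": [p for p, _ in branch_pairs],
            "child": [c for _, c in branch_pairs],
            "mean_insertions": branch_ins / n,
            "mean_deletions": branch_del / n,
        }
    )
    edge_df = pd.DataFrame(
        {
            "reaction_id": ref.reaction_ids,
            "mean_insertions": edge_ins / n,
            "mean_deletions": edge_del / n,
        }
    )
    record = ChainRecord(
        lam=np.array(lam_draws),
        mu=np.array(mu_draws),
        delta=np.array(delta_draws),
        internal_draws=(
            np.stack(state_draws) if state_draws else np.zeros((0, len(internal_labels), ref.M), dtype=np.uint8)
        ),
        internal_labels=internal_labels,
        reaction_ids=ref.reaction_ids,
        mask=mask,
        acceptance=accepted / max(it, 1),
        branch_events=branch_df,
        edge_events=edge_df,
        config=config,
        iterations_run=it,
        interrupted=interrupted,
    )
    if record.n_draws >= 10:
        diag = chain_diagnostics(record)
        record.ess = {k: v["ess"] for k, v in diag["parameters"].items()}
    return record


def ancestral_presence(
    record: ChainRecord, include_fixed: bool = False
) -> pd.DataFrame:
    """Per internal node, fraction of retained draws with each edge present.

    Default report covers only the alterable reactions; with
    ``include_fixed=True`` core edges report 1 and prohibited edges 0.
    """
    if record.n_draws < 1:
        raise InputError("no retained draws")
    frac = record.internal_draws.mean(axis=0)  # (n_internal, M)
    M = len(record.reaction_ids)
    for i in record.mask.core:
        frac[:, i] = 1.0
    for i in record.mask.prohibited:
        frac[:, i] = 0.0
    cols = list(range(M)) if include_fixed else list(record.mask.alterable(M))
    return pd.DataFrame(
        frac[:, cols],
        index=list(record.internal_labels),
        columns=[record.reaction_ids[i] for i in cols],
    )


# --------------------------------------------------------------------------
# diagnostics


def autocorrelation(x: np.ndarray, max_lag: int = 100) -> np.ndarray:
    """Sample autocorrelation function rho_0..rho_K (biased estimator)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise InputError("need at least 2 draws")
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0.0:
        return np.full(min(max_lag, n - 1) + 1, np.nan)
    K = min(max_lag, n - 1)
    acov = np.correlate(xc, xc, mode="full")[n - 1 : n + K]
    return acov / denom


def effective_sample_size(x: np.ndarray) -> float:
    """ESS by Geyer's initial-positive-sequence truncation.

    tau = -1 + 2 Σ_j (rho_{2j} + rho_{2j+1}) summed while the pair sums stay
    positive; ESS = n / tau.  Returns NaN for a degenerate (constant) chain.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 or np.var(x) == 0.0:
        return float("nan")
    rho = autocorrelation(x, max_lag=n - 1)
    tau = -1.0
    j = 0
    while 2 * j + 1 < rho.size:
        pair = rho[2 * j] + rho[2 * j + 1]
        if pair <= 0.0:
            break
        tau += 2.0 * pair
        j += 1
    tau = max(tau, 1.0 / n)
    return float(n / tau)


def chain_diagnostics(record: ChainRecord, max_lag: int = 100) -> Dict:
    """Per-parameter ESS and autocorrelation plus the acceptance fraction."""
    if record.n_draws < 10:
        raise InputError("need at least 10 retained draws for diagnostics")
    out: Dict = {"acceptance": record.acceptance, "parameters": {}}
    for name, draws in (("lam", record.lam), ("mu", record.mu), ("delta", record.delta)):
        ess = effective_sample_size(draws)
        out["parameters"][name] = {
            "ess": ess,
            "degenerate": bool(np.isnan(ess)),
            "acf": autocorrelation(draws, max_lag),
        }
    return out
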