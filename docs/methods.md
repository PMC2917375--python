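# Methods

## The model

A metabolic network is a directed hypergraph over a fixed metabolite set: a
reaction (hyperedge) joins a substrate set to a product set, and a reversible
reaction is written as two hyperedges, one per direction.  A *reference
network* fixes the universe of M labelled hyperedges, so any network is a
presence vector x ∈ {0,1}^M.  Evolution is a continuous-time Markov chain on
this space in which exactly one hyperedge is gained or lost at a time.

Two hyperedges are *neighbors* when they share at least one metabolite.  The
neighborhood component of edge i in network x is

    ν_x(i) = (# neighbors of i present in x) / (# hyperedges present in x),

with ν = 0 for the empty network.  (An alternative normalisation by the
neighbor count of i in the reference network is available via
`scope="reference"`; the default is the presence-count denominator.)

Three rate models are nested in one family.  With insertion rate λ, deletion
rate μ, and neighbor-dependence probability δ ∈ [0,1], the rate of flipping
edge i from network x is

    r(x → y) = [(1 − δ) + δ·ν_x(i)] · q,   q = λ (gain) or μ (loss).

δ = 0 is the independent-edge model, δ = 1 the fully neighbor-dependent
model, and intermediate δ mixes them; δ is interpretable as the probability
of being in the neighbor-dependent regime, and estimating it measures the
strength of neighborhood structure in the data.  ν is always evaluated on
the *source* state of a move, so the presence count in the denominator
includes edge i itself exactly when the move is a deletion.

Edges observed present in every taxon are *core* (never deleted), edges
absent everywhere are *prohibited* (never inserted); the chain acts on the m
remaining *alterable* edges.  Core edges still count as present context in
every ν evaluation.

At δ = 1 the empty network is absorbing (all ν = 0).  The equilibrium solver
detects the resulting reducibility and raises a diagnostic error naming the
absorbing class; the simulators stop with a warning when all rates vanish.

## Likelihoods

The joint generator over the m alterable edges is a 2^m × 2^m matrix (bit k
of the state index is the state of the k-th alterable edge, least-significant
bit = lowest edge index).  Dense work is capped at m ≤ 14.  The pairwise
likelihood of evolving x into y over branch length t is the (x, y) entry of
exp(Qt), conditioned on x.  Tree likelihoods close the root with the
equilibrium distribution π (πQ = 0); integrating over internal states uses
Felsenstein pruning over the joint state space (capped at m ≤ 10, with
max-rescaling of partial-likelihood vectors against underflow).

For larger systems a composite **pseudo-likelihood** replaces the exact one:
the alterable edges are partitioned greedily into blocks of at most N edges
— repeatedly seed with the pooled edge of highest remaining-neighbor count
(ties to the lowest index), absorb the seed's top pooled neighbors, and
recompute counts until the block is full — and the per-block exact
likelihoods are multiplied.  Within a block, ν sees the block's edges plus
the core edges (anchored permanently present); out-of-block *alterable*
edges are invisible.  This is the "border effect" of decomposition: the
composite likelihood understates neighborhood support for edges whose
neighbors fall in other blocks.  Core edges must not be dropped from the ν
context — they are permanent parts of every network, and excluding them
empirically collapses the inferred δ toward zero on systems whose stable
neighbors are core.  A `nu_scope="global"` variant instead freezes
out-of-block edges at the ancestor state.  With a single block (N ≥ m) the
pseudo-likelihood equals the exact likelihood bitwise, mask or no mask; at
δ = 0 it is exact for every N.  The pseudo root prior is the product of
block equilibria.

Model comparison uses the likelihood-ratio statistic 2(ℓ_alt − ℓ_null)
against an upper-tail chi-square.

## Gibbs sampling of ancestral networks

Internal nodes are resampled one hyperedge at a time conditioning on the
edge's state in the node's parent and two children.  For edge i at node n a
2×2 rate matrix is built from the hybrid rule with ν evaluated on n's
current network (insertion row with bit i forced 0, deletion row forced 1);
2-state transition matrices over the three incident branches are closed
form, and the conditional over {absent, present} is their normalized
product.  The edge equilibrium enters only at the root — the parent
transition carries the prior elsewhere (`pi_mode="always"` switches to the
literal always-multiply variant).  The sweep is a systematic scan: internal
nodes in post-order, edges in index order, ν recomputed after every flip.
Core/prohibited edges are returned at their forced state.  This per-edge
conditional is exact at δ = 0 and an approximation for δ > 0 (the joint
conditional would couple edges through ν); its effect at toy scale is a mild
upward bias in imputed event counts, visible in the parameter-recovery
experiment below.

## Parameter estimation

The outer loop alternates (1) a Gibbs sweep of the internal networks and
(2) a Metropolis–Hastings sweep of θ = (λ, μ, δ) against the pseudo tree
likelihood with uniform priors (δ on [0,1], rates on (0, rate_max], default
rate_max = 100 per unit branch length).

Proposals are independence proposals built from the currently imputed tree.
For each parent→child pair the insertion/deletion events and the allowed
events (edges absent/present in the parent, mask respected) are counted.
The rate proposals are gamma with shape 1 + Σ events and scale
1/(ε + Σ allowed·t), ε = 1e-6 — with no events the proposal reduces to an
exponential, and its mean tracks the naive estimate events/exposure.  The δ
proposal is Beta(a, b) with a = the mean over leaves of the average
present-neighbor count per present edge and b = the average neighbor count
per edge in the reference network (degenerate shapes fall back to
Beta(1,1) with a warning).  Because the hyper-parameters depend on the tree
only, forward and reverse densities come from the same distributions.

The MH sweep makes **two** moves: (λ, μ) jointly, then δ.  This choice was
validated against a brute-force grid posterior on a 2-leaf, 3-edge system:
a single joint 3-parameter move mixes poorly (each component must overlap
the posterior simultaneously), while fully componentwise rate moves let the
event-driven proposal centring walk the rate pair up the λ–μ ridge.  The
two-move sweep reproduced all three grid-posterior means within Monte-Carlo
error at ≈45% acceptance.  A chain started at δ exactly 0 or 1 is nudged
into the interior, since the boundary has zero proposal density and would
freeze the sampler.

Internal states are initialized by Fitch parsimony (presence tie-break) by
default; random initialization is available.  Defaults mirror realistic
production runs — 60,000 iterations, 10,000 burn-in, thinning 10 — and every
run is a pure function of its seed.  Ancestral reconstruction reports, per
internal node and alterable reaction, the fraction of retained draws in
which the hyperedge is present (core → 1, prohibited → 0 when included).

Diagnostics: MH acceptance fraction, per-parameter autocorrelation, and
effective sample size by Geyer's initial-positive-sequence estimator
(τ = −1 + 2 Σ_j Γ_j over positive pair sums Γ_j = ρ_{2j} + ρ_{2j+1};
ESS = n/τ; a constant chain reports NaN and is flagged degenerate).

## Fitch parsimony baseline

Each reaction is an independent binary character.  The bottom-up pass builds
candidate sets (intersection, else union with one change counted); the
top-down pass assigns the parent's state when admissible.  Only the root can
face an unforced {0,1} set; it resolves in favor of presence and is flagged.
The change count is invariant under the tie-break and equals the exhaustive
minimum; it lower-bounds the change count of any sampled ancestral history.

## Synthetic data

`make_toy_system()` returns a frozen 13-metabolite, 10-hyperedge system
(metabolites A–M, hyperedges "1"–"10" wired as a closed chain of small
reactions), three subset networks H1–H3, and a 3-leaf phylogeny
((H1,H2),H3).  The wiring is a synthetic stand-in with these canonical
dimensions, frozen so every toy-scale result is reproducible.
`random_system(n_metabolites, n_edges, max_arity, seed)` produces arbitrary
covered hypergraphs.  `simulate_leaf_data` draws the root from the (block)
equilibrium and runs the exact Gillespie simulator down each branch,
returning leaves, the full internal truth and the per-branch event log.

What the generator emulates: presence/absence panels over a known reference
network and a known, fixed phylogeny, with evolution exactly under the
hybrid model.  What it does not emulate: annotation noise (false
presence/absence calls), lineage-specific cores, uncertainty in the tree or
branch lengths, and reaction universes larger than the pathway-map scale.
Passing tests therefore demonstrate correctness of the machinery under the
model's own assumptions, not robustness to misspecified real data.

## Test-scale experiment designs

Numbers quoted by the test suite and the acceptance script use these
problem sizes, chosen as the package's validation defaults:

- **Gibbs vs enumeration (δ=0):** 4-edge chain system, 3-leaf tree, 25,000
  sweeps; per-edge marginal error < 0.02.
- **Visited-states likelihood (toy):** all 1024 joint states, δ = 0.8,
  λ = μ = 1, 25,000 sweeps with 10,000 burn-in; the visited-state sum is a
  subset of the exhaustive positive sum, so the log-likelihood gap is
  one-sided and observed ≈ 0.006 nats (tolerance 0.1).
- **Parameter recovery:** leaves simulated on the balanced 4-leaf tree
  ((L1:0.6,L2:0.6):0.3,(L3:0.6,L4:0.6):0.3) over the toy reference at
  (λ, μ, δ) = (1, 1, 0.8); three replicates; chains of 12,000 iterations
  (3,000 burn-in, thin 10, block cap N = 6).  Posterior means fall within 3
  posterior SDs of the truth.  The residual systematic tendency — rates
  high by ~1–2 SD, δ low by ~1–2 SD — is the per-edge Gibbs approximation
  plus the leaf-derived mask's ascertainment (constant edges, which carry
  evidence for low rates, are removed from the likelihood), and shrinks
  with more leaves.
- **Simulator limits:** 50,000 jump-chain steps at δ=0 (chi-square
  uniformity of insertion counts), 20,000 at δ=1 (Spearman correlation of
  toggle counts with reference neighbor counts, observed ρ ≈ 0.85).

## Numerical choices

- exp(Qt) via `scipy.linalg.expm` on dense generators; rows renormalized
  after clipping roundoff negatives.  2-state transitions use the closed
  form.
- Equilibria by direct solve of πQ = 0 with Σπ = 1 after a strong-
  connectivity check (`scipy.sparse.csgraph`); residual ‖πQ‖∞ must be
  < 1e-8.
- Impossible transitions carry log-probability −inf, which propagates
  through sums and comparisons without special casing.
- Generator construction is vectorized with 64-bit popcounts for M ≤ 63 and
  falls back to arbitrary-precision integer masks beyond that.
- Ties in the sub-network decomposition and the Gibbs scan order are broken
  by lowest edge index; the partition is deterministic given its inputs.

## Known limitations

- Exact likelihoods are capped at m ≤ 14 alterable edges (pruning at 10);
  beyond that only the pseudo-likelihood route is available, with the
  border-effect bias described above.
- The per-edge Gibbs conditional is approximate for δ > 0; posterior
  summaries inherit a modest bias at small sample sizes.
- Branch lengths and topology are taken as known; no missing-data states in
  presence matrices; no stoichiometry, flux, or viability checks on sampled
  ancestral networks.
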