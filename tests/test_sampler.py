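"""Gibbs internal-state sampling, MH parameter updates, diagnostics."""

import math

import numpy as np
import pytest
from scipy.stats import kstest

from hyperevo.evomodel import (
    EvolutionParams,
    edge_transition,
    equilibrium,
    full_generator,
    transition_probabilities,
)
from hyperevo.hypernet import EdgeMask, InputError, Reaction, build_reference, classify_edges
from hyperevo.phylo import read_newick
from hyperevo.sampler import (
    ChainConfig,
    ancestral_presence,
    autocorrelation,
    chain_diagnostics,
    effective_sample_size,
    event_proportions,
    gibbs_sweep_internals,
    mh_update_params,
    node_conditional,
    propose_delta,
    propose_rates,
    run_estimation,
    _init_internals,
)

from conftest import random_states


def _assigned_tree(toy, newick="((H1:0.3,H2:0.3)A:0.2,H3:0.5)R;"):
    tree = read_newick(newick)
    tree.set_leaf_states(toy.states)
    states = {"A": toy.states["H1"].copy(), "R": toy.states["H3"].copy()}
    for node in tree.internals:
        node.state = states[node.label]
    return tree


class TestNodeConditional:
    def test_core_and_prohibited_are_forced(self, toy):
        tree = _assigned_tree(toy)
        mask = EdgeMask(core={0}, prohibited={9})
        p = EvolutionParams(1, 1, 0.5)
        node = tree.node("A")
        assert node_conditional(node, toy.ref, p, mask, 0) == 1.0
        assert node_conditional(node, toy.ref, p, mask, 9) == 0.0

    def test_long_branches_give_edge_equilibrium(self, toy):
        # at delta=0 with all three branches long, the conditional forgets
        # the neighbors and returns lam/(lam+mu)
        tree = _assigned_tree(
            toy, "((H1:1e6,H2:1e6)A:1e6,H3:1e6)R;"
        )
        p = EvolutionParams(1.6, 0.4, 0.0)
        got = node_conditional(tree.node("A"), toy.ref, p, EdgeMask(), 4)
        assert got == pytest.approx(1.6 / 2.0, abs=1e-6)

    def test_matches_enumeration_posterior_at_delta0(self, chain4):
        """With independent edges the conditional equals the per-edge posterior
        computed by enumerating both internal nodes."""
        p = EvolutionParams(1.3, 0.7, 0.0)
        tree = read_newick("((X:0.4,Y:0.7)A:0.3,Z:0.6)R;")
        leaves = {n: s for n, s in zip("XYZ", random_states(4, 3, seed=5))}
        tree.set_leaf_states(leaves)
        rng = np.random.default_rng(0)
        _init_internals(tree, chain4, EdgeMask(), "random", rng)
        node = tree.node("A")
        for i in range(4):
            # per-edge 2-state oracle: condition on the root's current bit
            a, b = p.lam, p.mu
            Pp = edge_transition(a, b, 0.3)
            Px = edge_transition(a, b, 0.4)
            Py = edge_transition(a, b, 0.7)
            r = int(tree.node("R").state[i])
            w = [
                Pp[r, s] * Px[s, leaves["X"][i]] * Py[s, leaves["Y"][i]]
                for s in (0, 1)
            ]
            expected = w[1] / (w[0] + w[1])
            got = node_conditional(node, chain4, p, EdgeMask(), i)
            assert got == pytest.approx(expected, abs=1e-12)


class TestGibbsSweep:
    def test_all_core_sweep_is_noop(self, toy):
        tree = _assigned_tree(toy)
        # every edge pinned: nothing can change
        mask = EdgeMask(core=frozenset(range(10)))
        for node in tree.internals:
            node.state = np.ones(10, dtype=np.int8)
        before = {n.label: n.state.copy() for n in tree.internals}
        gibbs_sweep_internals(tree, toy.ref, EvolutionParams(1, 1, 0.5), mask,
                              np.random.default_rng(0))
        for n in tree.internals:
            assert (n.state == before[n.label]).all()

    def test_leaves_never_modified(self, toy):
        tree = _assigned_tree(toy)
        before = {l.label: l.state.copy() for l in tree.leaves}
        rng = np.random.default_rng(1)
        for _ in range(50):
            gibbs_sweep_internals(tree, toy.ref, EvolutionParams(1.5, 0.7, 0.8),
                                  EdgeMask(), rng)
        for l in tree.leaves:
            assert (l.state == before[l.label]).all()

    def test_marginals_match_enumeration_at_delta0(self, chain4):
        """Light version of the toy-network validation: sampled presence
        frequencies converge on the enumerated posterior marginals."""
        p = EvolutionParams(1.3, 0.7, 0.0)
        tree = read_newick("((X:0.4,Y:0.7)A:0.3,Z:0.6)R;")
        leaves = {n: s for n, s in zip("XYZ", random_states(4, 3, seed=5))}
        tree.set_leaf_states(leaves)
        gen = full_generator(chain4, p)
        pi = equilibrium(gen)
        P = {t: transition_probabilities(gen, t) for t in (0.3, 0.4, 0.7, 0.6)}
        ix, iy, iz = (gen.index_of(leaves[k]) for k in "XYZ")
        W = (pi[:, None] * P[0.3] * P[0.6][:, iz][:, None]
             * (P[0.4][:, ix] * P[0.7][:, iy])[None, :])
        W /= W.sum()
        marg = {
            "R": np.array([W.sum(axis=1) @ [(r >> k) & 1 for r in range(16)]
                           for k in range(4)]),
            "A": np.array([W.sum(axis=0) @ [(a >> k) & 1 for a in range(16)]
                           for k in range(4)]),
        }
        rng = np.random.default_rng(3)
        _init_internals(tree, chain4, EdgeMask(), "fitch", rng)
        counts = {n.label: np.zeros(4) for n in tree.internals}
        sweeps = 5000
        for _ in range(sweeps):
            gibbs_sweep_internals(tree, chain4, p, EdgeMask(), rng)
            for n in tree.internals:
                counts[n.label] += n.state
        for label in ("R", "A"):
            assert np.abs(counts[label] / sweeps - marg[label]).max() < 0.05


class TestEventProportions:
    def test_identical_states_have_no_events(self, toy):
        tree = _assigned_tree(toy)
        for n in tree.internals:
            n.state = toy.states["H1"].copy()
        tree.set_leaf_states({k: toy.states["H1"] for k in toy.states})
        props = event_proportions(tree, EdgeMask())
        assert all(p.pI == 0 and p.pD == 0 for p in props)

    def test_worked_example_proportions(self, toy):
        # 10 alterable hyperedges; parent has 8 present & 2 absent; child gains
        # one absent edge and loses one present edge
        parent = np.array([1, 1, 1, 1, 1, 1, 1, 1, 0, 0], dtype=np.int8)
        child = parent.copy()
        child[8] = 1   # one insertion (2 allowed)
        child[0] = 0   # one deletion (8 allowed)
        tree = read_newick("(L:1.0,Rr:1.0)P;")
        tree.set_leaf_states({"L": child, "Rr": parent})
        tree.root.state = parent
        props = {(e.parent, e.child): e for e in event_proportions(tree, EdgeMask())}
        e = props[("P", "L")]
        assert (e.pI, e.pD, e.aI, e.aD) == (0.1, 0.1, 0.2, 0.8)

    def test_matches_loop_oracle(self, toy):
        tree = _assigned_tree(toy)
        props = event_proportions(tree, EdgeMask())
        by_pair = {(e.parent, e.child): e for e in props}
        for node in tree.preorder():
            for child in node.children:
                ins = sum(1 for a, b in zip(node.state, child.state) if a == 0 and b == 1)
                dele = sum(1 for a, b in zip(node.state, child.state) if a == 1 and b == 0)
                e = by_pair[(node.label, child.label)]
                assert (e.insertions, e.deletions) == (ins, dele)
                assert e.allowed_insertions == int(np.sum(node.state == 0))
                assert e.allowed_deletions == int(np.sum(node.state == 1))


class TestProposals:
    def test_no_events_reduces_to_exponential(self, toy):
        tree = _assigned_tree(toy)
        same = toy.states["H2"].copy()
        tree.set_leaf_states({k: same for k in toy.states})
        for n in tree.internals:
            n.state = same.copy()
        rp = propose_rates(tree, EdgeMask(), np.random.default_rng(0))
        assert rp.insertion.shape == 1.0
        assert rp.deletion.shape == 1.0

    def test_gamma_proposal_tracks_event_rate(self, toy):
        tree = _assigned_tree(toy)
        props = event_proportions(tree, EdgeMask())
        n_ins = sum(p.insertions for p in props)
        expo = sum(p.allowed_insertions * p.t for p in props)
        rp = propose_rates(tree, EdgeMask(), np.random.default_rng(0))
        assert rp.insertion.shape == 1 + n_ins
        assert rp.insertion.shape * rp.insertion.scale == pytest.approx(
            (1 + n_ins) / expo, rel=1e-4
        )

    def test_gamma_draws_match_target_distribution(self, toy):
        tree = _assigned_tree(toy)
        rng = np.random.default_rng(42)
        rp = propose_rates(tree, EdgeMask(), rng)
        draws = [propose_rates(tree, EdgeMask(), rng).lam for _ in range(10_000)]
        res = kstest(draws, "gamma", args=(rp.insertion.shape, 0, rp.insertion.scale))
        assert res.pvalue > 0.01

    def test_delta_proposal_symmetric_when_leaves_equal_reference(self, toy):
        full = np.ones(10, dtype=np.int8)
        dp = propose_delta([full, full, full], toy.ref, np.random.default_rng(0))
        assert dp.proposal.a == pytest.approx(dp.proposal.b)

    def test_delta_proposal_degenerate_fallback(self):
        ref = build_reference(
            [Reaction("a", {"A"}, {"B"}), Reaction("b", {"C"}, {"D"})]
        )
        with pytest.warns(UserWarning, match="degenerate"):
            dp = propose_delta([np.zeros(2, dtype=np.int8)], ref,
                               np.random.default_rng(0))
        assert dp.degenerate
        assert (dp.proposal.a, dp.proposal.b) == (1.0, 1.0)

    def test_beta_draw_mean_matches_moments(self, toy):
        rng = np.random.default_rng(7)
        draws = [
            propose_delta(list(toy.states.values()), toy.ref, rng).delta
            for _ in range(10_000)
        ]
        dp = propose_delta(list(toy.states.values()), toy.ref, np.random.default_rng(0))
        a, b = dp.proposal.a, dp.proposal.b
        mean = a / (a + b)
        se = math.sqrt(mean * (1 - mean) / len(draws))  # conservative bound
        assert abs(np.mean(draws) - mean) < 4 * se


class TestMhUpdate:
    def test_proposals_outside_prior_support_auto_reject(self, toy):
        tree = _assigned_tree(toy)
        p = EvolutionParams(1.0, 1.0, 0.5)
        cfg = ChainConfig(iterations=10, burn_in=1, thin=1, rate_max=1e-9)
        rng = np.random.default_rng(0)
        out, acc, _ = mh_update_params(tree, toy.ref, EdgeMask(), p, cfg, rng)
        assert out.lam == p.lam and out.mu == p.mu  # rates move impossible

    def test_matches_brute_force_posterior_on_tiny_system(self):
        """Two shared-metabolite edges, two leaves: the sampled parameter
        posterior agrees with dense grid integration."""
        ref = build_reference(
            [Reaction("a", {"X"}, {"Y"}), Reaction("b", {"Y"}, {"Z"})]
        )
        L1 = np.array([1, 0], dtype=np.int8)
        L2 = np.array([0, 1], dtype=np.int8)
        tree = read_newick("(L1:0.5,L2:0.5);")
        tree.set_leaf_states({"L1": L1, "L2": L2})
        lam_g = np.linspace(0.05, 6.0, 40)
        mu_g = np.linspace(0.05, 6.0, 40)
        de_g = np.linspace(0.025, 0.975, 20)
        post = np.zeros((40, 40, 20))
        for i, l in enumerate(lam_g):
            for j, m in enumerate(mu_g):
                for k, d in enumerate(de_g):
                    p = EvolutionParams(l, m, d)
                    gen = full_generator(ref, p)
                    P = transition_probabilities(gen, 0.5)
                    pi = equilibrium(gen)
                    i1, i2 = gen.index_of(L1), gen.index_of(L2)
                    post[i, j, k] = float(np.sum(pi * P[:, i1] * P[:, i2]))
        post /= post.sum()
        truth = {
            "lam": float(post.sum(axis=(1, 2)) @ lam_g),
            "mu": float(post.sum(axis=(0, 2)) @ mu_g),
            "delta": float(post.sum(axis=(0, 1)) @ de_g),
        }
        cfg = ChainConfig(iterations=20_000, burn_in=4_000, thin=5, seed=2,
                          subnetwork_cap=2, rate_max=6.0)
        rec = run_estimation(tree, ref, EdgeMask(), cfg)
        got = {"lam": rec.lam.mean(), "mu": rec.mu.mean(), "delta": rec.delta.mean()}
        for name in truth:
            assert got[name] == pytest.approx(truth[name], abs=0.45), (name, truth, got)


class TestRunEstimation:
    def _small_setup(self, toy):
        tree = read_newick("((H1:0.3,H2:0.3):0.2,H3:0.5);")
        tree.set_leaf_states(toy.states)
        mask = classify_edges(list(toy.states.values()))
        return tree, mask

    def test_retention_arithmetic(self, toy):
        tree, mask = self._small_setup(toy)
        cfg = ChainConfig(iterations=51, burn_in=50, thin=1, seed=0, subnetwork_cap=4)
        rec = run_estimation(tree, toy.ref, mask, cfg)
        assert rec.n_draws == 1

    def test_same_seed_reproduces_chain_exactly(self, toy):
        tree, mask = self._small_setup(toy)
        cfg = ChainConfig(iterations=200, burn_in=100, thin=10, seed=7, subnetwork_cap=4)
        a = run_estimation(tree, toy.ref, mask, cfg)
        b = run_estimation(tree, toy.ref, mask, cfg)
        assert (a.lam == b.lam).all() and (a.mu == b.mu).all()
        assert (a.delta == b.delta).all()
        assert (a.internal_draws == b.internal_draws).all()

    def test_draw_masks_respected_and_presence_tally(self, toy):
        tree, mask = self._small_setup(toy)
        cfg = ChainConfig(iterations=300, burn_in=100, thin=5, seed=3, subnetwork_cap=4)
        rec = run_estimation(tree, toy.ref, mask, cfg)
        for i in mask.core:
            assert (rec.internal_draws[:, :, i] == 1).all()
        for i in mask.prohibited:
            assert (rec.internal_draws[:, :, i] == 0).all()
        frac = ancestral_presence(rec, include_fixed=True)
        recount = rec.internal_draws.mean(axis=0)
        for j, label in enumerate(rec.internal_labels):
            for i in mask.alterable(10):
                rid = rec.reaction_ids[i]
                assert frac.loc[label, rid] == pytest.approx(recount[j, i])
        for i in mask.core:
            assert (frac[rec.reaction_ids[i]] == 1.0).all()

    def test_default_report_shows_only_alterable(self, toy):
        tree, mask = self._small_setup(toy)
        cfg = ChainConfig(iterations=120, burn_in=100, thin=2, seed=3, subnetwork_cap=4)
        rec = run_estimation(tree, toy.ref, mask, cfg)
        df = ancestral_presence(rec)
        assert list(df.columns) == [rec.reaction_ids[i] for i in mask.alterable(10)]


class TestDiagnostics:
    def test_iid_chain_ess_close_to_n(self):
        x = np.random.default_rng(0).normal(size=4000)
        assert effective_sample_size(x) == pytest.approx(4000, rel=0.2)

    def test_constant_chain_flagged_degenerate(self):
        assert math.isnan(effective_sample_size(np.ones(100)))

    def test_ar1_chain_matches_closed_form(self):
        rho = 0.7
        rng = np.random.default_rng(1)
        n = 20_000
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.normal(size=n)
        for k in range(1, n):
            x[k] = rho * x[k - 1] + eps[k]
        expected = n * (1 - rho) / (1 + rho)
        assert effective_sample_size(x) == pytest.approx(expected, rel=0.3)

    def test_ess_agrees_with_arviz(self):
        az = pytest.importorskip("arviz")
        rho = 0.5
        rng = np.random.default_rng(4)
        n = 8000
        x = np.empty(n)
        x[0] = 0.0
        for k in range(1, n):
            x[k] = rho * x[k - 1] + rng.normal()
        ours = effective_sample_size(x)
        theirs = float(az.ess(x))
        assert ours == pytest.approx(theirs, rel=0.3)

    def test_autocorrelation_lag_zero_is_one(self):
        x = np.random.default_rng(2).normal(size=500)
        acf = autocorrelation(x, max_lag=20)
        assert acf[0] == pytest.approx(1.0)
        assert acf.size == 21

    def test_chain_diagnostics_requires_draws(self, toy):
        tree = read_newick("((H1:0.3,H2:0.3):0.2,H3:0.5);")
        tree.set_leaf_states(toy.states)
        mask = classify_edges(list(toy.states.values()))
        cfg = ChainConfig(iterations=52, burn_in=50, thin=1, seed=0, subnetwork_cap=4)
        rec = run_estimation(tree, toy.ref, mask, cfg)
        with pytest.raises(InputError):
            chain_diagnostics(rec)
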