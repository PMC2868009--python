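"""MCMC engine: acceptance rule, proposals, incremental updates, coupling."""

import math

import numpy as np
import pytest

import plfkit as pk
from plfkit.mcmc import (ChainState, RunConfig, _make_init_state,
                         _valid_nni_moves, acceptance_probability, propose,
                         run_chain, run_mc3)
from plfkit.node_store import NodeStore
from plfkit.substitution import GTRModel, GTRParams


def small_state(seed=0, n_taxa=6, length=60, **cfg_kw):
    spec = pk.SimSpec(n_taxa=n_taxa, tree_height=0.4, alignment_length=length,
                      seed=seed)
    tree, seqs = pk.simulate_dataset(spec)
    data = pk.compress_alignment(seqs)
    cfg = RunConfig(seed=seed, root_age_mean=0.4, **cfg_kw)
    rng = np.random.default_rng(seed)
    state = _make_init_state(data, GTRModel(GTRParams.jc()), cfg, rng,
                             chain_id=0, heat=1.0, init_tree=None)
    return state, data, cfg, rng


class TestAcceptanceProbability:
    def test_all_ratios_zero(self):
        assert acceptance_probability(0.0, 0.0, 0.0) == 1.0

    def test_half_likelihood_ratio(self):
        assert acceptance_probability(math.log(0.5), 0.0, 0.0) == pytest.approx(0.5)

    def test_nan_rejected(self):
        with pytest.raises(ArithmeticError):
            acceptance_probability(float("nan"), 0.0, 0.0)

    def test_two_state_toy_stationary_distribution(self):
        """A two-state target (0.3, 0.7) sampled with flip proposals through
        the acceptance rule must visit state 1 with frequency 0.7. The
        tolerance is 3 sigma of the autocorrelation-adjusted asymptotic
        variance (rho = -3/7 gives a 0.4 variance inflation factor)."""
        target = np.array([0.3, 0.7])
        rng = np.random.default_rng(42)
        state, visits = 0, 0
        n = 100_000
        for _ in range(n):
            prop = 1 - state
            p = acceptance_probability(
                math.log(target[prop]) - math.log(target[state]), 0.0, 0.0)
            if rng.random() < p:
                state = prop
            visits += state
        sigma = math.sqrt(0.3 * 0.7 * 0.4 / n)
        assert abs(visits / n - 0.7) < 3 * sigma


class TestProposals:
    def test_move_mixture_frequencies(self):
        state, _, cfg, rng = small_state(1)
        counts = {"nni": 0, "slide": 0, "root_scale": 0}
        n = 4000
        for _ in range(n):
            name, prop = propose(state, rng, (0.4, 0.4, 0.2))
            counts[name] += 1
            if prop is not None:
                prop.undo()
        for name, w in zip(("nni", "slide", "root_scale"), (0.4, 0.4, 0.2)):
            sd = math.sqrt(w * (1 - w) * n)
            assert abs(counts[name] - w * n) < 4 * sd

    def test_dirty_nodes_closed_under_ancestors(self):
        state, _, cfg, rng = small_state(2)
        for _ in range(50):
            name, prop = propose(state, rng)
            if prop is None:
                continue
            dirty = set(map(id, prop.dirty_nodes))
            for node in prop.dirty_nodes:
                while node.parent is not None:
                    node = node.parent
                    assert id(node) in dirty
            assert id(state.tree.root) in dirty
            prop.undo()

    def test_moves_preserve_clock_constraint(self):
        state, _, cfg, rng = small_state(3)
        for _ in range(200):
            name, prop = propose(state, rng)
            assert state.tree.is_ultrametric(tol=1e-9)
            if prop is not None:
                prop.undo()

    def test_undo_restores_tree_exactly(self):
        state, _, cfg, rng = small_state(4)
        before = state.tree.to_newick()
        for _ in range(100):
            name, prop = propose(state, rng)
            if prop is not None:
                prop.undo()
            assert state.tree.to_newick() == before

    def test_age_slide_is_symmetric(self):
        state, _, cfg, rng = small_state(5)
        for _ in range(50):
            name, prop = propose(state, rng, (0.0, 1.0, 0.0))
            assert prop.ln_hastings == 0.0
            assert prop.ln_prior_ratio == 0.0
            prop.undo()

    def test_nni_hastings_counts_valid_moves(self):
        state, _, cfg, rng = small_state(6)
        n_before = len(_valid_nni_moves(state.tree))
        name, prop = propose(state, rng, (1.0, 0.0, 0.0))
        n_after = len(_valid_nni_moves(state.tree))
        assert prop.ln_hastings == pytest.approx(
            math.log(n_before) - math.log(n_after))
        prop.undo()


class TestRunChain:
    def test_zero_generations_trace_has_initial_state_only(self):
        _, data, _, _ = small_state(0)
        trace = run_chain(data, RunConfig(n_generations=0, seed=1,
                                          root_age_mean=0.4))
        assert trace.generations == [0]
        assert len(trace.newicks) == 1

    def test_incremental_matches_full_recompute(self):
        """Audit mode: the incrementally maintained lnL equals a from-scratch
        evaluation throughout the run."""
        _, data, _, _ = small_state(0)
        run_chain(data, RunConfig(n_generations=500, sample_freq=100, seed=3,
                                  audit_every=100, root_age_mean=0.4))

    def test_incremental_matches_full_recompute_faithful_chebyshev(self):
        _, data, _, _ = small_state(0)
        run_chain(data, RunConfig(n_generations=300, sample_freq=100, seed=3,
                                  backend="chebyshev", precision="faithful",
                                  audit_every=100, root_age_mean=0.4))

    def test_fixed_seed_is_reproducible(self):
        _, data, _, _ = small_state(0)
        cfg = RunConfig(n_generations=300, sample_freq=50, seed=9,
                        root_age_mean=0.4)
        a, b = run_chain(data, cfg), run_chain(data, cfg)
        assert a.newicks == b.newicks
        assert a.lnls == b.lnls

    def test_rejection_restores_committed_state(self):
        """Force rejection of every proposal (impossible likelihood) and
        check lnL and committed vectors stay bitwise identical."""
        state, data, cfg, rng = small_state(1)
        lnl0 = state.lnL
        root_id = state.node_id[state.tree.root]
        rec0 = state.store.read_committed(0, root_id)
        nw0 = state.tree.to_newick()
        for _ in range(100):
            name, prop = propose(state, rng)
            if prop is None:
                continue
            state._evaluate(prop.dirty_nodes, prop.matrix_dirty)
            prop.undo()
            state.store.reject(0)
        assert state.lnL == lnl0
        assert state.store.read_committed(0, root_id) is rec0
        assert state.tree.to_newick() == nw0

    def test_topology_recovery(self, backend_study):
        """Majority-rule consensus from the exact backend recovers the
        generating topology (RF 0) in at least 4 of 5 replicate datasets."""
        hits = sum(
            pk.rf_distance(d["consensus"][("exact", 1)], d["true_tree"]) == 0
            for d in backend_study)
        assert hits >= 4


class TestMetropolisCoupling:
    def test_single_chain_reduces_to_run_chain(self):
        _, data, _, _ = small_state(0)
        cfg = RunConfig(n_generations=200, sample_freq=50, seed=4,
                        root_age_mean=0.4)
        a = run_chain(data, cfg)
        b = run_mc3(data, RunConfig(n_generations=200, sample_freq=50, seed=4,
                                    n_chains=1, root_age_mean=0.4))
        assert a.newicks == b.newicks and a.lnls == b.lnls

    def test_swap_between_identical_states_always_accepts(self):
        # the coupled ratio is (heat_a - heat_b) * (U_b - U_a); identical
        # states give U_a == U_b, hence acceptance probability exactly 1
        heat_a, heat_b, U = 1.0, 0.8, -123.4
        ratio = (heat_a - heat_b) * (U - U)
        assert min(1.0, math.exp(ratio)) == 1.0

    def test_coupled_run_executes_and_samples_cold_chain(self):
        _, data, _, _ = small_state(0, length=40)
        cfg = RunConfig(n_generations=400, sample_freq=100, seed=5,
                        n_chains=3, heat_increment=0.2, swap_freq=10,
                        audit_every=200, root_age_mean=0.4)
        trace = run_mc3(data, cfg)
        assert len(trace.newicks) == 5
        assert all(math.isfinite(v) for v in trace.lnls)

    def test_two_state_marginal_matches_single_chain(self):
        """Coupled chains leave the cold-chain target invariant: a heated
        two-state sampler with swaps keeps the cold marginal at (0.3, 0.7)."""
        target = np.log(np.array([0.3, 0.7]))
        heats = [1.0, 0.5]
        rng = np.random.default_rng(7)
        states = [0, 0]
        visits = 0
        n = 60_000
        for it in range(n):
            for c in range(2):
                prop = 1 - states[c]
                lr = heats[c] * (target[prop] - target[states[c]])
                if rng.random() < min(1.0, math.exp(lr)):
                    states[c] = prop
            if it % 5 == 0:
                ratio = (heats[0] - heats[1]) * (target[states[1]]
                                                 - target[states[0]])
                if rng.random() < min(1.0, math.exp(min(ratio, 0.0))):
                    states[0], states[1] = states[1], states[0]
            visits += states[0]
        assert abs(visits / n - 0.7) < 0.01
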