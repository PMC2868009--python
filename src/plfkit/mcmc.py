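"""Bayesian MCMC tree search over clock-constrained trees.

The sampler follows the classic single-chain loop: propose a move, compute
the acceptance probability from the likelihood, prior and proposal
(Hastings) ratios, accept or reject, and record samples at fixed intervals.
The likelihood of a proposal is computed incrementally: only nodes whose
conditional-likelihood tables are invalidated by the move (the "dirty"
nodes, closed upward to the root) are recomputed, writing into the node
store's pending slots; acceptance commits those slots by handle swap and
rejection discards them, so the committed state is never copied or mutated.

Moves (clock-preserving):

* **NNI** — swap a child of an internal node with that node's sibling,
  valid when the receiving node is older than the moved subtree's root.
  Drawn uniformly from the currently valid moves; the Hastings ratio is the
  ratio of valid-move counts before and after.
* **Node-age slide** — redraw a non-root internal node's age uniformly
  between its oldest child and its parent (symmetric; Hastings 0).
* **Root-age multiplier** — scale the root age by exp(tuning*(u-1/2)).

Priors: uniform over topologies; node ages i.i.d. uniform on
[0, root age] restricted to valid parent/child orderings (one common
normalizer, so topology moves incur no age-prior ratio); exponential root
age with configurable mean, which makes the joint density proper.

Metropolis coupling: chain i runs at heat 1/(1 + delta*i), which exponentiates
the (likelihood x prior) term; adjacent chains periodically propose heat
swaps with the standard coupled-MCMC ratio; only cold-chain states are
sampled.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .node_store import NodeRecord, NodeStore
from .plf import (PatternAlignment, compress_alignment, leaf_likelihoods,
                  root_log_likelihood, scale_conditional, update_conditional,
                  _quantize)
from .lnapprox import get_backend
from .simulate import SimSpec, random_clock_tree
from .substitution import GTRModel, GTRParams
from .trees import Node, Tree


@dataclass(frozen=True)
class RunConfig:
    """Chain settings. ``move_weights`` orders as (NNI, age slide, root scale)."""

    n_generations: int = 10000
    sample_freq: int = 100
    burn_in: float = 0.25
    seed: int = 0
    backend: str = "exact"
    precision: str = "double"
    n_chains: int = 1
    heat_increment: float = 0.1
    swap_freq: int = 10
    n_runs: int = 2
    root_age_mean: float = 0.5
    move_weights: tuple = (0.4, 0.4, 0.2)
    root_scale_tuning: float = 0.5
    audit_every: int = 0
    init_height: Optional[float] = None

    def __post_init__(self):
        if self.sample_freq < 1:
            raise ValueError("sample_freq must be >= 1")
        if not 0 <= self.burn_in < 1:
            raise ValueError("burn_in fraction must be in [0, 1)")


@dataclass
class ProposalResult:
    move: str
    ln_hastings: float
    ln_prior_ratio: float
    dirty_nodes: list            # internal nodes needing clP recomputation
    matrix_dirty: list           # nodes whose branch length changed
    undo: callable


@dataclass
class Trace:
    """Sampled states of one run: generation indices, newick strings, lnL."""

    generations: list = field(default_factory=list)
    newicks: list = field(default_factory=list)
    lnls: list = field(default_factory=list)
    move_counts: Counter = field(default_factory=Counter)
    accept_counts: Counter = field(default_factory=Counter)

    def trees(self) -> list:
        return [Tree.from_newick(nw) for nw in self.newicks]

    def post_burnin_trees(self, burn_in: float = 0.25) -> list:
        start = int(round(burn_in * len(self.newicks)))
        return [Tree.from_newick(nw) for nw in self.newicks[start:]]


def acceptance_probability(ln_like_ratio: float, ln_prior_ratio: float,
                           ln_hastings: float) -> float:
    """Metropolis-Hastings acceptance: min(1, exp(sum of the three ratios))."""
    total = ln_like_ratio + ln_prior_ratio + ln_hastings
    if math.isnan(total):
        raise ArithmeticError("NaN in acceptance-probability inputs")
    return min(1.0, math.exp(min(total, 0.0)))


def _ln_prior(tree: Tree, root_age_mean: float) -> float:
    """Joint ln prior of the clock tree (up to a topology-uniform constant)."""
    root_age = tree.root.age
    n_free = len(tree.internal_nodes()) - 1  # non-root internal ages
    return -root_age / root_age_mean - n_free * math.log(root_age)


class ChainState:
    """One MCMC chain: tree, model, node-store handles, cached lnL, heat."""

    def __init__(self, tree: Tree, model: GTRModel, data: PatternAlignment,
                 backend, precision: str, store: NodeStore, chain_id,
                 heat: float = 1.0, root_age_mean: float = 0.5):
        self.tree = tree
        self.model = model
        self.data = data
        self.backend = get_backend(backend)
        self.precision = precision
        self.store = store
        self.chain_id = chain_id
        self.heat = heat
        self.root_age_mean = root_age_mean
        self.node_id = {}
        self.lnL = None
        self._init_store()

    # ---- store wiring --------------------------------------------------
    def _init_store(self) -> None:
        for i, node in enumerate(self.tree.postorder()):
            self.node_id[node] = i
            self.store.allocate(self.chain_id, i)
        p = self.data.n_patterns
        for node in self.tree.leaves():
            clp = _quantize(leaf_likelihoods(self.data.column_codes(node.label)),
                            self.precision)
            rec = NodeRecord(cond_like=clp, scaler=np.zeros(p),
                             trans_matrix=None)
            self.store.write_pending(self.chain_id, self.node_id[node], rec)
        self.store.commit(self.chain_id,
                          [self.node_id[n] for n in self.tree.leaves()])
        self.lnL = self._evaluate(self.tree.internal_nodes(), [])
        self.store.commit(self.chain_id, list(self.node_id.values()))

    def _record(self, node) -> NodeRecord:
        return self.store.read_current(self.chain_id, self.node_id[node])

    def _evaluate(self, dirty_internal, matrix_dirty) -> float:
        """Recompute the listed internal nodes into pending slots; return the
        proposal's root log likelihood."""
        cid = self.chain_id
        # refresh transition matrices of re-lengthed nodes (handle reuse: the
        # conditional table and scaler objects are shared with the committed
        # record, never copied)
        dirty_set = set(map(id, dirty_internal))
        for node in matrix_dirty:
            if id(node) in dirty_set:
                continue
            old = self._record(node)
            self.store.write_pending(cid, self.node_id[node], NodeRecord(
                cond_like=old.cond_like, scaler=old.scaler,
                trans_matrix=self.model.transition_matrix(node.length)))
        # dirty lists arrive child-before-ancestor (moves emit ancestor
        # chains; full evaluation passes a postorder list)
        for node in dirty_internal:
            left, right = node.children
            lrec, rrec = self._record(left), self._record(right)
            P_l = self.model.transition_matrix(left.length)
            P_r = self.model.transition_matrix(right.length)
            clp = _quantize(update_conditional(lrec.cond_like, rrec.cond_like,
                                               P_l, P_r), self.precision)
            incoming = lrec.scaler + rrec.scaler
            clp, sv = scale_conditional(clp, incoming, self.backend)
            own_P = (self.model.transition_matrix(node.length)
                     if node.parent is not None else None)
            rec = NodeRecord(cond_like=_quantize(clp, self.precision),
                             scaler=_quantize(sv.ln_scaler, self.precision),
                             trans_matrix=own_P)
            self.store.write_pending(cid, self.node_id[node], rec)
        root_rec = self._record(self.tree.root)
        return root_log_likelihood(root_rec.cond_like, root_rec.scaler,
                                   self.model.freqs, self.data.num_sites,
                                   self.backend)

    def full_recompute(self) -> float:
        """Likelihood from scratch (audit oracle); leaves pending slots
        untouched on return."""
        from .plf import tree_log_likelihood
        return tree_log_likelihood(self.tree, self.model, self.data,
                                   self.backend, precision=self.precision)

    def ln_prior(self) -> float:
        return _ln_prior(self.tree, self.root_age_mean)


# ---------------------------------------------------------------------------
# Moves
# ---------------------------------------------------------------------------

def _ancestors(node) -> list:
    out = []
    while node is not None:
        out.append(node)
        node = node.parent
    return out


def _valid_nni_moves(tree: Tree) -> list:
    """(p, child_index) pairs for clock-valid sibling swaps."""
    moves = []
    for p in tree.internal_nodes():
        g = p.parent
        if g is None:
            continue
        s = g.children[1] if g.children[0] is p else g.children[0]
        if p.age > s.age:
            moves.append((p, 0))
            moves.append((p, 1))
    return moves


def _propose_nni(state: ChainState, rng) -> Optional[ProposalResult]:
    tree = state.tree
    moves = _valid_nni_moves(tree)
    if not moves:
        return None
    p, ci = moves[rng.integers(len(moves))]
    g = p.parent
    c = p.children[ci]
    si = 0 if g.children[0] is p else 1
    s = g.children[1 - si]
    # swap c and s
    p.children[ci] = s
    s.parent = p
    g.children[1 - si] = c
    c.parent = g
    c.length = g.age - c.age
    s.length = p.age - s.age
    n_after = len(_valid_nni_moves(tree))

    def undo():
        p.children[ci] = c
        c.parent = p
        g.children[1 - si] = s
        s.parent = g
        c.length = p.age - c.age
        s.length = g.age - s.age

    return ProposalResult(
        move="nni",
        ln_hastings=math.log(len(moves)) - math.log(n_after),
        ln_prior_ratio=0.0,
        dirty_nodes=_ancestors(p),
        matrix_dirty=[c, s],
        undo=undo)


def _propose_age_slide(state: ChainState, rng) -> Optional[ProposalResult]:
    tree = state.tree
    candidates = [n for n in tree.internal_nodes() if n.parent is not None]
    if not candidates:
        return None
    v = candidates[rng.integers(len(candidates))]
    lo = max(c.age for c in v.children)
    hi = v.parent.age
    old_age, old_len = v.age, v.length
    old_child_lens = [c.length for c in v.children]
    v.age = rng.uniform(lo, hi)
    v.length = v.parent.age - v.age
    for c in v.children:
        c.length = v.age - c.age

    def undo():
        v.age, v.length = old_age, old_len
        for c, l in zip(v.children, old_child_lens):
            c.length = l

    return ProposalResult(move="slide", ln_hastings=0.0, ln_prior_ratio=0.0,
                          dirty_nodes=_ancestors(v),
                          matrix_dirty=[v, *v.children], undo=undo)


def _propose_root_scale(state: ChainState, rng) -> Optional[ProposalResult]:
    tree = state.tree
    root = tree.root
    m = math.exp(state_tuning(state) * (rng.random() - 0.5))
    new_age = root.age * m
    if new_age <= max(c.age for c in root.children):
        return None  # out of support; counts as an auto-rejected proposal
    old_age = root.age
    old_child_lens = [c.length for c in root.children]
    root.age = new_age
    for c in root.children:
        c.length = root.age - c.age

    def undo():
        root.age = old_age
        for c, l in zip(root.children, old_child_lens):
            c.length = l

    n_free = len(tree.internal_nodes()) - 1
    ln_prior = (-(new_age - old_age) / state.root_age_mean
                - n_free * math.log(m))
    return ProposalResult(move="root_scale", ln_hastings=math.log(m),
                          ln_prior_ratio=ln_prior, dirty_nodes=[root],
                          matrix_dirty=list(root.children), undo=undo)


def state_tuning(state: ChainState) -> float:
    return getattr(state, "root_scale_tuning", 0.5)


_MOVES = (_propose_nni, _propose_age_slide, _propose_root_scale)
MOVE_NAMES = ("nni", "slide", "root_scale")


def propose(state: ChainState, rng, move_weights=(0.4, 0.4, 0.2)):
    """Draw one move from the configured mixture and apply it to the tree.

    Returns a ProposalResult (dirty sets closed up to the root, Hastings and
    prior ratios filled in), or None when the drawn move has no valid
    realization (treated as an immediate rejection).
    """
    total = sum(move_weights)
    u = rng.random() * total
    k = 0
    acc = move_weights[0]
    while u >= acc and k < len(_MOVES) - 1:
        k += 1
        acc += move_weights[k]
    result = _MOVES[k](state, rng)
    if result is None:
        return MOVE_NAMES[k], None
    return result.move, result


# ---------------------------------------------------------------------------
# Generation loop
# ---------------------------------------------------------------------------

def _step(state: ChainState, rng, config: RunConfig, trace: Optional[Trace]):
    move_name, prop = propose(state, rng, config.move_weights)
    if trace is not None:
        trace.move_counts[move_name] += 1
    if prop is None:
        return
    try:
        new_lnl = state._evaluate(prop.dirty_nodes, prop.matrix_dirty)
    except ArithmeticError:
        prop.undo()
        state.store.reject(state.chain_id)
        return
    if not math.isfinite(new_lnl):
        raise RuntimeError(
            f"non-finite log likelihood ({new_lnl}) in chain {state.chain_id}; "
            f"move {prop.move}, tree: {state.tree.to_newick()}")
    ln_like_ratio = state.heat * (new_lnl - state.lnL + prop.ln_prior_ratio)
    p_accept = acceptance_probability(ln_like_ratio, 0.0, prop.ln_hastings)
    if rng.random() < p_accept:
        ids = [state.node_id[n] for n in prop.dirty_nodes + prop.matrix_dirty]
        state.store.commit(state.chain_id, ids)
        state.lnL = new_lnl
        if trace is not None:
            trace.accept_counts[prop.move] += 1
    else:
        prop.undo()
        state.store.reject(state.chain_id)


def _make_init_state(data: PatternAlignment, model: GTRModel,
                     config: RunConfig, rng, chain_id, heat: float,
                     init_tree: Optional[Tree]) -> ChainState:
    if init_tree is not None:
        tree = init_tree.copy()
        if tree.root.age is None:
            tree.set_ages_from_lengths()
    else:
        height = config.init_height or config.root_age_mean
        spec = SimSpec(n_taxa=len(data.taxa), tree_height=height,
                       alignment_length=1, seed=0)
        tree = random_clock_tree(spec, rng)
        labels = list(data.taxa)
        rng.shuffle(labels)
        for leaf, lab in zip(tree.leaves(), labels):
            leaf.label = lab
    tree.set_lengths_from_ages()
    state = ChainState(tree, model, data, config.backend, config.precision,
                       NodeStore(), chain_id, heat=heat,
                       root_age_mean=config.root_age_mean)
    state.root_scale_tuning = config.root_scale_tuning
    return state


def _coerce_data(data) -> PatternAlignment:
    return data if isinstance(data, PatternAlignment) else compress_alignment(data)


def run_mc3(data, config: RunConfig, model=None,
            init_tree: Optional[Tree] = None, progress=None,
            progress_every: int = 1000) -> Trace:
    """Metropolis-coupled run; returns the cold chain's trace.

    With ``n_chains == 1`` this reduces exactly to a single-chain run (no
    swap randomness is consumed). ``model`` defaults to Jukes-Cantor when no
    GTRParams/GTRModel is given (kernel-validation mode keeps the
    substitution model fixed rather than sampled). ``progress``, if given,
    is called as ``progress(generation, cold_lnL)`` every
    ``progress_every`` generations.
    """
    data = _coerce_data(data)
    if model is None:
        model = GTRModel(GTRParams.jc())
    elif isinstance(model, GTRParams):
        model = GTRModel(model)
    rng = np.random.default_rng(config.seed)
    heats = [1.0 / (1.0 + config.heat_increment * i)
             for i in range(config.n_chains)]
    chains = [_make_init_state(data, model, config, rng, chain_id=i,
                               heat=heats[i], init_tree=init_tree)
              for i in range(config.n_chains)]
    trace = Trace()

    def cold() -> ChainState:
        return next(c for c in chains if c.heat == 1.0)

    def record(gen: int) -> None:
        c = cold()
        trace.generations.append(gen)
        trace.newicks.append(c.tree.to_newick())
        trace.lnls.append(c.lnL)

    record(0)
    for gen in range(1, config.n_generations + 1):
        for chain in chains:
            _step(chain, rng, config, trace if chain.heat == 1.0 else None)
        if config.n_chains > 1 and gen % config.swap_freq == 0:
            i = int(rng.integers(config.n_chains - 1))
            a, b = chains[i], chains[i + 1]
            ratio = (a.heat - b.heat) * ((b.lnL + b.ln_prior())
                                         - (a.lnL + a.ln_prior()))
            if rng.random() < min(1.0, math.exp(min(ratio, 0.0))):
                a.heat, b.heat = b.heat, a.heat
        if config.audit_every and gen % config.audit_every == 0:
            c = cold()
            full = c.full_recompute()
            if abs(full - c.lnL) > 1e-8 * max(1.0, abs(full)):
                raise AssertionError(
                    f"incremental lnL {c.lnL} drifted from full recompute "
                    f"{full} at generation {gen}")
        if gen % config.sample_freq == 0:
            record(gen)
        if progress is not None and gen % progress_every == 0:
            progress(gen, cold().lnL)
    return trace


def run_chain(data, config: RunConfig, model=None,
              init_tree: Optional[Tree] = None) -> Trace:
    """Single-chain MCMC (see run_mc3)."""
    if config.n_chains != 1:
        config = replace(config, n_chains=1)
    return run_mc3(data, config, model=model, init_tree=init_tree)


def run_independent(data, config: RunConfig, model=None,
                    init_tree: Optional[Tree] = None, progress=None) -> list:
    """``config.n_runs`` independent replicate runs (seeds seed, seed+1, ...)."""
    traces = []
    for i in range(config.n_runs):
        cfg = replace(config, seed=config.seed + i)
        run_progress = ((lambda g, l, _i=i: progress(_i + 1, g, l))
                        if progress is not None else None)
        traces.append(run_mc3(data, cfg, model=model, init_tree=init_tree,
                              progress=run_progress))
    return traces
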