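"""Shared fixtures.

The expensive MCMC study fixtures are session-scoped and lazy so that the
search-quality checks and the topology-recovery test share the same runs.
"""

import itertools

import numpy as np
import pytest

import plfkit as pk
from plfkit.mcmc import RunConfig, run_mc3
from plfkit.plf import IUPAC


# ---------------------------------------------------------------------------
# Brute-force likelihood oracle (independent of the kernel implementation)
# ---------------------------------------------------------------------------

def brute_force_lnl(tree, model, seqs):
    """Tree log likelihood by explicit summation over every assignment of
    states to internal nodes: sum over 4^(n internal) terms of
    pi(root state) * prod over edges of P[parent, child], with leaf
    compatibility vectors for ambiguity codes."""
    if isinstance(model, pk.GTRParams):
        model = pk.GTRModel(model)
    aln = pk.compress_alignment(seqs)
    internals = tree.internal_nodes()
    leaves = tree.leaves()
    P = {id(n): model.transition_matrix(n.length or 0.0)
         for n in tree.postorder() if n.parent is not None}
    total = 0.0
    for ci in range(aln.n_patterns):
        leaf_row = {id(lf): IUPAC[aln.column_codes(lf.label)[ci]]
                    for lf in leaves}
        site = 0.0
        for assign in itertools.product(range(4), repeat=len(internals)):
            amap = {id(n): s for n, s in zip(internals, assign)}
            pr = model.freqs[amap[id(tree.root)]]
            for n in tree.postorder():
                if n.parent is None:
                    continue
                ps = amap[id(n.parent)]
                if n.is_leaf:
                    pr *= sum(P[id(n)][ps][s] * leaf_row[id(n)][s]
                              for s in range(4))
                else:
                    pr *= P[id(n)][ps][amap[id(n)]]
            site += pr
        total += aln.num_sites[ci] * np.log(site)
    return total


@pytest.fixture(scope="session")
def default_table():
    return pk.default_segment_table()


def random_instance(seed, n_taxa=5, length=12, height=0.4):
    """A small random (tree, model, sequences) instance for oracle checks."""
    rng = np.random.default_rng(seed)
    params = pk.GTRParams(
        exchangeabilities=tuple(rng.uniform(0.3, 3.0, 6)),
        base_freqs=tuple(np.array([0.3, 0.2, 0.25, 0.25])))
    spec = pk.SimSpec(n_taxa=n_taxa, tree_height=height,
                      alignment_length=length, model=params, seed=seed)
    rng2 = np.random.default_rng(seed + 1)
    tree = pk.random_clock_tree(spec, rng2)
    seqs = pk.simulate_alignment(tree, params, length, rng2)
    return tree, params, seqs


# ---------------------------------------------------------------------------
# Session-scoped MCMC studies
# ---------------------------------------------------------------------------

N_STUDY_DATASETS = 5
STUDY_GENERATIONS = 50_000


@pytest.fixture(scope="session")
def backend_study():
    """Five 8-taxon, 2000-site datasets; per dataset, two exact-backend runs
    with different chain seeds plus one chebyshev-backend run, 50k
    generations each. Returns a list of dicts with the true tree and the
    majority-rule consensus of each run."""
    out = []
    for ds in range(N_STUDY_DATASETS):
        spec = pk.SimSpec(n_taxa=8, tree_height=0.5, alignment_length=2000,
                          seed=100 + ds)
        true_tree, seqs = pk.simulate_dataset(spec)
        data = pk.compress_alignment(seqs)
        cons = {}
        for backend, chain_seed in [("exact", 1), ("exact", 2),
                                    ("chebyshev", 1)]:
            cfg = RunConfig(n_generations=STUDY_GENERATIONS, sample_freq=100,
                            seed=chain_seed, backend=backend,
                            root_age_mean=0.5)
            trace = run_mc3(data, cfg)
            cons[(backend, chain_seed)] = pk.majority_consensus(
                trace.trees(), burn_in=0.25)
        out.append({"true_tree": true_tree, "consensus": cons})
    return out


@pytest.fixture(scope="session")
def trap_study():
    """The transversion-trap dataset run under the exact and the clamped
    de Soras backends, two independent runs each; returns per-backend ASDSF."""
    true_tree, seqs, model = pk.transversion_trap_dataset(seed=0)
    data = pk.compress_alignment(seqs)
    result = {}
    for backend, precision in [("exact", "double"), ("desoras", "faithful")]:
        cfg = RunConfig(n_generations=15000, sample_freq=100, seed=7,
                        backend=backend, precision=precision,
                        root_age_mean=0.005, n_runs=2)
        traces = pk.run_independent(data, cfg, model=model)
        result[backend] = pk.asdsf(
            [t.post_burnin_trees(0.25) for t in traces])
    return result
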