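"""Synthetic clock trees and simulated GTR alignments.

Random topologies come from a Yule (pure-birth) process, which yields
ultrametric trees by construction; node ages are rescaled so every
root-to-leaf path equals the requested tree height (expected substitutions
per site from root to tip). Alignments are simulated site-independently:
root states are drawn from the stationary frequencies and evolve down each
edge through the model's transition matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .substitution import GTRModel, GTRParams, STATES
from .trees import Node, Tree


@dataclass(frozen=True)
class SimSpec:
    """Study conditions for one synthetic dataset."""

    n_taxa: int
    tree_height: float
    alignment_length: int
    model: GTRParams = field(default_factory=GTRParams.jc)
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 3:
            raise ValueError("need at least 3 taxa")
        if self.alignment_length < 1:
            raise ValueError("alignment length must be >= 1")
        if self.tree_height <= 0:
            raise ValueError("tree height must be positive")


def random_clock_tree(spec: SimSpec, rng: np.random.Generator) -> Tree:
    """Yule-process topology with ages rescaled to the requested height."""
    n = spec.n_taxa
    # forward Yule: split a uniformly chosen active lineage at each event
    tips = [Node(label=None)]
    birth_time = {tips[0]: 0.0}
    t = 0.0
    while len(tips) < n:
        t += rng.exponential(1.0 / len(tips))
        k = rng.integers(len(tips))
        parent = tips[k]
        parent.age = t  # temporarily store split time
        left, right = Node(), Node()
        parent.add_child(left)
        parent.add_child(right)
        tips[k] = left
        tips.append(right)
        birth_time[left] = birth_time[right] = t
    t_end = t + rng.exponential(1.0 / n)
    root = tips[0]
    while root.parent is not None:
        root = root.parent
    tree = Tree(root)
    # convert split times to ages measured back from the present, rescaled
    root_split = root.age
    scale = spec.tree_height / (t_end - root_split)
    for node in tree.postorder():
        if node.is_leaf:
            node.age = 0.0
        else:
            node.age = (t_end - node.age) * scale
    # exchangeable labels: attach them in random order so the label-to-shape
    # assignment carries no topological information
    perm = rng.permutation(n)
    for i, leaf in enumerate(tree.leaves()):
        leaf.label = f"t{perm[i] + 1}"
    tree.set_lengths_from_ages()
    return tree


def simulate_alignment(tree: Tree, model, length: int,
                       rng: np.random.Generator,
                       ambiguity_rate: float = 0.0) -> dict:
    """Simulate a gapless nucleotide alignment along a tree.

    Returns a dict of taxon label -> sequence string. ``ambiguity_rate``
    optionally replaces characters with 'N' at the given i.i.d. rate, to
    exercise ambiguous-state handling downstream.
    """
    if isinstance(model, GTRParams):
        model = GTRModel(model)
    states = {tree.root: rng.choice(4, size=length, p=model.freqs)}
    seqs = {}
    for node in tree.preorder():
        if node.parent is not None:
            P = model.transition_matrix(node.length or 0.0)
            cum = np.cumsum(P, axis=1)
            parent_states = states[node.parent]
            u = rng.random(length)
            child = np.empty(length, dtype=np.int64)
            for s in range(4):
                mask = parent_states == s
                if mask.any():
                    child[mask] = np.searchsorted(cum[s], u[mask], side="right")
            np.clip(child, 0, 3, out=child)
            states[node] = child
        if node.is_leaf:
            chars = np.array(list(STATES))[states[node]]
            if ambiguity_rate > 0:
                chars = np.where(rng.random(length) < ambiguity_rate, "N", chars)
            seqs[node.label] = "".join(chars)
    return seqs


def simulate_dataset(spec: SimSpec):
    """Convenience: seeded tree + alignment for a SimSpec.

    Returns (tree, sequences dict). Fixing the seed reproduces both bitwise.
    """
    rng = np.random.default_rng(spec.seed)
    tree = random_clock_tree(spec, rng)
    seqs = simulate_alignment(tree, spec.model, spec.alignment_length, rng)
    return tree, seqs


def transversion_trap_dataset(n_taxa: int = 10, background_length: int = 300,
                              tree_height: float = 0.005,
                              markers_per_clade: int = 2, seed: int = 0):
    """A contrived dataset whose scalers fall below 1e-10 during a search.

    The model makes transversions nearly impossible (AC/AT/CG/GT
    exchangeabilities ~1e-7). The alignment couples (a) a near-identical
    transition-only background simulated on a very shallow clock tree,
    which pulls posterior branch lengths toward ~1/background_length, with
    (b) clade-marker sites — one fixed transversion (C inside the clade, A
    outside) per internal clade of the generating tree — that carry
    essentially all of the topological signal.

    Merging a marker site across its clade boundary yields a per-pattern
    scaler of roughly (transversion rate x branch length), i.e. ~1e-10 at
    the branch lengths the background favors. An exact log prices that
    merge at ln(rate x t), anchoring both branch lengths and topology; a
    backend that returns 0 for scalers below 1e-10 erases the penalty as
    soon as branches drift slightly shorter, so the markers stop
    constraining the topology and independent runs wander apart.

    Returns (tree, sequences, GTRParams).
    """
    eps = 1e-7
    model = GTRParams(exchangeabilities=(eps, 1.0, eps, eps, 1.0, eps),
                      base_freqs=(0.25, 0.25, 0.25, 0.25))
    spec = SimSpec(n_taxa=n_taxa, tree_height=tree_height,
                   alignment_length=background_length, model=model, seed=seed)
    rng = np.random.default_rng(seed)
    tree = random_clock_tree(spec, rng)
    seqs = {k: list(v) for k, v in
            simulate_alignment(tree, model, background_length, rng).items()}
    below: dict = {}
    for node in tree.postorder():
        below[id(node)] = ([node.label] if node.is_leaf else
                           [l for c in node.children for l in below[id(c)]])
    taxa = set(seqs)
    for node in tree.internal_nodes():
        if node.parent is None:
            continue
        clade = set(below[id(node)])
        for _ in range(markers_per_clade):
            for t in taxa:
                seqs[t].append("C" if t in clade else "A")
    return tree, {k: "".join(v) for k, v in seqs.items()}, model
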