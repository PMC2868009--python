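"""Split-based tree statistics: consensus, ASDSF, Robinson-Foulds.

Rooted trees are interpreted as unrooted for split extraction: each
internal edge induces a bipartition of the taxa, canonicalized as the side
not containing a fixed reference taxon (the lexicographically first label).
Trivial splits (singletons and the full set) are excluded, so an unrooted
binary tree on n taxa carries at most n - 3 nontrivial splits.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

import numpy as np

from .trees import Node, Tree


class TaxonMismatchError(ValueError):
    pass


def _as_tree(t) -> Tree:
    return t if isinstance(t, Tree) else Tree.from_newick(str(t))


def splits(tree) -> frozenset:
    """Nontrivial bipartitions of a tree, as canonical frozensets of labels."""
    tree = _as_tree(tree)
    labels = tree.taxa()
    if len(set(labels)) != len(labels):
        dupes = sorted(l for l, c in Counter(labels).items() if c > 1)
        raise TaxonMismatchError(f"duplicate taxon labels: {dupes}")
    all_taxa = frozenset(labels)
    ref = min(labels)
    out = set()
    below: dict = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[node] = frozenset([node.label])
        else:
            clade = frozenset().union(*(below[c] for c in node.children))
            below[node] = clade
            if node.parent is None:
                continue
            side = clade if ref not in clade else all_taxa - clade
            if 1 < len(side) < len(all_taxa) - 1:
                out.add(side)
    return frozenset(out)


def split_frequencies(trees: Sequence, burn_in: float = 0.0) -> dict:
    """Relative frequency of each nontrivial split over post-burn-in trees."""
    trees = list(trees)
    start = int(round(burn_in * len(trees)))
    kept = trees[start:]
    if not kept:
        raise ValueError("no trees left after burn-in")
    counts: Counter = Counter()
    for t in kept:
        counts.update(splits(t))
    return {s: c / len(kept) for s, c in counts.items()}


def majority_consensus(trees: Sequence, burn_in: float = 0.0) -> Tree:
    """Majority-rule consensus of sampled topologies.

    Splits with frequency > 0.5 are mutually compatible and nest into a
    (possibly multifurcating) tree; each internal node's label carries the
    split frequency.
    """
    trees = [_as_tree(t) for t in trees]
    taxa = sorted(trees[0].taxa())
    for t in trees[1:]:
        if sorted(t.taxa()) != taxa:
            raise TaxonMismatchError("trees have differing taxon sets")
    freqs = split_frequencies(trees, burn_in)
    majority = {s: f for s, f in freqs.items() if f > 0.5}
    ref = min(taxa)
    # represent each split as the clade not containing the reference taxon;
    # majority splits nest, so insertion by decreasing size builds the tree
    clades = sorted(majority, key=len, reverse=True)
    root = Node()
    node_clade = {id(root): frozenset(taxa)}

    def descend(test):
        host = root
        while True:
            nxt = next((c for c in host.children
                        if id(c) in node_clade and test(node_clade[id(c)])), None)
            if nxt is None:
                return host
            host = nxt

    for clade in clades:
        host = descend(lambda cl: clade < cl)
        assert clade <= node_clade[id(host)], "majority splits must nest"
        n = Node(label=f"{majority[clade]:.4f}")
        host.add_child(n)
        node_clade[id(n)] = clade
    for taxon in taxa:
        host = descend(lambda cl: taxon in cl)
        host.add_child(Node(label=taxon))
    return Tree(root)


def _trace_frequencies(run: Sequence, burn_in: float) -> dict:
    return split_frequencies([_as_tree(t) for t in run], burn_in)


def asdsf(run_traces: Sequence[Sequence], burn_in: float = 0.0,
          min_freq: float = 0.1) -> float:
    """Average standard deviation of split frequencies across runs.

    For every split reaching ``min_freq`` in at least one run, take the
    sample standard deviation of its frequency across runs; return the mean
    over those splits (0.0 if no split qualifies). Values below 0.1 are the
    conventional convergence cutoff.
    """
    runs = list(run_traces)
    if len(runs) < 2:
        raise ValueError("ASDSF needs at least 2 independent runs")
    freq_maps = [_trace_frequencies(r, burn_in) for r in runs]
    qualifying = {s for fm in freq_maps for s, f in fm.items() if f >= min_freq}
    if not qualifying:
        return 0.0
    sds = []
    for s in qualifying:
        fs = np.array([fm.get(s, 0.0) for fm in freq_maps])
        sds.append(fs.std(ddof=1))
    return float(np.mean(sds))


def rf_distance(tree_a, tree_b) -> int:
    """Robinson-Foulds distance: |symmetric difference of the split sets|."""
    a, b = _as_tree(tree_a), _as_tree(tree_b)
    if sorted(a.taxa()) != sorted(b.taxa()):
        raise TaxonMismatchError(
            f"taxon sets differ: {sorted(a.taxa())} vs {sorted(b.taxa())}")
    return len(splits(a) ^ splits(b))
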