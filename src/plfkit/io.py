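"""Alignment and tree file I/O.

Alignments are read through Biopython's AlignIO (FASTA, relaxed PHYLIP,
NEXUS data blocks) into plain taxon -> sequence dicts; trees go through
dendropy newick parsing into the package's own Tree.
"""

from __future__ import annotations

from pathlib import Path

from Bio import AlignIO

from .trees import Tree, read_trees  # noqa: F401  (re-exported)

_EXT_FORMATS = {
    ".fasta": "fasta", ".fa": "fasta", ".fna": "fasta", ".fas": "fasta",
    ".phy": "phylip-relaxed", ".phylip": "phylip-relaxed",
    ".nex": "nexus", ".nexus": "nexus",
}


def guess_format(path) -> str:
    ext = Path(path).suffix.lower()
    try:
        return _EXT_FORMATS[ext]
    except KeyError:
        raise ValueError(
            f"cannot guess alignment format from extension {ext!r}; "
            "pass format explicitly") from None


def read_alignment(path, fmt: str = None) -> dict:
    """Read an alignment file into a taxon -> sequence dict."""
    fmt = fmt or guess_format(path)
    aln = AlignIO.read(str(path), fmt)
    return {rec.id: str(rec.seq).upper() for rec in aln}


def write_fasta(seqs: dict, path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def read_tree(path) -> Tree:
    return read_trees(path)[0]


def write_tree(tree: Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def write_trees(trees, path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write((t if isinstance(t, str) else t.to_newick()) + "\n")
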