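"""The phylogenetic likelihood function (Felsenstein pruning) kernel.

Implements the conditional-likelihood recursion with per-node scaling and
the root log-likelihood assembly, plus the deterministic pipelined-adder
emulation used for the final site accumulation.

Site patterns: distinct alignment columns are collapsed once, with a
``num_sites`` multiplicity vector, so each conditional-likelihood table has
one row per pattern rather than per site.

Scaling: at every internal node the conditional table is normalized by its
per-pattern row maximum (scP); the log of the scaler accumulates into a
cumulative per-pattern lnScaler vector (a node inherits the elementwise sum
of its children's lnScaler vectors). The tree log likelihood is then

    lnL = sum_c numSites[c] * ( ln( sum_N pi_N clP_root[c,N] ) + lnScaler_root[c] )

which is invariant to whether scaling was applied, up to the accuracy of
the log backend.

Precision modes: ``double`` keeps all arithmetic in IEEE doubles;
``faithful`` rounds the conditional, scaler and lnScaler vectors to the
nearest single-precision value after each operation (the root accumulation
and logs stay double), mirroring a mixed-precision pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lnapprox import get_backend
from .substitution import GTRModel, GTRParams, N_STATES
from .trees import Tree


class AlignmentFormatError(ValueError):
    pass


class UnderflowError(ArithmeticError):
    pass


# IUPAC nucleotide codes -> state-compatibility rows over (A, C, G, T)
IUPAC = {
    "A": (1, 0, 0, 0), "C": (0, 1, 0, 0), "G": (0, 0, 1, 0), "T": (0, 0, 0, 1),
    "U": (0, 0, 0, 1),
    "R": (1, 0, 1, 0), "Y": (0, 1, 0, 1), "S": (0, 1, 1, 0), "W": (1, 0, 0, 1),
    "K": (0, 0, 1, 1), "M": (1, 1, 0, 0),
    "B": (0, 1, 1, 1), "D": (1, 0, 1, 1), "H": (1, 1, 0, 1), "V": (1, 1, 1, 0),
    "N": (1, 1, 1, 1), "-": (1, 1, 1, 1), "?": (1, 1, 1, 1),
}


@dataclass(frozen=True)
class PatternAlignment:
    """Compressed site patterns with per-pattern multiplicities."""

    taxa: tuple
    patterns: np.ndarray  # (p, n_taxa) array of single-character codes
    num_sites: np.ndarray  # (p,) ints

    @property
    def n_patterns(self) -> int:
        return len(self.num_sites)

    @property
    def n_sites(self) -> int:
        return int(self.num_sites.sum())

    def column_codes(self, taxon: str) -> np.ndarray:
        """Pattern-ordered character codes for one taxon."""
        idx = self.taxa.index(taxon)
        return self.patterns[:, idx]


def _as_sequence_dict(alignment) -> dict:
    if isinstance(alignment, dict):
        return {str(k): str(v).upper() for k, v in alignment.items()}
    # Bio.Align.MultipleSeqAlignment or iterable of SeqRecord-likes
    out = {}
    for rec in alignment:
        if hasattr(rec, "id") and hasattr(rec, "seq"):
            out[str(rec.id)] = str(rec.seq).upper()
        else:
            name, seq = rec
            out[str(name)] = str(seq).upper()
    return out


def compress_alignment(alignment) -> PatternAlignment:
    """Collapse identical alignment columns into patterns with multiplicities.

    Accepts a dict of taxon -> sequence, a Biopython alignment, or an
    iterable of (name, sequence) pairs. Pattern order preserves the first
    occurrence of each distinct column.
    """
    seqs = _as_sequence_dict(alignment)
    if not seqs:
        raise AlignmentFormatError("empty alignment")
    taxa = tuple(seqs)
    if len(taxa) < 2:
        raise AlignmentFormatError("need at least 2 taxa")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise AlignmentFormatError(f"ragged alignment: lengths {sorted(lengths)}")
    (L,) = lengths
    if L == 0:
        raise AlignmentFormatError("alignment has zero length")
    columns = ("".join(seqs[t][i] for t in taxa) for i in range(L))
    index: dict = {}
    counts: list = []
    for col in columns:
        k = index.setdefault(col, len(counts))
        if k == len(counts):
            counts.append(1)
        else:
            counts[k] += 1
    patterns = np.array([list(col) for col in index], dtype="U1")
    return PatternAlignment(taxa=taxa, patterns=patterns,
                            num_sites=np.asarray(counts, dtype=np.int64))


def leaf_likelihoods(codes) -> np.ndarray:
    """One row of state compatibilities per pattern for a single taxon.

    A/C/G/T map to one-hot rows; ambiguity codes set 1 for each compatible
    state; gaps and N are all-ones. The paired lnScaler starts at zero.
    """
    codes = np.asarray(codes, dtype="U1")
    out = np.empty((len(codes), N_STATES))
    for i, ch in enumerate(codes):
        try:
            out[i] = IUPAC[ch]
        except KeyError:
            raise AlignmentFormatError(
                f"invalid nucleotide code {ch!r} at pattern position {i}") from None
    return out


def update_conditional(clP_i: np.ndarray, clP_j: np.ndarray,
                       P_i: np.ndarray, P_j: np.ndarray) -> np.ndarray:
    """Felsenstein pruning step: parent conditional likelihoods from two
    children.

    result[c, N] = (sum_M P_i[N, M] clP_i[c, M]) * (sum_M P_j[N, M] clP_j[c, M])
    """
    if clP_i.shape != clP_j.shape:
        raise ValueError(
            f"child tables disagree in shape: {clP_i.shape} vs {clP_j.shape}")
    return (clP_i @ P_i.T) * (clP_j @ P_j.T)


@dataclass
class ScalerVector:
    """Per-pattern cumulative log scaler and the most recent scaler values."""

    ln_scaler: np.ndarray
    scp: np.ndarray


def scale_conditional(clP: np.ndarray, ln_scaler_children_sum: np.ndarray,
                      log_backend="exact"):
    """Normalize each pattern row by its maximum (scP) and fold ln(scP) into
    the cumulative lnScaler vector.

    Returns (normalized table with row maxima exactly 1, ScalerVector).
    """
    backend = get_backend(log_backend)
    scp = clP.max(axis=1)
    if np.any(scp <= 0):
        idx = int(np.argmax(scp <= 0))
        raise UnderflowError(
            f"conditional likelihoods underflowed to zero at pattern {idx}")
    normalized = clP / scp[:, None]
    ln_scaler = np.asarray(ln_scaler_children_sum, dtype=float) + backend.scaler_ln(scp)
    return normalized, ScalerVector(ln_scaler=ln_scaler, scp=scp)


def pipelined_accumulate(values, depth: int = 14) -> float:
    """Deterministic emulation of a deeply pipelined feedback accumulator.

    Values are distributed round-robin into ``depth`` partial sums (one per
    pipeline stage); the partial sums are then coalesced by repeated pairwise
    addition until a single sum remains.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    values = np.asarray(values, dtype=float).ravel()
    n = len(values)
    if n == 0:
        return 0.0
    pad = (-n) % depth
    if pad:
        values = np.concatenate([values, np.zeros(pad)])
    lanes = values.reshape(-1, depth)
    partials = np.add.reduce(lanes, axis=0)  # sequential within each lane
    sums = list(partials)
    while len(sums) > 1:
        nxt = [sums[i] + sums[i + 1] for i in range(0, len(sums) - 1, 2)]
        if len(sums) % 2:
            nxt.append(sums[-1])
        sums = nxt
    return float(sums[0])


def root_log_likelihood(clP_root: np.ndarray, ln_scaler_root: np.ndarray,
                        freqs, num_sites, log_backend="exact") -> float:
    """Assemble the tree log likelihood at the (virtual) root.

    lnL = sum_c numSites[c] * ( ln( sum_N pi_N clP_root[c, N] ) + lnScaler[c] ),
    accumulated in double precision through the pipelined accumulator.
    """
    backend = get_backend(log_backend)
    freqs = np.asarray(freqs, dtype=float)
    num_sites = np.asarray(num_sites)
    if not np.isclose(freqs.sum(), 1.0, atol=1e-9):
        raise ValueError("base frequencies must sum to 1")
    if not (len(clP_root) == len(ln_scaler_root) == len(num_sites)):
        raise ValueError("table, scaler and numSites lengths disagree")
    site_like = clP_root @ freqs
    if np.any(site_like <= 0):
        idx = int(np.argmax(site_like <= 0))
        raise UnderflowError(f"site likelihood <= 0 at pattern {idx}")
    per_pattern = backend.root_ln(site_like) + np.asarray(ln_scaler_root, dtype=float)
    return pipelined_accumulate(num_sites * per_pattern)


def _quantize(arr: np.ndarray, precision: str) -> np.ndarray:
    if precision == "faithful":
        return arr.astype(np.float32).astype(np.float64)
    return arr


def tree_log_likelihood(tree: Tree, model, data: PatternAlignment,
                        log_backend="exact", precision: str = "double",
                        scale: bool = True, return_site_lnl: bool = False):
    """Post-order likelihood of a rooted binary tree.

    ``model`` may be a GTRModel or GTRParams. Branch lengths are taken from
    ``node.length``. Scaling is applied at every internal node unless
    ``scale`` is False (useful only on short trees, for validation).
    """
    if precision not in ("double", "faithful"):
        raise ValueError(f"unknown precision mode {precision!r}")
    if isinstance(model, GTRParams):
        model = GTRModel(model)
    backend = get_backend(log_backend)

    tree_taxa = set(tree.taxa())
    data_taxa = set(data.taxa)
    if tree_taxa != data_taxa:
        only_tree = sorted(tree_taxa - data_taxa)
        only_data = sorted(data_taxa - tree_taxa)
        raise ValueError(
            f"tree/alignment taxon mismatch: only in tree {only_tree}, "
            f"only in alignment {only_data}")

    p = data.n_patterns
    tables = {}
    scalers = {}
    for node in tree.postorder():
        if node.is_leaf:
            tables[node] = _quantize(leaf_likelihoods(data.column_codes(node.label)),
                                     precision)
            scalers[node] = np.zeros(p)
        else:
            if len(node.children) != 2:
                raise ValueError("tree must be binary for likelihood evaluation")
            left, right = node.children
            P_l = model.transition_matrix(left.length or 0.0)
            P_r = model.transition_matrix(right.length or 0.0)
            clP = _quantize(update_conditional(tables[left], tables[right], P_l, P_r),
                            precision)
            incoming = scalers[left] + scalers[right]
            if scale:
                clP, sv = scale_conditional(clP, incoming, backend)
                clP = _quantize(clP, precision)
                tables[node] = clP
                scalers[node] = _quantize(sv.ln_scaler, precision)
            else:
                tables[node] = clP
                scalers[node] = incoming
            # child tables are no longer needed
            del tables[left], tables[right], scalers[left], scalers[right]

    root = tree.root
    lnl = root_log_likelihood(tables[root], scalers[root], model.freqs,
                              data.num_sites, backend)
    if return_site_lnl:
        site_like = tables[root] @ model.freqs
        per_pattern = backend.root_ln(site_like) + scalers[root]
        return lnl, per_pattern
    return lnl
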