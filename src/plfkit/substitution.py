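"""GTR-family nucleotide substitution models.

State order is fixed as A, C, G, T throughout the package. Rate matrices are
normalized to one expected substitution per unit branch length, and
transition probability matrices P(t) = exp(Qt) are computed through the
symmetric eigendecomposition that time reversibility guarantees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STATES = "ACGT"
N_STATES = 4

# exchangeability order: AC, AG, AT, CG, CT, GT
_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


class InvalidParameterError(ValueError):
    pass


@dataclass(frozen=True)
class GTRParams:
    """Exchangeabilities (AC, AG, AT, CG, CT, GT) and base frequencies (A,C,G,T)."""

    exchangeabilities: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    base_freqs: tuple = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self):
        ex = tuple(float(v) for v in self.exchangeabilities)
        fr = tuple(float(v) for v in self.base_freqs)
        object.__setattr__(self, "exchangeabilities", ex)
        object.__setattr__(self, "base_freqs", fr)
        if len(ex) != 6:
            raise InvalidParameterError("expected 6 exchangeabilities (AC,AG,AT,CG,CT,GT)")
        if len(fr) != 4:
            raise InvalidParameterError("expected 4 base frequencies (A,C,G,T)")
        if any(v <= 0 for v in ex):
            raise InvalidParameterError("exchangeabilities must be strictly positive")
        if any(v < 0 for v in fr) or any(v == 0 for v in fr):
            raise InvalidParameterError("base frequencies must be strictly positive")
        if abs(sum(fr) - 1.0) > 1e-12:
            raise InvalidParameterError(f"base frequencies must sum to 1 (got {sum(fr)})")

    @classmethod
    def jc(cls) -> "GTRParams":
        """Jukes-Cantor: equal exchangeabilities, uniform frequencies."""
        return cls()


def build_rate_matrix(params: GTRParams) -> np.ndarray:
    """GTR rate matrix Q with off-diagonals r_ij * pi_j, rows summing to zero,
    rescaled so that -sum_i pi_i Q_ii = 1 (one expected substitution per unit
    branch length)."""
    pi = np.asarray(params.base_freqs, dtype=float)
    Q = np.zeros((4, 4))
    for r, (i, j) in zip(params.exchangeabilities, _PAIRS):
        Q[i, j] = r * pi[j]
        Q[j, i] = r * pi[i]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(np.dot(pi, np.diag(Q)))
    return Q / mu


def stationary_distribution(rate_matrix: np.ndarray) -> np.ndarray:
    """Stationary frequencies of a rate matrix (left null vector, normalized)."""
    w, v = np.linalg.eig(rate_matrix.T)
    k = int(np.argmin(np.abs(w)))
    pi = np.real(v[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def transition_matrix(rate_matrix: np.ndarray, t: float,
                      freqs=None) -> np.ndarray:
    """P(t) = exp(Q t) via the pi-symmetrized eigendecomposition.

    ``freqs`` may be supplied to skip recovering the stationary distribution
    from the rate matrix.
    """
    if t < 0:
        raise InvalidParameterError(f"branch length must be >= 0 (got {t})")
    pi = np.asarray(freqs, dtype=float) if freqs is not None else stationary_distribution(rate_matrix)
    return GTRModel.from_rate_matrix(rate_matrix, pi).transition_matrix(t)


class GTRModel:
    """A GTR model with a cached eigendecomposition for fast P(t) evaluation.

    Reversibility makes D^{1/2} Q D^{-1/2} symmetric (D = diag(pi)), so the
    spectrum is real and exp(Qt) = D^{-1/2} V exp(L t) V^T D^{1/2}.
    """

    def __init__(self, params: GTRParams):
        self.params = params
        self.Q = build_rate_matrix(params)
        self.freqs = np.asarray(params.base_freqs, dtype=float)
        self._decompose()

    @classmethod
    def from_rate_matrix(cls, Q: np.ndarray, freqs: np.ndarray) -> "GTRModel":
        obj = cls.__new__(cls)
        obj.params = None
        obj.Q = np.asarray(Q, dtype=float)
        obj.freqs = np.asarray(freqs, dtype=float)
        obj._decompose()
        return obj

    def _decompose(self) -> None:
        sq = np.sqrt(self.freqs)
        S = (sq[:, None] * self.Q) / sq[None, :]
        S = 0.5 * (S + S.T)  # symmetrize away rounding noise
        lam, V = np.linalg.eigh(S)
        self._lam = lam
        self._left = V / sq[:, None]     # D^{-1/2} V
        self._right = V.T * sq[None, :]  # V^T D^{1/2}

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise InvalidParameterError(f"branch length must be >= 0 (got {t})")
        P = (self._left * np.exp(self._lam * t)) @ self._right
        # clamp rounding noise (~1e-17 negatives at tiny t); row sums stay
        # within 1e-12 of 1 so no renormalization is needed
        np.maximum(P, 0.0, out=P)
        np.minimum(P, 1.0, out=P)
        return P
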