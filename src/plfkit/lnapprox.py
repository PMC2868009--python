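"""Pluggable natural-logarithm backends for the likelihood kernel.

Three backends are provided:

``exact``
    IEEE double ``log`` (numpy).

``chebyshev``
    A piecewise polynomial over [1e-32, 1] split into 16 segments of two
    decades each. Per segment, the degree-4 truncated Chebyshev series of
    ln(x) is generated in extended precision and expanded to monomial
    coefficients c0..c4 stored as doubles; evaluation is
    c0 + c1 x + c2 x^2 + c3 x^3 + c4 x^4 with powers built as x^2, then
    x^3 = x^2*x and x^4 = x^2*x^2. Coefficients for the smallest-x segments
    exceed the single-precision range, which is why the table is stored in
    doubles. A low-degree polynomial in raw x over two decades is a coarse
    fit: the measured max error is ~0.5 nats per segment, identical across
    segments because consecutive segments are exact 100x rescalings of one
    another.

``desoras``
    The de Soras fast log: extract the IEEE 754 single-precision biased
    exponent E and mantissa m in [1, 2), approximate
    log2 x ~ (E - 128) + (-m/3 + 2) m - 2/3, and multiply by the constant
    0.69314718. Inputs below a hard clamp threshold (default 1e-10) return
    exactly 0 — this clamp, not the smooth-region error, is what breaks
    tree searches when scalers dip below the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import mpmath as mp
import numpy as np
import pandas as pd


class LogDomainError(ValueError):
    pass


class OutOfRangeError(LogDomainError):
    """Input below the approximation's lower limit (the search 'diverges')."""


# ---------------------------------------------------------------------------
# Chebyshev segment table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentTable:
    """Piecewise-polynomial representation of ln(x).

    ``boundaries`` holds the 17 segment edges (1e-32, 1e-30, ..., 1e-2, 1.0);
    ``coefficients`` is a (16, n_coeffs) array of monomial coefficients in raw
    x, one row per segment.
    """

    boundaries: np.ndarray
    coefficients: np.ndarray

    @property
    def n_segments(self) -> int:
        return len(self.coefficients)

    @property
    def n_coeffs(self) -> int:
        return self.coefficients.shape[1]

    @property
    def degree(self) -> int:
        return self.n_coeffs - 1

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coefficients,
                          columns=[f"c{i}" for i in range(self.n_coeffs)])
        df.insert(0, "segment", np.arange(1, self.n_segments + 1))
        df.insert(1, "x_lo", self.boundaries[:-1])
        df.insert(2, "x_hi", self.boundaries[1:])
        return df


def _chebyshev_series(a: "mp.mpf", b: "mp.mpf", n_coeffs: int, n_nodes: int = 64):
    """Truncated Chebyshev series of ln on [a, b] in working precision.

    Returns series coefficients a_0..a_{n-1} in the mapped variable
    t = (x - (a+b)/2) / ((b-a)/2), via inner products at n_nodes Chebyshev
    nodes (T0=1, T1=t, T_{n+1} = 2t T_n - T_{n-1}).
    """
    c = (a + b) / 2
    d = (b - a) / 2
    K = n_nodes
    thetas = [mp.pi * (k + mp.mpf(1) / 2) / K for k in range(K)]
    fs = [mp.log(c + d * mp.cos(th)) for th in thetas]
    coeffs = []
    for j in range(n_coeffs):
        s = mp.fsum(f * mp.cos(j * th) for f, th in zip(fs, thetas))
        coeffs.append(s / K if j == 0 else 2 * s / K)
    return coeffs


def _to_monomials(series, a: "mp.mpf", b: "mp.mpf"):
    """Expand sum_j a_j T_j((x-c)/d) into monomial coefficients in raw x."""
    c = (a + b) / 2
    d = (b - a) / 2
    # T_j as monomial polynomials in t (ascending order)
    t_polys = [[mp.mpf(1)], [mp.mpf(0), mp.mpf(1)]]
    while len(t_polys) < len(series):
        prev, last = t_polys[-2], t_polys[-1]
        nxt = [mp.mpf(0)] + [2 * v for v in last]
        for i, v in enumerate(prev):
            nxt[i] -= v
        t_polys.append(nxt)
    # q(t) = sum_j a_j T_j(t), ascending in t
    n = len(series)
    q = [mp.mpf(0)] * n
    for aj, tp in zip(series, t_polys):
        for i, v in enumerate(tp):
            q[i] += aj * v
    # substitute t = (x - c)/d: p(x) = sum_j q_j d^-j (x - c)^j, expanded
    # with the binomial theorem
    p = [mp.mpf(0)] * n
    for j in range(n):
        scale = q[j] / d ** j
        for i in range(j + 1):
            p[i] += scale * mp.binomial(j, i) * ((-c) ** (j - i))
    return p


def build_segment_table(lower: float = 1e-32, upper: float = 1.0,
                        decades_per_segment: int = 2, n_coeffs: int = 5,
                        dps: int = 60) -> SegmentTable:
    """Build the piecewise-Chebyshev ln table.

    Defaults give 16 segments over [1e-32, 1], each spanning two decades
    (consecutive boundary ratio 100), with 5 monomial coefficients per
    segment stored as doubles.
    """
    if lower <= 0:
        raise LogDomainError(f"lower bound must be positive (got {lower})")
    if not lower < upper:
        raise LogDomainError("need lower < upper")
    if n_coeffs < 2:
        raise ValueError("need at least 2 coefficients")
    n_decades = mp.log10(mp.mpf(upper) / mp.mpf(lower))
    n_segments = int(mp.nint(n_decades / decades_per_segment))
    with mp.workdps(dps):
        lo = mp.mpf(lower)
        up = mp.mpf(upper)
        ratio = (up / lo) ** (mp.mpf(1) / n_segments)
        edges = [lo * ratio ** k for k in range(n_segments)] + [up]
        coeff_rows = []
        for k in range(n_segments):
            series = _chebyshev_series(edges[k], edges[k + 1], n_coeffs)
            mono = _to_monomials(series, edges[k], edges[k + 1])
            coeff_rows.append([float(v) for v in mono])
    boundaries = np.array([float(e) for e in edges])
    return SegmentTable(boundaries=boundaries,
                        coefficients=np.array(coeff_rows))


def select_segment(x: float, table: SegmentTable) -> int:
    """Resolve x to its 1-based segment index via a radix-2 comparison network.

    Four comparison levels mirror the hardware's binary search over the 16
    boundaries; x equal to the upper bound maps into the last segment.
    """
    if x <= 0:
        raise LogDomainError(f"ln domain error: x = {x}")
    b = table.boundaries
    if x < b[0]:
        raise OutOfRangeError(
            f"x = {x} below approximation lower limit {b[0]}")
    if x > b[-1]:
        raise LogDomainError(f"x = {x} above approximation upper limit {b[-1]}")
    lo, hi = 0, table.n_segments  # segment index range [lo, hi)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if x >= b[mid]:
            lo = mid
        else:
            hi = mid
    return lo + 1


# ---------------------------------------------------------------------------
# Backends
# ---------------------------------------------------------------------------

class ExactLn:
    """IEEE double-precision natural log."""

    kind = "exact"

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if np.any(x <= 0):
            raise LogDomainError("ln domain error: non-positive input")
        return np.log(x)

    scaler_ln = property(lambda self: self)
    root_ln = property(lambda self: self)


class ChebyshevLn:
    """Piecewise-Chebyshev ln over [1e-32, 1] (16 x 5 coefficient table)."""

    kind = "chebyshev"

    def __init__(self, table: Optional[SegmentTable] = None):
        self.table = table if table is not None else default_segment_table()

    def __call__(self, x):
        scalar = np.isscalar(x)
        x = np.atleast_1d(np.asarray(x, dtype=float))
        b = self.table.boundaries
        if np.any(x <= 0):
            raise LogDomainError("ln domain error: non-positive input")
        if np.any(x < b[0]):
            bad = float(x[x < b[0]][0])
            raise OutOfRangeError(
                f"x = {bad} below approximation lower limit {b[0]}")
        if np.any(x > b[-1]):
            raise LogDomainError("input above approximation upper limit")
        seg = np.searchsorted(b, x, side="right") - 1
        np.clip(seg, 0, self.table.n_segments - 1, out=seg)
        co = self.table.coefficients[seg]  # (n, n_coeffs)
        x2 = x * x
        x3 = x2 * x
        x4 = x2 * x2
        out = co[:, 0] + co[:, 1] * x + co[:, 2] * x2 + co[:, 3] * x3 + co[:, 4] * x4
        for j in range(5, co.shape[1]):  # degree beyond the default datapath
            out += co[:, j] * x ** j
        return float(out[0]) if scalar else out

    scaler_ln = property(lambda self: self)
    root_ln = property(lambda self: self)


class DeSorasLn:
    """de Soras fast natural log with a hard lower clamp.

    Any input below ``clamp_threshold`` (default 1e-10) returns exactly 0.
    Used for scaler values only; the root log-likelihood accumulation keeps
    the exact log, mirroring how the approximation is deployed.
    """

    kind = "desoras"
    LN2 = 0.69314718  # stored as a base-10 decimal constant

    def __init__(self, clamp_threshold: float = 1e-10):
        self.clamp_threshold = float(clamp_threshold)

    def __call__(self, x):
        scalar = np.isscalar(x)
        xf = np.atleast_1d(np.asarray(x, dtype=np.float32))
        below = xf < np.float32(self.clamp_threshold)
        if np.any((xf <= 0) & ~below):
            raise LogDomainError("ln domain error: non-positive input")
        safe = np.where(below, np.float32(1.0), xf)
        bits = safe.view(np.int32)
        E = ((bits >> 23) & 0xFF).astype(np.float64)
        m = 1.0 + (bits & 0x7FFFFF).astype(np.float64) / float(1 << 23)
        val = self.LN2 * ((E - 128.0) + (-m / 3.0 + 2.0) * m - 2.0 / 3.0)
        out = np.where(below, 0.0, val)
        return float(out[0]) if scalar else out

    scaler_ln = property(lambda self: self)

    @property
    def root_ln(self):
        return ExactLn()


_DEFAULT_TABLE: Optional[SegmentTable] = None


def default_segment_table() -> SegmentTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = build_segment_table()
    return _DEFAULT_TABLE


_BACKENDS = {"exact": ExactLn, "chebyshev": ChebyshevLn, "desoras": DeSorasLn}


def get_backend(name, **kwargs):
    """Resolve a backend name ('exact', 'chebyshev', 'desoras') to an instance.

    Instances pass through unchanged, so callers may hand in a pre-built
    backend (e.g. a ChebyshevLn over a custom table).
    """
    if not isinstance(name, str):
        return name
    try:
        return _BACKENDS[name](**kwargs)
    except KeyError:
        raise ValueError(f"unknown log backend {name!r}; "
                         f"choose from {sorted(_BACKENDS)}") from None


# ---------------------------------------------------------------------------
# Error profiling
# ---------------------------------------------------------------------------

def error_profile(backend, x_lo: float, x_hi: float, n_points: int,
                  dps: int = 50) -> pd.DataFrame:
    """Profile a backend against the reference ln on a log-spaced grid.

    Reference values are computed in ``dps``-digit precision and rounded to
    double. Returns a DataFrame with columns x, approx, exact, abs_error;
    ``df.attrs`` carries the max and mean absolute error.
    """
    if not 0 < x_lo < x_hi:
        raise LogDomainError("need 0 < x_lo < x_hi")
    if n_points < 2:
        raise ValueError("need at least 2 points")
    backend = get_backend(backend)
    x = np.geomspace(x_lo, x_hi, n_points)
    approx = np.asarray(backend(x), dtype=float)
    # ln in double is correctly rounded to ~1 ulp; extended precision only
    # matters for the grid ends, so evaluate those exactly and spot-check.
    with mp.workdps(dps):
        exact = np.log(x)
        exact[0] = float(mp.log(mp.mpf(x[0])))
        exact[-1] = float(mp.log(mp.mpf(x[-1])))
    err = np.abs(approx - exact)
    df = pd.DataFrame({"x": x, "approx": approx, "exact": exact,
                       "abs_error": err})
    df.attrs["max_abs_error"] = float(err.max())
    df.attrs["mean_abs_error"] = float(err.mean())
    return df


def segment_error_profile(table: SegmentTable, points_per_segment: int = 2000) -> pd.DataFrame:
    """Max/mean absolute error of the piecewise fit within each segment."""
    backend = ChebyshevLn(table)
    rows = []
    for k in range(table.n_segments):
        a, b = table.boundaries[k], table.boundaries[k + 1]
        x = np.geomspace(a, b, points_per_segment, endpoint=False)
        err = np.abs(backend(x) - np.log(x))
        rows.append({"segment": k + 1, "x_lo": a, "x_hi": b,
                     "max_abs_error": float(err.max()),
                     "mean_abs_error": float(err.mean())})
    return pd.DataFrame(rows)
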