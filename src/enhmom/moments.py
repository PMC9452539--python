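"""Raw, central and discrete orthogonal Hahn moments of reshaped sequences.

A DNA sequence of length ``z`` is encoded numerically (A=1, C=2, G=3, T=4
by default, configurable) and filled row-major into a ``d x d`` matrix with
``d = ceil(sqrt(z))``, zero-padded at the tail.  Three families of 2-D
moments up to combined degree 3 are computed from such matrices:

* raw moments  ``M_jk = sum_a sum_b a^j b^k f(a, b)`` with 1-based grid
  indices, so the centroid ``(M10/M00, M01/M00)`` is meaningful;
* central moments, the same sums about the centroid;
* Hahn moments, the projection onto discrete orthogonal Hahn polynomials
  ``Q_m(i; x, y, N-1)`` weighted so that basis rows are orthonormal under
  plain summation.  The complete basis makes the transform an isometry, so
  the original grid is recoverable from its full Hahn spectrum.

Each family contributes the ten moments of order (j + k) <= 3 in the fixed
order (00, 01, 10, 11, 02, 20, 12, 21, 30, 03).

The Hahn polynomial is evaluated as a terminating hypergeometric sum with
multiplicative term updates, and its classical weight
``C(x+i, i) * C(y+N-1-i, N-1-i)`` in log-Gamma space, so that the 64-point
basis needed for the trinucleotide incidence matrices neither overflows nor
loses orthogonality.  The square norm ``k2_m`` is accumulated numerically
(``sum_i h_m(i)^2 rho(i)``) rather than from a closed form, which makes
orthonormality of the weighted rows exact by construction up to rounding.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .sequence_io import NucleotideSequence

logger = logging.getLogger(__name__)

#: Default nucleotide -> integer encoding, alphabetical order.
DEFAULT_ENCODING: dict[str, int] = {"A": 1, "C": 2, "G": 3, "T": 4}

#: Fixed serialization order of the ten degree-<=3 moment indices (j, k).
MOMENT_INDEX_ORDER: tuple[tuple[int, int], ...] = (
    (0, 0), (0, 1), (1, 0), (1, 1), (0, 2),
    (2, 0), (1, 2), (2, 1), (3, 0), (0, 3),
)

MAX_DEGREE = 3


class NumericStabilityError(ArithmeticError):
    """Raised when a polynomial or weight evaluation goes non-finite."""


@dataclass(frozen=True)
class IntegerSeries:
    """Numeric encoding of a sequence: values[k] = encoding_map[residue k]."""

    values: np.ndarray
    encoding_map: Mapping[str, int]

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class SquareMatrix:
    """A d x d grid produced by the row-major reshape (or an incidence matrix)."""

    entries: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.entries, dtype=float)
        if e.ndim != 2 or e.shape[0] != e.shape[1]:
            raise ValueError(f"expected a square 2-D grid, got shape {e.shape}")
        object.__setattr__(self, "entries", e)

    @property
    def dimension(self) -> int:
        return self.entries.shape[0]


@dataclass(frozen=True)
class MomentVector:
    """Ten moments of one kind in the fixed (00,01,10,11,02,20,12,21,30,03) order."""

    kind: str  # "raw" | "central" | "hahn"
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (10,):
            raise ValueError(f"a moment vector has exactly 10 entries, got {v.shape}")
        object.__setattr__(self, "values", v)

    def as_dict(self) -> dict[str, float]:
        return {
            f"{self.kind}_{j}{k}": float(v)
            for (j, k), v in zip(MOMENT_INDEX_ORDER, self.values)
        }


@dataclass(frozen=True)
class HahnParams:
    """Hahn polynomial parameters: shape parameters x, y >= 0 and support size N."""

    N: int
    x: float = 0.0
    y: float = 0.0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be a positive integer")
        if self.x < 0 or self.y < 0:
            raise ValueError("Hahn shape parameters must be >= 0")


@dataclass(frozen=True)
class HahnBasis:
    """Weighted Hahn polynomial values, orthonormal rows under summation.

    ``table[m, i]`` holds the weighted polynomial of degree m at grid point
    i in 0..N-1; ``norms[m]`` is the numerically accumulated square norm of
    the unweighted polynomial under the Hahn weight.
    """

    params: HahnParams
    table: np.ndarray
    norms: np.ndarray

    @property
    def max_degree(self) -> int:
        return self.table.shape[0] - 1


# ---------------------------------------------------------------------------
# encoding and reshape
# ---------------------------------------------------------------------------

def encode(
    seq: NucleotideSequence | str,
    encoding_map: Mapping[str, int] | None = None,
) -> IntegerSeries:
    """Substitute each residue by its integer code."""
    encoding_map = dict(encoding_map or DEFAULT_ENCODING)
    residues = seq.residues if isinstance(seq, NucleotideSequence) else seq.upper()
    if not residues:
        raise ValueError("cannot encode an empty sequence")
    bad = set(residues) - set(encoding_map)
    if bad:
        raise ValueError(f"residue(s) {sorted(bad)} not in encoding map")
    lut = {ord(r): v for r, v in encoding_map.items()}
    values = np.fromiter(
        (lut[ord(c)] for c in residues), dtype=np.int64, count=len(residues)
    )
    return IntegerSeries(values, encoding_map)


def reshape_to_square(series: IntegerSeries | np.ndarray) -> SquareMatrix:
    """Row-major reshape of a length-z series into a d x d matrix, d = ceil(sqrt(z)).

    Positions beyond z are zero-padded; a row-major scan truncated at z
    recovers the series exactly.
    """
    values = series.values if isinstance(series, IntegerSeries) else np.asarray(series)
    z = len(values)
    if z == 0:
        raise ValueError("cannot reshape an empty series")
    d = math.isqrt(z - 1) + 1  # ceil(sqrt(z)) without float round-off
    padded = np.zeros(d * d, dtype=float)
    padded[:z] = values
    return SquareMatrix(padded.reshape(d, d))


# ---------------------------------------------------------------------------
# raw and central moments
# ---------------------------------------------------------------------------

def _geometric_moments(entries: np.ndarray, a0: np.ndarray, b0: np.ndarray) -> np.ndarray:
    d = entries.shape[0]
    apow = np.vander(a0, MAX_DEGREE + 1, increasing=True)  # d x 4, columns a^0..a^3
    bpow = np.vander(b0, MAX_DEGREE + 1, increasing=True)
    out = np.empty(10)
    for idx, (j, k) in enumerate(MOMENT_INDEX_ORDER):
        out[idx] = apow[:, j] @ entries @ bpow[:, k]
    return out


def raw_moments(matrix: SquareMatrix) -> MomentVector:
    """Origin-referenced moments M_jk with 1-based row index a and column index b."""
    d = matrix.dimension
    idx = np.arange(1, d + 1, dtype=float)
    return MomentVector("raw", _geometric_moments(matrix.entries, idx, idx))


def central_moments(matrix: SquareMatrix) -> MomentVector:
    """Centroid-referenced moments; mu00 = M00 and mu10 = mu01 = 0 identically.

    An all-zero matrix has no centroid; it yields an all-zero vector and a
    logged warning rather than an error, so degenerate inputs do not abort
    a whole extraction run.
    """
    d = matrix.dimension
    idx = np.arange(1, d + 1, dtype=float)
    m00 = float(matrix.entries.sum())
    if m00 == 0.0:
        logger.warning("all-zero matrix: centroid undefined, central moments set to 0")
        return MomentVector("central", np.zeros(10))
    a_bar = float(idx @ matrix.entries.sum(axis=1)) / m00
    b_bar = float(matrix.entries.sum(axis=0) @ idx) / m00
    return MomentVector(
        "central", _geometric_moments(matrix.entries, idx - a_bar, idx - b_bar)
    )


def centroid(matrix: SquareMatrix) -> tuple[float, float]:
    """(a_bar, b_bar) = (M10/M00, M01/M00)."""
    m = raw_moments(matrix).as_dict()
    if m["raw_00"] == 0.0:
        raise ZeroDivisionError("centroid undefined for an all-zero matrix")
    return m["raw_10"] / m["raw_00"], m["raw_01"] / m["raw_00"]


# ---------------------------------------------------------------------------
# Hahn basis and moments
# ---------------------------------------------------------------------------

def _hahn_polynomial_row(m: int, N: int, x: float, y: float) -> np.ndarray:
    """Values of the degree-m Hahn polynomial Q_m(i; x, y, N-1) at i = 0..N-1.

    Terminating hypergeometric sum 3F2(-m, m+x+y+1, -i; x+1, -(N-1); 1),
    accumulated with multiplicative term updates: every factor is O(N^2),
    so degree-3 evaluation is overflow-safe even at N = 64 and beyond.
    """
    M = N - 1
    i = np.arange(N, dtype=float)
    total = np.ones(N)
    term = np.ones(N)
    for k in range(1, m + 1):
        # (-m+k-1), (m+x+y+k), (-i+k-1) / ((x+k), (-M+k-1), k)
        term = term * ((-m + k - 1) * (m + x + y + k) * (-i + k - 1)) / (
            (x + k) * (-M + k - 1) * k
        )
        total = total + term
    return total


def _hahn_weight(N: int, x: float, y: float) -> np.ndarray:
    """Classical Hahn weight C(x+i, i) * C(y+N-1-i, N-1-i), log-Gamma safe."""
    M = N - 1
    i = np.arange(N, dtype=float)
    log_w = (
        gammaln(x + i + 1) - gammaln(x + 1) - gammaln(i + 1)
        + gammaln(y + M - i + 1) - gammaln(y + 1) - gammaln(M - i + 1)
    )
    return np.exp(log_w)


def build_hahn_basis(params: HahnParams, max_degree: int = MAX_DEGREE) -> HahnBasis:
    """Weighted Hahn basis with numerically orthonormal rows.

    Row m holds ``h~_m(i) = Q_m(i) * sqrt(rho(i) / k2_m)`` with
    ``k2_m = sum_i Q_m(i)^2 rho(i)`` accumulated from the table itself.
    """
    N = params.N
    if max_degree >= N:
        raise ValueError(f"max_degree {max_degree} must be < N = {N}")
    raw = np.vstack(
        [_hahn_polynomial_row(m, N, params.x, params.y) for m in range(max_degree + 1)]
    )
    rho = _hahn_weight(N, params.x, params.y)
    if not (np.isfinite(raw).all() and np.isfinite(rho).all()):
        m_bad, i_bad = np.argwhere(~np.isfinite(raw * rho))[0]
        raise NumericStabilityError(
            f"non-finite Hahn evaluation at degree m={m_bad}, point i={i_bad}"
        )
    norms = (raw**2 * rho).sum(axis=1)
    table = raw * np.sqrt(rho / norms[:, None])
    return HahnBasis(params, table, norms)


def hahn_transform(matrix: SquareMatrix, basis: HahnBasis) -> np.ndarray:
    """Full Hahn spectrum T with T[u, v] = H_uv = sum_ab beta_ab h~_u(b) h~_v(a)."""
    if basis.params.N != matrix.dimension:
        raise ValueError(
            f"basis support N={basis.params.N} does not match "
            f"matrix dimension d={matrix.dimension}"
        )
    # (Phi B Phi^T)[v, u] = sum_a sum_b h~_v(a) beta_ab h~_u(b) = H_uv
    return (basis.table @ matrix.entries @ basis.table.T).T


def inverse_hahn_transform(spectrum: np.ndarray, basis: HahnBasis) -> SquareMatrix:
    """Invert a complete-basis Hahn spectrum back to the original grid."""
    if basis.max_degree != basis.params.N - 1:
        raise ValueError("inverse transform requires a complete basis (degree N-1)")
    return SquareMatrix(basis.table.T @ spectrum.T @ basis.table)


def hahn_moments(matrix: SquareMatrix, basis: HahnBasis) -> MomentVector:
    """The ten Hahn moments H_uv of combined degree u + v <= 3.

    If the basis carries fewer degrees than 3 (possible only for grids
    smaller than 4 x 4), unavailable orders are reported as 0 with a
    warning so the fixed 10-slot layout is preserved.
    """
    spectrum = hahn_transform(matrix, basis)
    deg = basis.max_degree
    out = np.zeros(10)
    clipped = False
    for idx, (u, v) in enumerate(MOMENT_INDEX_ORDER):
        if u <= deg and v <= deg:
            out[idx] = spectrum[u, v]
        else:
            clipped = True
    if clipped:
        logger.warning(
            "grid of dimension %d supports Hahn degrees <= %d; "
            "higher-order moments reported as 0",
            matrix.dimension,
            deg,
        )
    return MomentVector("hahn", out)


def moment_block(
    matrix: SquareMatrix,
    hahn_params: HahnParams | None = None,
) -> np.ndarray:
    """Concatenated raw(10) | central(10) | Hahn(10) moments of one matrix."""
    N = matrix.dimension
    if hahn_params is None:
        hahn_params = HahnParams(N=N)
    elif hahn_params.N != N:
        hahn_params = HahnParams(N=N, x=hahn_params.x, y=hahn_params.y)
    basis = build_hahn_basis(hahn_params, max_degree=min(MAX_DEGREE, N - 1))
    return np.concatenate(
        [
            raw_moments(matrix).values,
            central_moments(matrix).values,
            hahn_moments(matrix, basis).values,
        ]
    )
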