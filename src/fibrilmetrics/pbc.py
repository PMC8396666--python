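"""Triclinic periodic-cell arithmetic.

A D-banded fibril simulated as a single crystallographic unit cell is an
infinite fibril by construction: every neighbouring monomer is a periodic
image of the one molecule in the cell.  All inter-monomer geometry therefore
reduces to minimum-image arithmetic in a triclinic lattice, with the integer
lattice shift of the nearest image carrying the physical meaning
("same monomer" vs "neighbouring monomer").

Units are nm throughout; lattice vectors are Cartesian row vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

__all__ = [
    "InvalidCellError",
    "LatticeShift",
    "TriclinicCell",
    "wrap_to_cell",
    "min_image_disp",
    "min_image_disp_batch",
    "fibril_axis",
]

_VOLUME_TINY = 1e-12


class InvalidCellError(ValueError):
    """Raised for degenerate (zero/negative volume) or overly skewed cells."""


@dataclass(frozen=True, order=True)
class LatticeShift:
    """Integer lattice translation (n_a, n_b, n_c); (0,0,0) is the same image."""

    n_a: int
    n_b: int
    n_c: int

    def as_array(self) -> np.ndarray:
        return np.array([self.n_a, self.n_b, self.n_c], dtype=int)

    @property
    def is_zero(self) -> bool:
        return self.n_a == 0 and self.n_b == 0 and self.n_c == 0

    def __neg__(self) -> "LatticeShift":
        return LatticeShift(-self.n_a, -self.n_b, -self.n_c)

    def __iter__(self):
        return iter((self.n_a, self.n_b, self.n_c))


class TriclinicCell:
    """Three lattice vectors spanning a right-handed triclinic cell.

    The longest lattice vector is, for a D-banded fibril, the D-period
    (:meth:`dband_length`).  Construction validates a strictly positive
    scalar triple product.
    """

    __slots__ = ("matrix", "_inv")

    def __init__(self, a_vec, b_vec, c_vec):
        m = np.array([a_vec, b_vec, c_vec], dtype=float)
        if m.shape != (3, 3):
            raise InvalidCellError("lattice vectors must be 3-vectors")
        vol = float(np.linalg.det(m))
        if not np.isfinite(vol) or vol <= _VOLUME_TINY:
            raise InvalidCellError(
                f"cell volume must be positive (got {vol:g} nm^3); "
                "check handedness / degeneracy of the lattice vectors"
            )
        self.matrix = m
        self._inv = np.linalg.inv(m)

    # -- basic properties -------------------------------------------------
    @property
    def a_vec(self) -> np.ndarray:
        return self.matrix[0]

    @property
    def b_vec(self) -> np.ndarray:
        return self.matrix[1]

    @property
    def c_vec(self) -> np.ndarray:
        return self.matrix[2]

    def volume(self) -> float:
        return float(np.linalg.det(self.matrix))

    def lengths(self) -> np.ndarray:
        return np.linalg.norm(self.matrix, axis=1)

    def longest_axis_index(self) -> int:
        """Index of the longest lattice vector; exact ties prefer the third.

        Tie-break: among vectors within relative 1e-12 of the maximum norm,
        the highest index wins, so a cubic cell reports its c vector.
        """
        lengths = self.lengths()
        lmax = lengths.max()
        candidates = np.nonzero(lengths >= lmax * (1.0 - 1e-12))[0]
        return int(candidates.max())

    def dband_length(self) -> float:
        """Length of the longest lattice vector (the D-period), nm."""
        return float(self.lengths()[self.longest_axis_index()])

    # -- coordinate transforms -------------------------------------------
    def fractional(self, points) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self._inv

    def cartesian(self, frac) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.matrix

    def is_reduced(self, max_skew: float = 0.5) -> bool:
        """Whether off-axis projections stay within ``max_skew`` of the
        diagonal, in the spirit of the box restriction used by common MD
        engines.  Rounded-fractional minimum-image search (refined over the
        3x3x3 shift neighbourhood) is exact for such cells; extreme skew
        should be rejected at load time.
        """
        g = self.matrix @ self.matrix.T
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                # projection of vector i on vector j, in units of |v_j|
                if abs(g[i, j]) / g[j, j] > max_skew + 1e-9:
                    return False
        return True

    def __repr__(self) -> str:  # pragma: no cover
        a, b, c = self.matrix
        return f"TriclinicCell(a={a.tolist()}, b={b.tolist()}, c={c.tolist()})"


def wrap_to_cell(point, cell: TriclinicCell) -> np.ndarray:
    """Translate point(s) by integer lattice vectors so all fractional
    coordinates lie in [0, 1).  Accepts a single 3-vector or an (n, 3) array.
    Idempotent."""
    frac = cell.fractional(point)
    frac -= np.floor(frac)
    # guard against frac == 1.0 from floating-point round-off
    frac[frac >= 1.0] -= 1.0
    return cell.cartesian(frac)


# the 27 shifts of the {-1,0,1}^3 neighbourhood, lexicographically ordered
_NEIGHBOR_SHIFTS = np.array(sorted(product((-1, 0, 1), repeat=3)), dtype=int)


def min_image_disp_batch(p1, p2, cell: TriclinicCell):
    """Vectorized minimum-image displacement p2 + shift - p1.

    Parameters are (n, 3) arrays (or single 3-vectors, broadcast).  Returns
    ``(disp, shifts)`` with ``disp`` of shape (n, 3) and integer ``shifts``
    of shape (n, 3).  The shift of minimum Euclidean norm is found by
    rounding the fractional displacement and refining over the 3x3x3 shift
    neighbourhood; exact ties resolve to the lexicographically smallest
    (n_a, n_b, n_c).
    """
    p1 = np.atleast_2d(np.asarray(p1, dtype=float))
    p2 = np.atleast_2d(np.asarray(p2, dtype=float))
    p1, p2 = np.broadcast_arrays(p1, p2)
    frac = (p2 - p1) @ cell._inv
    base = -np.round(frac)  # (n, 3)
    # candidate shifts: base + each of the 27 neighbour offsets
    cand = base[:, None, :] + _NEIGHBOR_SHIFTS[None, :, :]  # (n, 27, 3)
    disp = (frac[:, None, :] + cand) @ cell.matrix  # (n, 27, 3)
    norm2 = np.einsum("ijk,ijk->ij", disp, disp)
    # lexicographic tie-break: _NEIGHBOR_SHIFTS is lex-sorted and `base` is
    # common to all candidates, so the first index attaining the minimum
    # (within tolerance) is the lex-smallest total shift.
    nmin = norm2.min(axis=1, keepdims=True)
    tol = 1e-12 * (1.0 + nmin)
    best = np.argmax(norm2 <= nmin + tol, axis=1)
    rows = np.arange(len(best))
    return disp[rows, best], cand[rows, best].astype(int)


def min_image_disp(p1, p2, cell: TriclinicCell):
    """Minimum-image displacement from p1 to p2 and the achieving shift.

    Returns ``(disp, LatticeShift)`` where ``disp = p2 + shift @ M - p1``
    has minimum Euclidean norm over integer lattice shifts.
    """
    disp, shift = min_image_disp_batch(p1, p2, cell)
    return disp[0], LatticeShift(*(int(x) for x in shift[0]))


def fibril_axis(cell: TriclinicCell) -> np.ndarray:
    """Unit vector along the longest lattice vector (the fibril axis).

    Ties between equal-norm vectors prefer the third lattice vector.
    """
    v = cell.matrix[cell.longest_axis_index()]
    return v / np.linalg.norm(v)
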