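"""Periodic simulation cells and minimum-image geometry.

A :class:`BoxSpec` holds the three lattice vectors of a periodic cell
(rows of a 3x3 matrix, in angstroms) together with a shape tag.  The
truncated octahedron — the cell used for solvated small-molecule MD —
is represented as the equivalent triclinic cell with a = b = c and
alpha = beta = gamma = arccos(-1/3) ~ 109.4712 deg, whose volume is
a^3 * sqrt(16/27).

All distance math goes through the minimum-image convention.  For
skewed cells, rounding fractional coordinates alone can select a
periodic image that is not the nearest one, so the displacement search
scans the 27 images surrounding the rounded candidate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BoxSpec",
    "TRUNCATED_OCTAHEDRON_ANGLE",
    "box_volume",
    "minimum_image_displacement",
    "minimum_image_distance",
    "wrap_coordinates",
]

#: Cell angle (degrees) of the truncated-octahedron triclinic cell,
#: arccos(-1/3).
TRUNCATED_OCTAHEDRON_ANGLE = math.degrees(math.acos(-1.0 / 3.0))

# all 27 integer lattice shifts, shape (27, 3)
_SHIFTS = np.array(
    [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)],
    dtype=float,
)


class DegenerateBoxError(ValueError):
    """The lattice vectors do not span a positive volume."""


@dataclass(frozen=True)
class BoxSpec:
    """A periodic cell defined by three lattice vectors (rows, angstrom)."""

    vectors: np.ndarray
    shape: str = "triclinic"

    _inverse: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        vectors = np.asarray(self.vectors, dtype=float)
        if vectors.shape != (3, 3):
            raise ValueError(f"lattice vectors must be 3x3, got {vectors.shape}")
        volume = abs(np.linalg.det(vectors))
        if volume <= 1e-9:
            raise DegenerateBoxError(
                "lattice vectors are degenerate (coplanar or zero); "
                f"volume = {volume:g} A^3"
            )
        object.__setattr__(self, "vectors", vectors)
        object.__setattr__(self, "_inverse", np.linalg.inv(vectors))

    # ---- constructors -------------------------------------------------

    @classmethod
    def cubic(cls, length: float) -> "BoxSpec":
        """Cubic cell of edge ``length`` angstrom."""
        return cls(np.eye(3) * float(length), shape="cubic")

    @classmethod
    def orthorhombic(cls, a: float, b: float, c: float) -> "BoxSpec":
        return cls(np.diag([float(a), float(b), float(c)]), shape="orthorhombic")

    @classmethod
    def truncated_octahedron(cls, a: float) -> "BoxSpec":
        """Truncated-octahedron cell with lattice parameter ``a`` angstrom."""
        ang = TRUNCATED_OCTAHEDRON_ANGLE
        return cls(
            lattice_vectors_from_parameters(a, a, a, ang, ang, ang),
            shape="truncated_octahedron",
        )

    @classmethod
    def from_parameters(
        cls, a: float, b: float, c: float, alpha: float, beta: float, gamma: float
    ) -> "BoxSpec":
        """Build from cell lengths (angstrom) and angles (degrees)."""
        return cls(lattice_vectors_from_parameters(a, b, c, alpha, beta, gamma))

    # ---- properties ---------------------------------------------------

    @property
    def volume(self) -> float:
        """Cell volume in cubic angstroms (scalar triple product)."""
        return float(abs(np.linalg.det(self.vectors)))

    @property
    def lengths(self) -> np.ndarray:
        """Lengths of the three lattice vectors, angstrom."""
        return np.linalg.norm(self.vectors, axis=1)

    def to_mdanalysis(self) -> np.ndarray:
        """``[lx, ly, lz, alpha, beta, gamma]`` as MDAnalysis expects."""
        a, b, c = self.vectors
        la, lb, lc = self.lengths

        def _angle(u, v):
            return math.degrees(
                math.acos(np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1))
            )

        return np.array(
            [la, lb, lc, _angle(b, c), _angle(a, c), _angle(a, b)], dtype=np.float32
        )


def lattice_vectors_from_parameters(
    a: float, b: float, c: float, alpha: float, beta: float, gamma: float
) -> np.ndarray:
    """Lattice-vector matrix (rows) from lengths (A) and angles (deg).

    Uses the crystallographic convention: **a** along x, **b** in the
    xy-plane.
    """
    al, be, ga = (math.radians(x) for x in (alpha, beta, gamma))
    cos_al, cos_be, cos_ga = math.cos(al), math.cos(be), math.cos(ga)
    sin_ga = math.sin(ga)
    v1 = [a, 0.0, 0.0]
    v2 = [b * cos_ga, b * sin_ga, 0.0]
    cx = c * cos_be
    cy = c * (cos_al - cos_be * cos_ga) / sin_ga
    cz_sq = c * c - cx * cx - cy * cy
    if cz_sq <= 0:
        raise DegenerateBoxError("cell angles do not define a 3D cell")
    v3 = [cx, cy, math.sqrt(cz_sq)]
    return np.array([v1, v2, v3], dtype=float)


def box_volume(box: BoxSpec) -> float:
    """Volume of the periodic cell, cubic angstrom."""
    return box.volume


def wrap_coordinates(box: BoxSpec, coords: np.ndarray) -> np.ndarray:
    """Wrap Cartesian coordinates into the primary cell [0, 1)^3 (fractional)."""
    frac = np.asarray(coords, float) @ box._inverse
    frac -= np.floor(frac)
    return frac @ box.vectors


def minimum_image_displacement(
    box: BoxSpec, a: np.ndarray, b: np.ndarray
) -> np.ndarray:
    """Shortest displacement ``b - a`` over all periodic images.

    Accepts single points or matching arrays of points (broadcast on the
    leading axes).  The rounded fractional displacement is refined by an
    explicit scan of the 27 surrounding images, which is exact for any
    cell in which the nearest image lies within one lattice shift of the
    rounded candidate (true for all physically sensible cells, including
    the truncated octahedron).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    d = b - a
    single = d.ndim == 1
    d = np.atleast_2d(d)

    frac = d @ box._inverse
    frac -= np.round(frac)
    base = frac @ box.vectors  # (n, 3) rounded-image candidate

    # candidate displacements over 27 neighbouring images: (n, 27, 3)
    cand = base[:, None, :] + (_SHIFTS @ box.vectors)[None, :, :]
    best = np.argmin(np.einsum("nij,nij->ni", cand, cand), axis=1)
    out = cand[np.arange(len(cand)), best]
    return out[0] if single else out


def minimum_image_distance(box: BoxSpec, a: np.ndarray, b: np.ndarray) -> float:
    """Minimum-image distance between two points, angstrom."""
    return float(np.linalg.norm(minimum_image_displacement(box, a, b)))
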