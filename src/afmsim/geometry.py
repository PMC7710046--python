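"""Rigid-body orientation, stage placement and scanning-grid construction.

The molecule is rotated about its centroid, dropped onto the virtual stage
plane z = 0 (so the lowest VdW sphere touches the plane and the tip
approaches from +z), and a square scanning lattice is laid over its
footprint.  The lattice is registered so that one cell centre coincides with
the centroid's lateral position, which makes maps reproducible under
rotations and step refinement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation as _Rotation

from .exceptions import ValidationError
from .structure_io import Structure

__all__ = ["Orientation", "ScanGrid", "orient", "stage", "build_grid"]

_ORTHONORMALITY_TOL = 1e-9


@dataclass(frozen=True)
class Orientation:
    """A proper rotation (orthonormal 3x3 matrix, det +1)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValidationError(f"rotation matrix must be 3x3, got {m.shape}")
        if not np.allclose(m @ m.T, np.eye(3), atol=_ORTHONORMALITY_TOL):
            raise ValidationError("rotation matrix is not orthonormal")
        if not math.isclose(float(np.linalg.det(m)), 1.0, abs_tol=1e-9):
            raise ValidationError("rotation matrix determinant is not +1")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "Orientation":
        return cls(np.eye(3))

    @classmethod
    def from_euler_zyz(cls, a: float, b: float, c: float) -> "Orientation":
        """Intrinsic Z-Y-Z Euler angles in degrees."""
        return cls(_Rotation.from_euler("ZYZ", [a, b, c], degrees=True).as_matrix())

    @classmethod
    def about_z(cls, degrees: float) -> "Orientation":
        return cls(_Rotation.from_euler("z", degrees, degrees=True).as_matrix())

    def compose(self, other: "Orientation") -> "Orientation":
        """Rotation equivalent to applying ``other`` first, then ``self``."""
        return Orientation(self.matrix @ other.matrix)


@dataclass(frozen=True)
class ScanGrid:
    """Square lattice of tip positions: cell centres at (x0 + i*a, y0 + j*a)."""

    origin: tuple
    step: float
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if not (self.step > 0):
            raise ValidationError(f"grid step must be positive, got {self.step}")
        if self.nx < 1 or self.ny < 1:
            raise ValidationError("grid must have at least one cell per axis")
        object.__setattr__(self, "origin", (float(self.origin[0]), float(self.origin[1])))

    @property
    def x_centers(self) -> np.ndarray:
        return self.origin[0] + self.step * np.arange(self.nx)

    @property
    def y_centers(self) -> np.ndarray:
        return self.origin[1] + self.step * np.arange(self.ny)


def orient(structure: Structure, orientation: Orientation) -> Structure:
    """Rotate atom positions about the structure centroid; radii and atom
    order are untouched."""
    coords = structure.coords
    centroid = coords.mean(axis=0)
    rotated = (coords - centroid) @ orientation.matrix.T + centroid
    return structure.with_coords(rotated)


def stage(structure: Structure) -> Structure:
    """Translate along z so the lowest VdW sphere rests on the plane z = 0."""
    coords = structure.coords
    dz = -float(np.min(coords[:, 2] - structure.radii))
    shifted = coords.copy()
    shifted[:, 2] += dz
    return structure.with_coords(shifted)


def _snapped_axis(lower: float, upper: float, center: float, step: float):
    """Origin on the lattice through ``center`` covering [lower, upper]."""
    k = math.ceil((center - lower) / step - 1e-12)
    origin = center - k * step
    n = int(math.floor((upper - origin) / step + 1e-12)) + 1
    return origin, max(n, 1)


def build_grid(
    structure: Structure,
    step: float,
    margin: float = 2.0,
    *,
    bounds: Optional[Sequence[float]] = None,
) -> ScanGrid:
    """Scanning grid covering the structure's VdW footprint plus a margin.

    The grid spans ``[min(x_i - r_i) - margin, max(x_i + r_i) + margin]``
    (likewise in y) and is registered so a cell centre lies at the centroid's
    lateral position.  ``bounds`` = (xmin, xmax, ymin, ymax) overrides the
    computed span (used for shared trajectory grids) but keeps the
    registration of this structure.
    """
    if not (step > 0):
        raise ValidationError(f"step must be positive, got {step}")
    if margin < 0:
        raise ValidationError(f"margin must be non-negative, got {margin}")
    coords = structure.coords
    radii = structure.radii
    cx, cy = coords[:, 0].mean(), coords[:, 1].mean()
    if bounds is None:
        x_lo = float(np.min(coords[:, 0] - radii)) - margin
        x_hi = float(np.max(coords[:, 0] + radii)) + margin
        y_lo = float(np.min(coords[:, 1] - radii)) - margin
        y_hi = float(np.max(coords[:, 1] + radii)) + margin
    else:
        x_lo, x_hi, y_lo, y_hi = (float(b) for b in bounds)
    x0, nx = _snapped_axis(x_lo, x_hi, cx, step)
    y0, ny = _snapped_axis(y_lo, y_hi, cy, step)
    return ScanGrid(origin=(x0, y0), step=float(step), nx=nx, ny=ny)
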