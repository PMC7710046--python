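"""Hard-collision simulated scanning engine.

The tip is a vertical probe sphere of radius R capped by a tangent infinite
cone of half-angle alpha.  For each lattice cell the tip is lowered along the
cell axis until it first touches any atomic VdW sphere; the height of the
tip's lowest point at first contact, clamped at the stage plane z = 0, is
the cell value.

Contact with one atom (radius r, centre height z, lateral offset d from the
tip axis) has a two-branch closed form:

* sphere branch, ``d <= (R + r) cos(alpha)``::

      h = z - R + sqrt((R + r)^2 - d^2)

* cone branch, ``d > (R + r) cos(alpha)``::

      h = z - R + (R + r)/sin(alpha) - d * cos(alpha)/sin(alpha)

The branches agree at the tangency distance ``d = (R + r) cos(alpha)``.  The
cone flank is infinite, so every atom yields a finite (possibly negative)
contact height; negative contributions are irrelevant after the z = 0 clamp.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import IO, Mapping, Optional, Union

import numpy as np

from .exceptions import ValidationError
from .geometry import ScanGrid
from .structure_io import Structure

__all__ = [
    "TipModel",
    "HeightMap",
    "collision_height",
    "scan",
    "save_heightmap",
    "load_heightmap",
]


@dataclass(frozen=True)
class TipModel:
    """Tip geometry: probe-sphere radius (nm) and cone half-angle (radians)."""

    radius: float
    half_angle: float

    def __post_init__(self) -> None:
        if not (self.radius > 0):
            raise ValidationError(f"probe radius must be positive, got {self.radius}")
        if not (0 < self.half_angle < math.pi / 2):
            raise ValidationError(
                f"cone half-angle must lie in (0, pi/2) rad, got {self.half_angle}"
            )

    @classmethod
    def from_degrees(cls, radius: float, half_angle_deg: float) -> "TipModel":
        return cls(radius=radius, half_angle=math.radians(half_angle_deg))

    @property
    def half_angle_degrees(self) -> float:
        return math.degrees(self.half_angle)


@dataclass
class HeightMap:
    """Stage-relative tip heights (nm) on a scanning grid.

    ``heights[j, i]`` is the value at lateral position
    ``(x0 + i*a, y0 + j*a)``; row index j runs along +y.
    """

    grid: ScanGrid
    heights: np.ndarray
    metadata: Optional[Mapping[str, str]] = None

    def __post_init__(self) -> None:
        h = np.asarray(self.heights, dtype=float)
        if h.shape != (self.grid.ny, self.grid.nx):
            raise ValidationError(
                f"heights shape {h.shape} does not match grid ({self.grid.ny}, {self.grid.nx})"
            )
        if not np.all(np.isfinite(h)):
            raise ValidationError("heights must be finite")
        self.heights = h


def collision_height(tip: TipModel, atom_z, atom_r, d):
    """First-contact height of the tip's lowest point over one atom.

    Vectorized over any mix of array arguments (NumPy broadcasting).  Heights
    are in the same z frame as ``atom_z`` and may be negative (the cone is
    infinite); no stage clamp is applied here.
    """
    atom_r = np.asarray(atom_r, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(atom_r <= 0):
        raise ValidationError("atom radius must be positive")
    if np.any(d < 0):
        raise ValidationError("lateral distance must be non-negative")
    R = tip.radius
    sin_a = math.sin(tip.half_angle)
    cos_a = math.cos(tip.half_angle)
    rr = R + atom_r
    d_tangent = rr * cos_a
    sphere = atom_z - R + np.sqrt(np.maximum(rr * rr - d * d, 0.0))
    cone = atom_z - R + rr / sin_a - d * (cos_a / sin_a)
    return np.where(d <= d_tangent, sphere, cone)


def _cone_zero_reach(tip: TipModel, atom_z: float, atom_r: float) -> float:
    """Lateral distance beyond which the contact height drops below 0."""
    sin_a = math.sin(tip.half_angle)
    cos_a = math.cos(tip.half_angle)
    return (atom_z - tip.radius + (tip.radius + atom_r) / sin_a) * sin_a / cos_a


def scan(structure: Structure, tip: TipModel, grid: ScanGrid) -> HeightMap:
    """Scan a staged structure over a grid.

    ``heights[j, i] = max(0, max over atoms of collision_height)`` at each
    cell centre; 0 encodes the tip resting on the stage.  The structure must
    already be staged (lowest sphere on z = 0) for heights to be
    stage-relative.
    """
    coords = structure.coords
    radii = structure.radii
    if coords.shape[0] == 0:
        raise ValidationError("cannot scan an empty structure")

    xs = grid.x_centers
    ys = grid.y_centers
    heights = np.zeros((grid.ny, grid.nx), dtype=float)

    R = tip.radius
    sin_a = math.sin(tip.half_angle)
    cos_a = math.cos(tip.half_angle)
    step = grid.step

    for (ax, ay, az), ar in zip(coords, radii):
        # contributions are <= 0 outside this lateral reach: skip those cells
        reach = _cone_zero_reach(tip, az, ar)
        if reach <= 0:
            continue
        i0 = max(0, int(math.ceil((ax - reach - grid.origin[0]) / step - 1e-12)))
        i1 = min(grid.nx, int(math.floor((ax + reach - grid.origin[0]) / step + 1e-12)) + 1)
        j0 = max(0, int(math.ceil((ay - reach - grid.origin[1]) / step - 1e-12)))
        j1 = min(grid.ny, int(math.floor((ay + reach - grid.origin[1]) / step + 1e-12)) + 1)
        if i0 >= i1 or j0 >= j1:
            continue
        dx = xs[i0:i1] - ax
        dy = ys[j0:j1] - ay
        d = np.sqrt(dx[None, :] ** 2 + dy[:, None] ** 2)
        rr = R + ar
        h = np.where(
            d <= rr * cos_a,
            az - R + np.sqrt(np.maximum(rr * rr - d * d, 0.0)),
            az - R + rr / sin_a - d * (cos_a / sin_a),
        )
        block = heights[j0:j1, i0:i1]
        np.maximum(block, h, out=block)

    return HeightMap(grid=grid, heights=heights)


# --- plain-text matrix export ------------------------------------------------
#
# '#'-prefixed header lines carry the grid geometry, tip parameters and any
# run configuration; data rows are tab-separated with full float precision
# (repr), so save -> load round-trips bit-exactly.


def save_heightmap(
    hmap: HeightMap,
    sink: Union[str, os.PathLike, IO[str]],
    *,
    tip: Optional[TipModel] = None,
    extra: Optional[Mapping[str, object]] = None,
) -> None:
    """Write a height map as a '#'-headed tab-separated text matrix."""
    lines = [
        "# afmsim height map v1",
        f"# nx\t{hmap.grid.nx}",
        f"# ny\t{hmap.grid.ny}",
        f"# step_nm\t{hmap.grid.step!r}",
        f"# origin_x_nm\t{hmap.grid.origin[0]!r}",
        f"# origin_y_nm\t{hmap.grid.origin[1]!r}",
    ]
    if tip is not None:
        lines.append(f"# tip_radius_nm\t{tip.radius!r}")
        lines.append(f"# tip_half_angle_deg\t{tip.half_angle_degrees!r}")
    merged = dict(hmap.metadata or {})
    if extra:
        merged.update({str(k): v for k, v in extra.items()})
    for key, value in merged.items():
        lines.append(f"# {key}\t{value}")
    for row in hmap.heights:
        lines.append("\t".join(repr(float(v)) for v in row))
    text = "\n".join(lines) + "\n"
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        with open(sink, "w") as fh:
            fh.write(text)


def load_heightmap(source: Union[str, os.PathLike, IO[str]]) -> HeightMap:
    """Read a height map written by :func:`save_heightmap` (bit-exact)."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r") as fh:
            text = fh.read()
    header: dict = {}
    rows = []
    for line in text.splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "\t" in body:
                key, _, value = body.partition("\t")
                header[key.strip()] = value.strip()
            continue
        rows.append([float(tok) for tok in line.split("\t")])
    if not rows:
        raise ValidationError("no data rows in height-map text")
    heights = np.array(rows, dtype=float)
    try:
        grid = ScanGrid(
            origin=(float(header["origin_x_nm"]), float(header["origin_y_nm"])),
            step=float(header["step_nm"]),
            nx=int(header["nx"]),
            ny=int(header["ny"]),
        )
    except KeyError as exc:
        raise ValidationError(f"missing height-map header field: {exc}") from exc
    return HeightMap(grid=grid, heights=heights, metadata=header)
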