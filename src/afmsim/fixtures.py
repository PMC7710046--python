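"""Synthetic structure generator.

Emits small structures with exactly known geometry (single atom, dimer,
chain, helix, ring) so every pipeline stage is testable without downloading
anything.  The ring fixture mimics a homo-oligomeric ring complex at
pseudo-atom scale; its multi-frame "opening" variant tilts each subunit arm
outward by a linearly interpolated angle, lowering and widening the ring —
the cavity-opening motion resolvable in simulated AFM movies.

All fixtures use real element symbols so the radius table is exercised;
``sphere_radius`` overrides the tabulated VdW radius for coarse pseudo-domain
mocks (the override does not survive a PDB round-trip, where radii are
re-assigned from the element).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .structure_io import Atom, Structure, Trajectory, element_radius

__all__ = ["FixtureSpec", "make_fixture", "fixture_remarks"]

_KINDS = ("single_atom", "dimer", "chain", "helix", "ring")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic structure.

    kind:
        One of ``single_atom``, ``dimer``, ``chain``, ``helix``, ``ring``.
    n:
        Atom count (chain/helix) or subunit count (ring).
    element:
        Element symbol used for every atom.
    sphere_radius:
        Optional explicit VdW radius (nm) overriding the element table.
    spacing:
        Centre-to-centre distance for dimer/chain atoms (nm).
    helix_radius, pitch, atoms_per_turn:
        Parametric helix: atom k sits at angle 2*pi*k/atoms_per_turn and
        height pitch*k/atoms_per_turn.
    ring_radius:
        Circle radius of ring subunit bases (nm).
    arm_length:
        Length of each ring subunit's arm (nm); the pseudo-atom sits at the
        arm tip.
    frames, tilt_degrees:
        Ring opening trajectory: the arm tilt is interpolated linearly from
        tilt_degrees[0] (frame 0) to tilt_degrees[1] (last frame).
    jitter, seed:
        Optional uniform coordinate jitter of amplitude ``jitter`` nm, seeded.
    """

    kind: str
    n: int = 7
    element: str = "C"
    sphere_radius: Optional[float] = None
    spacing: float = 0.4
    helix_radius: float = 0.5
    pitch: float = 0.55
    atoms_per_turn: int = 10
    ring_radius: float = 2.0
    arm_length: float = 1.0
    frames: int = 1
    tilt_degrees: Tuple[float, float] = (0.0, 40.0)
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; choose from {_KINDS}")
        if self.n < 1 or self.frames < 1:
            raise ValueError("n and frames must be positive")
        for name in ("spacing", "helix_radius", "pitch", "ring_radius", "arm_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sphere_radius is not None and self.sphere_radius <= 0:
            raise ValueError("sphere_radius must be positive")
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")


def fixture_remarks(spec: FixtureSpec) -> list:
    """REMARK lines recording the fixture parameters (incl. seed)."""
    return [f"afmsim fixture kind={spec.kind} n={spec.n} seed={spec.seed}", f"spec {spec!r}"]


def _radius(spec: FixtureSpec) -> float:
    if spec.sphere_radius is not None:
        return spec.sphere_radius
    return element_radius(spec.element)


def _structure(spec: FixtureSpec, coords: np.ndarray, label: str) -> Structure:
    r = _radius(spec)
    atoms = [
        Atom(element=spec.element, position=c, vdw_radius=r, serial=i + 1)
        for i, c in enumerate(coords)
    ]
    return Structure(atoms=atoms, label=label)


def _ring_coords(spec: FixtureSpec, tilt_rad: float) -> np.ndarray:
    """Subunit pseudo-atoms at the tips of arms hinged on the base circle.

    Closed (tilt 0): arms point straight up, atoms at radius ring_radius and
    height arm_length.  Opening: each arm tilts outward in its radial plane,
    moving the atom outward by arm*sin(tilt) and down by arm*(1-cos(tilt)).
    """
    angles = 2.0 * math.pi * np.arange(spec.n) / spec.n
    radial = spec.ring_radius + spec.arm_length * math.sin(tilt_rad)
    z = spec.arm_length * math.cos(tilt_rad)
    return np.column_stack(
        [radial * np.cos(angles), radial * np.sin(angles), np.full(spec.n, z)]
    )


def make_fixture(spec: FixtureSpec) -> Trajectory:
    """Build the synthetic trajectory described by ``spec``.

    Deterministic for a given spec and seed.  Single-frame kinds return a
    1-frame trajectory; the ring kind returns ``spec.frames`` frames
    interpolating the arm tilt linearly between ``spec.tilt_degrees``.
    """
    rng = np.random.default_rng(spec.seed)

    if spec.kind == "single_atom":
        frames_coords = [np.zeros((1, 3))]
    elif spec.kind == "dimer":
        frames_coords = [np.array([[0.0, 0.0, 0.0], [spec.spacing, 0.0, 0.0]])]
    elif spec.kind == "chain":
        xs = spec.spacing * np.arange(spec.n)
        frames_coords = [np.column_stack([xs, np.zeros(spec.n), np.zeros(spec.n)])]
    elif spec.kind == "helix":
        k = np.arange(spec.n)
        theta = 2.0 * math.pi * k / spec.atoms_per_turn
        frames_coords = [
            np.column_stack(
                [
                    spec.helix_radius * np.cos(theta),
                    spec.helix_radius * np.sin(theta),
                    spec.pitch * k / spec.atoms_per_turn,
                ]
            )
        ]
    else:  # ring
        if spec.frames == 1:
            tilts = [math.radians(spec.tilt_degrees[0])]
        else:
            tilts = [
                math.radians(
                    spec.tilt_degrees[0]
                    + (spec.tilt_degrees[1] - spec.tilt_degrees[0]) * t / (spec.frames - 1)
                )
                for t in range(spec.frames)
            ]
        frames_coords = [_ring_coords(spec, tilt) for tilt in tilts]

    if spec.jitter > 0:
        frames_coords = [
            c + rng.uniform(-spec.jitter, spec.jitter, size=c.shape) for c in frames_coords
        ]

    label = f"fixture:{spec.kind} seed={spec.seed}"
    frames = [
        _structure(spec, coords, f"{label} frame={k}")
        for k, coords in enumerate(frames_coords)
    ]
    return Trajectory(frames=frames)
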