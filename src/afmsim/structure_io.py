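"""PDB structure and trajectory input/output.

Reads fixed-column PDB text (ATOM / HETATM / MODEL / ENDMDL records; all
other records are ignored), converts coordinates from Angstrom to nanometre,
and assigns per-atom hard-sphere (Van der Waals) radii from a configurable
element table.  A minimal writer emits standards-conformant ATOM records so
synthetic fixtures round-trip losslessly to column precision.

Internal length unit is nanometre throughout.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .exceptions import (
    CoordinateOverflowError,
    PDBParseError,
    TrajectoryConsistencyError,
    UnknownElementError,
)

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "BONDI_RADII_NM",
    "element_radius",
    "parse_pdb",
    "write_fixture_pdb",
    "load_radius_overrides",
]

#: Van der Waals radii in nanometre, Bondi (1964) main-group values plus a
#: handful of metals commonly found in deposited structures.  The table is a
#: plain mapping so callers can copy and override entries.
BONDI_RADII_NM: Mapping[str, float] = {
    "H": 0.120,
    "He": 0.140,
    "Li": 0.182,
    "B": 0.192,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "F": 0.147,
    "Ne": 0.154,
    "Na": 0.227,
    "Mg": 0.173,
    "Al": 0.184,
    "Si": 0.210,
    "P": 0.180,
    "S": 0.180,
    "Cl": 0.175,
    "Ar": 0.188,
    "K": 0.275,
    "Ca": 0.231,
    "Mn": 0.205,
    "Fe": 0.204,
    "Co": 0.200,
    "Ni": 0.163,
    "Cu": 0.140,
    "Zn": 0.139,
    "As": 0.185,
    "Se": 0.190,
    "Br": 0.185,
    "Kr": 0.202,
    "I": 0.198,
    "Xe": 0.216,
}

_WATER_RESIDUES = frozenset({"HOH", "WAT", "DOD", "H2O"})

_ANGSTROM_PER_NM = 10.0


@dataclass(frozen=True)
class Atom:
    """A hard sphere: element symbol, centre position (nm) and VdW radius (nm)."""

    element: str
    position: np.ndarray
    vdw_radius: float
    serial: int = 0

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValueError(f"position must be a 3-vector, got shape {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise ValueError("position components must be finite")
        if not (self.vdw_radius > 0):
            raise ValueError(f"vdw_radius must be positive, got {self.vdw_radius}")
        object.__setattr__(self, "position", pos)

    def moved_to(self, position: np.ndarray) -> "Atom":
        return replace(self, position=np.asarray(position, dtype=float))


@dataclass
class Structure:
    """An ordered collection of atoms, e.g. one PDB MODEL."""

    atoms: Sequence[Atom]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise ValueError("a Structure needs at least one atom")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) array of atom centres in nm."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        """(n,) array of VdW radii in nm."""
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list:
        return [a.element for a in self.atoms]

    def with_coords(self, coords: np.ndarray, label: Optional[str] = None) -> "Structure":
        """Copy of the structure with replaced coordinates (radii, order kept)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [a.moved_to(c) for a, c in zip(self.atoms, coords)]
        return Structure(atoms=atoms, label=self.label if label is None else label)


@dataclass
class Trajectory:
    """Ordered frames with identical atom count and element sequence."""

    frames: Sequence[Structure]

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise TrajectoryConsistencyError("a Trajectory needs at least one frame")
        first = self.frames[0]
        for k, frame in enumerate(self.frames):
            if len(frame) != len(first):
                raise TrajectoryConsistencyError(
                    f"frame {k} has {len(frame)} atoms, frame 0 has {len(first)}"
                )
            if frame.elements != first.elements:
                raise TrajectoryConsistencyError(
                    f"frame {k} element sequence differs from frame 0"
                )

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, k: int) -> Structure:
        return self.frames[k]


def element_radius(
    element: str,
    table: Optional[Mapping[str, float]] = None,
    default: Optional[float] = None,
) -> float:
    """VdW radius (nm) for an element symbol.

    Parameters
    ----------
    element:
        Chemical element symbol, case-insensitive (``"C"``, ``"Fe"``, ...).
    table:
        Radius table to use instead of :data:`BONDI_RADII_NM`.
    default:
        Fallback radius for symbols absent from the table.  When ``None``
        (the default) an unknown symbol raises :class:`UnknownElementError`.
    """
    table = BONDI_RADII_NM if table is None else table
    key = element.strip().capitalize()
    if key in table:
        r = float(table[key])
    elif default is not None:
        r = float(default)
    else:
        raise UnknownElementError(f"no VdW radius configured for element {element!r}")
    if not r > 0:
        raise ValueError(f"radius for {element!r} must be positive, got {r}")
    return r


def load_radius_overrides(source: Union[str, os.PathLike, IO[str]]) -> dict:
    """Read an override radius table: lines of ``SYMBOL  radius_nm``.

    Blank lines and lines starting with ``#`` are skipped.  Returns a dict
    merging the overrides onto the Bondi table.
    """
    close = False
    if hasattr(source, "read"):
        fh = source
    else:
        fh = open(source, "r")
        close = True
    try:
        table = dict(BONDI_RADII_NM)
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"malformed radius override line: {line!r}")
            table[parts[0].capitalize()] = float(parts[1])
        return table
    finally:
        if close:
            fh.close()


def _infer_element(name_field: str, left_packed: bool) -> str:
    """Guess the element from the atom-name columns (13-16).

    Two-letter symbols (FE, ZN, ...) are left-packed into column 13; regular
    one-letter organic atoms start in column 14.  Digits and primes are
    stripped before matching.
    """
    cleaned = "".join(ch for ch in name_field if ch.isalpha())
    if not cleaned:
        return ""
    two = cleaned[:2].capitalize()
    if left_packed and len(cleaned) >= 2 and two in BONDI_RADII_NM:
        return two
    return cleaned[0].upper()


def _open_source(source) -> Iterable[str]:
    if hasattr(source, "read"):
        return source.read().splitlines()
    if isinstance(source, (str, os.PathLike)):
        text = str(source)
        if isinstance(source, str) and ("\n" in source or source.lstrip()[:6] in ("ATOM  ", "HETATM", "MODEL ")):
            return source.splitlines()
        with open(text, "r") as fh:
            return fh.read().splitlines()
    raise TypeError(f"cannot read PDB from {type(source)!r}")


def parse_pdb(
    source: Union[str, os.PathLike, IO[str]],
    *,
    exclude_water: bool = False,
    include_hetatm: bool = True,
    radius_table: Optional[Mapping[str, float]] = None,
    default_radius: Optional[float] = None,
) -> Trajectory:
    """Parse PDB text into a :class:`Trajectory`.

    One frame is produced per ``MODEL``/``ENDMDL`` block; a file without
    MODEL records yields exactly one frame.  Coordinates are converted from
    Angstrom to nanometre and each atom is assigned a radius via
    :func:`element_radius`.  The element is taken from columns 77-78 when
    present and otherwise inferred from the atom-name field.  Only the first
    alternate location of each atom is kept.

    Parameters
    ----------
    source:
        File path, open text handle, or a string containing PDB text.
    exclude_water:
        Skip records whose residue name is a water (HOH/WAT/DOD/H2O).
    include_hetatm:
        Scan HETATM records as well as ATOM records (default).
    radius_table, default_radius:
        Passed through to :func:`element_radius`.

    Raises
    ------
    PDBParseError
        If no ATOM/HETATM record is found.
    TrajectoryConsistencyError
        If MODEL blocks disagree in atom count or element sequence.
    UnknownElementError
        For an element missing from the table with no default configured.
    """
    lines = _open_source(source)

    frames: list = []
    current: list = []
    seen_altloc: dict = {}
    model_label = ""
    label_base = getattr(source, "name", "") if hasattr(source, "read") else (
        str(source) if isinstance(source, (str, os.PathLike)) and "\n" not in str(source) else ""
    )

    def _flush(label: str) -> None:
        nonlocal current, seen_altloc
        if current:
            frames.append(Structure(atoms=current, label=label))
        current = []
        seen_altloc = {}

    for line in lines:
        rec = line[:6]
        if rec == "MODEL ":
            _flush(model_label)
            model_label = f"{label_base} model {line[6:].strip()}".strip()
            continue
        if rec == "ENDMDL":
            _flush(model_label)
            model_label = ""
            continue
        if rec not in ("ATOM  ", "HETATM"):
            continue
        if rec == "HETATM" and not include_hetatm:
            continue

        line = line.rstrip("\n").ljust(80)
        res_name = line[17:20].strip().upper()
        if exclude_water and res_name in _WATER_RESIDUES:
            continue

        alt_loc = line[16]
        if alt_loc != " ":
            atom_key = (line[21], line[22:27], line[12:16])
            first = seen_altloc.setdefault(atom_key, alt_loc)
            if alt_loc != first:
                continue

        element = line[76:78].strip()
        if not element or not any(ch.isalpha() for ch in element):
            element = _infer_element(line[12:16], left_packed=line[12] != " ")
        element = element.capitalize()
        if not element:
            raise PDBParseError(f"cannot determine element for record: {line.rstrip()!r}")

        try:
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError as exc:
            raise PDBParseError(f"malformed coordinates in record: {line.rstrip()!r}") from exc
        try:
            serial = int(line[6:11])
        except ValueError:
            serial = len(current) + 1

        current.append(
            Atom(
                element=element,
                position=np.array([x, y, z]) / _ANGSTROM_PER_NM,
                vdw_radius=element_radius(element, table=radius_table, default=default_radius),
                serial=serial,
            )
        )

    _flush(model_label or label_base)

    if not frames:
        raise PDBParseError("no ATOM/HETATM records found in input")
    return Trajectory(frames=frames)


def _format_atom_line(atom: Atom, serial: int) -> str:
    x, y, z = np.asarray(atom.position, dtype=float) * _ANGSTROM_PER_NM
    for v in (x, y, z):
        if not (-999.999 <= v <= 9999.999):
            raise CoordinateOverflowError(
                f"coordinate {v:.3f} A does not fit the 8.3 PDB column format"
            )
    el = atom.element.strip().capitalize()
    # one-letter elements start in column 14, two-letter in column 13
    name = el.upper().ljust(3) if len(el) > 1 else (" " + el).ljust(4)[:4]
    name = name.ljust(4)[:4]
    res_seq = (serial - 1) % 9999 + 1
    return (
        f"ATOM  {serial % 100000:5d} {name} FIX A{res_seq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {el.upper():>2}"
    )


def write_fixture_pdb(
    structure: Union[Structure, Trajectory],
    sink: Optional[Union[str, os.PathLike, IO[str]]] = None,
    *,
    remarks: Sequence[str] = (),
) -> str:
    """Serialize a Structure or Trajectory to fixed-column PDB text.

    A Trajectory is written as one MODEL/ENDMDL block per frame.  Optional
    ``remarks`` become REMARK records (used to record fixture parameters).
    Returns the text; also writes it to ``sink`` when given.
    """
    frames = structure.frames if isinstance(structure, Trajectory) else [structure]
    buf = io.StringIO()
    for remark in remarks:
        buf.write(f"REMARK 999 {remark}\n")
    multi = len(frames) > 1
    for k, frame in enumerate(frames, start=1):
        if multi:
            buf.write(f"MODEL     {k:4d}\n")
        for i, atom in enumerate(frame.atoms, start=1):
            buf.write(_format_atom_line(atom, i) + "\n")
        if multi:
            buf.write("ENDMDL\n")
    buf.write("END\n")
    text = buf.getvalue()
    if sink is not None:
        if hasattr(sink, "write"):
            sink.write(text)
        else:
            with open(sink, "w") as fh:
                fh.write(text)
    return text
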