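"""Reading, writing and selecting atoms of PDB-format structures.

The pipeline operates on plain coordinate snapshots: single PDB frames or
ordered frame sets exported from a molecular-dynamics run (e.g. the 0 ns and
100 ns endpoints of a simulation). Parsing is delegated to :mod:`gemmi`;
this module applies the alternate-location policy, validates coordinate
fields, and exposes lightweight record types the rest of the pipeline
consumes.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "VDW_RADII",
    "DEFAULT_VDW_RADIUS",
    "AtomRecord",
    "Structure",
    "Trajectory",
    "ParseError",
    "SelectionError",
    "parse_pdb",
    "read_pdb",
    "write_pdb",
    "select_atoms",
    "write_table",
    "read_table",
    "vdw_radius",
]

#: Van-der-Waals radii (Å) used by every geometric computation in the
#: pipeline. Pinned in code so that surface areas, volumes and cavity
#: volumes are reproducible regardless of any external radius source.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "CU": 1.40,
    "P": 1.80,
}

#: Fallback radius (Å) for elements missing from :data:`VDW_RADII`.
DEFAULT_VDW_RADIUS: float = 1.70

#: Residue names treated as water by the geometry modules.
WATER_RESIDUES = frozenset({"HOH", "WAT", "H2O", "DOD"})


class ParseError(ValueError):
    """Raised for malformed or empty PDB input."""


class SelectionError(ValueError):
    """Raised for an unparseable atom-selection expression."""


def vdw_radius(element: str) -> float:
    """Return the pinned van-der-Waals radius for an element symbol (Å)."""
    return VDW_RADII.get(element.upper(), DEFAULT_VDW_RADIUS)


@dataclass(frozen=True, slots=True)
class AtomRecord:
    """One atom of a structure, as read from an ATOM/HETATM record."""

    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    coordinates: tuple[float, float, float]
    occupancy: float = 1.0
    alt_loc: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.coordinates)):
            raise ValueError(f"non-finite coordinates for atom {self.serial}")

    @property
    def radius(self) -> float:
        return vdw_radius(self.element)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    @property
    def is_water(self) -> bool:
        return self.residue_name.upper() in WATER_RESIDUES


@dataclass(slots=True)
class Structure:
    """An ordered collection of atoms, optionally tagged with a time label.

    ``frame_label`` carries the simulation time in ns when the structure is
    one frame of an exported trajectory (e.g. 0.0 for the post-minimization
    snapshot, 100.0 for the endpoint).
    """

    atoms: list[AtomRecord]
    identifier: str = ""
    frame_label: float | None = None

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ParseError("structure contains no atoms")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        """N×3 array of atom coordinates (Å)."""
        return np.array([a.coordinates for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    def identity_sequence(self) -> tuple[tuple[int, str, str, int], ...]:
        """Per-atom identity used to check frame compatibility."""
        return tuple(
            (a.serial, a.name, a.residue_name, a.residue_number) for a in self.atoms
        )

    def heavy_atoms(self, include_water: bool = False) -> "Structure":
        """Subset with hydrogens (and by default waters) removed.

        Geometry computations use the heavy-atom convention with
        implicit-hydrogen radii so results do not depend on whether an MD
        engine exported hydrogens.
        """
        kept = [
            a
            for a in self.atoms
            if not a.is_hydrogen and (include_water or not a.is_water)
        ]
        if not kept:
            raise ParseError("no heavy atoms after filtering")
        return Structure(kept, self.identifier, self.frame_label)

    def translated(self, shift: Sequence[float]) -> "Structure":
        dx, dy, dz = (float(v) for v in shift)
        atoms = [
            replace(a, coordinates=(a.coordinates[0] + dx,
                                    a.coordinates[1] + dy,
                                    a.coordinates[2] + dz))
            for a in self.atoms
        ]
        return Structure(atoms, self.identifier, self.frame_label)

    def transformed(self, rotation: np.ndarray, translation: Sequence[float]) -> "Structure":
        """Apply a rigid transform x -> R x + t to every atom."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        xyz = self.coordinates @ R.T + t
        atoms = [
            replace(a, coordinates=tuple(float(v) for v in row))
            for a, row in zip(self.atoms, xyz)
        ]
        return Structure(atoms, self.identifier, self.frame_label)


@dataclass(slots=True)
class Trajectory:
    """An ordered set of frames sharing one atom ordering."""

    frames: list[Structure]
    time_labels: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory needs at least one frame")
        if not self.time_labels:
            self.time_labels = [
                f.frame_label if f.frame_label is not None else float(i)
                for i, f in enumerate(self.frames)
            ]
        if len(self.time_labels) != len(self.frames):
            raise ValueError("time_labels and frames length mismatch")
        ref = self.frames[0].identity_sequence()
        for i, f in enumerate(self.frames[1:], start=1):
            if f.identity_sequence() != ref:
                raise ValueError(
                    f"frame {i} atom identity sequence differs from frame 0"
                )

    def __len__(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# PDB parsing

def _validate_coordinate_fields(text: str) -> None:
    # gemmi silently zero-fills malformed coordinates; reject them up front
    # so the caller gets the offending line number.
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        for lo, hi, label in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            fld = line[lo:hi]
            try:
                float(fld)
            except ValueError:
                raise ParseError(
                    f"line {lineno}: malformed {label} coordinate field {fld!r}"
                ) from None


def _resolve_alt_locs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per atom site: highest occupancy, ties to first."""
    best: dict[tuple, int] = {}
    for i, a in enumerate(atoms):
        if not a.alt_loc:
            continue
        key = (a.chain_id, a.residue_number, a.residue_name, a.name)
        j = best.get(key)
        if j is None or a.occupancy > atoms[j].occupancy:
            best[key] = i
    keep_idx = set(best.values())
    return [
        a
        for i, a in enumerate(atoms)
        if not a.alt_loc or i in keep_idx
    ]


def parse_pdb(text: str, identifier: str = "", frame_label: float | None = None) -> Structure:
    """Parse PDB v3.3 text into a :class:`Structure`.

    HETATM records (including metals and waters) are retained. When an atom
    site carries alternate locations, the conformer with the highest
    occupancy is kept (ties broken by file order).

    Raises
    ------
    ParseError
        For malformed coordinate fields (with the line number) or input
        containing no atoms.
    """
    _validate_coordinate_fields(text)
    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise ParseError("no models in PDB input")
    atoms: list[AtomRecord] = []
    model = st[0]
    for chain in model:
        for res in chain:
            for at in res:
                alt = at.altloc if at.altloc and at.altloc != "\x00" else ""
                atoms.append(
                    AtomRecord(
                        serial=at.serial,
                        name=at.name,
                        element=at.element.name,
                        residue_name=res.name,
                        chain_id=chain.name,
                        residue_number=res.seqid.num,
                        coordinates=(at.pos.x, at.pos.y, at.pos.z),
                        occupancy=at.occ,
                        alt_loc=alt,
                        is_hetero=res.het_flag == "H",
                    )
                )
    if not atoms:
        raise ParseError("no ATOM or HETATM records found")
    atoms = _resolve_alt_locs(atoms)
    return Structure(atoms, identifier=identifier, frame_label=frame_label)


def read_pdb(path: str | os.PathLike, frame_label: float | None = None) -> Structure:
    """Read a PDB file from disk."""
    p = Path(path)
    return parse_pdb(p.read_text(), identifier=p.stem, frame_label=frame_label)


_PDB_LINE = (
    "{record:<6s}{serial:>5d} {name:<4s}{alt:1s}{res:<3s} {chain:1s}"
    "{resnum:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
    "          {element:>2s}"
)


def _format_atom_name(name: str, element: str) -> str:
    # PDB column convention: element symbols of width 1 start in column 14.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(structure: Structure, destination: str | os.PathLike | io.TextIOBase) -> None:
    """Write a structure as fixed-column PDB v3.3 text."""
    lines = []
    for a in structure.atoms:
        record = "HETATM" if a.is_hetero else "ATOM"
        lines.append(
            _PDB_LINE.format(
                record=record,
                serial=a.serial % 100000,
                name=_format_atom_name(a.name, a.element),
                alt=a.alt_loc or " ",
                res=a.residue_name[:3],
                chain=(a.chain_id or "A")[:1],
                resnum=a.residue_number % 10000,
                x=a.coordinates[0],
                y=a.coordinates[1],
                z=a.coordinates[2],
                occ=a.occupancy,
                b=0.0,
                element=a.element.upper()[:2],
            )
        )
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if isinstance(destination, (str, os.PathLike)):
        Path(destination).write_text(text)
    else:
        destination.write(text)


# ---------------------------------------------------------------------------
# Atom selection
#
# A small conjunctive expression language covers every selection the
# pipeline needs (domain windows, metal picks, His nitrogen picks):
#
#   element = CU
#   residue_number in 19..118
#   atom_name in {ND1, NE2} and residue_name = HIS
#   chain = A and element != H

_FIELDS = {
    "element": lambda a: a.element.upper(),
    "atom_name": lambda a: a.name.upper(),
    "name": lambda a: a.name.upper(),
    "residue_name": lambda a: a.residue_name.upper(),
    "resname": lambda a: a.residue_name.upper(),
    "chain": lambda a: a.chain_id.upper(),
    "chain_id": lambda a: a.chain_id.upper(),
    "residue_number": lambda a: a.residue_number,
    "resnum": lambda a: a.residue_number,
    "serial": lambda a: a.serial,
}

_INT_FIELDS = {"residue_number", "resnum", "serial"}


def _parse_clause(clause: str):
    clause = clause.strip()
    if " in " in clause:
        fld, _, rhs = clause.partition(" in ")
        fld = fld.strip().lower()
        if fld not in _FIELDS:
            raise SelectionError(f"unknown field {fld!r}")
        rhs = rhs.strip()
        getter = _FIELDS[fld]
        if rhs.startswith("{") and rhs.endswith("}"):
            items = {v.strip().upper() for v in rhs[1:-1].split(",") if v.strip()}
            if not items:
                raise SelectionError(f"empty set in clause {clause!r}")
            if fld in _INT_FIELDS:
                ints = {int(v) for v in items}
                return lambda a: getter(a) in ints
            return lambda a: getter(a) in items
        if ".." in rhs:
            lo_s, _, hi_s = rhs.partition("..")
            try:
                lo, hi = int(lo_s), int(hi_s)
            except ValueError:
                raise SelectionError(f"bad range in clause {clause!r}") from None
            if fld not in _INT_FIELDS:
                raise SelectionError(f"range only valid for integer fields: {clause!r}")
            return lambda a: lo <= getter(a) <= hi
        raise SelectionError(f"cannot parse 'in' clause {clause!r}")
    for op in ("!=", "="):
        if op in clause:
            fld, _, rhs = clause.partition(op)
            fld = fld.strip().lower()
            rhs = rhs.strip().upper()
            if fld not in _FIELDS or not rhs:
                raise SelectionError(f"cannot parse clause {clause!r}")
            getter = _FIELDS[fld]
            val: object = int(rhs) if fld in _INT_FIELDS else rhs
            if op == "=":
                return lambda a: getter(a) == val
            return lambda a: getter(a) != val
    raise SelectionError(f"cannot parse clause {clause!r}")


def select_atoms(structure: Structure, predicate: str) -> Structure:
    """Subset a structure with a conjunctive selection expression.

    Clauses are joined with ``and``; each clause compares a field
    (``element``, ``atom_name``, ``residue_name``, ``chain``,
    ``residue_number``, ``serial``) with ``=``/``!=``, a set
    ``in {A, B}``, or an inclusive integer range ``in lo..hi``.
    The returned structure preserves input order and may be empty in the
    sense of carrying an ``atoms`` list selected lazily — an empty match
    returns a list, not a Structure, to keep the no-atom invariant intact.
    """
    if not predicate or not predicate.strip():
        raise SelectionError("empty selection expression")
    clauses = [_parse_clause(c) for c in predicate.split(" and ")]
    kept = [a for a in structure.atoms if all(c(a) for c in clauses)]
    return SelectionResult(kept, structure.identifier, structure.frame_label)


class SelectionResult(Structure):
    """A structure subset; unlike Structure it may legitimately be empty."""

    def __post_init__(self) -> None:  # empty selections allowed
        pass


# ---------------------------------------------------------------------------
# Tabular output

def write_table(
    records: Iterable,
    destination: str | os.PathLike | io.TextIOBase,
    fieldnames: Sequence[str] | None = None,
) -> None:
    """Write records as a TSV table (UTF-8, '.' decimal separator).

    Records may be dataclasses, mappings or namedtuples sharing one schema.
    ``fieldnames`` supplies the header when the record list is empty.
    Floats are rendered with Python's shortest round-trip representation so
    a read-back of the table reproduces the values exactly.
    """
    rows = []
    for r in records:
        if hasattr(r, "__dataclass_fields__"):
            rows.append({k: getattr(r, k) for k in r.__dataclass_fields__})
        elif isinstance(r, dict):
            rows.append(dict(r))
        elif hasattr(r, "_asdict"):
            rows.append(r._asdict())
        else:
            raise TypeError(f"unsupported record type {type(r).__name__}")
    if rows:
        schema = list(rows[0].keys())
        for row in rows[1:]:
            if list(row.keys()) != schema:
                raise ValueError("records do not share a field schema")
        df = pd.DataFrame(rows, columns=schema)
    elif fieldnames is not None:
        df = pd.DataFrame(columns=list(fieldnames))
    else:
        raise ValueError("empty record list requires fieldnames for the header")
    df.to_csv(destination, sep="\t", index=False)


def read_table(source: str | os.PathLike | io.TextIOBase) -> pd.DataFrame:
    """Read a TSV table written by :func:`write_table` (or hand-made)."""
    return pd.read_csv(source, sep="\t")
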