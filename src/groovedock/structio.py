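"""Atomic structures in PDB format: reading, writing, selection, constants.

Coordinates are author-numbered exactly as printed in the literature the
fragment registry comes from; nothing is renumbered on read.  Insertion codes
are rejected outright (the structures in scope never carry them, and silently
folding an icode into the residue number corrupts every downstream residue
range).  Alternate locations other than blank/'A' are skipped with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Structure",
    "HelixSegment",
    "TMTopology",
    "StructureError",
    "read_pdb",
    "write_pdb",
    "select",
    "fragment_bounds",
    "load_fragment_table",
    "FRAGMENTS",
]


class StructureError(ValueError):
    """Malformed or empty structure input."""


@dataclass(frozen=True)
class Atom:
    """One atom record: name, element, Cartesian position in Angstrom."""

    name: str
    element: str
    position: np.ndarray
    residue_number: int
    residue_name: str
    chain_id: str

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.name)


class Structure:
    """Ordered collection of atoms; iteration order is file order on read."""

    def __init__(self, atoms: Iterable[Atom], id: str = ""):
        self.atoms: list[Atom] = list(atoms)
        self.id = id
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            if a.key in seen:
                raise StructureError(f"duplicate atom {a.key}")
            seen.add(a.key)

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) array of positions in file order."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms])

    @property
    def heavy_coords(self) -> np.ndarray:
        pts = [a.position for a in self.atoms if a.is_heavy]
        return np.array(pts) if pts else np.zeros((0, 3))

    @property
    def chain_ids(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def with_coords(self, coords: np.ndarray, id: str | None = None) -> "Structure":
        """Copy with positions replaced (same atom identities and order)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise StructureError("coordinate array shape mismatch")
        atoms = [
            Atom(a.name, a.element, c, a.residue_number, a.residue_name, a.chain_id)
            for a, c in zip(self.atoms, coords)
        ]
        return Structure(atoms, id=self.id if id is None else id)

    def ca_coords(self, chain_id: str | None = None) -> np.ndarray:
        pts = [
            a.position
            for a in self.atoms
            if a.name == "CA" and (chain_id is None or a.chain_id == chain_id)
        ]
        return np.array(pts) if pts else np.zeros((0, 3))

    def __add__(self, other: "Structure") -> "Structure":
        return Structure(list(self.atoms) + list(other.atoms), id=f"{self.id}+{other.id}")

    def __repr__(self) -> str:
        return f"Structure(id={self.id!r}, n_atoms={len(self)})"


@dataclass(frozen=True)
class HelixSegment:
    """Inclusive residue range [start, end] of one helix on one chain."""

    chain_id: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment {self.label!r}: start {self.start} > end {self.end}")

    def __contains__(self, residue_number: int) -> bool:
        return self.start <= residue_number <= self.end


@dataclass(frozen=True)
class TMTopology:
    """Ordered, non-overlapping helix segments of one chain."""

    segments: tuple[HelixSegment, ...]

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        for prev, nxt in zip(segs, segs[1:]):
            if nxt.start <= prev.end:
                raise ValueError(
                    f"segments {prev.label!r} and {nxt.label!r} overlap or are out of order"
                )

    def __iter__(self):
        return iter(self.segments)

    def by_label(self, label: str) -> HelixSegment:
        for seg in self.segments:
            if seg.label == label:
                return seg
        raise KeyError(label)


def read_pdb(path: str | Path, include_hetatm: bool = False) -> Structure:
    """Read ATOM records (first model only) into a Structure.

    Altlocs other than blank/'A' are skipped with a logged warning; insertion
    codes raise; zero usable atoms raise.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    model = st[0]
    atoms: list[Atom] = []
    n_skipped_altloc = 0
    for chain in model:
        for residue in chain:
            if residue.het_flag == "H" and not include_hetatm:
                continue
            icode = residue.seqid.icode.strip()
            if icode:
                raise StructureError(
                    f"{path}: insertion code {icode!r} at {chain.name}{residue.seqid.num} "
                    "is not supported"
                )
            for atom in residue:
                if atom.altloc not in ("\x00", "", "A"):
                    n_skipped_altloc += 1
                    continue
                atoms.append(
                    Atom(
                        name=atom.name,
                        element=atom.element.name,
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        residue_number=residue.seqid.num,
                        residue_name=residue.name,
                        chain_id=chain.name,
                    )
                )
    if n_skipped_altloc:
        logger.warning("%s: skipped %d altloc atoms", path, n_skipped_altloc)
    if not atoms:
        raise StructureError(f"{path}: no ATOM records")
    return Structure(atoms, id=path.stem)


def write_pdb(s: Structure, path: str | Path) -> None:
    """Write fixed-column ATOM records (one model), 3-decimal coordinates."""
    if len(s) == 0:
        raise StructureError("refusing to write an empty structure")
    path = Path(path)
    lines = ["MODEL     1"]
    for i, a in enumerate(s.atoms, start=1):
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        x, y, z = a.position
        lines.append(
            f"ATOM  {i % 100000:5d} {name}{'':1s}{a.residue_name:>3s} "
            f"{a.chain_id:1s}{a.residue_number:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {a.element:>2s}"
        )
    lines += ["ENDMDL", "END"]
    path.write_text("\n".join(lines) + "\n")


def select(s: Structure, chain_id: str, segment: HelixSegment | None = None) -> Structure:
    """Atoms of one chain, optionally restricted to a residue range; order kept."""
    if chain_id not in s.chain_ids:
        raise KeyError(f"chain {chain_id!r} not in structure (chains: {s.chain_ids})")
    atoms = [a for a in s.atoms if a.chain_id == chain_id]
    if segment is not None:
        atoms = [a for a in atoms if a.residue_number in segment]
        if not atoms:
            raise StructureError(
                f"segment {segment.start}-{segment.end} selects no atoms on chain {chain_id!r}"
            )
    return Structure(atoms, id=s.id)


# Fragment registry: label -> (chain hint, start, end), author numbering.
# ND2 fragments follow the deletion-construct boundaries; GluN1-M4 spans the
# residues between the two CTD/M4 truncation points (stop codons at 837 / 813).
FRAGMENTS: dict[str, tuple[int, int]] = {
    "ND2-TM-6-11": (151, 347),
    "ND2-TM-10-11": (250, 347),
    "ND2-TM-6-8+loop": (151, 240),
    "ND2-TM-6-8": (151, 223),
    "ND2-TM-6-7": (151, 200),
    "ND2-TM-7-8": (175, 223),
    "GluN1-M4": (813, 836),
    "ND2-Src-anchor": (239, 321),
}


def fragment_bounds(name: str) -> tuple[int, int]:
    """Registered (start, end) residue numbers for a named fragment."""
    try:
        return FRAGMENTS[name]
    except KeyError:
        known = ", ".join(sorted(FRAGMENTS))
        raise KeyError(f"unknown fragment {name!r}; known fragments: {known}") from None


def load_fragment_table(path: str | Path) -> dict[str, HelixSegment]:
    """Load a registry from a tab-separated table: label, chain, start, end.

    Lines starting with '#' are comments.
    """
    out: dict[str, HelixSegment] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
        label, chain, start, end = parts
        out[label] = HelixSegment(chain, int(start), int(end), label=label)
    return out
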