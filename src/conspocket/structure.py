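"""PDB structure reading, atom/residue model, and protein/ligand splitting.

Parsing is backed by :mod:`gemmi`; on top of the gemmi model this module
resolves alternate locations to a single conformer, strips hydrogens and
waters, and splits the remaining heavy atoms into polymer (protein) atoms
and hetero ligand groups.  Only the first MODEL of multi-model files is
used.  Coordinates stay in the file frame; nothing is re-centered.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import gemmi
import numpy as np

from .errors import ConfigError, EmptyStructureError, FormatError, InputError

log = logging.getLogger(__name__)

WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

#: United heavy-atom van der Waals radii (Chothia 1976), in Angstrom.
RADIUS_SETS: dict[str, dict[str, float]] = {
    "chothia": {"C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85, "P": 1.90},
}
DEFAULT_RADIUS = 1.80


class ResidueKey(NamedTuple):
    """Unique residue identifier within one structure."""

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str

    @property
    def res_id(self) -> tuple[str, int, str]:
        """Identity triple used to join conservation grades (name-agnostic)."""
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclass
class Atom:
    """One heavy-atom record."""

    serial: int
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    residue_key: ResidueKey
    occupancy: float = 1.0
    altloc: str = ""
    vdw_radius: float = 0.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise FormatError(
                f"atom serial {self.serial}: coordinates must be a finite 3-vector"
            )


@dataclass
class LigandGroup:
    """One ligand instance: all atoms sharing (residue_name, chain, residue_number)."""

    key: tuple[str, str, int]
    atoms: list[Atom] = field(default_factory=list)

    @property
    def name(self) -> str:
        return self.key[0]


@dataclass
class ProteinComplex:
    """A parsed structure split into protein atoms and ligand groups."""

    protein_atoms: list[Atom]
    ligand_groups: list[LigandGroup]
    n_waters_removed: int = 0
    source_id: str = ""

    @property
    def ligand_atoms(self) -> list[Atom]:
        return [a for g in self.ligand_groups for a in g.atoms]

    def protein_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.protein_atoms], dtype=float)


def _infer_element(atom_name: str) -> str:
    """Fallback element inference from the atom name when the element
    column is blank: first alphabetic character, with standard biopolymer
    two-character names (CA = C-alpha, not calcium) resolved to one letter."""
    stripped = "".join(ch for ch in atom_name if ch.isalpha())
    if not stripped:
        return ""
    return stripped[0].upper()


def _validate_coordinate_columns(path: str) -> int:
    """Pre-scan ATOM/HETATM records; return the ATOM-record count.

    gemmi silently zeroes unparseable coordinate fields, so malformed
    x/y/z columns are caught here with the offending line number.
    """
    n_atom_records = 0
    with open(path, "r", errors="replace") as handle:
        for lineno, line in enumerate(handle, start=1):
            rec = line[:6]
            if rec not in ("ATOM  ", "HETATM"):
                continue
            if rec == "ATOM  ":
                n_atom_records += 1
            for lo, hi, label in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                fld = line[lo:hi]
                try:
                    float(fld)
                except ValueError:
                    raise FormatError(
                        f"{path}: line {lineno}: unparseable {label} "
                        f"coordinate field {fld.strip()!r}"
                    ) from None
    return n_atom_records


def _resolve_altlocs(atoms: Iterable[gemmi.Atom]) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties broken by
    lexicographically smallest altloc (so 'A' wins a 50/50 split)."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for at in atoms:
        by_name.setdefault(at.name, []).append(at)
    kept = []
    for variants in by_name.values():
        variants.sort(key=lambda a: (-a.occ, a.altloc or "~"))
        kept.append(variants[0])
    return kept


def read_pdb(
    path: str | os.PathLike,
    exclude_ligands: Iterable[str] = (),
) -> ProteinComplex:
    """Read a PDB file into a :class:`ProteinComplex`.

    ATOM records become protein atoms; non-water HETATM records become
    ligand groups keyed by (residue_name, chain, residue_number); waters
    are counted and dropped; hydrogens are dropped everywhere.  Residue
    names listed in ``exclude_ligands`` (e.g. crystallization additives
    like SO4, GOL) are dropped from the ligand list.
    """
    path = os.fspath(path)
    if not os.path.isfile(path):
        raise InputError(f"no such PDB file: {path}")
    n_atom_records = _validate_coordinate_columns(path)
    if n_atom_records == 0:
        raise EmptyStructureError(f"{path}: no ATOM records")
    try:
        st = gemmi.read_pdb(path)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no model")
    excl = {n.upper() for n in exclude_ligands}

    protein_atoms: list[Atom] = []
    groups: dict[tuple[str, str, int], LigandGroup] = {}
    n_waters = 0
    model = st[0]
    for chain in model:
        for res in chain:
            if res.name in WATER_NAMES:
                n_waters += 1
                continue
            is_het = res.het_flag == "H"
            if is_het and res.name.upper() in excl:
                continue
            for gat in _resolve_altlocs(res):
                element = gat.element.name.upper()
                if element in ("H", "D"):
                    continue
                if element in ("", "X"):
                    element = _infer_element(gat.name)
                rkey = ResidueKey(
                    chain_id=chain.name,
                    residue_number=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    residue_name=res.name,
                )
                atom = Atom(
                    serial=gat.serial,
                    name=gat.name,
                    element=element,
                    coords=np.array([gat.pos.x, gat.pos.y, gat.pos.z]),
                    residue_key=rkey,
                    occupancy=gat.occ,
                    altloc=gat.altloc or "",
                    is_hetero=is_het,
                )
                if is_het:
                    gk = (res.name, chain.name, res.seqid.num)
                    groups.setdefault(gk, LigandGroup(gk)).atoms.append(atom)
                else:
                    protein_atoms.append(atom)
    source_id = os.path.splitext(os.path.basename(path))[0]
    return ProteinComplex(
        protein_atoms=protein_atoms,
        ligand_groups=[groups[k] for k in sorted(groups)],
        n_waters_removed=n_waters,
        source_id=source_id,
    )


def assign_radii(atoms: Sequence[Atom], radius_set: str = "chothia") -> list[Atom]:
    """Set ``vdw_radius`` on every atom from a published radius table.

    Unknown elements receive a 1.80 A default and a logged warning.
    Atoms are modified in place and returned for chaining.
    """
    try:
        table = RADIUS_SETS[radius_set]
    except KeyError:
        raise ConfigError(
            f"unknown radius set {radius_set!r}; choose from {sorted(RADIUS_SETS)}"
        ) from None
    unknown: set[str] = set()
    for atom in atoms:
        r = table.get(atom.element)
        if r is None:
            unknown.add(atom.element)
            r = DEFAULT_RADIUS
        atom.vdw_radius = r
    if unknown:
        log.warning(
            "no %s radius for element(s) %s; using default %.2f A",
            radius_set, sorted(unknown), DEFAULT_RADIUS,
        )
    return list(atoms)


def _format_record(atom: Atom, record: str) -> str:
    k = atom.residue_key
    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
    return (
        f"{record:<6s}{atom.serial:>5d} {name:<4s}{'':1s}{k.residue_name:>3s} "
        f"{k.chain_id:1s}{k.residue_number:>4d}{k.insertion_code or '':1s}   "
        f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
        f"{atom.occupancy:6.2f}{0.0:6.2f}          {atom.element:>2s}\n"
    )


def write_pdb(complex_: ProteinComplex, path: str | os.PathLike) -> None:
    """Write a complex back to PDB (protein ATOM records, ligand HETATM)."""
    with open(path, "w") as out:
        for atom in complex_.protein_atoms:
            out.write(_format_record(atom, "ATOM"))
        for group in complex_.ligand_groups:
            for atom in group.atoms:
                out.write(_format_record(atom, "HETATM"))
        out.write("END\n")


def write_pocket_pdb(pockets, path: str | os.PathLike) -> None:
    """Write pocket centers as PKT pseudo-atom HETATM records.

    One record per pocket; the B-factor column carries the pocket score,
    so any molecular viewer can color centers by score.
    """
    with open(path, "w") as out:
        for i, p in enumerate(pockets, start=1):
            score = getattr(p, "score", None)
            if score is None:
                score = p.conservation_score
            out.write(
                f"HETATM{i:>5d}  PKT PKT P{i:>4d}    "
                f"{p.center[0]:8.3f}{p.center[1]:8.3f}{p.center[2]:8.3f}"
                f"{1.0:6.2f}{min(score, 999.99):6.2f}          {'C':>2s}\n"
            )
        out.write("END\n")
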