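"""Residue conservation grades: parsing, filtering, and the potential set P.

Grades follow the ConSurf 1-9 color scale: 1 = maximally variable,
9 = maximally conserved.  Grades are ordinal; the only arithmetic ever
done on them is a within-structure sum when scoring pockets.  Two file
dialects are supported: the ConSurf-DB per-chain grades table and a
plain 3-column TSV (chain, residue_number, grade).
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import FormatError, InputError, ParameterError
from .structure import Atom

log = logging.getLogger(__name__)

DEFAULT_CUTOFF = 7

#: ConSurf grades-table residue field, e.g. ``MET1:A`` or ``GLU45A:B``.
_CONSURF_RES = re.compile(r"^([A-Z]{1,3})(-?\d+)([A-Za-z]?):(\S+)$")


@dataclass
class ConservationMap:
    """Residue identifier -> integer conservation grade (1-9).

    Keys are ``(chain_id, residue_number, insertion_code)`` triples, the
    name-agnostic part of a residue key, because grade files do not always
    agree with the PDB on residue names.
    """

    grades: dict[tuple[str, int, str], int] = field(default_factory=dict)
    scale_min: int = 1
    scale_max: int = 9
    insufficient_data: set[tuple[str, int, str]] = field(default_factory=set)

    def grade_of(self, residue_key) -> int:
        """Grade for a residue; unmapped residues count as grade 0."""
        return self.grades.get(residue_key.res_id, 0)

    def __len__(self) -> int:
        return len(self.grades)


def _clamp_grade(raw: int, where: str) -> int:
    if 1 <= raw <= 9:
        return raw
    clamped = min(9, max(1, raw))
    log.warning("%s: grade %d outside [1, 9]; clamped to %d", where, raw, clamped)
    return clamped


def _parse_tsv(lines: list[str], path: str) -> ConservationMap:
    cmap = ConservationMap()
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 3:
            continue
        chain, resnum_s, grade_s = parts[0], parts[1], parts[2]
        try:
            resnum = int(resnum_s)
            grade = int(grade_s.rstrip("*"))
        except ValueError:
            if lineno == 1:
                continue  # header row
            raise FormatError(
                f"{path}: line {lineno}: expected 'chain  residue_number  grade'"
            ) from None
        key = (chain, resnum, "")
        if key in cmap.grades:
            raise FormatError(f"{path}: duplicate residue {key}")
        cmap.grades[key] = _clamp_grade(grade, f"{path}:{lineno}")
        if grade_s.endswith("*"):
            cmap.insufficient_data.add(key)
    return cmap


def _parse_consurf(lines: list[str], path: str) -> ConservationMap:
    """Parse a ConSurf-DB grades table.

    Rows carry a position, a 3LATOM residue field like ``MET1:A``, a
    continuous score, and the binned COLOR grade, possibly marked ``8*``
    when the grade rests on insufficient data.
    """
    cmap = ConservationMap()
    for lineno, line in enumerate(lines, start=1):
        tokens = line.split()
        if len(tokens) < 3:
            continue
        res_tok = None
        for tok in tokens:
            m = _CONSURF_RES.match(tok)
            if m:
                res_tok = m
                break
        if res_tok is None:
            continue
        color = None
        starred = False
        idx = tokens.index(res_tok.group(0))
        for tok in tokens[idx + 1:]:
            m = re.fullmatch(r"([1-9])(\*?)", tok)
            if m:
                color = int(m.group(1))
                starred = bool(m.group(2))
                break
        if color is None:
            continue
        _, resnum_s, icode, chain = res_tok.groups()
        key = (chain, int(resnum_s), icode.strip())
        if key in cmap.grades:
            raise FormatError(f"{path}: duplicate residue {key}")
        cmap.grades[key] = _clamp_grade(color, f"{path}:{lineno}")
        if starred:
            cmap.insufficient_data.add(key)
            log.info("%s: residue %s grade %d rests on insufficient data", path, key, color)
    return cmap


def parse_grades(path: str | os.PathLike, dialect: str = "auto") -> ConservationMap:
    """Read per-residue conservation grades from ``path``.

    ``dialect`` is ``"consurf"`` (ConSurf-DB grades table), ``"tsv"``
    (chain / residue_number / grade columns), or ``"auto"`` to sniff:
    files containing a 3LATOM-style residue token are read as ConSurf.
    """
    path = os.fspath(path)
    if not os.path.isfile(path):
        raise InputError(f"no such grades file: {path}")
    with open(path) as handle:
        lines = handle.readlines()
    if dialect == "auto":
        dialect = (
            "consurf"
            if any(_CONSURF_RES.search(tok) for ln in lines for tok in ln.split())
            else "tsv"
        )
    if dialect == "consurf":
        cmap = _parse_consurf(lines, path)
    elif dialect == "tsv":
        cmap = _parse_tsv(lines, path)
    else:
        raise ParameterError(f"unknown grades dialect {dialect!r}")
    if not cmap.grades:
        raise FormatError(f"{path}: no parseable grade rows ({dialect} dialect)")
    return cmap


def remap_chains(cmap: ConservationMap, chain_map: Mapping[str, str]) -> ConservationMap:
    """Rename grade-file chain IDs (author-chain vs PDB-chain mismatches)."""
    out = ConservationMap(scale_min=cmap.scale_min, scale_max=cmap.scale_max)
    for (chain, num, icode), grade in cmap.grades.items():
        out.grades[(chain_map.get(chain, chain), num, icode)] = grade
    out.insufficient_data = {
        (chain_map.get(c, c), n, i) for (c, n, i) in cmap.insufficient_data
    }
    return out


def conserved_atom_set(
    atoms: Sequence[Atom],
    cmap: ConservationMap,
    cutoff: int = DEFAULT_CUTOFF,
    coverage_warn_fraction: float = 0.10,
) -> frozenset[int]:
    """Set C: serials of all atoms in residues with grade >= ``cutoff``.

    Residues absent from the map count as grade 0 (never retained); if
    more than ``coverage_warn_fraction`` of residues are unmapped a
    coverage warning is logged so silent data loss stays visible.
    """
    if not (1 <= cutoff <= 9):
        raise ParameterError(f"conservation cutoff must be in [1, 9], got {cutoff}")
    residues = {a.residue_key for a in atoms}
    unmapped = {r for r in residues if r.res_id not in cmap.grades}
    if residues and len(unmapped) / len(residues) > coverage_warn_fraction:
        log.warning(
            "%d of %d residues (%.0f%%) have no conservation grade and are "
            "treated as unconserved",
            len(unmapped), len(residues), 100 * len(unmapped) / len(residues),
        )
    return frozenset(a.serial for a in atoms if cmap.grade_of(a.residue_key) >= cutoff)


def potential_atoms(
    cleft: frozenset[int] | set[int], set_C: frozenset[int] | set[int]
) -> frozenset[int]:
    """Set P: conserved cleft atoms (exact intersection cleft ∩ C)."""
    return frozenset(cleft) & frozenset(set_C)
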