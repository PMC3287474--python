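"""Pocket scoring and ranking: conservation-sum and volume schemes.

Two ranking schemes are provided.  The conservation score of a pocket is
the sum of grades over its distinct member residues — the sum (rather
than the mean) rewards pockets that are both large and conserved, which
is the point of combining geometry with evolution.  The volume scheme
ranks by an estimate of the pocket's occupied space, the classic
"largest pocket binds the ligand" heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .conservation import ConservationMap
from .errors import ParameterError
from .pockets import Pocket
from .structure import Atom

RANK_METHODS = ("conservation", "volume")
DEFAULT_VOLUME_GRID = 1.0  # Angstrom
PROBE_INFLATION = 1.4  # Angstrom added to vdW radii for the volume proxy


def conservation_score(
    pocket: Pocket, cmap: ConservationMap, aggregate: str = "sum"
) -> float:
    """Conservation score of a pocket over its distinct member residues.

    Each residue contributes its grade once, no matter how many of its
    atoms belong to the pocket; ungraded residues contribute 0.
    ``aggregate`` is ``"sum"`` (default) or ``"mean"``.
    """
    grades = [cmap.grade_of(r) for r in pocket.member_residues]
    if aggregate == "sum":
        return float(sum(grades))
    if aggregate == "mean":
        return float(np.mean(grades)) if grades else 0.0
    raise ParameterError(f"unknown aggregate {aggregate!r}; use 'sum' or 'mean'")


def pocket_volume(
    pocket: Pocket,
    atoms_by_serial: dict[int, Atom],
    grid_step: float = DEFAULT_VOLUME_GRID,
) -> float:
    """Occupied-space estimate: volume (A^3) of the union of
    probe-inflated spheres (r_vdw + 1.4 A) centered on member atoms.

    Counted on a deterministic axis-aligned voxel grid anchored at
    multiples of ``grid_step`` in the global frame, so the estimate is
    translation-consistent to within one voxel shell and converges to
    the analytic union volume as the step shrinks.
    """
    if grid_step <= 0:
        raise ParameterError(f"grid_step must be positive, got {grid_step}")
    members = [atoms_by_serial[s] for s in sorted(pocket.member_atoms)]
    if not members:
        return 0.0
    centers = np.array([a.coords for a in members])
    radii = np.array([a.vdw_radius for a in members]) + PROBE_INFLATION
    lo = np.floor((centers - radii[:, None]).min(axis=0) / grid_step) * grid_step
    hi = (centers + radii[:, None]).max(axis=0)
    axes = [np.arange(lo[d] + grid_step / 2, hi[d] + grid_step / 2, grid_step) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    voxels = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    occupied = np.zeros(len(voxels), dtype=bool)
    for c, r in zip(centers, radii):
        d2 = np.einsum("ij,ij->i", voxels - c, voxels - c)
        occupied |= d2 <= r * r
    return float(occupied.sum()) * grid_step**3


@dataclass
class RankedPrediction:
    """Pockets in rank order (rank 1 = best) under one scoring scheme."""

    pockets: list[Pocket]
    ranking_method: str
    structure_id: str = ""

    def top(self, n: int) -> list[Pocket]:
        return self.pockets[:n]


def rank_pockets(
    pockets: Sequence[Pocket],
    method: str,
    cmap: ConservationMap | None = None,
    atoms_by_serial: dict[int, Atom] | None = None,
    grid_step: float = DEFAULT_VOLUME_GRID,
    aggregate: str = "sum",
    structure_id: str = "",
) -> RankedPrediction:
    """Sort pockets by the chosen score, descending, and assign ranks 1..n.

    Ties are broken by more member atoms first, then by the smaller
    minimum member serial, so the order is deterministic.  Scores are
    written onto the pockets (``conservation_score`` always when a grade
    map is given; ``volume`` always when atoms are given).
    """
    if method not in RANK_METHODS:
        raise ParameterError(f"unknown ranking method {method!r}; use one of {RANK_METHODS}")
    pockets = list(pockets)
    if cmap is not None:
        for p in pockets:
            p.conservation_score = conservation_score(p, cmap, aggregate)
    if atoms_by_serial is not None:
        for p in pockets:
            p.volume = pocket_volume(p, atoms_by_serial, grid_step)
    if method == "conservation":
        if cmap is None:
            raise ParameterError("conservation ranking needs a grade map")
        keyfn = lambda p: (-p.conservation_score, -p.n_atoms, min(p.member_atoms))
    else:
        if atoms_by_serial is None:
            raise ParameterError("volume ranking needs the atom table")
        keyfn = lambda p: (-p.volume, -p.n_atoms, min(p.member_atoms))
    pockets.sort(key=keyfn)
    for i, p in enumerate(pockets, start=1):
        p.rank = i
    return RankedPrediction(pockets=pockets, ranking_method=method, structure_id=structure_id)
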