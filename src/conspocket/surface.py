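"""Surface geometry: per-atom SASA, surface set S, expanded hull set Q, cleft S\\Q.

The cleft-detection idea: surface atoms (solvent-exposed) that are *not*
close to the convex hull of the structure sit in concave depressions —
exactly where ligands bind.  Three atom sets are computed:

* ``S`` — atoms whose solvent-accessible surface area exceeds a threshold;
* ``Q`` — convex-hull vertex atoms plus every atom within an expansion
  distance of a hull vertex (the structure's convex "rind");
* cleft — the set difference ``S \\ Q``.

SASA uses the Shrake-Rupley method with a deterministic golden-spiral
point lattice, so results are bit-reproducible without any RNG.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .errors import GeometryError, ParameterError
from .structure import Atom

DEFAULT_PROBE = 1.4  # water-sized probe, Angstrom
DEFAULT_N_POINTS = 960
DEFAULT_SASA_THRESHOLD = 1.0  # Angstrom^2
DEFAULT_EXPAND_DIST = 6.5  # Angstrom


@dataclass
class SasaResult:
    """Per-atom solvent-accessible surface areas."""

    per_atom_area: dict[int, float]  # atom serial -> Angstrom^2
    probe_radius: float
    n_sphere_points: int


@dataclass
class AtomSets:
    """The three atom-serial sets of the cleft-detection stage."""

    set_S: frozenset[int]
    set_Q: frozenset[int]
    cleft: frozenset[int]


def golden_spiral_points(n: int) -> np.ndarray:
    """``n`` quasi-uniform points on the unit sphere (golden-spiral lattice).

    Deterministic: the same ``n`` always yields the same array.
    """
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = np.pi * (1.0 + 5.0**0.5) * k
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def compute_sasa(
    atoms: Sequence[Atom],
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> SasaResult:
    """Shrake-Rupley SASA for every atom, in Angstrom^2.

    For each atom, ``n_points`` test points are placed on a sphere of
    radius ``r_vdw + probe``; a point is accessible if it lies outside
    every neighbouring atom's expanded sphere.  Neighbour search is
    limited to atoms within ``r_i + r_j + 2*probe`` via a k-d tree;
    the result is identical to the all-pairs computation.
    """
    if probe <= 0:
        raise ParameterError(f"probe radius must be positive, got {probe}")
    if n_points < 100:
        raise ParameterError(f"n_points must be >= 100, got {n_points}")
    if not atoms:
        raise ParameterError("compute_sasa requires a non-empty atom list")
    coords = np.array([a.coords for a in atoms])
    radii = np.array([a.vdw_radius for a in atoms])
    if np.any(radii <= 0):
        raise ParameterError("all atoms need an assigned vdW radius; call assign_radii")
    expanded = radii + probe
    unit = golden_spiral_points(n_points)
    tree = cKDTree(coords)
    max_reach = expanded + expanded.max()
    areas: dict[int, float] = {}
    for i, atom in enumerate(atoms):
        pts = coords[i] + expanded[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in tree.query_ball_point(coords[i], max_reach[i]):
            if j == i:
                continue
            d = np.linalg.norm(coords[i] - coords[j])
            if d >= expanded[i] + expanded[j]:
                continue
            accessible &= (
                np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
                >= expanded[j] ** 2
            )
            if not accessible.any():
                break
        frac = accessible.sum() / n_points
        areas[atom.serial] = frac * 4.0 * np.pi * expanded[i] ** 2
    return SasaResult(per_atom_area=areas, probe_radius=probe, n_sphere_points=n_points)


def surface_set(sasa: SasaResult, threshold: float = DEFAULT_SASA_THRESHOLD) -> frozenset[int]:
    """Atoms with SASA strictly greater than ``threshold`` (set S)."""
    if threshold < 0:
        raise ParameterError(f"SASA threshold must be >= 0, got {threshold}")
    return frozenset(s for s, a in sasa.per_atom_area.items() if a > threshold)


def convex_hull_vertices(atoms: Sequence[Atom]) -> frozenset[int]:
    """Serials of atoms whose centers are vertices of the 3-D convex hull."""
    if len(atoms) < 4:
        raise GeometryError(f"convex hull needs >= 4 atoms, got {len(atoms)}")
    coords = np.array([a.coords for a in atoms])
    try:
        hull = ConvexHull(coords)
    except QhullError as exc:
        raise GeometryError(f"degenerate geometry for convex hull: {exc}") from exc
    return frozenset(atoms[i].serial for i in hull.vertices)


def expand_hull(
    hull: frozenset[int] | set[int],
    atoms: Sequence[Atom],
    expand_dist: float = DEFAULT_EXPAND_DIST,
) -> frozenset[int]:
    """Set Q: hull-vertex atoms plus atoms within ``expand_dist`` of any
    hull vertex (center-to-center, inclusive)."""
    if expand_dist < 0:
        raise ParameterError(f"expand_dist must be >= 0, got {expand_dist}")
    serials = np.array([a.serial for a in atoms])
    coords = np.array([a.coords for a in atoms])
    hull_mask = np.isin(serials, list(hull))
    if not hull_mask.any():
        return frozenset(hull)
    tree = cKDTree(coords[hull_mask])
    dists, _ = tree.query(coords, k=1)
    near = dists <= expand_dist
    return frozenset(hull) | frozenset(serials[near].tolist())


def cleft_atoms(set_S: frozenset[int] | set[int], set_Q: frozenset[int] | set[int]) -> frozenset[int]:
    """Cleft set: surface atoms outside the expanded hull (S \\ Q)."""
    return frozenset(set_S) - frozenset(set_Q)


def compute_atom_sets(
    atoms: Sequence[Atom],
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    sasa_threshold: float = DEFAULT_SASA_THRESHOLD,
    expand_dist: float = DEFAULT_EXPAND_DIST,
    sasa: SasaResult | None = None,
) -> AtomSets:
    """Full cleft-detection stage: S, Q, and cleft = S \\ Q.

    A precomputed ``sasa`` result may be supplied (it does not depend on
    the expansion distance, so parameter sweeps reuse it).
    """
    if sasa is None:
        sasa = compute_sasa(atoms, probe=probe, n_points=n_points)
    s = surface_set(sasa, sasa_threshold)
    hull = convex_hull_vertices(atoms)
    q = expand_hull(hull, atoms, expand_dist)
    return AtomSets(set_S=s, set_Q=q, cleft=cleft_atoms(s, q))
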