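"""Spatial clustering of potential atoms into candidate pockets.

Potential atoms are grouped by single-linkage clustering cut at a fixed
distance — equivalently, connected components of the graph joining atom
pairs closer than the link distance.  Cluster centers within a merge
distance are then fused (and the fused center recomputed from all member
atoms) until every pair of pocket centers is farther apart than the
merge distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .conservation import ConservationMap, conserved_atom_set, potential_atoms
from .structure import Atom, ProteinComplex, ResidueKey, assign_radii
from .surface import compute_atom_sets, SasaResult

log = logging.getLogger(__name__)

DEFAULT_ATOM_LINK_DIST = 4.5  # Angstrom; heavy-atom contact distance + slack
DEFAULT_CENTER_MERGE_DIST = 8.0  # Angstrom
DEFAULT_MIN_POCKET_ATOMS = 3


@dataclass
class ClusterParams:
    """Distance thresholds of the clustering stage."""

    atom_link_dist: float = DEFAULT_ATOM_LINK_DIST
    center_merge_dist: float = DEFAULT_CENTER_MERGE_DIST
    min_pocket_atoms: int = DEFAULT_MIN_POCKET_ATOMS

    def __post_init__(self) -> None:
        if self.atom_link_dist <= 0 or self.center_merge_dist <= 0:
            raise ValueError("cluster distances must be positive")


@dataclass
class Pocket:
    """A candidate binding site: a cluster of potential atoms."""

    member_atoms: frozenset[int]
    member_residues: frozenset[ResidueKey]
    center: np.ndarray  # geometric center, mean of member atom coords
    conservation_score: float = 0.0
    volume: float = 0.0
    rank: int = 0

    @property
    def n_atoms(self) -> int:
        return len(self.member_atoms)


def cluster_atoms(
    serials: Sequence[int],
    coords: np.ndarray,
    link_dist: float = DEFAULT_ATOM_LINK_DIST,
    min_size: int = DEFAULT_MIN_POCKET_ATOMS,
) -> list[frozenset[int]]:
    """Single-linkage clusters of the given atoms, cut at ``link_dist``.

    Implemented as connected components of the contact graph joining
    pairs with center distance <= ``link_dist`` — exactly the partition a
    single-linkage dendrogram yields when cut at that height.  Clusters
    smaller than ``min_size`` are discarded (logged).
    """
    serials = list(serials)
    if not serials:
        return []
    coords = np.asarray(coords, dtype=float)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(link_dist, output_type="ndarray")
    n = len(serials)
    if len(pairs):
        ones = np.ones(len(pairs))
        adj = coo_matrix((ones, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    else:
        adj = coo_matrix((n, n))
    n_comp, labels = connected_components(adj, directed=False)
    clusters: list[frozenset[int]] = []
    n_dropped = 0
    for c in range(n_comp):
        members = frozenset(serials[i] for i in np.flatnonzero(labels == c))
        if len(members) >= min_size:
            clusters.append(members)
        else:
            n_dropped += 1
    if n_dropped:
        log.info("discarded %d cluster(s) smaller than %d atoms", n_dropped, min_size)
    return clusters


def merge_centers(
    clusters: list[frozenset[int]],
    coords_by_serial: dict[int, np.ndarray],
    residue_by_serial: dict[int, ResidueKey],
    merge_dist: float = DEFAULT_CENTER_MERGE_DIST,
) -> list[Pocket]:
    """Fuse clusters whose geometric centers lie within ``merge_dist``.

    Merging is iterated to a fixpoint: after each fusion the center is
    recomputed as the mean over *all* member atoms, which can move it
    into range of further clusters.  On return all pairwise pocket-center
    distances exceed ``merge_dist``.
    """
    groups = [set(c) for c in clusters]
    while len(groups) > 1:
        centers = np.array(
            [np.mean([coords_by_serial[s] for s in g], axis=0) for g in groups]
        )
        d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
        pairs = np.argwhere(np.triu(d <= merge_dist, k=1))
        if not len(pairs):
            break
        # single-linkage grouping of centers: merge whole connected components
        adj = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
            shape=(len(groups), len(groups)),
        )
        _, labels = connected_components(adj, directed=False)
        merged: dict[int, set[int]] = {}
        for gi, lab in enumerate(labels):
            merged.setdefault(lab, set()).update(groups[gi])
        groups = [merged[lab] for lab in sorted(merged)]
    pockets = []
    for g in groups:
        members = frozenset(g)
        center = np.mean([coords_by_serial[s] for s in g], axis=0)
        residues = frozenset(residue_by_serial[s] for s in g)
        pockets.append(Pocket(member_atoms=members, member_residues=residues, center=center))
    # deterministic pre-ranking order: big pockets first, serial as tie-break
    pockets.sort(key=lambda p: (-p.n_atoms, min(p.member_atoms)))
    return pockets


@dataclass
class PredictionTrace:
    """Intermediate set sizes of one prediction run, for auditing."""

    n_surface: int = 0
    n_hull_expanded: int = 0
    n_cleft: int = 0
    n_conserved: int = 0
    n_potential: int = 0
    n_clusters: int = 0
    n_pockets: int = 0


def predict_pockets(
    complex_: ProteinComplex,
    cmap: ConservationMap | None,
    sasa_probe: float = 1.4,
    sasa_points: int = 960,
    sasa_threshold: float = 1.0,
    expand_dist: float = 6.5,
    conservation_cutoff: int | None = 7,
    atom_link_dist: float = DEFAULT_ATOM_LINK_DIST,
    center_merge_dist: float = DEFAULT_CENTER_MERGE_DIST,
    min_pocket_atoms: int = DEFAULT_MIN_POCKET_ATOMS,
    radius_set: str = "chothia",
    sasa: SasaResult | None = None,
    trace: PredictionTrace | None = None,
) -> list[Pocket]:
    """Full prediction pipeline on one complex: cleft detection,
    conservation filtering, spatial clustering.

    With ``conservation_cutoff=None`` (or no grade map) the conservation
    filter is skipped entirely and P equals the cleft set.  Returns an
    unranked (but deterministically ordered) pocket list; an empty list
    means no pocket was found, which is a result, not an error.
    """
    atoms = complex_.protein_atoms
    if not atoms:
        return []
    if any(a.vdw_radius <= 0 for a in atoms):
        assign_radii(atoms, radius_set)
    sets = compute_atom_sets(
        atoms,
        probe=sasa_probe,
        n_points=sasa_points,
        sasa_threshold=sasa_threshold,
        expand_dist=expand_dist,
        sasa=sasa,
    )
    if conservation_cutoff is None or cmap is None:
        set_p = sets.cleft
        n_conserved = len(atoms)
    else:
        set_c = conserved_atom_set(atoms, cmap, conservation_cutoff)
        set_p = potential_atoms(sets.cleft, set_c)
        n_conserved = len(set_c)
    coords_by_serial = {a.serial: a.coords for a in atoms}
    residue_by_serial = {a.serial: a.residue_key for a in atoms}
    p_serials = sorted(set_p)
    clusters = cluster_atoms(
        p_serials,
        np.array([coords_by_serial[s] for s in p_serials]).reshape(-1, 3),
        link_dist=atom_link_dist,
        min_size=min_pocket_atoms,
    )
    pockets = merge_centers(
        clusters, coords_by_serial, residue_by_serial, merge_dist=center_merge_dist
    )
    if trace is not None:
        trace.n_surface = len(sets.set_S)
        trace.n_hull_expanded = len(sets.set_Q)
        trace.n_cleft = len(sets.cleft)
        trace.n_conserved = n_conserved
        trace.n_potential = len(set_p)
        trace.n_clusters = len(clusters)
        trace.n_pockets = len(pockets)
    if not pockets:
        log.info(
            "%s: no pocket found (|cleft|=%d, |P|=%d)",
            complex_.source_id, len(sets.cleft), len(set_p),
        )
    return pockets
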