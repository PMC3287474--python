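"""Deterministic pseudo-protein fixtures with planted, recoverable pockets.

A fixture is a globular "protein" built from carbon pseudo-atoms tiling
concentric golden-spiral shells (a jittered solid ball).  Each planted
pocket is a spherical bite carved out of the ball surface: atoms inside
the bite sphere are removed, leaving a concave invagination of known
mouth radius and depth, and a small pseudo-ligand is placed at the
bottom of the cavity.  Residues are singletons by default (one atom =
one residue) so the residue-to-grade mapping is trivial; a multi-atom
variant groups consecutive atoms into residues to exercise residue-level
score aggregation.  Pocket-lining residues receive high conservation
grades with a configurable probability; everything else draws from a
background grade distribution.  All randomness comes from the stated
seed, so the same spec yields byte-identical files.

What these fixtures emulate: a single compact domain with concave,
conserved binding pockets and a bound ligand per pocket.  What they do
not emulate: real side-chain packing, chemistry, or sequence realism.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .conservation import ConservationMap
from .errors import FixtureSpecError
from .structure import (
    Atom,
    LigandGroup,
    ProteinComplex,
    ResidueKey,
    assign_radii,
    write_pdb,
)
from .surface import golden_spiral_points

#: Background grade probabilities for grades 1..9 — mildly bottom-heavy,
#: with ~25% of background residues reaching the conserved range (>= 7),
#: so conservation carries signal but is far from noise-free.
DEFAULT_BACKGROUND = (0.14, 0.14, 0.13, 0.12, 0.11, 0.11, 0.10, 0.08, 0.07)


@dataclass(frozen=True)
class PocketSpec:
    """One planted pocket: where it points and how big the bite is."""

    direction: tuple[float, float, float]
    mouth_radius: float = 7.0  # Angstrom, rim radius at the ball surface
    depth: float = 9.5  # Angstrom, how far the bite dips below the surface

    def unit(self) -> np.ndarray:
        v = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(v)
        if n == 0:
            raise FixtureSpecError("pocket direction must be non-zero")
        return v / n


@dataclass
class FixtureSpec:
    """Full recipe for one pseudo-protein fixture.

    ``pockets`` are real binding sites: their lining is conservation-
    enriched and each receives a ligand.  ``decoys`` are carved the same
    way but get neither — they model the large non-functional surface
    depressions real proteins have, which is what makes the conservation
    filter informative rather than redundant on these fixtures.
    """

    shell_radius: float = 16.0
    atom_spacing: float = 2.6
    pockets: Sequence[PocketSpec] = field(
        default_factory=lambda: (PocketSpec((0.0, 0.0, 1.0)),)
    )
    decoys: Sequence[PocketSpec] = ()
    conserved_fraction_in_pocket: float = 0.9
    background_grade_distribution: Sequence[float] = DEFAULT_BACKGROUND
    seed: int = 0
    atoms_per_residue: int = 1
    jitter: float = 0.25  # Angstrom, uniform positional noise

    def validate(self) -> None:
        if self.shell_radius <= 0 or self.atom_spacing <= 0:
            raise FixtureSpecError("shell_radius and atom_spacing must be positive")
        probs = np.asarray(self.background_grade_distribution, dtype=float)
        if probs.shape != (9,) or abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            raise FixtureSpecError("background_grade_distribution must be 9 probabilities summing to 1")
        bites = []
        all_specs = list(self.pockets) + list(self.decoys)
        for p in all_specs:
            if not (0 < p.depth < self.shell_radius):
                raise FixtureSpecError(f"pocket depth {p.depth} must lie in (0, shell_radius)")
            if not (0 < p.mouth_radius < self.shell_radius):
                raise FixtureSpecError(f"mouth radius {p.mouth_radius} must lie in (0, shell_radius)")
            bites.append(_bite_sphere(self.shell_radius, p))
        for i in range(len(all_specs)):
            for j in range(i + 1, len(all_specs)):
                ui, uj = all_specs[i].unit(), all_specs[j].unit()
                ang = np.arccos(np.clip(ui @ uj, -1, 1))
                min_sep = 2.0 * np.arcsin(
                    min(all_specs[i].mouth_radius, all_specs[j].mouth_radius)
                    / self.shell_radius
                )
                gap = np.linalg.norm(bites[i][0] - bites[j][0]) - bites[i][1] - bites[j][1]
                if ang <= min_sep or gap <= 0:
                    raise FixtureSpecError(
                        f"pockets {i} and {j} overlap: angular separation "
                        f"{np.degrees(ang):.1f} deg, bite-sphere gap {gap:.2f} A"
                    )


def _bite_sphere(shell_radius: float, pocket: PocketSpec) -> tuple[np.ndarray, float]:
    """Center and radius of the sphere carved out for one pocket.

    The bite sphere is chosen to pass through the rim circle of radius
    ``mouth_radius`` on the ball surface while its lowest point sits
    ``depth`` below the surface.
    """
    R, m, d = shell_radius, pocket.mouth_radius, pocket.depth
    cos_phi = np.sqrt(1.0 - (m / R) ** 2)
    a = R * cos_phi - (R - d)
    if a <= 0:
        raise FixtureSpecError(
            f"infeasible pocket: depth {d} too shallow for mouth radius {m} "
            f"at shell radius {R}"
        )
    rho = (m * m + a * a) / (2.0 * a)
    center = (R - d + rho) * pocket.unit()
    return center, rho


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3x3 rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def make_pocketed_structure(
    spec: FixtureSpec,
) -> tuple[ProteinComplex, ConservationMap, list[np.ndarray]]:
    """Build one fixture: complex, grade map, and ground-truth centroids.

    Returns the in-memory complex (radii assigned), the conservation map,
    and the list of planted ligand centroids (one per pocket) that serve
    as ground truth for recoverability checks.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    R, s = spec.shell_radius, spec.atom_spacing

    points: list[np.ndarray] = []
    for r in np.arange(R, 1.0, -s):
        n = max(6, int(round(4.0 * np.pi * r * r / (s * s))))
        layer = r * golden_spiral_points(n) @ _random_rotation(rng).T
        points.extend(layer)
    points.append(np.zeros(3))
    coords = np.array(points)
    coords += rng.uniform(-spec.jitter, spec.jitter, size=coords.shape)

    keep = np.ones(len(coords), dtype=bool)
    lining = np.zeros(len(coords), dtype=bool)
    for center, rho in (_bite_sphere(R, p) for p in spec.pockets):
        d = np.linalg.norm(coords - center, axis=1)
        keep &= d > rho
        lining |= d <= rho + 1.1 * s
    for center, rho in (_bite_sphere(R, p) for p in spec.decoys):
        keep &= np.linalg.norm(coords - center, axis=1) > rho
    coords = coords[keep]
    lining = lining[keep]

    protein_atoms: list[Atom] = []
    lining_residues: set[tuple[str, int, str]] = set()
    for i, xyz in enumerate(coords):
        resnum = i // spec.atoms_per_residue + 1
        rkey = ResidueKey("A", resnum, "", "GLY")
        protein_atoms.append(
            Atom(serial=i + 1, name="CA", element="C", coords=xyz, residue_key=rkey)
        )
        if lining[i]:
            lining_residues.add(rkey.res_id)

    # conservation grades: lining residues are conserved with high
    # probability, everything else draws from the background
    cmap = ConservationMap()
    grades = np.arange(1, 10)
    background = np.asarray(spec.background_grade_distribution, dtype=float)
    n_res = (len(coords) - 1) // spec.atoms_per_residue + 1
    for resnum in range(1, n_res + 1):
        key = ("A", resnum, "")
        if key in lining_residues and rng.random() < spec.conserved_fraction_in_pocket:
            cmap.grades[key] = int(rng.choice((7, 8, 9), p=(0.3, 0.4, 0.3)))
        else:
            cmap.grades[key] = int(rng.choice(grades, p=background))

    # one small ligand per pocket, nestled just above the cavity bottom
    ligand_groups: list[LigandGroup] = []
    ground_truth: list[np.ndarray] = []
    serial = len(protein_atoms)
    for li, pocket in enumerate(spec.pockets, start=1):
        u = pocket.unit()
        anchor = (R - pocket.depth + 1.9) * u
        n_lig = int(rng.integers(3, 9))
        offsets = 1.2 * golden_spiral_points(n_lig)
        group = LigandGroup(("LIG", "L", li))
        for atom_xyz in anchor + offsets:
            serial += 1
            group.atoms.append(
                Atom(
                    serial=serial,
                    name="C1",
                    element="C",
                    coords=atom_xyz,
                    residue_key=ResidueKey("L", li, "", "LIG"),
                    is_hetero=True,
                )
            )
        ligand_groups.append(group)
        ground_truth.append(np.mean([a.coords for a in group.atoms], axis=0))

    complex_ = ProteinComplex(
        protein_atoms=protein_atoms,
        ligand_groups=ligand_groups,
        source_id=f"fixture_seed{spec.seed}",
    )
    assign_radii(complex_.protein_atoms + complex_.ligand_atoms)
    return complex_, cmap, ground_truth


def write_grades_tsv(cmap: ConservationMap, path: str | os.PathLike) -> None:
    """Write a grade map in the 3-column TSV dialect the parser reads."""
    with open(path, "w") as out:
        out.write("chain\tresidue_number\tgrade\n")
        for (chain, resnum, _icode), grade in sorted(cmap.grades.items()):
            out.write(f"{chain}\t{resnum}\t{grade}\n")


def _suite_spec(base: FixtureSpec, index: int, child_seed: int) -> FixtureSpec:
    """Vary geometry across a suite: shell size, pocket count, bite shape.

    Each suite member carries one large unconserved decoy cleft besides
    its real pocket(s).  Deep pockets pull cluster centers toward the
    core of the ball, where distinct pockets could fall within the
    center-merge distance of each other, so directions are sampled with
    an angular separation that keeps expected cluster centers more than
    ~11 A apart, and full bite-sphere disjointness is re-checked by
    ``FixtureSpec.validate`` (with bounded resampling on failure).
    """
    rng = np.random.default_rng(child_seed)
    radius = float(base.shell_radius + [-2.0, -1.0, 0.0, 1.0, 2.0][index % 5])
    # bigger pseudo-proteins can host more pockets without their linings
    # approaching each other near the core
    max_pockets = 1 if radius < 15.0 else (2 if radius < 17.0 else 3)
    n_pockets = min(1 + index % 3, max_pockets)
    mouth = round([0.45, 0.48, 0.51][index % 3] * radius, 2)
    if n_pockets == 1:
        depth = min([9.5, 10.0, 10.5][index % 3], radius - 4.5)
    else:
        depth = min([9.0, 9.5, 10.0][index % 3], radius - 6.0)
    decoy_mouth = round(0.62 * radius, 2)
    decoy_depth = min(9.5, radius - 5.5)
    # directions from a randomly rotated tetrahedral template: pairwise
    # 109.5 deg separation keeps bites, linings and cluster centers apart
    template = np.array(
        [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
    ) / np.sqrt(3.0)
    directions = template[: n_pockets + 1] @ _random_rotation(rng).T
    spec = FixtureSpec(
        shell_radius=radius,
        atom_spacing=base.atom_spacing,
        pockets=tuple(
            PocketSpec(tuple(v), mouth_radius=mouth, depth=depth)
            for v in directions[:n_pockets]
        ),
        decoys=(
            PocketSpec(tuple(directions[n_pockets]), decoy_mouth, decoy_depth),
        ),
        conserved_fraction_in_pocket=base.conserved_fraction_in_pocket,
        background_grade_distribution=base.background_grade_distribution,
        seed=child_seed,
        atoms_per_residue=base.atoms_per_residue,
        jitter=base.jitter,
    )
    spec.validate()
    return spec


def make_suite(
    n: int,
    out_dir: str | os.PathLike,
    base_spec: FixtureSpec | None = None,
    seed: int = 1,
) -> str:
    """Generate ``n`` fixtures on disk and return the manifest path.

    Each fixture is written as a PDB file plus a grades TSV; the manifest
    is a TSV of (structure_id, pdb_path, grades_path) rows.  Per-fixture
    seeds derive from the suite seed by the counter scheme
    ``(seed * 1000 + index) % 2**31``, so any single fixture can be
    regenerated in isolation.
    """
    if n < 1:
        raise FixtureSpecError("suite size must be >= 1")
    base = base_spec or FixtureSpec()
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    manifest_path = os.path.join(out_dir, "manifest.tsv")
    with open(manifest_path, "w") as man:
        man.write("structure_id\tpdb_path\tgrades_path\n")
        for i in range(n):
            child_seed = (seed * 1000 + i) % 2**31
            spec = _suite_spec(base, i, child_seed)
            cplx, cmap, _truth = make_pocketed_structure(spec)
            sid = f"fx{i:03d}"
            pdb_path = os.path.join(out_dir, f"{sid}.pdb")
            grades_path = os.path.join(out_dir, f"{sid}_grades.tsv")
            write_pdb(cplx, pdb_path)
            write_grades_tsv(cmap, grades_path)
            man.write(f"{sid}\t{pdb_path}\t{grades_path}\n")
    return manifest_path


def read_manifest(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a dataset manifest into (pdb_path, grades_path) pairs."""
    pairs = []
    with open(path) as handle:
        header = handle.readline()
        for line in handle:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                pairs.append((parts[1], parts[2]))
    return pairs
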