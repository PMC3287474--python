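import numpy as np
import pytest
from scipy.optimize import linprog

from conspocket import (
    cleft_atoms,
    compute_atom_sets,
    compute_sasa,
    convex_hull_vertices,
    expand_hull,
    golden_spiral_points,
    surface_set,
)
from conspocket.errors import GeometryError, ParameterError
from conspocket.surface import SasaResult
from tests.conftest import make_atoms

PROBE = 1.4
C_EXPANDED = 1.87 + PROBE  # 3.27 A


def two_sphere_cap_areas(r1, r2, d):
    """Analytic accessible areas of two intersecting spheres (cap formula)."""
    full1, full2 = 4 * np.pi * r1**2, 4 * np.pi * r2**2
    if d >= r1 + r2:
        return full1, full2
    # height of the buried cap on sphere 1 (and symmetric for sphere 2)
    h1 = r1 - (d**2 + r1**2 - r2**2) / (2 * d)
    h2 = r2 - (d**2 + r2**2 - r1**2) / (2 * d)
    return full1 - 2 * np.pi * r1 * h1, full2 - 2 * np.pi * r2 * h2


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        atoms = make_atoms([[0, 0, 0]])
        res = compute_sasa(atoms, probe=PROBE, n_points=960)
        expected = 4 * np.pi * C_EXPANDED**2
        assert res.per_atom_area[1] == pytest.approx(expected, rel=0.005)

    def test_distant_atoms_fully_exposed(self):
        atoms = make_atoms([[0, 0, 0], [100, 0, 0]])
        res = compute_sasa(atoms)
        expected = 4 * np.pi * C_EXPANDED**2
        for serial in (1, 2):
            assert res.per_atom_area[serial] == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("d", [2.0, 3.0, 4.5])
    def test_two_sphere_cap_oracle(self, d):
        atoms = make_atoms([[0, 0, 0], [d, 0, 0]])
        res = compute_sasa(atoms, probe=PROBE, n_points=960)
        a1, a2 = two_sphere_cap_areas(C_EXPANDED, C_EXPANDED, d)
        assert res.per_atom_area[1] == pytest.approx(a1, rel=0.02)
        assert res.per_atom_area[2] == pytest.approx(a2, rel=0.02)

    def test_translation_invariance_is_exact(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(-5, 5, size=(30, 3))
        a = compute_sasa(make_atoms(coords))
        b = compute_sasa(make_atoms(coords + np.array([11.0, -7.0, 3.0])))
        assert a.per_atom_area == b.per_atom_area

    def test_rotation_invariance_within_one_percent(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(-5, 5, size=(30, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        a = compute_sasa(make_atoms(coords), n_points=960)
        b = compute_sasa(make_atoms(coords @ q.T), n_points=960)
        total_a = sum(a.per_atom_area.values())
        total_b = sum(b.per_atom_area.values())
        assert total_b == pytest.approx(total_a, rel=0.01)

    def test_against_independent_shrake_rupley(self):
        """Cross-check against biotite's Shrake-Rupley with matched radii."""
        biotite_struct = pytest.importorskip("biotite.structure")
        rng = np.random.default_rng(2)
        coords = rng.uniform(-6, 6, size=(40, 3))
        atoms = make_atoms(coords)
        ours = compute_sasa(atoms, probe=1.4, n_points=960)
        arr = biotite_struct.AtomArray(len(atoms))
        arr.coord = coords.astype(np.float32)
        arr.set_annotation("element", np.array(["C"] * len(atoms)))
        ref = biotite_struct.sasa(
            arr,
            probe_radius=1.4,
            vdw_radii=np.full(len(atoms), 1.87),
            point_number=2000,
        )
        mine = np.array([ours.per_atom_area[a.serial] for a in atoms])
        assert np.abs(mine - ref).max() < 0.05 * 4 * np.pi * C_EXPANDED**2

    def test_bad_parameters(self):
        atoms = make_atoms([[0, 0, 0]])
        with pytest.raises(ParameterError):
            compute_sasa(atoms, probe=-1.0)
        with pytest.raises(ParameterError):
            compute_sasa(atoms, n_points=10)

    def test_area_bounded_by_expanded_sphere(self, pocketed):
        cplx, _, _ = pocketed
        res = compute_sasa(cplx.protein_atoms[:200])
        bound = 4 * np.pi * C_EXPANDED**2 * (1 + 1e-9)
        assert all(0 <= a <= bound for a in res.per_atom_area.values())


class TestGoldenSpiral:
    def test_points_are_unit_and_deterministic(self):
        pts = golden_spiral_points(960)
        assert pts.shape == (960, 3)
        assert np.linalg.norm(pts, axis=1) == pytest.approx(1.0, abs=1e-12)
        assert np.array_equal(pts, golden_spiral_points(960))


class TestSurfaceSet:
    def test_strict_threshold(self):
        res = SasaResult({1: 1.5, 2: 0.5, 3: 1.0}, 1.4, 960)
        assert surface_set(res, 1.0) == {1}

    def test_zero_threshold_keeps_any_exposure(self):
        res = SasaResult({1: 0.01, 2: 0.0}, 1.4, 960)
        assert surface_set(res, 0.0) == {1}

    def test_negative_threshold_raises(self):
        with pytest.raises(ParameterError):
            surface_set(SasaResult({}, 1.4, 960), -1.0)


def hull_vertices_by_lp(coords):
    """Brute-force oracle: point i is a hull vertex iff it cannot be
    written as a convex combination of the other points (LP feasibility)."""
    n = len(coords)
    vertices = set()
    for i in range(n):
        others = np.delete(coords, i, axis=0)
        a_eq = np.vstack([others.T, np.ones(len(others))])
        b_eq = np.append(coords[i], 1.0)
        res = linprog(np.zeros(len(others)), A_eq=a_eq, b_eq=b_eq, bounds=(0, None))
        if not res.success:
            vertices.add(i)
    return vertices


class TestConvexHull:
    def test_tetrahedron_all_vertices(self):
        coords = [[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0], [0.5, 0.3, 1.0]]
        atoms = make_atoms(coords)
        assert convex_hull_vertices(atoms) == {1, 2, 3, 4}

    def test_cube_corners_exclude_centroid(self):
        corners = [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)]
        atoms = make_atoms(corners + [[0.5, 0.5, 0.5]])
        assert convex_hull_vertices(atoms) == set(range(1, 9))

    def test_random_ball_matches_lp_oracle(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(200, 3))
        coords = coords[np.linalg.norm(coords, axis=1) < 3]
        atoms = make_atoms(coords)
        ours = convex_hull_vertices(atoms)
        oracle = {i + 1 for i in hull_vertices_by_lp(coords)}
        assert ours == oracle

    def test_degenerate_input_raises(self):
        with pytest.raises(GeometryError):
            convex_hull_vertices(make_atoms([[0, 0, 0], [1, 0, 0], [2, 0, 0]]))
        coplanar = [[x, y, 0.0] for x in range(3) for y in range(3)]
        with pytest.raises(GeometryError):
            convex_hull_vertices(make_atoms(coplanar))


class TestExpandHull:
    @pytest.mark.parametrize(
        "x,included", [(6.0, True), (6.5, True), (7.0, False)]
    )
    def test_inclusive_distance_decision(self, x, included):
        # a tetrahedron hull plus one probe atom along +x from the origin vertex
        base = [[0, 0, 0], [20, 0, 0], [10, 20, 0], [10, 10, 20]]
        atoms = make_atoms(base + [[x, 0, 0]])
        hull = frozenset({1, 2, 3, 4})
        q = expand_hull(hull, atoms, expand_dist=6.5)
        assert (5 in q) == included

    def test_monotone_in_expand_dist(self, pocketed):
        cplx, _, _ = pocketed
        atoms = cplx.protein_atoms
        hull = convex_hull_vertices(atoms)
        sizes = [len(expand_hull(hull, atoms, d)) for d in (4.0, 5.5, 6.5, 8.0)]
        assert sizes == sorted(sizes)

    def test_negative_distance_raises(self):
        atoms = make_atoms([[0, 0, 0]])
        with pytest.raises(ParameterError):
            expand_hull(frozenset({1}), atoms, -1.0)


class TestCleft:
    def test_set_difference(self):
        assert cleft_atoms({1, 2, 3}, {2, 4}) == {1, 3}

    def test_subset_gives_empty(self):
        assert cleft_atoms({1, 2}, {1, 2, 3}) == frozenset()

    def test_cleft_lies_on_planted_invagination(self, pocketed):
        cplx, _, truth = pocketed
        sets = compute_atom_sets(cplx.protein_atoms)
        assert sets.cleft == sets.set_S - sets.set_Q
        assert sets.cleft & sets.set_Q == frozenset()
        assert sets.cleft <= sets.set_S
        coords = {a.serial: a.coords for a in cplx.protein_atoms}
        # every cleft atom sits near the planted pocket, not elsewhere
        for serial in sets.cleft:
            assert np.linalg.norm(coords[serial] - truth[0]) < 9.0
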