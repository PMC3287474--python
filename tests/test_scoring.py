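import numpy as np
import pytest

from conspocket import conservation_score, pocket_volume, rank_pockets
from conspocket.conservation import ConservationMap
from conspocket.errors import ParameterError
from conspocket.pockets import Pocket
from conspocket.structure import ResidueKey
from tests.conftest import make_atoms

INFLATED_C = 1.87 + 1.4  # 3.27 A


def make_pocket(atoms):
    serials = frozenset(a.serial for a in atoms)
    residues = frozenset(a.residue_key for a in atoms)
    center = np.mean([a.coords for a in atoms], axis=0)
    return Pocket(member_atoms=serials, member_residues=residues, center=center)


def sphere_volume(r):
    return 4.0 / 3.0 * np.pi * r**3


def two_sphere_union_volume(r1, r2, d):
    """Closed-form union volume of two spheres (lens subtraction)."""
    if d >= r1 + r2:
        inter = 0.0
    else:
        inter = (
            np.pi
            * (r1 + r2 - d) ** 2
            * (d**2 + 2 * d * (r1 + r2) - 3 * (r1 - r2) ** 2)
            / (12 * d)
        )
    return sphere_volume(r1) + sphere_volume(r2) - inter


class TestConservationScore:
    def test_sum_over_distinct_residues(self):
        atoms = make_atoms([[0, 0, 0], [3, 0, 0], [6, 0, 0]])
        cmap = ConservationMap(
            grades={("A", 1, ""): 7, ("A", 2, ""): 8, ("A", 3, ""): 9}
        )
        assert conservation_score(make_pocket(atoms), cmap) == 24

    def test_residue_counted_once_regardless_of_atoms(self):
        atoms = make_atoms(np.zeros((5, 3)) + np.arange(5)[:, None], atoms_per_residue=5)
        cmap = ConservationMap(grades={("A", 1, ""): 7})
        assert conservation_score(make_pocket(atoms), cmap) == 7

    def test_no_grade_overlap_scores_zero(self):
        atoms = make_atoms([[0, 0, 0]])
        assert conservation_score(make_pocket(atoms), ConservationMap()) == 0

    def test_mean_aggregate_option(self):
        atoms = make_atoms([[0, 0, 0], [3, 0, 0]])
        cmap = ConservationMap(grades={("A", 1, ""): 6, ("A", 2, ""): 8})
        assert conservation_score(make_pocket(atoms), cmap, aggregate="mean") == 7.0


class TestPocketVolume:
    def test_single_sphere_closed_form(self):
        atoms = make_atoms([[0.1, 0.2, 0.3]])
        vol = pocket_volume(make_pocket(atoms), {a.serial: a for a in atoms}, 0.25)
        assert vol == pytest.approx(sphere_volume(INFLATED_C), rel=0.05)

    def test_disjoint_spheres_additive(self):
        atoms = make_atoms([[0, 0, 0], [50, 0, 0]])
        vol = pocket_volume(make_pocket(atoms), {a.serial: a for a in atoms}, 0.25)
        assert vol == pytest.approx(2 * sphere_volume(INFLATED_C), rel=0.05)

    def test_overlapping_spheres_match_lens_formula(self):
        d = 3.0
        atoms = make_atoms([[0, 0, 0], [d, 0, 0]])
        vol = pocket_volume(make_pocket(atoms), {a.serial: a for a in atoms}, 0.25)
        expected = two_sphere_union_volume(INFLATED_C, INFLATED_C, d)
        assert vol == pytest.approx(expected, rel=0.05)

    def test_monotone_under_adding_atoms(self):
        small = make_atoms([[0, 0, 0], [3, 0, 0]])
        big = make_atoms([[0, 0, 0], [3, 0, 0], [6, 0, 0]])
        v_small = pocket_volume(make_pocket(small), {a.serial: a for a in small}, 0.5)
        v_big = pocket_volume(make_pocket(big), {a.serial: a for a in big}, 0.5)
        assert v_big >= v_small

    def test_translation_consistency_within_voxel_shell(self):
        atoms = make_atoms([[0, 0, 0], [2, 1, 0]])
        moved = make_atoms([[7.3, -2.1, 4.9], [9.3, -1.1, 4.9]])
        v1 = pocket_volume(make_pocket(atoms), {a.serial: a for a in atoms}, 0.5)
        v2 = pocket_volume(make_pocket(moved), {a.serial: a for a in moved}, 0.5)
        assert v2 == pytest.approx(v1, rel=0.05)

    def test_bad_grid_step_raises(self):
        atoms = make_atoms([[0, 0, 0]])
        with pytest.raises(ParameterError):
            pocket_volume(make_pocket(atoms), {a.serial: a for a in atoms}, 0.0)


class TestRankPockets:
    def _pockets_with_scores(self):
        """Three pockets: scores 24, 30, 24 with sizes 10, 5, 12."""
        pockets, cmap_grades = [], {}
        serial = 0
        for idx, (score, size) in enumerate([(24, 10), (30, 5), (24, 12)], start=1):
            atoms = []
            for k in range(size):
                serial += 1
                atoms.append(serial)
            residues = frozenset(
                ResidueKey("A", 100 * idx + k, "", "GLY") for k in range(size)
            )
            # grade the first few residues so the sum equals the target score
            res_sorted = sorted(residues)
            q, r = divmod(score, 8)
            for r_i in res_sorted[:q]:
                cmap_grades[r_i.res_id] = 8
            if r:
                cmap_grades[res_sorted[q].res_id] = r
            pockets.append(
                Pocket(
                    member_atoms=frozenset(atoms),
                    member_residues=residues,
                    center=np.zeros(3),
                )
            )
        return pockets, ConservationMap(grades=cmap_grades)

    def test_tie_break_by_size_then_serial(self):
        pockets, cmap = self._pockets_with_scores()
        ranked = rank_pockets(pockets, "conservation", cmap=cmap)
        assert [p.conservation_score for p in ranked.pockets] == [30, 24, 24]
        assert [p.n_atoms for p in ranked.pockets] == [5, 12, 10]
        assert [p.rank for p in ranked.pockets] == [1, 2, 3]

    def test_single_pocket_rank_one(self):
        atoms = make_atoms([[0, 0, 0]])
        cmap = ConservationMap(grades={("A", 1, ""): 5})
        ranked = rank_pockets([make_pocket(atoms)], "conservation", cmap=cmap)
        assert ranked.pockets[0].rank == 1

    def test_ranking_is_permutation(self):
        pockets, cmap = self._pockets_with_scores()
        ranked = rank_pockets(list(pockets), "conservation", cmap=cmap)
        assert {p.member_atoms for p in ranked.pockets} == {
            p.member_atoms for p in pockets
        }

    def test_unknown_method_raises(self):
        with pytest.raises(ParameterError):
            rank_pockets([], "energy")

    def test_conserved_vs_large_pocket_ranking_contrast(self):
        """A small deeply conserved pocket and a big unconserved cleft
        swap places between the two ranking schemes."""
        small = make_atoms([[0, 0, 0], [3, 0, 0], [6, 0, 0]])
        big = make_atoms(
            [[50 + 4 * i, 4 * j, 0] for i in range(3) for j in range(3)],
            start_serial=10,
            chain="B",
        )
        cmap = ConservationMap(
            grades={("A", i, ""): 9 for i in range(1, 4)}
            | {("B", i, ""): 1 for i in range(1, 10)}
        )
        pockets = [make_pocket(small), make_pocket(big)]
        atoms_by_serial = {a.serial: a for a in small + big}
        by_cons = rank_pockets(
            list(pockets), "conservation", cmap=cmap, atoms_by_serial=atoms_by_serial
        )
        by_vol = rank_pockets(
            list(pockets), "volume", cmap=cmap, atoms_by_serial=atoms_by_serial
        )
        assert by_cons.pockets[0].member_atoms == pockets[0].member_atoms
        assert by_vol.pockets[0].member_atoms == pockets[1].member_atoms
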