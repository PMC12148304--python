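"""Unit-cell math, symmetry expansion and clash filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fibrilforge as ff
from fibrilforge.crystal import Transform, has_clash, orientation_matrix
from fibrilforge.pdbio import PDBFormatError, Structure, write_pdb

from conftest import random_copy_system
from oracles import brute_force_copies, count_clash_pairs, random_valid_cell, triclinic_volume


def single_atom_structure(pos=(0.0, 0.0, 0.0), element="C"):
    return Structure(
        serial=np.array([1]), name=np.array(["CA"]), resname=np.array(["GLY"]),
        chain_id=np.array(["A"]), resseq=np.array([1]),
        element=np.array([element]), coords=np.array([pos], dtype=float),
    )


class TestParseTemplate:
    def test_cubic_identity_cell(self):
        text = write_pdb(single_atom_structure(),
                         cell=ff.UnitCell(10, 10, 10, 90, 90, 90, "P 1"))
        chains, cell = ff.parse_template(text)
        assert (cell.a, cell.b, cell.c) == (10, 10, 10)
        assert (cell.alpha, cell.beta, cell.gamma) == (90, 90, 90)
        assert cell.space_group == "P 1"

    def test_chain_grouping_and_atom_count(self, ideal_helix):
        text = write_pdb(ideal_helix, cell=ff.UnitCell(50, 50, 120, 90, 90, 90))
        chains, _ = ff.parse_template(text)
        assert len(chains) == 3
        assert sum(len(c) for c in chains) == text.count("\nATOM") + text.startswith("ATOM")

    def test_missing_cryst1_rejected(self, ideal_helix):
        with pytest.raises((PDBFormatError, ValueError), match="crystallographic"):
            ff.parse_template(write_pdb(ideal_helix))

    def test_template_roundtrip(self, template_text):
        chains, cell = ff.parse_template(template_text)
        merged = np.concatenate([c.coords for c in chains])
        text2 = write_pdb(
            Structure(
                serial=np.arange(1, len(merged) + 1),
                name=np.concatenate([c.name for c in chains]),
                resname=np.concatenate([c.resname for c in chains]),
                chain_id=np.concatenate([c.chain_id for c in chains]),
                resseq=np.concatenate([c.resseq for c in chains]),
                element=np.concatenate([c.element for c in chains]),
                coords=merged,
            ), cell=cell)
        chains2, cell2 = ff.parse_template(text2)
        merged2 = np.concatenate([c.coords for c in chains2])
        assert np.abs(merged2 - merged).max() < 1e-3
        assert cell2 == cell


class TestOrientationMatrix:
    def test_orthogonal_cell_is_diagonal(self):
        om = orientation_matrix(ff.UnitCell(10, 10, 10, 90, 90, 90))
        assert np.allclose(om.C, np.diag([10.0, 10.0, 10.0]))

    def test_monoclinic_entries_by_hand(self):
        om = orientation_matrix(ff.UnitCell(10, 20, 30, 90, 90, 120))
        assert om.C[0, 1] == pytest.approx(20 * np.cos(np.radians(120)))
        assert om.C[1, 1] == pytest.approx(20 * np.sin(np.radians(120)))
        assert om.C[0, 0] == 10.0
        assert np.allclose(om.C, np.triu(om.C))

    def test_determinant_is_triclinic_volume(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            cell = random_valid_cell(rng)
            om = orientation_matrix(cell)
            vol = triclinic_volume(cell.a, cell.b, cell.c,
                                   cell.alpha, cell.beta, cell.gamma)
            assert np.linalg.det(om.C) == pytest.approx(vol, rel=1e-9)

    def test_fractional_cartesian_roundtrip(self):
        rng = np.random.default_rng(11)
        cell = random_valid_cell(rng)
        om = orientation_matrix(cell)
        x = rng.normal(size=(50, 3)) * 30
        assert np.abs(om.to_cartesian(om.to_fractional(x)) - x).max() < 1e-9

    def test_degenerate_cell_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            orientation_matrix(ff.UnitCell(10, 10, 10, 10, 170, 90))


class TestTransforms:
    def test_identity_preserves_positions(self, ideal_helix):
        out = ff.apply_transform(ideal_helix, Transform())
        assert np.array_equal(out.coords, ideal_helix.coords)
        assert np.array_equal(out.name, ideal_helix.name)

    def test_translation(self):
        st_ = single_atom_structure((1.0, 1.0, 1.0))
        out = ff.apply_transform(st_, Transform(np.eye(3), [5, 0, 0]))
        assert np.allclose(out.coords[0], [6, 1, 1])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_inverse_roundtrip(self, seed):
        rng = np.random.default_rng(seed)
        # random proper rotation via QR
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        T = Transform(q, rng.normal(size=3) * 10)
        x = rng.normal(size=(20, 3))
        assert np.abs(T.inverse()(T(x)) - x).max() < 1e-9


class TestEnumerateSymmetryCopies:
    def test_small_cutoff_returns_identity_only(self):
        cell = ff.UnitCell(10, 10, 10, 90, 90, 90)
        out = ff.enumerate_symmetry_copies(single_atom_structure(), cell, 1.0)
        assert len(out) == 1 and out[0].is_identity

    def test_cubic_face_neighbors_at_exact_cutoff(self):
        # single atom, d_c = 10: the six axial neighbors sit exactly at
        # 10 Å (included), corner/edge neighbors at ≥ √200 (excluded)
        cell = ff.UnitCell(10, 10, 10, 90, 90, 90)
        out = ff.enumerate_symmetry_copies(single_atom_structure(), cell, 10.0)
        assert len(out) == 7
        lattice = sorted(tuple(np.round(T.t / 10).astype(int)) for T in out)
        assert lattice == brute_force_copies(np.zeros((1, 3)), cell, 10.0)

    def test_matches_bruteforce_on_random_cells(self):
        rng = np.random.default_rng(42)
        for _ in range(15):
            cell = random_valid_cell(rng)
            coords = rng.uniform(0, 5, size=(4, 3))
            d_c = rng.uniform(1.0, 0.9 * min(cell.a, cell.b, cell.c))
            got = ff.enumerate_symmetry_copies(
                Structure(
                    serial=np.arange(4), name=np.full(4, "CA"),
                    resname=np.full(4, "GLY"), chain_id=np.full(4, "A"),
                    resseq=np.arange(4), element=np.full(4, "C"), coords=coords,
                ), cell, d_c)
            om = orientation_matrix(cell)
            got_idx = sorted(tuple(np.round(om.inverse @ T.t).astype(int)) for T in got)
            assert got_idx == brute_force_copies(coords, cell, d_c)

    def test_copy_set_monotone_in_contact_distance(self):
        cell = ff.UnitCell(12, 9, 14, 85, 95, 100)
        st_ = single_atom_structure()
        prev: set = set()
        for d_c in (2.0, 8.0, 12.0, 20.0):
            cur = {tuple(np.round(T.t, 6)) for T in
                   ff.enumerate_symmetry_copies(st_, cell, d_c)}
            assert prev <= cur
            prev = cur

    def test_unknown_space_group_rejected(self):
        cell = ff.UnitCell(10, 10, 10, 90, 90, 90, "NOT A GROUP")
        with pytest.raises(ValueError, match="unknown space group"):
            ff.enumerate_symmetry_copies(single_atom_structure(), cell, 5.0)


class TestRemoveClashes:
    def test_distant_copies_retained(self):
        a = single_atom_structure((0, 0, 0))
        b = single_atom_structure((100, 0, 0))
        res = ff.remove_clashes([a, b])
        assert res.kept_indices == [0, 1]

    def test_superposed_copy_removed_identity_kept(self):
        a = single_atom_structure()
        res = ff.remove_clashes([a, a.copy()])
        assert res.kept_indices == [0]
        assert res.removed_indices == [1]

    def test_matches_bruteforce_on_random_systems(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            copies = random_copy_system(rng, n_copies=5, n_atoms=10, box=18.0)
            res = ff.remove_clashes(copies)
            assert count_clash_pairs(res.kept) == 0
            # greedy-order equivalence: re-running on the kept set keeps all
            res2 = ff.remove_clashes(res.kept)
            assert res2.kept_indices == list(range(len(res.kept)))

    def test_grid_and_bruteforce_paths_agree(self):
        rng = np.random.default_rng(5)
        copies = random_copy_system(rng, n_copies=6, n_atoms=30, box=22.0)
        res_a = ff.remove_clashes(copies, brute_force_threshold=10 ** 6)
        res_b = ff.remove_clashes(copies, brute_force_threshold=0)
        assert res_a.kept_indices == res_b.kept_indices

    def test_has_clash_threshold(self):
        # two carbons: clash iff distance < 0.6·(1.7+1.7) = 2.04
        r = np.array([1.7])
        a = np.zeros((1, 3))
        assert has_clash(a, r, np.array([[2.0, 0, 0]]), r)
        assert not has_clash(a, r, np.array([[2.1, 0, 0]]), r)
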