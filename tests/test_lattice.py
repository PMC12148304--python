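"""Bravais-lattice mapping, layer optimization and packing statistics."""

import numpy as np
import pytest

import fibrilforge as ff
from fibrilforge.lattice import LatticeError, SolutionSpace, layer_candidates
from fibrilforge.crystal import orientation_matrix
from fibrilforge.fixtures import make_lattice_system

from oracles import random_valid_cell


class TestMapToLattice:
    def test_forward_inverse_identity(self):
        om = orientation_matrix(ff.UnitCell(12, 15, 30, 80, 95, 100))
        t = om.C @ np.array([1.0, 2.0, 3.0])
        assert np.array_equal(ff.map_to_lattice(t, om), [1, 2, 3])

    def test_zero_translation(self):
        om = orientation_matrix(ff.UnitCell(10, 10, 10, 90, 90, 90))
        assert np.array_equal(ff.map_to_lattice(np.zeros(3), om), [0, 0, 0])

    def test_roundtrip_random_cells(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            cell = random_valid_cell(rng)
            om = orientation_matrix(cell)
            n = rng.integers(-20, 21, size=3)
            assert np.array_equal(ff.map_to_lattice(om.C @ n.astype(float), om), n)

    def test_off_lattice_translation_rejected(self):
        om = orientation_matrix(ff.UnitCell(10, 10, 10, 90, 90, 90))
        with pytest.raises(LatticeError, match="off Bravais lattice"):
            ff.map_to_lattice(np.array([5.0, 0.0, 0.0]), om)


class TestLayerCandidates:
    def test_rectangle_minus_occupied(self):
        system = make_lattice_system((3, 3, 1))
        # keep only (0,0) and (2,2) in layer 0
        system.molecules = [m for m in system.molecules
                            if tuple(m.lattice_point[:2]) in ((0, 0), (2, 2))]
        cands = layer_candidates(system, 0, SolutionSpace(0, 0, 1))
        assert len(cands) == 7
        assert (1, 1, 0) in cands and (0, 0, 0) not in cands

    def test_full_rectangle_has_no_candidates(self):
        system = make_lattice_system((3, 2, 1))
        assert layer_candidates(system, 0, SolutionSpace(0, 0, 1)) == set()

    def test_single_point_degenerate_rectangle(self):
        system = make_lattice_system((1, 1, 1))
        assert layer_candidates(system, 0, SolutionSpace(0, 0, 1)) == set()


class TestOptimizeLayers:
    def test_designed_vacancies_filled_exactly(self):
        for seed in (0, 1, 99):
            vac = [(1, 1, 0), (0, 2, 3)]
            system = make_lattice_system((3, 3, 4), vacancies=vac, seed=seed)
            n0 = system.n_molecules
            reports = ff.optimize_layers(system, SolutionSpace(0, 0, 2), seed=seed)
            assert system.n_molecules == n0 + 2
            filled = system.occupied()
            assert all(tuple(v) in filled for v in vac)
            assert sum(r.accepted for r in reports) == 2

    def test_delta_zero_leaves_system_unchanged(self):
        system = make_lattice_system((3, 3, 4), vacancies=[(1, 1, 0)])
        before = system.occupied()
        reports = ff.optimize_layers(system, SolutionSpace(0, 0, 0), seed=0)
        assert system.occupied() == before
        assert reports == []

    def test_never_removes_molecules_and_connectivity_non_decreasing(self):
        system = make_lattice_system((3, 3, 4), vacancies=[(1, 1, 0), (2, 0, 3)])
        ids_before = {m.model_id for m in system.molecules}
        both0, one0, _ = ff.connectivity_stats(system)
        ff.optimize_layers(system, SolutionSpace(0, 0, 2), seed=5)
        both1, one1, _ = ff.connectivity_stats(system)
        assert ids_before <= {m.model_id for m in system.molecules}
        assert both1 + one1 >= both0 + one0

    def test_accepted_molecules_satisfy_contact_criterion(self):
        system = make_lattice_system((3, 3, 4), vacancies=[(1, 1, 0)])
        ids0 = {m.model_id for m in system.molecules}
        ff.optimize_layers(system, SolutionSpace(0, 0, 2), seed=2)
        added = [m for m in system.molecules if m.model_id not in ids0]
        assert added
        for new in added:
            dmin = min(
                np.linalg.norm(new.site_coords()[:, None, :]
                               - other.site_coords()[None, :, :], axis=2).min()
                for other in system.molecules if other.model_id != new.model_id
                and len(other.site_coords())
            )
            assert dmin < 3.0

    def test_candidates_beyond_cutoff_rejected_by_distance(self):
        # neighboring reactive atoms sit 2 Å apart in this fixture:
        # accepted at the 3 Å contact cutoff, rejected below 2 Å
        vac = [(1, 1, 0)]
        system = make_lattice_system((3, 3, 1), vacancies=vac)
        reports = ff.optimize_layers(system, SolutionSpace(0, 0, 1),
                                     contact_cutoff=1.9, seed=0)
        assert sum(r.accepted for r in reports) == 0
        assert sum(r.rejected_distance for r in reports) == 1
        reports = ff.optimize_layers(system, SolutionSpace(0, 0, 1),
                                     contact_cutoff=3.0, seed=0)
        assert sum(r.accepted for r in reports) == 1


class TestConnectivity:
    def test_single_molecule_unconnected(self):
        system = ff.make_fibril(1)
        assert ff.connectivity_stats(system) == (0.0, 0.0, 1.0)

    def test_pair_linked_at_one_end(self):
        system = ff.make_fibril(2)
        # strip the C-terminal sites: pair remains linked at N only
        for m in system.molecules:
            m.sites = [s for s in m.sites if s.terminus == "N"]
        assert ff.connectivity_stats(system) == (0.0, 1.0, 0.0)

    def test_designed_full_connectivity(self):
        system = ff.make_fibril(20)
        assert ff.connectivity_stats(system) == (1.0, 0.0, 0.0)

    def test_fractions_sum_to_one(self):
        system = ff.make_fibril(7)  # odd: one unpaired molecule
        both, one, none = ff.connectivity_stats(system)
        assert both + one + none == pytest.approx(1.0, abs=1e-9)
        assert none == pytest.approx(1 / 7)


class TestDensityProfile:
    def test_uniform_grid_flat_density_zero_std(self):
        system = make_lattice_system((5, 5, 2))
        prof = ff.density_profile(system, shells=4)
        assert prof.occupancy_std == 0.0

    def test_vacancies_raise_occupancy_std_and_optimizer_lowers_it(self):
        vac = [(0, 0, 0), (2, 2, 0), (4, 0, 3)]
        system = make_lattice_system((5, 5, 4), vacancies=vac)
        std_before = ff.density_profile(system).occupancy_std
        assert std_before > 0.0
        ff.optimize_layers(system, SolutionSpace(0, 0, 2), seed=0)
        std_after = ff.density_profile(system).occupancy_std
        assert std_after < std_before

    def test_central_density_ratio_on_constructed_fixture(self):
        # dense 3×3 core plus sparse ring: inner shells denser than outer
        system = make_lattice_system((9, 9, 1))
        system.molecules = [
            m for m in system.molecules
            if max(abs(m.lattice_point[0] - 4), abs(m.lattice_point[1] - 4)) <= 1
            or (m.lattice_point[0] + m.lattice_point[1]) % 2 == 0
        ]
        # recenter lattice on the dense core
        for m in system.molecules:
            m.lattice_point = m.lattice_point - np.array([4, 4, 0])
            m.transform = ff.Transform(np.eye(3), system.orientation.C
                                       @ m.lattice_point.astype(float))
        prof = ff.density_profile(system, shells=np.array([0.0, 25.0, 70.0]))
        assert prof.density[0] > prof.density[1]
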