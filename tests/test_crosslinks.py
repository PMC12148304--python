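"""Crosslink registry, mixing, removal and link detection."""

import numpy as np
import pytest

import fibrilforge as ff
from fibrilforge.crosslinks import (CrosslinkType, CrosslinkUnit, MixSpec,
                                    derive_units, load_registry)
from fibrilforge.fixtures import make_fibril


class TestRegistry:
    def test_builtin_types(self):
        reg = load_registry()
        assert reg["HLKNL"].valence == "divalent"
        assert len(reg["HLKNL"].residues) == 2
        assert reg["PYD"].valence == "trivalent"
        assert len(reg["PYD"].residues) == 3

    def test_valence_member_count_enforced(self):
        with pytest.raises(ValueError, match="exactly 3"):
            CrosslinkType("BAD", "trivalent", ("A", "B"), {"A": ["NZ"]})
        with pytest.raises(ValueError, match="must have 2"):
            CrosslinkUnit("HLKNL", "divalent", "N", [(0, "A", 1)])

    def test_user_extension(self, tmp_path):
        extra = tmp_path / "extra.yaml"
        extra.write_text(
            "types:\n  GLUC:\n    valence: divalent\n"
            "    residues: [GLK, GLK]\n"
            "    reactive_atoms:\n      GLK: [NZ]\n")
        reg = load_registry(str(extra))
        assert "GLUC" in reg and "PYD" in reg


class TestAssignMix:
    def test_degenerate_weights_assign_single_class(self):
        system = make_fibril(12)
        counts = ff.assign_mix(system, MixSpec({"PYD": 1.0, "HLKNL": 0.0}), seed=0)
        assert counts == {"HLKNL": 0, "PYD": 12}
        assert all(m.crosslink_class == "PYD" for m in system.molecules)
        # member residues renamed to the registry code
        assert all("PYD" in set(m.structure.resname) for m in system.molecules)

    def test_equal_four_class_mix_binomial(self):
        system = make_fibril(10000, body_residues=2)
        mix = MixSpec({"HLKNL-HLKNL": 1, "PYD-HLKNL": 1, "HLKNL-PYD": 1, "PYD-PYD": 1})
        counts = ff.assign_mix(system, mix, seed=7)
        n, p = 10000, 0.25
        sigma = np.sqrt(n * p * (1 - p))
        for c in counts.values():
            assert abs(c - n * p) < 3 * sigma

    def test_fifty_fifty_pyd_hlknl(self):
        system = make_fibril(10000, body_residues=2)
        counts = ff.assign_mix(system, MixSpec({"PYD": 0.5, "HLKNL": 0.5}), seed=3)
        n, p = 10000, 0.5
        assert abs(counts["PYD"] - n * p) < 3 * np.sqrt(n * p * (1 - p))

    def test_reproducible_under_seed(self):
        mix = MixSpec({"PYD": 0.5, "HLKNL": 0.5})
        c1 = ff.assign_mix(make_fibril(100), mix, seed=11)
        c2 = ff.assign_mix(make_fibril(100), mix, seed=11)
        assert c1 == c2

    def test_unknown_class_rejected(self):
        system = make_fibril(2)
        with pytest.raises(KeyError, match="not in crosslink library"):
            ff.assign_mix(system, MixSpec({"NOPE": 1.0}), seed=0)

    def test_mix_parse_and_normalization(self):
        mix = MixSpec.parse("PYD=2,HLKNL=2")
        assert mix.weights == {"PYD": 0.5, "HLKNL": 0.5}


class TestRemoveCrosslinks:
    def test_rate_zero_is_identity(self):
        system = make_fibril(10)
        n_units = len(system.crosslink_units)
        atoms = [m.structure.coords.copy() for m in system.molecules]
        rep = ff.remove_crosslinks(system, 0.0, seed=0)
        assert rep.removed_units == 0
        assert len(system.crosslink_units) == n_units
        for m, c in zip(system.molecules, atoms):
            assert np.array_equal(m.structure.coords, c)

    def test_rate_point_three_leaves_seventy_percent(self):
        system = make_fibril(20)  # 20 crosslink units
        rep = ff.remove_crosslinks(system, 0.3, seed=4)
        assert rep.total_units == 20
        assert rep.removed_units == 6
        assert rep.remaining_fraction == pytest.approx(0.7)
        assert len(system.crosslink_units) == 14

    def test_rate_one_removes_everything_and_disconnects(self):
        system = make_fibril(10)
        rep = ff.remove_crosslinks(system, 1.0, seed=0)
        assert rep.remaining_units == 0
        assert ff.connectivity_stats(system) == (0.0, 0.0, 1.0)

    def test_members_removed_together_and_mutated_to_lysine(self):
        system = make_fibril(4)
        unit = system.crosslink_units[0]
        # force selection of exactly this unit
        system.crosslink_units = [unit]
        ff.remove_crosslinks(system, 1.0, seed=0)
        for model_id, chain_id, resseq in unit.members:
            mol = next(m for m in system.molecules if m.model_id == model_id)
            idx = mol.structure.residue_atoms(chain_id, resseq)
            assert set(mol.structure.resname[idx]) == {"LYS"}

    def test_atom_count_conserved_outside_selected_residues(self):
        system = make_fibril(6)
        per_res_before = {}
        for m in system.molecules:
            for ch, rs, rn, idx in m.structure.iter_residues():
                per_res_before[(m.model_id, ch, rs)] = (rn, len(idx))
        removed = ff.remove_crosslinks(system, 0.5, seed=1).removed
        mutated = {(mid, ch, rs) for u in removed for mid, ch, rs in u.members}
        for m in system.molecules:
            for ch, rs, rn, idx in m.structure.iter_residues():
                if (m.model_id, ch, rs) not in mutated:
                    assert (rn, len(idx)) == per_res_before[(m.model_id, ch, rs)]

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            ff.remove_crosslinks(make_fibril(2), 1.5, seed=0)

    def test_bernoulli_mode_rate_extremes(self):
        assert ff.remove_crosslinks(make_fibril(10), 0.0, seed=0,
                                    mode="bernoulli").removed_units == 0
        assert ff.remove_crosslinks(make_fibril(10), 1.0, seed=0,
                                    mode="bernoulli").remaining_units == 0

    def test_full_backbone_lysine_rebuild(self):
        # mutate a helix residue that has a complete backbone
        from fibrilforge.crosslinks import _mutate_to_lysine
        helix = ff.make_triple_helix()
        out = _mutate_to_lysine(helix, "A", 2)  # PRO -> LYS
        idx = out.residue_atoms("A", 2)
        names = set(out.name[idx])
        assert {"N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ"} <= names
        # backbone untouched
        for nm in ("N", "CA", "C", "O"):
            i_old = helix.atom_index("A", 2, nm)
            i_new = out.atom_index("A", 2, nm)
            assert np.array_equal(helix.coords[i_old], out.coords[i_new])


class TestDetectLinks:
    def test_threshold_behavior(self):
        system = make_fibril(2)
        a, b = system.molecules
        links = ff.detect_links(a, b, cutoff=3.0)
        assert links and all(d < 3.0 for _, _, d in links)
        assert ff.detect_links(a, b, cutoff=1.9) == []

    def test_symmetry(self):
        system = make_fibril(4)
        a, b = system.molecules[0], system.molecules[1]
        ab = {(round(d, 9)) for _, _, d in ff.detect_links(a, b)}
        ba = {(round(d, 9)) for _, _, d in ff.detect_links(b, a)}
        assert ab == ba

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(9)
        system = make_fibril(6)
        for i in range(len(system.molecules)):
            for j in range(i + 1, len(system.molecules)):
                a, b = system.molecules[i], system.molecules[j]
                got = len(ff.detect_links(a, b, cutoff=4.0))
                expected = 0
                for sa in a.sites:
                    for sb in b.sites:
                        d = np.linalg.norm(
                            sa.positions(a.structure)[:, None, :]
                            - sb.positions(b.structure)[None, :, :], axis=2).min()
                        expected += d < 4.0
                assert got == expected

    def test_derive_units_uses_each_site_once(self):
        system = make_fibril(12)
        units = derive_units(system)
        seen = set()
        for u in units:
            for member in u.members:
                assert member not in seen
                seen.add(member)
        # valence bookkeeping
        for u in units:
            assert len(u.members) == {"divalent": 2, "trivalent": 3}[u.valence]
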