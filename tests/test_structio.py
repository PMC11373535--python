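import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csens import synthdata
from csens.errors import SelectionError, StructureMismatchError
from csens.structio import (
    Conformer,
    ConformerGroup,
    backbone_dihedrals,
    delta_dihedral,
    per_atom_alignability,
    radius_of_gyration,
    read_conformers,
    select_extreme_frames,
    select_neighbors,
    superpose,
    superposed_rmsd,
    wrap_angle,
    write_conformers,
)

from conftest import toy_conformer


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

class TestReadConformers:
    def test_single_model_identity(self, tmp_path, small_groups):
        central = small_groups[0].central
        path = tmp_path / "one.pdb"
        write_conformers(path, [central])
        back = read_conformers(path)
        assert len(back) == 1
        assert len(back[0]) == len(central)
        assert back[0].atom_signature() == central.atom_signature()

    def test_multi_model_ordering(self, tmp_path, small_groups):
        members = small_groups[0].members
        path = tmp_path / "multi.pdb"
        write_conformers(path, members)
        back = read_conformers(path)
        assert len(back) == len(members)
        sig = back[0].atom_signature()
        assert all(c.atom_signature() == sig for c in back)
        np.testing.assert_allclose(back[2].coords, members[2].coords, atol=1e-3)

    def test_water_flags_counted(self, tmp_path):
        spec = synthdata.SyntheticSpec(n_residues=4, seed=5, n_waters=3)
        gs, _ = synthdata.make_conformer_groups(spec)
        path = tmp_path / "wet.pdb"
        write_conformers(path, [gs.central])
        back = read_conformers(path)[0]
        # hand count: 3 waters x 3 atoms each
        assert sum(a.is_water for a in back.atoms) == 9
        assert sum(a.is_cap for a in back.atoms) == 12  # ACE(6) + NME(6)

    def test_inconsistent_models_raise(self, tmp_path):
        text = (
            "MODEL        1\n"
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CB  ALA A   1       1.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\n"
            "MODEL        2\n"
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\nEND\n"
        )
        path = tmp_path / "bad.pdb"
        path.write_text(text)
        with pytest.raises(StructureMismatchError):
            read_conformers(path)


# ---------------------------------------------------------------------------
# radius of gyration
# ---------------------------------------------------------------------------

class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        c = toy_conformer([[1.0, 2.0, 3.0]])
        assert radius_of_gyration(c, selection=[0]) == 0.0

    def test_two_atoms_symmetric(self):
        c = toy_conformer([[0, 0, 0], [2, 0, 0]])
        assert radius_of_gyration(c, selection=[0, 1]) == pytest.approx(1.0)

    def test_matches_direct_mass_weighted_formula(self, small_groups):
        conf = small_groups[0].central
        sel = conf.backbone_heavy_indices()
        # independent oracle: explicit sum over atoms
        masses = np.array([conf.atoms[i].mass for i in sel])
        coords = conf.coords[sel]
        com = (masses[:, None] * coords).sum(axis=0) / masses.sum()
        expected = math.sqrt(
            float((masses * ((coords - com) ** 2).sum(axis=1)).sum() / masses.sum())
        )
        assert radius_of_gyration(conf) == pytest.approx(expected, abs=1e-12)

    def test_empty_selection_raises(self, small_groups):
        with pytest.raises(SelectionError):
            radius_of_gyration(small_groups[0].central, selection=[])

    def test_rigid_motion_invariance(self, small_groups):
        rng = np.random.default_rng(0)
        conf = small_groups[0].central
        base = radius_of_gyration(conf)
        from scipy.spatial.transform import Rotation

        for _ in range(5):
            rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
            moved = conf.with_coords(conf.coords @ rot.as_matrix().T + rng.normal(size=3))
            assert radius_of_gyration(moved) == pytest.approx(base, abs=1e-8)


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

class TestSuperpose:
    def test_identical_zero_rmsd(self, small_groups):
        conf = small_groups[0].central
        _, _, rmsd = superpose(conf, conf)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_rigid_rotation_zero_rmsd(self, small_groups):
        from scipy.spatial.transform import Rotation

        conf = small_groups[0].central
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = conf.with_coords(conf.coords @ rot.T + np.array([5.0, -3.0, 1.0]))
        _, _, rmsd = superpose(moved, conf)
        assert rmsd == pytest.approx(0.0, abs=1e-8)

    def test_single_displacement_matches_numeric_minimum(self):
        # large rigid set with one displaced atom; oracle: numeric optimization
        rng = np.random.default_rng(42)
        coords = rng.uniform(-10, 10, size=(40, 3))
        ref = toy_conformer(coords)
        displaced = coords.copy()
        displaced[7] += [1.0, 0.0, 0.0]
        mob = toy_conformer(displaced)
        sel = np.arange(40)
        _, _, rmsd = superpose(mob, ref, selection=sel)

        from scipy.optimize import minimize
        from scipy.spatial.transform import Rotation

        def objective(params):
            rot = Rotation.from_rotvec(params[:3]).as_matrix()
            moved = displaced @ rot.T + params[3:]
            return math.sqrt(np.mean(np.sum((moved - coords) ** 2, axis=1)))

        best = min(
            minimize(objective, x0, method="Nelder-Mead",
                     options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000}).fun
            for x0 in (np.zeros(6), np.full(6, 0.01))
        )
        assert rmsd == pytest.approx(best, abs=1e-5)
        # rmsd of 1 A displacement over N atoms scales like ~1/sqrt(N)
        assert rmsd < 1.0 / math.sqrt(40) * 1.05

    def test_underdetermined_raises(self):
        c = toy_conformer([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(SelectionError):
            superpose(c, c, selection=[0, 1, 2])  # collinear


# ---------------------------------------------------------------------------
# frame selection
# ---------------------------------------------------------------------------

class TestFrameSelection:
    def _scaled_frames(self, small_groups, factors):
        base = small_groups[0].central
        return [
            base.with_coords(base.coords * f, conformer_id=f"f{i}")
            for i, f in enumerate(factors)
        ]

    def test_extremes(self, small_groups):
        # rgyr scales linearly with the coordinates: 9.7/27.5/15.0-like ordering
        frames = self._scaled_frames(small_groups, [9.7, 27.5, 15.0])
        assert select_extreme_frames(frames) == (1, 0)

    def test_tie_breaks_lowest_index(self, small_groups):
        frames = self._scaled_frames(small_groups, [1.0, 1.0, 1.0])
        assert select_extreme_frames(frames) == (0, 0)

    def test_matches_exhaustive_scan(self, small_groups):
        rng = np.random.default_rng(7)
        frames = self._scaled_frames(small_groups, rng.uniform(0.5, 3.0, size=50))
        rgyr = [radius_of_gyration(f) for f in frames]
        assert select_extreme_frames(frames) == (int(np.argmax(rgyr)), int(np.argmin(rgyr)))


class TestSelectNeighbors:
    def test_k_zero_center_only(self, small_groups):
        members = small_groups[0].members
        group = select_neighbors(members, members[0], 0)
        assert group.members == [members[0]]
        assert group.central is members[0]

    def test_duplicate_center_ranked_first(self, small_groups):
        center = small_groups[0].central
        dup = center.with_coords(center.coords.copy(), conformer_id="dup")
        pool = list(small_groups[0].members) + [dup]
        group = select_neighbors(pool, center, 1)
        assert group.members[1] is dup

    def test_matches_exhaustive_ranking(self, small_groups):
        rng = np.random.default_rng(3)
        center = small_groups[0].central
        pool = [center] + [
            center.with_coords(center.coords + rng.normal(scale=amp, size=center.coords.shape),
                               conformer_id=f"p{i}")
            for i, amp in enumerate(rng.uniform(0.01, 2.0, size=20))
        ]
        group = select_neighbors(pool, center, 5)
        ranked = sorted(
            (c for c in pool if c is not center),
            key=lambda c: superposed_rmsd(c, center),
        )
        assert [m.conformer_id for m in group.members[1:]] == [c.conformer_id for c in ranked[:5]]

    def test_full_pool(self, small_groups):
        members = small_groups[0].members
        group = select_neighbors(members, members[0], len(members) - 1)
        assert set(id(m) for m in group.members) == set(id(m) for m in members)

    def test_negative_k_raises(self, small_groups):
        with pytest.raises(SelectionError):
            select_neighbors(small_groups[0].members, small_groups[0].central, -1)


# ---------------------------------------------------------------------------
# dihedrals
# ---------------------------------------------------------------------------

class TestBackboneDihedrals:
    @pytest.mark.parametrize("phi,psi", [(-135.0, 135.0), (-75.0, -30.0), (60.0, 40.0)])
    def test_recovers_construction_targets(self, phi, psi):
        atoms = synthdata.build_backbone("AAAAA", phi, psi)
        conf = Conformer("c", atoms)
        dih = backbone_dihedrals(conf)
        for resnum, (p, s) in dih.items():
            assert p == pytest.approx(phi, abs=1e-6)
            assert s == pytest.approx(psi, abs=1e-6)

    def test_uncapped_terminals_absent(self):
        from conftest import bare_chain

        conf = bare_chain(4)
        dih = backbone_dihedrals(conf)
        first, last = min(dih), max(dih)
        assert dih[first][0] is None and dih[first][1] is not None
        assert dih[last][1] is None and dih[last][0] is not None

    def test_mirror_image_negates(self, small_groups):
        conf = small_groups[0].central
        mirrored = conf.with_coords(conf.coords * np.array([-1.0, 1.0, 1.0]))
        for (p, s), (pm, sm) in zip(
            backbone_dihedrals(conf).values(), backbone_dihedrals(mirrored).values()
        ):
            if p is not None:
                assert pm == pytest.approx(-p, abs=1e-8)
            if s is not None:
                assert sm == pytest.approx(-s, abs=1e-8)


class TestDeltaDihedral:
    def test_wrap_around(self):
        assert delta_dihedral(170.0, -170.0) == pytest.approx(20.0)

    def test_identity_zero(self):
        assert delta_dihedral(42.0, 42.0) == 0.0

    def test_absent_propagates(self):
        assert delta_dihedral(None, 10.0) is None
        assert delta_dihedral(10.0, None) is None

    @given(
        g=st.floats(min_value=-180.0, max_value=180.0),
        s=st.floats(min_value=-180.0, max_value=180.0),
    )
    @settings(max_examples=200)
    def test_matches_bruteforce_over_k(self, g, s):
        # oracle: minimal |s - g + 360 k| over k in {-1, 0, 1}, with sign
        candidates = [s - g + 360.0 * k for k in (-1, 0, 1)]
        expected = min(candidates, key=abs)
        got = delta_dihedral(g, s)
        assert abs(got) == pytest.approx(abs(expected), abs=1e-9)
        assert abs(got) <= 180.0

    @given(
        g=st.floats(min_value=-179.0, max_value=179.0),
        s=st.floats(min_value=-179.0, max_value=179.0),
    )
    @settings(max_examples=100)
    def test_antisymmetry(self, g, s):
        d1 = delta_dihedral(g, s)
        d2 = delta_dihedral(s, g)
        assert wrap_angle(d1 + d2) == pytest.approx(0.0, abs=1e-9)


# ---------------------------------------------------------------------------
# alignability
# ---------------------------------------------------------------------------

class TestPerAtomAlignability:
    def test_identical_members_zero(self, small_spec):
        spec = synthdata.SyntheticSpec(n_residues=4, seed=1, replica_noise=0.0)
        gs, _ = synthdata.make_conformer_groups(spec)
        np.testing.assert_allclose(per_atom_alignability(gs), 0.0, atol=1e-10)

    def test_single_displaced_atom(self):
        # 5 members; one non-backbone-ish far atom displaced 1 A in one member;
        # enumerate the 10 pairs: 4 of them see distance 1 -> mean 0.4
        rng = np.random.default_rng(1)
        coords = rng.uniform(-8, 8, size=(30, 3))
        base = toy_conformer(coords)
        members = [base.with_coords(coords.copy(), conformer_id=f"m{i}") for i in range(5)]
        moved = coords.copy()
        moved[29] += [0.0, 0.0, 1.0]
        members[4] = base.with_coords(moved, conformer_id="m4")
        # superposition selection excludes the displaced atom so the fit is exact
        group = ConformerGroup("g", members, members[0])
        values = per_atom_alignability(group, selection=np.arange(29))
        np.testing.assert_allclose(values[:29], 0.0, atol=1e-8)
        assert values[29] == pytest.approx(4.0 / 10.0, abs=1e-8)

    def test_rigid_motion_invariance(self, small_groups):
        from scipy.spatial.transform import Rotation

        group = small_groups[0]
        base = per_atom_alignability(group)
        rng = np.random.default_rng(5)
        moved_members = []
        for m in group.members:
            rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
            moved_members.append(
                m.with_coords(m.coords @ rot.as_matrix().T + rng.normal(size=3))
            )
        moved_group = ConformerGroup(group.label, moved_members, moved_members[0])
        np.testing.assert_allclose(per_atom_alignability(moved_group), base, atol=1e-7)

    def test_member_order_invariance(self, small_groups):
        group = small_groups[0]
        reordered = ConformerGroup(
            group.label,
            [group.members[0]] + group.members[:0:-1],
            group.central,
        )
        np.testing.assert_allclose(
            per_atom_alignability(reordered), per_atom_alignability(group), atol=1e-10
        )

    def test_single_member_raises(self, small_groups):
        central = small_groups[0].central
        group = ConformerGroup("g", [central], central)
        with pytest.raises(SelectionError):
            per_atom_alignability(group)
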