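"""Molecular data model, XYZ I/O, bond perception, torsions, rigid poses."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pomscout.structures import (
    Molecule,
    RigidPose,
    Torsion,
    XYZParseError,
    apply_pose,
    center_of_mass,
    detect_rotatable_torsions,
    measure_torsion,
    perceive_bonds,
    read_xyz,
    set_torsions,
    wrap_angle,
    write_xyz,
)
from pomscout.periodic_data import ATOMIC_MASSES
from pomscout.synthetic import build_residue


def _methane():
    d = 1.09 / np.sqrt(3.0)
    coords = [[0, 0, 0], [d, d, d], [d, -d, -d], [-d, d, -d], [-d, -d, d]]
    return Molecule(elements=["C", "H", "H", "H", "H"], coords=np.array(coords))


def _butane():
    """n-butane, anti backbone, built from ideal internal coordinates."""
    from pomscout.synthetic import _zmat_to_molecule, _methyl, _methylene, _R, _TET

    rows = [
        ("C1", "C", None, None, None, None, None, None),
        ("C2", "C", "C1", _R["C-C"]),
        ("C3", "C", "C2", _R["C-C"], "C1", 112.0),
        ("C4", "C", "C3", _R["C-C"], "C2", 112.0, "C1", 180.0),
        *_methyl("H1", "C1", "C2", "C3"),
        *_methylene("H2", "C2", "C1", "C3"),
        *_methylene("H3", "C3", "C4", "C2"),
        *_methyl("H4", "C4", "C3", "C2"),
    ]
    mol, idx = _zmat_to_molecule(rows)
    return mol, idx


class TestXYZ:
    def test_round_trip_preserves_coordinates_and_comment(self, tmp_path, gly):
        mol = gly.molecule.copy()
        mol.comment = "glycine template"
        path = tmp_path / "gly.xyz"
        write_xyz(path, mol)
        back = read_xyz(path)
        assert back.elements == mol.elements
        assert back.comment == "glycine template"
        np.testing.assert_allclose(back.coords, mol.coords, atol=1e-6)

    def test_ch4_parses(self, tmp_path):
        path = tmp_path / "ch4.xyz"
        write_xyz(path, _methane())
        mol = read_xyz(path)
        assert mol.n_atoms == 5
        assert mol.elements == ["C", "H", "H", "H", "H"]

    @pytest.mark.parametrize(
        "content",
        [
            "",  # empty file
            "nonsense\ncomment\nC 0 0 0\n",  # malformed count
            "3\ncomment\nC 0 0 0\nH 1 0 0\n",  # count mismatch
            "1\ncomment\nXx 0 0 0\n",  # unknown element
            "1\ncomment\nC zero 0 0\n",  # non-numeric coordinate
        ],
    )
    def test_malformed_inputs_raise_with_line_number(self, tmp_path, content):
        path = tmp_path / "bad.xyz"
        path.write_text(content)
        with pytest.raises(XYZParseError, match="line"):
            read_xyz(path)

    def test_multi_frame_round_trip(self, tmp_path, gly):
        from pomscout.structures import read_xyz_frames

        frames = [gly.molecule, _methane()]
        path = tmp_path / "frames.xyz"
        write_xyz(path, frames)
        back = read_xyz_frames(path)
        assert [m.n_atoms for m in back] == [gly.molecule.n_atoms, 5]


class TestPerceiveBonds:
    def test_h2_bonded_at_074(self):
        mol = Molecule(elements=["H", "H"], coords=[[0, 0, 0], [0.74, 0, 0]])
        assert perceive_bonds(mol).bonds == [(0, 1)]

    def test_h2_unbonded_at_3A(self):
        mol = Molecule(elements=["H", "H"], coords=[[0, 0, 0], [3.0, 0, 0]])
        assert perceive_bonds(mol).bonds == []

    def test_glycine_has_nine_bonds(self, gly):
        perceived = perceive_bonds(gly.molecule)
        assert len(perceived.bonds) == 9
        assert sorted(perceived.bonds) == sorted(gly.molecule.bonds)

    def test_unknown_element_raises_with_name(self):
        mol = Molecule(elements=["H", "H"], coords=[[0, 0, 0], [1, 0, 0]])
        mol.elements[1] = "Uue"
        with pytest.raises(KeyError, match="Uue"):
            perceive_bonds(mol)


class TestRotatableTorsions:
    def test_glycine_three_torsions(self, gly):
        assert len(detect_rotatable_torsions(gly.molecule)) == 3

    def test_methane_none(self):
        assert detect_rotatable_torsions(perceive_bonds(_methane())) == []

    def test_no_bonds_gives_empty_list(self):
        mol = Molecule(elements=["He"], coords=[[0, 0, 0]])
        mol.elements = ["H"]
        assert detect_rotatable_torsions(mol) == []

    def test_butane_single_central_torsion(self):
        mol, idx = _butane()
        torsions = detect_rotatable_torsions(mol)
        assert len(torsions) == 1
        assert torsions[0].pivot == (idx["C2"], idx["C3"])

    def test_agrees_with_exhaustive_rule_application(self, gly):
        """Brute-force: apply the stated exclusion rules bond by bond."""
        from pomscout.structures import _in_ring, _is_methyl_rotor_end

        for template in ("Gly", "Leu", "Met"):
            mol = build_residue(template).molecule
            expected = []
            for b, c in sorted(mol.bonds):
                if mol.degree(b) < 2 or mol.degree(c) < 2:
                    continue
                if _is_methyl_rotor_end(mol, b, c) or _is_methyl_rotor_end(mol, c, b):
                    continue
                if _in_ring(mol, (b, c)):
                    continue
                expected.append((b, c))
            got = [t.pivot for t in detect_rotatable_torsions(mol)]
            assert got == expected


class TestSetTorsions:
    def test_identity_leaves_coordinates(self, gly):
        mol = gly.molecule
        torsions = list(gly.torsions)
        current = [measure_torsion(mol, t) for t in torsions]
        out = set_torsions(mol, torsions, current)
        np.testing.assert_allclose(out.coords, mol.coords, atol=1e-9)

    def test_full_turn_is_identity(self, gly):
        mol = gly.molecule
        t = gly.torsions[0]
        v0 = measure_torsion(mol, t)
        out = set_torsions(mol, [t], [v0 + 360.0])
        np.testing.assert_allclose(out.coords, mol.coords, atol=1e-6)

    def test_targets_hit_and_internals_preserved(self, gly):
        mol = gly.molecule
        torsions = list(gly.torsions)
        targets = [47.0, -120.0, 11.5]
        out = set_torsions(mol, torsions, targets)
        for t, target in zip(torsions, targets):
            assert abs(wrap_angle(measure_torsion(out, t) - target)) < 1e-6
        # all bond lengths unchanged
        for i, j in mol.bonds:
            d0 = np.linalg.norm(mol.coords[i] - mol.coords[j])
            d1 = np.linalg.norm(out.coords[i] - out.coords[j])
            assert abs(d0 - d1) < 1e-6

    def test_butane_anti_to_gauche_closed_form(self):
        """C1-C4 distance after driving the torsion matches the closed form
        from fixed internal coordinates r, theta."""
        mol, idx = _butane()
        (t,) = detect_rotatable_torsions(mol)
        # orient the quadruple as C1-C2-C3-C4 for the closed form
        quad = (idx["C1"], idx["C2"], idx["C3"], idx["C4"])
        r, theta = 1.53, np.radians(112.0)

        def closed_form(phi_deg):
            # distance C1-C4 in a 4-atom chain with equal r, theta
            phi = np.radians(phi_deg)
            # place the chain explicitly
            p1 = np.array([0.0, 0.0, 0.0])
            p2 = np.array([r, 0.0, 0.0])
            p3 = p2 + r * np.array([-np.cos(theta), np.sin(theta), 0.0])
            d23 = (p3 - p2) / r
            # torsion placement of p4
            n = np.array([0.0, 0.0, 1.0])
            m = np.cross(n, d23)
            local = np.array(
                [-r * np.cos(theta), r * np.sin(theta) * np.cos(phi), r * np.sin(theta) * np.sin(phi)]
            )
            p4 = p3 + local[0] * d23 + local[1] * m + local[2] * n
            return np.linalg.norm(p4 - p1)

        for phi in (180.0, 60.0, -60.0, 95.0):
            out = set_torsions(mol, [t], [phi])
            # measured torsion of the carbon quadruple matches phi up to sign
            got = measure_torsion(out, quad)
            d14 = np.linalg.norm(out.coords[quad[0]] - out.coords[quad[3]])
            assert abs(d14 - closed_form(got)) < 1e-6
        anti = np.linalg.norm(
            set_torsions(mol, [t], [180.0]).coords[quad[0]]
            - set_torsions(mol, [t], [180.0]).coords[quad[3]]
        )
        gauche = np.linalg.norm(
            set_torsions(mol, [t], [60.0]).coords[quad[0]]
            - set_torsions(mol, [t], [60.0]).coords[quad[3]]
        )
        assert gauche < anti

    def test_ring_pivot_rejected(self):
        # cyclopropane-like triangle: every bond is in a ring
        mol = Molecule(
            elements=["C", "C", "C"],
            coords=[[0, 0, 0], [1.5, 0, 0], [0.75, 1.3, 0]],
            bonds=[(0, 1), (1, 2), (0, 2)],
        )
        t = Torsion(atoms=(2, 0, 1, 2), moving_set=frozenset({2}))
        with pytest.raises(ValueError, match="ring"):
            set_torsions(mol, [t], [10.0])


class TestPose:
    def test_identity_pose(self, gly):
        mol = gly.molecule
        com = center_of_mass(mol)
        out = apply_pose(mol, RigidPose(translation=tuple(com), rotation=(0, 0, 0)))
        np.testing.assert_allclose(out.coords, mol.coords, atol=1e-9)

    def test_halfturn_about_z_flips_offset(self):
        mol = Molecule(elements=["O", "O"], coords=[[1.0, 0, 0], [-1.0, 0, 0]])
        com = center_of_mass(mol)
        out = apply_pose(mol, RigidPose(translation=tuple(com), rotation=(180, 0, 0)))
        np.testing.assert_allclose(out.coords[0], com + [-1.0, 0, 0], atol=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(
        tx=st.floats(-20, 20),
        ty=st.floats(-20, 20),
        tz=st.floats(-20, 20),
        h=st.floats(-179, 179),
        i=st.floats(-179, 179),
        j=st.floats(-179, 179),
    )
    def test_pose_is_isometry(self, gly, tx, ty, tz, h, i, j):
        mol = gly.molecule
        out = apply_pose(mol, RigidPose(translation=(tx, ty, tz), rotation=(h, i, j)))
        d0 = np.linalg.norm(mol.coords[:, None] - mol.coords[None, :], axis=-1)
        d1 = np.linalg.norm(out.coords[:, None] - out.coords[None, :], axis=-1)
        np.testing.assert_allclose(d1, d0, atol=1e-9)
        np.testing.assert_allclose(
            center_of_mass(out), [tx, ty, tz], atol=1e-9
        )


class TestCenterOfMass:
    def test_single_atom(self):
        mol = Molecule(elements=["C"], coords=[[1.0, 2.0, 3.0]])
        np.testing.assert_allclose(center_of_mass(mol), [1, 2, 3])

    def test_two_identical_atoms_midpoint(self):
        mol = Molecule(elements=["O", "O"], coords=[[0, 0, 0], [2, 0, 0]])
        np.testing.assert_allclose(center_of_mass(mol), [1, 0, 0])

    def test_water_hand_computation(self):
        coords = np.array([[0, 0, 0], [0.96, 0, 0], [-0.24, 0.93, 0]])
        mol = Molecule(elements=["O", "H", "H"], coords=coords)
        mo, mh = ATOMIC_MASSES["O"], ATOMIC_MASSES["H"]
        expected = (mo * coords[0] + mh * coords[1] + mh * coords[2]) / (mo + 2 * mh)
        np.testing.assert_allclose(center_of_mass(mol), expected, atol=1e-12)
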