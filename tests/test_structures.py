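"""PDB parsing, superposition, RMSD, radius of gyration and torsions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_rigid_transform
from etspep import structures
from etspep.structures import (Atom, Residue, Structure, dihedral, parse_pdb,
                               parse_pdb_models, per_residue_rmsd,
                               radius_of_gyration, superpose, write_pdb)


def _pdb_line(serial, name, resname, chain, resseq, x, y, z, occ=1.00, altloc=" ", element=None):
    element = element or name[0]
    return (f"ATOM  {serial:5d}  {name:<3s}{altloc}{resname:>3s} {chain}{resseq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00          {element:>2s}")


class TestParsePdb:
    def test_altloc_highest_occupancy_retained(self):
        text = "\n".join([
            _pdb_line(1, "N", "SER", "A", 1, 0, 0, 0),
            _pdb_line(2, "OG", "SER", "A", 1, 1, 0, 0, occ=0.6, altloc="A"),
            _pdb_line(3, "OG", "SER", "A", 1, 2, 0, 0, occ=0.4, altloc="B"),
        ])
        s = parse_pdb(text)
        og = s.residues[0].atom("OG")
        assert og.occupancy == pytest.approx(0.6)
        assert og.coords[0] == pytest.approx(1.0)

    def test_altloc_tie_prefers_a_deterministically(self):
        # oracle: enumerate both candidate conformers; the tie rule must pick
        # the same one regardless of file order
        for order in ((("A", 1.0), ("B", 2.0)), (("B", 2.0), ("A", 1.0))):
            lines = [_pdb_line(i + 1, "OG", "SER", "A", 1, x, 0, 0, occ=0.5, altloc=al)
                     for i, (al, x) in enumerate(order)]
            s = parse_pdb("\n".join(lines))
            assert s.residues[0].atom("OG").altloc == "A"

    def test_single_residue_identity(self):
        text = "\n".join([
            _pdb_line(1, "N", "GLY", "A", 1, 0, 0, 0),
            _pdb_line(2, "CA", "GLY", "A", 1, 1.4, 0, 0, element="C"),
        ])
        s = parse_pdb(text)
        assert [a.name for a in s.residues[0].atoms] == ["N", "CA"]

    def test_hydrogens_and_hetatm_excluded(self):
        text = "\n".join([
            _pdb_line(1, "CA", "GLY", "A", 1, 0, 0, 0, element="C"),
            _pdb_line(2, "H", "GLY", "A", 1, 1, 0, 0, element="H"),
            "HETATM    3  O   HOH A 100       0.0     0.0     0.0  1.00  0.00           O",
        ])
        s = parse_pdb(text)
        assert sum(1 for _ in s.iter_atoms()) == 1

    def test_missing_chain_names_available(self):
        text = _pdb_line(1, "CA", "GLY", "A", 1, 0, 0, 0, element="C")
        with pytest.raises(ValueError, match="available chains: A"):
            parse_pdb(text, chain="Z")

    def test_malformed_line_reports_line_number(self):
        text = "\n".join([
            _pdb_line(1, "CA", "GLY", "A", 1, 0, 0, 0, element="C"),
            "ATOM      2  CA  GLY A   2      bad coords here",
        ])
        with pytest.raises(ValueError, match="line 2"):
            parse_pdb(text)

    def test_roundtrip_idempotent(self, helix_structure):
        text = write_pdb(helix_structure)
        again = parse_pdb(text)
        assert len(again.residues) == len(helix_structure.residues)
        for r1, r2 in zip(again.residues, helix_structure.residues):
            assert (r1.chain_id, r1.seq_number, r1.res_name) == (
                r2.chain_id, r2.seq_number, r2.res_name)
            for a1, a2 in zip(r1.atoms, r2.atoms):
                assert a1.name == a2.name
                np.testing.assert_allclose(a1.coords, a2.coords, atol=1e-3)
        assert write_pdb(again) == text

    def test_multi_model_parsing(self, helix_structure):
        text = ("MODEL        1\n" + write_pdb(helix_structure).replace("END\n", "")
                + "ENDMDL\nMODEL        2\n"
                + write_pdb(helix_structure.transformed(np.eye(3), np.array([1.0, 0, 0])))
                .replace("END\n", "") + "ENDMDL\nEND\n")
        frames = parse_pdb_models(text)
        assert len(frames) == 2
        d = frames[1].residues[0].atom("N").coords - frames[0].residues[0].atom("N").coords
        np.testing.assert_allclose(d, [1.0, 0, 0], atol=1e-3)


class TestRadiusOfGyration:
    @staticmethod
    def _structure_from_points(points, element="C"):
        res = Residue("A", 1, "GLY", atoms=[
            Atom(f"C{i + 1}", element, np.asarray(p, dtype=float)) for i, p in enumerate(points)])
        return Structure(residues=[res])

    @pytest.mark.parametrize("points,expected", [
        ([(0, 0, 0), (2, 0, 0)], 1.0),                              # two atoms 2 A apart
        ([(1, 1, 1)] * 4, 0.0),                                     # coincident
        ([(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0)], math.sqrt(0.5)),  # unit square
    ])
    def test_hand_computed_values(self, points, expected):
        s = self._structure_from_points(points)
        assert radius_of_gyration(s) == pytest.approx(expected, abs=1e-12)

    def test_rigid_invariance_and_linear_scaling(self, helix_structure, rng):
        base = radius_of_gyration(helix_structure)
        rot, trans = random_rigid_transform(rng)
        assert radius_of_gyration(helix_structure.transformed(rot, trans)) == pytest.approx(base)
        scaled = helix_structure.transformed(3.0 * np.eye(3), np.zeros(3))
        assert radius_of_gyration(scaled) == pytest.approx(3.0 * base)

    def test_mass_weighting_changes_mixed_elements(self):
        res = Residue("A", 1, "CYS", atoms=[
            Atom("C", "C", np.array([0.0, 0, 0])), Atom("SG", "S", np.array([2.0, 0, 0]))])
        s = Structure(residues=[res])
        assert radius_of_gyration(s, mass_weighted=False) == pytest.approx(1.0)
        assert radius_of_gyration(s, mass_weighted=True) != pytest.approx(1.0)

    def test_empty_selection_errors(self, helix_structure):
        with pytest.raises(ValueError, match="empty"):
            radius_of_gyration(helix_structure, atom_names={"XX"})


def brute_force_min_rmsd(mobile, reference, levels=((180.0, 10.0), (12.0, 1.0), (1.5, 0.1),
                                                    (0.15, 0.01))):
    """Oracle: minimum RMSD over an Euler-angle rotation grid, refined."""
    from scipy.spatial.transform import Rotation

    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)
    centre = np.zeros(3)
    best = None
    for span, step in levels:
        g1 = np.arange(centre[0] - span, centre[0] + span + 1e-9, step)
        g2 = np.arange(centre[1] - span, centre[1] + span + 1e-9, step)
        g3 = np.arange(centre[2] - span, centre[2] + span + 1e-9, step)
        eul = np.stack(np.meshgrid(g1, g2, g3, indexing="ij"), axis=-1).reshape(-1, 3)
        mats = Rotation.from_euler("ZYX", eul, degrees=True).as_matrix()
        rotated = np.einsum("mij,nj->mni", mats, mob)
        rmsds = np.sqrt(np.mean(np.sum((rotated - ref) ** 2, axis=2), axis=1))
        i = int(np.argmin(rmsds))
        best = float(rmsds[i])
        centre = eul[i]
    return best


class TestSuperpose:
    def test_identity(self, rng):
        pts = rng.normal(size=(6, 3))
        res = superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_translation_invariance(self, rng):
        pts = rng.normal(size=(5, 3))
        res = superpose(pts + np.array([5.0, 0, 0]), pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_transform_recovered(self, rng):
        pts = rng.normal(size=(8, 3))
        rot, trans = random_rigid_transform(rng)
        res = superpose(pts @ rot.T + trans, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-8)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)

    def test_matches_brute_force_grid_oracle(self, rng):
        for _ in range(3):
            mob = rng.normal(size=(5, 3))
            ref = rng.normal(size=(5, 3))
            kabsch = superpose(mob, ref).rmsd
            grid = brute_force_min_rmsd(mob, ref)
            assert kabsch <= grid + 1e-9
            assert abs(kabsch - grid) < 1e-3

    def test_rmsd_invariant_under_rigid_motion_of_mobile(self, rng):
        mob = rng.normal(size=(7, 3))
        ref = rng.normal(size=(7, 3))
        base = superpose(mob, ref).rmsd
        rot, trans = random_rigid_transform(rng)
        assert superpose(mob @ rot.T + trans, ref).rmsd == pytest.approx(base, abs=1e-9)

    def test_reflection_not_allowed(self):
        # mirror-image point set: an improper fit would give rmsd 0, the
        # proper-rotation fit cannot
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1.5]], dtype=float)
        mirrored = pts * np.array([1, 1, -1.0])
        res = superpose(mirrored, pts)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)
        assert res.rmsd > 0.1

    def test_error_paths(self, rng):
        pts = rng.normal(size=(5, 3))
        with pytest.raises(ValueError, match="mismatch"):
            superpose(pts, pts[:4])
        with pytest.raises(ValueError, match="at least 3"):
            superpose(pts[:2], pts[:2])
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            superpose(line, line)


class TestPerResidueRmsd:
    def test_zero_for_identical(self, helix_structure):
        assert per_residue_rmsd(helix_structure, helix_structure, "A", 3) == 0.0

    def test_uniform_displacement(self, helix_structure):
        moved = helix_structure.transformed(np.eye(3), np.array([1.0, 0, 0]))
        assert per_residue_rmsd(moved, helix_structure, "A", 5) == pytest.approx(1.0)

    def test_mixed_displacements(self, helix_structure):
        import copy
        frame = copy.deepcopy(helix_structure)
        res = frame.residue("A", 4)
        # displace exactly two of the four main-chain atoms by 1 A
        res.atom("N").coords = res.atom("N").coords + np.array([1.0, 0, 0])
        res.atom("O").coords = res.atom("O").coords + np.array([0, 1.0, 0])
        assert per_residue_rmsd(frame, helix_structure, "A", 4) == pytest.approx(math.sqrt(0.5))

    def test_missing_mainchain_atom_named(self, helix_structure):
        import copy
        frame = copy.deepcopy(helix_structure)
        res = frame.residue("A", 2)
        res.atoms = [a for a in res.atoms if a.name != "O"]
        with pytest.raises(ValueError, match="atom O"):
            per_residue_rmsd(frame, helix_structure, "A", 2)


def _numeric_dihedral_oracle(a, b, c, d):
    """Independent atan2 formulation built directly from the definition."""
    a, b, c, d = (np.asarray(p, dtype=float) for p in (a, b, c, d))
    u = a - b
    axis = c - b
    v = d - c
    axis = axis / np.linalg.norm(axis)
    u_perp = u - (u @ axis) * axis
    v_perp = v - (v @ axis) * axis
    cosang = (u_perp @ v_perp) / (np.linalg.norm(u_perp) * np.linalg.norm(v_perp))
    sign = np.sign(np.cross(u_perp, v_perp) @ axis)
    ang = math.degrees(math.acos(np.clip(cosang, -1, 1)))
    # positive torsion: far bond rotated clockwise seen from the a side
    return -sign * ang if sign != 0 else ang


class TestDihedral:
    def test_planar_cis(self):
        assert dihedral((1, 0, 0), (0, 0, 0), (0, 0, 1), (1, 0, 1)) == pytest.approx(0.0)

    def test_planar_trans_is_plus_180(self):
        ang = dihedral((1, 0, 0), (0, 0, 0), (0, 0, 1), (-1, 0, 1))
        assert ang == pytest.approx(180.0)
        assert ang > 0

    def test_sign_convention_matches_independent_oracle(self, rng):
        for _ in range(25):
            pts = rng.normal(size=(4, 3)) * 3.0
            try:
                ours = dihedral(*pts)
            except ValueError:
                continue
            assert ours == pytest.approx(_numeric_dihedral_oracle(*pts), abs=1e-8)

    def test_right_handed_quarter_twist(self):
        ang = dihedral((1, 0, 0), (0, 0, 0), (0, 0, 1), (0, -1, 1))
        assert ang == pytest.approx(90.0)
        assert _numeric_dihedral_oracle((1, 0, 0), (0, 0, 0), (0, 0, 1), (0, -1, 1)) == \
            pytest.approx(90.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_symmetries_and_rigid_invariance(self, seed):
        # IUPAC torsions are invariant under path reversal and under rigid
        # motion, and change sign under mirror reflection
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(4, 3)) * 2.0
        try:
            fwd = dihedral(*pts)
        except ValueError:
            return
        assert dihedral(*pts[::-1]) == pytest.approx(fwd, abs=1e-8)
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        if abs(abs(fwd) - 180.0) > 1e-6:
            assert dihedral(*mirrored) == pytest.approx(-fwd, abs=1e-8)
        rot, trans = random_rigid_transform(rng)
        moved = pts @ rot.T + trans
        assert dihedral(*moved) == pytest.approx(fwd, abs=1e-6)

    def test_degenerate_geometry_errors(self):
        with pytest.raises(ValueError):
            dihedral((0, 0, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0))
        with pytest.raises(ValueError):
            dihedral((2, 0, 0), (1, 0, 0), (0, 0, 0), (-1, 0, 0))
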