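import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from oracles import two_sphere_sasa

from lactamscan import structmetrics as sm
from lactamscan import synthetic_data as synth

PDB_FIXTURE = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
END
"""

CIF_FIXTURE = """\
data_fixture
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_asym_id
ATOM 1 N N . ALA A 1 1 ? 0.000 0.000 0.000 1.00 0.00 1 A
ATOM 2 C CA . ALA A 1 1 ? 1.458 0.000 0.000 1.00 0.00 1 A
ATOM 3 C C . ALA A 1 1 ? 2.009 1.420 0.000 1.00 0.00 1 A
"""

ALTLOC_FIXTURE = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C
ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.60  0.00           C
END
"""


class TestStructureIO:
    def test_minimal_pdb_fixture(self, tmp_path):
        path = tmp_path / "fix.pdb"
        path.write_text(PDB_FIXTURE)
        s = sm.read_structure(path)
        assert len(s) == 3
        assert list(s.atname) == ["N", "CA", "C"]
        assert s.xyz[1] == pytest.approx([1.458, 0.0, 0.0])
        assert list(s.element) == ["N", "C", "C"]

    def test_pdb_and_mmcif_give_identical_structures(self, tmp_path):
        p1 = tmp_path / "fix.pdb"
        p2 = tmp_path / "fix.cif"
        p1.write_text(PDB_FIXTURE)
        p2.write_text(CIF_FIXTURE)
        a, b = sm.read_structure(p1), sm.read_structure(p2)
        assert list(a.atname) == list(b.atname)
        assert list(a.chain) == list(b.chain)
        assert list(a.resseq) == list(b.resseq)
        assert np.allclose(a.xyz, b.xyz)

    def test_altloc_highest_occupancy_kept(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(ALTLOC_FIXTURE)
        s = sm.read_structure(path, altloc_policy="occupancy")
        assert len(s) == 1 and s.xyz[0, 0] == pytest.approx(5.0)
        s2 = sm.read_structure(path, altloc_policy="first")
        assert s2.xyz[0, 0] == pytest.approx(0.0)

    def test_unparseable_file_rejected(self, tmp_path):
        path = tmp_path / "junk.cif"
        path.write_text("loop_ this is not a structure\n")
        with pytest.raises(ValueError):
            sm.read_structure(path)

    def test_write_read_roundtrip(self, tmp_path):
        structure, _ = synth.make_toy_structure(synth.GeneratorSpec(seed=1))
        path = tmp_path / "toy.pdb"
        sm.write_pdb(structure, path)
        back = sm.read_structure(path)
        assert len(back) == len(structure)
        assert np.allclose(back.xyz, structure.xyz, atol=1.5e-3)
        assert list(back.chain) == list(structure.chain)


class TestKabsch:
    def test_self_superposition_is_identity(self, rng):
        x = synth.random_cloud(rng, 25)
        res = sm.kabsch_superpose(x, x)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-10)

    def test_recovers_random_rigid_transforms(self, rng):
        for _ in range(20):
            x = synth.random_cloud(rng, 30)
            moved, rot, t = synth.rigid_copy(x, rng)
            res = sm.kabsch_superpose(moved, x)
            assert res.rmsd < 1e-8
            assert np.abs(res.rotation @ rot - np.eye(3)).max() < 1e-6
            # rotation stays proper and orthonormal
            assert np.abs(res.rotation @ res.rotation.T - np.eye(3)).max() < 1e-8
            assert np.linalg.det(res.rotation) == pytest.approx(1.0)

    def test_agrees_with_scipy_alignment(self, rng):
        x = synth.random_cloud(rng, 20)
        moved, _, _ = synth.rigid_copy(x, rng, noise_sigma=0.3)
        ours = sm.kabsch_superpose(moved, x)
        xc = x - x.mean(axis=0)
        mc = moved - moved.mean(axis=0)
        rot_sp, rssd = Rotation.align_vectors(xc, mc, return_sensitivity=False)[0], None
        assert np.allclose(ours.rotation, rot_sp.as_matrix(), atol=1e-6)

    def test_refinement_rejects_outlier(self, rng):
        x = synth.random_cloud(rng, 30)
        moved, _, _ = synth.rigid_copy(x, rng, noise_sigma=0.05)
        moved[7] += 25.0  # one displaced pair
        res = sm.kabsch_superpose(moved, x, refine=True)
        assert res.n_rejected >= 1
        assert res.rmsd < 0.2

    def test_collinear_set_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="degenerate"):
            sm.kabsch_superpose(line, line)

    def test_too_few_pairs_rejected(self):
        x = np.zeros((2, 3))
        with pytest.raises(ValueError, match="at least 3"):
            sm.kabsch_superpose(x, x)


class TestRmsdCa:
    def test_identical_structures_zero(self):
        s, _ = synth.make_toy_structure(synth.GeneratorSpec(seed=2))
        res = sm.rmsd_ca(s, s, chain_a="A", chain_b="A")
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert res.n_pairs == 18

    def test_exclusion_ranges_remove_pairs(self):
        s, _ = synth.make_toy_structure(synth.GeneratorSpec(seed=2))
        res = sm.rmsd_ca(s, s, chain_a="A", chain_b="A", exclude=[(1, 6)])
        assert res.n_pairs == 12

    def test_kabsch_beats_rotation_grid(self, rng):
        """Brute-force rotation grid never improves on the Kabsch optimum."""
        x = synth.random_cloud(rng, 4, scale=5.0)
        y = synth.random_cloud(rng, 4, scale=5.0)
        best = sm.kabsch_superpose(x, y).rmsd
        yc = y - y.mean(axis=0)
        xc = x - x.mean(axis=0)
        angles = np.arange(0, 360, 30)
        grid_best = math.inf
        for a in angles:
            for b in angles[: len(angles) // 2 + 1]:
                for c in angles:
                    rot = Rotation.from_euler("zyz", [a, b, c], degrees=True)
                    moved = rot.apply(xc)
                    grid_best = min(grid_best, float(np.sqrt(
                        np.mean(np.sum((moved - yc) ** 2, axis=1)))))
        assert best <= grid_best + 1e-9

    def test_empty_pairing_is_error(self):
        s, _ = synth.make_toy_structure(synth.GeneratorSpec(seed=2))
        with pytest.raises(ValueError, match="empty"):
            sm.rmsd_ca(s, s, chain_a="A", chain_b="A", exclude=[(1, 100)])


class TestSasa:
    def test_isolated_atom_matches_analytic_sphere(self):
        area = sm.sasa_points(np.zeros((1, 3)), np.array([1.70]),
                              probe=1.40, n_points=960)[0]
        exact = 4 * math.pi * 3.10 ** 2
        assert abs(area - exact) / exact < 0.005

    @pytest.mark.parametrize("d", [1.0, 2.5, 4.0, 5.9])
    def test_two_spheres_match_cap_formula(self, d):
        xyz = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, d]])
        areas = sm.sasa_points(xyz, np.array([1.7, 1.7]), 1.4, 960)
        exact = two_sphere_sasa(1.7, d, 1.4)
        assert areas[0] == pytest.approx(exact, rel=0.02)
        assert areas[1] == pytest.approx(exact, rel=0.02)

    def test_rigid_motion_invariance(self, rng):
        xyz = synth.random_cloud(rng, 25, scale=4.0)
        radii = np.full(25, 1.7)
        base = sm.sasa_points(xyz, radii)
        for _ in range(3):
            moved, _, _ = synth.rigid_copy(xyz, rng)
            got = sm.sasa_points(moved, radii)
            assert got.sum() == pytest.approx(base.sum(), rel=0.01)

    def test_point_count_convergence(self, rng):
        xyz = synth.random_cloud(rng, 30, scale=4.0)
        radii = np.full(30, 1.7)
        coarse = sm.sasa_points(xyz, radii, n_points=960).sum()
        fine = sm.sasa_points(xyz, radii, n_points=4000).sum()
        assert abs(coarse - fine) / fine < 0.01

    def test_agrees_with_biotite(self, rng):
        struc = pytest.importorskip("biotite.structure")
        n = 20
        xyz = synth.random_cloud(rng, n, scale=4.0)
        arr = struc.AtomArray(n)
        arr.coord = xyz.astype(np.float32)
        arr.element = np.array(["C"] * n)
        arr.atom_name = np.array(["CA"] * n)
        arr.res_name = np.array(["ALA"] * n)
        arr.res_id = np.arange(1, n + 1)
        arr.chain_id = np.array(["A"] * n)
        theirs = struc.sasa(arr, probe_radius=1.4, point_number=2000,
                            vdw_radii=np.full(n, 1.7))
        ours = sm.sasa_points(xyz, np.full(n, 1.7), 1.4, 2000)
        assert ours.sum() == pytest.approx(float(theirs.sum()), rel=0.02)

    def test_unknown_element_is_error(self):
        s = synth.coords_to_structure(np.zeros((1, 3)), element="QQ")
        with pytest.raises(ValueError, match="QQ"):
            sm.sasa(s)


class TestInterface:
    def _two_groups(self, gap):
        a = synth.coords_to_structure(synth.ideal_helix(10), chain="A")
        b_xyz = synth.ideal_helix(10) + np.array([gap, 0.0, 0.0])
        b = synth.coords_to_structure(b_xyz, chain="B")
        return synth.merge_structures(a, b)

    def test_far_apart_groups_bury_nothing(self):
        s = self._two_groups(100.0)
        report = sm.interface_area(s, s.mask(chain="A"), s.mask(chain="B"))
        assert report.buried_area == 0.0
        assert report.contacts == []

    def test_close_groups_bury_area_symmetrically(self):
        s = self._two_groups(6.0)
        ab = sm.interface_area(s, s.mask(chain="A"), s.mask(chain="B"))
        ba = sm.interface_area(s, s.mask(chain="B"), s.mask(chain="A"))
        assert ab.buried_area > 10.0
        assert ab.buried_area == pytest.approx(ba.buried_area, abs=1e-9)
        assert ab.contacts and ab.per_residue

    def test_overlapping_selections_rejected(self):
        s = self._two_groups(6.0)
        mask = s.mask(chain="A")
        with pytest.raises(ValueError, match="overlap"):
            sm.interface_area(s, mask, mask)


class TestHelixGeometry:
    def test_ideal_helix_axis_is_z(self):
        ax = sm.helix_axis(synth.ideal_helix(18))
        angle = math.degrees(math.acos(abs(float(ax.direction @ [0, 0, 1]))))
        assert angle < 1.0
        assert np.linalg.norm(ax.direction) == pytest.approx(1.0)

    @pytest.mark.parametrize("angle_deg", [20.0, 50.0, 130.0])
    def test_known_rotation_recovered(self, angle_deg):
        helix = synth.ideal_helix(18)
        rot = Rotation.from_euler("x", angle_deg, degrees=True)
        h1 = sm.helix_axis(helix)
        h2 = sm.helix_axis(rot.apply(helix))
        assert sm.interhelix_angle(h1, h2) == pytest.approx(angle_deg, abs=0.5)

    def test_orientation_distinguishes_antiparallel(self):
        helix = synth.ideal_helix(18)
        flipped = Rotation.from_euler("x", 180, degrees=True).apply(helix)
        angle = sm.interhelix_angle(sm.helix_axis(helix), sm.helix_axis(flipped))
        assert angle == pytest.approx(180.0, abs=1.0)

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            sm.helix_axis(synth.ideal_helix(4))


class TestTriadGeometryAndRg:
    def _triad_structure(self):
        rows = [
            ("CYS", 10, "CB", "C", [-1.5, 0.0, 0.0]),
            ("CYS", 10, "SG", "S", [0.0, 0.0, 0.0]),
            ("HIS", 20, "ND1", "N", [3.2, 0.0, 0.0]),
            ("HIS", 20, "NE2", "N", [3.2, 2.0, 0.0]),
            ("ASP", 30, "OD1", "O", [3.2, 0.0, 2.7]),
            ("ASP", 30, "OD2", "O", [3.2, 0.0, 5.0]),
        ]
        n = len(rows)
        return sm.Structure(
            chain=np.array(["A"] * n, dtype=object),
            resseq=np.array([r[1] for r in rows]),
            icode=np.array([""] * n, dtype=object),
            resname=np.array([r[0] for r in rows], dtype=object),
            atname=np.array([r[2] for r in rows], dtype=object),
            element=np.array([r[3] for r in rows], dtype=object),
            xyz=np.array([r[4] for r in rows]),
            occupancy=np.ones(n),
            altloc=np.array([""] * n, dtype=object),
            het=np.zeros(n, dtype=bool),
        )

    def test_toy_triad_distances_exact(self):
        s = self._triad_structure()
        d = sm.triad_geometry(s, nucleophile=10, asp=30, his=20)
        assert d["his_nucleophile"] == pytest.approx(3.2)
        assert d["his_asp"] == pytest.approx(2.7)

    def test_missing_side_chain_atoms_reported(self):
        s = self._triad_structure()
        no_sg = s.subset(s.atname != "SG")
        with pytest.raises(ValueError, match="missing side-chain"):
            sm.triad_geometry(no_sg, nucleophile=10, asp=30, his=20)

    def test_rg_closed_forms(self):
        assert sm.radius_of_gyration(np.zeros((1, 3))) == 0.0
        two = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        assert sm.radius_of_gyration(two) == pytest.approx(1.0)

    def test_rg_of_spherical_shell_approaches_radius(self, rng):
        radius = 7.5
        pts = rng.normal(size=(4000, 3))
        pts = radius * pts / np.linalg.norm(pts, axis=1, keepdims=True)
        assert sm.radius_of_gyration(pts) == pytest.approx(radius, rel=0.01)

    def test_rg_rigid_motion_invariance(self, rng):
        xyz = synth.random_cloud(rng, 50)
        moved, _, _ = synth.rigid_copy(xyz, rng)
        assert sm.radius_of_gyration(moved) == pytest.approx(
            sm.radius_of_gyration(xyz))


class TestSelections:
    def test_selection_mask_parses_ranges(self):
        s, _ = synth.make_toy_structure(synth.GeneratorSpec(seed=3))
        mask = sm.selection_mask(s, "A:1-6,10-12")
        assert mask.sum() == 9

    @pytest.mark.parametrize("spec", ["A:5-1", "A:x-y", ":1-5"])
    def test_bad_selection_tokens_rejected(self, spec):
        s, _ = synth.make_toy_structure(synth.GeneratorSpec(seed=3))
        with pytest.raises(ValueError, match="bad selection|empty chain"):
            sm.selection_mask(s, spec)
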