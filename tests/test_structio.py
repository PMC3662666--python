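"""Format readers/writers, amide-proton building, and ring perception."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from csprobe.structio import (
    AmideGroup,
    Atom,
    LigandPose,
    PeakList,
    ProteinStructure,
    RDCSet,
    StructureError,
    TableError,
    build_amide_protons,
    perceive_aromatic_rings,
    read_ligand_poses,
    read_peaklist,
    read_protein_structure,
    read_rdc_table,
    write_ligand_poses,
    write_peaklist,
    write_protein_structure,
    write_rdc_table,
)
from csprobe.synthfix import FixtureSpec, make_ring_pose

from conftest import ideal_benzene


MINIMAL_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  N   ALA A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      5  CA  ALA A   2       4.042   2.792   0.000  1.00  0.00           C
ATOM      6  C   ALA A   2       5.540   2.565   0.100  1.00  0.00           C
ATOM      7  N   PRO A   3       6.350   3.620   0.100  1.00  0.00           N
ATOM      8  CA  PRO A   3       7.800   3.500   0.200  1.00  0.00           C
HETATM    9  O   HOH A 101      10.000  10.000  10.000  1.00  0.00           O
END
"""


class TestReadProteinStructure:
    def test_minimal_pdb(self, tmp_path):
        path = tmp_path / "mini.pdb"
        path.write_text(MINIMAL_PDB)
        st = read_protein_structure(path)
        assert len(st.amides) == 3
        assert all(a.h_coord is None for a in st.amides)
        # water excluded from protein atoms
        assert all(a.residue_name != "HOH" for a in st.all_atoms)

    def test_missing_file(self, tmp_path):
        with pytest.raises(StructureError, match="not found"):
            read_protein_structure(tmp_path / "absent.pdb")

    def test_model_index_out_of_range(self, tmp_path):
        path = tmp_path / "mini.pdb"
        path.write_text(MINIMAL_PDB)
        with pytest.raises(StructureError, match="out of range"):
            read_protein_structure(path, model_index=3)

    def test_multi_model_selects_block(self, tmp_path):
        body = (
            "MODEL        1\n"
            "ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ENDMDL\n"
            "MODEL        2\n"
            "ATOM      1  N   GLY A   1       5.000   0.000   0.000  1.00  0.00           N\n"
            "ENDMDL\nEND\n"
        )
        path = tmp_path / "multi.pdb"
        path.write_text(body)
        st = read_protein_structure(path, model_index=1)
        assert st.amides[0].n_coord[0] == pytest.approx(5.0)

    def test_round_trip_of_synthetic_helix(self, tmp_path, helix20):
        path = tmp_path / "helix.pdb"
        write_protein_structure(helix20, path)
        back = read_protein_structure(path)
        assert len(back.amides) == len(helix20.amides)
        orig = {(a.residue_key, a.name): a.coord for a in helix20.all_atoms}
        for at in back.all_atoms:
            assert np.allclose(at.coord, orig[(at.residue_key, at.name)], atol=1e-3)


class TestBuildAmideProtons:
    def test_existing_proton_untouched(self, helix20):
        rebuilt = build_amide_protons(helix20)
        for a, b in zip(helix20.amides, rebuilt.amides):
            if a.h_coord is not None:
                assert np.array_equal(a.h_coord, b.h_coord)

    def test_placed_proton_coplanar_and_at_bond_length(self, tmp_path):
        path = tmp_path / "mini.pdb"
        path.write_text(MINIMAL_PDB)
        st = build_amide_protons(read_protein_structure(path), nh_length=1.02)
        amide = st.amide_map()[("A", 2)]
        assert amide.h_built
        assert np.linalg.norm(amide.h_coord - amide.n_coord) == pytest.approx(1.02)
        # coplanar with C(i-1), N, CA
        c_prev = st.atom(("A", 1), "C").coord
        ca = st.atom(("A", 2), "CA").coord
        normal = np.cross(c_prev - amide.n_coord, ca - amide.n_coord)
        normal /= np.linalg.norm(normal)
        assert abs(np.dot(amide.h_coord - amide.n_coord, normal)) < 1e-9

    def test_proline_and_n_terminus_left_bare(self, tmp_path):
        path = tmp_path / "mini.pdb"
        path.write_text(MINIMAL_PDB)
        st = build_amide_protons(read_protein_structure(path))
        assert st.amide_map()[("A", 1)].h_coord is None
        assert st.amide_map()[("A", 3)].h_coord is None   # PRO

    def test_idempotent(self, tmp_path):
        path = tmp_path / "mini.pdb"
        path.write_text(MINIMAL_PDB)
        once = build_amide_protons(read_protein_structure(path))
        twice = build_amide_protons(once)
        for a, b in zip(once.amides, twice.amides):
            if a.h_coord is None:
                assert b.h_coord is None
            else:
                assert np.array_equal(a.h_coord, b.h_coord)

    def test_missing_preceding_carbon_skipped_not_fatal(self, tmp_path, caplog):
        # residue 2 follows a gap: no residue 1 C record
        body = (
            "ATOM      1  N   ALA A   2       0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  CA  ALA A   2       1.458   0.000   0.000  1.00  0.00           C\n"
            "ATOM      3  C   ALA A   2       2.009   1.420   0.000  1.00  0.00           C\n"
            "ATOM      4  N   ALA A   4       3.300   1.500   0.000  1.00  0.00           N\n"
            "ATOM      5  CA  ALA A   4       4.000   2.800   0.000  1.00  0.00           C\n"
            "END\n"
        )
        path = tmp_path / "gap.pdb"
        path.write_text(body)
        with caplog.at_level("WARNING"):
            st = build_amide_protons(read_protein_structure(path))
        assert st.amide_map()[("A", 4)].h_coord is None
        assert "missing preceding C" in caplog.text


class TestReadLigandPoses:
    def test_multi_model_pose_ids(self, tmp_path, benzene_pose):
        poses = [
            LigandPose(i + 1, benzene_pose.atoms, [], cluster_id=(i % 3) + 1,
                       binding_energy=-4.3 - 0.1 * i)
            for i in range(10)
        ]
        path = tmp_path / "ens.pdb"
        write_ligand_poses(poses, path)
        back = read_ligand_poses(path)
        assert [p.pose_id for p in back] == list(range(1, 11))
        assert [p.cluster_id for p in back] == [(i % 3) + 1 for i in range(10)]
        assert back[0].binding_energy == pytest.approx(-4.3)

    def test_single_pose_plain_pdb(self, tmp_path):
        body = (
            "HETATM    1  C1  LIG L   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "HETATM    2  C2  LIG L   1       1.390   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        path = tmp_path / "one.pdb"
        path.write_text(body)
        poses = read_ligand_poses(path)
        assert len(poses) == 1
        assert poses[0].cluster_id is None
        assert len(poses[0].atoms) == 2

    def test_pdbqt_energy_and_elements(self, tmp_path):
        body = (
            "MODEL 1\n"
            "USER    Estimated Free Energy of Binding    =   -5.23 kcal/mol\n"
            "ATOM      1  C1  LIG d   1       0.000   0.000   0.000  0.00  0.00    +0.00 A \n"
            "ATOM      2  O1  LIG d   1       1.390   0.000   0.000  0.00  0.00    -0.30 OA\n"
            "ENDMDL\n"
        )
        path = tmp_path / "dock.pdbqt"
        path.write_text(body)
        poses = read_ligand_poses(path)
        assert poses[0].binding_energy == pytest.approx(-5.23)
        assert [a.element for a in poses[0].atoms] == ["C", "O"]

    def test_malformed_coordinate_line_reports_number(self, tmp_path):
        body = (
            "HETATM    1  C1  LIG L   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "HETATM    2  C2  LIG L   1       xxxxx   0.000   0.000  1.00  0.00           C\n"
        )
        path = tmp_path / "bad.pdb"
        path.write_text(body)
        with pytest.raises(StructureError, match="line 2"):
            read_ligand_poses(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("END\n")
        with pytest.raises(StructureError, match="no ligand poses"):
            read_ligand_poses(path)


class TestPerceiveAromaticRings:
    def test_ideal_benzene_one_ring(self):
        atoms = [Atom(f"C{i+1}", "C", c, ("L", 1)) for i, c in enumerate(ideal_benzene())]
        pose = perceive_aromatic_rings(LigandPose(1, atoms))
        assert len(pose.rings) == 1
        ring = pose.rings[0]
        assert ring.intensity_factor == pytest.approx(1.00)
        assert ring.ring_type == "benzene"
        centered = ring.coords - ring.coords.mean(axis=0)
        assert np.abs(centered[:, 2]).max() < 1e-12     # planarity RMS 0

    def test_biphenyl_two_rings(self):
        pose = make_ring_pose(FixtureSpec(ring_count=2, ligand_position=(0, 0, 0)))
        perceived = perceive_aromatic_rings(pose)
        assert len(perceived.rings) == 2

    def test_ethane_no_rings(self):
        atoms = [
            Atom("C1", "C", np.array([0.0, 0, 0]), ("L", 1)),
            Atom("C2", "C", np.array([1.54, 0, 0]), ("L", 1)),
        ]
        pose = perceive_aromatic_rings(LigandPose(1, atoms))
        assert pose.rings == []

    def test_nonplanar_ring_rejected(self, rng):
        coords = ideal_benzene()
        coords[:, 2] += np.array([0.3, -0.3, 0.3, -0.3, 0.3, -0.3])
        atoms = [Atom(f"C{i+1}", "C", c, ("L", 1)) for i, c in enumerate(coords)]
        pose = perceive_aromatic_rings(LigandPose(1, atoms))
        assert pose.rings == []

    def test_invariant_under_rigid_motion_and_permutation(self, rng):
        base = make_ring_pose(FixtureSpec(ring_count=2, ligand_position=(0, 0, 0)))
        rot = Rotation.from_euler("xyz", [31, -47, 101], degrees=True)
        shift = np.array([3.0, -7.0, 11.0])
        perm = rng.permutation(len(base.atoms))
        moved = LigandPose(
            1,
            [
                Atom(base.atoms[i].name, base.atoms[i].element,
                     rot.apply(base.atoms[i].coord) + shift, ("L", 1))
                for i in perm
            ],
        )
        p0 = perceive_aromatic_rings(base)
        p1 = perceive_aromatic_rings(moved)
        assert len(p1.rings) == len(p0.rings) == 2
        c0 = sorted(np.round(rot.apply(r.coords.mean(axis=0)) + shift, 6).tolist()
                    for r in p0.rings)
        c1 = sorted(np.round(r.coords.mean(axis=0), 6).tolist() for r in p1.rings)
        assert c0 == c1

    def test_heteroatom_ring_classified(self):
        coords = ideal_benzene(radius=1.35)
        atoms = [Atom("N1", "N", coords[0], ("L", 1))] + [
            Atom(f"C{i}", "C", coords[i], ("L", 1)) for i in range(1, 6)
        ]
        pose = perceive_aromatic_rings(LigandPose(1, atoms))
        assert len(pose.rings) == 1
        assert pose.rings[0].ring_type == "six-heterocycle"


class TestPeakListIO:
    def test_three_line_table(self, tmp_path):
        path = tmp_path / "peaks.tsv"
        path.write_text(
            "residue_number\tchain\tresidue_name\tdelta_h\tdelta_n\n"
            "1\tA\tGLY\t8.10\t118.2\n2\tA\tALA\t8.30\t120.0\n3\tA\tSER\t8.05\t115.9\n"
        )
        peaks = read_peaklist(path)
        assert len(peaks.entries) == 3
        assert peaks.entries[("A", 2)] == (8.30, 120.0)

    def test_duplicate_residue_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text(
            "residue_number\tdelta_h\tdelta_n\n5\t8.1\t118.0\n5\t8.2\t119.0\n"
        )
        with pytest.raises(TableError, match="duplicate"):
            read_peaklist(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "short.tsv"
        path.write_text("residue_number\tdelta_h\n1\t8.1\n")
        with pytest.raises(TableError, match="delta_n"):
            read_peaklist(path)

    def test_non_numeric_shift_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("residue_number\tdelta_h\tdelta_n\n1\tabc\t118.0\n")
        with pytest.raises(TableError, match="non-numeric"):
            read_peaklist(path)

    def test_round_trip_identity(self, tmp_path):
        peaks = PeakList(
            "free",
            {("A", i): (8.0 + 0.123456 * i, 115.0 + 0.654321 * i) for i in range(1, 8)},
        )
        path = tmp_path / "rt.tsv"
        write_peaklist(peaks, path)
        back = read_peaklist(path)
        for key, (dh, dn) in peaks.entries.items():
            assert back.entries[key][0] == pytest.approx(dh, abs=1e-6)
            assert back.entries[key][1] == pytest.approx(dn, abs=1e-6)


class TestRDCTableIO:
    def test_signs_preserved(self, tmp_path):
        path = tmp_path / "rdc.tsv"
        path.write_text("residue_number\trdc_hz\n1\t-33.0\n2\t29.0\n3\t-0.5\n")
        rdcs = read_rdc_table(path)
        assert rdcs.entries[("A", 1)] == -33.0
        assert rdcs.entries[("A", 2)] == 29.0

    def test_empty_table_rejected(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("residue_number\trdc_hz\n")
        with pytest.raises(TableError, match="no RDC entries"):
            read_rdc_table(path)

    def test_round_trip_identity(self, tmp_path, rng):
        rdcs = RDCSet("free", {("A", i): float(v) for i, v in
                               enumerate(rng.uniform(-30, 30, 12), start=1)})
        path = tmp_path / "rt.tsv"
        write_rdc_table(rdcs, path)
        back = read_rdc_table(path)
        for key, d in rdcs.entries.items():
            assert back.entries[key] == pytest.approx(d, abs=1e-6)


class TestInvariants:
    def test_amide_nh_length_validated(self):
        with pytest.raises(StructureError, match="0.8-1.2"):
            AmideGroup("A", 1, "ALA", np.zeros(3), np.array([2.0, 0, 0]))

    def test_ring_size_validated(self):
        with pytest.raises(StructureError, match="5 or 6"):
            from csprobe.structio import AromaticRing
            AromaticRing(atom_indices=[0, 1, 2], coords=np.zeros((3, 3)))
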