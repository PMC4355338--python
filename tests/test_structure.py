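"""PDB parsing, Kabsch superposition, site extraction, ligand contacts."""

import numpy as np
import pytest

import isopocket as ip

from .oracles import search_min_rmsd

MINIMAL_PDB = """\
ATOM      1  N   HIS A  94      10.000  10.000  10.000  1.00  0.00           N
ATOM      2  CA  HIS A  94      11.000  10.000  10.000  1.00  0.00           C
ATOM      3  CA AGLN A  92       5.000   5.000   5.000  0.50  0.00           C
ATOM      4  CA BGLN A  92       6.000   5.000   5.000  0.50  0.00           C
ATOM      5  H   HIS A  94      11.500  10.500  10.000  1.00  0.00           H
HETATM    6 ZN    ZN A 262       0.000   0.000   0.000  1.00  0.00          ZN
HETATM    7  C1  LIG A 300       3.000   0.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def minimal_structure(tmp_path):
    p = tmp_path / "site.pdb"
    p.write_text(MINIMAL_PDB)
    return ip.read_pdb(p, label="site")


def _random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


class TestReadPdb:
    def test_atoms_parsed(self, minimal_structure):
        s = minimal_structure
        # N + CA + altloc-A CA + zinc + ligand carbon; hydrogen and altloc B dropped
        assert len(s.atoms) == 5
        names = {(a.name, a.resnum) for a in s.atoms}
        assert ("CA", 94) in names and ("CA", 92) in names

    def test_zinc_becomes_metal_center(self, minimal_structure):
        assert minimal_structure.metal is not None
        assert minimal_structure.metal.element == "ZN"
        assert np.allclose(minimal_structure.metal.coord, 0.0)

    def test_ligand_atoms_detected(self, minimal_structure):
        s = minimal_structure
        assert [s.atoms[i].resname for i in s.ligand_indices] == ["LIG"]

    def test_first_model_only(self, tmp_path):
        p = tmp_path / "models.pdb"
        p.write_text(
            "MODEL        1\n"
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\n"
            "MODEL        2\n"
            "ATOM      2  CA  GLY A   1      99.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\nEND\n"
        )
        s = ip.read_pdb(p)
        assert len(s.atoms) == 1
        assert s.atoms[0].x == 0.0

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("END\n")
        with pytest.raises(ValueError):
            ip.read_pdb(p)

    def test_multiple_zincs_leave_center_unset(self, tmp_path):
        p = tmp_path / "twozn.pdb"
        p.write_text(
            "ATOM      1  CA  GLY A   1       1.000   0.000   0.000  1.00  0.00           C\n"
            "HETATM    2 ZN    ZN A 900       0.000   0.000   0.000  1.00  0.00          ZN\n"
            "HETATM    3 ZN    ZN A 901       5.000   0.000   0.000  1.00  0.00          ZN\n"
            "END\n"
        )
        assert ip.read_pdb(p).metal is None

    def test_write_read_round_trip(self, tmp_path):
        cfg = ip.StructureConfig(
            residue_distances={i: 4.0 + i for i in range(1, 8)},
            contact_positions=frozenset({2}),
            seed=5,
        )
        s, _ = ip.generate_toy_structure(cfg)
        p = tmp_path / "dump.pdb"
        ip.write_pdb(s, p)
        back = ip.read_pdb(p)
        assert len(back.atoms) == len(s.atoms)
        # the parser groups atoms by chain, so match by identity, not order
        def keyed(struct):
            return {
                (a.chain, a.resnum, a.name): a.coord for a in struct.atoms
            }

        orig, reread = keyed(s), keyed(back)
        assert orig.keys() == reread.keys()
        for key in orig:
            assert np.allclose(orig[key], reread[key], atol=1.5e-3)
        assert back.metal is not None


class TestKabsch:
    def test_identical_sets(self, rng):
        pts = rng.normal(size=(8, 3))
        res = ip.kabsch_superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-12)

    def test_rigid_motion_removed(self, rng):
        pts = rng.normal(size=(10, 3)) * 5
        rot = _random_rotation(rng)
        moved = pts @ rot.T + np.array([3.0, -2.0, 7.0])
        res = ip.kabsch_superpose(moved, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        # recovered rotation undoes the planted one
        assert np.allclose(res.rotation, rot.T, atol=1e-9)

    def test_ninety_degree_case(self):
        pts = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 0.0]])
        rot = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])  # 90 deg about z
        res = ip.kabsch_superpose(pts @ rot.T + 2.0, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_proper_rotation_even_for_reflected_input(self, rng):
        pts = rng.normal(size=(12, 3))
        reflected = pts * np.array([-1.0, 1.0, 1.0])
        res = ip.kabsch_superpose(reflected, pts)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)
        assert res.rmsd > 0

    def test_rmsd_not_worse_than_unaligned(self, rng):
        for _ in range(10):
            a = rng.normal(size=(9, 3)) * 3
            b = a + rng.normal(size=(9, 3)) * 0.8
            before = float(np.sqrt(((a - b) ** 2).sum() / 9))
            assert ip.kabsch_superpose(a, b).rmsd <= before + 1e-12

    def test_invariant_under_rigid_premotion(self, rng):
        a = rng.normal(size=(10, 3)) * 4
        b = a + rng.normal(size=(10, 3)) * 0.5
        base = ip.kabsch_superpose(a, b).rmsd
        rot = _random_rotation(rng)
        premoved = a @ rot.T + np.array([5.0, 1.0, -4.0])
        assert ip.kabsch_superpose(premoved, b).rmsd == pytest.approx(base, abs=1e-9)

    def test_noisy_rmsd_matches_rotation_search_oracle(self, rng):
        """The closed-form optimum agrees with an independent direct search."""
        for seed in range(3):
            local = np.random.default_rng(seed)
            a = local.normal(size=(10, 3)) * 3
            b = a @ _random_rotation(local).T + local.normal(size=(10, 3)) * 0.5
            ours = ip.kabsch_superpose(a, b).rmsd
            oracle = search_min_rmsd(a, b, seed=seed)
            assert ours == pytest.approx(oracle, abs=1e-3)
            assert ours <= oracle + 1e-9  # never worse than the search

    def test_matches_scipy_align_vectors(self, rng):
        from scipy.spatial.transform import Rotation

        a = rng.normal(size=(15, 3)) * 2
        b = a @ _random_rotation(rng).T + rng.normal(size=(15, 3)) * 0.3
        ours = ip.kabsch_superpose(a, b)
        rot, rssd = Rotation.align_vectors(
            b - b.mean(axis=0), a - a.mean(axis=0)
        )
        assert ours.rmsd == pytest.approx(rssd / np.sqrt(15), abs=1e-9)
        assert np.allclose(ours.rotation, rot.as_matrix(), atol=1e-6)

    def test_degenerate_inputs_rejected(self):
        line = np.array([[0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            ip.kabsch_superpose(line, line)
        with pytest.raises(ValueError):
            ip.kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))
        with pytest.raises(ValueError):
            ip.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestSiteResidues:
    def test_planted_distances(self):
        cfg = ip.StructureConfig(
            residue_distances={1: 3.0, 2: 10.0, 3: 20.0}, seed=1
        )
        s, _ = ip.generate_toy_structure(cfg)
        within = {r[1] for r in ip.site_residues(s, cutoff=15.0)}
        assert within == {1, 2}

    def test_monotone_in_cutoff(self):
        cfg = ip.StructureConfig(
            residue_distances={i: float(i) * 2 for i in range(1, 10)}, seed=2
        )
        s, _ = ip.generate_toy_structure(cfg)
        previous = set()
        for cutoff in (3.0, 7.0, 11.0, 20.0):
            current = ip.site_residues(s, cutoff=cutoff)
            assert previous <= current
            previous = current

    def test_no_center_rejected(self):
        s = ip.SiteStructure("x", [ip.Atom("C", "CA", "GLY", "A", 1, 1, 2, 3)])
        with pytest.raises(ValueError, match="metal"):
            ip.site_residues(s)

    def test_explicit_center(self, minimal_structure):
        got = ip.site_residues(
            minimal_structure, center=np.array([11.0, 10.0, 10.0]), cutoff=2.0
        )
        assert {r[1] for r in got} == {94}


class TestLigandContacts:
    def test_planted_contacts_recovered(self):
        cfg = ip.StructureConfig(
            residue_distances={p: 8.0 for p in (67, 91, 131, 199, 200)},
            contact_positions=frozenset({67, 91, 131}),
            rotation_angle=1.0,
            translation=(4.0, 4.0, 4.0),
            seed=9,
        )
        s, truth = ip.generate_toy_structure(cfg)
        result = ip.ligand_contacts(s, cutoff=4.0)
        assert result.positions == set(truth.contact_positions)
        assert result.unmapped == []

    def test_empty_when_ligand_far(self, minimal_structure):
        result = ip.ligand_contacts(minimal_structure, cutoff=1.0)
        assert result.positions == set()

    def test_near_residue_included(self, minimal_structure):
        # ligand at (3,0,0); CA of residue 92 at (5,5,5) is ~7.3 A away
        result = ip.ligand_contacts(minimal_structure, cutoff=8.0)
        assert 92 in result.positions

    def test_reference_map_translation(self, minimal_structure):
        from isopocket.alignment import MultipleAlignment

        # member carries a 2-residue N-terminal extension, so its residue k
        # sits at reference position k - 2
        body = ("ACDEFGHIKL" * 10)[:98]
        msa = MultipleAlignment(["REF", "M"], ["--" + body, "WW" + body])
        rm = ip.build_reference_map(msa, "REF")
        result = ip.ligand_contacts(
            minimal_structure, cutoff=8.0, refmap=rm, member="M"
        )
        assert 90 in result.positions  # structure residue 92 in member numbering
        assert 92 not in result.positions

    def test_no_ligand_rejected(self):
        s = ip.SiteStructure("x", [ip.Atom("C", "CA", "GLY", "A", 1, 0, 0, 0)])
        with pytest.raises(ValueError, match="ligand"):
            ip.ligand_contacts(s)
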