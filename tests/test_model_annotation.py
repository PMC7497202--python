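"""Model parsing, Kabsch-Sander H-bond energies, and the DSSP-variant
secondary-structure assignment with Ramachandran extension."""

import numpy as np
import pytest

from haruspex._geom import rotation_from_axis_angle
from haruspex.model_annotation import (NO_BOND,
                                       Residue, ResidueLabels,
                                       assign_secondary_structure,
                                       extend_by_ramachandran, hbond_energy,
                                       read_model)
from haruspex.phantoms import Pose, build_ideal_helix, _build_backbone
from haruspex.model_annotation import StructuralModel

PDB_FIXTURE = """\
HELIX    1   1 ALA A    5  ALA A   12  1                                   8
ATOM      1  N   ALA A   5      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   5      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   5      12.489   7.292  -4.800  1.00  0.00           C
ATOM      4  O   ALA A   5      12.904   7.449  -3.653  1.00  0.00           O
ATOM      5  N   ALA A   6      12.732   8.147  -5.797  1.00  0.00           N
ATOM      6  CA  ALA A   6      13.538   9.350  -5.605  0.60  0.00           C
ATOM      7  CA BALA A   6      14.000   9.999  -5.000  0.40  0.00           C
ATOM      8  C   ALA A   6      12.767  10.432  -4.856  1.00  0.00           C
ATOM      9  O   ALA A   6      13.361  11.248  -4.148  1.00  0.00           O
TER
ATOM     10  P     U B   1       0.000   0.000   0.000  1.00  0.00           P
ATOM     11  C4'   U B   1       1.000   1.000   1.000  1.00  0.00           C
ATOM     12  P     U B   2       5.900   0.000   0.000  1.00  0.00           P
ATOM     13  C4'   U B   2       6.900   1.000   1.000  1.00  0.00           C
ATOM     14  P     G B   3      11.800   0.000   0.000  1.00  0.00           P
ATOM     15  C4'   G B   3      12.800   1.000   1.000  1.00  0.00           C
ATOM     16  P     A B   4      17.700   0.000   0.000  1.00  0.00           P
ATOM     17  C4'   A B   4      18.700   1.000   1.000  1.00  0.00           C
END
"""


@pytest.fixture()
def pdb_file(tmp_path):
    p = tmp_path / "fixture.pdb"
    p.write_text(PDB_FIXTURE)
    return p


class TestReadModel:
    def test_author_helix_record(self, pdb_file):
        model = read_model(pdb_file)
        recs = [r for r in model.author_ss if r.ss_class == "helix"]
        assert len(recs) == 1
        assert recs[0].chain_id == "A"
        assert recs[0].start[0] == 5 and recs[0].end[0] == 12

    def test_rna_chain_kinds(self, pdb_file):
        model = read_model(pdb_file)
        chain_b = [c for c in model.chains if c.chain_id == "B"][0]
        assert len(chain_b.residues) == 4
        assert all(r.kind == "nuc" for r in chain_b.residues)

    def test_altloc_highest_occupancy_wins(self, pdb_file):
        model = read_model(pdb_file)
        chain_a = [c for c in model.chains if c.chain_id == "A"][0]
        res6 = [r for r in chain_a.residues if r.seqid == 6][0]
        np.testing.assert_allclose(res6.atoms["CA"], [13.538, 9.350, -5.605],
                                   atol=1e-3)

    def test_empty_model_raises(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(Exception):
            read_model(p)

    def test_pdbml_atom_sites(self, tmp_path):
        xml = """<?xml version="1.0"?>
<datablock xmlns="http://pdbml.pdb.org/schema/pdbx-v50.xsd">
 <atom_siteCategory>
  <atom_site id="1">
   <Cartn_x>1.0</Cartn_x><Cartn_y>2.0</Cartn_y><Cartn_z>3.0</Cartn_z>
   <auth_asym_id>A</auth_asym_id><auth_seq_id>1</auth_seq_id>
   <label_atom_id>CA</label_atom_id><label_comp_id>GLY</label_comp_id>
   <occupancy>1.0</occupancy><pdbx_PDB_model_num>1</pdbx_PDB_model_num>
  </atom_site>
  <atom_site id="2">
   <Cartn_x>4.0</Cartn_x><Cartn_y>5.0</Cartn_y><Cartn_z>6.0</Cartn_z>
   <auth_asym_id>A</auth_asym_id><auth_seq_id>2</auth_seq_id>
   <label_atom_id>CA</label_atom_id><label_comp_id>ALA</label_comp_id>
   <occupancy>1.0</occupancy><pdbx_PDB_model_num>1</pdbx_PDB_model_num>
  </atom_site>
 </atom_siteCategory>
</datablock>
"""
        p = tmp_path / "model.xml"
        p.write_text(xml)
        model = read_model(p)
        res = list(model.residues())
        assert len(res) == 2
        np.testing.assert_allclose(res[0].atoms["CA"], [1.0, 2.0, 3.0])


def _make_residue(name, chain, seq, atoms):
    return Residue(chain_id=chain, seqid=seq, icode="", name=name,
                   kind="aa", atoms={k: np.asarray(v, float) for k, v in atoms.items()})


class TestHbondEnergy:
    def _ideal_pair(self, r_on=2.9):
        """Linear N-H...O=C geometry with the donor's previous C=O aligned so
        the constructed H points straight at the acceptor O."""
        donor_prev = _make_residue("ALA", "A", 1, {
            "C": [0.0, 0.0, 0.0], "O": [-1.23, 0.0, 0.0],
            "N": [0.5, 1.0, 0.0], "CA": [0.0, 0.5, 0.0]})
        donor = _make_residue("ALA", "A", 2, {
            "N": [0.0, 0.0, 0.0], "CA": [-0.8, -1.2, 0.0]})
        acceptor = _make_residue("ALA", "A", 6, {
            "O": [r_on, 0.0, 0.0], "C": [r_on + 1.23, 0.0, 0.0]})
        return donor, acceptor, donor_prev

    def test_ideal_geometry_strong_bond(self):
        donor, acceptor, prev = self._ideal_pair(2.9)
        e = hbond_energy(donor, acceptor, prev)
        # independent brute-force evaluation of the electrostatic model
        q = 0.084 * 332.0
        h = np.array([1.0, 0.0, 0.0])
        expect = q * (1 / 2.9 + 1 / np.linalg.norm(np.array([4.13, 0, 0]) - h)
                      - 1 / 1.9 - 1 / 4.13)
        assert e == pytest.approx(expect, rel=1e-6)
        assert e < -0.5

    def test_proline_never_donates(self):
        donor, acceptor, prev = self._ideal_pair(2.9)
        donor.name = "PRO"
        assert hbond_energy(donor, acceptor, prev) == NO_BOND

    def test_distant_acceptor_below_threshold(self):
        donor, acceptor, prev = self._ideal_pair(20.0)
        e = hbond_energy(donor, acceptor, prev)
        assert abs(e) < 0.5

    def test_missing_previous_residue_is_no_bond(self):
        donor, acceptor, _ = self._ideal_pair(2.9)
        assert hbond_energy(donor, acceptor, None) == NO_BOND


class TestAssignSecondaryStructure:
    def test_ideal_helix_interior(self, helix12, helix12_labels):
        rs = helix12.chains[0].residues
        got = [helix12_labels.get(r) for r in rs]
        # residues 2..9 (0-based 1..8) must be helix; termini may be unassigned
        assert all(c == "helix" for c in got[1:9])
        assert "sheet" not in got

    def test_antiparallel_sheet_bridges(self, sheet2x9):
        labels = assign_secondary_structure(sheet2x9)
        got = [labels.get(r) for chain in sheet2x9.chains for r in chain.residues]
        assert got.count("sheet") >= 10
        assert "helix" not in got

    def test_isolated_extended_strand_unassigned(self):
        lone = StructuralModel(chains=[_build_backbone(10, -135.0, 135.0, "A", 1)])
        labels = assign_secondary_structure(lone)
        assert all(labels.get(r) == "unassigned" for r in lone.residues())

    def test_nucleotides_always_nucleotide(self, nucleic18):
        labels = assign_secondary_structure(nucleic18)
        assert all(labels.get(r) == "nucleotide" for r in nucleic18.residues())

    def test_rigid_motion_invariance(self, helix12, helix12_labels):
        R = rotation_from_axis_angle([1, 2, 3], 77.0)
        t = np.array([5.0, -3.0, 11.0])
        moved = build_ideal_helix(12, pose=Pose(rotation=R, translation=t))
        labels = assign_secondary_structure(moved)
        for a, b in zip(helix12.residues(), moved.residues()):
            assert helix12_labels.get(a) == labels.get(b)

    def test_author_annotation_wins(self, helix12):
        from haruspex.model_annotation import AuthorSS
        helix = build_ideal_helix(12)
        helix.author_ss.append(AuthorSS(chain_id="A", start=(3, ""), end=(6, ""),
                                        ss_class="sheet"))
        labels = assign_secondary_structure(helix)
        rs = helix.chains[0].residues
        assert all(labels.get(r) == "sheet" for r in rs if 3 <= r.seqid <= 6)

    def test_short_chains_left_unassigned(self):
        model = StructuralModel(chains=[_build_backbone(2, -57.0, -47.0, "A", 1)])
        labels = assign_secondary_structure(model)
        assert all(labels.get(r) == "unassigned" for r in model.residues())


class TestRamachandranExtension:
    def test_extends_helix_neighbour_in_window(self):
        helix = build_ideal_helix(12)
        rs = helix.chains[0].residues
        # seed labels: only residues 3..9 helix, others unassigned
        seed = ResidueLabels({r.key: "helix" for r in rs if 3 <= r.seqid <= 9})
        out = extend_by_ramachandran(seed, helix)
        # residue 10 has ideal helix torsions (-57, -47): inside the window
        assert out.get_key(("A", 10, "")) == "helix"

    def test_left_handed_region_not_extended(self):
        chain = _build_backbone(6, 60.0, 40.0, "A", 1)
        model = StructuralModel(chains=[chain])
        seed = ResidueLabels({chain.residues[1].key: "helix"})
        out = extend_by_ramachandran(seed, model)
        assert out.get_key(chain.residues[2].key) == "unassigned"

    def test_empty_labels_unchanged(self, helix12):
        out = extend_by_ramachandran(ResidueLabels(), helix12)
        assert all(out.get(r) == "unassigned" for r in helix12.residues())

    def test_monotone_never_removes_labels(self, sheet2x9):
        labels = assign_secondary_structure(sheet2x9, extend=False)
        extended = extend_by_ramachandran(labels, sheet2x9)
        for res in sheet2x9.residues():
            before = labels.get(res)
            if before != "unassigned":
                assert extended.get(res) == before

    def test_terminal_residues_never_extended(self):
        helix = build_ideal_helix(8)
        rs = helix.chains[0].residues
        seed = ResidueLabels({rs[1].key: "helix"})
        out = extend_by_ramachandran(seed, helix)
        # first residue lacks phi: must remain unassigned
        assert out.get(rs[0]) == "unassigned"
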