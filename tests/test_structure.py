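"""Strand annotation: parsing, dihedrals, labelling, ladders, directions."""
import numpy as np
import pytest

from barrelmap import _geom
from barrelmap.structure import (AnnotationConfig, NoBarrelError, annotate,
                                 annotation_variants, assemble_strands,
                                 compute_dihedrals, detect_hbonds,
                                 label_residues, read_backbone,
                                 strand_directions, VariantResult,
                                 write_annotations, read_annotations)
from barrelmap.synthgen import BarrelSpec, generate_barrel, to_pdb
from barrelmap.types import BackboneGeometry, ResidueRecord, StrandAnnotation


def residues_from_chain(chain):
    return [ResidueRecord(seq_index=i + 1, aa="A", n=chain["N"][i],
                          ca=chain["CA"][i], c=chain["C"][i], o=chain["O"][i])
            for i in range(len(chain["N"]))]


# --- read_backbone ---------------------------------------------------------

def test_read_backbone_roundtrip(barrel8):
    res = read_backbone(to_pdb(barrel8))
    assert len(res) == len(barrel8.residues)
    assert [r.aa for r in res] == list(barrel8.sequence)
    assert np.allclose(res[0].ca, barrel8.residues[0].ca, atol=1e-3)


def test_read_backbone_altloc_highest_occupancy():
    pdb = "\n".join([
        "ATOM      1  N  AALA A   1       0.000   0.000   0.000  0.40  0.00           N",
        "ATOM      2  N  BALA A   1       9.000   9.000   9.000  0.60  0.00           N",
        "ATOM      3  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C",
        "ATOM      4  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C",
        "ATOM      5  O   ALA A   1       2.000   2.000   1.000  1.00  0.00           O",
        "END"])
    res = read_backbone(pdb)
    assert len(res) == 1
    assert np.allclose(res[0].n, [9.0, 9.0, 9.0])


def test_read_backbone_hetatm_only_is_error():
    pdb = ("HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\n"
           "END\n")
    with pytest.raises(ValueError, match="no polymer residues"):
        read_backbone(pdb)


def test_read_backbone_drops_residue_missing_ca():
    pdb = "\n".join([
        "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N",
        "ATOM      2  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C",
        "ATOM      3  O   ALA A   1       2.000   2.000   1.000  1.00  0.00           O",
        "ATOM      4  N   GLY A   2       3.300   0.000   0.000  1.00  0.00           N",
        "ATOM      5  CA  GLY A   2       4.758   0.000   0.000  1.00  0.00           C",
        "ATOM      6  C   GLY A   2       5.300   1.400   0.000  1.00  0.00           C",
        "ATOM      7  O   GLY A   2       5.300   2.000   1.000  1.00  0.00           O",
        "END"])
    with pytest.warns(UserWarning, match="no CA"):
        res = read_backbone(pdb)
    assert len(res) == 1 and res[0].seq_index == 1 and res[0].aa == "G"


# --- dihedrals and labels --------------------------------------------------

@pytest.mark.parametrize("phi,psi,label", [
    (-120.0, 130.0, "strand_like"),
    (-57.0, -47.0, "helix_like"),
    (60.0, 60.0, "other"),
])
def test_dihedrals_and_labels_on_ideal_chains(phi, psi, label):
    chain = _geom.build_chain([phi] * 8, [psi] * 8)
    res = residues_from_chain(chain)
    geom = compute_dihedrals(res)
    assert geom.phi[3] == pytest.approx(phi, abs=1.0)
    assert geom.psi[3] == pytest.approx(psi, abs=1.0)
    assert np.isnan(geom.phi[0]) and np.isnan(geom.psi[-1])
    assert label_residues(geom)[3] == label


def test_dihedrals_require_three_residues():
    chain = _geom.build_chain([-120.0] * 2, [130.0] * 2)
    with pytest.raises(ValueError):
        compute_dihedrals(residues_from_chain(chain))


def test_labelling_invariant_under_rigid_motion(barrel8):
    from scipy.spatial.transform import Rotation
    rot = Rotation.from_euler("xyz", [31, -57, 113], degrees=True).as_matrix()
    shift = np.array([5.0, -3.0, 11.0])
    moved = [ResidueRecord(r.seq_index, r.aa, rot @ r.n + shift,
                           rot @ r.ca + shift, rot @ r.c + shift,
                           rot @ r.o + shift) for r in barrel8.residues]
    assert (label_residues(compute_dihedrals(moved))
            == label_residues(compute_dihedrals(barrel8.residues)))


# --- H-bonds ---------------------------------------------------------------

def test_hbond_ladder_between_adjacent_strands(barrel8):
    pairs = detect_hbonds(barrel8.residues)
    s1, s2 = barrel8.annotation.strands[0], barrel8.annotation.strands[1]
    ladder = [(i, j) for i, j in pairs
              if s1[0] <= j <= s1[1] and s2[0] <= i <= s2[1]]
    assert len(ladder) >= 2


def test_hbond_sequence_separation_and_cutoff():
    def res_at(i, n_xyz, o_xyz):
        zero = np.zeros(3)
        return ResidueRecord(i, "A", np.array(n_xyz), zero, zero, np.array(o_xyz))

    close = [res_at(1, [0, 0, 0], [50, 50, 50]), res_at(2, [60, 0, 0], [1.0, 0, 0])]
    assert detect_hbonds(close) == []  # |i-j| = 1 excluded
    apart = [res_at(1, [0, 0, 0], [50, 50, 50]), res_at(2, [70, 0, 0], [80, 0, 0]),
             res_at(3, [60, 0, 0], [90, 0, 0]), res_at(4, [65, 0, 0], [4.2, 0, 0])]
    assert detect_hbonds(apart) == []  # N...O at 4.2 A with 3.5 A cutoff
    apart[3] = res_at(4, [65, 0, 0], [3.4, 0, 0])
    assert (1, 4) in detect_hbonds(apart)


# --- strand assembly -------------------------------------------------------

def test_assemble_requires_hbonded_partner():
    labels = ["strand_like"] * 6 + ["other"] * 4 + ["strand_like"] * 6
    # runs bonded to each other: both kept
    bonds = [(1, 12), (2, 13), (3, 14)]
    ann = assemble_strands(labels, bonds)
    assert ann.strands == [(1, 6), (11, 16)]
    # one isolated run with no partner: no barrel at all
    with pytest.raises(NoBarrelError):
        assemble_strands(["strand_like"] * 6 + ["other"] * 10, [])


def test_assemble_all_helix_is_no_barrel():
    with pytest.raises(NoBarrelError, match="no barrel"):
        assemble_strands(["helix_like"] * 20, [])


def test_recovery_sweep_strand_counts():
    for n in range(8, 28, 2):
        b = generate_barrel(BarrelSpec(n_strands=n, seed=3))
        ann = annotate(b.residues)
        assert ann.n_strands == n
        for (ps, pe), (rs, re_) in zip(b.annotation.strands, ann.strands):
            inter = max(0, min(pe, re_) - max(ps, rs) + 1)
            assert inter / (pe - ps + 1) >= 0.9
        assert ann.directions == b.annotation.directions


# --- directions ------------------------------------------------------------

def test_directions_fixed_by_termini_rule_under_mirroring(barrel16):
    dirs = strand_directions(barrel16.annotation, barrel16.residues)
    mirrored = [ResidueRecord(r.seq_index, r.aa, r.n * [1, 1, -1],
                              r.ca * [1, 1, -1], r.c * [1, 1, -1],
                              r.o * [1, 1, -1]) for r in barrel16.residues]
    assert strand_directions(barrel16.annotation, mirrored) == dirs


def test_directions_degenerate_axis_rejected():
    # a collapsed structure has no usable axial extent
    rng = np.random.default_rng(0)
    blob = [ResidueRecord(i + 1, "A", *(rng.normal(size=3) * 0.3 for _ in range(4)))
            for i in range(40)]
    ann = StrandAnnotation(strands=[(1, 5), (11, 15), (21, 25), (31, 35)])
    with pytest.raises(ValueError, match="degenerate"):
        strand_directions(ann, blob)


# --- variants --------------------------------------------------------------

def test_variants_single_annotation_identity():
    ann = StrandAnnotation(strands=[(3, 12), (18, 27)], protein_id="x")
    out = annotation_variants([ann])
    assert out.longest.strands == out.shortest.strands == ann.strands
    assert out.consistent


def test_variants_union_and_intersection():
    a = StrandAnnotation(strands=[(5, 15)], protein_id="x")
    b = StrandAnnotation(strands=[(6, 14)], protein_id="x")
    out = annotation_variants([a, b])
    assert out.longest.strands == [(5, 15)]
    assert out.shortest.strands == [(6, 14)]


def test_variants_flag_strand_count_change():
    a = StrandAnnotation(strands=[(5, 15), (20, 30)], protein_id="x")
    b = StrandAnnotation(strands=[(5, 15)], protein_id="x")
    c = StrandAnnotation(strands=[(5, 16), (20, 31)], protein_id="x")
    out = annotation_variants([a, b, c])
    assert any("strand count" in f for f in out.flags)
    assert isinstance(out, VariantResult) and not out.consistent
    assert out.longest.n_strands == 2


# --- annotation table round trip ------------------------------------------

def test_annotation_tsv_roundtrip(barrel8):
    ann = annotate(barrel8.residues, protein_id="b8")
    back = read_annotations(write_annotations([ann]))
    assert back["b8"].strands == ann.strands
    assert back["b8"].directions == ann.directions
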