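"""Strand assignment from backbone coordinates.

Residues are labelled strand/helix/other from phi/psi windows; strands are
maximal strand-like runs supported by an inter-strand hydrogen-bond ladder;
per-strand membrane direction comes from the barrel principal axis signed so
that the chain termini sit on the periplasmic face.
"""
from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from ._geom import dihedral
from .types import BackboneGeometry, ResidueRecord, StrandAnnotation

STRAND_LIKE = "strand_like"
HELIX_LIKE = "helix_like"
OTHER_SS = "other"


class NoBarrelError(ValueError):
    """Raised when no hydrogen-bonded strand ladder can be assembled."""


@dataclass
class AnnotationConfig:
    """Tunable conventions of the strand annotator.

    The phi/psi windows are permissive Ramachandran-standard regions; the
    hydrogen-bond rule is a plain donor-N to acceptor-O distance cutoff with
    a minimum sequence separation, with no angular term.
    """
    beta_phi: tuple[float, float] = (-180.0, -45.0)
    beta_psi: tuple[float, float] = (45.0, 180.0)
    beta_psi_wrap: tuple[float, float] = (-180.0, -170.0)
    alpha_phi: tuple[float, float] = (-90.0, -35.0)
    alpha_psi: tuple[float, float] = (-70.0, -15.0)
    hbond_cutoff: float = 3.5
    hbond_min_sep: int = 3
    min_strand_len: int = 3
    bulge_tolerance: int = 2
    min_ladder_bonds: int = 2


def read_backbone(pdb_text: str) -> list[ResidueRecord]:
    """Parse ATOM records of the first polypeptide chain.

    Residues are re-indexed sequentially from 1. Alternate locations resolve
    to the highest-occupancy conformer. Residues missing any backbone atom
    are dropped with a warning.
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0 or len(st[0]) == 0:
        raise ValueError("no polymer residues: empty structure")
    chain = st[0][0]
    records = []
    idx = 0
    for res in chain:
        if res.het_flag != "A":
            continue
        picked = {}
        for atom in res:
            if atom.name not in ("N", "CA", "C", "O"):
                continue
            prev = picked.get(atom.name)
            if prev is None or atom.occ > prev.occ:
                picked[atom.name] = atom
        if "CA" not in picked:
            warnings.warn(f"residue {res.seqid.num} {res.name}: no CA, dropped")
            continue
        if len(picked) < 4:
            missing = sorted(set("N CA C O".split()) - set(picked))
            warnings.warn(f"residue {res.seqid.num} {res.name}: missing {missing}, dropped")
            continue
        idx += 1
        aa = gemmi.find_tabulated_residue(res.name)
        letter = aa.one_letter_code.upper() if aa else "X"
        records.append(ResidueRecord(
            seq_index=idx, aa=letter,
            n=np.array([picked["N"].pos.x, picked["N"].pos.y, picked["N"].pos.z]),
            ca=np.array([picked["CA"].pos.x, picked["CA"].pos.y, picked["CA"].pos.z]),
            c=np.array([picked["C"].pos.x, picked["C"].pos.y, picked["C"].pos.z]),
            o=np.array([picked["O"].pos.x, picked["O"].pos.y, picked["O"].pos.z])))
    if not records:
        raise ValueError("no polymer residues")
    return records


def compute_dihedrals(residues: list[ResidueRecord]) -> BackboneGeometry:
    """IUPAC phi/psi per residue; NaN at chain termini and degenerate quadruples."""
    if len(residues) < 3:
        raise ValueError("need at least 3 residues for dihedrals")
    n = len(residues)
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    for i in range(n):
        if i > 0:
            phi[i] = dihedral(residues[i - 1].c, residues[i].n,
                              residues[i].ca, residues[i].c)
        if i < n - 1:
            psi[i] = dihedral(residues[i].n, residues[i].ca,
                              residues[i].c, residues[i + 1].n)
    return BackboneGeometry(phi=phi, psi=psi)


def _in(window, x):
    return window[0] <= x <= window[1]


def label_residues(geometry: BackboneGeometry,
                   config: AnnotationConfig | None = None) -> list[str]:
    """Per-residue secondary-structure label from the phi/psi windows."""
    cfg = config or AnnotationConfig()
    labels = []
    for phi, psi in zip(geometry.phi, geometry.psi):
        if np.isnan(phi) or np.isnan(psi):
            labels.append(OTHER_SS)
        elif _in(cfg.beta_phi, phi) and (_in(cfg.beta_psi, psi) or
                                         (cfg.beta_psi_wrap[0] <= psi < cfg.beta_psi_wrap[1])):
            labels.append(STRAND_LIKE)
        elif _in(cfg.alpha_phi, phi) and _in(cfg.alpha_psi, psi):
            labels.append(HELIX_LIKE)
        else:
            labels.append(OTHER_SS)
    return labels


def detect_hbonds(residues: list[ResidueRecord],
                  config: AnnotationConfig | None = None) -> list[tuple[int, int]]:
    """Backbone H-bond candidates: donor N(i) within cutoff of acceptor O(j),
    |i - j| >= min_sep. Returns 1-based residue index pairs (donor, acceptor)."""
    cfg = config or AnnotationConfig()
    npos = np.array([r.n for r in residues])
    opos = np.array([r.o for r in residues])
    tree = cKDTree(opos)
    pairs = []
    for i, nn in enumerate(npos):
        for j in tree.query_ball_point(nn, cfg.hbond_cutoff):
            if abs(residues[i].seq_index - residues[j].seq_index) >= cfg.hbond_min_sep:
                pairs.append((residues[i].seq_index, residues[j].seq_index))
    pairs.sort()
    return pairs


def _strand_runs(labels: list[str], cfg: AnnotationConfig) -> list[tuple[int, int]]:
    """Maximal strand-like runs (1-based inclusive), tolerating short
    internal bulges of non-strand residues."""
    runs = []
    start = None
    for i, lab in enumerate(labels, start=1):
        if lab == STRAND_LIKE:
            if start is None:
                start = i
            end = i
        elif start is not None:
            runs.append((start, end))
            start = None
    if start is not None:
        runs.append((start, end))
    # bulge merging
    merged = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 <= cfg.bulge_tolerance:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    return [r for r in merged if r[1] - r[0] + 1 >= cfg.min_strand_len]


def assemble_strands(labels: list[str], hbonds: list[tuple[int, int]],
                     config: AnnotationConfig | None = None,
                     protein_id: str = "") -> StrandAnnotation:
    """Strands = strand-like runs connected to another run by at least
    min_ladder_bonds hydrogen bonds; numbered 1..n from the N-terminus."""
    cfg = config or AnnotationConfig()
    runs = _strand_runs(labels, cfg)
    if not runs:
        raise NoBarrelError("no barrel: no strand-like runs")

    def run_of(pos):
        for ri, (s, e) in enumerate(runs):
            if s <= pos <= e:
                return ri
        return None

    alive = set(range(len(runs)))
    while True:
        counts: dict[tuple[int, int], int] = {}
        for i, j in hbonds:
            a, b = run_of(i), run_of(j)
            if a is None or b is None or a == b:
                continue
            if a not in alive or b not in alive:
                continue
            key = (min(a, b), max(a, b))
            counts[key] = counts.get(key, 0) + 1
        keep = set()
        for (a, b), c in counts.items():
            if c >= cfg.min_ladder_bonds:
                keep.add(a)
                keep.add(b)
        if keep == alive:
            break
        alive = keep
        if not alive:
            raise NoBarrelError("no barrel: no hydrogen-bonded strand ladder")
    strands = [runs[i] for i in sorted(alive)]
    ann = StrandAnnotation(strands=strands, protein_id=protein_id)
    ann.validate()
    return ann


def strand_directions(annotation: StrandAnnotation,
                      residues: list[ResidueRecord]) -> list[int]:
    """Per-strand membrane direction (+1 periplasm->extracellular).

    The barrel axis is the mean of the sign-aligned per-strand end-to-end
    Calpha vectors (a plain principal axis of the coordinates degenerates for
    wide barrels, where the radial spread exceeds the axial one), signed so
    that the chain termini lie on the negative (periplasmic) side.
    """
    if annotation.n_strands < 4:
        raise ValueError("need at least 4 strands for a barrel axis")
    by_index = {r.seq_index: r for r in residues}
    coords = []
    vecs = []
    for s, e in annotation.strands:
        for pos in range(s, e + 1):
            if pos in by_index:
                coords.append(by_index[pos].ca)
        if s in by_index and e in by_index:
            vecs.append(by_index[e].ca - by_index[s].ca)
    coords = np.asarray(coords)
    center = coords.mean(axis=0)
    ref = vecs[0]
    aligned = [v if v @ ref >= 0 else -v for v in vecs]
    axis = np.mean(aligned, axis=0)
    norm = np.linalg.norm(axis)
    if norm < 1e-6:
        raise ValueError("degenerate axis: strand vectors cancel")
    axis = axis / norm
    proj = (coords - center) @ axis
    if proj.max() - proj.min() < 3.0:
        raise ValueError("degenerate axis: structure too flat for a barrel")
    term = np.array([residues[0].ca, residues[-1].ca])
    if ((term - center) @ axis).mean() > 0:
        axis = -axis
    dirs = []
    for s, e in annotation.strands:
        z_first = (by_index[s].ca - center) @ axis
        z_last = (by_index[e].ca - center) @ axis
        dirs.append(1 if z_last >= z_first else -1)
    return dirs


def annotate(residues: list[ResidueRecord],
             config: AnnotationConfig | None = None,
             protein_id: str = "") -> StrandAnnotation:
    """Full annotation pipeline: dihedrals -> labels -> H-bonds -> strands
    -> directions."""
    cfg = config or AnnotationConfig()
    geom = compute_dihedrals(residues)
    labels = label_residues(geom, cfg)
    hbonds = detect_hbonds(residues, cfg)
    ann = assemble_strands(labels, hbonds, cfg, protein_id=protein_id)
    try:
        ann.directions = strand_directions(ann, residues)
    except ValueError:
        ann.directions = None
    return ann


@dataclass
class VariantResult:
    """Longest/shortest strand definitions over alternative structures."""
    longest: StrandAnnotation
    shortest: StrandAnnotation
    flags: list[str] = field(default_factory=list)

    @property
    def consistent(self) -> bool:
        return not self.flags


def annotation_variants(annotations: list[StrandAnnotation]) -> VariantResult:
    """Per strand slot, the union (longest) and intersection (shortest)
    interval across alternative structures of the same protein.

    Annotations disagreeing on strand count are flagged; the variant is then
    computed from the majority strand count, keeping all inputs recorded in
    the flag.
    """
    if not annotations:
        raise ValueError("need at least one annotation")
    flags = []
    counts = [a.n_strands for a in annotations]
    if len(set(counts)) > 1:
        flags.append("alternative structure changes strand count: "
                     + ",".join(map(str, counts)))
        majority = max(set(counts), key=counts.count)
        used = [a for a in annotations if a.n_strands == majority]
    else:
        used = list(annotations)
    longest, shortest = [], []
    for slot in range(used[0].n_strands):
        starts = [a.strands[slot][0] for a in used]
        ends = [a.strands[slot][1] for a in used]
        longest.append((min(starts), max(ends)))
        lo, hi = max(starts), min(ends)
        if lo > hi:
            flags.append(f"strand {slot + 1}: empty intersection, union kept")
            lo, hi = min(starts), max(ends)
        shortest.append((lo, hi))
    pid = used[0].protein_id
    return VariantResult(
        longest=StrandAnnotation(strands=longest, directions=used[0].directions,
                                 protein_id=pid),
        shortest=StrandAnnotation(strands=shortest, directions=used[0].directions,
                                  protein_id=pid),
        flags=flags)


# --------------------------------------------------------------------------
# annotation table I/O

def write_annotations(annotations: list[StrandAnnotation]) -> str:
    """TSV: protein_id, strand_index (1-based), start, end, direction."""
    out = io.StringIO()
    out.write("protein_id\tstrand_index\tstart\tend\tdirection\n")
    for ann in annotations:
        dirs = ann.directions or [0] * ann.n_strands
        for i, ((s, e), d) in enumerate(zip(ann.strands, dirs), start=1):
            out.write(f"{ann.protein_id}\t{i}\t{s}\t{e}\t{d}\n")
    return out.getvalue()


def read_annotations(text: str) -> dict[str, StrandAnnotation]:
    rows = [ln.split("\t") for ln in text.strip().splitlines()[1:] if ln.strip()]
    grouped: dict[str, list] = {}
    for pid, idx, s, e, d in rows:
        grouped.setdefault(pid, []).append((int(idx), int(s), int(e), int(d)))
    out = {}
    for pid, items in grouped.items():
        items.sort()
        ann = StrandAnnotation(strands=[(s, e) for _, s, e, _ in items],
                               directions=[d for *_, d in items],
                               protein_id=pid)
        ann.validate()
        out[pid] = ann
    return out
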