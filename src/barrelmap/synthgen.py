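"""Idealized outer-membrane beta-barrel generator with planted ground truth.

Builds closed, even-stranded, antiparallel barrels from a cylindrical lattice
model: n strands of spacing b (Angstrom) tilted by the shear number S, with
Calpha sites on a cylinder of radius

    R = sqrt((n*b)^2 + (S*a)^2) / (2*pi)

where a is the rise per residue along a strand. Backbone N/CA/C/O atoms are
placed from an ideal beta-strand template so that phi/psi fall in the
beta-sheet region and carbonyls point at the neighbouring strand's amide,
giving a detectable inter-strand hydrogen-bond ladder. Loops and tails use the
mirror-image template, which lands their dihedrals outside the beta region.

Sequences follow the lipid-facing/pore-facing pleat: strand residues
alternate nonpolar/polar letters, loops are all-polar. A seeded,
class-preserving substitution rate adds letter diversity without changing any
polarity statistic.

Alignment scenarios plant known topological relationships (C-/N-terminal
anchoring, internal offsets, hairpin-shift self-alignments, loop-to-hairpin
transitions, large rearrangements, single-strand topology flips) as
residue-level alignment records whose strand-level interpretation is known
exactly.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import _geom
from .types import (AlignmentRecord, ResidueRecord, StrandAnnotation,
                    CTERM_ANCHORED, NTERM_ANCHORED, INTERNAL_OFFSET,
                    LOOP_TO_HAIRPIN, LARGE_REARRANGEMENT, OTHER,
                    HAIRPIN_SHIFT, DOUBLE_HAIRPIN_SHIFT, REPEAT_NONE)

NONPOLAR_STRAND = "L"
POLAR_STRAND = "T"
POLAR_LOOP = "S"
# class-preserving substitution alphabets (subsets of the polar/nonpolar partition)
NONPOLAR_ALT = "AFILMVWY"
POLAR_ALT = "CDEGHKNQRST"

AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

SCENARIO_KINDS = (
    "cterm_duplication", "nterm_duplication", "internal_offset",
    "hairpin_shift_self", "double_hairpin_shift_self", "loop_to_hairpin",
    "large_rearrangement", "topology_flip",
)


@dataclass
class BarrelSpec:
    """Parameters of one idealized barrel.

    shear defaults to n_strands + 2, which gives strand tilts around 35-45
    degrees and per-hairpin radius increments close to the ~1.66 A observed
    for real barrels.
    """
    n_strands: int
    shear: Optional[int] = None
    rise_per_residue: float = 3.3
    strand_spacing: float = 4.4
    residues_per_strand: int = 10
    loop_length_extracellular: int = 5
    loop_length_periplasmic: int = 4
    tail_length: int = 2
    seed: int = 0
    substitution_rate: float = 0.1
    loop_overrides: dict = field(default_factory=dict)  # loop index (1-based) -> length

    @property
    def S(self) -> int:
        return self.n_strands + 2 if self.shear is None else self.shear

    def validate(self) -> None:
        if self.n_strands % 2 != 0:
            raise ValueError("n_strands must be even (closed up-down barrel)")
        if self.n_strands < 4:
            raise ValueError("n_strands must be >= 4")
        if self.residues_per_strand < 3:
            raise ValueError("residues_per_strand must be >= 3")
        for v in (self.rise_per_residue, self.strand_spacing):
            if v <= 0:
                raise ValueError("lengths must be positive")
        if self.loop_length_extracellular < 2 or self.loop_length_periplasmic < 2:
            raise ValueError("loop lengths must be >= 2")

    def loop_length(self, loop_index: int) -> int:
        """Length of the loop after strand loop_index (1-based).

        Odd-indexed loops sit on the extracellular face (they follow an
        outward-pointing strand), even-indexed loops on the periplasmic face.
        """
        if loop_index in self.loop_overrides:
            return int(self.loop_overrides[loop_index])
        if loop_index % 2 == 1:
            return self.loop_length_extracellular
        return self.loop_length_periplasmic


def barrel_radius(spec: BarrelSpec) -> float:
    """Closed-form cylinder radius of the Calpha lattice."""
    n, S = spec.n_strands, spec.S
    a, b = spec.rise_per_residue, spec.strand_spacing
    return math.sqrt((n * b) ** 2 + (S * a) ** 2) / (2.0 * math.pi)


@dataclass
class Barrel:
    """A generated barrel: residue records, sequence and planted truth."""
    residues: list
    sequence: str
    annotation: StrandAnnotation
    spec: BarrelSpec
    regions: list  # ordered (kind, index, start, end) covering the chain

    def __len__(self) -> int:
        return len(self.residues)

    def region_span(self, kind: str, index: int) -> tuple[int, int]:
        for k, i, s, e in self.regions:
            if k == kind and i == index:
                return (s, e)
        raise KeyError(f"no region {kind} {index}")


def _loop_path(a: np.ndarray, b: np.ndarray, n_res: int, face: int) -> np.ndarray:
    """CA sites for a loop of n_res residues between anchor sites a and b,
    bulging along +/-z so the path length fits ~3.5 A per residue."""
    target = 3.5 * (n_res + 1)
    f = np.array([0.0, 0.0, float(face)])
    ts = np.linspace(0.0, 1.0, 64)

    def arclen(h):
        pts = a[None, :] * (1 - ts[:, None]) + b[None, :] * ts[:, None] \
            + h * np.sin(np.pi * ts)[:, None] * f[None, :]
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())

    lo, hi = 0.0, 40.0
    if arclen(0.0) < target:
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if arclen(mid) < target:
                lo = mid
            else:
                hi = mid
    h = 0.5 * (lo + hi)
    # place residues at equal arc-length fractions
    pts = a[None, :] * (1 - ts[:, None]) + b[None, :] * ts[:, None] \
        + h * np.sin(np.pi * ts)[:, None] * f[None, :]
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    out = []
    for i in range(1, n_res + 1):
        s = total * i / (n_res + 1)
        j = int(np.searchsorted(cum, s, side="right") - 1)
        j = min(j, len(seg) - 1)
        frac = (s - cum[j]) / max(seg[j], 1e-9)
        out.append(pts[j] * (1 - frac) + pts[j + 1] * frac)
    return np.asarray(out)


LOOP_PHI = 70.0  # left-handed loop torsions: deterministically outside the
LOOP_PSI = 40.0  # beta and alpha labelling windows


def _loop_entries(a_site: np.ndarray, b_site: np.ndarray, path: np.ndarray):
    """Loop residues with precomputed atoms.

    An ideal-geometry fragment built at fixed left-handed torsions is rigidly
    fitted onto the bulged CA path (with the two strand anchor sites as extra
    fit targets), so every interior loop residue's phi/psi equal the fixed
    non-beta values regardless of where the loop sits on the barrel.
    """
    L = len(path)
    frag = _geom.build_chain([LOOP_PHI] * (L + 2), [LOOP_PSI] * (L + 2))
    src = frag["CA"]
    dst = np.vstack([a_site, path, b_site])
    src_c = src - src.mean(axis=0)
    dst_c = dst - dst.mean(axis=0)
    h = src_c.T @ dst_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    shift = dst.mean(axis=0) - rot @ src.mean(axis=0)
    out = []
    for i in range(1, L + 1):
        atoms = {a: rot @ frag[a][i] + shift for a in ("N", "CA", "C", "O")}
        out.append(dict(kind="loop", atoms=atoms))
    return out


def _frame_atoms(site, d_hat, w_hat, offsets, mirror=False):
    """Place N/CA/C/O at a CA site given chain direction d and pleat normal w.

    The template frame is right-handed (u, v, w) with u = v x w; mirroring
    negates the w components, producing the mirror-image (non-beta) residue.
    """
    w_hat = w_hat - (w_hat @ d_hat) * d_hat
    w_hat = w_hat / np.linalg.norm(w_hat)
    u_hat = np.cross(d_hat, w_hat)
    sign = -1.0 if mirror else 1.0
    out = {}
    for atom, (u, v, w) in offsets.items():
        out[atom] = site + u * u_hat + v * d_hat + sign * w * w_hat
    return out


def generate_barrel(spec: BarrelSpec, protein_id: str = "SYN") -> Barrel:
    """Generate one idealized barrel with planted strand annotation.

    Returns a Barrel whose residues carry full backbone coordinates, whose
    sequence encodes the pleat polarity pattern, and whose annotation is the
    ground-truth strand table (directions alternate starting +1; both termini
    on the periplasmic face).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_strands, spec.residues_per_strand
    a, b = spec.rise_per_residue, spec.strand_spacing
    R = barrel_radius(spec)
    alpha = math.atan2(spec.S * a, n * b)
    ca, sa = math.cos(alpha), math.sin(alpha)
    du = b / ca  # horizontal offset between strand lines at equal height

    template, _rise = _geom.strand_template()

    # --- lattice sites -----------------------------------------------------
    # (strand k, height j): unrolled (u, v); parity p = j % 2 decides pleat
    # facing and which neighbour strand receives this residue's carbonyl.
    def site_uv(k, j):
        v = (j - (m - 1) / 2.0) * a * ca
        u = k * du + v * math.tan(alpha)
        return u, v

    def to3d(u, v):
        th = u / R
        return np.array([R * math.cos(th), R * math.sin(th), v])

    def strand_frame(k, j, chain_up):
        u, v = site_uv(k, j)
        th = u / R
        w_hat = np.array([math.cos(th), math.sin(th), 0.0])  # radial out
        t_hat = np.array([-math.sin(th), math.cos(th), 0.0])
        d_hat = sa * t_hat + ca * np.array([0.0, 0.0, 1.0])
        if not chain_up:
            d_hat = -d_hat
        return to3d(u, v), d_hat, w_hat

    def lattice_atoms(k, j):
        """Backbone atoms of the (possibly virtual) lattice site (k, j)."""
        up = (k % 2 == 0)
        site, d_hat, w_hat = strand_frame(k, j, up)
        parity = j % 2
        return _frame_atoms(site, d_hat, w_hat, template[parity], mirror=False)

    # --- assemble the chain ------------------------------------------------
    # entries: dicts with atoms + bookkeeping (kind, strand k, height j, parity)
    chain = []
    regions = []  # (kind, index, start, end) 1-based inclusive
    # loop/tail residues flanking a strand get junction atoms from the virtual
    # lattice extension of that strand, so that the strand-edge residues' own
    # phi/psi stay inside the beta window: (chain index, atom names, k, j_ext)
    junctions = []
    z_hat = np.array([0.0, 0.0, 1.0])

    def add_tail(anchor, going_up, length, before):
        ents = []
        for i in range(length):
            off = (length - i) if before else (i + 1)
            site = anchor - off * 3.4 * z_hat
            d_hat = z_hat if going_up else -z_hat
            th = math.atan2(site[1], site[0])
            w_hat = np.array([math.cos(th), math.sin(th), 0.0])
            ents.append(dict(site=site, d=d_hat, w=w_hat, kind="tail",
                             parity=i % 2, mirror=True))
        return ents if before else list(ents)

    strand_entries = {}  # (k, j) -> chain position (filled later)

    first_site, _, _ = strand_frame(0, 0, True)
    chain.extend(add_tail(first_site, True, spec.tail_length, before=True))
    if spec.tail_length:
        regions.append(("loop", 0, 1, spec.tail_length))
        junctions.append((spec.tail_length - 1, ("C", "O"), 0, -1))

    for k in range(n):
        up = (k % 2 == 0)
        heights = range(m) if up else range(m - 1, -1, -1)
        start = len(chain) + 1
        for j in heights:
            site, d_hat, w_hat = strand_frame(k, j, up)
            chain.append(dict(site=site, d=d_hat, w=w_hat, kind="strand",
                              k=k, j=j, parity=j % 2, mirror=False))
            strand_entries[(k, j)] = len(chain) - 1
        regions.append(("strand", k + 1, start, len(chain)))
        if k < n - 1:
            # loop from the end of strand k to the start of strand k+1
            face = 1 if up else -1
            lj = m - 1 if up else 0
            nj = m - 1 if not up else 0  # entry height of next strand
            a_site, _, _ = strand_frame(k, lj, up)
            b_site, _, _ = strand_frame(k + 1, nj, not up)
            llen = spec.loop_length(k + 1)
            path = _loop_path(a_site, b_site, llen, face)
            lstart = len(chain) + 1
            for ent in _loop_entries(a_site, b_site, path):
                chain.append(ent)
            regions.append(("loop", k + 1, lstart, len(chain)))
            j_exit = m if up else -1
            j_entry = m if up else -1  # next strand runs opposite: same side
            junctions.append((lstart - 1, ("N",), k, j_exit))
            junctions.append((len(chain) - 1, ("C", "O"), k + 1, j_entry))

    last_up = (n - 1) % 2 == 0
    last_site, _, _ = strand_frame(n - 1, 0 if not last_up else m - 1, last_up)
    if spec.tail_length:
        cstart = len(chain) + 1
        chain.extend(add_tail(last_site, False, spec.tail_length, before=False))
        regions.append(("loop", n, cstart, len(chain)))
        junctions.append((cstart - 1, ("N",), n - 1, m if last_up else -1))

    # --- place atoms -------------------------------------------------------
    atoms = []
    for ent in chain:
        if "atoms" in ent:
            atoms.append(dict(ent["atoms"]))
        else:
            atoms.append(_frame_atoms(ent["site"], ent["d"], ent["w"],
                                      {a_: template[ent["parity"]][a_] for a_ in ("N", "CA", "C", "O")},
                                      mirror=ent["mirror"]))
    for chain_idx, names, k, j_ext in junctions:
        ext = lattice_atoms(k, j_ext)
        for name in names:
            atoms[chain_idx][name] = ext[name]

    # carbonyl re-pointing: each strand residue's O aims at the amide N of its
    # hydrogen-bond partner on the neighbouring strand (parity picks the side)
    tan_a = math.tan(alpha)
    for idx, ent in enumerate(chain):
        if ent["kind"] != "strand":
            continue
        k, j, p = ent["k"], ent["j"], ent["parity"]
        nk = (k + 1) % n if p == 0 else (k - 1) % n
        sgn = 1.0 if p == 0 else -1.0
        best, best_d2 = None, None
        _, vj = site_uv(k, j)
        for jj in range(max(0, j - 2), min(m, j + 3)):
            _, vjj = site_uv(nk, jj)
            s = vjj - vj
            d2 = (sgn * du + s * tan_a) ** 2 + s ** 2
            if best_d2 is None or d2 < best_d2:
                best, best_d2 = jj, d2
        partner = strand_entries.get((nk, best))
        if partner is None:
            continue
        n_pos = atoms[partner]["N"]
        c_pos = atoms[idx]["C"]
        direction = n_pos - c_pos
        nd = np.linalg.norm(direction)
        if nd > 1e-6:
            atoms[idx]["O"] = c_pos + _geom.BOND_C_O * direction / nd

    # --- sequence ----------------------------------------------------------
    letters = []
    for ent in chain:
        if ent["kind"] == "strand":
            base = NONPOLAR_STRAND if ent["parity"] == 0 else POLAR_STRAND
            alt = NONPOLAR_ALT if ent["parity"] == 0 else POLAR_ALT
        else:
            base, alt = POLAR_LOOP, POLAR_ALT
        if rng.random() < spec.substitution_rate:
            letters.append(alt[rng.integers(len(alt))])
        else:
            letters.append(base)
    sequence = "".join(letters)

    residues = [ResidueRecord(seq_index=i + 1, aa=letters[i],
                              n=atoms[i]["N"], ca=atoms[i]["CA"],
                              c=atoms[i]["C"], o=atoms[i]["O"])
                for i in range(len(chain))]
    strands = [(s, e) for kind, _, s, e in regions if kind == "strand"]
    directions = [1 if k % 2 == 0 else -1 for k in range(n)]
    annotation = StrandAnnotation(strands=strands, directions=directions,
                                  protein_id=protein_id)
    annotation.validate()
    return Barrel(residues=residues, sequence=sequence, annotation=annotation,
                  spec=spec, regions=regions)


# --------------------------------------------------------------------------
# writers

def to_pdb(barrel: Barrel, protein_id: str = None) -> str:
    """Serialize backbone atoms as single-chain PDB ATOM records."""
    name = protein_id or barrel.annotation.protein_id or "SYN"
    lines = [f"HEADER    SYNTHETIC BARREL {name}"]
    serial = 1
    for res in barrel.residues:
        res3 = AA3.get(res.aa, "GLY")
        for atom_name, pos in (("N", res.n), ("CA", res.ca), ("C", res.c), ("O", res.o)):
            pad = f" {atom_name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {pad} {res3} A{res.seq_index:4d}    "
                f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}  1.00  0.00"
                f"          {atom_name[0]:>2s}")
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def to_fasta(barrel: Barrel, protein_id: str = None, width: int = 60) -> str:
    name = protein_id or barrel.annotation.protein_id or "SYN"
    seq = barrel.sequence
    body = "\n".join(seq[i:i + width] for i in range(0, len(seq), width))
    return f">{name}\n{body}\n"


# --------------------------------------------------------------------------
# alignment scenarios

@dataclass
class ScenarioSpec:
    """One planted alignment scenario between two generated barrels."""
    kind: str
    n_query: int = 8
    n_target: int = 16
    residues_per_strand: int = 10
    noise: float = 0.0  # fraction of alignment columns deleted at random
    seed: int = 0

    def validate(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.n_query % 2 or self.n_target % 2:
            raise ValueError("strand counts must be even")
        if self.kind.endswith("_self") and self.n_query != self.n_target:
            raise ValueError("self scenarios require a single barrel (nQ == nT)")
        if not (0.0 <= self.noise < 1.0):
            raise ValueError("noise must be in [0, 1)")


@dataclass
class ScenarioTruth:
    """Planted ground truth of a scenario."""
    kind: str
    strand_pairs: list  # (q_strand, t_strand)
    cross_matches: list  # (q_kind, q_idx, t_kind, t_idx)
    expected_category: str
    expected_repeat_class: str
    expected_flips: int

    def to_json(self) -> str:
        return json.dumps({
            "kind": self.kind,
            "strand_pairs": self.strand_pairs,
            "cross_matches": self.cross_matches,
            "expected_category": self.expected_category,
            "expected_repeat_class": self.expected_repeat_class,
            "expected_flips": self.expected_flips,
        }, indent=1)


def _positions(barrel: Barrel, kind: str, idx: int) -> list[int]:
    s, e = barrel.region_span(kind, idx)
    return list(range(s, e + 1))


def _pairs_from_region_map(q: Barrel, t: Barrel, region_map) -> list[tuple[int, int]]:
    """Residue-level aligned pairs from matched region lists.

    region_map: list of (q_regions, t_regions) where each side is a list of
    ("strand"|"loop", index). The concatenated position lists of the two
    sides of each entry must have equal length.
    """
    pairs = []
    for q_regions, t_regions in region_map:
        qp = [p for kind, i in q_regions for p in _positions(q, kind, i)]
        tp = [p for kind, i in t_regions for p in _positions(t, kind, i)]
        if len(qp) != len(tp):
            raise AssertionError(
                f"region map length mismatch: {q_regions}({len(qp)}) vs {t_regions}({len(tp)})")
        pairs.extend(zip(qp, tp))
    pairs.sort()
    return pairs


def _plant_strandlike_loop(barrel: Barrel, loop_idx: int) -> None:
    """Overwrite a loop's sequence with the alternating nonpolar/polar
    pattern of a strand — the sequence signature of a region caught mid
    loop<->strand transition."""
    s, e = barrel.region_span("loop", loop_idx)
    seq = list(barrel.sequence)
    for pos in range(s, e + 1):
        seq[pos - 1] = NONPOLAR_STRAND if (pos - s) % 2 == 0 else POLAR_STRAND
        barrel.residues[pos - 1].aa = seq[pos - 1]
    barrel.sequence = "".join(seq)


def _base_spec(n, m, seed, overrides=None) -> BarrelSpec:
    return BarrelSpec(n_strands=n, residues_per_strand=m, seed=seed,
                      loop_overrides=overrides or {})


def generate_alignment_scenario(spec: ScenarioSpec):
    """Generate (query Barrel, target Barrel, AlignmentRecord, ScenarioTruth).

    For self scenarios the same Barrel object is returned on both sides.
    The record's residue pairs, mapped through the two ground-truth
    annotations, realize exactly the planted relationship.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nQ, nT, m = spec.n_query, spec.n_target, spec.residues_per_strand
    base = BarrelSpec(n_strands=4, residues_per_strand=m)  # default loop lengths
    e = base.loop_length_extracellular
    p = base.loop_length_periplasmic

    def strands_and_loops(lo, hi, t_off):
        """Identity-style region map entries strand-by-strand plus loops."""
        out = []
        for i in range(lo, hi + 1):
            out.append(([("strand", i)], [("strand", i + t_off)]))
            if i < hi:
                out.append(([("loop", i)], [("loop", i + t_off)]))
        return out

    q_over, t_over = {}, {}
    region_map = []
    truth_cross = []
    expected_flips = 0
    repeat_class = REPEAT_NONE
    category = OTHER

    if spec.kind in ("cterm_duplication", "nterm_duplication"):
        if spec.kind == "cterm_duplication":
            if nT <= nQ:
                raise ValueError("cterm_duplication requires n_target > n_query")
            off = nT - nQ
            category = CTERM_ANCHORED
        else:
            if nT < nQ:
                raise ValueError("nterm_duplication requires n_target >= n_query")
            off = 0
            category = NTERM_ANCHORED
        region_map = strands_and_loops(1, nQ, off)
        strand_pairs = [(i, i + off) for i in range(1, nQ + 1)]

    elif spec.kind == "internal_offset":
        d = nT - nQ
        c = d - 2 if d >= 4 else d + 2
        qa, qb = 2, min(nQ - 1, nT - c)
        if qb - qa < 1:
            raise ValueError("barrels too small for internal_offset")
        region_map = strands_and_loops(qa, qb, c)
        strand_pairs = [(i, i + c) for i in range(qa, qb + 1)]
        category = INTERNAL_OFFSET

    elif spec.kind in ("hairpin_shift_self", "double_hairpin_shift_self"):
        off = 2 if spec.kind == "hairpin_shift_self" else 4
        if nQ - off < 2:
            raise ValueError("barrel too small for the requested shift")
        region_map = strands_and_loops(1, nQ - off, off)
        strand_pairs = [(i, i + off) for i in range(1, nQ - off + 1)]
        repeat_class = HAIRPIN_SHIFT if off == 2 else DOUBLE_HAIRPIN_SHIFT

    elif spec.kind == "loop_to_hairpin":
        if nT != nQ + 2:
            raise ValueError("loop_to_hairpin requires n_target == n_query + 2")
        k = 3 if nQ >= 8 else 1
        q_over = {k: e + m + p + m + e}  # long extracellular loop absorbs the hairpin
        region_map = strands_and_loops(1, k, 0)
        region_map.append(([("loop", k)],
                           [("loop", k), ("strand", k + 1), ("loop", k + 1),
                            ("strand", k + 2), ("loop", k + 2)]))
        region_map += strands_and_loops(k + 1, nQ, 2)
        strand_pairs = [(i, i) for i in range(1, k + 1)] + \
                       [(i, i + 2) for i in range(k + 1, nQ + 1)]
        truth_cross = [("loop", k, "strand", k + 1), ("loop", k, "strand", k + 2)]
        category = LOOP_TO_HAIRPIN

    elif spec.kind == "large_rearrangement":
        if nT != nQ + 2:
            raise ValueError("large_rearrangement requires n_target == n_query + 2")
        if nQ < 10:
            raise ValueError("large_rearrangement requires n_query >= 10")
        k = 3
        # loop k -> hairpin (strands k+1, k+2); loop k+1 -> strand k+4 (single
        # insertion, odd offset); strand k+3 -> loop k+5 (correction). The
        # single insertion makes strand pair (k+2 -> k+5) flip direction.
        q_over = {k: e + m + p + m + e,      # covers T hairpin k+1, k+2
                  k + 1: p + m + e}          # covers T strand k+4
        t_over = {k + 5: m + p}              # absorbs Q strand k+3 + loop k+3
        region_map = strands_and_loops(1, k, 0)
        region_map.append(([("loop", k)],
                           [("loop", k), ("strand", k + 1), ("loop", k + 1),
                            ("strand", k + 2), ("loop", k + 2)]))
        region_map.append(([("strand", k + 1)], [("strand", k + 3)]))
        region_map.append(([("loop", k + 1)],
                           [("loop", k + 3), ("strand", k + 4), ("loop", k + 4)]))
        region_map.append(([("strand", k + 2)], [("strand", k + 5)]))
        region_map.append(([("strand", k + 3), ("loop", k + 3)],
                           [("loop", k + 5)]))
        region_map += strands_and_loops(k + 4, nQ, 2)
        strand_pairs = [(i, i) for i in range(1, k + 1)] + \
                       [(k + 1, k + 3), (k + 2, k + 5)] + \
                       [(i, i + 2) for i in range(k + 4, nQ + 1)]
        truth_cross = [("loop", k, "strand", k + 1), ("loop", k, "strand", k + 2),
                       ("loop", k + 1, "strand", k + 4),
                       ("strand", k + 3, "loop", k + 5)]
        expected_flips = 1
        category = LARGE_REARRANGEMENT

    elif spec.kind == "topology_flip":
        if nT != nQ:
            raise ValueError("topology_flip scenario uses equal strand counts")
        if nQ < 8:
            raise ValueError("topology_flip requires n_query >= 8")
        k = 3
        # single-strand insertion (loop k -> strand k+1) flips strand k+1 of Q
        # against strand k+2 of T; a strand-to-loop correction restores the
        # downstream register.
        q_over = {k: e + m + p}
        t_over = {k + 2: p + m + e}
        region_map = strands_and_loops(1, k, 0)
        region_map.append(([("loop", k)],
                           [("loop", k), ("strand", k + 1), ("loop", k + 1)]))
        region_map.append(([("strand", k + 1)], [("strand", k + 2)]))
        region_map.append(([("loop", k + 1), ("strand", k + 2), ("loop", k + 2)],
                           [("loop", k + 2)]))
        region_map += strands_and_loops(k + 3, nQ, 0)
        strand_pairs = [(i, i) for i in range(1, k + 1)] + [(k + 1, k + 2)] + \
                       [(i, i) for i in range(k + 3, nQ + 1)]
        truth_cross = [("loop", k, "strand", k + 1),
                       ("strand", k + 2, "loop", k + 2)]
        expected_flips = 1
        category = OTHER

    else:  # pragma: no cover - guarded by validate()
        raise AssertionError(spec.kind)

    seed_q = int(rng.integers(2 ** 31))
    seed_t = int(rng.integers(2 ** 31))
    q = generate_barrel(_base_spec(nQ, m, seed_q, q_over), protein_id=f"Q{spec.seed:04d}")
    if spec.kind.endswith("_self"):
        t = q
    else:
        t = generate_barrel(_base_spec(nT, m, seed_t, t_over), protein_id=f"T{spec.seed:04d}")

    for qk, qi, tk, ti in truth_cross:
        if qk == "loop":
            _plant_strandlike_loop(q, qi)
        if tk == "loop":
            _plant_strandlike_loop(t, ti)

    pairs = _pairs_from_region_map(q, t, region_map)
    if spec.noise > 0:
        keep = rng.random(len(pairs)) >= spec.noise
        pairs = [pr for pr, k_ in zip(pairs, keep) if k_]

    evalue = float(10 ** rng.uniform(-20, -3))
    probability = float(rng.uniform(80, 99))
    record = AlignmentRecord(query_id=q.annotation.protein_id,
                             target_id=t.annotation.protein_id,
                             evalue=evalue, probability=probability,
                             aligned_pairs=pairs)
    record.validate()
    truth = ScenarioTruth(kind=spec.kind, strand_pairs=strand_pairs,
                          cross_matches=truth_cross,
                          expected_category=category,
                          expected_repeat_class=repeat_class,
                          expected_flips=expected_flips)
    return q, t, record, truth


# --------------------------------------------------------------------------
# HMM-membership fixtures

def generate_membership(n_profiles: int, planted_overlap: float, seed: int = 0,
                        set_size: int = 40) -> dict[str, set[str]]:
    """Per-profile homolog-ID sets with a planted overlap fraction.

    Profiles are paired (0,1), (2,3), ...; each designated pair shares
    round(planted_overlap * set_size) members; all other pairs are disjoint.
    """
    if n_profiles < 2:
        raise ValueError("need at least 2 profiles")
    if not (0.0 <= planted_overlap <= 1.0):
        raise ValueError("planted_overlap must be in [0, 1]")
    rng = np.random.default_rng(seed)
    shared_n = int(round(planted_overlap * set_size))
    out: dict[str, set[str]] = {}
    uid = 0

    def fresh(count):
        nonlocal uid
        ids = {f"seq{uid + i:06d}" for i in range(count)}
        uid += count
        return ids

    for i in range(0, n_profiles - 1, 2):
        shared = fresh(shared_n)
        out[f"P{i:03d}"] = shared | fresh(set_size - shared_n)
        out[f"P{i + 1:03d}"] = shared | fresh(set_size - shared_n)
    if n_profiles % 2:
        out[f"P{n_profiles - 1:03d}"] = fresh(set_size)
    # seeded shuffle keeps the generator deterministic end to end
    _ = rng.random()
    return out
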