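"""Residue-level statistics: polarity alternation, hydropathy, volumes.

The polar/nonpolar partition is the one used throughout the analysis:
A, F, I, L, M, P, V, W, Y nonpolar; C, D, E, G, H, K, N, Q, R, S, T polar.
Hydropathy uses the bundled Kyte-Doolittle scale; residue volumes the
bundled Zamyatnin table (see data/*.tsv for citations).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .types import (LOOP_TO_HAIRPIN, LOOP_TO_HAIRPIN_ALT, LARGE_REARRANGEMENT)

NONPOLAR = set("AFILMPVWY")
POLAR = set("CDEGHKNQRST")

TRANSITION_CATEGORIES = {LOOP_TO_HAIRPIN, LOOP_TO_HAIRPIN_ALT, LARGE_REARRANGEMENT}


def _load_scale(name: str) -> dict[str, float]:
    text = resources.files("barrelmap").joinpath(f"data/{name}").read_text()
    out = {}
    for ln in text.splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        aa, val = ln.split("\t")
        out[aa] = float(val)
    return out


KD_HYDROPATHY = _load_scale("kd_hydropathy.tsv")
RESIDUE_VOLUME = _load_scale("residue_volumes.tsv")


def polarity_class(aa: str) -> str:
    """"polar" or "nonpolar" under the fixed 9/11 partition."""
    if aa in NONPOLAR:
        return "nonpolar"
    if aa in POLAR:
        return "polar"
    raise ValueError(f"unknown residue letter {aa!r}")


@dataclass
class RegionSequence:
    """A strand or loop stretch as it occurs in an alignment.

    residues may contain '-' for gap columns; gap_mask marks positions whose
    partner in the alignment is a gap (excluded from hydropathy, and
    breaking the alternation walk).
    """
    residues: str
    gap_mask: list[bool] = field(default_factory=list)
    role: str = "strand"  # "strand" | "loop"
    source: tuple = ()

    def __post_init__(self):
        if not self.gap_mask:
            self.gap_mask = [False] * len(self.residues)
        if len(self.gap_mask) != len(self.residues):
            raise ValueError("residues and gap_mask lengths differ")

    def is_gap(self, i: int) -> bool:
        return self.residues[i] == "-" or self.gap_mask[i]


def alternation_fraction(region: RegionSequence,
                         denominator: str = "region") -> float:
    """Fraction of residues whose polarity differs from the previous residue.

    The walk starts at the second position and skips positions immediately
    after a gap. denominator="region" divides by the total region length
    (the default convention); "steps" divides by the number of comparisons
    actually made.
    """
    n = len(region.residues)
    if n < 2:
        raise ValueError("region too short for alternation")
    flips = 0
    steps = 0
    for i in range(1, n):
        if region.is_gap(i) or region.is_gap(i - 1):
            continue
        steps += 1
        if polarity_class(region.residues[i]) != polarity_class(region.residues[i - 1]):
            flips += 1
    if denominator == "region":
        return flips / n
    if denominator == "steps":
        if steps == 0:
            raise ValueError("no comparable positions in region")
        return flips / steps
    raise ValueError(f"unknown denominator {denominator!r}")


def mean_hydropathy(region: RegionSequence) -> float:
    """Mean Kyte-Doolittle hydropathy over non-gap positions."""
    vals = [KD_HYDROPATHY[region.residues[i]]
            for i in range(len(region.residues)) if not region.is_gap(i)]
    if not vals:
        raise ValueError("region is entirely gap-aligned")
    return sum(vals) / len(vals)


def mean_strand_residue_volume(annotation, sequence: str) -> float:
    """Mean residue volume (A^3) over all strand residues."""
    vals = []
    for s, e in annotation.strands:
        for pos in range(s, e + 1):
            aa = sequence[pos - 1]
            if aa in RESIDUE_VOLUME:
                vals.append(RESIDUE_VOLUME[aa])
            else:
                warnings.warn(f"unknown residue {aa!r} at {pos}, skipped")
    if not vals:
        raise ValueError("no strand residues")
    return sum(vals) / len(vals)


def _identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    return sum(x == y for x, y in zip(a, b)) / n


def _dedup_regions(regions: list[RegionSequence],
                   max_identity: float = 0.5) -> list[RegionSequence]:
    """Drop regions sharing >= max_identity with an already-kept copy of the
    same protein region (first-encountered region wins)."""
    kept: list[RegionSequence] = []
    by_source: dict[tuple, list[RegionSequence]] = {}
    for reg in regions:
        prior = by_source.setdefault(reg.source, [])
        if any(_identity(reg.residues, p.residues) >= max_identity for p in prior):
            continue
        prior.append(reg)
        kept.append(reg)
    return kept


def _region_from_pairs(sequence: str, span: tuple[int, int],
                       aligned_positions: set[int], role: str,
                       source: tuple) -> RegionSequence:
    lo, hi = span
    residues = sequence[lo - 1:hi]
    mask = [pos not in aligned_positions for pos in range(lo, hi + 1)]
    return RegionSequence(residues=residues, gap_mask=mask, role=role,
                          source=source)


def transition_region_stats(records, annotations: dict, sequences: dict,
                            classified=None,
                            denominator: str = "region") -> pd.DataFrame:
    """Mean alternation and hydropathy for loop<->strand transition regions
    and their controls.

    Transition regions come from cross-matches of alignments classified as
    loop-to-hairpin (plain or alternate) or large rearrangement: the
    loop-side stretch is the "loop conformation", the strand-side stretch
    the "strand conformation". Controls are all strands and extracellular
    loops of the annotated proteins that take part in no transition
    alignment. Regions aligned multiple times enter once unless below 50%
    identity to the kept copy.
    """
    from . import topomap
    from .classify import classify_one

    loop_regions: list[RegionSequence] = []
    strand_regions: list[RegionSequence] = []
    involved: set[tuple] = set()  # (protein, kind, region index)

    for rec in records:
        ann_q = annotations.get(rec.query_id)
        ann_t = annotations.get(rec.target_id)
        if ann_q is None or ann_t is None:
            continue
        corr = topomap.map_to_strands(rec, ann_q, ann_t)
        cls = classify_one(corr, ann_q.directions, ann_t.directions)
        if cls.category not in TRANSITION_CATEGORIES:
            continue
        for cm in corr.cross_matches:
            if {cm.q_kind, cm.t_kind} != {"loop", "strand"}:
                continue
            if cm.q_kind == "loop":
                loop_id, loop_ann, loop_seq = rec.query_id, ann_q, sequences.get(rec.query_id)
                strand_id, strand_ann, strand_seq = rec.target_id, ann_t, sequences.get(rec.target_id)
                loop_idx, strand_idx = cm.q_index, cm.t_index
                pair_iter = [(q, t) for q, t in rec.aligned_pairs]
            else:
                loop_id, loop_ann, loop_seq = rec.target_id, ann_t, sequences.get(rec.target_id)
                strand_id, strand_ann, strand_seq = rec.query_id, ann_q, sequences.get(rec.query_id)
                loop_idx, strand_idx = cm.t_index, cm.q_index
                pair_iter = [(t, q) for q, t in rec.aligned_pairs]
            if loop_seq is None or strand_seq is None:
                continue
            in_match = [(lp, sp) for lp, sp in pair_iter
                        if loop_ann.region_of(lp) == ("loop", loop_idx)
                        and strand_ann.region_of(sp) == ("strand", strand_idx)]
            if not in_match:
                continue
            lpos = {lp for lp, _ in in_match}
            spos = {sp for _, sp in in_match}
            loop_regions.append(_region_from_pairs(
                loop_seq, (min(lpos), max(lpos)), lpos, "loop",
                (loop_id, "loop", loop_idx)))
            strand_regions.append(_region_from_pairs(
                strand_seq, (min(spos), max(spos)), spos, "strand",
                (strand_id, "strand", strand_idx)))
            involved.add((loop_id, "loop", loop_idx))
            involved.add((strand_id, "strand", strand_idx))

    if not loop_regions:
        warnings.warn("no loop<->strand transition alignments found")
        return pd.DataFrame(columns=["group", "n_regions", "mean_alternation",
                                     "mean_hydropathy"])

    loop_regions = _dedup_regions(loop_regions)
    strand_regions = _dedup_regions(strand_regions)

    ctrl_strands: list[RegionSequence] = []
    ctrl_loops: list[RegionSequence] = []
    for pid, ann in annotations.items():
        seq = sequences.get(pid)
        if seq is None:
            continue
        for i, (s, e) in enumerate(ann.strands, start=1):
            if (pid, "strand", i) in involved:
                continue
            ctrl_strands.append(RegionSequence(seq[s - 1:e], role="strand",
                                               source=(pid, "strand", i)))
        dirs = ann.directions or []
        for i in range(1, ann.n_strands):
            # extracellular loops follow an outward-pointing strand
            if i - 1 < len(dirs) and dirs[i - 1] != 1:
                continue
            if (pid, "loop", i) in involved:
                continue
            s_end = ann.strands[i - 1][1]
            s_next = ann.strands[i][0]
            if s_next - s_end < 3:
                continue
            ctrl_loops.append(RegionSequence(seq[s_end:s_next - 1], role="loop",
                                             source=(pid, "loop", i)))

    def summarize(name, regs):
        alts, hyds = [], []
        for r in regs:
            if len(r.residues) >= 2:
                try:
                    alts.append(alternation_fraction(r, denominator=denominator))
                    hyds.append(mean_hydropathy(r))
                except ValueError:
                    continue
        return {"group": name, "n_regions": len(alts),
                "mean_alternation": sum(alts) / len(alts) if alts else float("nan"),
                "mean_hydropathy": sum(hyds) / len(hyds) if hyds else float("nan")}

    return pd.DataFrame([
        summarize("loop_conformation", loop_regions),
        summarize("strand_conformation", strand_regions),
        summarize("control_loops", ctrl_loops),
        summarize("control_strands", ctrl_strands),
    ])
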