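"""Topological classification of strand correspondences.

Self-alignments are classified by their strand-index offset (hairpin shift =
offset 2, double hairpin shift = offset 4), cross-protein alignments by
anchoring pattern and loop<->strand cross-matches:

* CTERM_ANCHORED — every strand pair keeps a constant offset from the
  C-terminal strand (last aligns with last, penultimate with penultimate ...),
* NTERM_ANCHORED — strand indices are equal (first with first ...),
* INTERNAL_OFFSET — a constant nonzero index offset not anchored at either
  terminus,
* LOOP_TO_HAIRPIN — a loop of one barrel corresponds to a two-strand hairpin
  of the other,
* LARGE_REARRANGEMENT — a loop-to-hairpin plus a strand-to-loop plus a
  loop-to-strand transition in one alignment,
* OTHER — anything else, including single-strand topology flips.

Anchoring tolerates one outlier pair when its support is below the theta
threshold: anchoring is offset-based, not conditioned on the last strand
actually being part of the alignment.
"""
from __future__ import annotations

import warnings
from collections import Counter

import pandas as pd

from . import topomap
from .types import (CTERM_ANCHORED, NTERM_ANCHORED, INTERNAL_OFFSET,
                    LOOP_TO_HAIRPIN, LOOP_TO_HAIRPIN_ALT, LARGE_REARRANGEMENT,
                    OTHER, HAIRPIN_SHIFT, DOUBLE_HAIRPIN_SHIFT, REPEAT_NONE,
                    REPEAT_OTHER, ClassifiedAlignment, StrandCorrespondence)


def classify_internal(corr: StrandCorrespondence) -> str:
    """Repeat class of a self-alignment from its strand-index offset."""
    if not corr.is_self:
        raise ValueError("classify_internal expects a self-alignment")
    offsets = {t - q for q, t, _ in corr.strand_pairs}
    if offsets == {0}:
        return REPEAT_NONE
    if len(offsets) == 1 and len(corr.strand_pairs) >= 2:
        off = abs(next(iter(offsets)))
        if off == 2:
            return HAIRPIN_SHIFT
        if off == 4:
            return DOUBLE_HAIRPIN_SHIFT
    return REPEAT_OTHER


def _hairpin_groups(corr: StrandCorrespondence):
    """Loop regions matched to two consecutive strands of the other protein.

    Returns (groups, used) where groups is a list of ("q"|"t" loop side,
    loop index, (strand, strand)) and used is the set of cross-matches that
    belong to a group.
    """
    groups = []
    used = set()
    by_loop: dict[tuple[str, int], list] = {}
    for c in corr.cross_matches:
        if c.q_kind == "loop" and c.t_kind == "strand":
            by_loop.setdefault(("q", c.q_index), []).append(c)
        elif c.q_kind == "strand" and c.t_kind == "loop":
            by_loop.setdefault(("t", c.t_index), []).append(c)
    for (side, loop_idx), matches in sorted(by_loop.items()):
        strands = sorted(c.t_index if side == "q" else c.q_index for c in matches)
        for a, b in zip(strands, strands[1:]):
            if b == a + 1:
                groups.append((side, loop_idx, (a, b)))
                for c in matches:
                    other = c.t_index if side == "q" else c.q_index
                    if other in (a, b):
                        used.add(id(c))
    return groups, used


def classify_cross(corr: StrandCorrespondence,
                   directions_q: list[int] | None = None,
                   directions_t: list[int] | None = None) -> ClassifiedAlignment:
    """Category of a cross-protein correspondence."""
    if corr.is_self:
        raise ValueError("classify_cross expects a cross-protein alignment")
    out = ClassifiedAlignment(query_id=corr.query_id, target_id=corr.target_id,
                              q_n=corr.q_n, t_n=corr.t_n)
    pairs = corr.strand_pairs
    if directions_q is not None and directions_t is not None:
        out.has_redirection = bool(
            topomap.detect_redirection(corr, directions_q, directions_t))
    out.includes_last_strands = any(
        (q, t) == (corr.q_n, corr.t_n) for q, t, _ in pairs)
    out.covers_all_query_strands = (
        {q for q, _, _ in pairs} == set(range(1, corr.q_n + 1)))

    if len(pairs) < 2 and not corr.cross_matches:
        out.category = OTHER
        out.insufficient = True
        return out

    hairpins, used = _hairpin_groups(corr)
    extra_q_loop = any(c.q_kind == "loop" and c.t_kind == "strand"
                       and id(c) not in used for c in corr.cross_matches)
    extra_t_loop = any(c.q_kind == "strand" and c.t_kind == "loop"
                       and id(c) not in used for c in corr.cross_matches)

    if hairpins and extra_q_loop and extra_t_loop:
        out.category = LARGE_REARRANGEMENT
        return out
    if hairpins:
        out.category = LOOP_TO_HAIRPIN
        return out

    def anchored(offsets):
        """All pairs share the anchor offset 0, tolerating one low-support
        outlier."""
        bad = [(q, t, s) for (q, t, s), off in zip(pairs, offsets) if off != 0]
        if not bad:
            return True
        if len(bad) == 1 and len(pairs) >= 3:
            q, t, s = bad[0]
            th = max(3, topomap.default_theta(10))
            return s < th
        return False

    c_off = [(corr.q_n - q) - (corr.t_n - t) for q, t, _ in pairs]
    n_off = [t - q for q, t, _ in pairs]
    is_cterm = len(pairs) >= 2 and anchored(c_off)
    is_nterm = len(pairs) >= 2 and anchored(n_off)
    if is_cterm:
        out.category = CTERM_ANCHORED
        out.ambiguous_anchor = is_nterm
        return out
    if is_nterm:
        out.category = NTERM_ANCHORED
        return out
    offsets = {t - q for q, t, _ in pairs}
    if len(offsets) == 1 and len(pairs) >= 2 and not corr.cross_matches:
        out.category = INTERNAL_OFFSET
        return out
    out.category = OTHER
    return out


def classify_one(corr: StrandCorrespondence,
                 directions_q=None, directions_t=None) -> ClassifiedAlignment:
    """Classify a correspondence, dispatching on self vs cross."""
    if corr.is_self:
        out = ClassifiedAlignment(query_id=corr.query_id,
                                  target_id=corr.target_id,
                                  category=OTHER, q_n=corr.q_n, t_n=corr.t_n)
        out.repeat_class = classify_internal(corr)
        if directions_q is not None and directions_t is not None:
            out.has_redirection = bool(
                topomap.detect_redirection(corr, directions_q, directions_t))
        return out
    return classify_cross(corr, directions_q, directions_t)


def _span(corr: StrandCorrespondence):
    regions = [q for q, _, _ in corr.strand_pairs]
    regions += [c.q_index for c in corr.cross_matches]
    return (min(regions), max(regions)) if regions else None


def classify_all(records, annotations: dict) -> tuple[pd.DataFrame, dict]:
    """Classify every record (not deduped) against the annotation table.

    annotations: protein_id -> StrandAnnotation (directions used if present).
    Returns (per-record table, summary). Records for unannotated proteins are
    skipped with a warning. Alternate-alignment flags are set across records
    that share a protein pair and overlap in the query-strand span; a
    LOOP_TO_HAIRPIN with an alternate in the same region becomes
    LOOP_TO_HAIRPIN_ALT.
    """
    classified = []
    by_pair: dict[tuple[str, str], list[int]] = {}
    for rec in records:
        ann_q = annotations.get(rec.query_id)
        ann_t = annotations.get(rec.target_id)
        if ann_q is None or ann_t is None:
            warnings.warn(f"unannotated protein in {rec.query_id}-{rec.target_id}, "
                          "record skipped")
            continue
        corr = topomap.map_to_strands(rec, ann_q, ann_t)
        cls = classify_one(corr, ann_q.directions, ann_t.directions)
        cls.evalue = rec.evalue
        classified.append((cls, corr))
        key = tuple(sorted((rec.query_id, rec.target_id)))
        by_pair.setdefault(key, []).append(len(classified) - 1)

    for key, idxs in by_pair.items():
        if len(idxs) < 2:
            continue
        for i in idxs:
            cls_i, corr_i = classified[i]
            span_i = _span(corr_i)
            for j in idxs:
                if i == j:
                    continue
                span_j = _span(classified[j][1])
                if span_i and span_j and span_i[0] <= span_j[1] and span_j[0] <= span_i[1]:
                    cls_i.has_alternate_alignment = True
                    if cls_i.category == LOOP_TO_HAIRPIN:
                        cls_i.category = LOOP_TO_HAIRPIN_ALT
                    break

    rows = []
    for cls, _corr in classified:
        rows.append({
            "query_id": cls.query_id, "target_id": cls.target_id,
            "evalue": cls.evalue, "q_n": cls.q_n, "t_n": cls.t_n,
            "category": cls.category, "repeat_class": cls.repeat_class,
            "is_self": cls.query_id == cls.target_id,
            "includes_last_strands": cls.includes_last_strands,
            "covers_all_query_strands": cls.covers_all_query_strands,
            "has_redirection": cls.has_redirection,
            "has_alternate_alignment": cls.has_alternate_alignment,
            "insufficient": cls.insufficient,
            "ambiguous_anchor": cls.ambiguous_anchor,
        })
    table = pd.DataFrame(rows)
    summary: dict = {"by_category": {}, "by_bucket": {}, "repeats": {}}
    if not table.empty:
        cross = table[~table.is_self]
        summary["by_category"] = Counter(cross.category).most_common()
        buckets = Counter(zip(cross.q_n, cross.t_n, cross.category))
        summary["by_bucket"] = {f"{q}-{t}:{c}": n
                                for (q, t, c), n in sorted(buckets.items())}
        selfs = table[table.is_self]
        summary["repeats"] = Counter(selfs.repeat_class).most_common()
    return table, summary
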