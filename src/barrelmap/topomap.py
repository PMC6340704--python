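"""Projection of residue-level alignments onto strand topology.

A strand pair (q_i, t_j) is emitted when at least theta aligned residue pairs
fall inside both strands, theta = max(3, ceil(0.5 * shorter strand length)).
Candidate pairs are resolved to the colinear chain of maximal total support
(dynamic programming); everything else that clears the threshold — leftover
strand pairs and loop<->strand matches — is kept as cross-matches.
"""
from __future__ import annotations

import math
from collections import Counter

from .types import AlignmentRecord, CrossMatch, StrandAnnotation, StrandCorrespondence


def default_theta(len_a: int, len_b: int | None = None) -> int:
    """Support threshold for calling a region pair aligned."""
    shorter = len_a if len_b is None else min(len_a, len_b)
    return max(3, math.ceil(0.5 * shorter))


def _strand_len(annot: StrandAnnotation, idx: int) -> int:
    s, e = annot.strands[idx - 1]
    return e - s + 1


def _best_chain(candidates: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Maximal-support colinear chain (strictly increasing in both strand
    indices). Ties break to more pairs, then to the smaller sum of indices,
    which keeps the choice invariant under query/target transposition."""
    cands = sorted(candidates)
    n = len(cands)
    # score: (support, count, -index_sum) maximized lexicographically
    best = [None] * n
    prev = [-1] * n
    for i, (qi, ti, si) in enumerate(cands):
        best[i] = (si, 1, -(qi + ti))
        for j in range(i):
            qj, tj, sj = cands[j]
            if qj < qi and tj < ti:
                cand = (best[j][0] + si, best[j][1] + 1, best[j][2] - (qi + ti))
                if cand > best[i]:
                    best[i] = cand
                    prev[i] = j
    if not cands:
        return []
    end = max(range(n), key=lambda i: best[i])
    chain = []
    while end != -1:
        chain.append(cands[end])
        end = prev[end]
    return chain[::-1]


def map_to_strands(record: AlignmentRecord, annot_q: StrandAnnotation,
                   annot_t: StrandAnnotation,
                   theta=default_theta) -> StrandCorrespondence:
    """Strand-level correspondence induced by one alignment record."""
    if not record.aligned_pairs:
        raise ValueError("alignment record has no aligned pairs")
    support: Counter = Counter()
    for qpos, tpos in record.aligned_pairs:
        qreg = annot_q.region_of(qpos)
        treg = annot_t.region_of(tpos)
        support[(qreg, treg)] += 1

    strand_cands = []
    cross = []
    thetas = {}
    for ((qk, qi), (tk, ti)), cnt in sorted(support.items()):
        if qk == "loop" and tk == "loop":
            continue
        if qk == "strand" and tk == "strand":
            th = theta(_strand_len(annot_q, qi), _strand_len(annot_t, ti))
        elif qk == "strand":
            th = theta(_strand_len(annot_q, qi))
        else:
            th = theta(_strand_len(annot_t, ti))
        if cnt < th:
            continue
        thetas[((qk, qi), (tk, ti))] = th
        if qk == "strand" and tk == "strand":
            strand_cands.append((qi, ti, cnt))
        else:
            cross.append(CrossMatch(q_kind=qk, q_index=qi, t_kind=tk,
                                    t_index=ti, support=cnt))
    chain = _best_chain(strand_cands)
    chosen = {(q, t) for q, t, _ in chain}
    for q, t, cnt in strand_cands:
        if (q, t) not in chosen:
            cross.append(CrossMatch(q_kind="strand", q_index=q,
                                    t_kind="strand", t_index=t, support=cnt))
    cross.sort(key=lambda c: (c.q_index, c.t_index, c.q_kind, c.t_kind))
    return StrandCorrespondence(
        query_id=record.query_id, target_id=record.target_id,
        strand_pairs=chain, cross_matches=cross,
        q_n=annot_q.n_strands, t_n=annot_t.n_strands,
        is_self=record.is_self,
        theta={f"{a[0][0]}{a[0][1]}-{a[1][0]}{a[1][1]}": th
               for a, th in thetas.items()})


def detect_redirection(corr: StrandCorrespondence,
                       directions_q: list[int],
                       directions_t: list[int]) -> list[tuple[int, int]]:
    """Strand pairs whose membrane directions disagree (topology flips)."""
    flips = []
    for q, t, _ in corr.strand_pairs:
        if directions_q[q - 1] != directions_t[t - 1]:
            flips.append((q, t))
    return flips


def transpose(corr: StrandCorrespondence) -> StrandCorrespondence:
    """Swap query and target roles of a correspondence."""
    return StrandCorrespondence(
        query_id=corr.target_id, target_id=corr.query_id,
        strand_pairs=sorted((t, q, s) for q, t, s in corr.strand_pairs),
        cross_matches=sorted(
            (CrossMatch(q_kind=c.t_kind, q_index=c.t_index, t_kind=c.q_kind,
                        t_index=c.q_index, support=c.support)
             for c in corr.cross_matches),
            key=lambda c: (c.q_index, c.t_index, c.q_kind, c.t_kind)),
        q_n=corr.t_n, t_n=corr.q_n, is_self=corr.is_self, theta=corr.theta)


def correspondence_to_dict(corr: StrandCorrespondence) -> dict:
    """JSON-ready representation (ids, pairs, cross-matches, parameters)."""
    return {
        "query_id": corr.query_id,
        "target_id": corr.target_id,
        "q_n": corr.q_n,
        "t_n": corr.t_n,
        "is_self": corr.is_self,
        "strand_pairs": [list(p) for p in corr.strand_pairs],
        "cross_matches": [[c.q_kind, c.q_index, c.t_kind, c.t_index, c.support]
                          for c in corr.cross_matches],
        "theta": corr.theta,
    }
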