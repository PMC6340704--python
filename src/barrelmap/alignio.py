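"""Reading, filtering and normalizing pairwise alignment tables.

The canonical dialect is a delimited table with a header row and columns
query_id, target_id, evalue, probability, q_start, q_end, t_start, t_end,
q_aln, t_aln, where q_aln/t_aln are gapped strings ('-' for gaps). Residue
pairs are derived by walking the two gapped strings from q_start/t_start.
Common column-name synonyms from profile-profile aligner outputs are mapped
automatically; unknown columns ride along as opaque metadata.
"""
from __future__ import annotations

import math
import re
import warnings

from .types import AlignmentRecord

_SYNONYMS = {
    "query_id": {"query_id", "query", "qid", "q", "id1", "protein1", "name1", "pdb1"},
    "target_id": {"target_id", "target", "hit", "tid", "t", "id2", "protein2",
                  "name2", "pdb2", "template"},
    "evalue": {"evalue", "e-value", "e_value", "eval", "e"},
    "probability": {"probability", "prob", "probab", "p"},
    "q_start": {"q_start", "qstart", "query_start", "qbeg"},
    "q_end": {"q_end", "qend", "query_end"},
    "t_start": {"t_start", "tstart", "target_start", "tbeg"},
    "t_end": {"t_end", "tend", "target_end"},
    "q_aln": {"q_aln", "qseq", "query_aln", "qaln", "query_seq"},
    "t_aln": {"t_aln", "tseq", "target_aln", "taln", "target_seq"},
    "n_aligned": {"n_aligned", "aligned_cols", "cols", "length", "aln_len"},
}
_CANON = {syn: key for key, syns in _SYNONYMS.items() for syn in syns}

MANDATORY = ("query_id", "target_id", "evalue")


def pairs_from_gapped(q_aln: str, t_aln: str, q_start: int = 1,
                      t_start: int = 1) -> list[tuple[int, int]]:
    """Residue-position pairs from two equal-length gapped strings."""
    if len(q_aln) != len(t_aln):
        raise ValueError("gapped alignment strings differ in length")
    pairs = []
    qp, tp = q_start - 1, t_start - 1
    for qc, tc in zip(q_aln, t_aln):
        qgap, tgap = qc == "-", tc == "-"
        if not qgap:
            qp += 1
        if not tgap:
            tp += 1
        if not qgap and not tgap:
            pairs.append((qp, tp))
    return pairs


def gapped_from_pairs(pairs, q_seq=None, t_seq=None):
    """Rebuild gapped strings from residue pairs (placeholder letters when
    sequences are not given). Returns (q_aln, t_aln, q_start, t_start)."""
    if not pairs:
        raise ValueError("no aligned pairs")

    def letter(seq, pos):
        if seq is None:
            return "X"
        return seq[pos - 1]

    q0, t0 = pairs[0]
    qa, ta = [], []
    prev_q, prev_t = q0 - 1, t0 - 1
    for q, t in pairs:
        for pos in range(prev_q + 1, q):
            qa.append(letter(q_seq, pos))
            ta.append("-")
        for pos in range(prev_t + 1, t):
            qa.append("-")
            ta.append(letter(t_seq, pos))
        qa.append(letter(q_seq, q))
        ta.append(letter(t_seq, t))
        prev_q, prev_t = q, t
    return "".join(qa), "".join(ta), q0, t0


def read_alignment_table(text: str, dialect: str = "auto") -> list[AlignmentRecord]:
    """Parse a delimited alignment table (header in the first row).

    dialect: "auto" (tab if the header contains tabs, else any whitespace),
    "tab", or "space".
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty alignment table")

    def split(ln):
        if dialect == "tab" or (dialect == "auto" and "\t" in lines[0]):
            return ln.rstrip("\n").split("\t")
        return ln.split()

    header = [h.strip().lower() for h in split(lines[0])]
    colmap = {}
    for i, h in enumerate(header):
        key = _CANON.get(h, h)
        colmap.setdefault(key, i)
    for col in MANDATORY:
        if col not in colmap:
            raise ValueError(f"missing mandatory column: {col}")
    records = []
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = split(ln)
        if len(fields) < len(header):
            warnings.warn(f"line {lineno}: too few fields, row rejected")
            continue

        def get(key, default=None):
            i = colmap.get(key)
            return fields[i] if i is not None and i < len(fields) else default

        try:
            evalue = float(get("evalue"))
            if not (evalue > 0) or math.isnan(evalue):
                raise ValueError
        except (TypeError, ValueError):
            warnings.warn(f"line {lineno}: malformed E-value {get('evalue')!r}, row rejected")
            continue
        prob = get("probability")
        probability = float(prob) if prob not in (None, "", "NA") else None
        q_aln, t_aln = get("q_aln"), get("t_aln")
        pairs = []
        if q_aln and t_aln:
            pairs = pairs_from_gapped(q_aln, t_aln,
                                      int(get("q_start", 1)), int(get("t_start", 1)))
        meta = {h: fields[i] for i, h in enumerate(header)
                if _CANON.get(h, h) not in
                ("query_id", "target_id", "evalue", "probability", "q_aln", "t_aln")}
        if not pairs:
            n_aln = get("n_aligned")
            if n_aln is not None:
                meta["n_aligned"] = int(float(n_aln))
            elif get("q_start") is not None and get("q_end") is not None:
                meta["n_aligned"] = int(get("q_end")) - int(get("q_start")) + 1
        rec = AlignmentRecord(query_id=get("query_id"), target_id=get("target_id"),
                              evalue=evalue, probability=probability,
                              aligned_pairs=pairs, meta=meta)
        rec.validate()
        records.append(rec)
    if not records:
        warnings.warn("alignment table contains no data rows")
    return records


def write_alignment_table(records: list[AlignmentRecord],
                          sequences: dict[str, str] | None = None) -> str:
    """Serialize records in the canonical TSV dialect."""
    seqs = sequences or {}
    out = ["query_id\ttarget_id\tevalue\tprobability\t"
           "q_start\tq_end\tt_start\tt_end\tq_aln\tt_aln"]
    for rec in records:
        if rec.aligned_pairs:
            qa, ta, q0, t0 = gapped_from_pairs(
                rec.aligned_pairs, seqs.get(rec.query_id), seqs.get(rec.target_id))
            qe, te = rec.aligned_pairs[-1]
        else:
            qa = ta = ""
            q0 = t0 = qe = te = 0
        prob = "" if rec.probability is None else f"{rec.probability:g}"
        out.append(f"{rec.query_id}\t{rec.target_id}\t{rec.evalue:g}\t{prob}\t"
                   f"{q0}\t{qe}\t{t0}\t{te}\t{qa}\t{ta}")
    return "\n".join(out) + "\n"


def filter_records(records, max_evalue: float, min_aligned: int = 20,
                   min_probability: float | None = None) -> list[AlignmentRecord]:
    """Keep records with evalue <= max_evalue (inclusive), at least
    min_aligned aligned residues, and — when min_probability is set —
    probability strictly greater than it."""
    if max_evalue <= 0 or min_aligned < 0:
        raise ValueError("thresholds must be positive")
    out = []
    for rec in records:
        if rec.evalue > max_evalue:
            continue
        if rec.n_aligned < min_aligned:
            continue
        if min_probability is not None:
            if rec.probability is None or not (rec.probability > min_probability):
                continue
        out.append(rec)
    return out


def dedup_min_evalue(records) -> list[AlignmentRecord]:
    """One record per unordered protein pair: the minimal E-value wins; ties
    break to the longer alignment, then lexicographically smaller ids."""
    best: dict[tuple[str, str], AlignmentRecord] = {}
    for rec in records:
        key = tuple(sorted((rec.query_id, rec.target_id)))
        cur = best.get(key)
        if cur is None:
            best[key] = rec
            continue
        cand = (rec.evalue, -rec.n_aligned, rec.query_id, rec.target_id)
        incumbent = (cur.evalue, -cur.n_aligned, cur.query_id, cur.target_id)
        if cand < incumbent:
            best[key] = rec
    return [best[k] for k in sorted(best)]


# --------------------------------------------------------------------------
# minimal HH-suite .hhr reader

_HHR_STAT = re.compile(
    r"Probab=(?P<prob>[\d.]+)\s+E-value=(?P<evalue>[\deE.+-]+)")


def read_hhr(text: str) -> list[AlignmentRecord]:
    """Parse alignment blocks of an HH-suite .hhr result file."""
    query_id = None
    for ln in text.splitlines():
        if ln.startswith("Query"):
            query_id = ln.split()[1]
            break
    if query_id is None:
        raise ValueError("not an hhr file: no Query line")
    records = []
    target = prob = evalue = None
    q_parts, t_parts = [], []
    q_start = t_start = None

    def flush():
        nonlocal target, prob, evalue, q_parts, t_parts, q_start, t_start
        if target is not None and q_parts:
            pairs = pairs_from_gapped("".join(q_parts), "".join(t_parts),
                                      q_start, t_start)
            rec = AlignmentRecord(query_id=query_id, target_id=target,
                                  evalue=evalue, probability=prob,
                                  aligned_pairs=pairs)
            rec.validate()
            records.append(rec)
        target = prob = evalue = None
        q_parts, t_parts = [], []
        q_start = t_start = None

    for ln in text.splitlines():
        if ln.startswith("No "):
            flush()
        elif ln.startswith(">"):
            target = ln[1:].split()[0]
        elif target is not None and (m := _HHR_STAT.search(ln)):
            prob = float(m.group("prob"))
            evalue = float(m.group("evalue"))
        elif ln.startswith("Q ") or ln.startswith("T "):
            parts = ln.split()
            if len(parts) < 5 or parts[1].lower() in ("consensus",) \
               or parts[1].startswith("ss_"):
                continue
            side, _name, start, seq = parts[0], parts[1], int(parts[2]), parts[3]
            if side == "Q":
                if q_start is None:
                    q_start = start
                q_parts.append(seq)
            else:
                if t_start is None:
                    t_start = start
                t_parts.append(seq)
    flush()
    return records
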