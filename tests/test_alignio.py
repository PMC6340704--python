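"""Alignment table parsing, filtering, dedup and the hhr reader."""
import pytest
from hypothesis import given, settings, strategies as st

from barrelmap.alignio import (dedup_min_evalue, filter_records,
                               gapped_from_pairs, pairs_from_gapped,
                               read_alignment_table, read_hhr,
                               write_alignment_table)
from barrelmap.types import AlignmentRecord

TABLE = """query_id target_id evalue probability q_start q_end t_start t_end q_aln t_aln
A B 1e-5 98.5 3 27 10 34 LTLTLTLTLTLTLTLTLTLTLTLTL LTLTLTLTLTLTLTLTLTLTLTLTL
A C 2e-4 90 1 5 1 5 LTLT-L LT-LTL
B C 1e-8 99 1 4 2 5 LTLT LTLT
"""


def test_read_alignment_table_parses_rows():
    recs = read_alignment_table(TABLE)
    assert len(recs) == 3
    assert recs[0].evalue == pytest.approx(1e-5)
    assert recs[0].n_aligned == 25
    # gapped walk: each gap removes one pair
    assert recs[1].n_aligned == 4
    assert recs[1].aligned_pairs[0] == (1, 1)


def test_read_alignment_table_missing_column():
    with pytest.raises(ValueError, match="evalue"):
        read_alignment_table("query_id target_id score\nA B 1\n")


def test_read_alignment_table_malformed_evalue_rejected():
    text = "query_id target_id evalue\nA B oops\nA C 1e-4\n"
    with pytest.warns(UserWarning, match="malformed E-value"):
        recs = read_alignment_table(text)
    assert [r.target_id for r in recs] == ["C"]


def test_read_alignment_table_header_only_warns():
    with pytest.warns(UserWarning, match="no data rows"):
        assert read_alignment_table("query_id target_id evalue\n") == []


def test_synonym_headers_accepted():
    recs = read_alignment_table("query\thit\tE-value\tprob\nA\tB\t1e-6\t99\n")
    assert recs[0].target_id == "B" and recs[0].probability == 99


# --- filtering -------------------------------------------------------------

def rec(q="A", t="B", e=1e-6, prob=None, n=25):
    pairs = [(i, i) for i in range(1, n + 1)]
    return AlignmentRecord(query_id=q, target_id=t, evalue=e,
                           probability=prob, aligned_pairs=pairs)


def test_filter_minimum_aligned_residues():
    # a 19-residue alignment is dropped regardless of its E-value
    assert filter_records([rec(n=19, e=1e-8)], max_evalue=1e-3) == []
    assert len(filter_records([rec(n=20, e=1e-8)], max_evalue=1e-3)) == 1


def test_filter_evalue_boundary_inclusive():
    assert len(filter_records([rec(e=1e-3)], max_evalue=1e-3)) == 1
    assert filter_records([rec(e=1.0001e-3)], max_evalue=1e-3) == []


def test_filter_probability_boundary_strict():
    assert filter_records([rec(prob=75.0)], max_evalue=1e-3,
                          min_probability=75.0) == []
    assert len(filter_records([rec(prob=75.1)], max_evalue=1e-3,
                              min_probability=75.0)) == 1


def test_dedup_keeps_minimum_evalue():
    records = [rec(e=1e-4), rec(e=1e-6)]
    kept = dedup_min_evalue(records)
    assert len(kept) == 1 and kept[0].evalue == 1e-6


def test_dedup_merges_both_orientations():
    records = [rec(q="A", t="B", e=1e-4), rec(q="B", t="A", e=1e-7)]
    kept = dedup_min_evalue(records)
    assert len(kept) == 1 and kept[0].evalue == 1e-7
    assert dedup_min_evalue([rec()]) == [rec()]


def test_filter_then_dedup_idempotent_and_monotone():
    records = [rec(e=1e-4), rec(e=1e-6), rec(q="A", t="C", e=1e-2),
               rec(q="B", t="C", e=5e-4, n=30)]
    f1 = filter_records(records, max_evalue=1e-3)
    f2 = filter_records(f1, max_evalue=1e-3)
    assert f1 == f2
    d1 = dedup_min_evalue(f1)
    assert dedup_min_evalue(d1) == d1
    assert len(d1) <= len(f1)
    tighter = filter_records(records, max_evalue=1e-5)
    assert {id(r) for r in tighter} <= {id(r) for r in f1}


# --- gapped-string round trip ---------------------------------------------

@settings(deadline=None, max_examples=50)
@given(st.lists(st.tuples(st.integers(1, 3), st.integers(1, 3)),
                min_size=1, max_size=30))
def test_pairs_gapped_roundtrip(deltas):
    pairs = []
    q = t = 0
    for dq, dt in deltas:
        q += dq
        t += dt
        pairs.append((q, t))
    qa, ta, q0, t0 = gapped_from_pairs(pairs)
    assert pairs_from_gapped(qa, ta, q0, t0) == pairs


def test_write_read_table_roundtrip(scenario_battery):
    records = [rec for *_, rec, _ in scenario_battery.values()]
    text = write_alignment_table(records)
    back = read_alignment_table(text)
    assert [r.aligned_pairs for r in back] == [r.aligned_pairs for r in records]
    assert [r.evalue for r in back] == pytest.approx([r.evalue for r in records])


# --- hhr -------------------------------------------------------------------

HHR = """Query         prot1
Match_columns 100

 No Hit    Prob E-value
  1 prot2  99.8 1.2E-18

No 1
>prot2 some description
Probab=99.80  E-value=1.2e-18  Score=120.0  Aligned_cols=10

Q prot1            3 LTLTL-TLTL   12 (100)
Q Consensus        3 ltltl.tltl   12 (100)
T prot2            5 LTLTLTTLTL   14 (90)
T ss_pred          CCEEEEEECC
"""


def test_read_hhr_alignment_block():
    recs = read_hhr(HHR)
    assert len(recs) == 1
    r = recs[0]
    assert r.query_id == "prot1" and r.target_id == "prot2"
    assert r.evalue == pytest.approx(1.2e-18)
    assert r.probability == pytest.approx(99.8)
    assert len(r.aligned_pairs) == 9
    assert r.aligned_pairs[0] == (3, 5)
    # the query gap advances only the target coordinate
    assert r.aligned_pairs[5] == (8, 11)
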