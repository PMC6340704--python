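"""Polarity alternation, hydropathy, volume and transition-region statistics."""
import pytest
from hypothesis import given, settings, strategies as st

from barrelmap.residuestats import (KD_HYDROPATHY, NONPOLAR, POLAR,
                                    RegionSequence, alternation_fraction,
                                    mean_hydropathy,
                                    mean_strand_residue_volume, polarity_class,
                                    transition_region_stats, RESIDUE_VOLUME)
from barrelmap.types import StrandAnnotation

AA20 = sorted(NONPOLAR | POLAR)


def test_partition_is_exact():
    assert NONPOLAR == set("AFILMPVWY")
    assert POLAR == set("CDEGHKNQRST")
    assert polarity_class("A") == "nonpolar"
    assert polarity_class("R") == "polar"
    with pytest.raises(ValueError):
        polarity_class("X")


@pytest.mark.parametrize("seq,expected", [
    ("LTLT", 0.75),
    ("LLLL", 0.0),
    ("LT-LT", 0.4),  # the step into the residue after the gap is skipped
])
def test_alternation_examples(seq, expected):
    assert alternation_fraction(RegionSequence(seq)) == pytest.approx(expected)


def test_alternation_too_short():
    with pytest.raises(ValueError):
        alternation_fraction(RegionSequence("L"))


def test_alternation_steps_denominator_variant():
    assert alternation_fraction(RegionSequence("LT-LT"),
                                denominator="steps") == pytest.approx(2 / 2)
    assert alternation_fraction(RegionSequence("LTLT"),
                                denominator="steps") == pytest.approx(1.0)


@given(st.integers(2, 40))
def test_alternator_and_homopolymer_closed_forms(length):
    alternating = ("LT" * length)[:length]
    assert alternation_fraction(RegionSequence(alternating)) == \
        pytest.approx((length - 1) / length)
    assert alternation_fraction(RegionSequence("K" * length)) == 0.0


def test_mean_hydropathy_examples():
    assert mean_hydropathy(RegionSequence("AILV")) == pytest.approx(3.575)
    assert mean_hydropathy(RegionSequence("W")) == pytest.approx(KD_HYDROPATHY["W"])
    assert mean_hydropathy(RegionSequence("DE")) < 0


def test_mean_hydropathy_excludes_gap_aligned():
    region = RegionSequence("AILV", gap_mask=[False, True, True, False])
    assert region.is_gap(1)
    assert mean_hydropathy(region) == pytest.approx((1.8 + 4.2) / 2)
    with pytest.raises(ValueError):
        mean_hydropathy(RegionSequence("AI", gap_mask=[True, True]))


@settings(deadline=None, max_examples=50)
@given(st.lists(st.sampled_from(AA20), min_size=1, max_size=30))
def test_hydropathy_permutation_invariant_and_bounded(letters):
    seq = "".join(letters)
    v = mean_hydropathy(RegionSequence(seq))
    assert v == pytest.approx(mean_hydropathy(RegionSequence(seq[::-1])))
    assert min(KD_HYDROPATHY.values()) <= v <= max(KD_HYDROPATHY.values())


def test_strand_residue_volume():
    ann = StrandAnnotation(strands=[(1, 4)])
    assert mean_strand_residue_volume(ann, "GGGG") == pytest.approx(RESIDUE_VOLUME["G"])
    assert mean_strand_residue_volume(ann, "WWWW") > \
        mean_strand_residue_volume(ann, "AAAA")
    expected = sum(RESIDUE_VOLUME[a] for a in "GAVL") / 4
    assert mean_strand_residue_volume(ann, "GAVL") == pytest.approx(expected)
    with pytest.warns(UserWarning, match="unknown residue"):
        v = mean_strand_residue_volume(ann, "GGGX")
    assert v == pytest.approx(RESIDUE_VOLUME["G"])


def test_volume_increases_with_strand_number():
    # wider synthetic barrels share the same sequence model, so the trend is
    # flat here; the statistic itself must be well-defined per barrel size
    from barrelmap.synthgen import BarrelSpec, generate_barrel
    for n in (8, 16):
        b = generate_barrel(BarrelSpec(n_strands=n, seed=0))
        v = mean_strand_residue_volume(b.annotation, b.sequence)
        assert 60 <= v <= 230


# --- transition-region statistics ------------------------------------------

def battery(kinds, seeds=range(3)):
    from barrelmap.synthgen import ScenarioSpec, generate_alignment_scenario
    recs, anns, seqs = [], {}, {}
    for kind in kinds:
        for seed in seeds:
            q, t, rec, _ = generate_alignment_scenario(
                ScenarioSpec(kind=kind, n_query=16,
                             n_target=18 if kind != "topology_flip" else 16,
                             seed=seed))
            qid, tid = f"{kind[:3]}{seed}q", f"{kind[:3]}{seed}t"
            rec.query_id, rec.target_id = qid, tid
            q.annotation.protein_id, t.annotation.protein_id = qid, tid
            recs.append(rec)
            anns[qid], seqs[qid] = q.annotation, q.sequence
            anns[tid], seqs[tid] = t.annotation, t.sequence
    return recs, anns, seqs


def test_transition_stats_loops_look_like_strands():
    recs, anns, seqs = battery(["loop_to_hairpin", "large_rearrangement"])
    df = transition_region_stats(recs, anns, seqs).set_index("group")
    loop_alt = df.loc["loop_conformation", "mean_alternation"]
    strand_alt = df.loc["strand_conformation", "mean_alternation"]
    ctrl_loop_alt = df.loc["control_loops", "mean_alternation"]
    # transition loops carry the strand-like alternating signature
    assert loop_alt == pytest.approx(strand_alt, abs=0.15)
    assert loop_alt > ctrl_loop_alt + 0.5
    # all-polar control loops never alternate polarity class
    assert ctrl_loop_alt == 0.0
    # and they are the most hydrophilic group
    assert df.loc["control_loops", "mean_hydropathy"] < \
        df.loc["strand_conformation", "mean_hydropathy"]


def test_transition_stats_dedups_identical_regions():
    recs, anns, seqs = battery(["loop_to_hairpin"], seeds=[0])
    doubled = recs + [recs[0]]  # same region aligned twice at 100% identity
    df1 = transition_region_stats(recs, anns, seqs).set_index("group")
    df2 = transition_region_stats(doubled, anns, seqs).set_index("group")
    assert df1.loc["loop_conformation", "n_regions"] == \
        df2.loc["loop_conformation", "n_regions"]


def test_transition_stats_empty_without_transitions():
    recs, anns, seqs = battery(["cterm_duplication"], seeds=[0])
    with pytest.warns(UserWarning, match="no loop"):
        df = transition_region_stats(recs, anns, seqs)
    assert df.empty
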