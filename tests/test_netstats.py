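"""Network construction and network-level statistics."""
import math

import pytest

from barrelmap.netstats import (build_network, conservation_profile,
                                largest_component, mean_log_evalue,
                                membership_overlap, same_vs_diff_probability,
                                threshold_series, write_edge_list,
                                write_graphml)
from barrelmap.types import AlignmentRecord, StrandCorrespondence


def rec(q, t, e):
    return AlignmentRecord(query_id=q, target_id=t, evalue=e,
                           aligned_pairs=[(i, i) for i in range(1, 25)])


def test_build_network_threshold_inclusive():
    net = build_network([rec("A", "B", 1e-4), rec("B", "C", 1e-2)], 1e-3)
    assert net.n_edges == 1 and net.graph.has_edge("A", "B")
    net2 = build_network([rec("A", "B", 1e-3)], 1e-3)
    assert net2.n_edges == 1


def test_network_includes_isolates():
    net = build_network([rec("A", "B", 1e-5)], 1e-3,
                        strand_counts={"A": 8, "B": 8, "C": 10})
    assert net.n_nodes == 3 and net.n_edges == 1


def test_threshold_series_monotone(scenario_battery):
    records = [r for *_, r, _ in scenario_battery.values() if not r.is_self]
    nets = threshold_series(records)
    edges = [set(map(frozenset, nets[t].graph.edges()))
             for t in (1e-3, 1e-5, 1e-7, 1e-12)]
    assert edges[3] <= edges[2] <= edges[1] <= edges[0]


def test_largest_component_and_ties():
    clique5 = [rec(a, b, 1e-5) for i, a in enumerate("ABCDE") for b in "ABCDE"[i + 1:]]
    clique3 = [rec(a, b, 1e-5) for i, a in enumerate("XYZ") for b in "XYZ"[i + 1:]]
    net = build_network(clique5 + clique3, 1e-3)
    assert largest_component(net) == set("ABCDE")
    isolated = build_network([], 1e-3, strand_counts={"b": 8, "a": 8, "c": 8})
    assert largest_component(isolated) == {"a"}


def test_same_vs_diff_probability_examples():
    # 3 same-n barrels fully connected -> probability exactly 1
    same = build_network([rec("A", "B", 1e-5), rec("A", "C", 1e-5),
                          rec("B", "C", 1e-5)], 1e-3,
                         strand_counts={"A": 8, "B": 8, "C": 8})
    assert same_vs_diff_probability(same)[(8, 8)] == 1.0
    # 2 vs 3 cross-n with 3 edges -> 3 / (2*3) = 0.5
    cross = build_network([rec("A", "X", 1e-5), rec("A", "Y", 1e-5),
                           rec("B", "Z", 1e-5)], 1e-3,
                          strand_counts={"A": 8, "B": 8,
                                         "X": 10, "Y": 10, "Z": 10})
    probs = same_vs_diff_probability(cross)
    assert probs[(8, 10)] == 0.5
    assert probs[(8, 8)] == 0.0
    # single-member bucket omitted for same-n
    single = build_network([], 1e-3, strand_counts={"A": 8})
    assert (8, 8) not in same_vs_diff_probability(single)


@pytest.mark.parametrize("evalues,expected", [
    ([1e-3, 1e-7], 1e-5),
    ([1e-6], 1e-6),
    ([1e-20, 1e-26], 1e-23),
])
def test_mean_log_evalue(evalues, expected):
    assert mean_log_evalue(evalues) == pytest.approx(expected, rel=1e-9)


def test_mean_log_evalue_errors():
    with pytest.raises(ValueError):
        mean_log_evalue([])
    with pytest.raises(ValueError):
        mean_log_evalue([1e-4, 0.0])


def test_mean_log_evalue_is_geometric_mean():
    vals = [1e-4, 1e-9, 1e-13]
    expected = 10 ** (sum(map(math.log10, vals)) / 3)
    assert mean_log_evalue(vals) == pytest.approx(expected)


# --- conservation profile --------------------------------------------------

def c8_16():
    return StrandCorrespondence(
        query_id="a", target_id="b",
        strand_pairs=[(i, i + 8, 7) for i in range(1, 9)],
        cross_matches=[], q_n=8, t_n=16)


def test_conservation_profile_cterm_example():
    profile = conservation_profile([c8_16()])
    assert profile[8] == [1] * 8
    assert profile[16] == [0] * 8 + [1] * 8


def test_conservation_profile_empty():
    assert conservation_profile([]) == {}


def test_conservation_total_is_twice_pair_count():
    corrs = [c8_16(), c8_16()]
    profile = conservation_profile(corrs)
    total = sum(sum(v) for v in profile.values())
    assert total == 2 * sum(len(c.strand_pairs) for c in corrs)


def test_cterm_biased_battery_shows_cterm_conservation():
    profile = conservation_profile([c8_16()] * 5)
    counts16 = profile[16]
    assert sum(counts16[8:]) > sum(counts16[:8])


# --- membership overlap ----------------------------------------------------

def test_membership_overlap_conventions():
    pairwise, avg, mx = membership_overlap(
        {"P1": {"a", "b", "c", "d"}, "P2": {"c", "d", "e", "f"}})
    assert pairwise[("P1", "P2")] == 50.0
    disjoint, avg0, _ = membership_overlap({"P1": {"a"}, "P2": {"b"}})
    assert disjoint[("P1", "P2")] == 0.0 and avg0 == 0.0
    identical, _, mx100 = membership_overlap({"P1": {"a"}, "P2": {"a"}})
    assert identical[("P1", "P2")] == 100.0 and mx100 == 100.0


def test_membership_overlap_cross_size_summary():
    memb = {"P1": {"a", "b"}, "P2": {"a", "b"}, "P3": {"a", "b"}}
    _, avg, mx = membership_overlap(memb, strand_counts={"P1": 8, "P2": 8, "P3": 10})
    # only the two cross-size pairs count: both are 100%
    assert avg == 100.0 and mx == 100.0


def test_membership_empty_set_warns():
    with pytest.warns(UserWarning, match="empty"):
        _, avg, _ = membership_overlap({"P1": set(), "P2": {"a"}})
    assert avg == 0.0


def test_writers_emit_text():
    net = build_network([rec("A", "B", 1e-5)], 1e-3)
    assert "A\tB" in write_edge_list(net)
    assert "<graphml" in write_graphml(net)
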