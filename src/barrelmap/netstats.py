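"""Similarity-network construction and network-level statistics.

Proteins are nodes (attributed with their strand count), deduplicated
minimum-E-value alignments are edges kept at or below an E-value threshold.
Edge sets nest monotonically across thresholds, so the canonical panel series
(1e-3, 1e-5, 1e-7, 1e-12) is a filtration of one network.
"""
from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass

import networkx as nx


@dataclass
class BarrelNetwork:
    """Similarity network at a fixed E-value threshold."""
    graph: nx.Graph
    threshold: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(records, threshold: float,
                  strand_counts: dict[str, int] | None = None) -> BarrelNetwork:
    """Build the network from deduplicated records.

    strand_counts lists every dataset protein (isolates included) with its
    strand number; when omitted, nodes are taken from the records alone.
    """
    g = nx.Graph()
    if strand_counts:
        for pid, n in strand_counts.items():
            g.add_node(pid, n=int(n))
    for rec in records:
        if rec.is_self:
            continue
        if rec.evalue <= threshold:
            a, b = rec.query_id, rec.target_id
            if not g.has_edge(a, b) or g.edges[a, b]["evalue"] > rec.evalue:
                g.add_edge(a, b, evalue=rec.evalue)
    return BarrelNetwork(graph=g, threshold=threshold)


def largest_component(network: BarrelNetwork) -> set[str]:
    """Largest connected component; ties break to the component containing
    the lexicographically smallest member."""
    comps = list(nx.connected_components(network.graph))
    if not comps:
        return set()
    return max(comps, key=lambda c: (len(c), [-ord(ch) for ch in min(c)]))


def threshold_series(records, thresholds=(1e-3, 1e-5, 1e-7, 1e-12),
                     strand_counts=None) -> dict[float, BarrelNetwork]:
    """Networks at a decreasing series of thresholds (a filtration)."""
    return {t: build_network(records, t, strand_counts) for t in thresholds}


def same_vs_diff_probability(network: BarrelNetwork) -> dict[tuple[int, int], float]:
    """Edge count divided by possible pairs, per (n_i, n_j) strand-count
    bucket; same-n buckets use C(k,2) pairs, cross-n buckets k1*k2."""
    by_n: dict[int, list[str]] = {}
    for node, data in network.graph.nodes(data=True):
        if "n" not in data:
            raise ValueError(f"node {node} lacks a strand count")
        by_n.setdefault(int(data["n"]), []).append(node)
    edge_count: dict[tuple[int, int], int] = {}
    for a, b in network.graph.edges():
        na, nb = network.graph.nodes[a]["n"], network.graph.nodes[b]["n"]
        key = (min(na, nb), max(na, nb))
        edge_count[key] = edge_count.get(key, 0) + 1
    out = {}
    ns = sorted(by_n)
    for i, na in enumerate(ns):
        for nb in ns[i:]:
            if na == nb:
                k = len(by_n[na])
                possible = k * (k - 1) // 2
            else:
                possible = len(by_n[na]) * len(by_n[nb])
            if possible == 0:
                continue
            out[(na, nb)] = edge_count.get((na, nb), 0) / possible
    return out


def mean_log_evalue(evalues) -> float:
    """Representative E-value: 10 ** mean(log10 E)."""
    evalues = list(evalues)
    if not evalues:
        raise ValueError("no E-values")
    logs = []
    for e in evalues:
        if not (e > 0):
            raise ValueError(f"nonpositive E-value {e}")
        logs.append(math.log10(e))
    return 10.0 ** (sum(logs) / len(logs))


def conservation_profile(correspondences,
                         strand_counts: dict[str, int] | None = None
                         ) -> dict[int, list[int]]:
    """Strand-position participation counts.

    For every correspondence, each strand of each side that appears in a
    strand pair increments the counter at (that barrel's strand count, that
    strand position). Returns {n: [count at position 1, ..., count at n]}.
    """
    profile: dict[int, list[int]] = {}

    def bump(n, pos):
        profile.setdefault(n, [0] * n)
        profile[n][pos - 1] += 1

    for corr in correspondences:
        for q, t, _ in corr.strand_pairs:
            bump(corr.q_n, q)
            bump(corr.t_n, t)
    return profile


def membership_overlap(memberships: dict[str, set],
                       strand_counts: dict[str, int] | None = None):
    """Pairwise percent overlap of homolog-ID sets.

    overlap(A, B) = |A & B| / min(|A|, |B|) * 100. The summary (average,
    maximum) is restricted to pairs with different strand counts when
    strand_counts is given, else taken over all pairs.
    """
    ids = sorted(memberships)
    if len(ids) < 2:
        raise ValueError("need at least 2 profiles")
    pairwise = {}
    summary_vals = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            sa, sb = memberships[a], memberships[b]
            denom = min(len(sa), len(sb))
            if denom == 0:
                warnings.warn(f"empty membership set in pair ({a}, {b}); overlap 0")
                ov = 0.0
            else:
                ov = 100.0 * len(sa & sb) / denom
            pairwise[(a, b)] = ov
            if strand_counts is None or strand_counts.get(a) != strand_counts.get(b):
                summary_vals.append(ov)
    avg = sum(summary_vals) / len(summary_vals) if summary_vals else 0.0
    mx = max(summary_vals) if summary_vals else 0.0
    return pairwise, avg, mx


# --------------------------------------------------------------------------
# writers

def write_edge_list(network: BarrelNetwork) -> str:
    out = ["source\ttarget\tevalue"]
    for a, b, data in sorted(network.graph.edges(data=True)):
        out.append(f"{a}\t{b}\t{data['evalue']:g}")
    return "\n".join(out) + "\n"


def write_graphml(network: BarrelNetwork) -> str:
    buf = io.BytesIO()
    nx.write_graphml(network.graph, buf)
    return buf.getvalue().decode()
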