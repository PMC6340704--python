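"""Plant every alignment-scenario kind and classify it back.

Each scenario encodes one mechanism of strand-number change between two
barrels: C-/N-terminal anchored duplication, internal offsets, hairpin-shift
self-alignments (the internal-repeat signature), loop-to-hairpin transitions,
large rearrangements and single-strand topology flips.
"""
from barrelmap import ScenarioSpec, classify_one, generate_alignment_scenario, map_to_strands

CASES = [
    ("cterm_duplication", 8, 16), ("nterm_duplication", 8, 16),
    ("internal_offset", 14, 22), ("hairpin_shift_self", 10, 10),
    ("double_hairpin_shift_self", 8, 8), ("loop_to_hairpin", 16, 18),
    ("large_rearrangement", 16, 18), ("topology_flip", 16, 16),
]

for kind, n_q, n_t in CASES:
    q, t, record, truth = generate_alignment_scenario(
        ScenarioSpec(kind=kind, n_query=n_q, n_target=n_t, seed=0))
    corr = map_to_strands(record, q.annotation, t.annotation)
    cls = classify_one(corr, q.annotation.directions, t.annotation.directions)
    flip = " +flip" if cls.has_redirection else ""
    rep = f" repeat={cls.repeat_class}" if record.is_self else ""
    print(f"{kind:26s} {n_q:2d}->{n_t:2d}  -> {cls.category}{rep}{flip}  "
          f"(E={record.evalue:.1e}, {len(corr.strand_pairs)} strand pairs)")
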