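import pytest

from barrelmap.synthgen import (BarrelSpec, ScenarioSpec, generate_barrel,
                                generate_alignment_scenario)

SCENARIO_CASES = [
    ("cterm_duplication", 8, 16),
    ("nterm_duplication", 8, 16),
    ("internal_offset", 14, 22),
    ("hairpin_shift_self", 10, 10),
    ("double_hairpin_shift_self", 8, 8),
    ("loop_to_hairpin", 16, 18),
    ("large_rearrangement", 16, 18),
    ("topology_flip", 16, 16),
]


@pytest.fixture(scope="session")
def barrel8():
    return generate_barrel(BarrelSpec(n_strands=8, seed=1), protein_id="b8")


@pytest.fixture(scope="session")
def barrel16():
    return generate_barrel(BarrelSpec(n_strands=16, seed=2), protein_id="b16")


@pytest.fixture(scope="session")
def scenario_battery():
    """One instance of every scenario kind (noise-free, fixed seed)."""
    out = {}
    for kind, n_q, n_t in SCENARIO_CASES:
        q, t, rec, truth = generate_alignment_scenario(
            ScenarioSpec(kind=kind, n_query=n_q, n_target=n_t, seed=7))
        qid = f"{kind[:4]}_q"
        tid = qid if rec.is_self else f"{kind[:4]}_t"
        rec.query_id, rec.target_id = qid, tid
        q.annotation.protein_id, t.annotation.protein_id = qid, tid
        out[kind] = (q, t, rec, truth)
    return out
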