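"""End-to-end orchestration: simulate, annotate, classify, network, stats.

Every stage writes plain-text intermediates (TSV/JSON) into the run's output
directory so that each summary number is traceable to a file. All stages are
deterministic given the configuration seed.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import alignio, classify, netstats, residuestats, structure, synthgen, topomap

log = logging.getLogger("barrelmap")

DEFAULT_THRESHOLDS = (1e-3, 1e-5, 1e-7, 1e-12)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""
    structures_dir: str | None = None
    alignment_table: str | None = None
    membership_file: str | None = None
    out_dir: str = "barrelmap_out"
    evalue_thresholds: tuple = DEFAULT_THRESHOLDS
    min_aligned: int = 20
    internal_max_evalue: float = 1e-3
    internal_min_probability: float = 75.0
    alternation_denominator: str = "region"
    seed: int = 0

    def validate(self) -> None:
        if self.min_aligned < 0 or self.internal_max_evalue <= 0:
            raise ValueError("thresholds must be positive")
        for t in self.evalue_thresholds:
            if t <= 0:
                raise ValueError("E-value thresholds must be positive")


# --------------------------------------------------------------------------
# synthetic study

@dataclass
class SyntheticStudy:
    """In-memory synthetic dataset: barrels, alignment records, truths."""
    barrels: dict  # id -> Barrel
    records: list
    truths: list  # ScenarioTruth per record
    memberships: dict

    @property
    def annotations(self) -> dict:
        return {pid: b.annotation for pid, b in self.barrels.items()}

    @property
    def sequences(self) -> dict:
        return {pid: b.sequence for pid, b in self.barrels.items()}


STUDY_SCENARIOS = (
    ("cterm_duplication", 8, 16),
    ("nterm_duplication", 8, 16),
    ("internal_offset", 14, 22),
    ("hairpin_shift_self", 10, 10),
    ("double_hairpin_shift_self", 8, 8),
    ("loop_to_hairpin", 16, 18),
    ("large_rearrangement", 16, 18),
    ("topology_flip", 16, 16),
)


def simulate_study(seed: int = 0, replicates: int = 3, noise: float = 0.0,
                   scenarios=STUDY_SCENARIOS) -> SyntheticStudy:
    """A battery of planted alignment scenarios with unique protein ids."""
    barrels, records, truths = {}, [], []
    for si, (kind, n_q, n_t) in enumerate(scenarios):
        for rep in range(replicates):
            sub = seed * 10007 + si * 101 + rep
            spec = synthgen.ScenarioSpec(kind=kind, n_query=n_q, n_target=n_t,
                                         noise=noise, seed=sub % (2 ** 31))
            q, t, rec, truth = synthgen.generate_alignment_scenario(spec)
            qid = f"{kind[:4]}{rep}q{n_q}"
            tid = qid if rec.is_self else f"{kind[:4]}{rep}t{n_t}"
            q.annotation.protein_id = qid
            t.annotation.protein_id = tid
            rec.query_id, rec.target_id = qid, tid
            barrels[qid] = q
            barrels[tid] = t
            records.append(rec)
            truths.append(truth)
    memberships = synthgen.generate_membership(
        n_profiles=len(barrels), planted_overlap=0.0, seed=seed)
    return SyntheticStudy(barrels=barrels, records=records, truths=truths,
                          memberships=memberships)


def write_study(study: SyntheticStudy, out_dir: str | Path) -> None:
    """Materialize a study as PDB files, FASTA, alignment TSV and truth JSON."""
    out = Path(out_dir)
    (out / "structures").mkdir(parents=True, exist_ok=True)
    for pid, barrel in study.barrels.items():
        (out / "structures" / f"{pid}.pdb").write_text(synthgen.to_pdb(barrel, pid))
        (out / "structures" / f"{pid}.fasta").write_text(synthgen.to_fasta(barrel, pid))
    (out / "alignments.tsv").write_text(
        alignio.write_alignment_table(study.records, study.sequences))
    truth_json = [json.loads(t.to_json()) for t in study.truths]
    (out / "truth.json").write_text(json.dumps(truth_json, indent=1))
    (out / "memberships.json").write_text(json.dumps(
        {k: sorted(v) for k, v in study.memberships.items()}, indent=1))


# --------------------------------------------------------------------------
# pipeline stages

def run_annotate(config: RunConfig) -> dict:
    """Annotate every structure in config.structures_dir; returns
    protein_id -> StrandAnnotation and writes annotations.tsv."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pdbs = sorted(Path(config.structures_dir).glob("*.pdb"))
    annotations = {}
    failures = []
    for path in pdbs:
        pid = path.stem
        try:
            residues = structure.read_backbone(path.read_text())
            ann = structure.annotate(residues, protein_id=pid)
            annotations[pid] = ann
        except (ValueError, structure.NoBarrelError) as exc:
            failures.append((pid, str(exc)))
            log.warning("annotation failed for %s: %s", pid, exc)
    if not annotations:
        raise RuntimeError("no structure could be annotated")
    (out / "annotations.tsv").write_text(
        structure.write_annotations(list(annotations.values())))
    if failures:
        (out / "annotation_failures.tsv").write_text(
            "\n".join(f"{p}\t{m}" for p, m in failures) + "\n")
    return annotations


def run_full(config: RunConfig) -> dict:
    """Run every applicable stage; returns the summary dict (also written to
    summary.json). Stages whose inputs are missing are skipped with a notice."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": {k: v for k, v in asdict(config).items()},
                     "skipped": []}

    annotations: dict = {}
    sequences: dict = {}
    if config.structures_dir:
        annotations = run_annotate(config)
        for pid in annotations:
            residues = structure.read_backbone(
                (Path(config.structures_dir) / f"{pid}.pdb").read_text())
            sequences[pid] = "".join(r.aa for r in residues)
        summary["n_structures"] = len(annotations)
    else:
        summary["skipped"].append("annotation: no structures_dir")

    if not config.alignment_table:
        summary["skipped"].append("alignment stages: no alignment_table")
        (out / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
        return summary

    records = alignio.read_alignment_table(Path(config.alignment_table).read_text())
    records = alignio.filter_records(records, max_evalue=max(config.evalue_thresholds),
                                     min_aligned=config.min_aligned)
    summary["n_records"] = len(records)
    deduped = alignio.dedup_min_evalue(r for r in records if not r.is_self)
    summary["n_records_deduped"] = len(deduped)

    strand_counts = {pid: ann.n_strands for pid, ann in annotations.items()}
    nets = netstats.threshold_series(deduped, config.evalue_thresholds,
                                     strand_counts or None)
    summary["network"] = {}
    for th, net in nets.items():
        comp = netstats.largest_component(net)
        (out / f"network_{th:g}.tsv").write_text(netstats.write_edge_list(net))
        summary["network"][f"{th:g}"] = {
            "nodes": net.n_nodes, "edges": net.n_edges,
            "largest_component": len(comp),
        }
    if strand_counts:
        probs = netstats.same_vs_diff_probability(nets[config.evalue_thresholds[0]])
        summary["same_vs_diff"] = {f"{a}-{b}": v for (a, b), v in sorted(probs.items())}

    if annotations:
        table, cls_summary = classify.classify_all(records, annotations)
        table.to_csv(out / "classification.tsv", sep="\t", index=False)
        summary["classification"] = cls_summary

        internal = alignio.filter_records(
            [r for r in records if r.is_self],
            max_evalue=config.internal_max_evalue,
            min_aligned=config.min_aligned,
            min_probability=config.internal_min_probability)
        repeats = []
        for rec in internal:
            ann = annotations.get(rec.query_id)
            if ann is None:
                continue
            corr = topomap.map_to_strands(rec, ann, ann)
            repeats.append((rec.query_id, classify.classify_internal(corr)))
        with_repeat = {pid for pid, rc in repeats
                       if rc not in (classify.REPEAT_NONE,)}
        summary["internal_repeats"] = {
            "n_self_alignments": len(internal),
            "proteins_with_repeat": sorted(with_repeat),
        }

        corrs = []
        for rec in records:
            if rec.query_id in annotations and rec.target_id in annotations:
                corrs.append(topomap.map_to_strands(
                    rec, annotations[rec.query_id], annotations[rec.target_id]))
        profile = netstats.conservation_profile(corrs)
        (out / "conservation.json").write_text(json.dumps(
            {str(n): counts for n, counts in sorted(profile.items())}, indent=1))
        summary["conservation_n_sizes"] = sorted(profile)

        if sequences:
            stats = residuestats.transition_region_stats(
                records, annotations, sequences,
                denominator=config.alternation_denominator)
            stats.to_csv(out / "transition_stats.tsv", sep="\t", index=False)
            summary["transition_stats"] = stats.to_dict(orient="records")
    else:
        summary["skipped"].append("classification/repeats/conservation: no annotations")

    if config.membership_file:
        memberships = {k: set(v) for k, v in
                       json.loads(Path(config.membership_file).read_text()).items()}
        _, avg, mx = netstats.membership_overlap(memberships)
        summary["membership_overlap"] = {"average_pct": avg, "max_pct": mx}

    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
    return summary
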