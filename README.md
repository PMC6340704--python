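# barrelmap

Strand-topology annotation and evolutionary alignment analysis for bacterial
outer-membrane β-barrels (OMBBs).

OMBBs are closed, even-stranded, antiparallel β-barrels (8–26 strands) whose
girth evolves by discrete strand-number changes — hairpin duplications,
internal repeats, and rarer non-duplication events such as loop-to-hairpin
transitions and large rearrangements. Tracing those events requires
(1) reliable strand and loop boundaries from 3D structures and (2) a way to
project residue-level profile–profile alignments onto strand topology.
`barrelmap` provides both, plus the network- and residue-level statistics
built on top of them, and a synthetic barrel generator that makes the whole
pipeline testable with planted ground truth.

## What it computes

* **Strand annotation** (`barrelmap.structure`): residues are labelled
  strand/helix/other from φ/ψ windows; strands are maximal strand-like runs
  supported by ≥ 2 inter-strand hydrogen bonds (donor N···acceptor O ≤ 3.5 Å,
  |i−j| ≥ 3); per-strand membrane direction comes from the barrel axis signed
  so the chain termini sit on the periplasmic face.
* **Alignment topology** (`alignio`, `topomap`): alignment tables (canonical
  TSV, deposited space-delimited tables, HH-suite `.hhr`) are filtered
  (E-value ≤ threshold, ≥ 20 aligned residues, probability > 75% for internal
  repeats) and projected onto strand annotations. A strand pair counts as
  aligned when ≥ θ residue pairs fall inside both strands,
  θ = max(3, ⌈0.5 · shorter strand length⌉).
* **Classification** (`classify`): C-/N-terminal anchoring, internal
  offsets, hairpin shifts (self-alignment offset 2) and double hairpin shifts
  (offset 4), loop-to-hairpin transitions, large rearrangements, and
  topology redirection (aligned strands of opposite membrane direction).
* **Statistics** (`netstats`, `residuestats`): similarity networks over an
  E-value filtration (10⁻³ … 10⁻¹²), largest components, same- vs
  different-strand-number alignment probabilities, log-space mean E-values
  (10^mean(log₁₀ E)), strand-position conservation profiles, HMM-membership
  overlap, polarity alternation, Kyte–Doolittle hydropathy, and residue
  volumes.
* **Synthetic barrels** (`synthgen`): idealized barrels with Cα atoms on a
  cylinder of radius R = √((n·b)² + (S·a)²) / 2π (n strands, shear S, rise
  a = 3.3 Å, spacing b = 4.4 Å), full N/CA/C/O backbones that annotate
  correctly, and alignment scenarios that plant each topological
  relationship with known truth.

## Worked example

```sh
python examples/classify_scenarios.py
```

prints one line per planted scenario kind:

```
cterm_duplication           8->16  -> CTERM_ANCHORED  (E=3.9e-16, 8 strand pairs)
nterm_duplication           8->16  -> NTERM_ANCHORED  (E=3.9e-16, 8 strand pairs)
internal_offset            14->22  -> INTERNAL_OFFSET  (E=3.9e-16, 12 strand pairs)
hairpin_shift_self         10->10  -> OTHER repeat=HAIRPIN_SHIFT  (E=3.9e-16, 8 strand pairs)
double_hairpin_shift_self   8-> 8  -> OTHER repeat=DOUBLE_HAIRPIN_SHIFT  (E=3.9e-16, 4 strand pairs)
loop_to_hairpin            16->18  -> LOOP_TO_HAIRPIN  (E=3.9e-16, 16 strand pairs)
large_rearrangement        16->18  -> LARGE_REARRANGEMENT +flip  (E=3.9e-16, 15 strand pairs)
topology_flip              16->16  -> OTHER +flip  (E=3.9e-16, 15 strand pairs)
```

Each line is a pair of generated barrels whose alignment was planted with one
topological relationship; the classifier recovers the planted category from
the re-annotated structures alone. `+flip` marks an aligned strand pair whose
membrane directions disagree. The other examples
(`build_a_barrel.py`, `annotate_structure.py`,
`network_and_residue_stats.py`) walk the geometry, the annotator and the
statistics the same way.

A thin CLI wraps the pipeline for directory-level runs:

```sh
barrelmap simulate --seed 1 --out study/
barrelmap annotate --structures study/structures --out run/
barrelmap full --structures study/structures --alignments study/alignments.tsv --out run/
```

On real data, point `--structures` at a directory of PDB files and
`--alignments` at a profile–profile alignment table; structure-independent
stages (network statistics) also run without structures.

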