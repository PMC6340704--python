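# Methods

## Scope and model

`barrelmap` analyses the evolution of outer-membrane β-barrel (OMBB)
topology from two inputs: backbone coordinates (strand/loop boundaries,
membrane directions) and pairwise profile–profile alignments (who is related
to whom, and which residues correspond). The package does not build or search
HMM profiles; alignments are consumed as tables (or synthesized). Everything
downstream — strand-level projection, duplication/rearrangement
classification, network and residue statistics — is implemented here.

## Idealized barrel geometry

The generator uses a cylindrical lattice model. With n strands, shear number
S, rise per residue a and inter-strand spacing b, Cα sites sit on a cylinder
of radius

    R = sqrt((n*b)^2 + (S*a)^2) / (2*pi),

with all strands tilted by α = atan(S·a / n·b) from the barrel axis.
Defaults: a = 3.3 Å, b = 4.4 Å, S = n + 2. The shear default is a
convention (real shear values vary by barrel family and are not dictated by
the inputs this package consumes); S = n + 2 yields strand tilts of ~35–45°
and per-hairpin radius increments of ~1.75 Å, close to the ~1.66 Å increment
observed for solved OMBBs. The generator records its parameters in the
`BarrelSpec` carried by every `Barrel`.

Backbone atoms come from an ideal β-strand template: a 12-residue strand is
built by internal-coordinate chain construction (NeRF) at φ = −120°,
ψ = +130°, its axis fitted, and the per-parity (pleat) offsets of N/CA/C/O
averaged. Each lattice site then receives template atoms in its local frame
(chain direction, surface normal). Two deliberate idealizations:

* **Carbonyl re-pointing.** Each strand residue's O is aimed at the amide N
  of its hydrogen-bond partner on the neighbouring strand (side alternating
  with pleat parity, nearest lattice site on that strand). This guarantees a
  detectable N···O ladder at any (n, S) without affecting φ/ψ, which do not
  involve O.
* **Left-handed loops.** Loops are NeRF fragments built at fixed
  φ = +70°, ψ = +40° and rigidly fitted onto a bulged path over the barrel
  rim (anchored at the flanking strand ends). Interior loop residues
  therefore have deterministically non-β dihedrals, so annotation cannot
  bleed strand runs across loops. The loop and tail residues flanking each
  strand get their junction atoms (the N of the first loop residue, the C/O
  of the last) from the virtual lattice extension of the strand, which keeps
  the strand-edge residues' own φ/ψ inside the β window.

Sequences encode the pleat: lipid-facing strand positions are nonpolar (L),
pore-facing polar (T), loops polar (S), with a seeded class-preserving
substitution rate (default 0.1) drawing from the fixed polar/nonpolar
partition. Substitutions never change a position's polarity class, so
polarity statistics stay analytically predictable. Scenario loops that are
"secretly strands" (loop-to-hairpin and rearrangement scenarios) are
overwritten with the alternating strand pattern.

What the generator does **not** emulate: side chains, β-bulges, tilted or
elliptic barrels, plug domains, missing density, crystallographic noise.
Passing tests on synthetic barrels therefore demonstrate the correctness of
the pipeline's logic, not robustness to the full heterogeneity of solved
structures; on real PDB files, strand-edge assignments can differ by a
residue or two from other annotators.

## Strand annotation

* φ/ψ from the standard four-atom torsions; NaN at termini and degenerate
  (collinear) quadruples.
* Labelling windows (configurable): β = φ ∈ [−180, −45] and
  ψ ∈ [45, 180) ∪ [−180, −170); α = φ ∈ [−90, −35], ψ ∈ [−70, −15]. These
  are permissive Ramachandran-standard regions.
* Hydrogen bonds: donor N(i)···acceptor O(j) ≤ 3.5 Å with |i − j| ≥ 3, no
  angular term — the simplest criterion that supports ladder detection.
* Strands: maximal strand-like runs (minimum 3 residues, internal bulges of
  up to 2 non-strand residues tolerated) kept only while connected to
  another kept run by ≥ 2 hydrogen bonds; the filter iterates to a fixed
  point. Strands are numbered 1..n from the N terminus.
* Directions: the barrel axis is the mean of sign-aligned per-strand
  end-to-end Cα vectors. A plain principal axis of the coordinates was
  rejected: for wide barrels the radial spread exceeds the axial spread and
  PCA returns an in-plane axis. The axis is signed so the chain termini lie
  on the negative (periplasmic) side; direction(strand) = sign of the axial
  displacement from its first to its last residue. Structures with < 3 Å
  axial extent or cancelling strand vectors are rejected as degenerate.
* Alternative structures: per strand slot, the union interval is the
  "longest" and the intersection the "shortest" definition; disagreeing
  strand counts are flagged and the majority count used.

## Alignment handling

The canonical table dialect is TSV with gapped alignment strings; the reader
maps common column-name synonyms and fails loudly on missing mandatory
columns (query, target, E-value). Filtering keeps records with
E ≤ threshold (inclusive), ≥ 20 aligned residues, and — for internal
repeats — probability strictly > 75%. Deduplication keeps one record per
unordered pair: minimal E-value, ties to the longer alignment, then
lexicographic order. Classification consumes all records; network edges only
the deduplicated minimum.

## Strand-level projection

A region pair (strand–strand or loop–strand) is supported when ≥ θ aligned
residue pairs fall inside both regions, θ = max(3, ⌈0.5 · shorter strand
length⌉) using the strand side(s) only. Strand-to-strand correspondence
statements require a colinear chain; among supported strand pairs the chain
of maximal total support (strictly increasing in both indices) is selected
by dynamic programming, with ties broken to more pairs and then the smaller
index sum — a criterion invariant under query/target transposition, which
makes the mapping exactly symmetric under swapping the two proteins.
Leftover supported pairs and loop↔strand matches become cross-matches.
θ is configurable; results at other θ can be produced by passing a different
threshold function.

## Classification

Self-alignments: constant strand-index offset 2 (≥ 2 pairs) = hairpin
shift, 4 = double hairpin shift, 0 = identity (no repeat), otherwise OTHER.

Cross-protein alignments, in precedence order: large rearrangement
(loop→hairpin plus strand→loop plus loop→strand), loop-to-hairpin (a loop
matched to two consecutive strands of the partner, either orientation),
C-terminal anchoring (all pairs share offset 0 from the C-terminal strand),
N-terminal anchoring (equal indices), internal offset (constant nonzero
offset, no qualifying cross-matches), else OTHER. Anchoring tolerates one
outlier pair when its support is below θ — anchoring is offset-based, not
conditioned on the last strand actually being aligned. When both anchorings
hold (equal counts, identity mapping) the C-terminal label wins and the
record is flagged ambiguous. Alignments whose strand pairs disagree in
membrane direction are flagged as redirections; a single-strand topology
flip (insertion corrected by a strand-to-loop change) classifies as OTHER
with the redirection flag — the flag, not the category, carries the signal.
Alternate-alignment flags are computed across records sharing a protein pair
whose query-side spans overlap; a loop-to-hairpin with an alternate becomes
LOOP_TO_HAIRPIN_ALT.

## Statistics

* Networks: nodes are all dataset proteins (isolates included), edges the
  deduplicated minimal E-value per pair at E ≤ threshold. Largest component
  ties break to the component containing the lexicographically smallest id.
* Same- vs different-n probabilities: edges per bucket divided by possible
  pairs (C(k,2) within a size, k₁·k₂ across sizes).
* Log-space mean E-value: 10^mean(log₁₀ E); errors on empty or nonpositive
  input.
* Conservation profiles count, per barrel size and strand position, how
  often that position appears in a strand pair (both sides of every
  alignment), so the total is twice the number of strand pairs.
* Membership overlap: |A ∩ B| / min(|A|, |B|) × 100. The denominator is a
  convention ("percent overlap" admits several); min(|A|,|B|) is the most
  conservative for detecting profile contamination.
* Polarity alternation: positions after the first whose polarity class
  differs from the previous residue, skipping positions immediately after a
  gap, divided by the **total region length including gap columns** — the
  convention fixed by the formula's worked examples ("LTLT" → 3/4,
  "LT-LT" → 2/5). The alternative denominator (comparisons actually made)
  is available as `denominator="steps"`. Hydropathy is the Kyte–Doolittle
  mean over non-gap positions; volumes the Zamyatnin means (both bundled as
  cited data files).
* Transition-region statistics: loop- and strand-side stretches of
  loop↔strand cross-matches in alignments classified as loop-to-hairpin
  (plain or alternate) or large rearrangement, deduplicated at ≥ 50%
  identity per protein region (first kept); controls are all strands and
  extracellular loops (those following an outward-pointing strand, length
  ≥ 3) of the annotated proteins that take part in no transition alignment.

## Problem sizes and determinism

The test suite and the acceptance script use synthetic studies of 8 scenario
kinds × 3–5 replicates (≈ 24–40 alignments over ≈ 28–42 barrels) and
strand-recovery sweeps over n ∈ {8..26} with 5–20 seeds per size; these
sizes exercise every code path while keeping a full run in tens of seconds.
Barrel geometry is deterministic given the BarrelSpec (seeds affect sequence
letters and scenario E-values); all randomness flows through
`numpy.random.default_rng` seeded from the caller, so identical seeds give
byte-identical outputs.

## Known limitations

* The φ/ψ windows and H-bond rule are conventions; published strand tables
  for real structures may differ at strand edges.
* Multimeric barrels and barrels with large plug domains are out of scope
  (first chain only; plugs annotate as non-strand but may contribute
  spurious short runs on real data).
* The classifier's category set is closed; genuinely novel topological
  relationships land in OTHER with flags rather than new labels.
* Synthetic noise models only alignment-column loss, not systematic aligner
  biases such as shifted registers.
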