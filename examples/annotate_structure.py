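"""Round-trip a barrel through PDB text and the strand annotator.

Annotation assigns strand intervals from phi/psi labelling plus the
hydrogen-bond ladder, then membrane directions from the barrel axis with
the chain termini fixed on the periplasmic face.
"""
from barrelmap import BarrelSpec, annotate, generate_barrel, read_backbone, to_pdb

barrel = generate_barrel(BarrelSpec(n_strands=16, seed=4), protein_id="demo16")
pdb_text = to_pdb(barrel)
print(f"PDB text: {len(pdb_text.splitlines())} lines")

residues = read_backbone(pdb_text)
annotation = annotate(residues, protein_id="demo16")

print(f"recovered {annotation.n_strands} strands (planted: "
      f"{barrel.annotation.n_strands})")
for i, ((s, e), d) in enumerate(zip(annotation.strands, annotation.directions), 1):
    arrow = "up (extracellular)" if d == 1 else "down (periplasmic)"
    print(f"  strand {i:2d}: residues {s:3d}-{e:3d}  N->C points {arrow}")
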