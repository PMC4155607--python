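"""Reading alignments, choosing a Y-axis scale, and rendering a small MSA.

The Y-axis order changes only where lines are drawn, never any statistic;
swapping scales is how one probes different physicochemical patterns in
the same alignment.
"""

from pathlib import Path

from seqbundles import (
    builtin_scale,
    consensus,
    custom_scale,
    export,
    read_alignment,
    render_bundle,
    single_group,
    write_alignment,
)

# plain-text input: one aligned row per line, gaps as '-'
Path("demo.txt").write_text("PPKKA\nPPK-A\nPP-KV\nPPKKA\n")
aln = read_alignment("demo.txt", "txt")
print(f"read {aln.n_rows} sequences x {aln.n_cols} columns")

ga = single_group(aln)
print(f"consensus: {consensus(ga)}")

mw = builtin_scale("molecular_weight_lide")
residues = [s for s in mw.order if s != "-"]
print(f"molecular-weight axis: {residues[0]} (lightest, top) ... "
      f"{residues[-1]} (heaviest, bottom)")

doc = render_bundle(ga, mw)
export(doc, "demo_bundle.svg", "svg")
print(f"wrote demo_bundle.svg with {len(doc.paths())} paths")

# any alphabet works: a 4-letter DNA axis has 5 slots (4 bases + gap)
dna = custom_scale(list("ACGT"), "top", alphabet="ACGT")
print(f"DNA scale slots: {dna.order}")

write_alignment(aln, "demo.fasta", "fasta")
print("round-tripped demo.txt -> demo.fasta")
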