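"""Annotate a single lineage edge and print each mutation in detail.

Reproduces the canonical display form "92: G->A (position 31: S->N)": a
nucleotide substitution at alignment position 92 of an in-frame V(D)J
sequence falls in codon 31, replacing serine with asparagine in CDR1.
"""

from iglineage import diff_edge, parse_region_fasta

backbone = "GCT" * 120                      # in-frame Ala backbone, 360 nt
parent = backbone[:90] + "AGT" + backbone[93:]   # codon 31 = AGT (Ser)
child = parent[:91] + "A" + parent[92:]          # position 92: G -> A

region_map = parse_region_fasta(f">UCA 78 114 165 195 312 360\n{parent}\n")
annotation = diff_edge(parent, child, region_map)

print(f"substitutions on edge: {annotation.nt_count} "
      f"({annotation.aa_count} amino-acid changing)")
for ev in annotation.events:
    print(f"  {ev.nt_position}: {ev.from_nt}->{ev.to_nt} "
          f"(position {ev.aa_label}: {ev.from_aa}->{ev.to_aa}) "
          f"[{ev.rs_class}, {ev.region}]")
# 'R' marks a replacement mutation; CDR1 is the first antigen-contact loop.
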