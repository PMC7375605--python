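# iglineage

Processing, annotation and export of **immunoglobulin clonal-lineage
trees** — for immunologists studying antibody affinity maturation from
B-cell receptor sequencing data.

A clonal family is the set of Ig sequences descending from one V(D)J
recombination event; its evolution under somatic hypermutation (SHM) is
reconstructed upstream by a phylogenetic tool and explored downstream in
terms of *which mutations arose where*. `iglineage` sits between the two: it
ingests trees inferred either by **PHYLIP dnaml** (the plain-text `outfile`
with reconstructed interior sequences) or by **Immcantation's IgPhyML**
(Change-O AIRR table + tab file + `--asr` ancestral FASTA), normalizes them
into a single rooted lineage model, annotates every edge with its
mutations, and exports the results in analysis-ready formats — headless,
deterministic, scriptable.

## What it computes

Given a lineage rooted at the unmutated common ancestor (UCA), with
observed Igs at the leaves and inferred branch points (BPs) in between:

* **Ambiguity resolution** — an IUPAC code at a BP position is replaced by
  the base, among those the code denotes, most frequent at that position
  across the *observed* descendants of the BP (ties break A < C < G < T).
* **Collapsing** — a BP whose sequence equals one of its children is merged
  into that child (a "theoretical" intermediate that coincides with a real
  Ig); identical observed siblings are clustered into one multi-member node.
* **Mutation annotation** — for every edge, each position where parent and
  child both hold a concrete base and differ yields a substitution event
  with its codon context. An event is **replacement (R)** if the encoded
  amino acid changes under the standard genetic code and **silent (S)**
  otherwise; events are mapped to the antibody FW1–CDR3(–FW4) regions via
  IMGT-gapped end positions, and labeled with the absolute codon index (or
  a user-supplied Kabat-style numbering map). Per-edge totals are reported
  as `nt (aa)` and per-region as R/S tallies.
* **Exports** — lossless XML (byte-stable, reloadable), JSON dump,
  nucleotide/protein alignment TSVs with a region ruler, a BASELINe-ready
  grouped FASTA (germline first, `>>` header), and SVG/PNG/EPS renderings.

A seeded simulator (`iglineage.simulate`) generates ground-truth lineages
under a simple SHM model and emits byte-valid dnaml outfiles and
Immcantation triples, so the full pipeline is testable without external
tools.

## Worked example

```python
from iglineage import diff_edge, parse_region_fasta

backbone = "GCT" * 120                           # in-frame 360 nt V(D)J
parent = backbone[:90] + "AGT" + backbone[93:]   # codon 31 = AGT (Ser)
child = parent[:91] + "A" + parent[92:]          # position 92: G -> A

rm = parse_region_fasta(f">UCA 78 114 165 195 312 360\n{parent}\n")
ann = diff_edge(parent, child, rm)
for ev in ann.events:
    print(f"{ev.nt_position}: {ev.from_nt}->{ev.to_nt} "
          f"(position {ev.aa_label}: {ev.from_aa}->{ev.to_aa}) "
          f"[{ev.rs_class}, {ev.region}]")
```

prints

```
92: G->A (position 31: S->N) [R, CDR1]
```

— the substitution at nucleotide 92 falls in codon 31, replacing serine
with asparagine in the first antigen-contact loop (CDR1): a replacement
mutation of the kind whose recurrence across a family suggests
antigen-driven selection. More narrative scripts live in `examples/`
(`dnaml_workflow.py`, `immcantation_workflow.py`, `mutation_report.py`,
`export_bundle.py`).

## Command line

```sh
iglineage simulate --seed 1 --n-leaves 6 --out fixture
iglineage run-dnaml fixture/dnaml_outfile.txt \
    --region-fasta fixture/region.fasta --out output
iglineage run-immcantation --airr fixture/airr.tsv --tab fixture/igphyml.tab \
    --asr-fasta fixture/asr.fasta --clone 1 --out output
```

Each run creates a sub-folder named after the input file (or
`<tabfile>_clone<ID>`) holding `lineage.xml`, `lineage.json`, the two
alignment TSVs, `baseline_input.fasta` (when the region FASTA was given)
and the renderings. EC50 titers and free-text comments can be attached per
node with `--annotate-file` (TSV: label, EC50 with optional units, comment)
and appear in all exports.

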