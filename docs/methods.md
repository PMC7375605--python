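# Methods

## The lineage model

A processed clonal family is a rooted tree. The root carries the unmutated
common ancestor (UCA) — the inferred germline-configuration V(D)J sequence —
observed immunoglobulins sit at (or, after collapsing, also inside) the
tree, and the remaining internal vertices are branch points (BPs) carrying
reconstructed intermediate sequences. All sequences share one alignment
length; children are kept in input-file order, which is the deterministic
tie-break wherever order matters. Each node lists the *member labels* merged
into it; the first member is always the display label. After processing,
surviving BPs (and BP labels absorbed into member lists) are renamed `BP1`,
`BP2`, … in pre-order, so repeated runs are bit-identical.

## Normalization steps

**Ambiguity resolution.** Upstream maximum-likelihood reconstruction can
leave IUPAC ambiguity codes in BP sequences. Each such position is resolved
to the base — among those the code denotes — most frequent at that position
across the observed descendants of that BP. Only observed sequences vote:
they are the empirical evidence; the UCA and other BPs are themselves
inferences. Ties break in the fixed order A < C < G < T. If no descendant
carries an allowed base, the position becomes `N` and a warning is logged
rather than aborting the run on a single site. The operation is idempotent
and never touches UCA or observed sequences. (IgPhyML ancestral sequences
are normally already ambiguity-free; the resolver runs on that route only
when codes are actually detected.)

**Collapsing.** A BP whose sequence is identical to one of its children is
merged into that child — the typical case being a theoretical intermediate
that coincides with an existing Ig. Identity is case-insensitive and treats
`.` and `-` as the same gap character (both are alignment padding), while
`N` matches only `N` (explicit uncertainty is not a wildcard). When several
children tie, the earliest in child order wins; merging is applied
bottom-up to a fixed point. The rule applies only to BP-versus-child pairs;
a BP identical to its *parent* is left alone (collapsing upward would
silently re-root evidence onto an inference).

**Clustering.** Observed sibling leaves with identical sequences are merged
into one node whose member list records every label. Non-sibling duplicates
are left apart: topology is respected.

Both operations preserve the multiset of observed sequences (counting one
copy per observed member label) and the set of member labels, and are
idempotent; the test suite checks these invariants over randomized trees
and cross-checks the fixed point against an independent naive O(n²)
pairwise implementation.

## Mutation annotation

Edges are diffed position by position. An event is recorded only where both
sequences hold a concrete base (A/C/G/T) and differ; columns involving a
gap, `N` or residual ambiguity code are excluded from events but counted
separately (`untallied`) so nothing is dropped silently — indel calling is
out of scope, and inventing an R/S class for an untranslatable change would
be worse than reporting none.

Coordinates follow a two-system convention: the *nucleotide position* is
1-based in alignment coordinates (gap columns counted), which keeps display
positions stable against the input alignment; the *codon index* is computed
on the gap-stripped sequence read in frame from alignment position 1 (V(D)J
sequences begin at the V start under the IMGT convention). Inserting a
shared gap column therefore shifts nucleotide positions but never changes
codon indices, amino acids or R/S classes — a property the suite tests
directly.

R/S classification uses the standard genetic code (a table owned by this
package and verified exhaustively against Biopython's translator over all
64×64 ordered codon pairs): silent iff the translation is unchanged; any
change to or from a stop codon (`*`) is replacement. When two substitutions
hit one codon, each nucleotide event is reported (sharing the codon's
from/to context) but the edge's amino-acid count increments once per codon
whose translation changed — "aa mutations" counts changed residues, not
changed bases.

Regions come from a `RegionMap` parsed from the single-record UCA FASTA
whose header lists 6 or 7 strictly increasing, 1-based *inclusive end
positions* (FW1, CDR1, FW2, CDR2, FW3, CDR3, optional FW4); region *k*
starts one past the end of region *k−1*, and positions beyond the last end
are `UNASSIGNED`. Amino-acid display labels default to the absolute codon
index; a user-supplied two-column TSV can map indices to Kabat-style labels
(e.g. `52a`). Numbering is offline-only by design — reproducibility beats a
network lookup, and the absolute index is the documented fallback anyway.

## Input dialects

**dnaml.** The parser targets the PHYLIP 3.69-family `outfile`: it ignores
the whitespace-fragile ASCII tree sketch and trusts only the
`Between/And/Length` branch table and the interleaved
"Probable sequences at interior nodes" blocks (menu option 5 upstream is
mandatory; its absence is a fatal, actionable error). Lowercase bases —
dnaml's marker for reconstruction confidence ≤ 0.95 — are uppercased for
all computation with their positions retained for display/export; the
original behaviour for these sites is undocumented upstream, and silently
discarding the flag would lose information. Rooting follows the outgroup
convention: the UCA is the outgroup taxon, by default the first taxon,
overridable by flag; all branches are oriented away from it, which provably
preserves the undirected branch set.

**Immcantation.** AIRR Rearrangement TSVs are read with pandas using the
standard column names (`sequence_id`, `clone_id`, `sequence_alignment`,
`germline_alignment`, with `germline_alignment_d_mask` accepted as alias);
the IgPhyML tab file (`CLONE`/`TREE`, case-insensitive) supplies one newick
per clone, parsed with dendropy. The germline node is located by a
case-insensitive label pattern (default: contains `GERM`), falling back to
the leaf at the outgroup position with a warning. Internal newick nodes
must be labeled and resolved by the `--asr` FASTA — positional guessing
across Immcantation releases would be unsafe, so an unlabeled internal node
is fatal with a pointer at the `--asr` requirement. Length disagreements
between AIRR, germline and ASR sequences abort assembly; alignment repair
is out of scope. Newick branch lengths are retained as metadata but never
used: edges are annotated by mutation counts, not by model-scaled lengths.

## Serialization

The XML schema is this package's own (versioned, `schema-version="1.0"`);
`read_xml(write_xml(t))` is the identity on the full data model and the
writer is byte-stable, both property-tested over random simulated trees.
The BASELINe input follows the grouped-FASTA submission convention: the
germline record first with a `>>` header prefix (config constant
`GERMLINE_PREFIX`), then one record per observed member label, all
IMGT-gapped and equal-length — which is why this export requires the region
FASTA. The BASELINe *results* reader is fixture-defined and tolerant to
column supersets: it needs a region-class column (`Type`/`Region`/`Class`)
plus any `Sigma`/CI/P columns, and attaches the summary to tree provenance
so it survives the XML round trip. SVG rendering is hand-written and
byte-deterministic with `nt (aa)` edge labels and member/EC50 node labels;
PNG and EPS are produced directly by matplotlib's Agg backend rather than
by converting the SVG — no SVG converter dependency, and byte stability is
only promised for SVG.

## The simulator

`simulate_lineage` draws a random bifurcating topology by sequential edge
attachment, a random in-frame stop-free UCA (default 360 nt = 120 codons,
the canonical IMGT heavy-chain partition 78/114/165/195/312/360), and 1–4
substitutions per edge at positions sampled with a 3× rate multiplier
inside CDRs — a coarse stand-in for SHM targeting, chosen so region tallies
are non-trivial. Substituted bases are uniform over the three alternatives;
there is no hot-spot motif model (RGYW/WRCY), no indels, no sequencing
error — the simulator validates plumbing, not SHM realism, so passing tests
demonstrate correct parsing/processing/annotation, not fidelity to real
repertoires. With reversions disabled (default) no position mutates twice
on any root-to-leaf path, making per-edge ground truth exactly recoverable
and path events additive; a path that would exhaust free positions is a
fatal config error. `ambiguity_rate` rewrites that fraction of BP positions
as two-base IUPAC codes, only at sites where the true base holds a strict
majority among observed descendants over the chosen alternative — precisely
the regime in which resolution is determinate. `duplicate_leaf_rate` copies
leaves verbatim as new siblings to exercise clustering. Ground-truth
amino-acid effects are computed with Biopython's translator, keeping the
simulator independent of the annotator's own code table. Everything is
driven by one integer seed; identical config + seed gives byte-identical
emitted files.

Problem sizes used by the test suite: the recovery sweep runs 100 seeded
lineages of 2–12 leaves through both ingestion routes; invariant checks use
200 random trees of ≤ 12 nodes; the scale test runs one 1,000-leaf lineage
through simulate → emit → parse → process → annotate → XML round trip.

## Known limitations

* Substitutions only: columns with gaps on one side are reported as
  untallied differences, never as events.
* The dnaml parser handles the 3.69-family dialect; exotic variants may
  need the tolerant-whitespace paths extended.
* Kabat numbering requires a user-supplied mapping; no online lookup.
* Compatibility with any other tool's XML schema is not claimed.
* The member-weighted majority in ambiguity resolution counts each observed
  leaf node once, regardless of how many identical sequences it represents.
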