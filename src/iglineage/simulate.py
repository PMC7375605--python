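"""Synthetic clonal-lineage simulator and byte-valid format emitters.

Simulates a ground-truth B-cell lineage under a simple somatic-hypermutation
model — a random bifurcating topology over the observed leaves, a random
in-frame UCA sequence, and per-edge point substitutions whose positions are
biased toward the CDRs — then emits the files the parsers in this package
ingest: a PHYLIP-dnaml-dialect outfile and the Immcantation triple (AIRR
TSV, IgPhyML tab file, ancestral-sequence FASTA) plus the region FASTA.

The simulator exists to make every parsing and annotation path testable
without external tools; it deliberately has no SHM hot-spot motif model.
Ground-truth amino-acid effects are computed with Biopython's translator,
independent of the annotation module's own genetic-code table.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .annotate import REGION_NAMES, UNASSIGNED, MutationEvent, RegionMap
from .model import (
    BASES, BP, IUPAC_AMBIGUITY, OBSERVED, UCA, LineageNode, LineageTree,
)

#: inverse IUPAC lookup for two-base ambiguity codes
_CODE_FOR_PAIR = {
    frozenset(bases): code
    for code, bases in IUPAC_AMBIGUITY.items() if len(bases) == 2
}

_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(
    a + b + c
    for a in BASES for b in BASES for c in BASES
    if a + b + c not in _STOPS
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated lineage.

    Defaults emulate a small expanded human heavy-chain clone: a 360 nt
    (120 codon) IMGT-gapped V(D)J with the canonical FW/CDR partition, a
    handful of substitutions per tree edge with a 3x rate bias toward CDRs,
    and no back-mutations.
    """

    seed: int = 0
    uca_length: int = 360
    n_leaves: int = 8
    mutations_per_edge: tuple[int, int] = (1, 4)
    region_ends: tuple[int, ...] = (78, 114, 165, 195, 312, 360)
    cdr_rate_multiplier: float = 3.0
    allow_reversions: bool = False
    ambiguity_rate: float = 0.0
    duplicate_leaf_rate: float = 0.0

    def validate(self) -> None:
        if self.n_leaves < 1:
            raise ValueError("n_leaves must be >= 1")
        if self.uca_length % 3 != 0 or self.uca_length <= 0:
            raise ValueError("uca_length must be a positive multiple of 3")
        if self.mutations_per_edge[0] < 0 or self.mutations_per_edge[1] < self.mutations_per_edge[0]:
            raise ValueError("mutations_per_edge must be a non-negative (lo, hi) range")
        if self.cdr_rate_multiplier < 1:
            raise ValueError("cdr_rate_multiplier must be >= 1")
        if not 0 <= self.ambiguity_rate <= 1 or not 0 <= self.duplicate_leaf_rate <= 1:
            raise ValueError("rates must lie in [0, 1]")
        if len(self.region_ends) not in (6, 7):
            raise ValueError("region_ends must hold 6 or 7 boundaries")
        if self.region_ends[-1] > self.uca_length:
            raise ValueError("last region end exceeds uca_length")
        if self.mutations_per_edge[1] > self.uca_length:
            raise ValueError("impossible config: more mutations per edge than positions")


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must recover."""

    #: (parent_label, child_label) pairs, pre-order
    topology: list[tuple[str, str]] = field(default_factory=list)
    #: label -> true (unperturbed) sequence
    node_sequences: dict[str, str] = field(default_factory=dict)
    #: (parent_label, child_label) -> implanted substitution events
    events: dict[tuple[str, str], list[MutationEvent]] = field(default_factory=dict)
    #: BP label -> {1-based position: true base} for ambiguity-perturbed sites
    perturbed: dict[str, dict[int, str]] = field(default_factory=dict)
    #: groups of leaf labels sharing one verbatim-copied sequence
    duplicate_groups: list[list[str]] = field(default_factory=list)


def _region_of(pos: int, ends: tuple[int, ...]) -> str:
    for name, end in zip(REGION_NAMES, ends):
        if pos <= end:
            return name
    return UNASSIGNED


def _aa(codon: str) -> str:
    if set(codon) - set(BASES) or len(codon) != 3:
        return "X"
    return str(Seq(codon).translate())


def simulate_lineage(config: SimulationConfig) -> tuple[LineageTree, GroundTruth]:
    """Simulate one lineage; identical config + seed gives identical output.

    Returns the lineage tree exactly as it will be emitted (BP sequences may
    contain IUPAC codes when ``ambiguity_rate > 0``) and the ground truth
    (true sequences, implanted per-edge events, perturbed sites).
    """
    config.validate()
    rng = random.Random(config.seed)

    uca_seq = "".join(rng.choice(_SENSE_CODONS) for _ in range(config.uca_length // 3))
    tree = LineageTree(alignment_length=config.uca_length, provenance={"source": "SIMULATION"})
    tree.region_map = RegionMap(
        names=REGION_NAMES[: len(config.region_ends)],
        ends=tuple(config.region_ends),
        uca_gapped=uca_seq,
    )
    root = LineageNode(node_id="root", label="UCA", kind=UCA, sequence=uca_seq)
    tree.add_node(root)

    # --- topology: random sequential attachment ---------------------------
    leaf_counter = 1
    bp_counter = 0
    first = LineageNode(node_id="L1", label="Ig1", kind=OBSERVED, sequence="")
    tree.add_node(first, parent_id="root")
    for _ in range(config.n_leaves - 1):
        edges = list(tree.edges())
        pid, cid = edges[rng.randrange(len(edges))]
        bp_counter += 1
        bp = LineageNode(node_id=f"B{bp_counter}", label=f"BP@{bp_counter}", kind=BP, sequence="")
        # splice the BP into the chosen edge, preserving child order
        kids = tree.children[pid]
        kids[kids.index(cid)] = bp.node_id
        tree.nodes[bp.node_id] = bp
        tree.bp_tokens.add(bp.label)
        tree.children[bp.node_id] = [cid]
        tree.parent[bp.node_id] = pid
        tree.parent[cid] = bp.node_id
        leaf_counter += 1
        leaf = LineageNode(
            node_id=f"L{leaf_counter}", label=f"Ig{leaf_counter}", kind=OBSERVED, sequence=""
        )
        tree.add_node(leaf, parent_id=bp.node_id)

    # --- sequences & events ------------------------------------------------
    gt = GroundTruth()
    weights = [
        config.cdr_rate_multiplier
        if _region_of(p, tuple(config.region_ends)).startswith("CDR") else 1.0
        for p in range(1, config.uca_length + 1)
    ]
    mutated_on_path: dict[str, set[int]] = {"root": set()}

    for node in tree.preorder():
        if node.node_id == "root":
            continue
        pid = tree.parent[node.node_id]
        parent_seq = tree.nodes[pid].sequence
        k = rng.randint(*config.mutations_per_edge)
        forbidden = set() if config.allow_reversions else mutated_on_path[pid]
        pool = [p for p in range(1, config.uca_length + 1) if p not in forbidden]
        if len(pool) < k:
            raise ValueError(
                "impossible config: a lineage path exhausted the unmutated "
                "positions (reversions are disabled); shorten the tree, lower "
                "mutations_per_edge or allow reversions"
            )
        pool_weights = [weights[p - 1] for p in pool]
        positions: list[int] = []
        for _ in range(min(k, len(pool))):
            pick = rng.choices(range(len(pool)), weights=pool_weights, k=1)[0]
            positions.append(pool.pop(pick))
            pool_weights.pop(pick)
        positions.sort()
        chars = list(parent_seq)
        subs: list[tuple[int, str, str]] = []
        for p in positions:
            old = chars[p - 1]
            new = rng.choice([b for b in BASES if b != old])
            chars[p - 1] = new
            subs.append((p, old, new))
        child_seq = "".join(chars)
        node.sequence = child_seq
        mutated_on_path[node.node_id] = mutated_on_path[pid] | set(positions)

        events = []
        for p, old, new in subs:
            codon_idx = math.ceil(p / 3)
            lo = (codon_idx - 1) * 3
            from_codon = parent_seq[lo:lo + 3]
            to_codon = child_seq[lo:lo + 3]
            from_aa, to_aa = _aa(from_codon), _aa(to_codon)
            events.append(MutationEvent(
                nt_position=p, from_nt=old, to_nt=new,
                codon_index=codon_idx, from_codon=from_codon, to_codon=to_codon,
                from_aa=from_aa, to_aa=to_aa,
                rs_class="S" if (from_aa == to_aa and from_aa != "X") else "R",
                region=_region_of(p, tuple(config.region_ends)),
                aa_label=str(codon_idx),
            ))
        parent_label = tree.nodes[pid].label
        gt.events[(parent_label, node.label)] = events

    # --- verbatim duplicate leaves (exercise clustering) -------------------
    n_dup = int(round(config.duplicate_leaf_rate * config.n_leaves))
    if n_dup:
        leaves = [n for n in tree.preorder() if n.kind == OBSERVED]
        for src in rng.sample(leaves, min(n_dup, len(leaves))):
            leaf_counter += 1
            dup = LineageNode(
                node_id=f"L{leaf_counter}", label=f"Ig{leaf_counter}",
                kind=OBSERVED, sequence=src.sequence,
            )
            tree.add_node(dup, parent_id=tree.parent[src.node_id])
            mutated_on_path[dup.node_id] = mutated_on_path[tree.parent[src.node_id]]
            gt.events[(tree.nodes[tree.parent[src.node_id]].label, dup.label)] = []
            gt.duplicate_groups.append([src.label, dup.label])

    for pid, cid in tree.edges():
        gt.topology.append((tree.nodes[pid].label, tree.nodes[cid].label))
    for node in tree.preorder():
        gt.node_sequences[node.label] = node.sequence

    # --- IUPAC perturbation of BP sequences (exercise resolution) ----------
    if config.ambiguity_rate > 0:
        for node in tree.preorder():
            if node.kind != BP:
                continue
            descendants = [d.sequence for d in tree.observed_below(node.node_id)]
            n_target = int(round(config.ambiguity_rate * config.uca_length))
            candidates = rng.sample(range(1, config.uca_length + 1), config.uca_length)
            chars = list(node.sequence)
            done = 0
            for p in candidates:
                if done >= n_target:
                    break
                true_base = chars[p - 1]
                if true_base not in BASES:
                    continue
                counts = {b: sum(1 for d in descendants if d[p - 1] == b) for b in BASES}
                alts = [b for b in BASES if b != true_base and counts[b] < counts[true_base]]
                if not alts:
                    continue  # no strict majority over any alternative; skip
                alt = rng.choice(alts)
                chars[p - 1] = _CODE_FOR_PAIR[frozenset((true_base, alt))]
                gt.perturbed.setdefault(node.label, {})[p] = true_base
                done += 1
            node.sequence = "".join(chars)

    return tree, gt


# ---------------------------------------------------------------------------
# emitters
# ---------------------------------------------------------------------------

def _blocks(seq: str, width: int = 60, group: int = 10) -> list[str]:
    out = []
    for start in range(0, len(seq), width):
        chunk = seq[start:start + width]
        out.append(" ".join(chunk[i:i + group] for i in range(0, len(chunk), group)))
    return out


def emit_dnaml_outfile(tree: LineageTree) -> str:
    """Emit the lineage as a PHYLIP-3.69-dialect dnaml outfile.

    Interior (BP) nodes are numbered 1.. in pre-order; the UCA is emitted as
    an ordinary tip (it is the outgroup taxon of the dnaml run) and is listed
    first in the branch table so it is the default rooting choice on re-parse.
    """
    interior_no: dict[str, int] = {}
    tip_name: dict[str, str] = {}
    for node in tree.preorder():
        if node.kind == BP:
            interior_no[node.node_id] = len(interior_no) + 1
        else:
            tip_name[node.node_id] = node.source_label or node.label

    def endpoint(nid: str) -> str:
        return str(interior_no.get(nid, tip_name.get(nid)))

    n_taxa = len(tip_name)
    L = tree.alignment_length
    lines: list[str] = []
    lines.append("Nucleic acid sequence Maximum Likelihood method, version 3.696")
    lines.append("")
    lines.append(f"  {n_taxa} sequences,  {L} sites")
    lines.append("")
    lines.append("  +" + "-" * 24 + "synthetic tree sketch omitted" + "-" * 24 + "+")
    lines.append("")
    lines.append("remember: this is an unrooted tree!")
    lines.append("")
    total_mut = sum(
        sum(1 for a, b in zip(tree.nodes[p].sequence, tree.nodes[c].sequence) if a != b)
        for p, c in tree.edges()
    )
    lines.append(f"Ln Likelihood = {-(L * 0.1 + total_mut * 1.5):.5f}")
    lines.append("")
    lines.append(" Between        And            Length      Approx. Confidence Limits")
    lines.append(" -------        ---            ------      ------- ---------- ------")
    lines.append("")
    # UCA edge first so the UCA is the first taxon on re-parse
    ordered_edges = sorted(
        tree.edges(), key=lambda e: 0 if tree.nodes[e[0]].kind == UCA else 1
    )
    for pid, cid in ordered_edges:
        # the root (outgroup/UCA) edge comes first with the UCA in the first
        # column, so the UCA is the first taxon seen on re-parse
        a, b = endpoint(pid), endpoint(cid)
        length = tree.edge_lengths.get((pid, cid))
        lines.append(_branch_row(a, b, length, tree, pid, cid))
    lines.append("")
    lines.append("     *  = significantly positive, P < 0.05")
    lines.append("     ** = significantly positive, P < 0.01")
    lines.append("")
    lines.append("Probable sequences at interior nodes:")
    lines.append("")
    lines.append("  node       Reconstructed sequence (caps if > 0.95)")
    lines.append("")
    per_node = [(endpoint(n.node_id), _blocks(n.sequence)) for n in tree.preorder()]
    n_blocks = len(per_node[0][1]) if per_node else 0
    for bi in range(n_blocks):
        for name, blocks in per_node:
            lines.append(f"  {name:<10}  {blocks[bi]}")
        lines.append("")
    return "\n".join(lines) + "\n"


def _branch_row(a: str, b: str, length, tree, pid, cid) -> str:
    if length is None:
        p, c = tree.nodes[pid].sequence, tree.nodes[cid].sequence
        ham = sum(1 for x, y in zip(p, c) if x != y)
        length = max(ham / max(len(p), 1), 1e-5)
    hi = length * 2.2 + 1e-5
    return f"   {a:<12}{b:<15}{length:9.5f}     (     zero,  {hi:10.5f}) **"


def emit_immcantation(
    tree: LineageTree, clone_id: str = "1"
) -> dict[str, str]:
    """Emit the Immcantation triple plus the region FASTA for one lineage.

    Returns ``{"airr": ..., "tab": ..., "asr_fasta": ..., "region_fasta": ...}``.
    The newick places the germline as a leaf (label ``<clone>_GERM``) beside
    the UCA's child subtree, matching how IgPhyML roots clone trees on the
    reconstructed germline.
    """
    root = tree.root
    uca_seq = root.sequence
    L = tree.alignment_length

    internal_label: dict[str, str] = {}
    for node in tree.preorder():
        if node.kind == BP:
            internal_label[node.node_id] = f"{clone_id}_I{len(internal_label) + 1}"

    def bl(pid: str, cid: str) -> str:
        length = tree.edge_lengths.get((pid, cid))
        if length is None:
            p, c = tree.nodes[pid].sequence, tree.nodes[cid].sequence
            length = sum(1 for x, y in zip(p, c) if x != y) / max(L, 1)
        return f"{length:.6f}"

    def sub(nid: str, pid: str) -> str:
        node = tree.nodes[nid]
        if not tree.children[nid]:
            return f"{node.label}:{bl(pid, nid)}"
        inner = ",".join(sub(c, nid) for c in tree.children[nid])
        return f"({inner}){internal_label.get(nid, node.label)}:{bl(pid, nid)}"

    germ_label = f"{clone_id}_GERM"
    kids = tree.children[root.node_id]
    if len(kids) == 1 and tree.children[kids[0]]:
        # usual shape: root the newick at the UCA's single BP child and hang
        # the germline beside that node's children
        top = kids[0]
        inner = ",".join(sub(c, top) for c in tree.children[top])
        newick = (
            f"({inner},{germ_label}:{bl(root.node_id, top)})"
            f"{internal_label[top]};"
        )
    else:
        # degenerate lineage (single observed leaf, or multifurcating root):
        # introduce one pass-through internal node carrying the UCA sequence
        extra = f"{clone_id}_I{len(internal_label) + 1}"
        inner = ",".join(sub(c, root.node_id) for c in kids)
        newick = f"({inner},{germ_label}:0.000001){extra};"
        internal_label["__extra__"] = extra

    asr_lines = []
    for nid, lbl in internal_label.items():
        seq = uca_seq if nid == "__extra__" else tree.nodes[nid].sequence
        asr_lines.append(f">{lbl}")
        asr_lines.append(seq)

    airr_rows = [
        "\t".join([
            "sequence_id", "clone_id", "sequence_alignment",
            "germline_alignment", "v_call", "j_call",
        ])
    ]
    true_uca = "".join(
        ch if ch in "ACGTN-." else "N" for ch in uca_seq
    )
    for node in tree.preorder():
        if node.kind != OBSERVED:
            continue
        airr_rows.append("\t".join([
            node.label, clone_id, node.sequence, true_uca,
            "IGHV1-18*01", "IGHJ4*02",
        ]))

    tab = "CLONE\tTREE\n" + f"{clone_id}\t{newick}\n"

    region = ""
    if tree.region_map is not None:
        ends = " ".join(str(e) for e in tree.region_map.ends)
        region = f">{clone_id}_UCA {ends}\n{tree.region_map.uca_gapped}\n"

    return {
        "airr": "\n".join(airr_rows) + "\n",
        "tab": tab,
        "asr_fasta": "\n".join(asr_lines) + "\n",
        "region_fasta": region,
    }


def emit_region_fasta(tree: LineageTree, name: str = "UCA_VDJ") -> str:
    """Region FASTA (IMGT-gapped UCA + region ends in the header)."""
    rm = tree.region_map
    if rm is None:
        raise ValueError("tree has no region map")
    ends = " ".join(str(e) for e in rm.ends)
    return f">{name} {ends}\n{rm.uca_gapped}\n"


def leafset_index(tree: LineageTree) -> dict[frozenset, tuple[str, str]]:
    """Map each edge to the frozenset of observed member labels below it.

    Stable across parsing/processing round trips, so ground-truth per-edge
    event lists can be matched to pipeline output without relying on BP
    label equality.
    """
    below: dict[str, frozenset] = {}
    for node in tree.postorder():
        acc: set[str] = set()
        if node.kind == OBSERVED:
            acc.update(m for m in node.members if m not in tree.bp_tokens)
        for cid in tree.children[node.node_id]:
            acc |= below[cid]
        below[node.node_id] = frozenset(acc)
    return {below[cid]: (pid, cid) for pid, cid in tree.edges()}
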