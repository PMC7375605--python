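"""Immcantation-side input handling: AIRR TSV, IgPhyML tab file, ASR FASTA.

The Immcantation route supplies three files: a Change-O table in AIRR
Rearrangement format (one row per sequence, with IMGT-gapped sequence and
germline alignments), the IgPhyML tab file holding one newick tree per
clone, and the FASTA of ancestral sequences reconstructed by IgPhyML's
``--asr`` option for the internal nodes of each tree.  One clone is selected
and assembled into a :class:`~iglineage.model.LineageTree` rooted at the
germline (UCA) node.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from typing import Optional

import dendropy
import pandas as pd
from Bio import SeqIO

from .errors import AssemblyError, ParseError
from .model import (
    BP, OBSERVED, UCA, LineageNode, LineageTree, IUPAC_AMBIGUITY,
    normalize_seq, resolve_ambiguities, validate_tree,
)

logger = logging.getLogger(__name__)

GERMLINE_ALIGNMENT_COLUMNS = ("germline_alignment", "germline_alignment_d_mask")
DEFAULT_GERMLINE_PATTERN = "GERM"


@dataclass
class CloneRecord:
    """One AIRR rearrangement row."""

    sequence_id: str
    clone_id: str
    sequence_alignment: str
    germline_alignment: str
    v_call: str = ""
    j_call: str = ""


@dataclass
class CloneTreeBundle:
    """Everything needed to assemble one clone's lineage tree."""

    clone_id: str
    newick: str
    asr_sequences: dict[str, str] = field(default_factory=dict)
    records: list[CloneRecord] = field(default_factory=list)


def parse_airr(text: str) -> list[CloneRecord]:
    """Parse an AIRR Rearrangement TSV into :class:`CloneRecord` rows.

    Requires ``sequence_id``, ``clone_id``, ``sequence_alignment`` and a
    germline alignment column (``germline_alignment`` or its ``_d_mask``
    alias).  Rows with an empty required field are skipped (count logged).
    """
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str, keep_default_na=False)
    header = list(df.columns)
    germ_col = next((c for c in GERMLINE_ALIGNMENT_COLUMNS if c in header), None)
    required = ["sequence_id", "clone_id", "sequence_alignment"]
    missing = [c for c in required if c not in header]
    if germ_col is None:
        missing.append("germline_alignment")
    if missing:
        raise ParseError(
            f"AIRR file is missing required column(s) {', '.join(missing)}; "
            f"header found: {', '.join(header)}"
        )
    records: list[CloneRecord] = []
    skipped = 0
    for _, row in df.iterrows():
        values = [row["sequence_id"], row["clone_id"], row["sequence_alignment"], row[germ_col]]
        if any(not v for v in values):
            skipped += 1
            continue
        records.append(CloneRecord(
            sequence_id=row["sequence_id"],
            clone_id=row["clone_id"],
            sequence_alignment=normalize_seq(row["sequence_alignment"]),
            germline_alignment=normalize_seq(row[germ_col]),
            v_call=row.get("v_call", ""),
            j_call=row.get("j_call", ""),
        ))
    if skipped:
        logger.warning("skipped %d AIRR rows with empty required fields", skipped)
    if not records:
        logger.warning("AIRR file contains no usable data rows")
    return records


def _check_newick(newick: str, clone_id: str) -> None:
    depth = 0
    for ch in newick:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ParseError(f"malformed newick for clone {clone_id!r}: unbalanced ')'")
    if depth != 0 or not newick.rstrip().endswith(";"):
        raise ParseError(
            f"malformed newick for clone {clone_id!r}: unbalanced parentheses "
            "or missing ';'"
        )


def parse_igphyml_tab(
    text: str, clone_column: str = "CLONE", tree_column: str = "TREE"
) -> dict[str, str]:
    """Parse the IgPhyML tab file into a clone_id -> newick map.

    Column names default to IgPhyML's upper-case ``CLONE``/``TREE``; a
    case-insensitive match is accepted.  Newick strings are syntax-checked.
    """
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str, keep_default_na=False)
    lower = {c.lower(): c for c in df.columns}
    ccol = lower.get(clone_column.lower())
    tcol = lower.get(tree_column.lower())
    if ccol is None or tcol is None:
        raise ParseError(
            f"IgPhyML tab file must contain columns {clone_column!r} and "
            f"{tree_column!r}; header found: {', '.join(df.columns)}"
        )
    out: dict[str, str] = {}
    for _, row in df.iterrows():
        clone, newick = row[ccol], row[tcol]
        if not clone or not newick:
            continue
        if clone in out:
            raise ParseError(f"duplicate clone id {clone!r} in IgPhyML tab file")
        _check_newick(newick, clone)
        out[clone] = newick
    return out


def list_clones(
    records: list[CloneRecord], igphyml_map: dict[str, str]
) -> list[tuple[str, int]]:
    """Clones present in both inputs, sorted by descending sequence count, then id."""
    counts: dict[str, int] = {}
    for rec in records:
        counts[rec.clone_id] = counts.get(rec.clone_id, 0) + 1
    common = [(cid, n) for cid, n in counts.items() if cid in igphyml_map]
    if not common:
        logger.warning("no clone id appears in both the AIRR file and the IgPhyML tab file")
    return sorted(common, key=lambda kv: (-kv[1], kv[0]))


def parse_asr_fasta(text: str) -> dict[str, str]:
    """Read the IgPhyML ``--asr`` FASTA into a label -> sequence map."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        out[rec.id] = normalize_seq(str(rec.seq))
    return out


def build_clone_bundle(
    records: list[CloneRecord],
    igphyml_map: dict[str, str],
    asr_fasta_text: str,
    clone_id: str,
) -> CloneTreeBundle:
    """Select one clone's records, newick and ancestral sequences."""
    if clone_id not in igphyml_map:
        available = ", ".join(f"{c} ({n} seqs)" for c, n in list_clones(records, igphyml_map))
        raise AssemblyError(
            f"clone {clone_id!r} not found in the IgPhyML tab file; "
            f"available clones: {available or 'none'}"
        )
    clone_records = [r for r in records if r.clone_id == clone_id]
    if not clone_records:
        raise AssemblyError(f"no AIRR records for clone {clone_id!r}")
    return CloneTreeBundle(
        clone_id=clone_id,
        newick=igphyml_map[clone_id],
        asr_sequences=parse_asr_fasta(asr_fasta_text),
        records=clone_records,
    )


def assemble_clone_tree(
    bundle: CloneTreeBundle, germline_pattern: str = DEFAULT_GERMLINE_PATTERN
) -> LineageTree:
    """Assemble the selected clone into a germline-rooted lineage tree.

    The germline node is found by a case-insensitive label pattern (default:
    any label containing "GERM"), falling back to the first leaf child of the
    newick root.  All branches are oriented away from it; labeled internal
    nodes become branch points carrying their ``--asr`` sequences, leaves
    carry the AIRR ``sequence_alignment``, and the germline carries the AIRR
    ``germline_alignment``.  IgPhyML normally emits ambiguity-free ancestral
    sequences; resolution is run only if ambiguity codes are detected.
    """
    dtree = dendropy.Tree.get(
        data=bundle.newick, schema="newick", preserve_underscores=True,
        suppress_internal_node_taxa=False,
    )

    def label_of(nd) -> Optional[str]:
        if nd.taxon is not None and nd.taxon.label:
            return nd.taxon.label
        return nd.label or None

    pat = re.compile(germline_pattern, re.IGNORECASE)
    germ_node = None
    for nd in dtree.preorder_node_iter():
        lbl = label_of(nd)
        if lbl and pat.search(lbl):
            germ_node = nd
            break
    if germ_node is None:
        fallback = next(
            (c for c in dtree.seed_node.child_nodes() if c.is_leaf()), None
        )
        if fallback is None:
            raise AssemblyError(
                f"no germline node found (pattern {germline_pattern!r}) and the "
                "newick root has no leaf child to fall back on; IgPhyML roots "
                "its trees on the clonal germline — check the tree labels"
            )
        logger.warning(
            "no label matches germline pattern %r; falling back to outgroup-"
            "position leaf %r", germline_pattern, label_of(fallback),
        )
        germ_node = fallback

    by_id = {r.sequence_id: r for r in bundle.records}
    germ_label = label_of(germ_node) or "GERMLINE"
    germ_seqs = {r.germline_alignment for r in bundle.records}
    if len(germ_seqs) > 1:
        logger.warning(
            "clone %s: records disagree on germline_alignment; using the first",
            bundle.clone_id,
        )
    germline_seq = bundle.records[0].germline_alignment
    aln_len = len(germline_seq)

    # undirected adjacency over dendropy nodes, children in newick order
    adjacency: dict[int, list] = {}
    nodes_by_key: dict[int, object] = {}

    def key(nd) -> int:
        k = id(nd)
        nodes_by_key[k] = nd
        return k

    for nd in dtree.preorder_node_iter():
        adjacency.setdefault(key(nd), [])
        for ch in nd.child_nodes():
            adjacency[key(nd)].append(key(ch))
            adjacency.setdefault(key(ch), []).append(key(nd))

    tree = LineageTree(
        alignment_length=aln_len,
        provenance={"source": "IGPHYML", "clone_id": bundle.clone_id},
    )
    root = LineageNode(
        node_id="root", label="UCA", kind=UCA, sequence=germline_seq,
        source_label=germ_label,
    )
    tree.add_node(root)

    counter = 0
    seen = {key(germ_node)}
    queue: list[tuple[int, str]] = [(k, "root") for k in adjacency[key(germ_node)]]
    while queue:
        k, parent_id = queue.pop(0)
        if k in seen:
            continue
        seen.add(k)
        nd = nodes_by_key[k]
        lbl = label_of(nd)
        neighbors = [n for n in adjacency[k] if n not in seen]
        is_leaf_here = not neighbors
        counter += 1
        if is_leaf_here:
            if lbl is None:
                raise AssemblyError("newick contains an unlabeled leaf")
            rec = by_id.get(lbl)
            if rec is None:
                raise AssemblyError(
                    f"leaf {lbl!r} in the newick tree has no matching AIRR "
                    f"record for clone {bundle.clone_id!r}"
                )
            node = LineageNode(
                node_id=f"leaf{counter}", label=lbl, kind=OBSERVED,
                sequence=rec.sequence_alignment, source_label=lbl,
            )
        else:
            if lbl is None:
                raise AssemblyError(
                    "newick contains an unlabeled internal node; internal nodes "
                    "must be labeled and carry sequences from IgPhyML's --asr output"
                )
            seq = bundle.asr_sequences.get(lbl)
            if seq is None:
                raise AssemblyError(
                    f"internal node {lbl!r} has no sequence in the --asr FASTA"
                )
            node = LineageNode(
                node_id=f"bp{counter}", label=f"BP@{counter}", kind=BP,
                sequence=seq, source_label=lbl,
            )
        if len(node.sequence) != aln_len:
            raise AssemblyError(
                f"sequence length mismatch for {lbl!r}: {len(node.sequence)} "
                f"vs alignment length {aln_len}"
            )
        tree.add_node(node, parent_id=parent_id)
        el = nd.edge.length
        if el is not None:
            tree.edge_lengths[(parent_id, node.node_id)] = float(el)
        for n in neighbors:
            queue.append((n, node.node_id))

    n_tree_leaves = sum(1 for n in tree.preorder() if n.kind == OBSERVED)
    unplaced = [r.sequence_id for r in bundle.records if r.sequence_id not in
                {n.label for n in tree.preorder()}]
    if unplaced:
        logger.warning(
            "clone %s: %d AIRR record(s) absent from the newick tree: %s",
            bundle.clone_id, len(unplaced), ", ".join(unplaced),
        )
    assert n_tree_leaves == len(bundle.records) - len(unplaced)

    problems = validate_tree(tree)
    if problems:
        raise AssemblyError("assembled tree is invalid: " + "; ".join(problems))

    ambiguous = any(
        set(n.sequence) & set(IUPAC_AMBIGUITY)
        for n in tree.preorder() if n.kind == BP
    )
    if ambiguous:
        logger.info("ambiguity codes detected in ancestral sequences; resolving")
        tree = resolve_ambiguities(tree)
    return tree
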