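"""Core lineage-tree data model and post-processing.

A B-cell clonal lineage is represented as a rooted tree whose root carries the
unmutated common ancestor (UCA) sequence, whose leaves carry the observed
immunoglobulin sequences, and whose internal nodes are inferred branch points
(BPs) carrying reconstructed intermediate sequences.  This module owns the
three normalization steps applied after tree ingestion:

1. :func:`resolve_ambiguities` — replace IUPAC ambiguity codes in BP sequences
   by the base most frequent among the observed descendants of that BP;
2. :func:`collapse_redundant_bps` — merge a BP into a child with an identical
   sequence (a "theoretical" intermediate that coincides with a real Ig);
3. :func:`cluster_identical_observed` — merge sibling observed leaves whose
   sequences are identical into a single multi-member node.

All three return a processed copy; the input tree is never mutated.
"""

from __future__ import annotations

import copy as _copy
import logging
from dataclasses import dataclass, field
from typing import Iterator, Optional

from .errors import AssemblyError, ParseError

logger = logging.getLogger(__name__)

GAP_CHARS = frozenset("-.")

#: IUPAC ambiguity codes (excluding N) and the concrete bases each denotes.
IUPAC_AMBIGUITY: dict[str, str] = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT",
    "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
}

BASES = "ACGT"
VALID_SEQ_CHARS = frozenset("ACGTN-.") | frozenset(IUPAC_AMBIGUITY)

UCA = "UCA"
OBSERVED = "OBSERVED"
BP = "BP"
NODE_KINDS = (UCA, OBSERVED, BP)


def normalize_seq(seq: str) -> str:
    """Uppercase and map '.' gaps to '-' (both are alignment padding)."""
    return seq.upper().replace(".", "-")


def check_alphabet(seq: str, where: str) -> None:
    """Reject characters outside the nucleotide/ambiguity/gap alphabet."""
    for i, ch in enumerate(normalize_seq(seq), start=1):
        if ch not in VALID_SEQ_CHARS:
            raise ParseError(
                f"malformed base character {ch!r} at position {i} in {where}"
            )


@dataclass
class LineageNode:
    """One tree vertex: an aligned sequence plus the labels merged into it.

    ``members`` always starts with the node's own display label; collapsing
    and clustering append the labels of absorbed nodes.  ``ec50`` is a
    user-entered neutralization titer with free-text units.
    """

    node_id: str
    label: str
    kind: str
    sequence: str
    members: list[str] = field(default_factory=list)
    ec50: Optional[float] = None
    ec50_units: str = ""
    comment: str = ""
    source_label: Optional[str] = None
    low_confidence: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {self.kind!r}")
        if not self.members:
            self.members = [self.label]


class LineageTree:
    """Rooted lineage tree with ordered children and annotated edges.

    Children are kept in insertion (input-file) order; this order is the
    deterministic tie-break for collapsing and for branch-point numbering.
    """

    def __init__(self, alignment_length: int, provenance: Optional[dict] = None):
        if alignment_length <= 0:
            raise ValueError("alignment_length must be positive")
        self.alignment_length = int(alignment_length)
        self.nodes: dict[str, LineageNode] = {}
        self.children: dict[str, list[str]] = {}
        self.parent: dict[str, str] = {}
        self.root_id: Optional[str] = None
        self.region_map = None  # annotate.RegionMap, optional
        self.provenance: dict = dict(provenance or {})
        self.edge_annotations: dict[tuple[str, str], object] = {}
        self.edge_lengths: dict[tuple[str, str], float] = {}
        #: labels of branch-point origin (provisional or final "BP<k>" names);
        #: used to tell Ig member labels from BP member labels after merging.
        self.bp_tokens: set[str] = set()

    # -- construction -------------------------------------------------------

    def add_node(self, node: LineageNode, parent_id: Optional[str] = None) -> LineageNode:
        if node.node_id in self.nodes:
            raise ValueError(f"duplicate node id {node.node_id!r}")
        self.nodes[node.node_id] = node
        self.children[node.node_id] = []
        if node.kind == BP:
            self.bp_tokens.add(node.label)
        if parent_id is None:
            if self.root_id is not None:
                raise ValueError("tree already has a root")
            self.root_id = node.node_id
        else:
            self.children[parent_id].append(node.node_id)
            self.parent[node.node_id] = parent_id
        return node

    # -- traversal ----------------------------------------------------------

    @property
    def root(self) -> LineageNode:
        if self.root_id is None:
            raise AssemblyError("tree has no root")
        return self.nodes[self.root_id]

    def preorder(self) -> Iterator[LineageNode]:
        if self.root_id is None:
            return
        stack = [self.root_id]
        while stack:
            nid = stack.pop()
            yield self.nodes[nid]
            stack.extend(reversed(self.children[nid]))

    def postorder(self) -> Iterator[LineageNode]:
        out = list(self.preorder())
        yield from reversed(out)

    def edges(self) -> Iterator[tuple[str, str]]:
        """Parent->child node-id pairs in pre-order."""
        for node in self.preorder():
            for cid in self.children[node.node_id]:
                yield (node.node_id, cid)

    def leaves(self) -> list[LineageNode]:
        return [n for n in self.preorder() if not self.children[n.node_id]]

    def observed_below(self, node_id: str) -> list[LineageNode]:
        """All OBSERVED nodes strictly below ``node_id``, pre-order."""
        out = []
        stack = list(reversed(self.children[node_id]))
        while stack:
            nid = stack.pop()
            node = self.nodes[nid]
            if node.kind == OBSERVED:
                out.append(node)
            stack.extend(reversed(self.children[nid]))
        return out

    def copy(self) -> "LineageTree":
        return _copy.deepcopy(self)

    # -- equality (used by serialization round-trip checks) -----------------

    def equals(self, other: "LineageTree") -> bool:
        if not isinstance(other, LineageTree):
            return False
        return (
            self.alignment_length == other.alignment_length
            and self.root_id == other.root_id
            and self.nodes == other.nodes
            and self.children == other.children
            and self.parent == other.parent
            and self.provenance == other.provenance
            and self.edge_annotations == other.edge_annotations
            and self.edge_lengths == other.edge_lengths
            and self.region_map == other.region_map
            and self.bp_tokens == other.bp_tokens
        )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_tree(tree: LineageTree) -> list[str]:
    """Return a list of invariant violations (empty when the tree is valid)."""
    problems: list[str] = []
    if not tree.nodes:
        return ["tree has no nodes"]

    parentless = [nid for nid in tree.nodes if nid not in tree.parent]
    if len(parentless) > 1:
        problems.append(
            "multiple parentless nodes: " + ", ".join(sorted(parentless))
        )
    elif not parentless:
        problems.append("no parentless node (cycle?)")
    if tree.root_id is None:
        problems.append("root not set")
    elif tree.root_id not in tree.nodes:
        problems.append(f"root id {tree.root_id!r} not among nodes")
    elif parentless and tree.root_id not in parentless:
        problems.append(f"declared root {tree.root_id!r} has a parent")

    ucas = [n for n in tree.nodes.values() if n.kind == UCA]
    if len(ucas) != 1:
        problems.append(f"expected exactly one UCA node, found {len(ucas)}")
    elif tree.root_id is not None and ucas[0].node_id != tree.root_id:
        problems.append(f"UCA node {ucas[0].node_id!r} is not the root")

    # connectivity
    if tree.root_id in tree.nodes:
        seen = set()
        stack = [tree.root_id]
        while stack:
            nid = stack.pop()
            if nid in seen:
                problems.append(f"cycle through node {nid!r}")
                break
            seen.add(nid)
            stack.extend(tree.children.get(nid, []))
        unreachable = set(tree.nodes) - seen
        if unreachable:
            problems.append(
                "unreachable nodes: " + ", ".join(sorted(unreachable))
            )

    all_members: list[str] = []
    for node in tree.nodes.values():
        if len(node.sequence) != tree.alignment_length:
            problems.append(
                f"node {node.label!r}: sequence length {len(node.sequence)} "
                f"!= alignment length {tree.alignment_length}"
            )
        if not node.members:
            problems.append(f"node {node.label!r}: empty members list")
        elif node.members[0] != node.label:
            problems.append(
                f"node {node.label!r}: members[0] is {node.members[0]!r}"
            )
        all_members.extend(node.members)
    if len(all_members) != len(set(all_members)):
        dupes = sorted({m for m in all_members if all_members.count(m) > 1})
        problems.append("duplicate member labels: " + ", ".join(dupes))

    for pid, cid in tree.edges():
        if pid not in tree.nodes or cid not in tree.nodes:
            problems.append(f"edge ({pid!r}, {cid!r}) references unknown node")
        elif tree.parent.get(cid) != pid:
            problems.append(f"edge ({pid!r}, {cid!r}) inconsistent with parent map")
    return problems


# ---------------------------------------------------------------------------
# ambiguity resolution
# ---------------------------------------------------------------------------

def resolve_ambiguities(tree: LineageTree) -> LineageTree:
    """Replace IUPAC ambiguity codes in BP sequences by a majority vote.

    For each BP node and each position holding an ambiguity code, the code is
    replaced by the base — among those the code denotes — most frequent at
    that position across the sequences of all OBSERVED descendants of the BP.
    Ties break in the fixed order A < C < G < T.  If no descendant carries an
    allowed base the position becomes ``N`` and a warning is logged.  Observed
    and UCA sequences are never modified.  Idempotent.
    """
    out = tree.copy()
    for node in out.preorder():
        seq = normalize_seq(node.sequence)
        if node.kind != BP:
            node.sequence = seq
            for i, ch in enumerate(seq, start=1):
                if ch not in VALID_SEQ_CHARS:
                    raise ParseError(
                        f"malformed base character {ch!r} at position {i} "
                        f"in node {node.label!r}"
                    )
            continue
        descendants = [normalize_seq(d.sequence) for d in out.observed_below(node.node_id)]
        chars = list(seq)
        for i, ch in enumerate(chars):
            if ch in "ACGTN-":
                continue
            if ch not in IUPAC_AMBIGUITY:
                raise ParseError(
                    f"malformed base character {ch!r} at position {i + 1} "
                    f"in node {node.label!r}"
                )
            allowed = IUPAC_AMBIGUITY[ch]
            counts = {b: 0 for b in allowed}
            for d in descendants:
                b = d[i]
                if b in counts:
                    counts[b] += 1
            best = max(counts.values(), default=0)
            if best == 0:
                logger.warning(
                    "node %s position %d: ambiguity code %s has no supporting "
                    "observed descendant base; writing N",
                    node.label, i + 1, ch,
                )
                chars[i] = "N"
            else:
                # fixed tie-break order A < C < G < T
                chars[i] = next(b for b in BASES if counts.get(b, 0) == best)
        node.sequence = "".join(chars)
    return out


# ---------------------------------------------------------------------------
# collapsing and clustering
# ---------------------------------------------------------------------------

def _remove_edge_metadata(tree: LineageTree, pid: str, cid: str) -> None:
    tree.edge_annotations.pop((pid, cid), None)
    tree.edge_lengths.pop((pid, cid), None)


def _rekey_child_edges(tree: LineageTree, old_parent: str, new_parent: str) -> None:
    for cid in tree.children[new_parent]:
        if (old_parent, cid) in tree.edge_lengths:
            tree.edge_lengths[(new_parent, cid)] = tree.edge_lengths.pop((old_parent, cid))
        if (old_parent, cid) in tree.edge_annotations:
            tree.edge_annotations[(new_parent, cid)] = tree.edge_annotations.pop((old_parent, cid))


def collapse_redundant_bps(tree: LineageTree) -> LineageTree:
    """Merge every BP whose sequence equals one of its children into that child.

    Comparison is case-insensitive and gap-character insensitive ('.' == '-');
    'N' matches only 'N'.  When several children tie, the earliest in child
    order wins.  The merged node takes the child's kind, label and sequence;
    the BP's label is appended to the child's member list and the BP's other
    children are re-parented to the merged node.  Applied bottom-up to a
    fixed point.  Idempotent; preserves the observed-sequence multiset and
    the set of member labels.
    """
    out = tree.copy()
    changed = True
    while changed:
        changed = False
        for node in list(out.postorder()):
            if node.node_id not in out.nodes or node.kind != BP:
                continue
            norm = normalize_seq(node.sequence)
            target = None
            for cid in out.children[node.node_id]:
                if normalize_seq(out.nodes[cid].sequence) == norm:
                    target = cid
                    break
            if target is None:
                continue
            child = out.nodes[target]
            # absorb the child into the BP's slot in the topology
            kids = out.children[node.node_id]
            idx = kids.index(target)
            grandchildren = out.children[target]
            new_children = kids[:idx] + grandchildren + kids[idx + 1:]
            _remove_edge_metadata(out, node.node_id, target)
            for gid in grandchildren:
                out.parent[gid] = node.node_id
            _rekey_child_edges(out, target, node.node_id)
            out.children[node.node_id] = new_children
            del out.children[target]
            out.parent.pop(target, None)
            del out.nodes[target]

            node.members = child.members + node.members
            node.label = child.label
            node.kind = child.kind
            node.sequence = child.sequence
            node.source_label = child.source_label or node.source_label
            if child.ec50 is not None:
                node.ec50, node.ec50_units = child.ec50, child.ec50_units
            if child.comment:
                node.comment = (node.comment + " " + child.comment).strip()
            changed = True
    return out


def cluster_identical_observed(tree: LineageTree) -> LineageTree:
    """Merge sibling OBSERVED leaves with identical sequences into one node.

    The earliest sibling (child order) is kept; the member labels of the
    others are appended.  The union of member labels over the tree is
    invariant.  Idempotent.
    """
    out = tree.copy()
    for node in list(out.preorder()):
        if node.node_id not in out.nodes:
            continue
        groups: dict[str, str] = {}  # normalized sequence -> keeper node id
        for cid in list(out.children[node.node_id]):
            child = out.nodes[cid]
            if child.kind != OBSERVED or out.children[cid]:
                continue
            key = normalize_seq(child.sequence)
            keeper_id = groups.get(key)
            if keeper_id is None:
                groups[key] = cid
                continue
            keeper = out.nodes[keeper_id]
            keeper.members = keeper.members + child.members
            if keeper.ec50 is None and child.ec50 is not None:
                keeper.ec50, keeper.ec50_units = child.ec50, child.ec50_units
            if child.comment:
                keeper.comment = (keeper.comment + " " + child.comment).strip()
            out.children[node.node_id].remove(cid)
            _remove_edge_metadata(out, node.node_id, cid)
            out.parent.pop(cid, None)
            del out.children[cid]
            del out.nodes[cid]
    return out


def renumber_branch_points(tree: LineageTree) -> LineageTree:
    """Assign final "BP1", "BP2", ... labels in a deterministic pre-order walk.

    Covers both live BP nodes and BP labels surviving only inside member
    lists of merged nodes, so re-runs are bit-stable.  Mutates in place and
    returns the tree.
    """
    mapping: dict[str, str] = {}
    k = 1
    for node in tree.preorder():
        for m in node.members:
            if m in tree.bp_tokens and m not in mapping:
                mapping[m] = f"BP{k}"
                k += 1
    for node in tree.preorder():
        node.members = [mapping.get(m, m) for m in node.members]
        if node.label in mapping:
            node.label = mapping[node.label]
    tree.bp_tokens = {mapping.get(t, t) for t in tree.bp_tokens if t in mapping}
    return tree


def process_tree(tree: LineageTree) -> LineageTree:
    """Full post-processing: resolve ambiguities, collapse, cluster, renumber."""
    out = resolve_ambiguities(tree)
    out = collapse_redundant_bps(out)
    out = cluster_identical_observed(out)
    return renumber_branch_points(out)
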