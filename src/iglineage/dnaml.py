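"""Parser for PHYLIP dnaml "outfile" text output.

The parser targets the PHYLIP 3.69-family dialect: an ASCII tree sketch
(skipped — only the branch table is trusted), a ``Between / And / Length``
branch table whose endpoints are interior node numbers or tip names, and,
when dnaml was run with hypothetical-sequence reconstruction (menu option 5),
a ``Probable sequences at interior nodes`` section of interleaved 60-column
blocks.  Lowercase bases (dnaml's marker for reconstruction confidence
<= 0.95) are normalized to uppercase with the positions recorded.

Rooting follows the stated convention: the outgroup taxon is the unmutated
common ancestor (UCA), by default the first taxon of the alignment; all
branches are oriented away from it.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Optional, Union

from .errors import AssemblyError, ParseError
from .model import (
    BP, OBSERVED, UCA, LineageNode, LineageTree, check_alphabet, validate_tree,
)

logger = logging.getLogger(__name__)

Endpoint = Union[int, str]

_BRANCH_HEADER_RE = re.compile(r"Between\s+And\s+L?ength", re.IGNORECASE)
_BRANCH_ROW_RE = re.compile(
    r"^\s*(\S+)\s+(\S+)\s+(zero|infinity|-?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?)"
)
_SEQ_SECTION_RE = re.compile(r"Probable sequences at interior nodes", re.IGNORECASE)
_LNL_RE = re.compile(r"Ln\s+Likelihood\s*=\s*(-?\d+(?:\.\d+)?)", re.IGNORECASE)
_SEQ_CHARS_RE = re.compile(r"^[A-Za-z\-\.\s]+$")


@dataclass
class DnamlDocument:
    """Raw content of a dnaml outfile before tree orientation."""

    taxon_names: list[str] = field(default_factory=list)
    branch_records: list[tuple[Endpoint, Endpoint, float]] = field(default_factory=list)
    interior_sequences: dict[int, str] = field(default_factory=dict)
    tip_sequences: dict[str, str] = field(default_factory=dict)
    log_likelihood: Optional[float] = None
    #: per node key (int or name): 1-based positions printed lowercase
    low_confidence: dict[Endpoint, tuple[int, ...]] = field(default_factory=dict)


def _as_endpoint(token: str) -> Endpoint:
    return int(token) if token.isdigit() else token


def parse_dnaml_outfile(text: str) -> DnamlDocument:
    """Parse dnaml outfile content into a :class:`DnamlDocument`.

    Raises :class:`ParseError` if the file is empty, the branch table is
    unreadable, the reconstructed-sequence section is missing (dnaml must be
    rerun with option 5), or assembled sequences disagree in length.
    """
    if not text.strip():
        raise ParseError("empty dnaml outfile")
    lines = text.splitlines()

    doc = DnamlDocument()
    m = _LNL_RE.search(text)
    if m:
        doc.log_likelihood = float(m.group(1))

    # --- branch table ------------------------------------------------------
    header_idx = next(
        (i for i, ln in enumerate(lines) if _BRANCH_HEADER_RE.search(ln)), None
    )
    if header_idx is None:
        raise ParseError("could not locate the 'Between / And / Length' branch table")
    i = header_idx + 1
    seen_row = False
    while i < len(lines):
        line = lines[i]
        if set(line.strip()) <= {"-", " "} and not seen_row:
            i += 1  # the ---- divider under the header
            continue
        mrow = _BRANCH_ROW_RE.match(line)
        if mrow:
            a, b, raw = mrow.group(1), mrow.group(2), mrow.group(3)
            length = 0.0 if raw == "zero" else (float("inf") if raw == "infinity" else float(raw))
            doc.branch_records.append((_as_endpoint(a), _as_endpoint(b), length))
            seen_row = True
            i += 1
            continue
        if seen_row:
            break
        if not line.strip():
            i += 1
            continue
        raise ParseError(f"unreadable branch table at line {i + 1}: {line!r}")
    if not doc.branch_records:
        raise ParseError(f"branch table at line {header_idx + 1} contains no rows")

    # --- reconstructed sequences ------------------------------------------
    sec_idx = next((i for i, ln in enumerate(lines) if _SEQ_SECTION_RE.search(ln)), None)
    if sec_idx is None:
        raise ParseError(
            "no reconstructed-sequence section found: rerun dnaml with menu "
            "option 5 ('reconstruct hypothetical sequences')"
        )
    raw_chunks: dict[Endpoint, list[str]] = {}
    order: list[Endpoint] = []
    for line in lines[sec_idx + 1:]:
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.lower().startswith("node") and "reconstructed" in stripped.lower():
            continue  # column header line
        parts = stripped.split(None, 1)
        if len(parts) != 2 or not _SEQ_CHARS_RE.match(parts[1]):
            break  # end of section
        key = _as_endpoint(parts[0])
        chunk = parts[1].replace(" ", "")
        if key not in raw_chunks:
            raw_chunks[key] = []
            order.append(key)
        raw_chunks[key].append(chunk)

    if not raw_chunks:
        raise ParseError(
            "reconstructed-sequence section is empty: rerun dnaml with menu option 5"
        )
    lengths = set()
    for key in order:
        seq = "".join(raw_chunks[key])
        low = tuple(i + 1 for i, ch in enumerate(seq) if ch.islower())
        if low:
            doc.low_confidence[key] = low
        seq = seq.upper().replace(".", "-")
        check_alphabet(seq, f"dnaml node {key}")
        lengths.add(len(seq))
        if isinstance(key, int):
            doc.interior_sequences[key] = seq
        else:
            doc.tip_sequences[key] = seq
    if len(lengths) != 1:
        detail = ", ".join(
            f"{key}:{len(''.join(raw_chunks[key]))}" for key in order
        )
        raise ParseError(f"sequence length mismatch across blocks ({detail})")

    # taxon order: tips in order of first appearance in the branch table
    for a, b, _ in doc.branch_records:
        for ep in (a, b):
            if isinstance(ep, str) and ep not in doc.taxon_names:
                doc.taxon_names.append(ep)

    # every branch endpoint must have a sequence
    for a, b, _ in doc.branch_records:
        for ep in (a, b):
            known = (
                doc.interior_sequences if isinstance(ep, int) else doc.tip_sequences
            )
            if ep not in known:
                raise ParseError(f"branch endpoint {ep!r} has no sequence")
    return doc


def dnaml_to_lineage(doc: DnamlDocument, uca_name: Optional[str] = None) -> LineageTree:
    """Orient the dnaml branch set away from the UCA tip into a rooted tree.

    ``uca_name`` defaults to the first taxon (the convention of listing the
    UCA first in the PHYLIP input and rooting on it as outgroup).  The UCA
    tip becomes the root, interior numbers become provisional branch points,
    remaining tips become observed nodes.
    """
    if not doc.taxon_names:
        raise AssemblyError("document has no taxa")
    if uca_name is None:
        uca_name = doc.taxon_names[0]
    if uca_name not in doc.tip_sequences:
        raise AssemblyError(
            f"UCA taxon {uca_name!r} not found; available taxa: "
            + ", ".join(doc.taxon_names)
        )

    adjacency: dict[Endpoint, list[Endpoint]] = {}
    for a, b, _length in doc.branch_records:
        adjacency.setdefault(a, []).append(b)
        adjacency.setdefault(b, []).append(a)
    lengths = {
        frozenset((a, b)): length for a, b, length in doc.branch_records
    }
    n_nodes = len(adjacency)
    if len(doc.branch_records) != n_nodes - 1:
        raise AssemblyError(
            f"branch records do not form a tree: {n_nodes} endpoints, "
            f"{len(doc.branch_records)} branches"
        )

    aln_len = len(doc.tip_sequences[uca_name])
    tree = LineageTree(alignment_length=aln_len, provenance={"source": "DNAML"})

    def make_node(ep: Endpoint) -> LineageNode:
        if isinstance(ep, int):
            return LineageNode(
                node_id=f"n{ep}", label=f"BP@{ep}", kind=BP,
                sequence=doc.interior_sequences[ep], source_label=str(ep),
                low_confidence=doc.low_confidence.get(ep, ()),
            )
        return LineageNode(
            node_id=f"t_{ep}", label=ep, kind=OBSERVED,
            sequence=doc.tip_sequences[ep], source_label=ep,
            low_confidence=doc.low_confidence.get(ep, ()),
        )

    root = LineageNode(
        node_id="root", label="UCA", kind=UCA,
        sequence=doc.tip_sequences[uca_name], source_label=uca_name,
        low_confidence=doc.low_confidence.get(uca_name, ()),
    )
    tree.add_node(root)

    seen: set[Endpoint] = {uca_name}
    stack: list[tuple[Endpoint, str]] = []
    for nb in adjacency.get(uca_name, []):
        stack.append((nb, "root"))
    while stack:
        ep, parent_id = stack.pop(0)
        if ep in seen:
            raise AssemblyError(f"branch records contain a cycle at {ep!r}")
        seen.add(ep)
        node = make_node(ep)
        tree.add_node(node, parent_id=parent_id)
        key = frozenset((ep, _parent_endpoint(parent_id))) if parent_id != "root" else frozenset((ep, uca_name))
        if key in lengths:
            tree.edge_lengths[(parent_id, node.node_id)] = lengths[key]
        for nb in adjacency.get(ep, []):
            if nb not in seen:
                stack.append((nb, node.node_id))
    if len(seen) != n_nodes:
        missing = set(adjacency) - seen
        raise AssemblyError(
            "branch records are not connected; unreachable: "
            + ", ".join(str(m) for m in sorted(missing, key=str))
        )
    problems = validate_tree(tree)
    if problems:
        raise AssemblyError("assembled tree is invalid: " + "; ".join(problems))
    return tree


def _parent_endpoint(node_id: str) -> Endpoint:
    if node_id.startswith("n"):
        return int(node_id[1:])
    if node_id.startswith("t_"):
        return node_id[2:]
    raise ValueError(node_id)
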