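"""Serialization of annotated lineage trees.

Formats written:

* **XML** — a lossless, byte-stable round-trip format for the full data
  model (topology, sequences, member lists, EC50/comments, per-edge
  annotations, provenance).  The schema is this package's own, versioned via
  the ``schema-version`` root attribute.
* **alignment TSV** — one row per node (UCA first), one column per position,
  preceded by a region ruler row; nucleotide or gap-stripped protein mode.
* **BASELINe FASTA** — grouped-FASTA input for the BASELINe selection-
  pressure server: germline record first with a ``>>`` header prefix,
  followed by one record per observed member label (clusters expanded).
* **SVG/PNG/EPS** renderings and a machine-readable **JSON** dump.

Also reads BASELINe result tables back into a per-region selection summary.
"""

from __future__ import annotations

import io
import json
import logging
import math
import xml.etree.ElementTree as ET
from dataclasses import asdict
from typing import Optional

from .annotate import EdgeAnnotation, MutationEvent, RegionMap, translate_codon
from .errors import IgLineageError, ParseError
from .model import GAP_CHARS, OBSERVED, LineageNode, LineageTree, UCA, normalize_seq

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"
#: BASELINe grouped-FASTA convention: germline headers start with '>>'
GERMLINE_PREFIX = ">>"
RENDER_FORMATS = ("SVG", "PNG", "EPS")


# ---------------------------------------------------------------------------
# XML
# ---------------------------------------------------------------------------

def write_xml(tree: LineageTree) -> str:
    """Serialize the tree (with annotations) to byte-stable XML text."""
    root = ET.Element("ig-lineage", {"schema-version": SCHEMA_VERSION})
    prov = ET.SubElement(root, "provenance")
    prov.text = json.dumps(tree.provenance, sort_keys=True)
    ET.SubElement(root, "alignment", {"length": str(tree.alignment_length)})

    if tree.region_map is not None:
        rm = ET.SubElement(root, "regions")
        for name, end in zip(tree.region_map.names, tree.region_map.ends):
            ET.SubElement(rm, "region", {"name": name, "end": str(end)})
        uca = ET.SubElement(rm, "uca-gapped")
        uca.text = tree.region_map.uca_gapped

    nodes_el = ET.SubElement(root, "nodes")
    for node in tree.preorder():
        attrs = {"id": node.node_id, "label": node.label, "kind": node.kind}
        if node.ec50 is not None:
            attrs["ec50"] = repr(node.ec50)
            if node.ec50_units:
                attrs["ec50-units"] = node.ec50_units
        if node.comment:
            attrs["comment"] = node.comment
        if node.source_label is not None:
            attrs["source-label"] = node.source_label
        if node.low_confidence:
            attrs["low-confidence"] = ",".join(str(p) for p in node.low_confidence)
        el = ET.SubElement(nodes_el, "node", attrs)
        seq = ET.SubElement(el, "sequence")
        seq.text = node.sequence
        members = ET.SubElement(el, "members")
        for m in node.members:
            mel = ET.SubElement(members, "member")
            mel.text = m
            if m in tree.bp_tokens:
                mel.set("bp", "true")

    edges_el = ET.SubElement(root, "edges")
    for pid, cid in tree.edges():
        attrs = {"parent": pid, "child": cid}
        if (pid, cid) in tree.edge_lengths:
            attrs["length"] = repr(tree.edge_lengths[(pid, cid)])
        eel = ET.SubElement(edges_el, "edge", attrs)
        ann = tree.edge_annotations.get((pid, cid))
        if ann is not None:
            eel.set("nt", str(ann.nt_count))
            eel.set("aa", str(ann.aa_count))
            eel.set("untallied", str(ann.untallied))
            for ev in ann.events:
                ET.SubElement(eel, "event", {
                    "pos": str(ev.nt_position), "from-nt": ev.from_nt,
                    "to-nt": ev.to_nt, "codon": str(ev.codon_index),
                    "from-codon": ev.from_codon, "to-codon": ev.to_codon,
                    "from-aa": ev.from_aa, "to-aa": ev.to_aa,
                    "class": ev.rs_class, "region": ev.region,
                    "label": ev.aa_label,
                })
            for region in sorted(ann.region_tally):
                r, s = ann.region_tally[region]
                ET.SubElement(eel, "tally", {
                    "region": region, "r": str(r), "s": str(s),
                })
    ET.indent(root, space="  ")
    return '<?xml version="1.0" encoding="UTF-8"?>\n' + ET.tostring(
        root, encoding="unicode"
    ) + "\n"


def read_xml(text: str) -> LineageTree:
    """Reconstruct a tree from :func:`write_xml` output (lossless inverse)."""
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise ParseError(f"malformed XML: {exc}") from exc
    version = root.get("schema-version")
    if version != SCHEMA_VERSION:
        raise ParseError(
            f"schema version mismatch: file has {version!r}, "
            f"this reader supports {SCHEMA_VERSION!r}"
        )
    aln = root.find("alignment")
    if aln is None:
        raise ParseError("XML lacks <alignment> element")
    tree = LineageTree(alignment_length=int(aln.get("length")))
    prov_el = root.find("provenance")
    if prov_el is not None and prov_el.text:
        tree.provenance = json.loads(prov_el.text)

    rm_el = root.find("regions")
    if rm_el is not None:
        names = tuple(r.get("name") for r in rm_el.findall("region"))
        ends = tuple(int(r.get("end")) for r in rm_el.findall("region"))
        uca_el = rm_el.find("uca-gapped")
        tree.region_map = RegionMap(
            names=names, ends=ends,
            uca_gapped=(uca_el.text or "") if uca_el is not None else "",
        )

    nodes_el = root.find("nodes")
    edges_el = root.find("edges")
    if nodes_el is None or edges_el is None:
        raise ParseError("XML lacks <nodes> or <edges> element")
    parent_of: dict[str, str] = {}
    for eel in edges_el.findall("edge"):
        parent_of[eel.get("child")] = eel.get("parent")

    order = list(nodes_el.findall("node"))
    for nel in order:
        members = [m.text or "" for m in nel.find("members").findall("member")]
        node = LineageNode(
            node_id=nel.get("id"), label=nel.get("label"), kind=nel.get("kind"),
            sequence=(nel.find("sequence").text or ""),
            members=members,
            ec50=float(nel.get("ec50")) if nel.get("ec50") is not None else None,
            ec50_units=nel.get("ec50-units", ""),
            comment=nel.get("comment", ""),
            source_label=nel.get("source-label"),
            low_confidence=tuple(
                int(p) for p in nel.get("low-confidence", "").split(",") if p
            ),
        )
        tree.add_node(node, parent_id=parent_of.get(node.node_id))
        for mel in nel.find("members").findall("member"):
            if mel.get("bp") == "true":
                tree.bp_tokens.add(mel.text or "")
    # re-register BP labels exactly as the writer saw them
    tree.bp_tokens = {
        m.text or ""
        for nel in order for m in nel.find("members").findall("member")
        if m.get("bp") == "true"
    }
    # restore child order as written
    for eel in edges_el.findall("edge"):
        pid, cid = eel.get("parent"), eel.get("child")
        if eel.get("length") is not None:
            tree.edge_lengths[(pid, cid)] = float(eel.get("length"))
        if eel.get("nt") is not None:
            ann = EdgeAnnotation(
                nt_count=int(eel.get("nt")), aa_count=int(eel.get("aa")),
                untallied=int(eel.get("untallied", "0")),
            )
            for evel in eel.findall("event"):
                ann.events.append(MutationEvent(
                    nt_position=int(evel.get("pos")),
                    from_nt=evel.get("from-nt"), to_nt=evel.get("to-nt"),
                    codon_index=int(evel.get("codon")),
                    from_codon=evel.get("from-codon"), to_codon=evel.get("to-codon"),
                    from_aa=evel.get("from-aa"), to_aa=evel.get("to-aa"),
                    rs_class=evel.get("class"), region=evel.get("region"),
                    aa_label=evel.get("label"),
                ))
            ann.region_tally = {
                t.get("region"): (int(t.get("r")), int(t.get("s")))
                for t in eel.findall("tally")
            }
            tree.edge_annotations[(pid, cid)] = ann
    ordered_children: dict[str, list[str]] = {}
    for eel in edges_el.findall("edge"):
        ordered_children.setdefault(eel.get("parent"), []).append(eel.get("child"))
    for pid, kids in ordered_children.items():
        tree.children[pid] = kids
    return tree


# ---------------------------------------------------------------------------
# alignment TSV
# ---------------------------------------------------------------------------

def _node_rows(tree: LineageTree) -> list[LineageNode]:
    nodes = list(tree.preorder())
    return sorted(nodes, key=lambda n: 0 if n.kind == UCA else 1)


def write_alignment_tsv(
    tree: LineageTree,
    region_map: Optional[RegionMap] = None,
    mode: str = "nucleotide",
) -> str:
    """Export the alignment as TSV: position header, region ruler, UCA first.

    In ``protein`` mode sequences are gap-stripped, read in-frame and
    translated; a trailing partial codon is marked 'X' with a warning.
    """
    if mode not in ("nucleotide", "protein"):
        raise ValueError(f"unknown alignment mode {mode!r}")
    rm = region_map if region_map is not None else tree.region_map
    rows = _node_rows(tree)
    L = tree.alignment_length

    out = io.StringIO()
    if mode == "nucleotide":
        ncols = L
        header = ["label"] + [str(i) for i in range(1, ncols + 1)]
        ruler = ["REGION"] + [
            (rm.region_of(i) if rm is not None else "UNASSIGNED")
            for i in range(1, ncols + 1)
        ]
        out.write("\t".join(header) + "\n")
        out.write("\t".join(ruler) + "\n")
        for node in rows:
            out.write("\t".join([",".join(node.members)] + list(node.sequence)) + "\n")
        return out.getvalue()

    # protein mode
    translated: list[tuple[LineageNode, str]] = []
    ncols = 0
    for node in rows:
        stripped = "".join(ch for ch in normalize_seq(node.sequence) if ch not in GAP_CHARS)
        if len(stripped) % 3:
            logger.warning(
                "node %s: gap-stripped length %d not divisible by 3; "
                "trailing partial codon marked 'X'", node.label, len(stripped),
            )
        n_codons = math.ceil(len(stripped) / 3)
        aa = "".join(
            translate_codon(stripped[3 * k: 3 * k + 3]) for k in range(n_codons)
        )
        translated.append((node, aa))
        ncols = max(ncols, n_codons)
    header = ["label"] + [str(i) for i in range(1, ncols + 1)]
    # ruler per codon: region of the codon's first nucleotide in UCA coordinates
    uca = rows[0].sequence if rows else (rm.uca_gapped if rm is not None else "")
    coding_cols = [i + 1 for i, ch in enumerate(normalize_seq(uca)) if ch not in GAP_CHARS]
    ruler = ["REGION"]
    for k in range(ncols):
        if rm is not None and 3 * k < len(coding_cols):
            ruler.append(rm.region_of(coding_cols[3 * k]))
        else:
            ruler.append("UNASSIGNED")
    out.write("\t".join(header) + "\n")
    out.write("\t".join(ruler) + "\n")
    for node, aa in translated:
        cells = list(aa) + [""] * (ncols - len(aa))
        out.write("\t".join([",".join(node.members)] + cells) + "\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# BASELINe
# ---------------------------------------------------------------------------

def write_baseline_fasta(tree: LineageTree) -> str:
    """Write the grouped FASTA consumed by the BASELINe selection server.

    The IMGT-gapped germline (UCA) record comes first, its header marked
    with the ``>>`` prefix; one record follows per observed member label
    (clusters expanded).  Requires the optional region FASTA to have been
    supplied, since BASELINe needs the IMGT-gapped UCA V(D)J sequence.
    """
    rm = tree.region_map
    if rm is None or not rm.uca_gapped:
        raise IgLineageError(
            "BASELINe export requires the optional UCA region FASTA "
            "(IMGT-gapped UCA V(D)J sequence with region end positions)"
        )
    uca_seq = rm.uca_gapped
    L = len(uca_seq)
    lines = [f"{GERMLINE_PREFIX}{tree.root.label}", uca_seq]
    for node in tree.preorder():
        if node.kind != OBSERVED:
            continue
        if len(node.sequence) != L:
            raise IgLineageError(
                f"node {node.label!r}: sequence length {len(node.sequence)} "
                f"does not match the IMGT-gapped UCA length {L}"
            )
        for member in node.members:
            if member in tree.bp_tokens:
                continue
            lines.append(f">{member}")
            lines.append(node.sequence)
    return "\n".join(lines) + "\n"


_CLASS_COLUMN_NAMES = ("type", "region", "class")


def load_baseline_output(text: str) -> list[dict]:
    """Parse a BASELINe results table into a per-region selection summary.

    Expects a tab-separated table with a region-class column (``Type``,
    ``Region`` or ``Class``; values like CDR/FWR) and numeric selection
    columns (anything matching ``sigma``/``ci``/``p``); column supersets are
    tolerated, unrecognized layouts are fatal.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError("empty BASELINe output file")
    header = lines[0].split("\t")
    lower = [h.strip().lower() for h in header]
    try:
        class_idx = next(i for i, h in enumerate(lower) if h in _CLASS_COLUMN_NAMES)
    except StopIteration:
        raise ParseError(
            "unrecognized BASELINe output layout; observed header: "
            + ", ".join(header)
        )
    numeric_cols = [
        (i, header[i].strip())
        for i, h in enumerate(lower)
        if any(tag in h for tag in ("sigma", "ci", "p_", "pvalue")) or h == "p"
    ]
    if not numeric_cols:
        raise ParseError(
            "no selection-statistic columns found; observed header: "
            + ", ".join(header)
        )
    summary = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        entry: dict = {"region_class": cells[class_idx].strip()}
        for i, name in numeric_cols:
            if i < len(cells) and cells[i].strip():
                try:
                    entry[name] = float(cells[i])
                except ValueError:
                    entry[name] = cells[i].strip()
        summary.append(entry)
    return summary


def attach_baseline_summary(tree: LineageTree, summary: list[dict]) -> LineageTree:
    """Store a BASELINe summary in the tree's provenance (exported with XML)."""
    tree.provenance["baseline_summary"] = summary
    return tree


# ---------------------------------------------------------------------------
# JSON dump
# ---------------------------------------------------------------------------

def write_json(tree: LineageTree) -> str:
    """Machine-readable dump of nodes, edges and annotations for viewers."""
    doc = {
        "alignment_length": tree.alignment_length,
        "provenance": tree.provenance,
        "region_map": (
            {"names": list(tree.region_map.names), "ends": list(tree.region_map.ends),
             "uca_gapped": tree.region_map.uca_gapped}
            if tree.region_map is not None else None
        ),
        "nodes": [
            {
                "id": n.node_id, "label": n.label, "kind": n.kind,
                "sequence": n.sequence, "members": n.members,
                "ec50": n.ec50, "ec50_units": n.ec50_units,
                "comment": n.comment,
            }
            for n in tree.preorder()
        ],
        "edges": [
            {
                "parent": pid, "child": cid,
                "length": tree.edge_lengths.get((pid, cid)),
                "annotation": (
                    asdict(tree.edge_annotations[(pid, cid)])
                    if (pid, cid) in tree.edge_annotations else None
                ),
            }
            for pid, cid in tree.edges()
        ],
    }
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _layout(tree: LineageTree) -> tuple[dict[str, tuple[float, float]], int]:
    """Layered layout: leaves evenly spaced, internals centred, x = depth."""
    pos: dict[str, tuple[float, float]] = {}
    next_y = [0.0]
    depth: dict[str, int] = {tree.root_id: 0}
    maxdepth = 0
    for node in tree.preorder():
        if node.node_id != tree.root_id:
            depth[node.node_id] = depth[tree.parent[node.node_id]] + 1
            maxdepth = max(maxdepth, depth[node.node_id])

    def place(nid: str) -> float:
        kids = tree.children[nid]
        if not kids:
            y = next_y[0]
            next_y[0] += 1.0
        else:
            ys = [place(c) for c in kids]
            y = sum(ys) / len(ys)
        pos[nid] = (float(depth[nid]), y)
        return y

    place(tree.root_id)
    return pos, maxdepth


def _node_text(node: LineageNode) -> str:
    text = ",".join(node.members)
    if node.ec50 is not None:
        units = f" {node.ec50_units}" if node.ec50_units else ""
        text += f" EC50={node.ec50:g}{units}"
    return text


def _edge_text(tree: LineageTree, pid: str, cid: str) -> str:
    ann = tree.edge_annotations.get((pid, cid))
    if ann is None:
        return ""
    return f"{ann.nt_count} ({ann.aa_count})"


def render_svg(tree: LineageTree) -> str:
    """Deterministic hand-written SVG rendering of the annotated tree."""
    pos, maxdepth = _layout(tree)
    xscale, yscale, margin = 180.0, 60.0, 60.0
    width = (maxdepth + 1) * xscale + 2 * margin + 160
    n_leaves = max(1, len(tree.leaves()))
    height = n_leaves * yscale + 2 * margin

    def xy(nid: str) -> tuple[float, float]:
        x, y = pos[nid]
        return (margin + x * xscale, margin + y * yscale)

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width:.0f}" '
        f'height="{height:.0f}" viewBox="0 0 {width:.0f} {height:.0f}">',
        '<style>text{font-family:monospace;font-size:12px}</style>',
    ]
    for pid, cid in tree.edges():
        x1, y1 = xy(pid)
        x2, y2 = xy(cid)
        parts.append(
            f'<path d="M {x1:.1f} {y1:.1f} L {x1:.1f} {y2:.1f} L {x2:.1f} {y2:.1f}" '
            'fill="none" stroke="#444" stroke-width="1.5"/>'
        )
        label = _edge_text(tree, pid, cid)
        if label:
            parts.append(
                f'<text x="{(x1 + x2) / 2:.1f}" y="{y2 - 5:.1f}" '
                f'text-anchor="middle" class="edge-label">{label}</text>'
            )
    for node in tree.preorder():
        x, y = xy(node.node_id)
        fill = {"UCA": "#2166ac", "BP": "#bbbbbb", "OBSERVED": "#b2182b"}[node.kind]
        parts.append(f'<circle cx="{x:.1f}" cy="{y:.1f}" r="6" fill="{fill}"/>')
        parts.append(
            f'<text x="{x + 10:.1f}" y="{y + 4:.1f}">{_node_text(node)}</text>'
        )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def render_tree(tree: LineageTree, out_path=None, fmt: str = "SVG"):
    """Render the tree to SVG (returned as text) or PNG/EPS (written to file).

    ``fmt`` must be one of SVG, PNG, EPS; anything else is fatal.  PNG and
    EPS require ``out_path``.
    """
    token = fmt.upper()
    if token not in RENDER_FORMATS:
        raise IgLineageError(
            f"unsupported render format {fmt!r}; supported: "
            + ", ".join(RENDER_FORMATS)
        )
    if token == "SVG":
        text = render_svg(tree)
        if out_path is not None:
            with open(out_path, "w") as fh:
                fh.write(text)
        return text

    if out_path is None:
        raise IgLineageError(f"{token} rendering requires an output path")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos, maxdepth = _layout(tree)
    n_leaves = max(1, len(tree.leaves()))
    fig, ax = plt.subplots(figsize=(3 + 2.2 * (maxdepth + 1), 1 + 0.45 * n_leaves))
    for pid, cid in tree.edges():
        x1, y1 = pos[pid]
        x2, y2 = pos[cid]
        ax.plot([x1, x1, x2], [y1, y2, y2], color="#444444", lw=1.2)
        label = _edge_text(tree, pid, cid)
        if label:
            ax.annotate(label, ((x1 + x2) / 2, y2), textcoords="offset points",
                        xytext=(0, 4), ha="center", fontsize=8)
    colors = {"UCA": "#2166ac", "BP": "#bbbbbb", "OBSERVED": "#b2182b"}
    for node in tree.preorder():
        x, y = pos[node.node_id]
        ax.plot([x], [y], "o", color=colors[node.kind], ms=7)
        ax.annotate(_node_text(node), (x, y), textcoords="offset points",
                    xytext=(8, -3), fontsize=8)
    ax.invert_yaxis()
    ax.axis("off")
    fig.savefig(out_path, format=token.lower(), dpi=150, bbox_inches="tight")
    plt.close(fig)
    return out_path
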