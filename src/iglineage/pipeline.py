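"""End-to-end orchestration: parse, process, annotate, export.

These functions tie the modules together for the two ingestion routes (the
Dnaml outfile and the Immcantation triple) and write the standard output
bundle: XML, JSON dump, nucleotide and protein alignment TSVs, BASELINe
FASTA (when the region FASTA was supplied) and tree renderings.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

from . import annotate as _annotate
from . import dnaml as _dnaml
from . import exports as _exports
from . import immcantation as _imm
from .annotate import RegionMap, annotate_tree, parse_region_fasta
from .errors import IgLineageError, ParseError
from .model import LineageTree, process_tree

logger = logging.getLogger(__name__)


def run_dnaml(
    outfile_text: str,
    region_fasta_text: Optional[str] = None,
    uca_name: Optional[str] = None,
    numbering_map: Optional[dict[int, str]] = None,
) -> LineageTree:
    """Dnaml route: parse the outfile, process and annotate the lineage."""
    doc = _dnaml.parse_dnaml_outfile(outfile_text)
    tree = _dnaml.dnaml_to_lineage(doc, uca_name=uca_name)
    region_map = parse_region_fasta(region_fasta_text) if region_fasta_text else None
    if region_map is not None:
        _check_region_map(region_map, tree)
        tree.region_map = region_map
    tree = process_tree(tree)
    return annotate_tree(tree, numbering_map=numbering_map)


def run_immcantation(
    airr_text: str,
    tab_text: str,
    asr_fasta_text: str,
    clone_id: str,
    region_fasta_text: Optional[str] = None,
    numbering_map: Optional[dict[int, str]] = None,
    germline_pattern: str = _imm.DEFAULT_GERMLINE_PATTERN,
) -> LineageTree:
    """Immcantation route: assemble the selected clone, process, annotate."""
    records = _imm.parse_airr(airr_text)
    tab = _imm.parse_igphyml_tab(tab_text)
    bundle = _imm.build_clone_bundle(records, tab, asr_fasta_text, clone_id)
    tree = _imm.assemble_clone_tree(bundle, germline_pattern=germline_pattern)
    region_map = parse_region_fasta(region_fasta_text) if region_fasta_text else None
    if region_map is not None:
        _check_region_map(region_map, tree)
        tree.region_map = region_map
    tree = process_tree(tree)
    return annotate_tree(tree, numbering_map=numbering_map)


def _check_region_map(region_map: RegionMap, tree: LineageTree) -> None:
    if region_map.uca_gapped and len(region_map.uca_gapped) != tree.alignment_length:
        raise IgLineageError(
            f"region FASTA sequence length {len(region_map.uca_gapped)} does "
            f"not match the alignment length {tree.alignment_length}"
        )
    if region_map.ends[-1] > tree.alignment_length:
        raise IgLineageError(
            f"last region end {region_map.ends[-1]} exceeds the alignment "
            f"length {tree.alignment_length}"
        )


def apply_node_annotations(tree: LineageTree, text: str) -> LineageTree:
    """Apply a user TSV of per-node EC50/comment entries (label, ec50, comment).

    The EC50 cell may carry units after the number ("12.5 ng/ml").  Unknown
    labels are reported; matching is against node labels and member labels.
    """
    by_label: dict[str, object] = {}
    for node in tree.preorder():
        for m in node.members:
            by_label[m] = node
        by_label[node.label] = node
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cells = line.split("\t")
        label = cells[0].strip()
        node = by_label.get(label)
        if node is None:
            raise IgLineageError(
                f"annotation line {lineno}: no node or member labelled {label!r}"
            )
        if len(cells) > 1 and cells[1].strip():
            parts = cells[1].strip().split(None, 1)
            try:
                node.ec50 = float(parts[0])
            except ValueError as exc:
                raise ParseError(
                    f"annotation line {lineno}: EC50 {parts[0]!r} is not a number"
                ) from exc
            if node.ec50 < 0:
                raise ParseError(f"annotation line {lineno}: EC50 must be >= 0")
            node.ec50_units = parts[1] if len(parts) > 1 else ""
        if len(cells) > 2 and cells[2].strip():
            node.comment = cells[2].strip()
    return tree


def export_bundle(
    tree: LineageTree,
    outdir: Path,
    render_formats: tuple[str, ...] = ("SVG",),
) -> list[Path]:
    """Write the standard output bundle into ``outdir``; returns paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def write(name: str, text: str) -> None:
        path = outdir / name
        path.write_text(text)
        written.append(path)

    write("lineage.xml", _exports.write_xml(tree))
    write("lineage.json", _exports.write_json(tree))
    write("alignment_nt.tsv", _exports.write_alignment_tsv(tree, mode="nucleotide"))
    write("alignment_aa.tsv", _exports.write_alignment_tsv(tree, mode="protein"))
    if tree.region_map is not None and tree.region_map.uca_gapped:
        write("baseline_input.fasta", _exports.write_baseline_fasta(tree))
    for fmt in render_formats:
        token = fmt.upper()
        path = outdir / f"tree.{token.lower()}"
        _exports.render_tree(tree, out_path=path, fmt=token)
        written.append(path)
    return written
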