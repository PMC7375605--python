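"""Per-edge mutation annotation: R/S classification, regions, numbering.

Each parent->child edge of a processed lineage tree is diffed position by
position.  A substitution is recorded only where both sequences hold a
concrete base (A/C/G/T); gap or N columns never produce events and are
counted separately as "untallied" differences.  Codons are read in-frame on
the gap-stripped sequence starting at alignment position 1 (V(D)J sequences
begin at the V start, IMGT convention), so the reported nucleotide position
counts gap columns while the amino-acid (codon) index does not.

A mutation is replacement (R) if it changes the encoded amino acid — the
standard genetic code, with changes to or from a stop codon counted as R —
and silent (S) otherwise.  Region assignment (FW1..CDR3[, FW4]) uses the
inclusive 1-based end positions carried by a :class:`RegionMap`, typically
parsed from the IMGT-gapped UCA FASTA header.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import Optional

from Bio import SeqIO

from .errors import ParseError
from .model import GAP_CHARS, LineageTree, normalize_seq

logger = logging.getLogger(__name__)

REGION_NAMES = ("FW1", "CDR1", "FW2", "CDR2", "FW3", "CDR3", "FW4")
UNASSIGNED = "UNASSIGNED"

#: Standard genetic code (DNA codons, stop = '*').
GENETIC_CODE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate_codon(codon: str) -> str:
    """Translate one codon; 'X' for anything not a clean A/C/G/T triplet."""
    return GENETIC_CODE.get(codon.upper(), "X") if len(codon) == 3 else "X"


def classify_rs(from_codon: str, to_codon: str) -> str:
    """Classify a codon change as replacement ('R') or silent ('S').

    Silent iff both codons translate (standard code) to the same amino acid;
    any change to or from a stop codon is replacement.  Raises ``ValueError``
    for codons containing gaps, N, or other non-ACGT characters — such events
    are excluded upstream by :func:`diff_edge`.
    """
    a = GENETIC_CODE.get(from_codon.upper())
    b = GENETIC_CODE.get(to_codon.upper())
    if a is None or b is None:
        bad = from_codon if a is None else to_codon
        raise ValueError(f"invalid codon {bad!r}: expected 3 bases over ACGT")
    return "S" if a == b else "R"


@dataclass(frozen=True)
class RegionMap:
    """FW/CDR boundaries as inclusive 1-based nucleotide end positions.

    ``ends[i]`` is the last alignment position of ``names[i]``; region k
    starts at ``ends[k-1] + 1``.  Coordinates refer to the IMGT-gapped
    alignment carried by ``uca_gapped``.
    """

    names: tuple[str, ...]
    ends: tuple[int, ...]
    uca_gapped: str = ""

    def __post_init__(self) -> None:
        if len(self.names) != len(self.ends):
            raise ValueError("names and ends differ in length")
        if self.names != REGION_NAMES[: len(self.names)]:
            raise ValueError(f"region names must be {REGION_NAMES} prefix")
        if any(b <= a for a, b in zip(self.ends, self.ends[1:])):
            raise ParseError("region end positions must be strictly increasing")
        if self.uca_gapped and self.ends[-1] > len(self.uca_gapped):
            raise ParseError(
                f"last region end {self.ends[-1]} exceeds sequence length "
                f"{len(self.uca_gapped)}"
            )

    def spans(self) -> list[tuple[str, int, int]]:
        """(name, start, end) triples, 1-based inclusive."""
        out, start = [], 1
        for name, end in zip(self.names, self.ends):
            out.append((name, start, end))
            start = end + 1
        return out

    def region_of(self, nt_position: int) -> str:
        if nt_position < 1:
            raise ValueError(f"position {nt_position} out of range")
        for name, end in zip(self.names, self.ends):
            if nt_position <= end:
                return name
        return UNASSIGNED


def parse_region_fasta(text: str) -> RegionMap:
    """Parse the single-record UCA FASTA whose header lists region ends.

    Header convention: ``>name e1 e2 e3 e4 e5 e6[ e7]`` with whitespace-
    separated 1-based inclusive nucleotide end positions for FW1, CDR1, FW2,
    CDR2, FW3, CDR3 and optionally FW4; the record is the IMGT-gapped UCA
    V(D)J nucleotide sequence.
    """
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if len(records) != 1:
        raise ParseError(
            f"region FASTA must contain exactly one record, found {len(records)}"
        )
    rec = records[0]
    tokens = rec.description.split()
    try:
        ends = tuple(int(t) for t in tokens[1:])
    except ValueError as exc:
        raise ParseError(f"non-integer region end in header {rec.description!r}") from exc
    if len(ends) not in (6, 7):
        raise ParseError(
            f"expected 6 or 7 region end positions, found {len(ends)} "
            f"in header {rec.description!r}"
        )
    seq = normalize_seq(str(rec.seq))
    rm = RegionMap(names=REGION_NAMES[: len(ends)], ends=ends, uca_gapped=seq)
    if ends[-1] > len(seq):
        raise ParseError(
            f"last region end {ends[-1]} exceeds sequence length {len(seq)}"
        )
    return rm


def region_of_position(nt_position: int, region_map: RegionMap) -> str:
    """Region name for a 1-based alignment position (UNASSIGNED past the end)."""
    limit = len(region_map.uca_gapped) or region_map.ends[-1]
    if not 1 <= nt_position <= limit:
        raise ValueError(
            f"position {nt_position} outside alignment (1..{limit})"
        )
    return region_map.region_of(nt_position)


def aa_position_label(codon_index: int, numbering_map: Optional[dict[int, str]] = None) -> str:
    """Display label for an amino-acid position.

    Absolute codon index by default; with a user-supplied map (absolute index
    -> Kabat-style label, e.g. "52a") the mapped label, falling back to the
    absolute index with a warning for unmapped positions.
    """
    if numbering_map is not None:
        label = numbering_map.get(codon_index)
        if label is not None:
            return label
        logger.warning("codon %d missing from numbering map; using absolute index", codon_index)
    return str(codon_index)


def load_numbering_map(text: str) -> dict[int, str]:
    """Read a two-column TSV mapping absolute codon index -> display label."""
    out: dict[int, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ParseError(f"numbering map line {lineno}: expected 2 columns")
        try:
            out[int(parts[0])] = parts[1]
        except ValueError as exc:
            raise ParseError(f"numbering map line {lineno}: non-integer index") from exc
    return out


@dataclass(frozen=True)
class MutationEvent:
    """One nucleotide substitution on an edge with its codon context."""

    nt_position: int          # 1-based, alignment coordinates (gaps counted)
    from_nt: str
    to_nt: str
    codon_index: int          # 1-based, gap-stripped in-frame codon number
    from_codon: str
    to_codon: str
    from_aa: str              # single letter, '*' stop, 'X' untranslatable
    to_aa: str
    rs_class: str             # 'R' or 'S'
    region: str = UNASSIGNED
    aa_label: str = ""


@dataclass
class EdgeAnnotation:
    """All substitutions on one edge plus per-region R/S tallies.

    ``nt_count`` counts substitution events; ``aa_count`` counts codons whose
    translation changed (two substitutions in one codon are one amino-acid
    mutation); ``untallied`` counts differing columns excluded because one
    side holds a gap, N or ambiguity code.
    """

    nt_count: int = 0
    aa_count: int = 0
    events: list[MutationEvent] = field(default_factory=list)
    region_tally: dict[str, tuple[int, int]] = field(default_factory=dict)
    untallied: int = 0


def diff_edge(
    parent_seq: str,
    child_seq: str,
    region_map: Optional[RegionMap] = None,
    numbering_map: Optional[dict[int, str]] = None,
) -> EdgeAnnotation:
    """Diff two equal-length aligned sequences into an :class:`EdgeAnnotation`."""
    p = normalize_seq(parent_seq)
    c = normalize_seq(child_seq)
    if len(p) != len(c):
        raise ValueError(
            f"aligned sequences differ in length ({len(p)} vs {len(c)})"
        )
    # gap-stripped coding coordinates follow the parent sequence
    coding_cols = [i for i, ch in enumerate(p) if ch not in GAP_CHARS]
    coding_index = {col: k + 1 for k, col in enumerate(coding_cols)}

    ann = EdgeAnnotation()
    changed_codons: set[int] = set()
    tally: dict[str, list[int]] = {}
    for i, (a, b) in enumerate(zip(p, c)):
        if a == b:
            continue
        if a not in "ACGT" or b not in "ACGT":
            ann.untallied += 1
            continue
        k = coding_index[i]
        codon_idx = math.ceil(k / 3)
        cols = coding_cols[(codon_idx - 1) * 3: codon_idx * 3]
        from_codon = "".join(p[j] for j in cols)
        to_codon = "".join(c[j] for j in cols)
        from_aa = translate_codon(from_codon)
        to_aa = translate_codon(to_codon)
        if from_aa != "X" and to_aa != "X":
            rs = classify_rs(from_codon, to_codon)
        else:
            rs = "R"
        if from_aa != to_aa:
            changed_codons.add(codon_idx)
        region = region_map.region_of(i + 1) if region_map is not None else UNASSIGNED
        ann.events.append(MutationEvent(
            nt_position=i + 1, from_nt=a, to_nt=b,
            codon_index=codon_idx, from_codon=from_codon, to_codon=to_codon,
            from_aa=from_aa, to_aa=to_aa, rs_class=rs, region=region,
            aa_label=aa_position_label(codon_idx, numbering_map),
        ))
        tally.setdefault(region, [0, 0])[0 if rs == "R" else 1] += 1
    ann.nt_count = len(ann.events)
    ann.aa_count = len(changed_codons)
    ann.region_tally = {r: (v[0], v[1]) for r, v in tally.items()}
    if ann.untallied:
        logger.debug("%d differing gap/N columns excluded from events", ann.untallied)
    return ann


def annotate_tree(
    tree: LineageTree,
    region_map: Optional[RegionMap] = None,
    numbering_map: Optional[dict[int, str]] = None,
) -> LineageTree:
    """Attach a :class:`EdgeAnnotation` to every edge of the tree (in place)."""
    rm = region_map if region_map is not None else tree.region_map
    if region_map is not None:
        tree.region_map = region_map
    for pid, cid in tree.edges():
        tree.edge_annotations[(pid, cid)] = diff_edge(
            tree.nodes[pid].sequence, tree.nodes[cid].sequence, rm, numbering_map
        )
    return tree
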