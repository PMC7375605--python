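"""Tests for mutation annotation: R/S classes, regions, numbering, edge diffs."""

import itertools
import random

import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from iglineage.annotate import (
    EdgeAnnotation, RegionMap, aa_position_label, annotate_tree, classify_rs,
    diff_edge, load_numbering_map, parse_region_fasta, region_of_position,
)
from iglineage.errors import ParseError
from iglineage.model import BP, OBSERVED, UCA
from iglineage.simulate import SimulationConfig, simulate_lineage

from conftest import make_tree

BASES = "ACGT"
ALL_CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]


def _bio_rs(from_codon, to_codon):
    return "S" if Seq(from_codon).translate() == Seq(to_codon).translate() else "R"


class TestClassifyRs:
    def test_worked_examples(self):
        assert classify_rs("AGT", "AAT") == "R"   # Ser -> Asn
        assert classify_rs("GCT", "GCC") == "S"   # Ala -> Ala
        assert classify_rs("TGG", "TGA") == "R"   # Trp -> stop

    def test_exhaustive_against_translation_oracle(self):
        for a in ALL_CODONS:
            for b in ALL_CODONS:
                assert classify_rs(a, b) == _bio_rs(a, b)

    @pytest.mark.parametrize("bad", ["AG-", "AGN", "AG", "AGTT", "A.T"])
    def test_invalid_codon_rejected(self, bad):
        with pytest.raises(ValueError):
            classify_rs(bad, "AAA")

    @given(st.text(alphabet="ACGT", min_size=3, max_size=3),
           st.text(alphabet="ACGT", min_size=3, max_size=3))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_silence_is_symmetric_and_reflexive(self, a, b):
        assert classify_rs(a, b) == classify_rs(b, a)
        assert classify_rs(a, a) == "S"


class TestRegionFasta:
    HEADER = ">UCA 78 114 165 195 312 360"

    def _fasta(self, header=None, length=360):
        seq = ("ACG" * 120)[:length]
        return f"{header or self.HEADER}\n{seq}\n"

    def test_six_region_parse_and_spans(self):
        rm = parse_region_fasta(self._fasta())
        assert rm.names == ("FW1", "CDR1", "FW2", "CDR2", "FW3", "CDR3")
        assert rm.spans()[1] == ("CDR1", 79, 114)
        assert rm.ends[-1] == 360

    def test_seven_regions_accepted(self):
        rm = parse_region_fasta(self._fasta(header=">U 78 114 165 195 312 330 360"))
        assert rm.names[-1] == "FW4"

    def test_non_increasing_ends_fatal(self):
        with pytest.raises(ParseError, match="increasing"):
            parse_region_fasta(self._fasta(header=">U 10 9 165 195 312 360"))

    def test_wrong_count_fatal(self):
        with pytest.raises(ParseError, match="expected 6 or 7"):
            parse_region_fasta(self._fasta(header=">U 78 114 165"))

    def test_end_beyond_sequence_fatal(self):
        with pytest.raises(ParseError):
            parse_region_fasta(self._fasta(length=300))

    def test_region_of_position(self):
        rm = parse_region_fasta(self._fasta())
        assert region_of_position(92, rm) == "CDR1"
        assert region_of_position(1, rm) == "FW1"
        assert region_of_position(114, rm) == "CDR1"   # inclusive end
        assert region_of_position(115, rm) == "FW2"
        assert region_of_position(360, rm) == "CDR3"
        with pytest.raises(ValueError):
            region_of_position(0, rm)
        with pytest.raises(ValueError):
            region_of_position(361, rm)


class TestNumbering:
    def test_absolute_default_and_mapped_labels(self, caplog):
        assert aa_position_label(31) == "31"
        assert aa_position_label(31, {31: "31"}) == "31"
        assert aa_position_label(53, {52: "52", 53: "52a"}) == "52a"
        with caplog.at_level("WARNING"):
            assert aa_position_label(7, {52: "52"}) == "7"
        assert any("missing from numbering map" in r.message for r in caplog.records)

    def test_load_numbering_map(self):
        nm = load_numbering_map("# comment\n31\t31\n53\t52a\n")
        assert nm == {31: "31", 53: "52a"}
        with pytest.raises(ParseError):
            load_numbering_map("x\ty\n")


def _seq_with_codon(codon31: str, length: int = 360) -> str:
    """In-frame sequence whose codon 31 (positions 91-93) is ``codon31``."""
    base = ("GCT" * (length // 3))
    return base[:90] + codon31 + base[93:length]


class TestDiffEdge:
    def test_position_92_maps_to_codon_31(self):
        rm = parse_region_fasta(f">U 78 114 165 195 312 360\n{_seq_with_codon('AGT')}\n")
        parent = _seq_with_codon("AGT")
        child = _seq_with_codon("AAT")
        ann = diff_edge(parent, child, rm)
        assert ann.nt_count == 1 and ann.aa_count == 1
        ev = ann.events[0]
        assert ev.nt_position == 92
        assert (ev.from_nt, ev.to_nt) == ("G", "A")
        assert ev.codon_index == 31
        assert (ev.from_codon, ev.to_codon) == ("AGT", "AAT")
        assert (ev.from_aa, ev.to_aa) == ("S", "N")
        assert ev.rs_class == "R"
        assert ev.region == "CDR1"
        assert ev.aa_label == "31"
        assert ann.region_tally == {"CDR1": (1, 0)}

    def test_identical_sequences_all_zero(self):
        s = _seq_with_codon("AGT")
        ann = diff_edge(s, s)
        assert ann == EdgeAnnotation()

    def test_gap_and_n_columns_excluded_but_counted(self):
        ann = diff_edge("ACGTGA", "A-GTGN")
        assert ann.nt_count == 0
        assert ann.untallied == 2

    def test_length_mismatch_fatal(self):
        with pytest.raises(ValueError, match="length"):
            diff_edge("ACGT", "ACG")

    def test_silent_mutation_tally(self):
        ann = diff_edge("GCTGCT", "GCCGCT")
        assert ann.nt_count == 1 and ann.aa_count == 0
        assert ann.events[0].rs_class == "S"
        assert ann.region_tally == {"UNASSIGNED": (0, 1)}

    def test_two_hits_in_one_codon_count_one_aa_mutation(self):
        ann = diff_edge("GCTAAA", "GGGAAA")   # GCT(Ala) -> GGG(Gly), 2 nt hits
        assert ann.nt_count == 2
        assert ann.aa_count == 1
        for ev in ann.events:
            assert (ev.from_codon, ev.to_codon) == ("GCT", "GGG")
            assert ev.rs_class == "R"

    def test_frame_invariance_under_shared_gap_column(self):
        parent = _seq_with_codon("AGT", length=120)
        child = _seq_with_codon("AAT", length=120)
        gapped_p = parent[:50] + "-" + parent[50:]
        gapped_c = child[:50] + "-" + child[50:]
        plain = diff_edge(parent, child).events[0]
        gapped = diff_edge(gapped_p, gapped_c).events[0]
        assert gapped.nt_position == plain.nt_position + 1
        assert (gapped.codon_index, gapped.from_aa, gapped.to_aa, gapped.rs_class) \
            == (plain.codon_index, plain.from_aa, plain.to_aa, plain.rs_class)

    def test_region_tally_reconciles_with_counts(self):
        rng = random.Random(3)
        for _ in range(20):
            L = 60
            parent = "".join(rng.choice(BASES) for _ in range(L))
            chars = list(parent)
            for pos in rng.sample(range(L), 5):
                chars[pos] = rng.choice([b for b in BASES if b != chars[pos]])
            ann = diff_edge(parent, "".join(chars))
            r = sum(v[0] for v in ann.region_tally.values())
            s = sum(v[1] for v in ann.region_tally.values())
            assert r + s == ann.nt_count
            assert s == sum(1 for e in ann.events if e.rs_class == "S")


class TestAnnotateTree:
    def test_simulated_lineage_recovers_implanted_events(self):
        tree, gt = simulate_lineage(SimulationConfig(seed=77, n_leaves=6))
        annotate_tree(tree, region_map=tree.region_map)
        for pid, cid in tree.edges():
            key = (tree.nodes[pid].label, tree.nodes[cid].label)
            assert list(tree.edge_annotations[(pid, cid)].events) == list(gt.events[key])

    def test_single_node_tree_no_annotations(self):
        tree = make_tree({"label": "UCA", "kind": UCA, "seq": "ACGT"})
        annotate_tree(tree)
        assert tree.edge_annotations == {}

    def test_star_tree_annotations_independent_of_leaf_order(self):
        spec = {
            "label": "UCA", "kind": UCA, "seq": "GCTGCT",
            "children": [
                {"label": "Ig1", "kind": OBSERVED, "seq": "GCTGCC"},
                {"label": "Ig2", "kind": OBSERVED, "seq": "ACTGCT"},
                {"label": "Ig3", "kind": OBSERVED, "seq": "GCTGAT"},
            ],
        }
        tree = make_tree(spec)
        spec["children"].reverse()
        rev = make_tree(spec)
        annotate_tree(tree)
        annotate_tree(rev)
        by_label = lambda t: {
            t.nodes[c].label: t.edge_annotations[(p, c)] for p, c in t.edges()
        }
        assert by_label(tree) == by_label(rev)
        assert len(by_label(tree)) == 3

    def test_path_additivity_without_reversions(self):
        tree, _ = simulate_lineage(SimulationConfig(seed=13, n_leaves=8))
        annotate_tree(tree, region_map=tree.region_map)
        for leaf in tree.leaves():
            path_events = []
            nid = leaf.node_id
            while nid != tree.root_id:
                pid = tree.parent[nid]
                path_events.extend(
                    (e.nt_position, e.from_nt, e.to_nt)
                    for e in tree.edge_annotations[(pid, nid)].events
                )
                nid = pid
            direct = diff_edge(tree.root.sequence, leaf.sequence)
            assert sorted(path_events) == sorted(
                (e.nt_position, e.from_nt, e.to_nt) for e in direct.events
            )
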