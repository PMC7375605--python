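"""Tests for the lineage-tree model and its post-processing operations."""

import random

import pytest

from iglineage.errors import ParseError
from iglineage.model import (
    BP, IUPAC_AMBIGUITY, OBSERVED, UCA, LineageNode, LineageTree,
    cluster_identical_observed, collapse_redundant_bps, process_tree,
    renumber_branch_points, resolve_ambiguities, validate_tree,
)

from conftest import (
    make_tree, naive_canonical, naive_collapse_cluster, random_processing_tree,
    tree_canonical,
)


def _bp_tree(bp_seq, leaf_seqs, uca_seq=None):
    """UCA -> BP -> leaves, all sequences of equal length."""
    L = len(leaf_seqs[0])
    uca_seq = uca_seq or "A" * L
    return make_tree({
        "label": "UCA", "kind": UCA, "seq": uca_seq,
        "children": [{
            "label": "BP@1", "kind": BP, "seq": bp_seq,
            "children": [
                {"label": f"Ig{i+1}", "kind": OBSERVED, "seq": s}
                for i, s in enumerate(leaf_seqs)
            ],
        }],
    })


class TestResolveAmbiguities:
    @pytest.mark.parametrize("code,desc_bases,expected", [
        ("R", ["A", "A", "G"], "A"),   # majority among the denoted bases
        ("R", ["G", "G", "A"], "G"),
        ("Y", ["C", "T"], "C"),        # tie -> fixed order A < C < G < T
        ("K", ["T", "G"], "G"),
        ("B", ["T", "T", "G"], "T"),
    ])
    def test_majority_vote_with_fixed_tiebreak(self, code, desc_bases, expected):
        tree = _bp_tree(code + "AAA", [b + "AAA" for b in desc_bases])
        out = resolve_ambiguities(tree)
        bp = next(n for n in out.preorder() if n.kind == BP)
        assert bp.sequence[0] == expected
        assert bp.sequence[1:] == "AAA"

    def test_unambiguous_positions_unchanged(self):
        tree = _bp_tree("ACGT", ["ACGT", "ACGA"])
        out = resolve_ambiguities(tree)
        bp = next(n for n in out.preorder() if n.kind == BP)
        assert bp.sequence == "ACGT"

    def test_vote_uses_only_observed_descendants(self):
        # the UCA carries 'G' at the voted position but only leaves vote
        tree = _bp_tree("RAAA", ["AAAA", "AAAA"], uca_seq="GAAA")
        out = resolve_ambiguities(tree)
        bp = next(n for n in out.preorder() if n.kind == BP)
        assert bp.sequence[0] == "A"

    def test_no_supporting_descendant_writes_n(self, caplog):
        # code R denotes A/G but all descendants carry C
        tree = _bp_tree("RAAA", ["CAAA", "CAAA"])
        with caplog.at_level("WARNING"):
            out = resolve_ambiguities(tree)
        bp = next(n for n in out.preorder() if n.kind == BP)
        assert bp.sequence[0] == "N"
        assert any("no supporting" in r.message for r in caplog.records)

    def test_observed_and_uca_sequences_never_modified(self):
        tree = _bp_tree("YAAA", ["CAAA", "TAAA"], uca_seq="TAAA")
        out = resolve_ambiguities(tree)
        assert out.root.sequence == "TAAA"
        assert sorted(n.sequence for n in out.preorder() if n.kind == OBSERVED) \
            == ["CAAA", "TAAA"]

    def test_malformed_character_rejected_with_location(self):
        tree = _bp_tree("AZAA", ["AAAA", "AAAA"])
        with pytest.raises(ParseError, match="position 2.*BP@1"):
            resolve_ambiguities(tree)

    def test_idempotent_and_base_within_denoted_set(self, rng):
        for _ in range(30):
            code = rng.choice(list(IUPAC_AMBIGUITY))
            leaves = ["".join(rng.choice("ACGT") for _ in range(4)) for _ in range(3)]
            tree = _bp_tree(code + "ACG", leaves)
            once = resolve_ambiguities(tree)
            bp = next(n for n in once.preorder() if n.kind == BP)
            assert bp.sequence[0] in IUPAC_AMBIGUITY[code] + "N"
            assert not set(bp.sequence) & set(IUPAC_AMBIGUITY)
            twice = resolve_ambiguities(once)
            assert tree_canonical(twice) == tree_canonical(once)


class TestCollapseRedundantBps:
    def test_bp_identical_to_child_absorbs_child(self):
        tree = make_tree({
            "label": "UCA", "kind": UCA, "seq": "AAAA",
            "children": [{
                "label": "BP@1", "kind": BP, "seq": "ACAA",
                "children": [
                    {"label": "IgX", "kind": OBSERVED, "seq": "ACAA"},
                    {"label": "IgY", "kind": OBSERVED, "seq": "ACGA"},
                ],
            }],
        })
        out = collapse_redundant_bps(tree)
        labels = {n.label: n for n in out.preorder()}
        assert set(labels) == {"UCA", "IgX", "IgY"}
        merged = labels["IgX"]
        assert merged.kind == OBSERVED
        assert merged.members == ["IgX", "BP@1"]
        assert [out.nodes[c].label for c in out.children[merged.node_id]] == ["IgY"]

    def test_all_distinct_sequences_is_fixed_point(self):
        tree = _bp_tree("ACGG", ["ACGT", "ACGA"])
        out = collapse_redundant_bps(tree)
        assert len(out.nodes) == len(tree.nodes)
        assert tree_canonical(out) == tree_canonical(tree)

    def test_tie_merges_with_earliest_child(self):
        tree = make_tree({
            "label": "UCA", "kind": UCA, "seq": "AAAA",
            "children": [{
                "label": "BP@1", "kind": BP, "seq": "ACAA",
                "children": [
                    {"label": "IgA", "kind": OBSERVED, "seq": "ACAA"},
                    {"label": "IgB", "kind": OBSERVED, "seq": "ACAA"},
                ],
            }],
        })
        out = collapse_redundant_bps(tree)
        labels = {n.label: n for n in out.preorder()}
        assert labels["IgA"].members == ["IgA", "BP@1"]
        # the other identical child is now IgA's child (clustering is separate)
        assert [out.nodes[c].label for c in out.children[labels["IgA"].node_id]] == ["IgB"]

    def test_gap_and_case_insensitive_identity(self):
        tree = _bp_tree("ac-t", ["AC.T", "ACGT"])
        out = collapse_redundant_bps(tree)
        assert "BP@1" not in {n.label for n in out.preorder()}

    def test_n_matches_only_n(self):
        tree = _bp_tree("ACNT", ["ACGT", "ACAT"])
        out = collapse_redundant_bps(tree)
        assert "BP@1" in {n.label for n in out.preorder()}

    def test_cascading_merges_reach_fixed_point(self):
        tree = make_tree({
            "label": "UCA", "kind": UCA, "seq": "AAAA",
            "children": [{
                "label": "BP@1", "kind": BP, "seq": "ACGT",
                "children": [{
                    "label": "BP@2", "kind": BP, "seq": "ACGT",
                    "children": [
                        {"label": "IgX", "kind": OBSERVED, "seq": "ACGT"},
                        {"label": "IgY", "kind": OBSERVED, "seq": "TCGA"},
                    ],
                }],
            }],
        })
        out = collapse_redundant_bps(tree)
        labels = {n.label: n for n in out.preorder()}
        assert set(labels) == {"UCA", "IgX", "IgY"}
        assert labels["IgX"].members == ["IgX", "BP@2", "BP@1"]
        for node in out.preorder():
            if node.kind == BP:
                for cid in out.children[node.node_id]:
                    assert out.nodes[cid].sequence != node.sequence


class TestClusterIdenticalObserved:
    def test_identical_siblings_merge(self):
        tree = _bp_tree("ACGG", ["ACGT", "ACGT", "ACGA"])
        out = cluster_identical_observed(tree)
        leaves = [n for n in out.preorder() if n.kind == OBSERVED]
        merged = next(n for n in leaves if len(n.members) == 2)
        assert merged.members == ["Ig1", "Ig2"]
        assert len(leaves) == 2

    def test_identical_non_siblings_not_merged(self):
        tree = make_tree({
            "label": "UCA", "kind": UCA, "seq": "AAAA",
            "children": [
                {"label": "BP@1", "kind": BP, "seq": "ACAA",
                 "children": [{"label": "IgA", "kind": OBSERVED, "seq": "ACGT"},
                              {"label": "IgC", "kind": OBSERVED, "seq": "AGGT"}]},
                {"label": "IgB", "kind": OBSERVED, "seq": "ACGT"},
            ],
        })
        out = cluster_identical_observed(tree)
        assert {n.label for n in out.preorder()} == {"UCA", "BP@1", "IgA", "IgB", "IgC"}

    def test_all_unique_leaves_unchanged(self):
        tree = _bp_tree("ACGG", ["ACGT", "ACGA", "AGGA"])
        out = cluster_identical_observed(tree)
        assert tree_canonical(out) == tree_canonical(tree)


class TestValidateTree:
    def test_well_formed_tree_is_clean(self):
        assert validate_tree(_bp_tree("ACGG", ["ACGT", "ACGA"])) == []

    def test_sequence_length_mismatch_names_node(self):
        tree = _bp_tree("ACGG", ["ACGT", "ACGA"])
        next(n for n in tree.preorder() if n.label == "Ig1").sequence = "ACG"
        problems = validate_tree(tree)
        assert any("Ig1" in p and "length" in p for p in problems)

    def test_two_roots_reported(self):
        tree = _bp_tree("ACGG", ["ACGT", "ACGA"])
        orphan = LineageNode(node_id="x", label="Stray", kind=OBSERVED, sequence="ACGT")
        tree.nodes["x"] = orphan
        tree.children["x"] = []
        problems = validate_tree(tree)
        assert any("parentless" in p for p in problems)

    def test_duplicate_member_labels_reported(self):
        tree = _bp_tree("ACGG", ["ACGT", "ACGA"])
        next(n for n in tree.preorder() if n.label == "Ig2").members.append("Ig1")
        assert any("duplicate member" in p for p in validate_tree(tree))


class TestProcessingProperties:
    def test_idempotence_and_preservation_on_random_trees(self):
        rng = random.Random(7)
        for _ in range(60):
            tree = random_processing_tree(rng)
            before_obs = sorted(
                n.sequence.upper().replace(".", "-")
                for n in tree.preorder() if n.kind == OBSERVED
            )
            before_members = {m for n in tree.preorder() for m in n.members}
            out = cluster_identical_observed(collapse_redundant_bps(tree))
            # observed sequence multiset preserved, counting one copy per
            # observed (non-BP) member label of each observed node
            expanded = sorted(
                n.sequence.upper().replace(".", "-")
                for n in out.preorder() if n.kind == OBSERVED
                for m in n.members if m not in out.bp_tokens
            )
            assert expanded == before_obs
            after_members = {m for n in out.preorder() for m in n.members}
            assert after_members == before_members
            # idempotence
            again = cluster_identical_observed(collapse_redundant_bps(out))
            assert tree_canonical(again) == tree_canonical(out)
            # no BP still identical to a child
            for node in out.preorder():
                if node.kind == BP:
                    for cid in out.children[node.node_id]:
                        assert (node.sequence.upper().replace(".", "-")
                                != out.nodes[cid].sequence.upper().replace(".", "-"))

    def test_matches_naive_pairwise_oracle(self):
        rng = random.Random(11)
        for _ in range(80):
            tree = random_processing_tree(rng, max_nodes=12)
            ours = cluster_identical_observed(collapse_redundant_bps(tree))
            naive = naive_collapse_cluster(tree)
            assert tree_canonical(ours) == naive_canonical(naive)


class TestRenumbering:
    def test_bp_labels_assigned_preorder_and_stable(self):
        tree = make_tree({
            "label": "UCA", "kind": UCA, "seq": "AAAA",
            "children": [{
                "label": "BP@7", "kind": BP, "seq": "ACAA",
                "children": [
                    {"label": "BP@3", "kind": BP, "seq": "ACGA",
                     "children": [{"label": "Ig1", "kind": OBSERVED, "seq": "ACGG"},
                                  {"label": "Ig2", "kind": OBSERVED, "seq": "ACGC"}]},
                    {"label": "Ig3", "kind": OBSERVED, "seq": "ATAA"},
                ],
            }],
        })
        tree.bp_tokens = {"BP@7", "BP@3"}
        out = renumber_branch_points(tree.copy())
        labels = [n.label for n in out.preorder()]
        assert labels == ["UCA", "BP1", "BP2", "Ig1", "Ig2", "Ig3"]
        again = renumber_branch_points(out.copy())
        assert [n.label for n in again.preorder()] == labels

    def test_merged_bp_labels_also_renumbered(self):
        tree = make_tree({
            "label": "UCA", "kind": UCA, "seq": "AAAA",
            "children": [{
                "label": "BP@5", "kind": BP, "seq": "ACGT",
                "children": [{"label": "IgX", "kind": OBSERVED, "seq": "ACGT"},
                             {"label": "IgY", "kind": OBSERVED, "seq": "AGGT"}],
            }],
        })
        tree.bp_tokens = {"BP@5"}
        out = renumber_branch_points(collapse_redundant_bps(tree))
        merged = next(n for n in out.preorder() if n.label == "IgX")
        assert merged.members == ["IgX", "BP1"]
        assert out.bp_tokens == {"BP1"}

    def test_full_processing_clean(self):
        tree = _bp_tree("RCGT", ["ACGT", "ACGT", "GCGA"])
        out = process_tree(tree)
        assert validate_tree(out) == []
        for node in out.preorder():
            assert not set(node.sequence) & set(IUPAC_AMBIGUITY)
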