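"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import random

import pytest

from iglineage.model import BP, OBSERVED, UCA, LineageNode, LineageTree
from iglineage.simulate import leafset_index


def make_tree(spec: dict, alignment_length: int | None = None) -> LineageTree:
    """Build a LineageTree from a nested dict.

    ``spec`` = {"label": ..., "kind": ..., "seq": ..., "children": [...]}.
    Node ids are derived from labels.
    """
    if alignment_length is None:
        alignment_length = len(spec["seq"])
    tree = LineageTree(alignment_length=alignment_length)

    def add(d: dict, parent_id: str | None) -> None:
        node = LineageNode(
            node_id="id_" + d["label"], label=d["label"], kind=d["kind"],
            sequence=d["seq"], members=list(d.get("members", [])),
            ec50=d.get("ec50"), comment=d.get("comment", ""),
        )
        tree.add_node(node, parent_id=parent_id)
        for child in d.get("children", []):
            add(child, node.node_id)

    add(spec, None)
    return tree


def random_processing_tree(rng: random.Random, max_nodes: int = 12) -> LineageTree:
    """Random small lineage tree engineered to exercise collapse/cluster.

    Sequences are drawn from a tiny space so identical BP/child and identical
    sibling-leaf sequences are frequent; gap characters and case are mixed to
    exercise normalization.
    """
    L = 6
    alphabet = "ACGT"

    def rand_seq() -> str:
        chars = [rng.choice(alphabet) for _ in range(L)]
        if rng.random() < 0.3:
            chars[rng.randrange(L)] = rng.choice(".-")
        if rng.random() < 0.3:
            i = rng.randrange(L)
            chars[i] = chars[i].lower()
        return "".join(chars)

    tree = LineageTree(alignment_length=L)
    tree.add_node(LineageNode(node_id="root", label="UCA", kind=UCA, sequence=rand_seq()))
    n_nodes = rng.randint(2, max_nodes)
    internals = ["root"]
    leaf_no = bp_no = 0
    for _ in range(n_nodes - 1):
        parent = rng.choice(internals)
        if rng.random() < 0.4:
            bp_no += 1
            node = LineageNode(
                node_id=f"b{bp_no}", label=f"BP@{bp_no}", kind=BP, sequence=rand_seq()
            )
            internals.append(node.node_id)
        else:
            leaf_no += 1
            node = LineageNode(
                node_id=f"l{leaf_no}", label=f"Ig{leaf_no}", kind=OBSERVED,
                sequence=rand_seq(),
            )
        tree.add_node(node, parent_id=parent)
    # force some BP == child coincidences and duplicate sibling leaves
    for node in list(tree.preorder()):
        kids = tree.children[node.node_id]
        if node.kind == BP and kids and rng.random() < 0.5:
            node.sequence = tree.nodes[rng.choice(kids)].sequence
        leaf_kids = [k for k in kids if tree.nodes[k].kind == OBSERVED and not tree.children[k]]
        if len(leaf_kids) >= 2 and rng.random() < 0.5:
            a, b = rng.sample(leaf_kids, 2)
            tree.nodes[b].sequence = tree.nodes[a].sequence
    # drop childless BPs (they are not meaningful lineage trees)
    changed = True
    while changed:
        changed = False
        for node in list(tree.preorder()):
            if node.kind == BP and not tree.children[node.node_id]:
                pid = tree.parent[node.node_id]
                tree.children[pid].remove(node.node_id)
                del tree.children[node.node_id]
                del tree.parent[node.node_id]
                del tree.nodes[node.node_id]
                changed = True
    return tree


# ---------------------------------------------------------------------------
# naive O(n^2) oracle for collapse + cluster (independent implementation)
# ---------------------------------------------------------------------------

def _norm(seq: str) -> str:
    return seq.upper().replace(".", "-")


def naive_collapse_cluster(tree: LineageTree) -> dict:
    """Brute-force reference for collapse + cluster on a plain-dict tree.

    Repeatedly scans every BP/child pair (collapse, earliest child wins) and
    then every identical observed sibling-leaf pair, merging one pair per
    scan, until no pair remains.  Returns the plain-dict forest keyed by id.
    """
    nodes = {
        n.node_id: {
            "kind": n.kind, "label": n.label, "seq": n.sequence,
            "members": list(n.members),
            "children": list(tree.children[n.node_id]),
        }
        for n in tree.preorder()
    }
    root = tree.root_id

    def parent_of(nid):
        for pid, d in nodes.items():
            if nid in d["children"]:
                return pid
        return None

    merged = True
    while merged:
        merged = False
        for nid in sorted(nodes):
            d = nodes[nid]
            if d["kind"] != BP:
                continue
            for cid in d["children"]:
                if _norm(nodes[cid]["seq"]) == _norm(d["seq"]):
                    c = nodes[cid]
                    i = d["children"].index(cid)
                    d["children"] = d["children"][:i] + c["children"] + d["children"][i + 1:]
                    d["members"] = c["members"] + d["members"]
                    d["label"], d["kind"], d["seq"] = c["label"], c["kind"], c["seq"]
                    del nodes[cid]
                    merged = True
                    break
            if merged:
                break
    merged = True
    while merged:
        merged = False
        for nid in sorted(nodes):
            kids = nodes[nid]["children"]
            leaves = [k for k in kids if nodes[k]["kind"] == OBSERVED and not nodes[k]["children"]]
            for i in range(len(leaves)):
                for j in range(i + 1, len(leaves)):
                    a, b = leaves[i], leaves[j]
                    if _norm(nodes[a]["seq"]) == _norm(nodes[b]["seq"]):
                        nodes[a]["members"] = nodes[a]["members"] + nodes[b]["members"]
                        kids.remove(b)
                        del nodes[b]
                        merged = True
                        break
                if merged:
                    break
            if merged:
                break
    return {"nodes": nodes, "root": root}


def naive_canonical(forest: dict) -> str:
    nodes, root = forest["nodes"], forest["root"]

    def canon(nid: str) -> str:
        kids = sorted(canon(c) for c in nodes[nid]["children"])
        d = nodes[nid]
        return (
            f"({','.join(kids)})"
            f"{_norm(d['seq'])}|{d['kind']}|{sorted(d['members'])}"
        )

    return canon(root)


def tree_canonical(tree: LineageTree) -> str:
    def canon(nid: str) -> str:
        kids = sorted(canon(c) for c in tree.children[nid])
        n = tree.nodes[nid]
        return (
            f"({','.join(kids)})"
            f"{_norm(n.sequence)}|{n.kind}|{sorted(n.members)}"
        )

    return canon(tree.root_id)


# ---------------------------------------------------------------------------
# ground-truth event matching (edges identified by descendant leaf sets)
# ---------------------------------------------------------------------------

def events_by_leafset(gt_tree: LineageTree, gt) -> dict:
    index = leafset_index(gt_tree)
    child_to_leafset = {cid: ls for ls, (_, cid) in index.items()}
    label_to_id = {n.label: n.node_id for n in gt_tree.preorder()}
    return {
        child_to_leafset[label_to_id[c]]: evs
        for (_, c), evs in gt.events.items()
    }


def assert_events_match(processed: LineageTree, gt_tree: LineageTree, gt) -> None:
    expected = events_by_leafset(gt_tree, gt)
    got = leafset_index(processed)
    assert set(got) == set(expected)
    for ls, (pid, cid) in got.items():
        ann = processed.edge_annotations[(pid, cid)]
        assert list(ann.events) == list(expected[ls])


@pytest.fixture
def rng():
    return random.Random(20240901)
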