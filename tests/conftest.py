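"""Shared fixtures: random trees, the synthetic reference package, oracles."""

from __future__ import annotations

import random

import pytest

from taxoplace.io import RefTree
from taxoplace.red import compute_red, rank_medians
from taxoplace.synth import FixtureSpec, gen_reference


def random_tree(rng: random.Random, n_leaves: int,
                max_length: float = 2.0, decorate: bool = False) -> RefTree:
    """A random rooted binary tree built by successive leaf bisections."""
    assert n_leaves >= 2
    tree = RefTree()
    tree.add_node("R")
    counter = [0]

    def new_internal() -> str:
        counter[0] += 1
        return f"I{counter[0]}"

    def length() -> float:
        return rng.uniform(0.01, max_length)

    from taxoplace.io import Node

    leaves = []
    for name in ("L0", "L1"):
        tree.add_node(name, parent="R", length=length())
        leaves.append(name)
    for i in range(2, n_leaves):
        # splice a new junction into a random terminal edge and hang a leaf
        host = rng.choice(leaves)
        node = tree.nodes[host]
        junction = new_internal()
        parent = node.parent
        split = rng.uniform(0, node.length)
        siblings = tree.nodes[parent].children
        siblings[siblings.index(host)] = junction
        tree.nodes[junction] = Node(id=junction, parent=parent,
                                    length=node.length - split,
                                    children=[host])
        node.parent = junction
        node.length = split
        leaf = f"L{i}"
        tree.nodes[junction].children.append(leaf)
        tree.nodes[leaf] = Node(id=leaf, parent=junction, length=length())
        leaves.append(leaf)
    if decorate:
        codes = "pcofg"
        for nd in list(tree.preorder()):
            if nd.is_leaf or nd.parent is None:
                continue
            if rng.random() < 0.4:
                depth = len(tree.path_to_root(nd.id))
                code = codes[min(depth - 1, len(codes) - 1)]
                nd.taxa = (f"{code}__T{nd.id}",)
            if rng.random() < 0.5:
                nd.support = round(rng.uniform(0, 100), 1)
    tree.validate()
    return tree


def red_oracle(tree: RefTree) -> dict[str, float]:
    """Brute-force RED by explicit path enumeration (independent of compute_red)."""

    def leaves_below(node_id: str) -> list[str]:
        nd = tree.nodes[node_id]
        if nd.is_leaf:
            return [node_id]
        out = []
        for c in nd.children:
            out.extend(leaves_below(c))
        return out

    def path_length(ancestor: str, descendant: str) -> float:
        total = 0.0
        nid = descendant
        while nid != ancestor:
            nd = tree.nodes[nid]
            total += nd.length
            nid = nd.parent
        return total

    red = {tree.root_id: 0.0}

    def walk(node_id: str) -> None:
        for cid in tree.nodes[node_id].children:
            child = tree.nodes[cid]
            if child.is_leaf:
                red[cid] = 1.0
            else:
                d = child.length
                below = leaves_below(cid)
                u = sum(path_length(node_id, leaf) for leaf in below) / len(below)
                p = red[node_id]
                red[cid] = p if u == 0 else p + (d / u) * (1.0 - p)
            walk(cid)

    walk(tree.root_id)
    return red


@pytest.fixture(scope="session")
def reference():
    return gen_reference(FixtureSpec(seed=7))


@pytest.fixture(scope="session")
def redmap(reference):
    return compute_red(reference.tree)


@pytest.fixture(scope="session")
def medians(reference, redmap):
    return rank_medians(reference.tree, redmap)
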