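"""Relative evolutionary divergence (RED).

RED maps every node of a rooted tree onto [0, 1]: 0 at the root, 1 at every
leaf.  For an internal node ``n`` with parent ``p``,

    red(n) = red(p) + (d / u) * (1 - red(p))

where ``d`` is the branch length from ``p`` to ``n`` and ``u`` is the mean
path length from ``p`` to the leaves descended through ``n`` (i.e. ``d``
plus the mean leaf depth below ``n``).  Because ``d <= u``, RED is
non-decreasing along every root-to-leaf path, and because it only depends
on the ratio ``d/u`` it is invariant under global branch-length rescaling.
"""

from __future__ import annotations

from pathlib import Path
from statistics import median
from typing import Mapping, Optional

from .errors import ValidationError
from .io import Placement, RefTree, rank_index

#: ranks that receive a median RED (species are handled by ANI, not RED)
MEDIAN_RANKS = "pcofg"


def compute_red(tree: RefTree) -> dict[str, float]:
    """Per-node RED for a rooted tree with complete branch lengths."""
    tree.validate()
    leaves = tree.leaves()
    if len(leaves) < 2:
        raise ValidationError("RED needs a rooted tree with >= 2 leaves")

    # postorder: mean distance from each node down to its leaves
    mean_to_leaf: dict[str, float] = {}
    n_leaves: dict[str, int] = {}
    for nd in tree.postorder():
        if nd.is_leaf:
            mean_to_leaf[nd.id] = 0.0
            n_leaves[nd.id] = 1
        else:
            total = 0.0
            count = 0
            for cid in nd.children:
                child = tree.nodes[cid]
                count += n_leaves[cid]
                total += n_leaves[cid] * (mean_to_leaf[cid] + child.length)
            mean_to_leaf[nd.id] = total / count
            n_leaves[nd.id] = count

    red: dict[str, float] = {}
    for nd in tree.preorder():
        if nd.parent is None:
            red[nd.id] = 0.0
        elif nd.is_leaf:
            red[nd.id] = 1.0
        else:
            p = red[nd.parent]
            d = nd.length
            u = d + mean_to_leaf[nd.id]
            red[nd.id] = p if u == 0 else p + (d / u) * (1.0 - p)
    return red


def rank_medians(tree: RefTree, redmap: Mapping[str, float]) -> dict[str, float]:
    """Median RED per rank (p, c, o, f, g) over labeled internal nodes.

    Ranks without any labeled internal node are absent from the result.
    """
    by_rank: dict[str, list[float]] = {}
    for nd in tree.preorder():
        if nd.is_leaf:
            continue
        for lab in nd.taxa:
            code = lab[0]
            if code in MEDIAN_RANKS:
                by_rank.setdefault(code, []).append(redmap[nd.id])
    return {code: median(vals) for code, vals in by_rank.items()}


def red_at_placement(tree: RefTree, redmap: Mapping[str, float],
                     placement: Placement) -> float:
    """RED of an attachment point, linearly interpolated along the host edge.

    The pendant branch does not contribute: the query must be comparable to
    reference nodes whose RED ignores it.
    """
    child = tree.node(placement.edge_id)
    if child.parent is None:
        raise ValidationError("cannot place on the root node")
    edge_len = child.length or 0.0
    if placement.distal_length > edge_len:
        raise ValidationError(
            f"distal_length {placement.distal_length} exceeds edge length {edge_len}")
    red_p = redmap[child.parent]
    if edge_len == 0:
        return red_p
    frac = placement.distal_length / edge_len
    return red_p + frac * (redmap[child.id] - red_p)


def write_red_table(tree: RefTree, redmap: Mapping[str, float], path) -> None:
    """Debug dump: node_id, red, semicolon-joined taxa."""
    with open(path, "w") as fh:
        fh.write("node_id\tred\ttaxa\n")
        for nd in tree.preorder():
            fh.write(f"{nd.id}\t{redmap[nd.id]:.10f}\t{';'.join(nd.taxa)}\n")


def rank_index_of_code(code: str) -> int:
    """Rank position for a one-letter rank code (d=0 ... s=6)."""
    return rank_index(code + "__x")
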