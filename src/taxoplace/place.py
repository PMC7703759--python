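"""Attach a query to the reference tree.

Two routes: ingest an external jplace placement (see :mod:`taxoplace.io`)
or fall back to a naive placer that drops the query on the terminal edge of
the nearest reference leaf by normalized Hamming distance over the masked
concatenated alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .errors import ValidationError
from .io import Placement, RefTree

GAP = "-"

#: queries with fewer non-gap columns than this fraction get a warning
MIN_NONGAP_FRACTION = 0.10


@dataclass(frozen=True)
class AlignedQuery:
    """One genome's masked, concatenated alignment row."""

    genome_id: str
    row: str

    def nongap_fraction(self) -> float:
        if not self.row:
            return 0.0
        return 1.0 - self.row.count(GAP) / len(self.row)


def pairwise_distance(a: str, b: str) -> tuple[float, int]:
    """Normalized Hamming distance with pairwise gap deletion.

    Returns (p-distance, number of comparable columns); columns where either
    row has a gap are ignored.
    """
    if len(a) != len(b):
        raise ValidationError(f"row width mismatch: {len(a)} vs {len(b)}")
    compared = 0
    mismatches = 0
    for x, y in zip(a, b):
        if x == GAP or y == GAP:
            continue
        compared += 1
        if x != y:
            mismatches += 1
    if compared == 0:
        return 1.0, 0
    return mismatches / compared, compared


def naive_place(query: AlignedQuery, ref_alignment: Mapping[str, str],
                tree: RefTree) -> tuple[Placement, list[str]]:
    """Place a query on the terminal edge of its nearest reference leaf.

    Distance is per-site p-distance with pairwise gap deletion; ties are
    broken by lexicographically smallest leaf id (with a warning).  Returns
    the placement (distal = full edge length, pendant = p-distance) plus any
    warnings raised along the way.
    """
    if len(ref_alignment) < 2:
        raise ValidationError("need at least 2 reference rows")
    warnings: list[str] = []
    if query.nongap_fraction() == 0.0:
        raise ValidationError(f"query {query.genome_id} is all gaps")
    if query.nongap_fraction() < MIN_NONGAP_FRACTION:
        warnings.append(
            f"low-quality alignment: only {query.nongap_fraction():.1%} non-gap columns")

    best_leaf = None
    best_dist = None
    tied = False
    for leaf_id in sorted(ref_alignment):
        dist, compared = pairwise_distance(query.row, ref_alignment[leaf_id])
        if compared == 0:
            continue
        if best_dist is None or dist < best_dist:
            best_leaf, best_dist, tied = leaf_id, dist, False
        elif dist == best_dist:
            tied = True  # current best is lexicographically smaller; keep it
    if best_leaf is None:
        raise ValidationError(
            f"query {query.genome_id} shares no non-gap columns with any reference")
    if tied:
        warnings.append(f"distance tie broken to leaf {best_leaf}")

    leaf = tree.node(best_leaf)
    if leaf.parent is None or not leaf.is_leaf:
        raise ValidationError(f"{best_leaf!r} is not a leaf of the tree")
    placement = Placement(edge_id=best_leaf, distal_length=leaf.length or 0.0,
                          pendant_length=best_dist)
    return placement, warnings


def graft(tree: RefTree, query_id: str, placement: Placement) -> RefTree:
    """Return a new tree with the query attached at the placement point.

    The host edge is split at ``distal_length`` from its parent end; the
    query hangs off the new junction by ``pendant_length``.  Original node
    ids are preserved; the junction is named ``__graft_<query_id>``.
    """
    if query_id in tree.nodes:
        raise ValidationError(f"query id {query_id!r} collides with a tree node")
    child = tree.node(placement.edge_id)
    if child.parent is None:
        raise ValidationError("cannot graft onto the root")
    edge_len = child.length or 0.0
    if placement.distal_length > edge_len:
        raise ValidationError(
            f"distal_length {placement.distal_length} exceeds edge length {edge_len}")

    out = tree.copy()
    junction_id = f"__graft_{query_id}"
    if junction_id in out.nodes:
        raise ValidationError(f"junction id {junction_id!r} already present")

    parent_id = child.parent
    parent = out.nodes[parent_id]
    pos = parent.children.index(placement.edge_id)

    from .io import Node  # local import to keep module surfaces tidy

    junction = Node(id=junction_id, parent=parent_id,
                    length=placement.distal_length,
                    children=[placement.edge_id, query_id])
    out.nodes[junction_id] = junction
    parent.children[pos] = junction_id

    host_child = out.nodes[placement.edge_id]
    host_child.parent = junction_id
    host_child.length = edge_len - placement.distal_length

    out.nodes[query_id] = Node(id=query_id, parent=junction_id,
                               length=placement.pendant_length)
    return out
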