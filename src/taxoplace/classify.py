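"""The classification decision engine.

Combines, in order of precedence: ANI species assignment against the
representatives of the candidate genus; the topology of the attachment
point (ancestor and descendant taxon labels); and nearest-median RED to
resolve rank windows that topology alone leaves ambiguous.  The query's
novel rank (if any) is reported as a warning, never as an invented name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .ani import (DEFAULT_AF_THRESHOLD, ANIResult, SpeciesRadius, best_hit,
                  species_assign)
from .errors import ValidationError
from .io import (METHOD_ANI, METHOD_RED, METHOD_TOPOLOGY, N_RANKS,
                 RANK_CODES, RANK_NAMES, ClassificationResult, Placement,
                 RefTree, TaxonomyString, rank_index)
from .place import graft
from .red import red_at_placement


@dataclass
class DecisionContext:
    """Everything the rank decision needs, bundled for tracing."""

    grafted: RefTree
    query_id: str
    junction_id: str
    host_child_id: str
    query_red: float
    ancestors: TaxonomyString
    medians: Mapping[str, float]
    ani_results: Sequence[ANIResult] = ()
    radii: Mapping[str, SpeciesRadius] = field(default_factory=dict)


def ancestor_taxonomy(grafted: RefTree, query_id: str) -> TaxonomyString:
    """Union of taxon labels on the path root -> attachment junction.

    Conflicting labels at one rank raise a validation error (the reference
    tree would be internally inconsistent).
    """
    leaf = grafted.node(query_id)
    if leaf.parent is None:
        raise ValidationError("query leaf has no parent; not grafted?")
    labels: list[str] = []
    for nd in grafted.path_to_root(leaf.parent):
        labels.extend(nd.taxa)
    return TaxonomyString.from_labels(labels)


def make_context(tree: RefTree, redmap: Mapping[str, float],
                 medians: Mapping[str, float], placement: Placement,
                 query_id: str,
                 ani_results: Sequence[ANIResult] = (),
                 radii: Optional[Mapping[str, SpeciesRadius]] = None,
                 ) -> DecisionContext:
    """Graft the query and collect the ancestor/RED evidence."""
    query_red = red_at_placement(tree, redmap, placement)
    grafted = graft(tree, query_id, placement)
    junction_id = grafted.node(query_id).parent
    junction = grafted.node(junction_id)
    host_child_id = next(c for c in junction.children if c != query_id)
    ancestors = ancestor_taxonomy(grafted, query_id)
    return DecisionContext(
        grafted=grafted, query_id=query_id, junction_id=junction_id,
        host_child_id=host_child_id, query_red=query_red,
        ancestors=ancestors, medians=medians,
        ani_results=tuple(ani_results), radii=radii or {})


def candidate_ranks(context: DecisionContext) -> list[int]:
    """The contiguous window of ranks the query's own taxon could occupy.

    The window starts strictly below the deepest ancestor-labeled rank.  If
    the node on the descendant side of the attachment is itself labeled, the
    query may alternatively fall just inside that taxon, extending the
    window one rank below the node's deepest label; otherwise topology
    forces a single rank.
    """
    lo = context.ancestors.deepest_rank() + 1
    if lo >= N_RANKS:
        raise ValidationError("attachment below a species-labeled path")
    host = context.grafted.node(context.host_child_id)
    if host.taxa:
        hi = min(max(rank_index(t) for t in host.taxa) + 1, N_RANKS - 1)
        if hi < lo:
            raise ValidationError(
                f"descendant labels above ancestor labels at {host.id!r}")
    else:
        hi = lo
    return list(range(lo, hi + 1))


def nearest_median_rank(window: Sequence[int], query_red: float,
                        medians: Mapping[str, float],
                        ) -> tuple[int, list[str]]:
    """Rank in the window whose median RED is closest to the query's RED.

    Ties and ranks without a median fall back toward the more inclusive
    rank, with warnings; under-classifying is the conservative failure mode.
    """
    warnings: list[str] = []
    scored: list[tuple[float, int]] = []
    for rank in window:
        code = RANK_CODES[rank]
        if code in medians:
            scored.append((abs(query_red - medians[code]), rank))
        else:
            warnings.append(f"no median RED for rank {RANK_NAMES[rank]}; "
                            "excluded from RED resolution")
    if not scored:
        best = min(window)
        warnings.append(
            f"no rank medians available; defaulting to {RANK_NAMES[best]}")
        return best, warnings
    best_dist = min(d for d, _ in scored)
    best_ranks = [r for d, r in scored if d == best_dist]
    if len(best_ranks) > 1:
        warnings.append("RED tie; choosing the more inclusive rank")
    return min(best_ranks), warnings


def resolve_by_red(context: DecisionContext) -> tuple[int, list[str]]:
    """Resolve an ambiguous candidate window by nearest-median RED."""
    window = candidate_ranks(context)
    if len(window) < 2:
        raise ValidationError("resolve_by_red needs a window of size >= 2")
    return nearest_median_rank(window, context.query_red, context.medians)


def ani_candidate_genomes(tree: RefTree, radii: Mapping[str, SpeciesRadius],
                          placement: Placement) -> list[str]:
    """Representative genomes of the genus the attachment lies in or beside.

    The candidate genus is the ancestor genus when the attachment path has
    one; otherwise the single genus labeled in the descendant clade of the
    host edge.  Attachments not adjacent to exactly one genus yield no
    candidates (ANI is then not attempted).
    """
    host = tree.node(placement.edge_id)
    genus_node: Optional[str] = None
    nid = host.parent
    for nd in tree.path_to_root(nid) if nid else []:
        if any(t.startswith("g__") for t in nd.taxa):
            genus_node = nd.id
            break
    if genus_node is None:
        genus_nodes = []
        stack = [host.id]
        while stack:
            nd = tree.node(stack.pop())
            if any(t.startswith("g__") for t in nd.taxa):
                genus_nodes.append(nd.id)
            stack.extend(nd.children)
        if len(genus_nodes) == 1:
            genus_node = genus_nodes[0]
    if genus_node is None:
        return []
    reps = {r.representative_genome for r in radii.values()}
    out = []
    stack = [genus_node]
    while stack:
        nd = tree.node(stack.pop())
        if nd.is_leaf and nd.id in reps:
            out.append(nd.id)
        stack.extend(nd.children)
    return sorted(out)


def _lineage_through_species(tree: RefTree, radius: SpeciesRadius,
                             ) -> TaxonomyString:
    """Full taxonomy of a species: its representative's path labels + s__."""
    labels: list[str] = [radius.species_name]
    for nd in tree.path_to_root(radius.representative_genome):
        labels.extend(nd.taxa)
    return TaxonomyString.from_labels(labels)


def classify_query(tree: RefTree, redmap: Mapping[str, float],
                   medians: Mapping[str, float], placement: Placement,
                   ani_results: Sequence[ANIResult],
                   radii: Mapping[str, SpeciesRadius], query_id: str,
                   af_threshold: float = DEFAULT_AF_THRESHOLD,
                   ) -> ClassificationResult:
    """Assign a rank-normalized taxonomy to one placed query genome.

    Precedence: (1) ANI species assignment; (2) topology when the candidate
    rank window has a single rank; (3) nearest-median RED otherwise.  Every
    query yields a result.
    """
    context = make_context(tree, redmap, medians, placement, query_id,
                           ani_results=ani_results, radii=radii)
    warnings: list[str] = []

    species = species_assign(ani_results, radii, af_threshold)
    if species is not None:
        radius = radii[species]
        hit = next(r for r in ani_results
                   if r.reference_id == radius.representative_genome)
        return ClassificationResult(
            genome_id=query_id,
            taxonomy=_lineage_through_species(tree, radius),
            method=METHOD_ANI,
            closest_reference=radius.representative_genome,
            ani_pct=hit.ani_pct,
            align_frac=hit.align_frac,
            red_value=context.query_red,
            warnings=warnings,
        )

    window = candidate_ranks(context)
    if len(window) == 1:
        novel_rank = window[0]
        method = METHOD_TOPOLOGY
    else:
        novel_rank, red_warnings = nearest_median_rank(
            window, context.query_red, context.medians)
        warnings.extend(red_warnings)
        method = METHOD_RED

    host = context.grafted.node(context.host_child_id)
    labels = [t for t in
              list(_iter_names(context.ancestors)) + list(host.taxa)
              if rank_index(t) < novel_rank]
    taxonomy = TaxonomyString.from_labels(labels)
    warnings.append(f"novel {RANK_NAMES[novel_rank]}")

    hit = best_hit(ani_results, af_threshold)
    if hit is None and ani_results:
        with_ani = [r for r in ani_results if r.ani_pct is not None]
        hit = max(with_ani, key=lambda r: (r.ani_pct, r.reference_id),
                  default=None)
    return ClassificationResult(
        genome_id=query_id,
        taxonomy=taxonomy,
        method=method,
        closest_reference=hit.reference_id if hit else None,
        ani_pct=hit.ani_pct if hit else None,
        align_frac=hit.align_frac if hit else None,
        red_value=context.query_red,
        warnings=warnings,
    )


def _iter_names(taxonomy: TaxonomyString):
    return (n for n in taxonomy.names if n)


def classify_with_ani(tree: RefTree, redmap: Mapping[str, float],
                      medians: Mapping[str, float], placement: Placement,
                      radii: Mapping[str, SpeciesRadius], query_id: str,
                      query_seqs, ref_genome_lookup,
                      af_threshold: float = DEFAULT_AF_THRESHOLD,
                      **ani_kwargs) -> ClassificationResult:
    """Convenience orchestrator: run ANI against the candidate genus, then
    classify.  ``ref_genome_lookup`` maps a representative genome id to its
    sequence set."""
    from .ani import fragment_ani

    candidates = ani_candidate_genomes(tree, radii, placement)
    ani_results = [
        fragment_ani(query_seqs, ref_genome_lookup(rep), reference_id=rep,
                     **ani_kwargs)
        for rep in candidates]
    return classify_query(tree, redmap, medians, placement, ani_results,
                          radii, query_id, af_threshold=af_threshold)
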