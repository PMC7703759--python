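import pytest

from taxoplace.ani import ANIResult, SpeciesRadius
from taxoplace.classify import (ancestor_taxonomy, ani_candidate_genomes,
                                candidate_ranks, classify_query, make_context,
                                nearest_median_rank, resolve_by_red)
from taxoplace.errors import ValidationError
from taxoplace.io import Placement, parse_newick
from taxoplace.place import graft
from taxoplace.red import compute_red, rank_medians
from taxoplace.synth import gen_query


def _tree_and_red(text):
    tree = parse_newick(text)
    return tree, compute_red(tree)


@pytest.fixture()
def genus_tree():
    # family with two genera of two species each; species live in the radii map
    text = ("(((A:2,B:2)'g__Escherichia':2,(C:2,D:2)'g__Salmonella':2)"
            "'f__Enterobacteriaceae':2,(E:4,F:4)'f__Other':2)"
            "'d__B;p__P;c__C;o__Enterobacterales';")
    return _tree_and_red(text)


RADII = {
    "s__Escherichia coli": SpeciesRadius("s__Escherichia coli", "A", 95.0),
    "s__Escherichia albertii": SpeciesRadius("s__Escherichia albertii", "B", 95.0),
    "s__Salmonella enterica": SpeciesRadius("s__Salmonella enterica", "C", 95.0),
}


class TestAncestorTaxonomy:
    def test_inside_genus(self, genus_tree):
        tree, _ = genus_tree
        grafted = graft(tree, "q", Placement("A", 1.0, 0.1))
        tax = ancestor_taxonomy(grafted, "q")
        assert tax.names[3] == "o__Enterobacterales"
        assert tax.names[4] == "f__Enterobacteriaceae"
        assert tax.names[5] == "g__Escherichia"
        assert tax.names[6] == ""

    def test_basal_attachment_only_upper_ranks(self, genus_tree):
        tree, _ = genus_tree
        fam = next(nid for nid, nd in tree.nodes.items()
                   if "f__Enterobacteriaceae" in nd.taxa)
        grafted = graft(tree, "q", Placement(fam, 1.0, 0.1))
        tax = ancestor_taxonomy(grafted, "q")
        assert tax.names[3] == "o__Enterobacterales"
        assert tax.names[4] == ""

    def test_conflicting_labels_rejected(self):
        tree = parse_newick(
            "(((A:1,B:1)'g__X':1)'g__Y':1,(C:2,D:2)'g__Z':1)"
            "'d__B;p__P;c__C;o__O;f__F';")
        grafted = graft(tree, "q", Placement("A", 0.5, 0.1))
        with pytest.raises(ValidationError):
            ancestor_taxonomy(grafted, "q")


class TestCandidateRanks:
    def test_basal_to_all_phyla_forces_phylum(self):
        # attachment above an unlabeled node grouping two phyla (Fig-1a shape)
        tree, red = _tree_and_red(
            "(((A:1,B:1)'p__P1':1,(C:1,D:1)'p__P2':1):1,(E:2,F:2)'p__P3':1)'d__B';")
        hub = next(nid for nid, nd in tree.nodes.items()
                   if not nd.is_leaf and not nd.taxa and nd.parent is not None)
        ctx = make_context(tree, red, {}, Placement(hub, 0.5, 0.1), "q")
        assert candidate_ranks(ctx) == [1]  # phylum only

    def test_adjacent_genus_window(self, genus_tree):
        # family ancestor + genus descendant: novel genus or basal species
        tree, red = genus_tree
        genus = next(nid for nid, nd in tree.nodes.items()
                     if "g__Escherichia" in nd.taxa)
        ctx = make_context(tree, red, {}, Placement(genus, 1.0, 0.1), "q")
        assert candidate_ranks(ctx) == [5, 6]  # genus, species

    def test_stacked_labels_widen_window(self):
        # sole class in its phylum: both labels on one node (Fig-1d shape)
        tree, red = _tree_and_red(
            "(((A:2,B:2)'o__O1':2,(C:2,D:2)'o__O2':2)"
            "'p__Aerophobetota;c__Aerophobia':2,(E:4,F:4)'p__Other':2)'d__B';")
        stacked = next(nid for nid, nd in tree.nodes.items()
                       if "c__Aerophobia" in nd.taxa)
        ctx = make_context(tree, red, {}, Placement(stacked, 1.0, 0.1), "q")
        assert candidate_ranks(ctx) == [1, 2, 3]  # phylum, class, order

    def test_terminal_edge_inside_genus(self, genus_tree):
        tree, red = genus_tree
        ctx = make_context(tree, red, {}, Placement("A", 1.0, 0.1), "q")
        assert candidate_ranks(ctx) == [6]  # species only


class TestNearestMedianRank:
    def test_nearest_median_exhaustive(self):
        # oracle: exhaustive comparison over the window
        medians = {"c": 0.45, "o": 0.62}
        rank, warnings = nearest_median_rank([2, 3], 0.60, medians)
        assert rank == 3  # order
        assert warnings == []
        assert abs(0.60 - medians["o"]) < abs(0.60 - medians["c"])

    def test_exact_midpoint_ties_to_inclusive(self):
        medians = {"c": 0.4, "o": 0.6}
        rank, warnings = nearest_median_rank([2, 3], 0.5, medians)
        assert rank == 2  # class, the more inclusive
        assert any("tie" in w.lower() for w in warnings)

    def test_below_lowest_median(self):
        medians = {"p": 0.3, "c": 0.45, "o": 0.62}
        rank, _ = nearest_median_rank([1, 2, 3], 0.2, medians)
        assert rank == 1  # phylum

    def test_missing_median_excluded_with_warning(self):
        medians = {"g": 0.9}
        rank, warnings = nearest_median_rank([5, 6], 0.97, medians)
        assert rank == 5
        assert any("no median" in w for w in warnings)

    def test_all_missing_falls_back_inclusive(self):
        rank, warnings = nearest_median_rank([2, 3], 0.5, {})
        assert rank == 2
        assert any("defaulting" in w for w in warnings)

    def test_resolve_by_red_requires_window(self, genus_tree):
        tree, red = genus_tree
        ctx = make_context(tree, red, {}, Placement("A", 1.0, 0.1), "q")
        with pytest.raises(ValidationError):
            resolve_by_red(ctx)


class TestAniCandidates:
    def test_ancestor_genus(self, genus_tree):
        tree, _ = genus_tree
        assert ani_candidate_genomes(tree, RADII, Placement("A", 1.0, 0.1)) == \
            ["A", "B"]

    def test_sibling_genus(self, genus_tree):
        tree, _ = genus_tree
        genus = next(nid for nid, nd in tree.nodes.items()
                     if "g__Salmonella" in nd.taxa)
        assert ani_candidate_genomes(tree, RADII, Placement(genus, 1.0, 0.1)) == \
            ["C"]

    def test_multi_genus_clade_gives_none(self, genus_tree):
        tree, _ = genus_tree
        fam = next(nid for nid, nd in tree.nodes.items()
                   if "f__Enterobacteriaceae" in nd.taxa)
        assert ani_candidate_genomes(tree, RADII, Placement(fam, 1.0, 0.1)) == []


class TestClassifyQuery:
    def _medians(self, tree, red):
        return rank_medians(tree, red)

    def test_ani_assignment_wins(self, genus_tree):
        tree, red = genus_tree
        results = [ANIResult("A", 97.1, 0.82), ANIResult("B", 90.0, 0.82)]
        out = classify_query(tree, red, self._medians(tree, red),
                             Placement("A", 1.0, 0.02), results, RADII, "q")
        assert out.method == "ANI"
        assert out.taxonomy.names[6] == "s__Escherichia coli"
        assert out.closest_reference == "A"
        assert out.ani_pct == pytest.approx(97.1)

    def test_ani_precedence_over_red(self, genus_tree):
        # species assignment must short-circuit any RED-based rank choice
        tree, red = genus_tree
        genus = next(nid for nid, nd in tree.nodes.items()
                     if "g__Escherichia" in nd.taxa)
        results = [ANIResult("A", 99.0, 0.9)]
        out = classify_query(tree, red, self._medians(tree, red),
                             Placement(genus, 1.0, 0.02), results, RADII, "q")
        assert out.method == "ANI"
        assert not any("novel" in w for w in out.warnings)

    def test_below_radius_is_novel_species(self, genus_tree):
        tree, red = genus_tree
        results = [ANIResult("A", 94.2, 0.82)]
        out = classify_query(tree, red, self._medians(tree, red),
                             Placement("A", 1.0, 0.05), results, RADII, "q")
        assert out.method == "TOPOLOGY"
        assert out.taxonomy.names[5] == "g__Escherichia"
        assert out.taxonomy.names[6] == ""
        assert "novel species" in out.warnings
        assert out.closest_reference == "A"

    def test_af_failure_is_novel_species(self, genus_tree):
        tree, red = genus_tree
        results = [ANIResult("A", 99.0, 0.60)]
        out = classify_query(tree, red, self._medians(tree, red),
                             Placement("A", 1.0, 0.05), results, RADII, "q")
        assert out.method == "TOPOLOGY"
        assert "novel species" in out.warnings

    def test_basal_phylum_topology(self):
        tree = parse_newick(
            "(((A:1,B:1)'p__P1':1,(C:1,D:1)'p__P2':1):1,(E:2,F:2)'p__P3':1)'d__B';")
        red = compute_red(tree)
        hub = next(nid for nid, nd in tree.nodes.items()
                   if not nd.is_leaf and not nd.taxa and nd.parent is not None)
        out = classify_query(tree, red, rank_medians(tree, red),
                             Placement(hub, 0.5, 0.1), [], {}, "q")
        assert out.method == "TOPOLOGY"
        assert out.taxonomy.to_string() == "d__B;p__;c__;o__;f__;g__;s__"
        assert "novel phylum" in out.warnings

    def test_every_result_prefix_closed(self, reference, redmap, medians):
        from taxoplace.ani import fragment_ani
        from taxoplace.classify import ani_candidate_genomes
        for mode in ("known_species", "novel_genus", "novel_phylum"):
            q = gen_query(reference, mode, 5)
            cands = ani_candidate_genomes(reference.tree, reference.radii,
                                          q.placement)
            results = [fragment_ani(q.genome, reference.node_genomes[c],
                                    reference_id=c) for c in cands]
            out = classify_query(reference.tree, redmap, medians, q.placement,
                                 results, reference.radii, q.query_id)
            # TaxonomyString construction enforces prefix closure; touch it
            assert out.taxonomy.to_string().startswith("d__")

    def test_determinism(self, reference, redmap, medians):
        from taxoplace.ani import fragment_ani
        q = gen_query(reference, "novel_species", 8)
        cands = ani_candidate_genomes(reference.tree, reference.radii,
                                      q.placement)
        outs = set()
        for _ in range(10):
            results = [fragment_ani(q.genome, reference.node_genomes[c],
                                    reference_id=c) for c in cands]
            out = classify_query(reference.tree, redmap, medians, q.placement,
                                 results, reference.radii, q.query_id)
            outs.add((out.taxonomy.to_string(), out.method,
                      out.closest_reference, out.ani_pct, out.red_value))
        assert len(outs) == 1
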