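"""Ontology parsing, hierarchy queries, propagation, information accretion."""

import math

import numpy as np
import pytest

from goranker import (
    AnnotationSet,
    ParseError,
    ValidationError,
    ancestors,
    information_accretion,
    parse_obo,
    propagate_labels,
    propagate_scores,
    term_depth,
)
from goranker.scores import ScoreMatrix

from _oracles import closure_oracle, bfs_depth, max_over_descendants, reachable_ancestors
from conftest import make_graph, random_dag, random_annotations

OBO_SMALL = """format-version: 1.2

[Term]
id: GO:0000001
name: root
namespace: molecular_function

[Term]
id: GO:0000002
name: child
namespace: molecular_function
alt_id: GO:0000009
is_a: GO:0000001 ! root

[Term]
id: GO:0000003
name: grandchild
namespace: molecular_function
relationship: part_of GO:0000002 ! child

[Term]
id: GO:0000004
name: gone
namespace: molecular_function
is_obsolete: true
"""


class TestParseObo:
    def test_is_a_and_part_of_become_parent_edges(self):
        g = parse_obo(OBO_SMALL)
        assert g.terms == {"GO:0000001", "GO:0000002", "GO:0000003"}
        assert g.parents("GO:0000002") == {"GO:0000001"}
        assert g.parents("GO:0000003") == {"GO:0000002"}
        assert g.roots == {"MF": "GO:0000001"}

    def test_obsolete_terms_are_excluded_but_recorded(self):
        g = parse_obo(OBO_SMALL)
        assert "GO:0000004" in g.obsolete
        assert "GO:0000004" not in g.terms

    def test_alt_id_resolves_to_canonical(self):
        g = parse_obo(OBO_SMALL)
        assert g.resolve("GO:0000009") == "GO:0000002"
        assert g.ancestors("GO:0000009") == {"GO:0000001"}

    def test_malformed_id_names_the_line(self):
        bad = OBO_SMALL.replace("id: GO:0000003", "id: banana")
        with pytest.raises(ParseError, match="line 16"):
            parse_obo(bad)

    def test_cross_namespace_edge_is_dropped_with_warning(self, caplog):
        text = OBO_SMALL + (
            "\n[Term]\nid: GO:0000005\nname: stray\n"
            "namespace: biological_process\nis_a: GO:0000001 ! root\n"
        )
        with caplog.at_level("WARNING"):
            g = parse_obo(text)
        assert g.parents("GO:0000005") == frozenset()
        assert "cross-namespace" in caplog.text


class TestHierarchyQueries:
    def test_root_has_no_ancestors_and_depth_zero(self, chain_graph):
        assert ancestors(chain_graph, "GO:0000001") == frozenset()
        assert term_depth(chain_graph, "GO:0000001") == 0

    def test_chain_ancestors_and_depths(self, chain_graph):
        assert ancestors(chain_graph, "GO:0000003") == {"GO:0000001", "GO:0000002"}
        assert term_depth(chain_graph, "GO:0000002") == 1
        assert term_depth(chain_graph, "GO:0000003") == 2

    def test_diamond_ancestors(self, diamond_graph):
        assert ancestors(diamond_graph, "GO:0000004") == {
            "GO:0000001", "GO:0000002", "GO:0000003",
        }

    def test_depth_is_shortest_path(self):
        # diamond with a 2-edge and a 3-edge route to the root
        g = make_graph(
            {
                "r": set(), "a": {"r"}, "b": {"r"}, "c": {"b"},
                "x": {"a", "c"},
            }
        )
        assert g.depth("x") == 2

    def test_unknown_term_raises(self, chain_graph):
        with pytest.raises(ValidationError):
            ancestors(chain_graph, "GO:9999999")

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_breadth_first_search_on_random_dags(self, seed):
        rng = np.random.default_rng(seed)
        parents = random_dag(rng)
        g = make_graph(parents)
        for term in parents:
            assert g.ancestors(term) == reachable_ancestors(parents, term)
            assert g.depth(term) == bfs_depth(parents, term)


class TestPropagateLabels:
    def test_chain_closure_includes_root(self, chain_graph):
        ann = AnnotationSet({"P1": {"GO:0000003"}})
        closed = propagate_labels(chain_graph, ann)
        assert closed.by_protein["P1"] == {"GO:0000001", "GO:0000002", "GO:0000003"}

    def test_idempotent_on_closed_sets(self, chain_graph):
        closed = propagate_labels(chain_graph, AnnotationSet({"P1": {"GO:0000003"}}))
        assert propagate_labels(chain_graph, closed) == closed

    def test_obsolete_annotation_dropped_with_warning(self, caplog):
        g = parse_obo(OBO_SMALL)
        with caplog.at_level("WARNING"):
            closed = propagate_labels(g, AnnotationSet({"P1": {"GO:0000004"}}))
        assert not closed
        assert "obsolete" in caplog.text

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_reachability_oracle_and_is_monotone(self, seed):
        rng = np.random.default_rng(100 + seed)
        parents = random_dag(rng)
        g = make_graph(parents)
        ann = random_annotations(rng, sorted(parents))
        closed = propagate_labels(g, ann)
        assert closed.by_protein == closure_oracle(parents, ann.by_protein)
        for p, ts in ann.by_protein.items():  # never removes pairs
            assert ts <= closed.by_protein[p]


class TestPropagateScores:
    def test_single_leaf_score_lifts_to_ancestors(self, chain_graph):
        m = ScoreMatrix({"P1": {"GO:0000003": 0.7}})
        out = propagate_scores(chain_graph, m)
        assert out.row("P1") == {
            "GO:0000001": 0.7, "GO:0000002": 0.7, "GO:0000003": 0.7,
        }

    def test_higher_parent_score_is_kept(self, chain_graph):
        m = ScoreMatrix({"P1": {"GO:0000002": 0.9, "GO:0000003": 0.7}})
        out = propagate_scores(chain_graph, m)
        assert out.get("P1", "GO:0000002") == 0.9

    def test_score_outside_unit_interval_rejected(self, chain_graph):
        m = ScoreMatrix.__new__(ScoreMatrix)  # bypass constructor validation
        m.source, m.namespace = "", None
        m._data = {"P1": {"GO:0000003": 1.5}}
        with pytest.raises(ValidationError):
            propagate_scores(chain_graph, m)

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_max_over_descendants_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        parents = random_dag(rng)
        g = make_graph(parents)
        terms = sorted(parents)
        row = {
            terms[j]: float(rng.uniform(0.05, 1.0))
            for j in rng.choice(len(terms), size=len(terms) // 2, replace=False)
        }
        out = propagate_scores(g, ScoreMatrix({"P1": row}))
        assert out.row("P1") == pytest.approx(max_over_descendants(parents, row))
        out.check_hierarchy(g)


class TestInformationAccretion:
    def test_always_co_annotated_child_carries_no_information(self, chain_graph):
        ann = propagate_labels(
            chain_graph, AnnotationSet({f"P{i}": {"GO:0000003"} for i in range(5)})
        )
        ic = information_accretion(chain_graph, ann)
        assert ic["GO:0000003"] == 0.0

    def test_chain_conditional_frequency(self):
        g = make_graph({"r": set(), "a": {"r"}})
        ann = AnnotationSet(
            {f"P{i}": ({"r", "a"} if i < 2 else {"r"}) for i in range(8)}
        )
        ic = information_accretion(g, ann)
        assert ic["a"] == pytest.approx(2.0)  # -log2(2/8)
        assert ic["r"] == 0.0

    def test_diamond_counts_parent_intersection(self, diamond_graph):
        # 10 proteins at the root; 6 carry a, 5 carry b, 4 carry both, 3 carry c
        rows = {}
        for i in range(10):
            terms = {"GO:0000001"}
            if i < 6:
                terms.add("GO:0000002")
            if 2 <= i < 7:
                terms.add("GO:0000003")
            if 2 <= i < 5:
                terms.add("GO:0000004")
            rows[f"P{i}"] = terms
        ic = information_accretion(diamond_graph, AnnotationSet(rows))
        assert ic["GO:0000004"] == pytest.approx(-math.log2(3 / 4))

    def test_unpropagated_input_rejected(self, chain_graph):
        with pytest.raises(ValidationError, match="not propagated"):
            information_accretion(
                chain_graph, AnnotationSet({"P1": {"GO:0000003"}})
            )

    def test_zero_count_terms_get_finite_pseudocount_value(self, chain_graph):
        ann = propagate_labels(
            chain_graph, AnnotationSet({f"P{i}": {"GO:0000002"} for i in range(4)})
        )
        ic = information_accretion(chain_graph, ann)
        assert math.isfinite(ic["GO:0000003"])
        assert ic["GO:0000003"] >= 0.0

    def test_plain_ic_variant(self):
        g = make_graph({"r": set(), "a": {"r"}})
        ann = AnnotationSet({f"P{i}": ({"r", "a"} if i < 2 else {"r"}) for i in range(8)})
        ic = information_accretion(g, ann, conditional=False)
        assert ic["a"] == pytest.approx(2.0)  # same on a chain: -log2(2/8)

    @pytest.mark.parametrize("seed", range(10))
    def test_values_non_negative_and_root_zero(self, seed):
        rng = np.random.default_rng(300 + seed)
        parents = random_dag(rng)
        g = make_graph(parents)
        ann = propagate_labels(g, random_annotations(rng, sorted(parents)))
        ic = information_accretion(g, ann)
        assert all(v >= 0.0 for v in ic.ia_of.values())
        root = next(t for t, ps in parents.items() if not ps)
        assert ic[root] == 0.0
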