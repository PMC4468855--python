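"""Null-model shuffles, leave-one-out recovery and set enrichment."""

import itertools
from collections import Counter

import networkx as nx
import pytest

from moonnet.io_formats import ClusterSystem, GeneList
from moonnet.validation import (
    known_set_enrichment,
    leave_one_out_recovery,
    randomization_report,
    randomize_edges,
    shuffle_annotations,
    shuffle_pair_probabilities,
)
from tests.conftest import make_annotations


class TestShuffleAnnotations:
    @pytest.fixture
    def amap(self, flat_dag):
        return make_annotations(flat_dag, {
            "p1": {"Ta"}, "p2": {"Ta", "Tb"}, "p3": {"Tc"},
            "p4": {"Tb", "Tc", "Td"},
        })

    def test_multiset_of_sets_conserved(self, amap):
        shuffled = shuffle_annotations(amap, seed=3)
        assert Counter(amap.direct.values()) == \
            Counter(shuffled.direct.values())
        assert set(shuffled.direct) == set(amap.direct)

    def test_same_seed_reproduces_permutation(self, amap):
        assert shuffle_annotations(amap, seed=3).direct == \
            shuffle_annotations(amap, seed=3).direct

    def test_term_mode_conserves_per_protein_counts(self, amap):
        shuffled = shuffle_annotations(amap, seed=3, mode="terms")
        pool = Counter(t for ts in amap.direct.values() for t in ts)
        got = Counter(t for ts in shuffled.direct.values() for t in ts)
        assert sum(pool.values()) == sum(got.values())


class TestRandomizeEdges:
    @pytest.fixture
    def graph(self, easy_scenario):
        return easy_scenario.network

    def test_degree_preserving_conserves_degree_sequence(self, graph):
        rewired = randomize_edges(graph, "degree_preserving", seed=5)
        assert sorted(dict(rewired.degree()).values()) == \
            sorted(dict(graph.degree()).values())
        assert rewired.number_of_edges() == graph.number_of_edges()
        # and it actually rewires something
        assert set(map(frozenset, rewired.edges())) != \
            set(map(frozenset, graph.edges()))

    def test_uniform_conserves_node_and_edge_counts(self, graph):
        random_graph = randomize_edges(graph, "uniform", seed=5)
        assert set(random_graph.nodes()) == set(graph.nodes())
        assert random_graph.number_of_edges() == graph.number_of_edges()
        assert not any(u == v for u, v in random_graph.edges())

    def test_deterministic_given_seed(self, graph):
        for mode in ("uniform", "degree_preserving"):
            a = randomize_edges(graph, mode, seed=9)
            b = randomize_edges(graph, mode, seed=9)
            assert set(map(frozenset, a.edges())) == \
                set(map(frozenset, b.edges()))

    def test_unknown_mode_rejected(self, graph):
        with pytest.raises(ValueError):
            randomize_edges(graph, "bogus", seed=1)


class TestShufflePairProbabilities:
    def test_tuple_multiset_conserved_and_deterministic(self, easy_pipeline):
        table = easy_pipeline.pair_table
        shuffled = shuffle_pair_probabilities(table, seed=2)
        before = Counter((r.p_annot, r.p_inter) for r in table.rows.values())
        after = Counter((r.p_annot, r.p_inter)
                        for r in shuffled.rows.values())
        assert before == after
        assert set(shuffled.rows) == set(table.rows)
        assert shuffled.n_tests == table.n_tests
        again = shuffle_pair_probabilities(table, seed=2)
        assert {k: (r.p_annot, r.p_inter) for k, r in shuffled.rows.items()} \
            == {k: (r.p_annot, r.p_inter) for k, r in again.rows.items()}


class TestLeaveOneOut:
    def test_fully_shared_term_recovers_everyone(self, flat_dag):
        system = ClusterSystem([frozenset({"p1", "p2", "p3"})])
        ann = make_annotations(flat_dag,
                               {p: {"Ta"} for p in ("p1", "p2", "p3")})
        assert leave_one_out_recovery(system, ann, flat_dag) == 1.0

    def test_unique_term_member_fails_its_case(self, flat_dag):
        # p1, p2 share Ta; p3 carries a unique term: held out, the
        # remaining members only support Ta, so 2 of 3 cases succeed
        system = ClusterSystem([frozenset({"p1", "p2", "p3"})])
        ann = make_annotations(flat_dag, {"p1": {"Ta"}, "p2": {"Ta"},
                                          "p3": {"Te"}})
        assert leave_one_out_recovery(system, ann, flat_dag) == \
            pytest.approx(2 / 3)

    def test_ancestor_closure_of_inferred_terms_counts(self, chain_dag):
        # held-out protein carries the parent T2; the others support the
        # leaf T3, whose ancestor closure contains T2 -> recovered
        system = ClusterSystem([frozenset({"p1", "p2", "p3"})])
        ann = make_annotations(chain_dag, {"p1": {"T3"}, "p2": {"T3"},
                                           "p3": {"T2"}})
        assert leave_one_out_recovery(system, ann, chain_dag) == 1.0

    def test_no_evaluable_case_is_an_error(self, flat_dag):
        system = ClusterSystem([frozenset({"u1", "u2"})])
        with pytest.raises(ValueError):
            leave_one_out_recovery(system, make_annotations(flat_dag, {}),
                                   flat_dag)

    def test_fraction_increases_with_annotation_purity(self):
        from moonnet.ocg import ocg_cluster
        from moonnet.synthetic import ScenarioParams, generate_scenario

        means = []
        for purity in (0.5, 0.95):
            values = []
            for seed in (0, 1, 2):
                sc = generate_scenario(ScenarioParams(
                    annotation_purity=purity, seed=seed))
                system = ocg_cluster(sc.network)
                values.append(leave_one_out_recovery(
                    system, sc.annotations, sc.dag))
            means.append(sum(values) / len(values))
        assert 0.0 <= means[0] < means[1] <= 1.0


def enum_upper_tail(N, K, n, k):
    """P(overlap >= k) by enumerating every K-subset as the candidate
    set against a fixed n-subset."""
    universe = list(range(N))
    known = set(universe[:n])
    hits = total = 0
    for cand in itertools.combinations(universe, K):
        total += 1
        if len(known & set(cand)) >= k:
            hits += 1
    return hits / total


class TestKnownSetEnrichment:
    def test_reported_scale_counts(self):
        universe = GeneList(tuple(f"P{i}" for i in range(12865)))
        candidates = GeneList(tuple(f"P{i}" for i in range(430)))
        known = GeneList(tuple(f"P{i}" for i in range(424, 463)))  # k = 6
        res = known_set_enrichment(candidates, known, universe)
        assert res.k == 6
        assert res.fold == pytest.approx(4.6, abs=0.05)
        assert res.p == pytest.approx(1.72e-3, rel=1e-2)
        assert res.p_point == pytest.approx(1.45e-3, rel=1e-2)

    def test_identity_case(self):
        genes = GeneList(("A", "B", "C"))
        res = known_set_enrichment(genes, genes, genes)
        assert res.fold == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_zero_overlap(self):
        universe = GeneList(("A", "B", "C", "D"))
        res = known_set_enrichment(GeneList(("A",)), GeneList(("B",)),
                                   universe)
        assert res.fold == 0.0
        assert res.p == pytest.approx(1.0)

    def test_matches_enumeration_oracle_small_universes(self):
        import random
        rng = random.Random(13)
        for _ in range(10):
            N = rng.randint(2, 12)
            K = rng.randint(1, N)
            n = rng.randint(1, N)
            ids = [f"g{i}" for i in range(N)]
            universe = GeneList(tuple(ids))
            known = GeneList(tuple(ids[:n]))
            cand_ids = tuple(sorted(rng.sample(ids, K)))
            candidates = GeneList(cand_ids)
            res = known_set_enrichment(candidates, known, universe)
            assert res.p == pytest.approx(enum_upper_tail(N, K, n, res.k))

    def test_subset_violations_rejected(self):
        universe = GeneList(("A", "B"))
        with pytest.raises(ValueError):
            known_set_enrichment(GeneList(("Z",)), GeneList(("A",)),
                                 universe)
        with pytest.raises(ValueError):
            known_set_enrichment(GeneList(("A",)), GeneList(("Z",)),
                                 universe)


class TestRandomizationReport:
    def test_annotation_shuffle_collapses_annotation_and_candidates(
            self, easy_scenario, easy_pipeline):
        report = randomization_report(
            "annotation_shuffle", easy_scenario.network,
            easy_scenario.annotations, easy_scenario.dag,
            n_reps=5, seed=100,
        )
        observed_annotated = len(
            easy_pipeline.annotated_system.annotated_indices)
        assert report.mean_annotated_clusters < observed_annotated
        assert report.mean_candidates <= len(easy_pipeline.candidates)
        assert report.n_reps == 5

    def test_probability_shuffle_bounded_by_multiclustered(
            self, easy_scenario, easy_pipeline):
        from moonnet.emf import find_multiclustered
        report = randomization_report(
            "probability_shuffle", easy_scenario.network,
            easy_scenario.annotations, easy_scenario.dag,
            n_reps=5, seed=100,
        )
        n_multi = len(find_multiclustered(
            easy_pipeline.annotated_system.system))
        assert all(c <= n_multi for c in report.candidate_counts)

    def test_unknown_scheme_and_bad_reps_rejected(self, easy_scenario):
        with pytest.raises(ValueError):
            randomization_report("bogus", easy_scenario.network,
                                 easy_scenario.annotations,
                                 easy_scenario.dag, n_reps=1, seed=0)
        with pytest.raises(ValueError):
            randomization_report("edge_random", easy_scenario.network,
                                 easy_scenario.annotations,
                                 easy_scenario.dag, n_reps=0, seed=0)
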