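"""Protein groups, topology features and group comparisons."""

import itertools
import math

import networkx as nx
import pandas as pd
import pytest

from moonnet.characterization import (
    assign_groups,
    compare_groups,
    default_hub_threshold,
    group_shortest_paths,
    list_enrichment,
    topology_features,
)
from moonnet.emf import find_emf_candidates
from moonnet.io_formats import ClusterSystem, GeneList


def oracle_betweenness(g: nx.Graph) -> dict:
    """Count shortest paths through each node by full enumeration."""
    out = {v: 0.0 for v in g.nodes()}
    for s, t in itertools.combinations(sorted(g.nodes(), key=str), 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in g.nodes():
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            out[v] += through / len(paths)
    return out


class TestAssignGroups:
    def test_star_center_is_the_only_hub(self):
        g = nx.star_graph(10)  # center 0, mean degree 20/11
        assert default_hub_threshold(g) == math.ceil(40 / 11)
        system = ClusterSystem([frozenset(g.nodes())])
        groups = assign_groups(g, system, GeneList(()))
        assert set(groups["Hubs"]) == {0}

    def test_bowtie_partition(self, bowtie, bowtie_system):
        groups = assign_groups(bowtie, bowtie_system, GeneList(()),
                               hub_threshold=100)
        assert set(groups["Multi"]) == {"c"}
        assert set(groups["Mono"]) == {"a", "b", "d", "e"}

    def test_group_invariants_on_scenario(self, easy_scenario,
                                          easy_pipeline):
        groups = assign_groups(easy_scenario.network,
                               easy_pipeline.annotated_system.system,
                               easy_pipeline.candidates)
        nodes = set(easy_scenario.network.nodes())
        assert groups["Multi"] | groups["Mono"] == nodes
        assert groups["Multi"] & groups["Mono"] == frozenset()
        assert groups["Cands"] <= groups["Multi"]
        assert groups["Multi_NC"] == groups["Multi"] - groups["Cands"]
        assert groups["NC"] == nodes - groups["Cands"]
        threshold = groups.hub_threshold
        for p in nodes:
            assert (easy_scenario.network.degree(p) >= threshold) == \
                (p in groups["Hubs"])

    def test_foreign_candidates_rejected(self, bowtie, bowtie_system):
        with pytest.raises(ValueError):
            assign_groups(bowtie, bowtie_system, GeneList(("zz",)))


class TestTopologyFeatures:
    def test_path_middle_node_bridges_once(self):
        g = nx.path_graph(3)
        table = topology_features(g)
        assert table.loc[1, "betweenness"] == pytest.approx(1.0)
        assert table.loc[0, "betweenness"] == pytest.approx(0.0)

    def test_cycle_ties_split(self):
        table = topology_features(nx.cycle_graph(4))
        assert table["betweenness"].tolist() == pytest.approx([0.5] * 4)

    def test_matches_enumeration_oracle_on_small_graphs(self):
        for seed in range(4):
            g = nx.gnp_random_graph(8, 0.35, seed=seed)
            table = topology_features(g)
            oracle = oracle_betweenness(g)
            for node, expected in oracle.items():
                assert table.loc[node, "betweenness"] == \
                    pytest.approx(expected)

    def test_cluster_membership_column(self, bowtie, bowtie_system):
        table = topology_features(bowtie, bowtie_system)
        assert table.loc["c", "n_clusters"] == 2
        assert table.loc["a", "n_clusters"] == 1


class TestGroupShortestPaths:
    def test_clique_mean_is_one(self):
        g = nx.complete_graph(5)
        assert group_shortest_paths(g, [0, 1, 2]).mean_length == 1.0

    def test_path_endpoints(self):
        g = nx.path_graph(3)
        summary = group_shortest_paths(g, [0, 2])
        assert summary.mean_length == 2.0 and summary.n_pairs == 1

    def test_between_two_groups(self):
        g = nx.path_graph(4)
        summary = group_shortest_paths(g, [0], [2, 3])
        assert summary.mean_length == pytest.approx(2.5)

    def test_unreachable_pairs_counted(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("x", "y")])
        summary = group_shortest_paths(g, ["a", "b", "x"])
        assert summary.n_unreachable == 2
        assert summary.mean_length == 1.0

    def test_all_unreachable_is_an_error(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("x", "y")])
        with pytest.raises(ValueError):
            group_shortest_paths(g, ["a"], ["x"])


class TestCompareGroups:
    @pytest.fixture
    def table(self):
        return pd.DataFrame(
            {"degree": [1, 2, 3, 4, 5, 6]},
            index=["a", "b", "c", "d", "e", "f"],
        )

    def test_exact_two_sided_p(self, table):
        # U = 0 in 1 of C(6,3)=20 equally likely rank splits, two-sided
        mean_a, mean_b, p = compare_groups(table, "degree",
                                           ["a", "b", "c"],
                                           ["d", "e", "f"])
        assert (mean_a, mean_b) == (2.0, 5.0)
        assert p == pytest.approx(0.1)

    def test_identical_groups_p_one(self, table):
        _, _, p = compare_groups(table, "degree", ["a", "b", "c"],
                                 ["a", "b", "c"])
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_for_small_samples(self, table):
        from scipy.stats import mannwhitneyu
        xa, xb = [1, 2, 6], [3, 4, 5]
        # enumeration over all rank assignments of the pooled sample
        pooled = xa + xb
        observed = sum(1 for x in xa for y in xb if x > y)
        count = total = 0
        for combo in itertools.combinations(range(6), 3):
            a = [pooled[i] for i in combo]
            b = [pooled[i] for i in range(6) if i not in combo]
            u = sum(1 for x in a for y in b if x > y)
            total += 1
            if min(u, 9 - u) <= min(observed, 9 - observed):
                count += 1
        frame = pd.DataFrame({"v": pooled},
                             index=[f"i{i}" for i in range(6)])
        _, _, p = compare_groups(frame, "v", ["i0", "i1", "i2"],
                                 ["i3", "i4", "i5"])
        assert p == pytest.approx(count / total)

    def test_empty_group_is_an_error(self, table):
        with pytest.raises(ValueError):
            compare_groups(table, "degree", ["zz"], ["a"])

    def test_shift_alternative_shrinks_p(self):
        import numpy as np
        rng = np.random.default_rng(21)
        base = rng.normal(0, 1, 200)
        frame_index = [f"p{i}" for i in range(400)]
        ps = []
        for shift in (0.2, 1.0):
            values = list(base) + list(rng.normal(shift, 1, 200))
            frame = pd.DataFrame({"v": values}, index=frame_index)
            _, _, p = compare_groups(frame, "v", frame_index[:200],
                                     frame_index[200:])
            ps.append(p)
        assert ps[1] < ps[0]


class TestListEnrichment:
    def test_list_equal_to_group_gives_inverse_frequency_fold(self, bowtie,
                                                              bowtie_system):
        groups = assign_groups(bowtie, bowtie_system, GeneList(()),
                               hub_threshold=100)
        universe = GeneList(tuple(sorted(bowtie.nodes())))
        gene_list = GeneList(tuple(sorted(groups["Multi"])), "multi")
        table = list_enrichment(groups, gene_list, universe)
        # |universe| / |Multi| = 5 / 1
        assert table.loc["Multi", "fold"] == pytest.approx(5.0)

    def test_empty_intersection_fold_zero_p_one(self, bowtie,
                                                bowtie_system):
        groups = assign_groups(bowtie, bowtie_system,
                               GeneList(("c",)), hub_threshold=100)
        universe = GeneList(tuple(sorted(bowtie.nodes())))
        table = list_enrichment(groups, GeneList(("a",), "list"), universe)
        assert table.loc["Cands", "fold"] == 0.0
        assert table.loc["Cands", "p"] == pytest.approx(1.0)

    def test_depletion_reported_as_fold_below_one(self, easy_scenario,
                                                  easy_pipeline):
        groups = assign_groups(easy_scenario.network,
                               easy_pipeline.annotated_system.system,
                               easy_pipeline.candidates)
        universe = GeneList(tuple(sorted(easy_scenario.network.nodes())))
        # the planted EMFs: enriched among Cands, depleted among Mono
        table = list_enrichment(groups, easy_scenario.planted_emfs,
                                universe)
        assert table.loc["Cands", "fold"] > 1.0
        assert table.loc["Mono", "fold"] < 1.0
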