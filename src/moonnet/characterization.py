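"""Topological characterization of candidate groups.

Groups: the whole network, multiclustered proteins (Multi), their
complement (Mono), EMF candidates (Cands), multiclustered
non-candidates (Multi_NC), all non-candidates (NC) and hubs (degree at
least twice the network mean by default).  The groups overlay: only
Multi/Mono partition the node set.

Betweenness convention: unnormalized Brandes betweenness over unordered
source-target pairs, endpoints excluded, shortest-path-count weighted —
i.e. the number of times a node bridges a shortest path between two
other nodes, with tied paths splitting the count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd
from scipy.stats import mannwhitneyu

from .emf import EMFCandidate
from .io_formats import ClusterSystem, GeneList
from .validation import EnrichmentResult, known_set_enrichment

GROUP_NAMES = ("Cands", "Multi", "Multi_NC", "Mono", "NC", "Hubs")


@dataclass
class ProteinGroups:
    """Overlapping protein categories used in the group comparisons."""

    groups: dict[str, frozenset[str]]
    hub_threshold: float

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.groups[name]

    def of(self, protein: str) -> set[str]:
        return {g for g, members in self.groups.items() if protein in members}


def default_hub_threshold(network: nx.Graph) -> int:
    """Twice the mean degree, rounded up."""
    n = network.number_of_nodes()
    if n == 0:
        raise ValueError("empty network")
    mean_degree = 2 * network.number_of_edges() / n
    return math.ceil(2 * mean_degree)


def assign_groups(
    network: nx.Graph,
    system: ClusterSystem,
    candidates: list[EMFCandidate] | GeneList,
    hub_threshold: float | None = None,
) -> ProteinGroups:
    """Build the Cands/Multi/Multi_NC/Mono/NC/Hubs overlay."""
    nodes = frozenset(network.nodes())
    cand_ids = frozenset(
        c.protein if isinstance(c, EMFCandidate) else c for c in candidates
    )
    if not cand_ids <= nodes:
        raise ValueError("candidates are not a subset of the network nodes")
    membership = system.membership
    multi = frozenset(p for p in nodes if len(membership.get(p, ())) >= 2)
    if hub_threshold is None:
        hub_threshold = default_hub_threshold(network)
    hubs = frozenset(p for p in nodes if network.degree(p) >= hub_threshold)
    return ProteinGroups(
        groups={
            "Cands": cand_ids,
            "Multi": multi,
            "Multi_NC": multi - cand_ids,
            "Mono": nodes - multi,
            "NC": nodes - cand_ids,
            "Hubs": hubs,
        },
        hub_threshold=hub_threshold,
    )


def topology_features(network: nx.Graph,
                      system: ClusterSystem | None = None,
                      annotations=None) -> pd.DataFrame:
    """Per-protein degree, betweenness and cluster-membership count.

    Optional user-supplied feature tables (disorder, motifs, domains...)
    can be joined onto the returned frame; they are never computed here.
    """
    nodes = sorted(network.nodes(), key=str)
    betweenness = nx.betweenness_centrality(network, normalized=False)
    data = {
        "degree": [network.degree(p) for p in nodes],
        "betweenness": [betweenness[p] for p in nodes],
    }
    if system is not None:
        membership = system.membership
        data["n_clusters"] = [len(membership.get(p, ())) for p in nodes]
    if annotations is not None:
        data["n_BP_annotations"] = [len(annotations.propagated(p))
                                    for p in nodes]
    return pd.DataFrame(data, index=pd.Index(nodes, name="protein"))


@dataclass(frozen=True)
class PathSummary:
    mean_length: float
    n_pairs: int
    n_unreachable: int


def group_shortest_paths(network: nx.Graph, group_a, group_b=None) -> PathSummary:
    """Mean shortest-path length within group_a or between two groups.

    Unordered distinct pairs only; unreachable pairs are excluded from
    the mean and counted.
    """
    a = sorted(set(group_a), key=str)
    b = sorted(set(group_b), key=str) if group_b is not None else a
    if not a or not b:
        raise ValueError("groups must be non-empty")
    total = n_pairs = n_unreachable = 0
    seen: set[frozenset[str]] = set()
    for u in a:
        lengths = nx.single_source_shortest_path_length(network, u)
        for v in b:
            if v == u:
                continue
            key = frozenset((u, v))
            if key in seen:
                continue
            seen.add(key)
            if v in lengths:
                total += lengths[v]
                n_pairs += 1
            else:
                n_unreachable += 1
    if n_pairs == 0:
        raise ValueError("all pairs unreachable")
    return PathSummary(total / n_pairs, n_pairs, n_unreachable)


def compare_groups(
    feature_table: pd.DataFrame,
    feature: str,
    group_a,
    group_b,
) -> tuple[float, float, float]:
    """(mean_a, mean_b, p) with a two-sided Wilcoxon rank-sum test.

    Exact for small tie-free samples, normal approximation with tie
    correction otherwise (scipy's automatic method selection).
    """
    xa = feature_table.loc[sorted(set(group_a) & set(feature_table.index)),
                           feature].to_numpy()
    xb = feature_table.loc[sorted(set(group_b) & set(feature_table.index)),
                           feature].to_numpy()
    if len(xa) == 0 or len(xb) == 0:
        raise ValueError("both groups need at least one measured protein")
    stat = mannwhitneyu(xa, xb, alternative="two-sided", method="auto")
    return float(xa.mean()), float(xb.mean()), float(stat.pvalue)


def list_enrichment(
    groups: ProteinGroups,
    gene_list: GeneList,
    universe: GeneList,
) -> pd.DataFrame:
    """Fold over/under-representation of a gene list in every group.

    fold < 1 reads as depletion; p is one-sided (over-representation).
    """
    rows = {}
    for name in GROUP_NAMES:
        members = groups[name] & set(universe.ids)
        if not members:
            continue
        res = known_set_enrichment(
            GeneList(tuple(sorted(members)), label=name),
            GeneList(tuple(i for i in gene_list.ids if i in set(universe.ids)),
                     label=gene_list.label),
            universe,
        )
        rows[name] = {"k": res.k, "expected": res.expected,
                      "fold": res.fold, "p": res.p}
    return pd.DataFrame.from_dict(rows, orient="index")
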