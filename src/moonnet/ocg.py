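"""Overlapping cluster generation by greedy modularity-gain merging.

The network is first covered by *centered cliques* (one greedy clique
grown around each vertex), then cluster pairs are merged while the
overlap modularity strictly increases.  The result is a system of
possibly overlapping clusters in which every node appears at least once
and no cluster is a subset of another.

Overlap modularity convention used throughout this package
----------------------------------------------------------
With ``m`` edges, adjacency ``A`` and degrees ``d``,

    Q = (1/2m) * sum over ordered node pairs (u, v) that share at least
        one cluster of [ A_uv - d_u * d_v / (2m) ],

where the sum *includes* the diagonal (u = v) null terms, as in
classical Newman modularity, so that a single cluster containing the
whole graph scores exactly 0.  Each node pair is counted once no matter
how many clusters it shares; the diagonal term is a clustering-
independent constant under full coverage, so merge decisions are
unaffected by the convention.  This is this package's pinned definition
of the algorithm: no attempt is made to replicate any particular
legacy binary bit-for-bit.

The procedure is fully deterministic: vertices are processed in
lexicographic order, clique growth breaks degree ties lexicographically
and merge ties are broken by the smallest lexicographic pair of cluster
fingerprints.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable

import networkx as nx

from .io_formats import ClusterSystem

logger = logging.getLogger(__name__)

_EPS = 1e-12


def build_centered_cliques(network: nx.Graph) -> ClusterSystem:
    """Initial cluster system: one greedily grown clique per vertex.

    For each vertex ``v`` (lexicographic order) the clique starts as
    ``{v}`` and repeatedly adds the neighbour of ``v`` adjacent to all
    current members with the highest degree (ties broken by smallest
    ID).  Identical cliques are deduplicated and cliques that are
    subsets of others removed.  An isolated vertex yields a singleton.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    cliques: set[frozenset[str]] = set()
    degree = dict(network.degree())
    for v in sorted(network.nodes(), key=str):
        clique = {v}
        candidates = set(network.neighbors(v))
        while True:
            feasible = [
                u for u in candidates
                if all(network.has_edge(u, w) for w in clique)
            ]
            if not feasible:
                break
            best = min(feasible, key=lambda u: (-degree[u], str(u)))
            clique.add(best)
            candidates.discard(best)
        cliques.add(frozenset(clique))
    return ClusterSystem(_remove_subsets(cliques))


def _remove_subsets(clusters: Iterable[frozenset[str]]) -> list[frozenset[str]]:
    """Drop clusters that are subsets of another; deterministic order."""
    ordered = sorted(set(clusters), key=lambda c: (-len(c), tuple(sorted(c))))
    kept: list[frozenset[str]] = []
    for c in ordered:
        if not any(c < k for k in kept):
            kept.append(c)
    return sorted(kept, key=lambda c: tuple(sorted(c)))


def _covered_pairs(system: ClusterSystem) -> set[frozenset[str]]:
    covered: set[frozenset[str]] = set()
    for cluster in system.clusters:
        for u, v in itertools.combinations(sorted(cluster), 2):
            covered.add(frozenset((u, v)))
    return covered


def overlap_modularity(network: nx.Graph, system: ClusterSystem) -> float:
    """Overlap modularity Q of a cluster system (see module docstring)."""
    m = network.number_of_edges()
    if m == 0:
        raise ValueError("modularity undefined on an edgeless network")
    degree = dict(network.degree())
    two_m = 2.0 * m
    total = 0.0
    for pair in _covered_pairs(system):
        u, v = tuple(pair)
        a_uv = 1.0 if network.has_edge(u, v) else 0.0
        total += 2.0 * (a_uv - degree[u] * degree[v] / two_m)
    for node in system.proteins:  # diagonal null terms
        total -= degree[node] ** 2 / two_m
    return total / two_m


def _merge_gain(
    c1: frozenset[str],
    c2: frozenset[str],
    network: nx.Graph,
    degree: dict,
    two_m: float,
    pair_cover_count: dict[frozenset[str], int],
) -> float:
    """Modularity change from merging c1 and c2.

    Only node pairs straddling the two exclusive parts and not yet
    covered by any cluster contribute; each enters Q as an ordered pair
    twice, hence the factor 2/(2m).
    """
    gain = 0.0
    only1 = c1 - c2
    only2 = c2 - c1
    for u in only1:
        for v in only2:
            if pair_cover_count.get(frozenset((u, v)), 0) == 0:
                a_uv = 1.0 if network.has_edge(u, v) else 0.0
                gain += a_uv - degree[u] * degree[v] / two_m
    return 2.0 * gain / two_m


def ocg_cluster(
    network: nx.Graph,
    max_cluster_size: int | None = None,
    min_final_clusters: int | None = None,
) -> ClusterSystem:
    """Cover ``network`` with overlapping clusters (OCG-style).

    Starting from :func:`build_centered_cliques`, repeatedly merge the
    cluster pair that (i) shares at least one node or is connected by at
    least one edge and (ii) yields the maximal strictly positive gain in
    :func:`overlap_modularity`; stop when no such merge exists or an
    optional limit is hit, then enforce the no-subset invariant.
    Deterministic given the input; disconnected components are never
    merged together because cross-component gains are always negative.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    system = build_centered_cliques(network)
    if network.number_of_edges() == 0:
        return system
    clusters = list(system.clusters)
    degree = dict(network.degree())
    two_m = 2.0 * network.number_of_edges()

    pair_cover_count: dict[frozenset[str], int] = {}
    for cluster in clusters:
        _adjust_cover(pair_cover_count, cluster, +1)

    n_merges = 0
    while True:
        if min_final_clusters is not None and len(clusters) <= min_final_clusters:
            break
        best_gain: float | None = None
        best_fp: tuple[tuple, tuple] | None = None
        best_idx: tuple[int, int] | None = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            c1, c2 = clusters[i], clusters[j]
            if max_cluster_size is not None and len(c1 | c2) > max_cluster_size:
                continue
            if not _mergeable(c1, c2, network):
                continue
            gain = _merge_gain(c1, c2, network, degree, two_m, pair_cover_count)
            if gain <= _EPS:  # only strictly positive gains are accepted
                continue
            fp = _fingerprint_pair(c1, c2)
            if (
                best_gain is None
                or gain > best_gain + _EPS
                or (abs(gain - best_gain) <= _EPS and fp < best_fp)
            ):
                best_gain, best_fp, best_idx = gain, fp, (i, j)
        if best_idx is None:
            break
        i, j = best_idx
        c1, c2 = clusters[i], clusters[j]
        merged = c1 | c2
        _adjust_cover(pair_cover_count, c1, -1)
        _adjust_cover(pair_cover_count, c2, -1)
        _adjust_cover(pair_cover_count, merged, +1)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
        n_merges += 1

    final = _remove_subsets(clusters)
    logger.info("ocg_cluster: %d merges, %d final clusters", n_merges, len(final))
    return ClusterSystem(final)


def _mergeable(c1: frozenset[str], c2: frozenset[str], network: nx.Graph) -> bool:
    if c1 & c2:
        return True
    small, large = (c1, c2) if len(c1) <= len(c2) else (c2, c1)
    return any(v in large for u in small for v in network.neighbors(u))


def _fingerprint_pair(c1: frozenset[str], c2: frozenset[str]) -> tuple[tuple, tuple]:
    f1, f2 = tuple(sorted(c1)), tuple(sorted(c2))
    return (f1, f2) if f1 <= f2 else (f2, f1)


def _adjust_cover(
    counts: dict[frozenset[str], int], cluster: frozenset[str], delta: int
) -> None:
    for u, v in itertools.combinations(sorted(cluster), 2):
        key = frozenset((u, v))
        counts[key] = counts.get(key, 0) + delta
        if counts[key] == 0:
            del counts[key]
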