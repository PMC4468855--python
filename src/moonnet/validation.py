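"""Randomization controls, leave-one-out recovery and set enrichment.

Four null schemes probe the pipeline's specificity: shuffling protein
annotations, resampling the network uniformly, degree-preserving edge
rewiring, and permuting the term-pair probabilities.  Each conserves a
stated invariant exactly (the multiset of annotation sets, node/edge
counts, the degree sequence, the multiset of probability tuples) and is
deterministic given its seed.  On a real modular network all four
collapse the candidate count towards zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import mean

import networkx as nx
import numpy as np

from .io_formats import GeneList
from .ontology import AnnotationMap, OntologyDAG
from .module_annotation import annotate_cluster_members
from .io_formats import UNKNOWN, ClusterSystem
from .pronto import PairProbabilityTable, PairRow, hypergeom_upper
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

SCHEMES = ("annotation_shuffle", "edge_random", "degree_preserving",
           "probability_shuffle")


def shuffle_annotations(annotations: AnnotationMap, seed: int,
                        mode: str = "sets") -> AnnotationMap:
    """Permute annotations across proteins (deterministic given seed).

    ``mode="sets"`` (default) permutes whole per-protein direct-term
    sets, conserving both the multiset of annotation sets and each
    protein's status as annotated; ``mode="terms"`` pools all
    (protein, term) assignments and deals the terms back out, conserving
    per-protein annotation counts instead.
    """
    rng = np.random.default_rng(seed)
    proteins = sorted(annotations.direct)
    if mode == "sets":
        sets = [annotations.direct[p] for p in proteins]
        perm = rng.permutation(len(sets))
        direct = {p: sets[perm[i]] for i, p in enumerate(proteins)}
    elif mode == "terms":
        pool = [t for p in proteins for t in sorted(annotations.direct[p])]
        perm = rng.permutation(len(pool))
        direct = {}
        pos = 0
        for p in proteins:
            size = len(annotations.direct[p])
            direct[p] = frozenset(pool[perm[i]] for i in range(pos, pos + size))
            pos += size
    else:
        raise ValueError(f"unknown shuffle mode {mode!r}")
    return annotations.with_direct(direct)


def randomize_edges(network: nx.Graph, mode: str, seed: int,
                    swaps_per_edge: int = 10) -> nx.Graph:
    """Return a randomized copy of the network.

    ``mode="uniform"`` draws a fresh simple graph on the same node set
    with the same edge count (the modular structure is destroyed);
    ``mode="degree_preserving"`` applies ``swaps_per_edge * m`` double
    edge swaps, conserving the degree sequence exactly.
    """
    m = network.number_of_edges()
    nodes = sorted(network.nodes(), key=str)
    if mode == "uniform":
        rng = np.random.default_rng(seed)
        out = nx.Graph()
        out.add_nodes_from(nodes)
        n = len(nodes)
        chosen: set[tuple[int, int]] = set()
        while len(chosen) < m:
            i, j = rng.integers(0, n, size=2)
            if i == j:
                continue
            key = (min(i, j), max(i, j))
            chosen.add(key)
        out.add_edges_from((nodes[i], nodes[j]) for i, j in chosen)
        return out
    if mode == "degree_preserving":
        out = network.copy()
        if m < 2 or out.number_of_nodes() < 4:
            return out
        nswap = swaps_per_edge * m
        nx.double_edge_swap(out, nswap=nswap, max_tries=100 * nswap,
                            seed=int(seed))
        return out
    raise ValueError(f"unknown randomization mode {mode!r}")


def shuffle_pair_probabilities(table: PairProbabilityTable,
                               seed: int) -> PairProbabilityTable:
    """Permute the (p_annot, p_inter) tuples across term-pair keys."""
    rng = np.random.default_rng(seed)
    keys = sorted(table.rows)
    rows = [table.rows[k] for k in keys]
    perm = rng.permutation(len(keys))
    shuffled = {
        k: PairRow(
            p_annot=rows[perm[i]].p_annot,
            p_inter=rows[perm[i]].p_inter,
            counts_annot=rows[perm[i]].counts_annot,
            counts_inter=rows[perm[i]].counts_inter,
        )
        for i, k in enumerate(keys)
    }
    return table.with_rows(shuffled)


def leave_one_out_recovery(
    system: ClusterSystem,
    annotations: AnnotationMap,
    dag: OntologyDAG,
    threshold: float = 0.5,
) -> float:
    """Fraction of held-out protein annotations re-inferred from modules.

    For every (cluster, member) case where the member has at least one
    propagated BP term: the member's annotations are removed, the
    cluster re-annotated from the remaining members, and the case
    succeeds iff at least one held-out propagated term appears among the
    inferred cluster terms or their ancestors.
    """
    cases = successes = 0
    for members in system.clusters:
        for protein in sorted(members):
            held_out = annotations.propagated(protein)
            if not held_out:
                continue
            cases += 1
            rest = {
                p: annotations.direct.get(p, frozenset())
                for p in members if p != protein
            }
            loo_ann = annotations.with_direct(rest)
            inferred = annotate_cluster_members(
                frozenset(rest), loo_ann, dag, threshold
            )
            if inferred == UNKNOWN:
                continue
            matchable = dag.closure(inferred, include_root=False)
            if matchable & held_out:
                successes += 1
    if cases == 0:
        raise ValueError("no evaluable (cluster, protein) case")
    return successes / cases


@dataclass(frozen=True)
class EnrichmentResult:
    """Overlap of a candidate set with a known gene set.

    ``fold`` is observed/expected overlap; ``p`` the upper-tail
    hypergeometric probability P(X >= k); ``p_point`` the point mass
    P(X = k), the convention some legacy enrichment tools report.
    """

    k: int
    expected: float
    fold: float
    p: float
    p_point: float


def known_set_enrichment(candidates: GeneList, known: GeneList,
                         universe: GeneList) -> EnrichmentResult:
    """Hypergeometric enrichment of ``known`` among ``candidates``.

    One-sided (upper tail): the reported direction is over-representation
    of the known set among candidates relative to the universe.
    """
    uni = set(universe.ids)
    if not uni:
        raise ValueError("empty universe")
    known_set = set(known.ids)
    if not known_set:
        raise ValueError("empty known set")
    cand_set = set(candidates.ids)
    if not known_set <= uni:
        raise ValueError("known set is not a subset of the universe")
    if not cand_set <= uni:
        raise ValueError("candidate set is not a subset of the universe")
    N, K, n = len(uni), len(cand_set), len(known_set)
    k = len(cand_set & known_set)
    expected = K * n / N
    fold = k / expected if expected > 0 else float("nan")
    return EnrichmentResult(
        k=k,
        expected=expected,
        fold=fold,
        p=hypergeom_upper(N, K, n, k),
        p_point=float(hypergeom.pmf(k, N, K, n)),
    )


@dataclass
class RandomizationReport:
    """Per-replicate pipeline outcomes under one null scheme."""

    scheme: str
    n_reps: int
    candidate_counts: list[int] = field(default_factory=list)
    annotated_cluster_counts: list[int] = field(default_factory=list)

    @property
    def mean_candidates(self) -> float:
        return mean(self.candidate_counts)

    @property
    def mean_annotated_clusters(self) -> float:
        return mean(self.annotated_cluster_counts)

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "n_reps": self.n_reps,
            "candidate_counts": self.candidate_counts,
            "annotated_cluster_counts": self.annotated_cluster_counts,
            "mean_candidates": self.mean_candidates,
            "mean_annotated_clusters": self.mean_annotated_clusters,
        }


def randomization_report(
    scheme: str,
    network: nx.Graph,
    annotations: AnnotationMap,
    dag: OntologyDAG,
    n_reps: int,
    seed: int,
    alpha: float = 0.05,
    annot_threshold: float = 0.5,
) -> RandomizationReport:
    """Run the full pipeline under one null scheme, ``n_reps`` times.

    Replicate r uses seed ``seed + r``.  Edge-randomization schemes
    recluster the randomized network; the annotation and probability
    shuffles keep the observed clustering and perturb downstream stages
    only, mirroring what each control is meant to isolate.
    """
    from .pipeline import detect_from_inputs  # local import: no cycle

    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    report = RandomizationReport(scheme=scheme, n_reps=n_reps)
    base_system = None
    if scheme in ("annotation_shuffle", "probability_shuffle"):
        from .ocg import ocg_cluster
        base_system = ocg_cluster(network)
    for rep in range(n_reps):
        rep_seed = seed + rep
        net, ann, system = network, annotations, base_system
        if scheme == "annotation_shuffle":
            ann = shuffle_annotations(annotations, rep_seed)
        elif scheme == "edge_random":
            net = randomize_edges(network, "uniform", rep_seed)
            system = None
        elif scheme == "degree_preserving":
            net = randomize_edges(network, "degree_preserving", rep_seed)
            system = None
        result = detect_from_inputs(
            net, ann, dag, alpha=alpha, annot_threshold=annot_threshold,
            system=system,
            shuffle_probs_seed=(rep_seed if scheme == "probability_shuffle"
                                else None),
        )
        report.candidate_counts.append(len(result.candidates))
        report.annotated_cluster_counts.append(
            len(result.annotated_system.annotated_indices)
        )
    return report
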