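"""Majority-rule functional annotation of clusters.

A cluster becomes a *functional module* when at least half (by default)
of its annotated members share a propagated BP term; the set of
qualifying terms is reduced to its most specific members, because the
ancestor closure would otherwise always co-assign every parent of a
qualifying term.  Clusters whose members share nothing below the BP
root get the sentinel annotation "BP unknown".  Each protein then
inherits the annotations of every module it belongs to, on top of its
own propagated terms.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import UNKNOWN, ClusterSystem
from .ontology import AnnotationMap, OntologyDAG


@dataclass
class AnnotatedClusterSystem:
    """A cluster system plus per-cluster BP terms (or UNKNOWN).

    ``cluster_terms[i]`` is either a non-empty frozenset of mutually
    non-ancestral BP terms or the :data:`~moonnet.io_formats.UNKNOWN`
    sentinel.
    """

    system: ClusterSystem
    cluster_terms: dict[int, frozenset[str] | str]
    dag: OntologyDAG

    def terms_of(self, index: int) -> frozenset[str]:
        terms = self.cluster_terms[index]
        return frozenset() if terms == UNKNOWN else terms

    @property
    def annotated_indices(self) -> list[int]:
        return [i for i in range(len(self.system.clusters))
                if self.cluster_terms[i] != UNKNOWN]

    @property
    def term_universe(self) -> frozenset[str]:
        """All terms assigned to at least one cluster."""
        out: set[str] = set()
        for i in self.annotated_indices:
            out |= self.terms_of(i)
        return frozenset(out)


def annotate_cluster_members(
    members: frozenset[str],
    annotations: AnnotationMap,
    dag: OntologyDAG,
    threshold: float = 0.5,
) -> frozenset[str] | str:
    """Majority-rule terms for one member set (UNKNOWN if none qualify)."""
    annotated = [p for p in members if annotations.propagated(p)]
    if not annotated:
        return UNKNOWN
    support: dict[str, int] = {}
    for p in annotated:
        for term in annotations.propagated(p):
            support[term] = support.get(term, 0) + 1
    needed = threshold * len(annotated)
    qualifying = {t for t, c in support.items() if c >= needed}
    qualifying.discard(dag.root)
    if not qualifying:
        return UNKNOWN
    return dag.most_specific(qualifying)


def annotate_clusters(
    system: ClusterSystem,
    annotations: AnnotationMap,
    dag: OntologyDAG,
    threshold: float = 0.5,
) -> AnnotatedClusterSystem:
    """Assign majority-rule BP terms to every cluster of ``system``.

    For each cluster, let S be the members with at least one propagated
    BP term (root excluded).  A term qualifies iff at least
    ``threshold * |S|`` members of S carry it in their propagated sets;
    the assigned terms are the most specific qualifying terms.  Clusters
    with no qualifying non-root term (or empty S) are UNKNOWN.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    cluster_terms: dict[int, frozenset[str] | str] = {}
    for i, members in enumerate(system.clusters):
        cluster_terms[i] = annotate_cluster_members(
            members, annotations, dag, threshold
        )
    return AnnotatedClusterSystem(system=system, cluster_terms=cluster_terms,
                                  dag=dag)


def inherit_annotations(
    protein: str,
    annotated_system: AnnotatedClusterSystem,
    annotations: AnnotationMap,
) -> frozenset[str]:
    """A protein's own propagated terms plus its modules' assigned terms."""
    membership = annotated_system.system.membership
    if protein not in membership:
        raise KeyError(f"protein {protein} is not in the cluster system")
    inherited: set[str] = set(annotations.propagated(protein))
    for i in membership[protein]:
        inherited |= annotated_system.terms_of(i)  # UNKNOWN contributes nothing
    return frozenset(inherited)
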