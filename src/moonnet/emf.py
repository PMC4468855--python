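"""Extreme-multifunctional (EMF) candidate calling.

A protein is an EMF candidate when it sits at the intersection of two
clusters whose assigned biological processes are significantly
dissimilar: for some cross pair of the two clusters' terms, both the
annotation e-value and the interaction e-value are at or below the
significance threshold (0.05 by default).  Every qualifying
(cluster pair, term pair) combination is kept as evidence, which is what
the provenance classification and function-pair summaries consume.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass

from .io_formats import GeneList
from .module_annotation import AnnotatedClusterSystem
from .ontology import AnnotationMap
from .pronto import PairProbabilityTable

logger = logging.getLogger(__name__)

PROVENANCE_CLASSES = ("both_known", "one_inherited", "both_inherited")


@dataclass(frozen=True)
class Evidence:
    """One (cluster pair, term pair) combination that flags a protein."""

    cluster_a: int
    cluster_b: int
    go_a: str
    go_b: str
    e_annot: float
    e_inter: float


@dataclass(frozen=True)
class EMFCandidate:
    protein: str
    evidence: tuple[Evidence, ...]

    @property
    def term_pairs(self) -> set[tuple[str, str]]:
        return {tuple(sorted((ev.go_a, ev.go_b))) for ev in self.evidence}


def find_multiclustered(system) -> GeneList:
    """Proteins belonging to two or more clusters (sorted by ID)."""
    counts = {p: len(idx) for p, idx in system.membership.items()}
    multi = sorted(p for p, c in counts.items() if c >= 2)
    return GeneList(tuple(multi), label="multiclustered")


def find_emf_candidates(
    annotated_system: AnnotatedClusterSystem,
    pair_table: PairProbabilityTable,
    alpha: float = 0.05,
) -> list[EMFCandidate]:
    """Call EMF candidates from an annotated cluster system.

    For every multiclustered protein, every unordered pair of its
    clusters (both annotated), and every cross pair of distinct assigned
    terms, evidence is recorded iff both e-values are <= ``alpha``.
    Term pairs absent from ``pair_table`` are treated as non-significant
    (counted and logged).  Output is sorted by protein ID.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    system = annotated_system.system
    n_missing = 0
    candidates: list[EMFCandidate] = []
    for protein in sorted(system.membership, key=str):
        indices = sorted(system.membership[protein])
        if len(indices) < 2:
            continue
        evidence: list[Evidence] = []
        for i, j in itertools.combinations(indices, 2):
            terms_i = annotated_system.terms_of(i)
            terms_j = annotated_system.terms_of(j)
            if not terms_i or not terms_j:  # UNKNOWN clusters are skipped
                continue
            for go_a in sorted(terms_i):
                for go_b in sorted(terms_j):
                    if go_a == go_b:  # a term is never dissimilar to itself
                        continue
                    if (go_a, go_b) not in pair_table:
                        n_missing += 1
                        continue
                    if pair_table.is_dissimilar(go_a, go_b, alpha):
                        evidence.append(Evidence(
                            cluster_a=i, cluster_b=j, go_a=go_a, go_b=go_b,
                            e_annot=pair_table.e_annot(go_a, go_b),
                            e_inter=pair_table.e_inter(go_a, go_b),
                        ))
        if evidence:
            candidates.append(EMFCandidate(protein, tuple(evidence)))
    if n_missing:
        logger.info("find_emf_candidates: %d term pairs absent from the "
                    "pair table were treated as non-significant", n_missing)
    return candidates


def candidate_provenance(
    candidate: EMFCandidate, annotations: AnnotationMap
) -> str:
    """Did the protein already carry the dissimilar terms, or inherit them?

    Classified against the protein's own propagated terms, taking the
    best-supported evidence entry (both known > one inherited > both
    inherited).
    """
    if not candidate.evidence:
        raise ValueError("candidate has no evidence")
    own = annotations.propagated(candidate.protein)
    best = 0
    for ev in candidate.evidence:
        best = max(best, (ev.go_a in own) + (ev.go_b in own))
        if best == 2:
            break
    return {2: "both_known", 1: "one_inherited", 0: "both_inherited"}[best]


def provenance_breakdown(
    candidates: list[EMFCandidate], annotations: AnnotationMap
) -> dict[str, int]:
    """Counts of candidates per provenance class."""
    counts = Counter(candidate_provenance(c, annotations) for c in candidates)
    return {cls: counts.get(cls, 0) for cls in PROVENANCE_CLASSES}


def function_pair_summary(candidates: list[EMFCandidate]) -> Counter:
    """How many candidates each dissimilar term pair identified."""
    counts: Counter = Counter()
    for cand in candidates:
        for pair in cand.term_pairs:
            counts[pair] += 1
    return counts
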