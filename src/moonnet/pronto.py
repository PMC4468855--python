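"""Hypergeometric GO term-pair association probabilities ("PrOnto").

Two measures are computed for every unordered pair of distinct BP terms:

* the **annotation** probability asks whether the two terms annotate the
  same proteins more or less often than chance, counting proteins;
* the **interaction** probability asks whether proteins annotated to one
  term interact with proteins annotated to the other more or less often
  than chance, counting network edges.

Both use the hypergeometric distribution with counts (N, K, n, k):

annotation view (counting unit = proteins, direct annotations only,
restricted to proteins with >=2 distinct direct terms):
    N = proteins with at least two different direct annotations
    K = of those, proteins directly annotated to GO1
    n = of those, proteins directly annotated to GO2
    k = of those, proteins directly annotated to both

interaction view (counting unit = edges, both endpoints in the
multi-annotated universe):
    N = qualifying edges
    K = qualifying edges with an endpoint annotated to GO1
    n = qualifying edges with an endpoint annotated to GO2
    k = qualifying edges joining a GO1-annotated protein to a
        GO2-annotated one (either orientation; a single endpoint
        carrying both terms does not by itself create a cross pair)

Dissimilarity uses the LOWER tail P(X <= k): a small value means the two
processes co-occur (in proteins, or across interactions) far less than
expected, i.e. they are rarely performed together.  The upper tail is
exposed for similarity queries.  Multiple testing is corrected
Bonferroni-style: e-value = p * number of pairs evaluated.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx
from scipy.stats import hypergeom

from .ontology import AnnotationMap

logger = logging.getLogger(__name__)


def _check_counts(N: int, K: int, n: int, k: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"inconsistent hypergeometric counts N={N}, K={K}, "
                         f"n={n}, k={k}")


def hypergeom_lower(N: int, K: int, n: int, k: int) -> float:
    """P(X <= k) for X ~ Hypergeom(N, K, n)."""
    _check_counts(N, K, n, k)
    return float(hypergeom.cdf(k, N, K, n))


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n)."""
    _check_counts(N, K, n, k)
    return float(hypergeom.sf(k - 1, N, K, n))


@dataclass(frozen=True)
class PairCounts:
    N: int
    K: int
    n: int
    k: int


def annotation_counts(go1: str, go2: str, annotations: AnnotationMap,
                      propagated: bool = False) -> PairCounts:
    """(N, K, n, k) for the protein-counting (annotation) view."""
    if go1 == go2:
        raise ValueError("term pair must consist of two distinct terms")
    view = (
        {p: annotations.propagated(p) for p in annotations.proteins}
        if propagated
        else annotations.direct
    )
    universe = [ts for ts in view.values() if len(ts) >= 2]
    K = sum(1 for ts in universe if go1 in ts)
    n = sum(1 for ts in universe if go2 in ts)
    k = sum(1 for ts in universe if go1 in ts and go2 in ts)
    return PairCounts(N=len(universe), K=K, n=n, k=k)


def annotation_pvalue(go1: str, go2: str, annotations: AnnotationMap,
                      tail: str = "lower", propagated: bool = False) -> float:
    """Hypergeometric probability that GO1 and GO2 co-annotate proteins.

    ``tail="lower"`` (default) is the dissimilarity direction: small
    values mean the terms share fewer proteins than expected by chance.
    """
    c = annotation_counts(go1, go2, annotations, propagated=propagated)
    fn = hypergeom_lower if tail == "lower" else hypergeom_upper
    return fn(c.N, c.K, c.n, c.k)


def interaction_counts(go1: str, go2: str, network: nx.Graph,
                       annotations: AnnotationMap,
                       propagated: bool = False) -> PairCounts:
    """(N, K, n, k) for the edge-counting (interaction) view."""
    if go1 == go2:
        raise ValueError("term pair must consist of two distinct terms")
    if propagated:
        terms_of = annotations.propagated
    else:
        terms_of = lambda p: annotations.direct.get(p, frozenset())
    multi = {
        p for p in network.nodes()
        if len(terms_of(p)) >= 2
    }
    N = K = n = k = 0
    for u, v in network.edges():
        if u not in multi or v not in multi:
            continue
        N += 1
        tu, tv = terms_of(u), terms_of(v)
        has1 = go1 in tu or go1 in tv
        has2 = go2 in tu or go2 in tv
        if has1:
            K += 1
        if has2:
            n += 1
        if (go1 in tu and go2 in tv) or (go1 in tv and go2 in tu):
            k += 1
    return PairCounts(N=N, K=K, n=n, k=k)


def interaction_pvalue(go1: str, go2: str, network: nx.Graph,
                       annotations: AnnotationMap, tail: str = "lower",
                       propagated: bool = False) -> float:
    """Hypergeometric probability that GO1- and GO2-proteins interact."""
    c = interaction_counts(go1, go2, network, annotations,
                           propagated=propagated)
    fn = hypergeom_lower if tail == "lower" else hypergeom_upper
    return fn(c.N, c.K, c.n, c.k)


@dataclass(frozen=True)
class PairRow:
    p_annot: float
    p_inter: float
    counts_annot: PairCounts
    counts_inter: PairCounts


@dataclass
class PairProbabilityTable:
    """Per term-pair annotation/interaction p-values plus e-values.

    Rows are keyed by the unordered pair; ``n_tests`` is the number of
    pairs actually evaluated and multiplies every p-value into its
    e-value (reported values are capped at 1).
    """

    rows: dict[tuple[str, str], PairRow]
    n_tests: int
    n_skipped: int = 0

    @staticmethod
    def key(go1: str, go2: str) -> tuple[str, str]:
        return (go1, go2) if go1 <= go2 else (go2, go1)

    def __getitem__(self, pair: tuple[str, str]) -> PairRow:
        return self.rows[self.key(*pair)]

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return self.key(*pair) in self.rows

    def pairs(self) -> Iterator[tuple[str, str]]:
        return iter(self.rows)

    def e_annot(self, go1: str, go2: str) -> float:
        return min(1.0, self[go1, go2].p_annot * self.n_tests)

    def e_inter(self, go1: str, go2: str) -> float:
        return min(1.0, self[go1, go2].p_inter * self.n_tests)

    def is_dissimilar(self, go1: str, go2: str, alpha: float = 0.05) -> bool:
        """Both e-values at or below ``alpha``; unseen pairs are not
        dissimilar."""
        if (go1, go2) not in self:
            return False
        return (self.e_annot(go1, go2) <= alpha
                and self.e_inter(go1, go2) <= alpha)

    def dissimilar_pairs(self, alpha: float = 0.05) -> list[tuple[str, str]]:
        return sorted(p for p in self.rows if self.is_dissimilar(*p, alpha))

    def with_rows(self, rows: Mapping[tuple[str, str], PairRow]) -> "PairProbabilityTable":
        return PairProbabilityTable(rows=dict(rows), n_tests=self.n_tests,
                                    n_skipped=self.n_skipped)


def build_pair_table(
    terms: Iterable[str],
    network: nx.Graph,
    annotations: AnnotationMap,
    tail: str = "lower",
    propagated: bool = False,
) -> PairProbabilityTable:
    """Evaluate both PrOnto probabilities for every unordered term pair.

    ``terms`` is typically the set of terms assigned to clusters
    (:attr:`AnnotatedClusterSystem.term_universe`) but may be any term
    list.  Pairs with an empty margin (K = 0 or n = 0) in either view
    carry no information and are skipped; they do not count toward
    ``n_tests``.
    """
    term_list = sorted(set(terms))
    if len(term_list) < 2:
        raise ValueError("term universe must contain at least two terms")
    rows: dict[tuple[str, str], PairRow] = {}
    n_skipped = 0
    for go1, go2 in itertools.combinations(term_list, 2):
        ca = annotation_counts(go1, go2, annotations, propagated=propagated)
        ci = interaction_counts(go1, go2, network, annotations,
                                propagated=propagated)
        if min(ca.K, ca.n, ci.K, ci.n) == 0:
            n_skipped += 1
            continue
        fn = hypergeom_lower if tail == "lower" else hypergeom_upper
        rows[(go1, go2)] = PairRow(
            p_annot=fn(ca.N, ca.K, ca.n, ca.k),
            p_inter=fn(ci.N, ci.K, ci.n, ci.k),
            counts_annot=ca,
            counts_inter=ci,
        )
    if n_skipped:
        logger.info("build_pair_table: skipped %d pairs with an empty margin",
                    n_skipped)
    return PairProbabilityTable(rows=rows, n_tests=len(rows),
                                n_skipped=n_skipped)
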