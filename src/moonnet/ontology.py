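"""GO biological-process ontology handling and protein annotation maps.

The ontology is reduced to its biological_process (BP) sub-DAG.  True-path
propagation follows ``is_a`` and ``part_of`` edges only; regulates-type
relations are not propagated (logged once per parse).  The BP root is
never assignable as an annotation: it is excluded from propagated sets so
that a cluster whose members share only the root is reported as unknown.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: Relations that follow the GO true-path rule and are propagated.
PROPAGATED_RELATIONS = ("is_a", "part_of")


class OntologyError(ValueError):
    """Structural problem in the ontology (cycle, dangling parent...)."""


@dataclass
class OntologyDAG:
    """A rooted, acyclic BP term DAG.

    ``parents`` holds the union of ``is_a`` and ``part_of`` parents for
    every term; ``root`` is the unique parentless BP term.
    """

    parents: dict[str, frozenset[str]]
    root: str
    names: dict[str, str] = field(default_factory=dict)
    _ancestor_cache: dict[str, frozenset[str]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        terms = set(self.parents)
        for term, ps in self.parents.items():
            missing = ps - terms
            if missing:
                raise OntologyError(
                    f"term {term} has parent(s) outside the ontology: "
                    f"{sorted(missing)}"
                )
        if self.root not in terms:
            raise OntologyError(f"root {self.root} not among terms")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        graph = nx.DiGraph()
        graph.add_nodes_from(self.parents)
        for term, ps in self.parents.items():
            for p in ps:
                graph.add_edge(term, p)
        try:
            cycle = nx.find_cycle(graph)
        except nx.NetworkXNoCycle:
            return
        raise OntologyError(f"ontology contains a cycle through {cycle[0][0]}")

    @property
    def terms(self) -> set[str]:
        return set(self.parents)

    def __contains__(self, term: object) -> bool:
        return term in self.parents

    def ancestors(self, term: str) -> frozenset[str]:
        """All (proper) ancestors of ``term`` under is_a/part_of."""
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        if term not in self.parents:
            raise KeyError(term)
        out: set[str] = set()
        stack = list(self.parents[term])
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents[t])
        result = frozenset(out)
        self._ancestor_cache[term] = result
        return result

    def closure(self, terms: Iterable[str], include_root: bool = False) -> frozenset[str]:
        """Terms plus all their ancestors (root excluded unless asked)."""
        out: set[str] = set()
        for t in terms:
            out.add(t)
            out |= self.ancestors(t)
        if not include_root:
            out.discard(self.root)
        return frozenset(out)

    def is_ancestor(self, candidate: str, term: str) -> bool:
        return candidate in self.ancestors(term)

    def most_specific(self, terms: Iterable[str]) -> frozenset[str]:
        """Drop every term that is an ancestor of another term in the set."""
        terms = set(terms)
        redundant = set()
        for t in terms:
            redundant |= self.ancestors(t) & terms
        return frozenset(terms - redundant)


def read_obo(path: str | Path, namespace: str = "biological_process") -> OntologyDAG:
    """Parse an OBO 1.2 ontology and keep the BP sub-DAG.

    Obsolete terms are dropped (obonet default); ``is_a`` and
    ``relationship: part_of`` edges are retained, anything else ignored.
    The root is the unique parentless term of the namespace.
    """
    graph = obonet.read_obo(path)
    parents: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    keep = {
        t for t, data in graph.nodes(data=True)
        if data.get("namespace", namespace) == namespace
    }
    for term in keep:
        parents[term] = set()
        names[term] = graph.nodes[term].get("name", "")
    n_other_rel = 0
    for child, parent, rel in graph.edges(keys=True):
        if child not in keep:
            continue
        if rel not in PROPAGATED_RELATIONS:
            n_other_rel += 1
            continue
        if parent not in keep:
            raise OntologyError(
                f"term {child} has {rel} parent {parent} outside the "
                f"{namespace} namespace or missing from the file"
            )
        parents[child].add(parent)
    if n_other_rel:
        logger.info("read_obo(%s): ignored %d non-is_a/part_of relations",
                    path, n_other_rel)
    roots = sorted(t for t, ps in parents.items() if not ps)
    if len(roots) != 1:
        raise OntologyError(
            f"expected exactly one parentless {namespace} term, found "
            f"{roots[:5]}"
        )
    return OntologyDAG(
        parents={t: frozenset(ps) for t, ps in parents.items()},
        root=roots[0],
        names=names,
    )


def build_dag(parents: Mapping[str, Iterable[str]], root: str,
              names: Mapping[str, str] | None = None) -> OntologyDAG:
    """Construct a DAG directly from a term → parents mapping."""
    return OntologyDAG(
        parents={t: frozenset(ps) for t, ps in parents.items()},
        root=root,
        names=dict(names or {}),
    )


@dataclass
class AnnotationMap:
    """Direct and propagated protein → BP-term assignments.

    ``direct`` holds the terms as annotated; propagated sets add every
    is_a/part_of ancestor with the BP root excluded, so
    ``propagated(p) ⊇ direct(p)`` minus the root and propagated sets are
    closed under parents.
    """

    direct: dict[str, frozenset[str]]
    dag: OntologyDAG
    _propagated: dict[str, frozenset[str]] | None = field(
        default=None, repr=False, compare=False
    )

    def propagated(self, protein: str, include_root: bool = False) -> frozenset[str]:
        if include_root:
            return self.dag.closure(self.direct.get(protein, frozenset()),
                                    include_root=True)
        if self._propagated is None:
            self._propagated = {}
        cached = self._propagated.get(protein)
        if cached is None:
            cached = self.dag.closure(self.direct.get(protein, frozenset()))
            self._propagated[protein] = cached
        return cached

    @property
    def proteins(self) -> set[str]:
        return set(self.direct)

    def multi_annotated(self) -> set[str]:
        """Proteins carrying >=2 distinct direct terms (the PrOnto universe)."""
        return {p for p, ts in self.direct.items() if len(ts) >= 2}

    def with_direct(self, direct: Mapping[str, Iterable[str]]) -> "AnnotationMap":
        return AnnotationMap(
            direct={p: frozenset(ts) for p, ts in direct.items()},
            dag=self.dag,
        )


def read_gaf(path: str | Path, dag: OntologyDAG) -> AnnotationMap:
    """Read protein annotations from GAF 2.x or a two-column TSV.

    GAF rows with a NOT qualifier are excluded; rows whose term is not in
    the (BP) DAG are skipped with a logged warning.  Evidence codes are
    deliberately not filtered: electronically inferred (IEA) annotations
    are kept.
    """
    path = Path(path)
    with open(path) as handle:
        first = handle.readline()
    if first.startswith("!") or len(first.rstrip("\n").split("\t")) >= 15:
        direct = _read_gaf_proper(path)
    else:
        direct = _read_two_column(path)
    kept: dict[str, set[str]] = {}
    n_skipped = 0
    for protein, terms in direct.items():
        for term in terms:
            if term in dag:
                kept.setdefault(protein, set()).add(term)
            else:
                n_skipped += 1
    if n_skipped:
        logger.warning("read_gaf(%s): skipped %d rows with terms outside "
                       "the DAG/namespace", path, n_skipped)
    return AnnotationMap(
        direct={p: frozenset(ts) for p, ts in kept.items()}, dag=dag
    )


def _read_gaf_proper(path: Path) -> dict[str, set[str]]:
    from Bio.UniProt import GOA

    direct: dict[str, set[str]] = {}
    with open(path) as handle:
        for rec in GOA.gafiterator(handle):
            if "NOT" in rec.get("Qualifier", []):
                continue
            if rec.get("Aspect") not in ("P", ""):  # BP only
                continue
            direct.setdefault(rec["DB_Object_ID"], set()).add(rec["GO_ID"])
    return direct


def _read_two_column(path: Path) -> dict[str, set[str]]:
    direct: dict[str, set[str]] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'protein<TAB>GO term'"
                )
            direct.setdefault(fields[0], set()).add(fields[1])
    return direct
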