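"""Readers and writers for every external artifact the pipeline touches.

Networks arrive as two-column TSV edge lists or PSI-MITAB 2.5; cluster
systems ("class files") use a simple one-cluster-per-line dialect; gene
lists are one ID per line.  All writers emit lexicographically sorted,
deterministic TSVs so identical inputs yield byte-identical outputs.

Protein identifiers are opaque, case-sensitive strings throughout: any
mapping between identifier spaces (UniProt accessions, gene symbols,
isoform collapsing) is assumed to have happened upstream.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

_GO_TERM_RE = re.compile(r"^GO:\d+$")

#: Sentinel used for clusters whose members share no informative BP term.
UNKNOWN = "BP unknown"

#: Single-token spelling of the sentinel used in class files.
_UNKNOWN_TOKEN = "BP_unknown"


class ParseError(ValueError):
    """A malformed input file; the message names the offending line."""


@dataclass(frozen=True)
class GeneList:
    """An ordered, duplicate-free list of protein IDs with a label."""

    ids: tuple[str, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError(f"duplicate IDs in gene list {self.label!r}")

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(self.ids)

    def __contains__(self, item: object) -> bool:
        return item in set(self.ids)


@dataclass
class ClusterSystem:
    """An overlapping system of protein clusters covering a network.

    ``clusters`` is an ordered list of member sets; ``ids`` are the
    cluster labels used in class files (defaults to 1-based indices).
    ``membership`` maps each protein to the indices of the clusters that
    contain it and is always the exact inverse of ``clusters``.
    """

    clusters: list[frozenset[str]]
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.ids:
            self.ids = [str(i + 1) for i in range(len(self.clusters))]
        if len(self.ids) != len(self.clusters):
            raise ValueError("cluster ids and clusters differ in length")
        self.clusters = [frozenset(c) for c in self.clusters]

    @property
    def membership(self) -> dict[str, set[int]]:
        out: dict[str, set[int]] = {}
        for i, cluster in enumerate(self.clusters):
            for protein in cluster:
                out.setdefault(protein, set()).add(i)
        return out

    @property
    def proteins(self) -> set[str]:
        out: set[str] = set()
        for c in self.clusters:
            out |= c
        return out

    def __len__(self) -> int:
        return len(self.clusters)


def read_network(path: str | Path, format: str = "tsv") -> nx.Graph:
    """Read an undirected simple interaction network.

    Self-interactions and duplicate edges are silently dropped (counts
    are logged); the node set is the union of all edge endpoints.

    Parameters
    ----------
    path
        Edge-list file.
    format
        ``"tsv"`` — two whitespace-separated ID columns per line,
        ``#`` comments allowed; ``"mitab"`` — PSI-MITAB 2.5, interactor
        primary identifiers taken from columns 1–2 with any
        ``uniprotkb:`` prefix stripped.
    """
    path = Path(path)
    if format not in ("tsv", "mitab"):
        raise ValueError(f"unknown network format {format!r}")
    graph = nx.Graph()
    n_self = n_dup = 0
    n_edges_seen = 0
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if format == "mitab" and line.startswith("ID("):  # header row
                continue
            if format == "tsv":
                fields = line.split()
                if len(fields) != 2:
                    raise ParseError(
                        f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                    )
                a, b = fields
            else:
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ParseError(
                        f"{path}:{lineno}: expected >=2 tab-separated MITAB "
                        f"columns, got {len(fields)}"
                    )
                a, b = (_mitab_id(fields[0]), _mitab_id(fields[1]))
            n_edges_seen += 1
            if a == b:
                n_self += 1
                graph.add_node(a)
                continue
            if graph.has_edge(a, b):
                n_dup += 1
                continue
            graph.add_edge(a, b)
    if n_edges_seen == 0:
        raise ParseError(f"{path}: no interactions found")
    if n_self or n_dup:
        logger.info(
            "read_network(%s): dropped %d self-interactions, %d duplicate edges",
            path, n_self, n_dup,
        )
    return graph


def _mitab_id(column: str) -> str:
    """First identifier of a MITAB interactor column, prefix stripped."""
    first = column.split("|")[0].strip()
    if first.lower().startswith("uniprotkb:"):
        return first.split(":", 1)[1]
    return first


def write_network(network: nx.Graph, path: str | Path) -> None:
    """Write a sorted two-column TSV edge list (isolated nodes as comments)."""
    path = Path(path)
    edges = sorted(tuple(sorted(e)) for e in network.edges())
    isolated = sorted(n for n in network.nodes() if network.degree(n) == 0)
    with open(path, "w") as handle:
        for node in isolated:
            handle.write(f"# isolated\t{node}\n")
        for a, b in edges:
            handle.write(f"{a}\t{b}\n")


def read_gene_list(path: str | Path, label: str = "") -> GeneList:
    """Read a plain-text one-ID-per-line gene list ('#' comments allowed)."""
    ids: list[str] = []
    seen: set[str] = set()
    with open(path) as handle:
        for raw in handle:
            token = raw.strip()
            if not token or token.startswith("#"):
                continue
            if token not in seen:
                seen.add(token)
                ids.append(token)
    return GeneList(tuple(ids), label or Path(path).stem)


def write_gene_list(genes: GeneList, path: str | Path) -> None:
    with open(path, "w") as handle:
        for protein in genes:
            handle.write(protein + "\n")


def read_class_file(
    path: str | Path,
) -> tuple[ClusterSystem, dict[str, frozenset[str]] | None]:
    """Read a cluster "class file".

    Dialect (auto-detected and logged): one record per line,
    ``clusterID<TAB>member1 member2 ...``.  A line whose tokens are all
    GO terms (``GO:``-prefixed) is an *annotation* line attaching terms
    to a previously declared cluster.  Returns the cluster system and,
    if any annotation line was present, a cluster-ID → term-set map.
    """
    path = Path(path)
    clusters: dict[str, frozenset[str]] = {}
    order: list[str] = []
    annotations: dict[str, frozenset[str]] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 'clusterID<TAB>members', "
                    f"got {len(parts)} tab-separated fields"
                )
            cid, payload = parts[0].strip(), parts[1].split()
            if not payload:
                raise ParseError(f"{path}:{lineno}: empty member list")
            is_annotation = all(
                _GO_TERM_RE.match(t) or t == _UNKNOWN_TOKEN for t in payload
            )
            if is_annotation:
                if cid not in clusters:
                    raise ParseError(
                        f"{path}:{lineno}: annotation line references "
                        f"undeclared cluster {cid!r}"
                    )
                annotations[cid] = frozenset(
                    t for t in payload if t != _UNKNOWN_TOKEN
                )
            else:
                if cid in clusters:
                    raise ParseError(
                        f"{path}:{lineno}: duplicate cluster ID {cid!r}"
                    )
                clusters[cid] = frozenset(payload)
                order.append(cid)
    if not clusters:
        raise ParseError(f"{path}: no clusters found")
    dialect = "annotated" if annotations else "plain"
    logger.info("read_class_file(%s): dialect=%s, %d clusters", path, dialect,
                len(clusters))
    system = ClusterSystem([clusters[cid] for cid in order], ids=list(order))
    return system, (
        {cid: annotations.get(cid, frozenset()) for cid in order}
        if annotations
        else None
    )


def write_class_file(
    system: ClusterSystem,
    path: str | Path,
    annotations: Mapping[int, frozenset[str] | str] | None = None,
) -> None:
    """Write a class file; ``annotations`` maps cluster index → terms.

    UNKNOWN clusters are written with the sentinel on their annotation
    line so the file round-trips the full annotation state.
    """
    with open(path, "w") as handle:
        for i in sorted(range(len(system.clusters)), key=lambda j: system.ids[j]):
            members = " ".join(sorted(system.clusters[i]))
            handle.write(f"{system.ids[i]}\t{members}\n")
            if annotations is not None and i in annotations:
                terms = annotations[i]
                if terms == UNKNOWN or not terms:
                    handle.write(f"{system.ids[i]}\t{_UNKNOWN_TOKEN}\n")
                else:
                    handle.write(f"{system.ids[i]}\t{' '.join(sorted(terms))}\n")


def write_outputs(candidates, pair_table, annotated_system, out_dir: str | Path) -> dict[str, Path]:
    """Write candidates.tsv, pronto.tsv and classes.tsv into ``out_dir``.

    All tables are lexicographically sorted; re-running on identical
    inputs produces byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "candidates": out_dir / "candidates.tsv",
        "pronto": out_dir / "pronto.tsv",
        "classes": out_dir / "classes.tsv",
    }

    rows = []
    for cand in candidates:
        for ev in cand.evidence:
            rows.append((
                cand.protein,
                annotated_system.system.ids[ev.cluster_a],
                annotated_system.system.ids[ev.cluster_b],
                ev.go_a, ev.go_b,
                f"{ev.e_annot:.6g}", f"{ev.e_inter:.6g}",
            ))
    with open(paths["candidates"], "w") as handle:
        handle.write("protein\tclusterA\tclusterB\tGO_a\tGO_b\te_annot\te_inter\n")
        for row in sorted(rows):
            handle.write("\t".join(row) + "\n")

    with open(paths["pronto"], "w") as handle:
        handle.write("GO1\tGO2\tp_annot\te_annot\tp_inter\te_inter\n")
        for go1, go2 in sorted(pair_table.pairs()):
            row = pair_table[go1, go2]
            handle.write(
                f"{go1}\t{go2}\t{row.p_annot:.6g}\t"
                f"{pair_table.e_annot(go1, go2):.6g}\t{row.p_inter:.6g}\t"
                f"{pair_table.e_inter(go1, go2):.6g}\n"
            )

    write_class_file(
        annotated_system.system, paths["classes"],
        annotations=annotated_system.cluster_terms,
    )
    return paths
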