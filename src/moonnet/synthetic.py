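"""Seeded synthetic scenarios with planted modules and planted EMFs.

The generator emulates the structure the detection method assumes: a
network of dense functional modules (intra-module edge probability
``p_in``, inter-module noise ``p_out``), a shallow ontology with one
branch of two leaf terms per module under a common root, and proteins
annotated to their module's leaf pair with probability
``annotation_purity`` (otherwise to another module's pair).  Every
protein therefore carries two distinct direct terms, as the pair
statistics require.  Shared nodes belong to two modules each and are
the planted extreme-multifunctional proteins: their clusters end up
annotated to different branches, and cross-branch term pairs are
dissimilar on this corpus because no protein (up to noise) and almost
no interaction links the two branches.

Everything is deterministic given the seed; no global random state is
touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .io_formats import ClusterSystem, GeneList, write_gene_list, write_network
from .ontology import AnnotationMap, OntologyDAG, build_dag

ROOT = "GO:0000001"


@dataclass(frozen=True)
class ScenarioParams:
    """Study conditions for a planted scenario.

    Defaults are the "easy" regime used throughout the test suite:
    clique modules, near-zero background noise, high annotation purity.
    """

    n_modules: int = 3
    module_size: int = 20
    p_in: float = 1.0
    p_out: float = 0.0
    n_shared_nodes: int = 2
    annotation_purity: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module_size < 3:
            raise ValueError("module_size must be >= 3")
        if self.n_modules < 2:
            raise ValueError("need at least two modules")
        if self.n_shared_nodes > self.module_size:
            raise ValueError("more shared nodes than fit in a module")
        for p in (self.p_in, self.p_out, self.annotation_purity):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def recoverable(self) -> bool:
        """Planted modules are in principle recoverable (denser inside)."""
        return self.p_in > self.p_out


@dataclass
class PlantedScenario:
    network: nx.Graph
    true_modules: list[frozenset[str]]
    dag: OntologyDAG
    annotations: AnnotationMap
    planted_emfs: GeneList
    #: leaf-term pair of each module's ontology branch
    module_terms: list[tuple[str, str]] = field(default_factory=list)
    params: ScenarioParams = field(default_factory=ScenarioParams)


def _term_id(i: int) -> str:
    return f"GO:{i:07d}"


def generate_scenario(params: ScenarioParams) -> PlantedScenario:
    """Build a fully deterministic planted scenario from ``params``."""
    rng = np.random.default_rng(params.seed)
    k = params.n_modules

    # shared nodes: node s is a member of modules (s mod k, s+1 mod k)
    shared = [f"S{s:02d}" for s in range(params.n_shared_nodes)]
    shared_modules = {
        s_name: (s % k, (s + 1) % k) for s, s_name in enumerate(shared)
    }
    modules: list[set[str]] = [set() for _ in range(k)]
    for s_name, (i, j) in shared_modules.items():
        modules[i].add(s_name)
        modules[j].add(s_name)
    for i in range(k):
        n_exclusive = params.module_size - len(modules[i])
        if n_exclusive < 2:
            raise ValueError("module_size too small for the shared nodes")
        modules[i].update(f"M{i}_{j:02d}" for j in range(n_exclusive))

    network = nx.Graph()
    nodes = sorted(set().union(*modules))
    network.add_nodes_from(nodes)
    within: set[frozenset[str]] = set()
    for members in modules:
        ordered = sorted(members)
        for a_idx in range(len(ordered)):
            for b_idx in range(a_idx + 1, len(ordered)):
                within.add(frozenset((ordered[a_idx], ordered[b_idx])))
    for pair in sorted(within, key=sorted):
        if rng.random() < params.p_in:
            network.add_edge(*sorted(pair))
    if params.p_out > 0:
        for a_idx in range(len(nodes)):
            for b_idx in range(a_idx + 1, len(nodes)):
                pair = frozenset((nodes[a_idx], nodes[b_idx]))
                if pair in within:
                    continue
                if rng.random() < params.p_out:
                    network.add_edge(nodes[a_idx], nodes[b_idx])

    # ontology: one branch (parent + two leaves) per module under the root
    parents: dict[str, set[str]] = {ROOT: set()}
    names = {ROOT: "biological process (root)"}
    module_terms: list[tuple[str, str]] = []
    next_id = 2
    for i in range(k):
        branch = _term_id(next_id); next_id += 1
        leaf_a = _term_id(next_id); next_id += 1
        leaf_b = _term_id(next_id); next_id += 1
        parents[branch] = {ROOT}
        parents[leaf_a] = {branch}
        parents[leaf_b] = {branch}
        names[branch] = f"planted process {i}"
        names[leaf_a] = f"planted process {i}, facet a"
        names[leaf_b] = f"planted process {i}, facet b"
        module_terms.append((leaf_a, leaf_b))
    dag = build_dag(parents, root=ROOT, names=names)

    home = {}
    for i, members in enumerate(modules):
        for p in members:
            home.setdefault(p, i)  # shared nodes: lowest module index wins
    direct: dict[str, frozenset[str]] = {}
    for p in nodes:
        module = home[p]
        if rng.random() >= params.annotation_purity:
            others = [i for i in range(k) if i != module]
            module = others[int(rng.integers(len(others)))]
        direct[p] = frozenset(module_terms[module])
    annotations = AnnotationMap(direct=direct, dag=dag)

    return PlantedScenario(
        network=network,
        true_modules=[frozenset(m) for m in modules],
        dag=dag,
        annotations=annotations,
        planted_emfs=GeneList(tuple(shared), label="planted EMFs"),
        module_terms=module_terms,
        params=params,
    )


def recovery_score(found_clusters, true_modules) -> float:
    """Best-match Jaccard: mean over true modules of the best overlap."""
    if isinstance(found_clusters, ClusterSystem):
        found = list(found_clusters.clusters)
    else:
        found = [frozenset(c) for c in found_clusters]
    true = [frozenset(m) for m in true_modules]
    if not found or not true:
        raise ValueError("both cluster systems must be non-empty")
    total = 0.0
    for module in true:
        best = 0.0
        for cluster in found:
            union = len(module | cluster)
            if union:
                best = max(best, len(module & cluster) / union)
        total += best
    return total / len(true)


def write_scenario(scenario: PlantedScenario, out_dir: str | Path) -> dict[str, Path]:
    """Write the scenario in standard formats (TSV network, OBO, 2-col
    annotations, planted-EMF gene list)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": out_dir / "network.tsv",
        "obo": out_dir / "ontology.obo",
        "annotations": out_dir / "annotations.tsv",
        "planted": out_dir / "planted_emfs.txt",
    }
    write_network(scenario.network, paths["network"])
    _write_obo(scenario.dag, paths["obo"])
    with open(paths["annotations"], "w") as handle:
        for protein in sorted(scenario.annotations.direct):
            for term in sorted(scenario.annotations.direct[protein]):
                handle.write(f"{protein}\t{term}\n")
    write_gene_list(scenario.planted_emfs, paths["planted"])
    return paths


def _write_obo(dag: OntologyDAG, path: Path) -> None:
    with open(path, "w") as handle:
        handle.write("format-version: 1.2\n")
        for term in sorted(dag.terms):
            handle.write("\n[Term]\n")
            handle.write(f"id: {term}\n")
            handle.write(f"name: {dag.names.get(term, term)}\n")
            handle.write("namespace: biological_process\n")
            for parent in sorted(dag.parents[term]):
                handle.write(f"is_a: {parent} ! {dag.names.get(parent, '')}\n")
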