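"""End-to-end orchestration: cluster → annotate → pair table → detect.

:func:`detect_from_inputs` is the in-memory pipeline used by the
library, the CLI and the randomization controls;
:func:`run_pipeline` adds file I/O, a ``summary.json`` with every
headline count, and deterministic outputs (identical inputs and
configuration yield byte-identical files).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from . import io_formats
from .emf import EMFCandidate, find_emf_candidates, find_multiclustered, \
    provenance_breakdown
from .io_formats import ClusterSystem
from .module_annotation import AnnotatedClusterSystem, annotate_clusters
from .ocg import ocg_cluster
from .ontology import AnnotationMap, OntologyDAG, read_gaf, read_obo
from .pronto import PairProbabilityTable, build_pair_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    network: nx.Graph
    annotated_system: AnnotatedClusterSystem
    pair_table: PairProbabilityTable
    candidates: list[EMFCandidate]

    def summary(self, annotations: AnnotationMap | None = None) -> dict:
        system = self.annotated_system.system
        multi = find_multiclustered(system)
        sizes = [len(c) for c in system.clusters]
        out = {
            "n_nodes": self.network.number_of_nodes(),
            "n_edges": self.network.number_of_edges(),
            "n_clusters": len(system.clusters),
            "mean_cluster_size": sum(sizes) / len(sizes),
            "n_annotated_clusters": len(self.annotated_system.annotated_indices),
            "n_multiclustered": len(multi),
            "n_candidates": len(self.candidates),
            "n_tests": self.pair_table.n_tests,
        }
        if annotations is not None:
            out["provenance"] = provenance_breakdown(self.candidates,
                                                     annotations)
        return out


def detect_from_inputs(
    network: nx.Graph,
    annotations: AnnotationMap,
    dag: OntologyDAG,
    alpha: float = 0.05,
    annot_threshold: float = 0.5,
    system: ClusterSystem | None = None,
    shuffle_probs_seed: int | None = None,
) -> PipelineResult:
    """Run cluster → annotate → pair table → detect in memory.

    ``system`` short-circuits the clustering stage (e.g. a class file
    read from disk, or a cached clustering reused across null
    replicates); ``shuffle_probs_seed`` permutes the pair-probability
    table before detection (the probability-reshuffle control).
    """
    if system is None:
        system = ocg_cluster(network)
    annotated = annotate_clusters(system, annotations, dag,
                                  threshold=annot_threshold)
    terms = annotated.term_universe
    if len(terms) < 2:
        logger.info("detect_from_inputs: fewer than two distinct cluster "
                    "terms; no pairs to test")
        empty = PairProbabilityTable(rows={}, n_tests=0)
        return PipelineResult(network, annotated, empty, [])
    table = build_pair_table(terms, network, annotations)
    if shuffle_probs_seed is not None:
        from .validation import shuffle_pair_probabilities
        table = shuffle_pair_probabilities(table, shuffle_probs_seed)
    candidates = find_emf_candidates(annotated, table, alpha=alpha)
    return PipelineResult(network, annotated, table, candidates)


@dataclass
class RunConfig:
    """Paths and knobs for a file-based pipeline run."""

    network: str | Path
    obo: str | Path
    gaf: str | Path
    out_dir: str | Path
    network_format: str = "tsv"
    alpha: float = 0.05
    annot_threshold: float = 0.5
    classes: str | Path | None = None  # precomputed class file

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if not 0 < self.annot_threshold <= 1:
            raise ValueError("annot_threshold must be in (0, 1]")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full flow from files, writing all outputs.

    Writes ``classes.tsv``, ``pronto.tsv``, ``candidates.tsv`` and
    ``summary.json`` into ``config.out_dir`` and returns that directory.
    Stage failures propagate with the stage name prefixed.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def _stage(name, fn, *args, **kwargs):
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        logger.info("stage %s: done", name)
        return result

    network = _stage("read_network", io_formats.read_network,
                     config.network, format=config.network_format)
    dag = _stage("read_obo", read_obo, config.obo)
    annotations = _stage("read_gaf", read_gaf, config.gaf, dag)
    if config.classes is not None:
        system, _ = _stage("read_class_file", io_formats.read_class_file,
                           config.classes)
    else:
        system = _stage("cluster", ocg_cluster, network)
    result = _stage(
        "detect", detect_from_inputs, network, annotations, dag,
        alpha=config.alpha, annot_threshold=config.annot_threshold,
        system=system,
    )
    _stage("write_outputs", io_formats.write_outputs,
           result.candidates, result.pair_table, result.annotated_system,
           out_dir)
    summary = result.summary(annotations)
    with open(out_dir / "summary.json", "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return out_dir
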