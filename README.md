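# moonnet

Detection of **extreme multifunctional (EMF) proteins** — candidates for
moonlighting behaviour — from a protein–protein interaction network and
Gene Ontology annotations.

Moonlighting proteins perform several autonomous, often unrelated
functions. They are discovered serendipitously, so no large catalogue
exists to learn from. `moonnet` implements a network-based inference
that needs no training data: a protein sitting at the intersection of
two network modules whose biological processes are *statistically
dissimilar* is a candidate for extreme multifunctionality.

The pipeline has four stages:

1. **Overlapping clustering.** The interactome is covered with a system
   of possibly overlapping clusters: centered cliques are grown around
   every vertex and greedily merged while the overlap modularity

   `Q = (1/2m) · Σ_{(u,v) share a cluster} [A_uv − d_u·d_v/(2m)]`

   strictly increases (sum over ordered node pairs including the
   diagonal null terms, each pair counted once however many clusters it
   shares). Dense, functionally coherent neighbourhoods end up in the
   same cluster; multifunctional proteins end up in several.

2. **Module annotation.** A cluster becomes a *functional module* when
   ≥ 50 % of its annotated members share a GO biological-process term
   (direct annotations plus all `is_a`/`part_of` ancestors; the BP root
   never counts). Assigned terms are reduced to the most specific ones,
   and every protein inherits its modules' annotations.

3. **Term-pair dissimilarity.** For each pair of module terms
   (GO₁, GO₂), two hypergeometric probabilities with counts (N, K, n, k)
   ask whether the terms co-occur *less* often than chance —
   over proteins (N = proteins with ≥ 2 distinct direct terms,
   K/n = those annotated to GO₁/GO₂, k = both) and over interactions
   (N = edges between multi-annotated proteins, K/n = edges involving
   GO₁/GO₂, k = edges joining a GO₁ protein to a GO₂ protein). Small
   lower-tail values mean the two processes are rarely performed
   together. Each p-value is Bonferroni-corrected into an e-value by the
   number of pairs tested.

4. **Candidate calling.** A protein in two modules whose term pair has
   both e-values ≤ 0.05 is an EMF candidate; every qualifying
   (cluster pair, term pair) combination is kept as evidence.

Also included: the four randomization controls (annotation shuffle,
uniform and degree-preserving edge randomization, probability
reshuffle), leave-one-out annotation recovery, hypergeometric gene-set
enrichment, topological characterization of candidate groups
(degree, betweenness, shortest paths, hubs, rank-sum comparisons), and a
seeded generator of planted synthetic scenarios that makes the whole
pipeline testable offline.

## Worked example

```python
import moonnet as mn
from moonnet.synthetic import ScenarioParams, generate_scenario

scenario = generate_scenario(ScenarioParams(seed=7))
result = mn.detect_from_inputs(scenario.network, scenario.annotations,
                               scenario.dag)
print(result.summary(scenario.annotations))
```

prints

```
{'n_nodes': 58, 'n_edges': 570, 'n_clusters': 3, 'mean_cluster_size': 20.0,
 'n_annotated_clusters': 3, 'n_multiclustered': 2, 'n_candidates': 2,
 'n_tests': 15, 'provenance': {'both_known': 0, 'one_inherited': 2,
 'both_inherited': 0}}
```

The scenario plants three clique-like modules of 20 proteins with two
shared proteins; the pipeline recovers all three modules, tests 15 term
pairs, and calls exactly the two shared proteins as candidates. Each is
classified `one_inherited`: it carried one of the dissimilar processes
itself and inherited the other from a module — the signature of an
inferred extra function. The scripts in `examples/` walk through each
capability (clustering, pair dissimilarity, detection + controls) and
print a line explaining every number; the `moonnet` command exposes the
same stages as subcommands (`moonnet simulate`, `cluster`, `annotate`,
`pronto`, `detect` via `run`, `randomize`, `validate`, `characterize`).

At its published scale this method, applied to a 12,865-protein human
interactome, identified 430 EMF candidates that were 4.6-fold enriched
in independently curated moonlighting proteins.

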