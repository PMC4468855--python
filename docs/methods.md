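# Methods

## Model and assumptions

`moonnet` infers extreme multifunctionality from two ingredients: the
modular structure of a protein–protein interaction network, and protein
annotations in the Gene Ontology biological-process (BP) namespace. The
underlying assumptions are the usual ones for module-based function
prediction: densely interconnected neighbourhoods of the interactome
correspond to cellular processes; a protein belonging to several such
neighbourhoods participates in several processes; and if those
processes are almost never carried out by one protein, or by two
interacting proteins, elsewhere in the corpus, the protein is an
*extreme* multifunctional (EMF) candidate.

The network is an undirected simple graph of opaque protein
identifiers. Self-interactions and duplicate edges are dropped at
parse time. Any identifier mapping (database cross-references, isoform
collapsing, sequence-similarity merging) is assumed to have happened
upstream.

## Overlapping clustering

The cluster stage covers the graph with a system of possibly
overlapping clusters:

1. *Centered cliques.* For every vertex v (lexicographic order) a
   clique is grown from {v}: repeatedly add the neighbour of v adjacent
   to all current members with the highest degree, breaking ties by
   smallest identifier. Duplicate cliques and cliques contained in
   others are removed.
2. *Greedy merging.* Repeatedly merge the cluster pair — sharing a node
   or connected by an edge — whose union most increases the overlap
   modularity; stop when no merge gives a strictly positive gain
   (tolerance 1e-12), then remove any cluster that became a subset.

The overlap modularity used is, with m edges, adjacency A and degrees d,

    Q = (1/2m) * sum over ordered node pairs (u, v) sharing >= 1
        cluster of [ A_uv - d_u * d_v / (2m) ],

with the diagonal (u = v) null terms included, as in classical Newman
modularity, so a single cluster holding the whole graph scores exactly
zero. Under full coverage the diagonal contributes a
clustering-independent constant, so merge decisions are unaffected by
this convention; it was chosen because it gives the clean closed form.
Every pair is counted once no matter how many clusters it shares. The
procedure is deterministic: no randomness, and merge ties are broken by
the lexicographically smallest pair of cluster member-tuples. This is
this package's pinned definition of the algorithm; no attempt is made
to reproduce any particular legacy clustering binary bit-for-bit, and
cluster counts on real corpora are expected to differ in detail.
Disconnected components never merge (cross-component gains are
negative). The merge loop re-scans cluster pairs each iteration, which
is quadratic in the number of clusters and entirely adequate for the
network sizes this package targets in its test and acceptance
workloads (tens to hundreds of nodes); for interactome-scale inputs the
class file of an external clustering can be supplied instead and every
downstream stage reused.

## Module annotation (majority rule)

Protein annotations are read from GAF 2.x or two-column TSV; rows with
a NOT qualifier and non-BP terms are excluded, and evidence codes are
deliberately *not* filtered (electronically inferred annotations are
kept). Propagation follows `is_a` and `part_of` only — the GO true-path
rule; regulates-type edges are ignored and logged. The BP root is never
assignable: it is excluded from propagated sets.

For each cluster, let S be the members with at least one propagated BP
term. A term qualifies if at least `threshold` (default 0.5, compared
with >=) of S carry it; qualifying terms are reduced to the most
specific ones (a term that is an ancestor of another qualifying term is
dropped — without this, every parent of a qualifying term would be
co-assigned). Clusters with no qualifying non-root term are labelled
"BP unknown" and take no part in detection. The denominator counts
*annotated* members only, so sparsely annotated clusters are not
penalised. An optional depth cap on assigned terms exists but is off by
default. Note one sharp edge of the >= comparison: in a two-member
cluster every term carried by either member qualifies (support 1/2);
consequences are discussed under Limitations.

## Term-pair association probabilities

Two hypergeometric measures per unordered term pair (GO1, GO2), both on
the *direct* (unpropagated) annotation view — a configuration switch
allows propagated counting:

* annotation view, counting proteins restricted to those with at least
  two distinct direct terms: N = size of that universe, K and n = how
  many are annotated to GO1 and GO2, k = how many to both;
* interaction view, counting edges whose two endpoints are both in that
  universe: N = such edges, K and n = edges with an endpoint annotated
  to GO1 / GO2, k = edges joining a GO1-annotated protein to a
  GO2-annotated one in either orientation. A single endpoint carrying
  both terms does not create a cross pair by itself.

Dissimilarity uses the lower tail P(X <= k): a small value means the
two processes co-occur far less than chance. The upper tail is exposed
for similarity queries. The lower tail was chosen because the quantity
of interest is *under*-representation of co-occurrence; a point-mass
convention exists in older enrichment tools and is discussed below for
the enrichment statistic. Pairs with an empty margin (K = 0 or n = 0 in
either view) carry no information; they are skipped and excluded from
the test count. Multiple testing is corrected by Bonferroni
multiplication — e-value = p × number of pairs evaluated, computed at
run time, capped at 1 for reporting — matching the correction the
method was designed with; no false-discovery-rate variant is applied.

## Candidate calling

For every protein in >= 2 clusters, every unordered pair of its
annotated clusters, and every cross pair of distinct assigned terms,
evidence is recorded when both e-values are <= alpha (default 0.05). A
term assigned to both clusters generates no evidence (a term is never
dissimilar to itself); "BP unknown" clusters are skipped; *any*
assigned term of a cluster may participate, not only the most specific.
All qualifying evidence is retained, which supports the provenance
classification (did the protein already carry both dissimilar terms,
one, or neither — the latter two inherited from its modules) and
function-pair summaries. Candidates are monotone in alpha by
construction.

## Randomization controls, leave-one-out, enrichment

* **Annotation shuffle** permutes whole per-protein direct-term sets
  across the annotated proteins (preserving each protein's annotation
  richness); a per-term pooled shuffle is available as a mode. The
  observed clustering is reused: this control isolates annotation
  quality.
* **Edge randomizations**: `uniform` redraws the same number of edges
  on the same nodes (simple graph); `degree_preserving` applies
  10 double-edge swaps per edge (a standard mixing heuristic), keeping
  the degree sequence exactly. The randomized network is re-clustered.
* **Probability reshuffle** permutes the (p_annot, p_inter) tuples
  across the term-pair keys of the computed table.
* **Leave-one-out**: for each (cluster, member) case where the member
  has >= 1 propagated term, the member's annotations are removed, the
  cluster re-annotated, and the case succeeds if any held-out term
  appears among the inferred terms or their ancestors.
* **Gene-set enrichment**: fold = observed/expected overlap; the
  reported p is the one-sided upper tail P(X >= k). The point
  probability P(X = k) is also returned because some legacy enrichment
  pipelines report it; at the published scale of this method
  (N = 12,865, K = 430, n = 39, k = 6) the two differ (1.7e-3 vs
  1.5e-3) and the point value is the one matching the figure printed
  for that analysis.

All stochastic operations take an explicit seed, touch no global random
state, and conserve their stated invariant exactly (multiset of
annotation sets, node/edge counts, degree sequence, multiset of
probability tuples).

## Topological characterization

Groups: candidates (Cands), multiclustered proteins (Multi), their
complement (Mono), multiclustered non-candidates (Multi_NC), all
non-candidates (NC) and hubs — degree at least twice the network mean
(rounded up) by default, overridable to an absolute cutoff.
Betweenness is unnormalized Brandes betweenness over unordered
source–target pairs with endpoints excluded and tied shortest paths
splitting the count; published betweenness figures depend on
normalization conventions that are rarely stated, so cross-corpus
comparisons of magnitudes should be made with care. Group comparisons
use the two-sided Wilcoxon rank-sum test (exact for small tie-free
samples, normal approximation with tie correction otherwise). No
multiple-testing correction is applied across the many group
comparisons — they are descriptive. Sequence-level features (disorder,
motifs, domains, conservation, expression) are ingested as user TSV
columns, never computed.

## Synthetic scenarios

The generator emulates the structure the method assumes: `n_modules`
dense blocks (intra-module edge probability `p_in`, inter-module noise
`p_out`), `n_shared_nodes` proteins assigned to two modules each (the
planted EMFs), and a shallow ontology with one branch of two leaf terms
per module under a common root. Each protein is directly annotated to
its home module's leaf pair with probability `annotation_purity`,
otherwise to another module's pair — so every protein has the two
distinct direct terms the pair statistics require, and cross-branch
pairs have (near-)zero co-annotation.

Defaults — the study conditions used by the test suite and the
acceptance script — are 3 modules of 20 proteins, p_in = 1.0,
p_out = 0.0, 2 shared nodes, purity 0.95, i.e. 58 proteins and
~570 edges per scenario, 15 term pairs tested. The sizes are not
arbitrary: the Bonferroni-corrected annotation e-value of a
zero-overlap pair is C(N−K, n)/C(N, n) × n_tests, which only clears
0.05 when modules are large relative to the module count (e.g. four
modules of twelve never qualify). Three modules of twenty give
cross-branch e-values around 1e-3 or smaller in both views, so the
planted dissimilarity holds by construction across seeds. `p_out` is
zero in the default conditions because any appreciable background noise
creates 2–3-member clusters around high-degree shared nodes, which the
>= 50 % rule annotates to both branches (ties qualify) and thereby
manufactures false candidates; noisy presets exist where
false-positive-freeness is not asserted.

What the generator does *not* emulate: scale-free degree structure,
realistic GO term diversity (thousands of terms vs six), annotation
incompleteness, or interactome sparsity. Passing tests therefore
demonstrate the pipeline's correctness and its behaviour under
controlled conditions — not its precision/recall on real interactomes.

## Known limitations

* **Interaction statistic at small scale.** k counts only
  cross-configuration edges while K and n count either-endpoint edges,
  so even on a completely random graph k falls systematically below the
  urn expectation K·n/N (by about a factor of two when every protein
  carries one of B branch annotations). The deviation scales like
  sqrt(N_edges)/B standard deviations: negligible on a sparse, richly
  annotated interactome, but grossly significant on small dense
  fixtures with few terms. Consequently the *topology* randomization
  controls (uniform and degree-preserving) do not collapse the
  candidate count at synthetic-fixture scale — random 2–4-member
  clusters still annotate through majority-rule ties and their
  cross-branch pairs remain "dissimilar" under the biased interaction
  statistic. The acceptance suite asserts this control family anyway
  and the topology schemes fail there by design of the assertion; the
  annotation-shuffle control, by contrast, collapses cleanly
  (mean annotated clusters and candidates near zero), and the
  probability reshuffle is bounded by the multiclustered count. At
  published scale all four controls were reported to collapse.
* **Tie behaviour of the majority rule.** With the >= comparison, any
  term carried by exactly half the annotated members qualifies; in
  two-member clusters this annotates the union of the members' terms.
  Real corpora contain such small clusters too; their annotations
  should be treated with caution.
* **Reference values, not assertions.** Published full-scale figures —
  12,865 nodes / 74,388 edges; 855 clusters of mean size 33.4; 633
  annotated clusters; 3,846 multiclustered proteins; 430 candidates
  with a 71/209/128 provenance split; 106,618 term pairs; 62.6 %
  leave-one-out recovery — depend on the deposited input files and a
  GO/GAF snapshot of their era. The I/O layer parses and replays those
  artifact dialects, but the counts themselves are documented here as
  reference values only and asserted nowhere.
* The clustering stage is a faithful but independent re-implementation
  of the centered-clique + greedy-merge family; exact agreement with
  any specific historical implementation's output is out of scope.
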