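# Methods

## Model and procedure

A PPI network is treated as a simple undirected graph whose edges carry no
confidence scores; the only edge weight used anywhere is the Jaccard
coefficient of the endpoint neighbourhoods. The working assumption is the
usual one for density-based complex detection: protein complexes appear as
locally dense, robust subgraphs, while false-positive interactions appear
as thin connections whose endpoints share few neighbours.

Detection runs in five stages:

1. **Initialization.** Every edge of the input graph receives its Jaccard
   weight, computed once on the raw graph; edges of weight 0 are then
   deleted. The deletions do not trigger recomputation — iterated
   reweighting could cascade (each deletion lowers neighbour overlap
   elsewhere) and on sparse graphs would eventually empty the network.
   Nodes stripped of all edges remain as isolated nodes with node weight 0.
2. **Seed selection.** The node weight of v is the average degree of its
   pruned neighbourhood graph G_v′: take v, its neighbours and the edges
   among them, then remove all nodes of degree 1 *in a single simultaneous
   pass* (the centre included when it has only one neighbour). The pruning
   is deliberately not iterated: a single pass reflects one removal act,
   and iterating would change the value on simple configurations (e.g. a
   triangle with a pendant path) in ways that no longer measure the
   original neighbourhood's density. The unvisited node of maximum weight
   seeds the next cluster; node weights depend only on the filtered
   network, so the table is computed once per run.
3. **Cluster formation.** The frontier is every non-member adjacent to the
   cluster, minus candidates already rejected for this cluster. The
   candidate minimizing the modified Czekanovski–Dice distance is tested:
   the enlarged cluster must keep robustness ≥ θ and minimum internal edge
   weight ≥ γ. Failures are blacklisted permanently for this cluster (this
   also bounds the work per cluster by |V| additions plus |V| rejections).
   In the distance, deg(K) counts edges with exactly one endpoint in K —
   the external-degree reading; with 2m subtracted in the denominator this
   reproduces the union-size structure of the Czekanovski–Dice distance.
   "Common neighbours of K and v" excludes K's members and v itself, so the
   three OUT categories partition the external edges cleanly.
4. **Post-processing.** A finished cluster is compared against all existing
   clusters; the one maximizing neighbour affinity absorbs it when
   NA ≥ 0.5, otherwise it is appended. Merging is single-shot: the union is
   neither cascaded against other clusters nor re-checked against θ/γ.
5. **Termination.** The loop ends when every node is visited or the best
   unvisited node weight is 0. Visited status is set for the seed at
   selection and for all members at finalization, but expansion ignores it,
   which is what makes overlapping output possible. Clusters below the
   minimum output size still mark their members visited — they are
   generated, just not reported.

## Parameters

| Parameter | Meaning | Default | Notes |
|---|---|---|---|
| θ (`theta`) | minimum robustness degree, in [0,1] | 0.5 | at least half of a cluster's nodes must be removable (always the current max-degree node) before it disconnects; 1.0 accepts only clique-like cores |
| γ (`gamma`) | minimum internal Jaccard edge weight, in [0,1] | 0.1 | filters thin attachments; raising it shrinks clusters quickly since even K4 edges only weigh 0.5 |
| `min_size` | smallest reported cluster | 3 | dimers are conventionally excluded from complex prediction |
| `merge_threshold` | neighbour-affinity merge cutoff | 0.5 | above it two detections are considered the same complex seen twice |
| ω (`omega`) | match threshold for evaluation | 0.2 | the conventional value for neighbour-affinity matching |

Determinism: all ties (seed choice, candidate choice, robustness removal)
break to the lexicographically smallest protein ID, and output files are
canonically ordered (size descending, then lexicographic members), so
identical inputs and parameters give byte-identical outputs.

## Synthetic data

The generator plants `n_complexes` groups with sizes uniform in
[`size_min`, `size_max`]; each internal pair is joined with probability
`p_within`, rejection-resampled until the complex is connected (rejection
keeps the internal edge distribution homogeneous, unlike spanning-tree
patching); consecutive complexes share exactly one node with probability
`overlap_fraction`; all remaining node pairs — background and cross-complex
— are joined with probability `p_background`. Defaults are five size-5
complexes with `p_within` = 0.9 and `p_background` = 0.01: a small network
whose complexes are clearly but not perfectly dense, and whose noise edges
mostly carry Jaccard weight 0 and disappear at initialization.

What the generator does **not** emulate: scale-free degree structure,
noise calibrated to real screens' false-positive profiles, complexes with
core–attachment architecture, or shared cores larger than one protein.
Tests passing on this generator therefore show that the pipeline recovers
planted dense groups under mild noise — not that it matches any particular
published benchmark performance, which additionally depends on the real
networks, the curated reference set and thresholds not derivable here.

## Evaluation metrics

Precision = N_cp/|P| and recall = N_cb/|B| count, respectively, predictions
matching at least one reference and references matched by at least one
prediction (a prediction may match several references; each reference
counts once). F is their harmonic mean, defined as 0 at precision = recall
= 0. Co-localization of a complex is the maximal fraction of its
*annotated* members sharing one location; unannotated proteins are dropped
from both numerator and denominator and fully unannotated complexes are
skipped. The set-level score is size-weighted (Σ best-location counts / Σ
annotated members), matching the convention of the standard evaluation
tooling for this metric; per-complex scores are exported too, so an
unweighted mean is one line away. GO semantic similarity is consumed as a
precomputed pairwise table (computing term-level similarity from the
ontology DAG is out of scope); complexes average their scorable member
pairs, ontologies average their scorable complexes, and the set score is
the geometric mean over the cellular-component, biological-process and
molecular-function ontologies.

## Numerical and design choices

- The denominator of the cluster-node distance is ≥ |K| ≥ 1, so the
  distance is always finite; the only guarded failure modes are an empty
  cluster or a candidate already in the cluster.
- Robustness of a single node is 1.0 (one removal empties the graph), which
  the stopping rule forces.
- θ and γ defaults (0.5, 0.1) are the package's own choice of a balanced
  operating point; both are prominent CLI flags and config keys since
  appropriate values depend on network density.
- Percentages in reports are printed to two decimals; the raw ratios are
  emitted alongside so no downstream computation needs to re-parse rounded
  values.
- Edge lists cannot express isolated nodes; the simulate command's written
  networks therefore omit isolated background nodes, while the in-memory
  generator keeps them.

## Problem sizes

The test suite and the acceptance script run on networks of 25–75 nodes
(five planted complexes, optionally with background nodes) and on ~1000
random graphs of ≤ 12 nodes for the brute-force distance cross-check; the
noisy-recovery experiment averages ten independent replicates. These sizes
exercise every code path while keeping the whole suite in the
seconds-to-a-minute range.

## Known limitations

- The greedy expansion is sequential and O(|V|) distance evaluations per
  step; very large networks (10⁵+ edges) would need caching of frontier
  distances to be comfortable.
- Merged clusters are not re-validated against θ/γ, so a merged union can
  in principle fall below the thresholds its parts satisfied.
- Rejected candidates never re-enter a cluster's frontier even if later
  growth would make them acceptable.
- Exact reproduction of published benchmark cluster sets is impossible in
  principle here: it would require the original interaction datasets and
  threshold settings, which the package deliberately does not bundle.
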