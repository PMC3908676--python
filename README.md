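# robcomplex

Detection of **overlapping protein complexes** in protein–protein
interaction (PPI) networks, based on cluster robustness.

High-throughput interaction screens produce large but noisy PPI networks,
and locally dense regions of those networks tend to correspond to protein
complexes. `robcomplex` is for computational biologists who want to extract
such complexes from an interaction network given as a plain edge list, and
to score predicted complex sets against curated references.

## Method

The network is a simple undirected graph G = (V, E); self-interactions and
duplicate edges are discarded. The algorithm rests on five quantities:

- **Edge weight** — Jaccard similarity of endpoint neighbourhoods:
  w_uv = |Γ(u) ∩ Γ(v)| / |Γ(u) ∪ Γ(v)|. Edges with w_uv = 0 are removed
  before detection, since interactions without any shared neighbour are
  typically unreliable.
- **Node weight** — average degree of the node's neighbourhood graph after
  pruning degree-1 nodes (w_v = Σ deg(u) / |V″| over the pruned graph
  G_v′). High node weight marks a densely interconnected neighbourhood,
  i.e. a good seed.
- **Cluster–node distance** — a modified Czekanovski–Dice distance between
  a cluster K and a frontier node v:
  d(v, K) = (|K| − m)/|K| + (OUT(K) + OUT(v)) / (deg(K) + deg(v) − 2m + |K|),
  where m counts edges between v and K and OUT(·) excludes edges towards
  common neighbours of K and v. Candidates are absorbed in order of
  increasing distance.
- **Robustness degree** — repeatedly delete the current maximum-degree node
  of the cluster's induced subgraph until it disconnects or empties;
  R_K = (nodes removed)/|K|. A clique scores 1, a star 1/(k+1).
- **Neighbour affinity** — NA(A, B) = |A ∩ B|² / (|A|·|B|), used both to
  merge strongly overlapping detections (threshold 0.5) and to match
  predictions against reference complexes (threshold ω = 0.2).

Detection loops: pick the unvisited node of highest node weight as seed,
grow the cluster greedily while robustness stays ≥ θ and the minimum
internal edge weight stays ≥ γ, then merge or append the result. Visited
status gates only seeding, so output clusters may share proteins. Clusters
with ≥ 3 members are reported. Predicted sets are scored with
precision = N_cp/|P|, recall = N_cb/|B| and their harmonic mean
(F-measure), plus co-localization and GO semantic-similarity aggregation.

## Worked example

Simulate a small planted-complex network (five size-5 complexes, 10% of
internal edges missing, 1% background noise), detect, and evaluate against
the ground truth:

```sh
robcomplex simulate --seed 7 --n-complexes 5 --p-within 0.9 --p-background 0.01 --out-prefix demo
robcomplex detect --network demo.edges.tsv --out predicted.txt
robcomplex evaluate --predicted predicted.txt --reference demo.truth.txt --out report.tsv
```

prints

```
25 nodes, 48 edges, 5 planted complexes -> demo.edges.tsv
5 complexes -> predicted.txt
precision 100.00%  recall 100.00%  F 100.00%
```

and `report.tsv` contains

```
Ncp	|P|	Ncb	|B|	Precision(%)	Recall(%)	F-measure(%)	precision	recall	f_measure
5	5	5	5	100.00	100.00	100.00	1.0	1.0	1.0
```

All five planted complexes were recovered exactly: every predicted complex
matches a true one at neighbour affinity ≥ 0.2 (N_cp = 5 of |P| = 5) and
every true complex is matched (N_cb = 5 of |B| = 5). Each command also
writes a `*.manifest.json` recording inputs, parameters and seed so the run
can be reproduced byte-for-byte.

The same pipeline is available as a library:

```python
from robcomplex import SyntheticConfig, generate, detect_complexes, evaluate

net, truth = generate(SyntheticConfig(rng_seed=7))
predicted = detect_complexes(net)           # theta=0.5, gamma=0.1 defaults
print(evaluate(predicted, truth).f_measure) # 1.0
```

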