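# Methods

## Scope and model

`netprox` implements the network-pharmacology inference chain for a
multi-target drug (e.g. a multi-herb formula) against a disease on a human
protein–protein interactome: compound screening → target/disease-gene
overlap → drug–disease network proximity → subnetwork extraction → random
walk with restart (RWR) gene prioritization → modularity clustering →
gene-set enrichment. The interactome is treated as a simple undirected,
unweighted graph; edge confidences exist only to filter edges at load time
(STRING-style 0–999 scores are divided by 1000, and a ≥ 0.9 cut is the
conventional high-confidence setting). All distances are hop counts, because
the proximity statistic is defined on unweighted shortest paths.

## Proximity and its null

The closest-distance statistic is
d_c(V, T) = (1/‖T‖) Σ_{t∈T} min_{v∈V} d(v, t). Computation uses one
multi-source BFS from V per evaluation (scipy's unweighted Dijkstra with
`min_only`), so a full null calibration stays cheap. Design choices:

- **Unreachable targets** are excluded from the mean and counted
  (`n_dropped_targets`) rather than given an infinite or capped distance:
  the statistic is undefined for unreachable pairs, and the count keeps the
  exclusion auditable. Gene-set members absent from the graph are dropped
  with a warning before computation.
- **Degree-matched null.** Nodes are sorted by degree and grown into bins
  from the lowest degree upward until each bin holds ≥ 100 nodes (graphs
  with < 200 nodes use max(10, n/10)); a bin never splits a degree value,
  and an undersized final bin is absorbed into its predecessor. Each
  replicate draws V_rand matched to V's bin histogram and T_rand matched to
  T's, uniformly without replacement within bins. Both sets are redrawn
  independently every replicate.
- **Disjointness mirroring.** When the observed V and T are disjoint, each
  null pair is forced disjoint too (T_rand is drawn from bins with V_rand's
  members removed). Without this, chance collisions insert spurious zero
  distances into the null; with it, a complete graph correctly yields a
  degenerate null (every replicate d_c = 1) and an explicit
  `DegenerateNullError` instead of a meaningless Z.
- **σ is the population standard deviation** over replicates (the null is
  treated as the reference distribution itself, not a sample from a larger
  one); at the default n_random = 1000 the sample/population difference is
  negligible. A zero σ raises rather than emitting ±inf.
- n_random defaults to 1,000 — the convention for this statistic, enough to
  stabilize σ to a few percent.

## Random walk with restart

p_{t+1} = (1 − r)·M·p_t + r·p_0 with M the column-normalized adjacency
(M[i,j] = A[i,j]/deg(j)), p_0 uniform over the seed genes present in the
graph, restart probability r = 0.75 (the standard setting for
gene-prioritization walks on monoplex PPI graphs), and convergence when the
L1 change drops below 10⁻¹⁰ (cap 10,000 iterations; with r = 0.75 the map's
contraction factor is 0.25, so convergence takes ~20 iterations). Isolated
nodes get zero columns and are flagged; pipelines run the walk on the
largest connected component of the subnetwork so probability mass is
conserved (checked to 10⁻⁸ each iteration). Ranking sorts by descending
score with ties broken by ascending node id; seeds are kept in the ranking
by default, with an `exclude_seeds` switch. The iterative result is verified
against the closed form p = r·(I − (1−r)·M)⁻¹·p_0 by direct dense solve.

## Communities

Quality is Newman–Girvan modularity Q = Σ_c (e_cc − a_c²), implemented
in-package and cross-checked against networkx. Partitions come from
Clauset–Newman–Moore greedy agglomeration (networkx's implementation behind
the package's interface), run on a canonically sorted copy of the graph so
results are deterministic. Greedy agglomeration is a heuristic: tests bound
its gap to the exhaustive optimum (≤ 0.05 on all enumerable graphs) rather
than asserting equality. Communities smaller than `min_size` (default 3)
are reported as unclustered — they carry no enrichment signal. Edgeless
graphs yield all-singleton partitions with Q = 0 by convention.

## Enrichment

p = P(X ≥ k) for X ~ Hypergeometric(N, K, n), computed with scipy's exact
survival function and verified against combinatorial enumeration. The
universe is the collection's declared universe; query genes outside it are
dropped with a warning. Benjamini–Hochberg is the default correction, with
a raw-p mode for fidelity to reports that cut on uncorrected p < 0.05.
Term collections are flat (no ontology traversal or term–term propagation).

## Synthetic data: what it emulates, and what it does not

- `generate_interactome`: preferential attachment (connected by
  construction, exactly (n − m)·m edges) reproduces the heavy-tailed degree
  structure of genome-scale interactomes at desk scale (defaults: 2,000
  nodes, m = 5 ≈ 10⁴ edges). It does **not** reproduce the high clustering,
  date-hub structure, or study bias of curated interactomes, so passing
  tests demonstrate algorithmic correctness and calibration, not biological
  effect sizes.
- `plant_pair`: the disease module is a randomized BFS ball (connected, as
  disease genes tend to cluster in the interactome); ⌈q·‖T‖⌉ targets come
  from the module's hop-1 ring, the rest uniformly from outside the closed
  neighborhood, disjoint from V. q dials topological proximity: q = 1
  forces d_c ≤ 1; q = 0 plants nothing beyond chance.
- `generate_compound_table`: exactly round(pass_fraction·n) compounds pass
  both ADME cuts, and one passing compound sits exactly on the boundary
  (OB = 30.0, DL = 0.18) to pin the inclusive comparison. OB/DL values are
  otherwise uniform within the pass/fail ranges — no attempt to mimic real
  ADME score distributions.
- `generate_term_collection`: random flat terms plus one planted term with
  an exact query overlap. Calibration simulations use a 2,000-gene universe,
  term sizes 50–200, and 150-gene queries: in that regime the discrete
  hypergeometric's achievable type-I mass just below the 0.05 cut averages
  ≈ 0.036 analytically, so the empirical null rate is informative (in a
  small-N regime discreteness would push it toward 0 and the check would be
  vacuous). The planted effect (overlap 30 vs. a chance expectation of
  4–15) gives a worst-case p ≈ 9·10⁻⁵ before correction.

Generators take explicit seeds/Generators and are bit-reproducible.

## Numerical and procedural choices

- Node order is always the sorted identifier list; all outputs are written
  in sorted order with fixed float formatting, so identical config + seed ⇒
  byte-identical run directories.
- Gene identifiers are matched case-sensitively after whitespace trimming;
  no alias mapping (that would require external dictionaries).
- Ties in rankings and component selection break lexicographically.
- The pipeline restricts graphs to their largest connected component by
  default (`use_lcc`), since proximity needs finite distances and the walk
  needs an irreducible component; the switch is exposed because published
  analyses do not always state this step.
- The pipeline accepts two graphs (a broad one for proximity, a
  high-confidence one for the subnetwork/RWR arm), defaulting to one graph
  for both.
- Problem sizes in tests and in `scripts/acceptance.py` (2,000-node graphs;
  60–200 null draws at n_random = 100; 50–200 enrichment simulations) are
  the package's chosen desk-scale study conditions: large enough for stable
  calibration statistics, small enough to run interactively.

## Known limitations

- Proximity variants other than closest distance (shortest, centre, kernel,
  separation s_AB) are not implemented.
- RWR is monoplex and unweighted; no multiplex/heterogeneous networks or
  edge-weighted walks.
- Community detection offers only greedy modularity (no Louvain/Leiden or
  edge-betweenness), and modularity's resolution limit applies.
- Enrichment is flat over-representation; no GSEA-style ranked statistics
  and no GO DAG propagation.
- No identifier namespace mapping: inputs must already share a gene
  vocabulary with the interactome.
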