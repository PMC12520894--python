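# Methods

`ccdriver` implements a driver-discovery workflow for cumulus-cell (CC)
transcriptomes: starting from a genes × samples log2 expression table and a
gene-interaction edge list, it calls differentially expressed genes (DEGs),
builds DEG-induced interaction networks, extracts dense modules, and nominates
two kinds of candidate drivers — fold-change outliers ("highly modulated"
DEGs) and consensus centrality hubs — which are then partitioned into shared
and comparison-specific (distinctive) sets. A seeded synthetic-data generator
provides ground truth for every stage.

## Differential expression

For a pairwise comparison `a` vs `b`, each gene's effect is
`log2FC = mean_a − mean_b` on log2 intensities, reported alongside the signed
linear fold change `signed_fc = 2^log2FC` (positive) or `−2^(−log2FC)`
(negative) — the microarray-console convention in which the magnitude is
never inside (−1, 1). Significance is a one-way ANOVA across the groups
(identical to the pooled-variance t-test for two groups); with three
replicates per group the test has 4 error degrees of freedom, which matters
for every power statement below. Benjamini–Hochberg adjusted p-values are
computed over all genes and carried on every record.

A gene is a DEG when `|signed_fc| > 2` and its p-value is below α = 0.05. The
default gate is the **raw** ANOVA p. With 3 replicates and realistic noise
(0.25 log2 units), BH-gating at α = 0.05 cannot reach 90% sensitivity on
effects just above the fold-change threshold — the FC > 2 gate, not the
p-value, is what controls false discoveries here, because a null gene needs a
≈5σ mean shift to cross it. Gating on adjusted p remains available
(`use_adjusted=True`).

Degenerate variance is handled explicitly: zero within-group variance with a
nonzero difference yields p = 0 (logged); an all-constant gene yields p = 1.

Summary tables use half-up rounding with an explicit 0- or 1-decimal policy,
because published count tables mix both precisions. The up/down percentages
of an empty DEG set are reported as undefined, not zero.

### Annotation filter

Before network construction, DEGs with an empty symbol, a lncRNA biotype, or
no protein annotation are removed (gene ids absent from the annotation table
count as uncharacterized). Order is preserved and both partitions returned,
so exclusion percentages can be reported.

## Network construction and topology

The network is the subgraph of a user-supplied interactome induced on DEG
symbols; isolated DEGs are kept as singletons (they count toward connected
components). The topology report gives node/edge counts, mean degree,
diameter and characteristic path length on the largest connected component
(the NetworkAnalyzer convention, so disconnected graphs get finite values),
and the mean local clustering coefficient both over nodes of degree ≥ 2 and
over all nodes.

The scale-free screen regresses log10 P(k) on log10 k over non-empty degree
bins and calls a network scale-free when R² ≥ 0.8 with exponent γ ∈ [1, 4].
This is a pragmatic screening convention, not a maximum-likelihood power-law
test; degenerate degree distributions (fewer than three distinct degrees) are
flagged not-fittable rather than scored.

## Dense modules (MCODE-style)

Vertex weight = `k_max × density` of the highest k-core of the closed
neighborhood. Complexes expand breadth-first from unvisited seeds in
descending weight order (ties broken lexicographically), admitting neighbors
whose weight is ≥ `(1 − vwp) × seed_weight` with vwp = 0.2; the haircut then
iteratively strips nodes with within-complex degree < 2, and complexes below
two nodes are discarded. Nodes removed by the haircut, or belonging to a
discarded expansion, are released back to the candidate pool; only members of
returned complexes (and spent seeds) stay visited, so returned complexes are
node-disjoint but a failed expansion cannot silently consume a genuine
module. Fluff is off and loops are ignored.

Retention keeps modules with k-core number **greater than** 5 and node degree
**greater than** 5. "Node degree" is ambiguous in the source protocol; the
default statistic is the mean within-module degree (the result-panel figure a
Cytoscape user reads), with `min` and `seed` available as alternatives. A
7-clique (k-core 6, degrees 6) is the smallest retained clique; a 6-clique
(k-core 5) is correctly rejected.

## Centrality consensus hubs

Twelve per-node coefficients: Degree, Closeness (harmonic, defined on
disconnected graphs), Betweenness (unnormalized pair-fraction sum), Stress
(shortest-path counts), Eccentricity (reported as 1/eccentricity so that
"highest score" means most central for every metric; the raw value is kept),
Radiality, local ClusteringCoefficient, MCC (sum of (|C|−1)! over maximal
cliques of size ≥ 2 containing the node, which reduces to the degree for
edgeless neighborhoods), MNC and DMNC (size, and edges/size^1.7, of the
largest component of the open-neighborhood subgraph), BottleNeck (over
deterministic BFS shortest-path trees rooted at each node of a component —
parent = lexicographically smallest neighbor one step closer — count trees in
which the node's subtree exceeds a quarter of the tree), and EPC (mean
reachable-node count over seeded edge-percolation realizations, retention 0.5,
1000 realizations by default; at retention 1 it equals component size − 1
exactly). Isolated nodes score 0 on all path-based metrics.

Hub rule: per metric, take the nodes with competition rank ≤ 10 (boundary
ties all included, so a set may exceed 10); a gene in the top-10 of at least
5 of the 12 metrics is a hub. In the pipeline, hub candidates default to the
members of retained modules — the workflow filters *clustered* DEGs for
highly interconnected genes — and fall back to the whole network when no
module survives retention; whole-network scope is a configuration switch.

## Highly modulated (outlier) drivers

Outlier detection runs on the signed log2FC distribution of the called DEGs
(a Gaussian reference is meaningful only on the log scale). Two criteria are
conjoined by default:

1. **IQR fences** — quartiles by linear interpolation (type 7, stated because
   fence placement depends on it); fences at Q1 − 1.5·IQR and Q3 + 1.5·IQR.
2. **Deviation test** — fence candidates are tested most-extreme-first
   against the remaining values with an externally studentized Grubbs-style
   statistic, `t = |x − mean| / (s·√(1 + 1/n))` with df = n − 1, removing
   candidates while two-sided p < 0.05 and stopping at the first
   non-significant one.

Either criterion can be required alone. A caveat the synthetic studies made
visible: on a strongly direction-imbalanced DEG table (≫75% down), Q3 can sit
below zero and the upper fence collapses onto the up-regulated body; the
method inherits this fragility of signed-scale Tukey fences.

## Shared/distinctive partition, driver panel, endpoint path

Outlier and hub sets from 2–4 comparisons are Venn-partitioned into every
exclusive and intersection region. Distinctive drivers are the exclusive
regions, shared drivers the multi-set regions, and the driver panel is the
union of all distinctive outliers and hubs (a gene in both categories counts
once). Each distinctive driver's first neighbors and their regulation
directions are extracted from its own network.

Comparisons yielding fewer than 20 DEGs skip network stages entirely (module
detection and driver filtering are meaningless at that size): the annotation
filter is applied and a per-gene marker table sorted by |log2FC| is emitted.
The threshold is configurable; the source protocol only establishes that 13
was too few.

## ΔΔCt qPCR validation

Technical replicates are averaged per (sample, gene); ΔCt subtracts the
arithmetic mean of the reference-gene Cts (GAPDH and YWHAZ by default —
equivalent to the geometric mean of reference quantities); ΔΔCt subtracts
the calibrator-group mean ΔCt; RQ = 2^(−ΔΔCt) with amplification efficiency
fixed at 2. Per-sample RQ and per-group mean ± SD are reported. The
construction is invariant to per-sample constant Ct shifts and gives
reciprocal group ratios when the regulation is flipped.

## Synthetic data generator

The generator emulates the study's data shape, not its biology: log2
intensities with baseline N(7, 1), three biological replicates per group,
i.i.d. Gaussian noise (default 0.25 log2 units — the source reports no
variance estimates, so this is a package choice of a realistic array-level
spread), and ~6% planted DEGs whose |log2FC| is lognormal on the linear-FC
scale (median 2.8, shape 0.5), resampled below FC 2 so every planted DEG
clears the fold-change gate. Signs are drawn so the expected down-fraction is
54%. The interactome is a Barabási–Albert backbone (m = 2; scale-free by
construction) with planted modules (edges added among chosen nodes to a
target density) and planted hubs wired to 20% of the network.

The bundled **study fixture** is a three-group design (baseline `GV_start`,
endpoints `MII_end` and `GV_end`): most planted effects are shared by both
endpoint groups, so the two endpoint-vs-baseline comparisons produce
full-sized DEG sets with large overlap, while a 14-gene endpoint-specific
block makes the endpoint-vs-endpoint comparison small enough to exercise the
marker fallback. Defaults: 1,000 genes, 60 planted DEGs, a 500-node
interactome covering all planted DEGs.

Fixture design choices that the recovery experiments forced us to make
explicit:

- **Outlier floor 10 log2 units.** The planted-DEG body has Q3 ≈ 2 and IQR ≈ 4
  on the signed scale, so the upper Tukey fence sits near +8 once outliers
  contaminate the quartiles; planted outliers must clear that with margin to
  be recoverable even in principle. Magnitudes are drawn as 10 + |N(0, 0.5)|.
- **Direction balance is enforced globally.** Hub and module genes are planted
  down-regulated (as in the real networks' cell-cycle modules), so the free
  genes' sign probability is solved to keep the overall expected
  down-fraction at 54%; otherwise sampling noise can push a table to >75%
  down and collapse the upper fence (see the caveat above).
- **Planted modules are cliques** (14-node hub module, 6-node minor module
  that deliberately fails retention since a 6-clique has k-core exactly 5).
  Near-cliques of heterogeneous density produce heterogeneous MCODE vertex
  weights, and the expansion's (1 − vwp) weight window then fragments a
  planted module stochastically at this scale; cliques give uniform weights
  and a well-defined module ground truth.
- **Hub wiring avoids planted-module nodes**, because a hub edge landing
  inside a module dilutes that member's closed-neighborhood core density and
  can push it below the expansion window — the two planted motifs must stay
  separable for recovery metrics to mean anything.
- **12 planted hubs** (9 shared, 2 MII-specific, 1 GV-specific) sit inside the
  hub module with two plain members. The top-10/≥5-of-12 consensus rule keeps
  its k = 10 regardless of network size, so at a ~50-node DEG network its
  carrying capacity is ~10–12 nodes; the planted hub count matches that
  capacity, exactly as the published networks' 4–5 hubs match the rule's
  selectivity at ~1,100 nodes.
- Hub/module genes draw effect magnitudes with a linear-FC floor of 2.83
  (log2 1.5) so DEG-calling noise does not erode planted network structure;
  outlier directions follow the study pattern (3 specific down in the
  competent comparison; 5 up + 1 down in the incompetent one; 2 shared).

What the fixture does **not** emulate: probe-level intensities, batch or chip
artifacts, correlated noise, annotation errors beyond random uncharacterized
genes, and any real interactome topology beyond preferential attachment.
Passing recovery tests therefore demonstrates that the pipeline's logic is
correct and well-calibrated under the stated noise model — not that the
thresholds are optimal for real microarray data.

## Problem sizes and numerics

Property suites compare every path-based and clique-based centrality, the
topology statistics, and module k-cores against exhaustive-enumeration
oracles on hundreds of random graphs of ≤ 8–12 nodes; recovery experiments
use the 1,000-gene / 500-node fixture, which runs the full three-comparison
pipeline in a few seconds. Determinism is part of the contract: one seed
fixes every draw (expression noise, backbone growth, module/hub placement,
EPC realizations), and re-running any stage with the same configuration
reproduces byte-identical TSV/JSON outputs. Ties are broken
lexicographically everywhere a choice is otherwise unspecified (MCODE seeds,
BFS tree parents, ranked outputs).

## Known limitations

- The ANOVA is unmoderated; with 3 replicates per group an empirical-Bayes
  variance model would be more powerful, but its reference implementation is
  proprietary to the vendor console and unspecified, so the plain test is
  used and documented.
- The published up-rate cell "40.7%" (and its complement 59.3%) is a
  truncation of 579/1420 = 40.77%; the package's half-up rounding reproduces
  every other printed percentage but reports 40.8/59.2 for that pair.
- Hub calling on graphs much smaller than k = 10 degenerates (every node is
  top-10); the pipeline logs this and the consensus rule loses selectivity.
- The scale-free screen is a regression heuristic; it will happily pass any
  sufficiently heavy-tailed distribution and is not evidence against
  alternatives such as log-normal degree laws.
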