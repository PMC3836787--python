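# Methods

This note documents the models, conventions and numerical choices behind
`txnet`, and what the synthetic benchmarks do and do not demonstrate.

## Network construction

Gene–gene association is the Pearson product–moment correlation computed
across the samples of one group (at least 3 samples; any zero-variance gene
is a hard error, since its correlation is undefined). An edge joins genes
`i, j` when `|r_ij| >= tau` (default *absolute* mode: co-variation of either
sign counts, because negative regulation is as informative as positive;
a positive-only mode is available). The result is a simple undirected graph
carrying `tau` and the mode as metadata. Degree-0 genes are normally pruned:
the analysis concerns the connected co-expression structure, which is why a
thresholded network usually retains fewer genes than the input matrix.

**Threshold selection.** When no fixed `tau` is given, `auto_threshold`
scans a descending grid (default 0.9999 → 0.90, step 0.0005) and returns the
largest `tau` satisfying

1. *connectivity* — at least `connect_frac` (default 1.0) of the
   non-isolated nodes lie in the largest connected component, and
2. *stability* — between `tau` and `tau − step`, the relative changes of
   edge count and giant-component size are both ≤ `stability_eps`
   (default 0.05), with relative change defined as
   `|a − b| / max(a, b, 1)`.

The stability rule operationalizes the qualitative requirement that small
threshold changes should not reshape the topology; 0.05 was chosen as a
round "5% change" tolerance. A grid with no qualifying point is an error
instructing the user to widen the grid — silently returning a bad threshold
would be worse. An empty graph never qualifies (the connectivity fraction of
no nodes is defined as 0).

## Concentric degrees

For a reference node, ring `R_l` is the set of nodes at shortest-path
distance `l` (BFS). The level-`l` concentric degree is

    h_l = |{(u, v) in E : u in R_l, v in R_{l+1}}|

counting only edges *between* consecutive rings — edges internal to a ring
are excluded. This is the hierarchical-degree convention of the concentric
measurement literature, and it is the convention that produces the VIP
phenomenology: a node attached to two hubs that each carry 5 private leaves
has degree 2 but `h_1 = 10`. The alternative reading (all edges incident to
ring `l`) was considered and rejected because it conflates ring-internal
clustering with outward reach and breaks that signature. `h_0` equals the
ordinary degree by construction. Rings beyond a node's component are empty,
never an error. BFS is recomputed per node (networkx shortest-path lengths)
rather than cached globally; for the graph sizes involved the simplicity is
worth more than the speed.

## Hub / VIP / high-hub classification

Degree distributions of real co-expression networks are heavy-tailed, so no
absolute threshold separates "hubs" from the rest. Selection is therefore
rank-based: the hub candidate set is the top of the degree ranking, the VIP
candidate set the top of the `h_1` ranking (defaults: top 1% by quantile;
exact set sizes reproducible with `top_n`). Nodes in both sets are
high-hubs, in one set hubs or VIPs respectively, otherwise none. Boundary
ties are inclusive — all nodes tied with the selection boundary enter the
set — which makes the output independent of input order. Two documented
degenerate outcomes: on a vertex-transitive graph every node ties into both
sets and is labelled high-hub; isolated (degree-0) nodes are never selected,
so an edgeless graph is all "none".

**Betweenness** is exact Brandes shortest-path betweenness with endpoints
excluded, normalized by `(n−1)(n−2)/2` *within each connected component* of
size `n`, so a star centre scores exactly 1 and all values lie in [0, 1]
regardless of how many components the network has. Components smaller than
3 score 0. Exact computation (no sampling) keeps the values reproducible to
machine precision.

## Scale-free testing

The degree model is the discrete power law
`P(k) = k^(−gamma) / zeta(gamma, x_min)` for integer `k ≥ x_min`, with the
Hurwitz zeta normalizer. `gamma` is estimated by numerical maximum
likelihood (bounded scalar minimization of the negative log-likelihood on
`gamma ∈ [1.01, 8]`); `x_min`, when not supplied, is chosen among observed
degree values by minimizing the KS distance between the empirical tail CDF
and the fitted model — the standard estimation protocol for heavy-tailed
data. A fit requires at least 50 tail observations; fewer cannot pin an
exponent and raise an error rather than return noise.

Goodness of fit is a semiparametric bootstrap: each synthetic dataset draws
from the fitted tail model with probability `n_tail/n` and otherwise
resamples the observed body below `x_min`, is refitted from scratch
(including cut-off selection), and the p-value is the fraction of synthetic
datasets with a larger KS distance than the observed one. The default of
100 replicates is a precision/runtime trade-off (the literature's 1000
replicates resolve the p-value to ±0.03 instead of ±0.1; the decision
boundary used here, p ≈ 0.1, does not need that resolution). The exact
inverse-CDF sampler tabulates the CDF over 2^16 support points and inverts
the Hurwitz-zeta survival function by bisection beyond the table, so draws
are exact for any `gamma > 1`.

## Force-directed layout

Nodes are unit-mass particles in 2D or 3D. Forces:

- Coulomb repulsion between every pair, magnitude `k_c / d²`;
- spring attraction along every edge, magnitude `k_s · d` (zero rest
  length);
- viscous drag `−lam · v`.

An isolated connected pair balances at `d* = (k_c/k_s)^(1/3)`, the natural
length unit of the drawing; this closed form anchors the tests. The
equations of motion are integrated with classical RK4. Defaults
(`k_c = k_s = 1`, `lam = 0.5`, `dt = 0.01`, `speed_tol = 1e-3`,
`max_iter = 50000`) give stable, converged layouts for graphs up to ~10⁴
nodes and are all overridable. Convergence is declared when the maximum
node speed falls below `speed_tol`; hitting `max_iter` first is flagged,
not raised.

Numerical details: initial positions are i.i.d. uniform in the unit
square/cube from the run's seed; coincident particles are separated by a
deterministic per-node jitter of magnitude 1e-9 (per-node offsets keep
pairwise forces antisymmetric, so total momentum is conserved when
`lam = 0`); node evaluation order is fixed by sorted node id, making runs
bit-reproducible. Exact `O(n²)` repulsion is the reference path; an
optional Barnes–Hut tree (opening criterion `cell_size / distance < theta`,
default `theta = 0.7`) approximates it for large graphs and reduces to the
exact sum as `theta → 0` (a cell containing the target point is never
accepted for `theta ≤ 1`, so self-interaction is excluded structurally).
The reported energy — kinetic `Σ ½m|v|²` plus potential
`Σ_pairs k_c/d + Σ_edges ½k_s d²` — is the function whose negative gradient
is the conservative force, and decreases monotonically (after the initial
transient) whenever `lam > 0`.

## Differential-expression filter

The only gene selector shipped is the fold-change filter: genes with
`mean(group_a) / mean(group_b) ≥ min_fold` (default 3.0) on the linear
intensity scale, with log2 input exponentiated first via the matrix's scale
flag. Fold change is a ratio of arithmetic group means; genes with a
non-positive reference mean are skipped with a warning since their ratio is
undefined. Upstream normalization (e.g. Lowess) and permutation-based DE
procedures are out of scope — they are standard external preprocessing, not
part of the network methodology.

## Synthetic data: what it emulates and what it does not

`gen_expression` uses a latent-factor construction: gene `i` in module `m`
is `√rho_bg·g + √(rho_m − rho_bg)·f_m + √(1 − rho_m)·ε_i` per sample, with
independent standard normal global factor `g`, module factor `f_m` and
private noise. The population correlation is then exactly `rho_m` within a
module and `rho_bg` across, positive-definite by construction, and the
expected empirical correlation is analytic — which is what makes the
planted-adjacency recovery tests sharp. Default design: two groups of 6 and
12 samples (a realistic case/control imbalance for surgical-explant
studies), two 5-gene modules at `rho_in = 0.95`, 10 background genes.

`gen_motif_graph` plants the three node archetypes directly: hubs with 30
private leaves, VIPs on 3 hubs each, high-hubs with 25 leaves plus 5 hubs,
over an Erdős–Rényi background of edge probability 2·10⁻⁴. The background is
deliberately sparse: in real threshold networks at stringent cut-offs,
spurious edges are rare, and the planted `(k, h1)` margins (VIP `h1 ≈ 95`
vs. worst-case hub `h1 ≈ 65` at these defaults) are what make exact
recovery the expected outcome.

What passing these benchmarks does **not** show: robustness to microarray
noise physics (probe effects, intensity-dependent variance, normalization
artifacts), to correlated background structure between modules, or to the
annotation-dependent gene filtering real datasets require. The synthetic
correlation gap is clean by design; real co-expression matrices have a
continuum of correlations, and threshold choice there leans on the
stability scan rather than a visible gap.

## Problem sizes

The test suite and the acceptance script run at desk scale — graphs up to
20 000 nodes for exponent fitting, 50-graph ensembles up to 100 nodes for
oracle comparisons, 500-sample expression matrices for recovery — sizes at
which every check completes in seconds while exercising the same code paths
a full-scale analysis would use.

## Known limitations

- `pearson_matrix` materializes the dense gene × gene matrix: ~2 GB at
  15 000 genes. Fine for the intended scale; a blocked implementation would
  be needed far beyond it.
- The brute-force betweenness and layout are exact but not tuned for graphs
  beyond ~10⁵ edges.
- `auto_threshold` rescans the full matrix per grid point; with the default
  200-point grid this is the slowest step on large matrices.
- The KS bootstrap p-value has resolution 1/`n_boot`; borderline decisions
  need a larger `n_boot`.
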