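# Methods

This note documents the models behind `ecoassembly`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate about real sequencing data.

## Data model

An `OtuTable` stores integer counts (samples × taxa); relative abundances
are computed on demand and never stored, so repeated normalisation cannot
drift. Rarefaction subsamples each sample to a common depth without
replacement (multivariate hypergeometric), dropping and logging samples
below the target depth; the default depth is 30,892 reads and is always
configurable. Single-draw rarefaction is used (no repeated-rarefaction
averaging). Trees are rooted `skbio.TreeNode` objects; a basal
trifurcation is treated as unrooted input and midpoint-rooted with a
warning.

## Alpha and beta diversity

Chao1 uses the bias-corrected form S_obs + F1(F1−1)/(2(F2+1)), defined at
F2 = 0 and equal to observed richness when F1 = 0. Shannon entropy is in
natural log. Good's coverage is 1 − F1/N. Faith PD is the total branch
length of the rooted subtree spanning the present tips, **including the
root stem** — so a single-taxon sample has PD equal to that tip's
root-to-tip path. Bray–Curtis is computed on relative abundances and
Jaccard on presence/absence; both are bounded [0, 1].

The Mantel test correlates (Spearman) the upper triangles of two distance
matrices and permutes sample labels of the first; the one-sided p is
(1 + #{r_perm ≥ r_obs})/(1 + permutations), with 999 permutations by
default, exact enumeration available for small n, and a first-order
partial variant for controlling a third matrix (e.g. geographic
distance). Simple Mantel is the default; the partial form is opt-in.
Implementation detail: a label permutation only redistributes the same
multiset of pairwise values, so ranks are computed once and gathered per
permutation; mean and variance of the permuted rank vector are constants,
leaving one dot product per permutation.

When α-diversity indices are tested against environmental factors, the
index is converted to a Euclidean distance between samples and the
environment to a Euclidean distance on z-scored covariates.

## Phylogenetic null model (βMNTD / βNTI)

βMNTD is the abundance-weighted mean distance from each taxon in one
sample to its nearest relative in the other (weighted by default,
presence/absence by flag). The null shuffles taxa labels on the patristic
distance matrix — equivalent to the "taxa.labels" randomisation — with
999 randomisations by default; βNTI is the z-score of the observed βMNTD.
The patristic matrix is computed once; each null draw is a joint
row/column permutation, so a full run costs O(reps · pairs · S²) array
work rather than repeated tree traversals. One shared set of tip shuffles
drives all pairs within a fit: the null is a property of the
randomisation scheme, not of the pair. Tip shuffles span the full table's
taxon set (a per-group option exists). A degenerate null (zero spread,
e.g. a star phylogeny) yields NaN with a warning, and such pairs are
excluded from process summaries with a logged count.

βNTI is invariant under uniform scaling of branch lengths, which the
tests assert.

## Taxonomic null model (RC_bray)

Each null replicate reassembles both samples from the regional pool: a
sample keeps its observed richness, draws that many distinct taxa with
probability proportional to occupancy, then allocates its observed read
total multinomially proportional to pool relative abundance restricted to
the drawn taxa. RC = [#(BC_null < BC_obs) + ½·#(=)]/reps, rescaled to
(RC − 0.5)·2 ∈ [−1, 1]. The pool defaults to the pair's analysis group
(per-month classification); the full table is an option. The weighted
draw without replacement uses the Gumbel top-k construction, which is
exactly successive sampling proportional to weights. For very small pools
an analytic mode enumerates the entire null distribution; the test suite
holds the Monte-Carlo and analytic paths to each other and to an
independently coded enumeration oracle.

## Process classification

* variable selection: βNTI > 2
* homogeneous selection: βNTI < −2
* dispersal limitation: |βNTI| < 2 and RC ≥ 0.95
* homogenizing dispersal: |βNTI| < 2 and RC ≤ −0.95
* undominated: |βNTI| < 2 and |RC| < 0.95

Boundary convention: βNTI of exactly ±2 is not selection (the selection
inequalities are strict); |RC| of exactly 0.95 is assigned to the
dispersal classes. Process percentages are reported per group over
within-group pairs and sum to 100.

## Sloan neutral community model

F(p) = 1 − I_d(Nmp, Nm(1−p)) with N the mean sample depth, d = 1/N the
detection limit, and I the regularized incomplete beta CDF. m is fitted
by unweighted nonlinear least squares on the observed detection
frequencies (optimised in log m; bounds 10⁻⁶..10⁴ internally). R² = 1 −
SSE/SST. The 95% band is the Wilson score interval of the predicted
frequency at n = number of samples — preferred over the normal
approximation because predictions pile up near 0 and 1. Fitted m > 1 is
clipped to 1 with a warning by default; `allow_m_gt_1=True` keeps the
unconstrained value, since published fits sometimes report m above the
parameter's nominal domain.

**Known recovery bias.** The model equates detection with the latent
relative abundance exceeding d = 1/N, whereas in count data a taxon is
detected when it draws ≥ 1 read. Against the package's own generative
twin (Beta-marginal drift + multinomial reads) this inflates the fitted m
by ≈ 20–27% of its value at m_true = 0.1, N = 5000: detection probability
1 − E[(1−x)^N] exceeds P(x > 1/N) for rare taxa. Re-fitting on
threshold-detected presences (x > 1/N) from the same latent draws
recovers m almost exactly (0.0987 for a true 0.1 in a direct check), so
the bias is attributable to the detection-limit approximation, not the
optimiser. Users comparing fitted m across tables of similar depth are
unaffected; absolute interpretation of m should allow for this bias.

## Niche breadth and generalist/specialist calls

Levins breadth B_j = 1/Σᵢ P²ᵢⱼ over the share of taxon j's reads per
sample, from 1 (one sample) to n_samples (even use); Pianka's symmetric
index is the overlap measure (Levins' asymmetric overlap was considered
and not needed). The generalist/specialist null permutes the table while
preserving all row and column totals. Two schemes are provided:

* **hypergeometric** (default): reads are individually reshuffled across
  samples (Patefield r2dtable distribution). Under the hypothesis that
  every read is exchangeable — true when each sample is one multinomial
  draw from a common pool — this null is exact, and measured
  generalist + specialist calls on such tables are ≈ 4–5%, the nominal
  rate.
* **swap**: a serial unit-transfer Markov chain over 2×2 submatrices,
  uniform over margin-preserving count tables. This distribution weights
  extreme tables far more heavily than read exchange does; on null-true
  tables it mis-calls the large majority of taxa, and it is retained only
  for comparison with tools that use table-uniform nulls.

Calls: observed B above the null's 97.5th percentile → generalist, below
the 2.5th → specialist, else neutralist (the breadth-based reading of the
95%-interval rule; an occurrence-based variant was considered and left
out as redundant with the breadth null at fixed margins).

## Co-occurrence networks

Per analysis group the top-k taxa by total count (default 300; ties to
the lexicographically smaller id) enter pairwise Spearman correlation
(midrank ties). p-values use the t approximation on n−2 df for n ≥ 10
samples and the exact permutation distribution of ρ (all n! orders,
cached per n) below that. Edges require |r| > 0.9 and raw p < 0.05; no
multiple-testing correction by default (a Benjamini–Hochberg flag
exists). Constant taxa are excluded with a warning. Edge weight is |r|
with the sign kept as an attribute, because negative weights break
standard modularity; nodes are the taxa incident to at least one edge.

Topology metrics mirror Gephi's: average degree 2E/N, weighted degree on
|r|, density 2E/(N(N−1)), diameter and average path length on the largest
connected component (unweighted hops), mean local clustering (nodes of
degree < 2 contribute 0), and Louvain modularity at resolution 1.0 with
10 seeded restarts keeping the max-modularity partition — Louvain is
stochastic and an external tool's exact partition is not reproducible, so
modularity is compared as a property, not an identity.

Zi (within-module degree z-score; module sd 0 or isolated node → 0) and
Pi = 1 − Σ_t (k_t/k)² classify roles at thresholds 2.5 / 0.62: peripheral
(≤, ≤), module hub (>, ≤), network hub (>, >), connector (≤, >); the
boundary values fall to the peripheral/connector side, and any
non-peripheral node is a keystone. Abundance categories at 1% and 0.01%
relative abundance (AAT, CAT, ART, CRT, MT, CRAT) are checked in an order
that makes them exhaustive and mutually exclusive, property-tested over
random profiles. Core-taxa analysis reports every Venn region of
per-group presence with counts and percentages of the union.

## Synthetic data: what it emulates and what it does not

* **Neutral communities**: local relative abundances are drawn from the
  stationary Beta marginal of drift with immigration,
  x_i ~ Beta(Nmp_i, Nm(1−p_i)), normalised across taxa, then sampled as N
  multinomial reads. The metacommunity is a 500-taxon lognormal
  rank-abundance curve (σ = 1.5) — realistic skew without tails that
  destabilise multinomial sampling. A slow forward Moran simulator
  (death–replacement with immigration probability m) is kept purely as an
  oracle: its stationary mean and variance for a focal taxon match the
  Beta marginal within Monte-Carlo error.
* **Selection-structured communities**: a Yule tree (exponential waiting
  times, ultrametric, bifurcating), Brownian tip traits (z-scored by
  default so environments are in trait SD units), and sampling weights
  x_i·exp(−w(trait_i − e_s)²). With drift_m = 1 (default) x is the
  metacommunity itself, so w = 0 reduces exactly to the neutral lottery at
  m = 1. With drift_m < 1 a Beta drift lottery runs underneath selection;
  this matters because purely deterministic weights make equal-environment
  samples nearly identical (βMNTD ≈ 0 ≈ null), and only the combination
  of a shared (extreme) environment with drift underneath produces the
  homogeneous-selection signature (βNTI < −2) — the regime test uses
  e = 2 trait SD, w = 5, drift_m = 0.1.
* **Planted networks**: planted-partition graphs with optional designated
  hubs (wired through their module) and connectors (edges replaced by an
  even spread across modules, 8 links per module by default — simply
  adding cross-links leaves within-module degree dominant and Pi below
  threshold).

Not emulated: sequencing error, chimeras, compositional (closure)
artifacts, multivariate environments, spatial autocorrelation, and real
phylogenetic uncertainty. Passing tests therefore demonstrate the
*inference machinery* is correct under its own assumptions — they do not
certify behaviour on real amplicon data, where those unmodelled effects
are present.

## Problem sizes and numerics

The test and acceptance workloads use deliberately compact study
conditions chosen to exercise each regime: 20-sample / 200-taxon neutral
tables at 2,000 reads with 999 randomisations for βNTI; 10 + 10 samples
across environments at ±2 trait SD for variable selection; 50-sample /
500-taxon tables at 5,000 reads for neutral-model recovery; 500
independent 100-sample Mantel replicates at 999 permutations for type-I
calibration. Equality comparisons against enumeration oracles are at
1e-10; stochastic regime checks assert the fractions the generators
reproducibly achieve. All generators and null models take explicit seeds
and are bit-reproducible; the pipeline derives per-stage streams from one
master seed.

Known limitations: the NCM detection-limit bias quantified above; RC_bray
exact mode is exponential and only for toy pools; exact Spearman p-values
are enumerated only for n < 10; Louvain partitions (and hence modularity
and role assignments on near-ties) depend on the seeded restarts.
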