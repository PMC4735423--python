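# Methods

## Problem and scope

`structconn` implements a structural-connectome group analysis for
clinically similar cohorts (the motivating case: clinically isolated
syndrome, CIS, versus early relapsing–remitting multiple sclerosis,
RRMS, plus healthy controls). Two network families are analysed:

1. **Subject-level tractography networks.** Each subject contributes a
   directed 116×116 matrix `PT`, where `PT[i, j]` counts the
   streamlines seeded in atlas region *i* that reached region *j* out
   of a fixed number drawn per seed (5000 by default). Counts are
   normalised to proportions and symmetrised (elementwise mean by
   default) because the topology measures are defined on undirected
   graphs.
2. **Group-level structural covariance networks.** For each group, the
   region×region Pearson correlation matrix `S` of a regional
   morphometric feature (cortical thickness in mm, or mean fractional
   anisotropy) across the group's subjects.

The pipeline starts from these ROI-level inputs; image acquisition,
tractography itself, surface reconstruction and registration are out of
scope.

## Density thresholding

Weighted matrices are reduced to binary graphs at fixed link densities
`d = m / (n(n−1)/2)` by keeping the `L = round(d·n(n−1)/2)` largest
off-diagonal weights. Fixing the density (rather than a weight cutoff)
ensures group contrasts in topology are not confounded by a different
number of edges. The default sweep is 20 evenly spaced densities on
[0.1, 0.6].

Numerical choices:

- Weights are ranked by **signed value**, so strong positive
  correlations always win over negative ones — the standard
  structural-covariance convention; an `absolute` ranking flag exists.
- Ties at the cutoff are broken by lexicographic (i, j) upper-triangle
  order. With this fixed rule thresholding is deterministic and edge
  sets are **nested** across densities.
- The achieved density is reported alongside the target; they differ by
  at most one edge's worth because L is an integer.

## Topology measures (binary graphs)

- **Modularity** `Q = (1/2m) Σ_ij [A_ij − k_i k_j/2m] δ(g_i, g_j)`,
  with the configuration (degree-preserving) null model. The partition
  is found by a deterministic maximiser: greedy agglomeration from
  singletons (largest-gain merge, smallest-index tie-break, best
  partition along the full merge path) **and** leading-eigenvector
  recursive bisection of the modularity matrix, each polished by
  Kernighan–Lin style sweeps (every node moved once per sweep, best
  intermediate state kept); the higher-Q candidate is returned. Plain
  greedy agglomeration alone stalls in local optima even on 7-node
  graphs; with the KL sweeps the maximiser matched exhaustive partition
  enumeration on every random graph (n ≤ 8) we tested. The all-in-one
  partition (Q = 0) is always a candidate, so returned Q ≥ 0.
  `quality_of` scores an arbitrary partition by the direct double sum.
- **Clustering coefficient** `C_i = 2 t_i / (k_i (k_i − 1))` with `t_i`
  the triangles through node *i*; nodes with degree < 2 get `C_i = 0`
  (the formula is 0/0 there). The network value is the unweighted node
  mean.
- **Shortest paths** are unit-weight Dijkstra (scipy.sparse.csgraph);
  unreachable pairs have infinite distance.
- **Global efficiency** `E_glob = (1/(N(N−1))) Σ_{i≠j} 1/d_ij` with
  `1/∞ = 0`; subgraphs with fewer than 2 nodes score 0.
- **Local efficiency** `E_loc = (1/N) Σ_i E_glob(G_i)` where `G_i` is
  the subgraph induced on the neighbours of *i*; nodes with < 2
  neighbours contribute 0. A complete graph scores 1 on both
  efficiencies and 1 on every `C_i`, and has optimal Q = 0.

## Group comparison

Subject-level (tractography) profiles are compared **per density** with
a two-tailed two-sample t-test, pooled variance by default (Welch via a
flag). No multiple-testing correction is applied across densities; the
count of significant densities is descriptive. A density at which both
groups are constant yields t = 0, p = 1 with a warning.

Group-level correlation networks have no within-group replicates (one
network per group), so they are compared with a **subject-relabelling
permutation test**: subjects are reshuffled between the two groups
(sizes preserved), both networks rebuilt, and the per-density metric
difference referred to that null with the add-one correction
`p = (1 + #{|null| ≥ |obs|}) / (n_perm + 1)`, giving a p-value floor of
`1/(n_perm+1)`. Demographics use a two-sided Mann–Whitney U (normal
approximation, tie-corrected).

## Classification

One topology metric over the density sweep is a subject's feature
vector (20 values by default). The classifier is a soft-margin SVM with
a polynomial kernel, gamma 0.25. Protocol:

- one stratified split at the training fraction (default 75%);
- C selected by grid search over 10 log-spaced values on [1, 1000]
  (the source protocol gives the range 1–1000 and a ~10-point grid; we
  read the two statements together as 10 log-spaced points), maximising
  stratified CV accuracy on the **training split only**;
- the polynomial degree is not stated in the source protocol, so it is
  part of the grid (2–4) — a documented divergence risk;
- features are standardised inside the model pipeline (fold-internal,
  so no leakage); polynomial kernels are scale-sensitive, hence the
  default-on flag;
- reported: training accuracy, held-out testing accuracy, and
  stratified 10-fold CV accuracy of the chosen pipeline on all data
  (the "overall" accuracy);
- ROC validation on cross-validated decision scores: AUC as the
  Mann–Whitney rank statistic, 95% CI by stratified bootstrap (2000
  resamples), p-value against AUC = 0.5 by label permutation.

For correlation networks, per-subject features are derived by a
**leave-one-out jackknife**: subject *s*'s vector is the full-group
profile minus the profile with *s* removed — the subject's marginal
contribution to the group topology. The source protocol does not state
how group-level networks yielded per-subject samples; the jackknife is
this package's documented choice. Tractography features need no
jackknife (subject-level networks exist).

## Synthetic cohort generator

No cohort of this kind is publicly deposited, so the generator creates
cohorts carrying the structure the analysis is designed to detect.

- **Connectivity**: planted-module (stochastic block) model. Each of
  the 116 regions belongs to one of 4 planted modules (contiguous
  near-equal blocks — a fixture choice loosely mirroring
  parieto-occipital / mesio-temporal / cerebellar / frontal groupings).
  The streamline count for an ordered region pair is
  `Binomial(5000, p)` — binomial rather than Poisson because counts are
  bounded by the streamlines drawn ("samples passed / samples drawn").
  `p` is the group's within- or between-module probability, perturbed
  per subject **and per region pair** by Gaussian noise (SD 0.2,
  clipped to [0, 1]). The per-pair noise matters: at 5000 draws the
  binomial error on a proportion is ~0.007, so without pair-level
  variability any within/between gap survives rank thresholding
  perfectly and all groups produce identical block graphs. With it,
  module *crispness* after thresholding — hence Q and C — scales with
  the gap-to-noise ratio, which is the group contrast the analysis
  detects. The SD 0.2 represents anatomical and tracking variability
  across connections, the dominant error source in probabilistic
  tractography.
- **Features**: per group, multivariate Gaussian with block-structured
  correlation — `rho` within planted modules, 0 between (the simplest
  structure that makes the downstream covariance-network contrast
  plantable; the source gives no generative model). Moments are fixture
  choices: thickness ~ N(2.5 mm, 0.3 mm), FA ~ N(0.45, 0.05). FA is
  clipped to [0, 1] and thickness to > 0 after the Gaussian draw; at
  these moments clipping affects < 10⁻¹⁰ of draws, a negligible
  distortion.
- **Group defaults** mirror the reference cohort sizes (20 CIS, 33
  RRMS, 40 HC) with within-module edge probability 0.25 (HC), 0.30
  (CIS), 0.40 (RRMS) over a common between-module 0.05, and feature
  correlation 0.30 / 0.45 / 0.60 — the qualitative ordering
  RRMS > CIS > HC in modular strength that the clinical findings
  report. No treatment covariate is simulated (the effect of
  immunomodulatory treatment on these features is unknown).

What the generator does **not** emulate: voxel-level diffusion signal,
streamline geometry, lesions, scanner noise, distance-dependent
connection probabilities, hemispheric symmetry, or realistic
between-region heterogeneity of feature means. Passing tests therefore
show that the pipeline recovers planted block-structure contrasts under
realistic noise — not that it would detect disease effects in real
MRI data.

## Problem sizes used in validation

The validation suite runs closed-form limits on canonical small graphs;
brute-force oracle agreement on 200 random graphs (n ≤ 12) and
exhaustive-partition comparison on 60 graphs (n ≤ 8); the reference
116-region, 20-density shape checks on one simulated subject;
calibration of the t-test (1000 null replicates) and of the permutation
test (300–400 replicates, 199 permutations, 12 subjects × 10 regions);
and planted-contrast recovery on a 20 + 20 cohort at full 116-region
scale (within-module edge probability 0.8 vs 0.5, feature correlation
0.8 vs 0.4), including the SVM protocol and its label-permutation
chance control.

## Known limitations

- The modularity maximiser is a heuristic; exactness was verified only
  at desk scale (n ≤ 8). At 116 nodes it is deterministic but not
  certified optimal.
- The jackknife construction of per-subject covariance features is a
  methodological choice without a stated reference protocol.
- Per-density inference is uncorrected for multiple comparisons by
  design, matching the source analysis; treat significant-density
  counts descriptively.
- The clinical accuracies reported in the motivating study depend on
  its unreleased patient cohort and are not reproduced numerically;
  the package reproduces the method and its qualitative behaviour on
  planted contrasts.
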