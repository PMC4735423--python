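# structconn

Structural brain-connectome analysis for differentiating clinically
similar patient groups — built for the CIS vs early-RRMS problem in
multiple sclerosis, where a first demyelinating episode (clinically
isolated syndrome) must be told apart from definite relapsing–remitting
disease from a single anatomical scan.

The package builds two network families from ROI-level inputs on a
116-region atlas parcellation:

- **subject-level tractography networks** from streamline-count
  matrices `PT_ij` (streamlines seeded in region *i* reaching region
  *j*, out of 5000 drawn per seed), normalised and symmetrised;
- **group-level structural covariance networks** `S_ij`, the Pearson
  correlation of a regional feature (cortical thickness or fractional
  anisotropy) across each group's subjects.

Each weighted network is thresholded to binary graphs over a sweep of
20 link densities on [0.1, 0.6] (density = m / (n(n−1)/2), so groups
are compared at equal edge counts), and four topology measures are
profiled at every density:

- modularity Q = (1/2m) Σ_ij [A_ij − k_i k_j/2m] δ(g_i, g_j),
  maximised by a deterministic greedy/spectral optimiser;
- clustering coefficient C_i = 2t_i / (k_i(k_i − 1)), node-averaged;
- global efficiency E_glob = ⟨1/d_ij⟩ over node pairs;
- local efficiency E_loc = ⟨E_glob(G_i)⟩ over neighbour subgraphs G_i.

Profiles are compared between groups per density (two-tailed t-test for
subject-level networks; subject-relabelling permutation test for
one-per-group covariance networks), and the density-profile vectors
feed a polynomial-kernel SVM (gamma 0.25, C grid-searched on [1, 1000],
stratified 75/25 split, 10-fold cross-validation, ROC/AUC validation).

Because no patient cohort of this kind is publicly deposited, the
package includes a first-class synthetic cohort generator: a planted-
module (stochastic block) model for connectivity and block-correlated
Gaussian features, with group-dependent parameters defaulting to the
reference cohort design (20 CIS / 33 RRMS / 40 controls, 116 regions).
See `docs/methods.md` for the model and its limitations.

## Worked example

Simulate a two-group cohort with a planted contrast (within-module
connection probability 0.8 vs 0.5; feature correlation 0.8 vs 0.4),
profile every subject's tractography network, compare groups, and
classify:

```python
import numpy as np
from structconn import (CohortConfig, SVMConfig, generate_cohort, density_grid,
                        normalize_pt, symmetrize, topology_profile,
                        compare_subject_profiles, build_feature_vectors,
                        train_evaluate)

cfg = CohortConfig(
    n_per_group={"CIS": 15, "RRMS": 15},
    n_regions=60,
    within_module_p={"CIS": 0.5, "RRMS": 0.8},
    between_module_p={"CIS": 0.05, "RRMS": 0.05},
    feature_block_rho={"CIS": 0.4, "RRMS": 0.8},
    seed=42,
)
cohort = generate_cohort(cfg)
dens = density_grid()                      # 20 densities on [0.1, 0.6]
profiles = []
for sid, mat in cohort.pt_matrices.items():
    w = symmetrize(normalize_pt(mat, cfg.streamline_total))
    profiles.append(topology_profile(w.counts, dens,
                    entity_id=f"{cohort.labels[sid]}/{sid}",
                    which=("Q", "C_mean")))

cis = [p for p in profiles if p.entity_id.startswith("CIS/")]
rrms = [p for p in profiles if p.entity_id.startswith("RRMS/")]
res = compare_subject_profiles(rrms, cis, "Q")
print(f"modularity: {res.n_significant_densities}/20 densities significant, "
      f"mean t = {np.mean(res.statistic):.2f}")

X, y = build_feature_vectors(profiles, "C_mean")
report = train_evaluate(X, y, SVMConfig(seed=0), metric="C_mean")
print(report.summary())
```

Output:

```
modularity: 20/20 densities significant, mean t = 8.72
SVM classification (C_mean; CIS vs RRMS)
  train fraction     : 75%
  chosen C / degree  : 1 / 2
  training accuracy  : 100.0%
  testing accuracy   : 100.0%
  10-fold CV accuracy : 100.0%
  ROC AUC            : 1.00 (95% CI 1.00-1.00, p = 0.0004998)
```

The planted group (higher within-module probability, i.e. the
"RRMS-like" group) shows significantly higher modularity at every
density, and the clustering-coefficient density profiles separate the
groups perfectly under cross-validation — the qualitative pattern the
method is designed to expose. With weaker planted contrasts the
accuracies degrade toward chance (50%).

The same analysis runs from the shell:

```sh
structconn run-all --out run1 --seed 42
structconn simulate --out data --seed 1
structconn metrics --pt-dir data/pt --out profiles.tsv
structconn compare --profiles profiles.tsv --metric Q --groups CIS RRMS
structconn classify --profiles profiles.tsv --metric C_mean --groups CIS RRMS
```

All outputs are plain text (TSV tables, edge lists, JSON reports) with
a manifest of checksums; a re-run with the same config and seed is
byte-identical.

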