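# lumastrat

Prognostic stratification of luminal-A breast cancer expression cohorts
through deep-autoencoder latent features.

Luminal-A is the most common intrinsic breast-cancer subtype and is usually
assigned a favorable prognosis, yet recurrence under endocrine therapy
varies widely between patients. `lumastrat` implements a stratification
pipeline that finds prognostic subgroups which linear feature
representations miss: it trains a five-layer symmetric autoencoder on
renormalized bulk expression, clusters patients on the middle hidden
layer's activations, selects the stratification by survival separation,
and names the resulting subgroups **BPS** (better prognostic subgroup) and
**WPS** (worse prognostic subgroup). External cohorts — possibly profiled
on a different platform — are renormalized against the *training* cohort
and assigned to the nearest subgroup centroid in latent space.

Because the cohorts the method targets are controlled-access, the package
ships a first-class synthetic-cohort generator that plants every structure
the analysis assumes (latent subgroups, co-expressed modules,
subgroup-dependent survival, cross-platform distortion), so the entire
pipeline is testable end to end.

## The model

Input expression (median Z-scores, genes × samples) is filtered to the
top-k genes by median absolute deviation, then min-max renormalized per
gene with the **training** cohort's extremes:

    X1_i(j) = (e_i(j) − min_i) / (max_i − min_i)

The autoencoder has layer widths (N, dim, dim, dim, N), ReLU activations
on the hidden layers, sigmoid on the output, and is trained with Adam
(batch 16, 100 epochs) to minimize

    MSE = (1/NM) Σ_j Σ_i (X5_i(j) − X1_i(j))²

Widths {16, 32, 64, 128, 256, 512, 1024, 2048} are swept; widths past the
validation-MSE elbow are treated as overfit. Latent features are the
second hidden layer's activations

    X3 = f3(W3 · f2(W2 · X1 + b2) + b3)

K-means (k = 2..5) partitions the latent features; a (dim, k) candidate is
admissible if every pairwise log-rank p < 0.05, and the admissible
candidate with the smallest multivariate log-rank p is selected. The
cluster with the larger restricted mean survival time is BPS. Downstream,
subgroup differences are interpreted through moderated-t (empirical-Bayes)
differential expression intersected across cohorts, and through
WGCNA-style weighted co-expression modules (|cor|^β adjacency, topological
overlap, average-linkage modules, permutation preservation tests,
hypergeometric gene-set enrichment).

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
import lumastrat as ls
from lumastrat.pipeline import RunConfig, run_discovery, run_validation

cfg = ls.SimulationConfig(n_genes=300, n_samples=300, module_count=3,
                          module_size=40, seed=5)
expr, surv, truth = ls.generate_tumor_cohort(cfg)
vexpr, vsurv, vtruth = ls.generate_validation_cohort(cfg, truth)

run_cfg = RunConfig(top_k=300, dims_sweep=(16, 32, 64),
                    dims_survival=(16, 32, 64), epochs=50, seed=5)
disc = run_discovery(expr, surv, config=run_cfg, val_expr=vexpr)
print(f"selected: dim={disc.stratifier.hidden_dim}, k={disc.stratifier.k}")
print(f"multivariate log-rank p = {disc.logrank_p:.3g}")
print(f"ARI vs planted subgroups = "
      f"{adjusted_rand_score(truth.subgroup_label, disc.cluster_labels):.3f}")

val = run_validation(disc, vexpr, vsurv)
acc = ((np.array(val.prognosis_labels) == "WPS")
       == (vtruth.subgroup_label == 1)).mean()
print(f"validation assignment accuracy = {acc:.3f}, "
      f"log-rank p = {val.logrank_p:.3g}")
```

Output:

```
selected: dim=16, k=2
multivariate log-rank p = 3.56e-13
ARI vs planted subgroups = 0.934
validation assignment accuracy = 0.970, log-rank p = 5.71e-08
```

The search selected a two-subgroup stratification whose survival curves
separate far beyond chance (multivariate log-rank p ≈ 4e-13); the clusters
recover the planted subgroups almost exactly (ARI 0.93), and samples of a
platform-shifted cohort generated from the same truth are assigned to the
correct subgroup 97% of the time, reproducing the prognostic separation
there as well.

The same workflow is available from the shell:

```sh
lumastrat simulate --out data/ --seed 5
lumastrat run-discovery --train data/train_expression.tsv \
    --clinical data/train_clinical.tsv --out disc/ --seed 5
lumastrat run-validation --discovery disc/ \
    --val data/validation_expression.tsv \
    --clinical data/validation_clinical.tsv --out val/
```

`lumastrat --help` lists the remaining subcommands (`preprocess`, `train`,
`encode`, `stratify`, `assign`, `survival`, `baselines`, `degs`,
`coexpress`, `concordance`).

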