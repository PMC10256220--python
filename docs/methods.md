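# Methods

## Pipeline overview

The package stratifies a discovery expression cohort into prognostic
subgroups and transfers the stratification to external cohorts. The
stages, in order:

1. **Gene filtering.** Keep the top-k genes by unscaled median absolute
   deviation (MAD = median |x − median x|) across the training samples.
   No consistency factor is applied — scaling cannot change the ranking.
   Ties are broken by descending MAD then ascending gene id, so the
   selection is deterministic.
2. **Anchored min-max renormalization.** Each retained gene is mapped to
   [0, 1] using its minimum and maximum over the *training* samples; the
   same per-gene anchors renormalize every external cohort, which may
   therefore produce values outside [0, 1]. These are deliberately not
   clipped: the encoder accepts any real input, and clipping would discard
   cross-platform scale information. A gene with zero range on the
   training set makes the transform undefined and aborts with an error
   naming the gene.
3. **Autoencoder.** A five-layer symmetric network (N, dim, dim, dim, N)
   with ReLU hidden layers and a sigmoid output, trained with mini-batch
   Adam (batch 16, 100 epochs, learning rate 1e-3) to minimize the mean
   squared reconstruction error over all genes and samples jointly. The
   network is implemented directly in numpy with hand-written
   backpropagation: a fixed seed fixes the Glorot-uniform initial weights
   and the per-epoch shuffling, so training is bit-reproducible —
   something GPU frameworks do not guarantee. Widths
   {16, 32, 64, 128, 256, 512, 1024, 2048} are swept; the width at the
   validation-MSE minimum marks the elbow and larger widths are flagged
   as overfit. Latent features are the second hidden layer's activations
   (non-negative by construction).
4. **Stratification.** K-means (k-means++ seeding, 10 restarts, Euclidean)
   with k = 2..5 on each admitted width's latent features. A (dim, k)
   candidate is admissible when every pairwise log-rank p-value is below
   0.05 (raw; no multiplicity adjustment, reflecting how pairwise screens
   are conventionally reported); among admissible candidates the smallest
   multivariate (G−1 df) log-rank p wins. If no candidate is admissible
   the search returns an explicit no-stratification outcome rather than
   forcing a split.
5. **Prognosis naming.** For k = 2 the cluster with the larger restricted
   mean survival time is BPS, the other WPS; for k > 2, ordinal names
   P1..Pk by decreasing RMST. The RMST horizon is the full follow-up
   window (largest observed time over clusters), with the Kaplan–Meier
   estimate carried forward beyond a cluster's own follow-up; integrating
   only to the shortest cluster follow-up would make the comparison
   degenerate when one cluster's events all occur early. RMST ties break
   toward the larger cluster (logged).
6. **External assignment.** External samples are renormalized with the
   training anchors, encoded with the selected-width autoencoder, and
   assigned to the nearest subgroup centroid (Euclidean; ties to the lower
   cluster index, logged).
7. **Baselines.** K-means with identical hyperparameters on the full
   expression matrix, the top-k matrix, and PCA projections (gene-wise
   mean centering, no variance scaling — the input is already on a
   z-score-like scale) of both at 64 and 2 components. All arms consume
   identical sample sets, so differences isolate the representation.
8. **Differential expression.** Per cohort, a two-group moderated t per
   gene: pooled variances shrunk toward a prior estimated by moment
   matching on log variances (digamma/trigamma inversion); the moderated
   t has d0 + d_g degrees of freedom. When the observed log-variance
   spread does not exceed sampling noise the prior is infinitely
   informative and the pooled mean variance (the MLE of the common scale)
   is used — matching current Bioconductor limma behavior, against which
   the implementation is cross-checked in the test suite. Benjamini–
   Hochberg adjustment; consensus DEGs are genes significant
   (adjusted p < 0.01 by default) in **both** cohorts with concordant
   direction. Sign concordance is on by default (a gene "differential in
   both cohorts" with opposite directions is biologically incoherent) and
   can be disabled for strict two-list intersection. DEG testing runs on
   the z-score-scale matrices, not the min-max-renormalized ones.
9. **Co-expression modules (WGCNA-lite).** From normal-tissue expression:
   genes with median read count ≤ 10 are dropped (strict inequality);
   samples split 80/20; the soft power β is the smallest candidate
   (grid 1..10, 12..20 by 2) whose scale-free topology fit reaches
   R² ≥ 0.8 with negative slope, falling back to the maximal-R² power
   with a warning when no candidate qualifies (planted block-modular data
   is not scale-free, so the fallback is routinely exercised there);
   unsigned adjacency a_ij = |cor|^β with zero diagonal; topological
   overlap TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i, k_j) + 1 − a_ij).
   Modules are flat cuts of average-linkage clustering on 1 − TOM with a
   minimum size, renumbered by decreasing size — a deliberate
   simplification of dynamic tree cut with its parameters exposed.
   Preservation in the held-out split is the mean within-module test TOM
   against a random-gene-set permutation null
   (p = (1 + #{null ≥ obs})/(1 + n_perm)), a lightweight surrogate for the
   Zsummary suite. Each module's graph view keeps the ceil(10%) highest-
   weight within-module edges (membership unchanged). Module–DEG overlap
   is 100·|module ∩ DEGs|/|module|; gene-set enrichment is the
   hypergeometric upper tail over GMT collections with BH adjustment and
   a 1e-4 default significance threshold.
10. **Concordance.** Cross-tabulation against an external labeling over
    shared samples (unshared samples dropped and counted), Pearson
    chi-squared with Yates correction for 2×2 tables only (toggleable).

## Synthetic cohorts

The generator plants exactly the structure the pipeline assumes, with
ground truth recorded for every draw:

- **Latent subgroup model.** Samples carry a latent vector (default 8
  dims); subgroup 1 (Bernoulli 1/2) is shifted by delta (default 4
  z-score units) on 2 designated dims. Genes load on one latent dim each
  (contiguous blocks, loading magnitudes U(0.6, 1.4)); genes loading on
  shifted dims are the planted DEGs. With delta = 0 the subgroups are
  exchangeable and the planted DEG set is empty.
- **Modules.** Block factors with loading sqrt(rho) give within-module
  pairwise correlation ≈ rho; module genes are drawn outside the
  subgroup-signal blocks when possible so co-expression and differential
  structure stay distinguishable. Normal-tissue cohorts use the pure
  factor model and exponentiate to count-like integers
  (counts = round(2^(baseline + signal))) so the median-read-count filter
  is exercisable; module genes get higher baselines so quantization does
  not erode the planted correlation.
- **Expression scale.** Raw values are centred per gene on a finite
  reference panel's median (80 subgroup-free samples) and scaled by one
  cohort-level robust factor (the median of per-gene reference MADs),
  emulating reference-normalized "median Z-scores". Full per-gene
  self-standardization would force every per-gene mean toward 0 and MAD
  to exactly 1, destroying the cross-platform rank-concordance
  diagnostics the pipeline computes; the reference-panel scheme preserves
  gene-level structure while still centring robustly. Gene noise is
  standardized gamma (shapes U(2, 20)), giving the right-skewed,
  gene-specific asymmetry real expression shows — this is what makes
  per-gene means rank-correlate across cohorts.
- **Survival.** Exponential recurrence times with subgroup hazards
  (h, h·HR), administratively censored at U(0, 120 months). The base
  hazard is solved numerically so the expected overall event fraction
  hits the target (default 60%). Real cohort censoring is more complex
  (staggered accrual, loss to follow-up); administrative-uniform is the
  simplest mechanism with a controllable event fraction, and nothing
  downstream depends on the censoring shape beyond that.
- **Platform shift.** Validation cohorts redraw samples from the same
  gene-level structure (same seed-derived loadings), then distort each
  gene with a monotone affine map (scale U(0.6, 1.4), offset
  U(−0.5, 0.5)) before reference normalization. Offsets cancel in the
  reference centring; per-gene scale differences survive, which is
  exactly what the anchored min-max renormalization must absorb, while
  per-gene mean/MAD *ranks* stay positively correlated — mirroring the
  cross-platform concordance seen between microarray and RNA-seq cohorts.

What the generator does **not** emulate: probe-level microarray artifacts,
count-level RNA-seq noise (distortion acts on the normalized scale),
batch structure within a cohort, non-exponential hazards, or informative
censoring. Passing tests therefore demonstrate that the pipeline recovers
the structures it models, under its own assumptions — not performance on
any real cohort.

## Defaults and problem sizes

Analysis defaults follow the reference protocol: top-k 5,000 genes, width
sweep 16..2048 with widths 16/32/64/128 admitted to survival selection,
k = 2..5, epochs 100, batch 16, Adam learning rate 1e-3 (the optimizer's
conventional default; only the optimizer itself is prescribed), pairwise
alpha 0.05, DEG adjusted-p 0.01, enrichment adjusted-p 1e-4, edge fraction
0.10, median read count > 10, 80/20 split.

Simulated experiments run at a deliberately desk-sized scale chosen to
exercise every code path with comfortable margins: discovery cohorts of
1,000 genes × 600 samples with the sweep restricted to the four admitted
widths, and a 459-sample normal-tissue cohort with 23 planted modules of
20 genes for the co-expression stage. At this scale the full discovery +
validation analysis completes in about a minute on one CPU.

## Numerical choices and edge cases

- Adam uses (β1, β2, ε) = (0.9, 0.999, 1e-8); sigmoid is evaluated in the
  numerically stable split form.
- K-means restarts: n_init = 10 with best-inertia selection; all
  clustering and assignment ties resolve to the lower index.
- Log-rank tests use the standard convention that events precede
  censorings at tied times; p-values come from the chi-squared reference
  distribution.
- Zero-variance genes: fatal in min-max fitting and correlation networks
  (named in the error); harmless in moderated-t, where shrinkage keeps
  the denominator positive whenever d0 > 0.
- The trigamma inversion for the variance prior uses Newton iterations on
  the standard closed-form start and is guarded for extreme targets.
- Edge filtering rounds up (ceil) and breaks weight ties by gene-id pair,
  so the kept edge set is deterministic.
- Empty external cohorts propagate as empty outputs without error.

## Known limitations

- Module detection is a flat dendrogram cut, not dynamic tree cut; module
  counts on real data would differ from a full WGCNA run, and no
  module-for-module agreement with any published network is claimed. The
  data-driven soft threshold also varies across simulated draws, and the
  detected module count varies with it.
- The preservation statistic is a single permutation test, not the
  Zsummary battery.
- The (dim, k) selection rule — admissible-then-minimum-p — is a
  formalization of a narrative "most distinct prognostic difference"
  criterion; other formalizations (e.g. adjusted pairwise p) are
  plausible and the alpha is exposed.
- No Cox regression or covariate adjustment; survival comparisons are
  unadjusted log-rank tests.
- Enrichment is a local hypergeometric over-representation test over GMT
  files, not a web-service query, and inherits GMT coverage limitations.
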