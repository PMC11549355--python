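# Methods

## Model

Each target gene carries a hard module label; module *i* owns a regulatory
program (R_i, s_i, B_i): a set of regulator indices, one sign per regulator,
and non-negative per-gene coefficients. Conditional on its label, a target
gene's expression is Gaussian with mean `Zr[:, R_i] @ diag(s_i) @ B_i[:, j]`
and gene-specific variance σ²_{i,j}. Targets are assumed conditionally
uncorrelated given the regulators — the module structure, not residual
correlation, carries the co-expression. Regulators never switch roles with
targets; the program is a module-level summary, not a gene-to-gene network.

## Data preparation

Cells are randomly split into a training and an assessment half (default
50–50, stratified when sample labels are given; a dedicated RNG stream keyed
by one integer seed makes the split reproducible bit for bit). Target columns
are centered and regulator columns centered and scaled to unit standard
deviation, with all statistics computed **on the training half only** and the
same affine transform applied to the assessment half. The source text for
this procedure can be read two ways (train-only statistics vs. re-centering
each half); we use train-only statistics to keep the assessment half free of
any leakage. Duplicate gene or cell names are an error, never silently
deduplicated. Unbiased variance estimation requires n₁ > p_r, hence the
recommendation that the number of cells be at least twice the number of
regulators; below that a ridge fallback with a documented penalty
(smallest eigenvalue of Zr₁ᵀZr₁ + 1e-4) and effective degrees of freedom
(trace of the ridge hat matrix) is used.

## Initialization

Target genes are represented by their Pearson correlations with all
regulators on the training half and clustered by k-means++ (scikit-learn,
10 restarts, Lloyd tolerance 1e-8, best WCSS kept; empty clusters are
relocated by scikit-learn's standard farthest-point remedy). Because the
representation is regulator-correlation space, this differs from clustering
raw target expression: genes with similar expression magnitude but opposite
regulator correlations separate (tested on a constructed counterexample).

## Step 1 — regulator selection (cooperative Lasso)

Per module, minimize

    1/2 Σ_{j∈C_i} 1/(n₁σ²_{i,j}) ‖Zt₁[:,j] − Zr₁ B[:,j]‖² +
    λ Σ_k w_k (‖B₊^(k,:)‖₂ + ‖B₋^(k,:)‖₂)

The variances are plugged in from OLS (denominator n₁ − p_r) or the ridge
fallback; weights are adaptive, w_k = sqrt(|C_i| / ‖B_OLS^(k,:)‖₂), with a
zero OLS row giving weight +∞ (the row is removed from the problem and
forced to zero — it would never be selected at any positive penalty).

The solver is over-relaxed ADMM with the loss block solved in closed form
through one cached eigendecomposition of Zr₁ᵀZr₁ (the per-gene weights enter
only through the diagonal), and the penalty block solved by the exact
proximal operator of the cooperative penalty: group soft-thresholding applied
independently to the positive and negative part of each row. Defaults:
ρ₀ = 1, over-relaxation α = 1.6 (fixed; the step length, not α, is adapted),
residual-balancing ρ adaptation (×2 / ÷2 when one residual exceeds the other
tenfold, checked every 10 iterations), stopping at relative residual 1e-7
(absolute floor 1e-10), max 5000 iterations, warm start from the previous
cycle when the module's membership is unchanged. Selected regulators are the
rows with any entry above 1e-10; the regulator sign is the sign of the row
mean, with an exact-zero tie resolved to +1.

The solver is validated against an independent convex oracle (L-BFGS-B on
the split B = P − N, P, N ≥ 0, with smoothing continuation on the group
norms): objectives agree to 1e-6 relative on random instances, and the prox
to 1e-8 against direct numerical minimization.

## Step 2 — re-estimation and reallocation

For every module the coefficients of **all** target genes are re-estimated
without penalty by NNLS on the signed design `Zr₁[:, R_i] diag(s_i)` (this
removes the shrinkage bias and enforces the selected signs; scipy's NNLS is
applied per response column on a Cholesky-reduced Gram system, validated
against exhaustive active-set enumeration). Residual variances use the
unbiased denominator n₁ − |R_i|, floored at 1e-12.

On the assessment half, the predictive R² of every gene under every module's
program is computed (total sum of squares about the assessment gene mean; can
be negative; −∞ for inactive modules or constant genes). Genes whose best R²
falls below τ (default 0.05) go to the rag bag for this cycle — rag-bag
membership is recomputed every cycle, so a gene can re-enter. Remaining genes
are reassigned by votes: per assessment cell, the module maximizing
(1 − μ)·log L + μ·log p wins (likelihoods normalized across modules per cell
by log-sum-exp; all likelihood work in log space), and the gene goes to the
modal module. Votes and per-cell argmaxes break ties toward the lowest module
index. Genes are processed in a seeded random order and the prior fractions
f_{i,j} = (links of j into module i) / |module i| are recomputed from the
partially updated partition, shifted by α = 1e-6 and normalized, so earlier
assignments inform later ones within a cycle.

Modules smaller than `min_module_size` after allocation are released (their
genes go to the rag bag for that cycle and are redistributed in the next).
The default floor is 2 genes. A floor of 2·|R_i| is available as
`min_module_size="auto"` but is **not** the default: at small penalties the
coop-Lasso selects many regulators, 2·|R_i| then exceeds the module size and
releases healthy modules wholesale (in our experiments K = 10 fits collapsed
to a single module at λ = 0.02 under that rule).

## Convergence

A history of partitions (rag-bag membership included — a gene moving in or
out of the rag bag is a change) is kept; the run stops when the current
partition equals any stored one. Distance 1 is convergence; distance L > 1 is
a limit cycle and all L configurations (partition, selections, models, R²)
are returned so diagnostics can be computed for each. Hitting `max_cycles`
(default 50) without a repeat returns the last configuration with a warning.

## Diagnostics

* **Module predictive R²**: 1 − RSS_i/TSS_i over the module's members on the
  assessment half. (The source formula prints the ratio RSS/TSS without the
  "1 −"; the surrounding usage and the importance definition require a
  coefficient of determination, so the complement is implemented.)
* **Regulator importance**: drop regulator k, re-fit the module by NNLS on
  the training half, rescore on the assessment half;
  I = 1 − R²_{i,−k}/R²_i clipped to [0, 1]. Modules with R²_i ≤ 0 report
  missing importances rather than clipped ones. Removing the sole regulator
  leaves the empty model (prediction 0), so a sole informative regulator has
  importance ≈ 1; a duplicated regulator has importance ≈ 0.
* **Silhouette**: per gene, a = own-module R², b = max(0, best other-module
  R²), S = (a − b)/max(a, b); rag-bag genes are missing; the degenerate case
  max(a, b) ≤ 0 is defined as 0 and logged.
* **Regulatory table**: T[k, i] = mean coop-Lasso coefficient of regulator k
  over module i's members, kept only when the median training-half Pearson
  correlation of regulator k with those members exceeds 0.025, else 0.

External validation against a known truth: adjusted Rand index (rag bag as
its own label; sklearn implementation cross-checked against a pair-counting
oracle), cluster homogeneity (mean over truth clusters of the largest
fraction landing in one estimated cluster — blind to merging, hence always
paired with ARI), and per-gene regulator TPR/FPR (a gene's estimated set is
its module's R_i; genes with empty truth sets are excluded from the TPR
average; the FPR denominator is the non-regulator complement).

## Cross-dataset merging and annotation

Regulatory tables are outer-joined on regulator names (missing entries 0),
rows and columns with zero absolute sum are dropped, and each **row** is
z-scored. Row-wise scaling is a deliberate choice where the source is
ambiguous: the landscape is read by comparing one regulator across modules,
which requires a common per-regulator scale. Module identifiers are
qualified `<dataset>:<module>` to stay unique. Annotation of module gene
sets against signatures (GMT input supported) uses the Jaccard index on
case-normalized symbols.

## Synthetic data

The generator plants K_true modules: latent per-cell regulator activities
a_k ~ N(0, 1) drive both the regulator's own counts (log-mean = baseline +
1.5·a_k) and its targets (log-mean = baseline + Σ sign·β·a_k over the
module's regulators); counts are negative binomial with dispersion θ
(variance m + m²/θ). Noise genes carry baseline only. Defaults state the
reference scenario used throughout the tests: 2000 cells, 50 regulators,
5 modules × 40 genes, 3 regulators per module, 25% repressing links,
baseline log-mean log(10) (mean ≈ 10 counts), θ = 5, effect size β = 0.6.
β was calibrated once so that a typical target gene has out-of-split R² ≈
0.5 against its true regulators after log-CPM normalization (measured
0.50–0.53 across seeds), and is not revisited per test.

What the generator emulates: NB overdispersion, library-size variation,
sign-consistent module programs, an observable-regulator path from activity
to effect. What it does not: dropout beyond NB zeros, batch effects,
cell-type mixtures, gene-length effects, regulator–regulator interactions or
cooperativity, mean–variance trends beyond the single θ. A green recovery
test therefore establishes that the estimator recovers planted linear,
sign-consistent structure at moderate signal strength — not performance on
any particular real dataset.

Normalization helpers: `log1p_cpm` (log of counts-per-10k + 1) and
`log2_tpm10` (log2(TPM/10 + 1), TPM as depth-scaled counts without length
correction). Note that depth normalization couples genes: with few
unstructured genes, "pure-noise" genes inherit regulator signal through the
library size and are genuinely predictable — the rag-bag specificity
experiment therefore uses a majority-unstructured transcriptome (400 noise
genes against 200 structured), which is also the realistic composition.

## Choosing λ and K — and two caveats

Along an increasing penalty grid the selected-regulator count falls, module
predictive R² decays and regulator importance rises; the elbow (high R²,
moderate importance) marks a good penalty, and we recommend at least five
grid values. Two measured caveats:

* **Under-penalization**: below λ ≈ 0.05 in the reference scenario the
  selector keeps > 20 regulators per module and out-of-split module R² is
  *lower* than at λ = 0.05 — predictive R² is non-monotone once coefficient
  overfitting sets in. The monotone-decay description applies from the point
  where the penalty starts to bind.
* **Over-specified K at strong penalties**: with K = 2·K_true and λ ≥ 0.1
  the empty-module mechanics collapse the fit onto the K_true solution
  exactly (a feature: the method sheds redundant modules). The silhouette
  contrast that flags over-specification — split twins dragging S toward
  zero — is visible at smaller penalties (λ ≈ 0.03) where the extra modules
  survive. Under-specified K keeps silhouettes high while fusing programs,
  so silhouette must be read jointly with the realized module count and
  module R².

## Limitations

* n₁ > p_r is needed for unbiased variances; the ridge fallback changes the
  estimator, and |R_i| must stay below n₁.
* Hard assignment only; no soft membership.
* One penalty λ shared across modules.
* The likelihood treats cells as independent and Gaussian on the normalized
  scale; heavy-tailed residuals inflate σ² rather than being modeled.
* Dormant (emptied) modules do not re-seed; a run that sheds modules reports
  fewer than K modules rather than re-splitting large ones.
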