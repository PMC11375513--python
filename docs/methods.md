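# Methods

This note records the statistical model, the numeric conventions, the design
choices that were genuinely open, and what the synthetic validation does and
does not demonstrate.

## Sparse CCA by penalized matrix decomposition

Given standardized blocks `X` (n × p genes) and `Y` (n × q species), each
component maximises `uᵀ Xᵀ Y v` under `‖u‖₂ ≤ 1, ‖u‖₁ ≤ c₁` and
`‖v‖₂ ≤ 1, ‖v‖₁ ≤ c₂`. The inner subproblem — maximise `aᵀu` under those two
constraints — has the closed form `u = S(a, δ)/‖S(a, δ)‖₂` with the
soft-threshold `S(a, δ) = sign(a)·max(|a|−δ, 0)`; δ = 0 when the plain
normalised vector already satisfies the L1 budget, otherwise the unique δ at
which the budget binds, found by bisection to 1e-8 (the L1/L2 ratio of the
thresholded vector is non-increasing in δ). When entries of `a` are exactly
tied the ratio jumps discontinuously and no δ binds; the solver then falls
back to equal mass on the top `⌊c²⌋` entries (deterministic index
tie-break). Alternation stops when the largest coordinate change falls below
`tol` (default 1e-7, cap 200 iterations; non-convergence is flagged, not
fatal). Initialisation is the leading right singular vector of the current
cross-product, sign-fixed, so runs are deterministic.

Feasible L1 budgets live in `[1, √dim]`; the API parameterises them as
fractions of `√dim` gridded over {0.1, …, 1.0} by default. With fractions of
1.0 the penalties are inactive and the component sequence equals the SVD of
`XᵀY` — the main correctness oracle (singular values agree to ~1e-14 in the
validation run).

### Sign conventions

`d = uᵀZ_k v ≥ 0` holds at any fixed point by construction (Z_k the deflated
cross-product the component was fitted on). The reported score correlation
`r = corr(Xu, Yv)` is computed against the *original* matrices and can come
out negative for k ≥ 2; a joint (u, v) flip cannot change it, so when r < 0
only v (and the y-scores) are flipped and the component records
`deflation_sign = −1`, keeping the deflation identity
`Z₁ = Σ d_k·u_k·(sign_k·v_k)ᵀ + residual` exact. A final joint flip makes the
largest-|weight| gene entry positive for reproducible reporting.

### Penalty tuning

Each grid cell is scored by 5-fold cross-validated held-out
`|corr(X_test·u, Y_test·v)|` of the first component (training-fold SVD
initialisation shared across cells; degenerate zero-variance scores count 0).
Held-out correlation barely penalises spurious small weights, so a strict
argmax drifts toward dense cells on fold noise. Selection therefore uses the
cross-validated analogue of the one-standard-error convention: a cell is
tied with the argmax unless the argmax beats it in a one-sided paired t-test
across folds at the 5% level, and the sparsest tied cell (smallest fraction
sum, then smallest gene-side fraction) wins. A permutation-z criterion in
the style of the reference sparse-CCA tooling was evaluated and found to
overshoot toward extreme sparsity (its null variance collapses for sparse
cells), so cross-validation remains the default.

### Component count and deflation echoes

The retained count is the largest K whose components all achieve
permutation p < α (default 0.05), with `p = (1 + #{d_null ≥ d_obs})/(1 +
n_perm)` from refitting the full sequence on row-permuted Y. Two properties
are worth knowing:

* With `n_perm = 19` (the minimum) the smallest attainable p is exactly
  0.05, which the strict threshold never retains; use ≥ 39 permutations.
* When the L1 budgets are tighter than the true support scale, the shrunken
  (u, v) do not capture a planted rank-one term completely; deflation leaves
  an "echo" that can genuinely exceed the permutation null, so the test may
  retain more components than planted factors. This is residual signal, not
  a false positive — the echo scores still track a true latent — and it is
  consistent with selecting a handful of components per phenotype on real
  data. With inactive penalties deflation is exact and the test stops at the
  planted rank (verified in the suite). Compositional closure has the same
  effect on the species side: a latent that raises some taxa necessarily
  depresses the rest, spreading signal beyond any sparse support.

## Filtering stages

* Differential expression: Welch's unequal-variance t-test per gene on log2
  values, Benjamini–Hochberg adjustment across genes; degenerate genes
  (zero variance in both arms, equal means) receive p = 1. The gate keeps
  adjusted p < 0.05 AND |log2 FC| > 0.5 — two-sided, so down-regulated genes
  survive. A moderated-variance test would be a reasonable alternative; the
  Welch test is assumption-light and is a deliberate simplification. The
  gate is applied only when a control (healthy) arm is supplied.
* Variance filter: a feature is retained iff its within-group variance
  strictly exceeds the q-quantile (linear interpolation, default q = 0.25)
  of that group's feature variances in at least one group. Note this
  operation is not idempotent: re-application recomputes the quantile on the
  survivors and removes more.
* Abundance filter: a species is retained iff its relative abundance is
  ≥ 0.01 in ≥ 10% of samples of at least one group (both comparisons
  inclusive at the boundary). "At least one group" keeps group-specific
  signal available to both per-group fits. The surviving matrix is a
  subcomposition and is deliberately not renormalised.
* Transforms: expression is standardized per gene (sample-sd convention,
  ddof = 1); abundances go through a centered log-ratio transform with
  pseudocount 1e-6 (the standard compositional treatment; the pseudocount
  guards zeros) and are then standardized.

## Enrichment

Component gene sets default to all nonzero-weight genes (the lasso already
selects); a top-N rule by |weight| with lexicographic tie-break exists for
the enrichment-score stage's explicit top-10 convention. The test is the
one-sided hypergeometric tail over the universe of genes that entered the
decomposition (conditioning on the tested feature space guards against
filter-induced inflation); raw p < 0.05 flags enrichment, with BH-adjusted
values emitted alongside. Pathways enriched in ≥ 1 component of each
phenotype are "shared", otherwise phenotype-only. Species are linked to a
pathway when they carry nonzero weight in a component where that pathway is
enriched. Note the discrete test is conservative: at small overlaps its
attainable size can be far below the nominal 0.05.

## Per-sample enrichment scores

Step 1: Gaussian-kernel ECDF statistic `z_ij = mean_k Φ((x_ij − x_ik)/h_i)`
with bandwidth `h_i = sd_i/4` — the conventional choice; invariant to
per-gene affine rescaling. Step 2: per-sample gene ranking by decreasing z,
symmetrised as `r = |N/2 − rank|`. Step 3: a weighted Kolmogorov-like walk
down the ranked list (`|r|^τ`-normalised steps inside the set, `−1/(N−m)`
outside, τ = 1), scored as maximum positive plus minimum negative deviation
(bounded in [−1, 1]); the largest-|deviation| variant is a switch. The
implementation is from scratch and agrees exactly (≤ 1e-9) with the
independent GSVA implementation in gseapy on dense Gaussian data.

Two behavioural notes. Because the score is rank-based *within* a sample, a
strong up-shift of one gene set slightly depresses the scores of unrelated
sets in the same samples — decoy-set AUROC against a shifted phenotype sits
a little below 0.5 rather than at it. And a gene set containing both up- and
down-regulated members cancels in the walk; the synthetic generator
therefore plants coherently up-regulated gene modules, which is what makes
"enrichment score recovers the clinical link" a well-posed property.

## Synthetic data

The generator emulates the paired sputum design at desk scale: 99 samples by
default (EO/LO split available), log2-microarray-like expression (gene
baselines N(7, 1)), and compositional abundances built by softmax of latent
Gaussian log-abundances. K latent per-sample score vectors are sampled,
centered, QR-orthogonalised (pairwise Pearson r = 0 to machine precision)
and scaled to unit sd; each loads with strength `signal_sd` on a disjoint
gene support (+1 loadings, see above) and a disjoint species support
(random-sign loadings), so `signal_sd/noise_sd` is the per-feature SNR
(default 3). Planted species draw baseline log-abundance from N(1.0, 0.5)
versus N(0, 1.5) for decoys — detectable, moderately abundant taxa, the
kind a prevalence filter targets. Clinical covariates are
`coefficient·z_k + noise` squashed onto (0, 100) by a strictly monotone
Gaussian-CDF transform, so Spearman links survive exactly. Gene-set
collections mix sets seeded from planted supports with uniform decoys and
round-trip through GMT.

What the generator does **not** emulate: sequencing-read noise, batch
effects, missing data, gene–gene correlation beyond the planted factors,
realistic taxon abundance distributions, or mixed-sign regulatory modules.
Passing the recovery suite therefore shows the machinery is correct and
well-calibrated under its own assumptions, not that the pipeline's findings
on any real cohort are right.

## Validation scenario sizes

The acceptance battery uses: 50×40/50×30 blocks for SVD equivalence; 200
random problems for the constraint suite; n = 150, p = 400, q = 60 with two
planted components and SNR 3 over 20 replicates for support recovery
(mean F1 ≈ 0.96–0.99, mean score–latent Spearman ≈ 0.995); 20 + 200
pure-noise replicates with 49 permutations for null calibration; the full
universe-≤ 60 sweep (~6.3×10⁵ tables) for the Fisher oracle; 500 random
vectors for the BH oracle; and 20 replicates of a two-group scenario
(56 LO + 43 EO samples, 300 genes, 50 species, one LO-specific component
linked to sputum neutrophilia) for the asymmetric-link property, where the
LO component's top-10 gene set correlates with neutrophilia in ≥ 85% of
replicates in LO samples only.
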