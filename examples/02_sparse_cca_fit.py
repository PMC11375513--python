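"""Tune the lasso budgets, fit sparse canonical components, and select how
many to keep by permutation.

Each component couples a sparse set of genes (weights u) with a sparse set
of species (weights v) so that the sample scores Xu and Yv are maximally
correlated. The printed support F1 compares the genes/species each component
selects with the planted ground truth.
"""

import numpy as np
from scipy.stats import spearmanr

import duomics as dm

expr, abund, truth = dm.generate_paired_omics(
    n_samples=150, p_genes=400, q_species=60, k_latent=2, seed=1
)
X = dm.standardize(expr)
Y = dm.standardize(dm.clr_transform(abund))  # CLR for compositional data

grid = dm.tune_penalties(X, Y, seed=1)
print(f"selected penalty fractions (c1, c2) = {grid.selected} "
      "(sparsest cell tied with the best cross-validated score correlation)")

c1 = dm.penalty_from_fraction(grid.selected[0], X.n_features)
c2 = dm.penalty_from_fraction(grid.selected[1], Y.n_features)
comps, retained = dm.permutation_component_test(
    X, Y, K_max=4, n_perm=99, c1=c1, c2=c2, seed=1
)
print(f"permutation test retains K = {retained} components "
      "(sequential rule, p < 0.05)\n")

for comp in comps[:retained]:
    k = max(range(2), key=lambda j: abs(
        spearmanr(comp.x_scores, truth.latent_scores[:, j])[0]))
    rho = spearmanr(comp.x_scores, truth.latent_scores[:, k])[0]
    sel_g = set(comp.nonzero_genes())
    sup_g = truth.gene_support_ids(k)
    f1 = 2 * len(sel_g & sup_g) / (len(sel_g) + len(sup_g))
    print(f"component {comp.index}: d={comp.d:8.1f}  "
          f"score correlation r={comp.score_correlation:.3f}  "
          f"genes={len(sel_g)}  species={len(comp.nonzero_species())}  "
          f"support F1={f1:.2f}  |rho(score, planted z{k+1})|={abs(rho):.3f}")
print("\nhigh F1 / rho mean the lasso recovered the planted gene-species "
      "coupling and its per-sample latent scores; components beyond the "
      "planted two (if retained) are 'echoes' — the L1 shrinkage leaves part "
      "of each signal behind after deflation, and the permutation test "
      "rightly flags that residual as non-random")
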