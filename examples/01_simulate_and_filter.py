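"""Generate a synthetic paired sputum dataset and run the filtering stages.

The generator plants two sparse canonical components: latent per-sample
scores that drive a small block of genes (log2 expression scale) and a small
block of species (relative-abundance scale, rows on the unit simplex).
"""

import duomics as dm

expr, abund, truth = dm.generate_paired_omics(
    n_samples=99, p_genes=500, q_species=60, k_latent=2, seed=1
)
print(f"expression: {expr.n_samples} samples x {expr.n_features} genes (log2 scale)")
print(f"abundance:  {abund.n_samples} samples x {abund.n_features} species "
      f"(row sums = {abund.values.sum(axis=1).round(6).unique().tolist()})")
print(f"planted components: {truth.k_latent}, gene supports of "
      f"{[len(s) for s in truth.gene_supports]}, species supports of "
      f"{[len(s) for s in truth.species_supports]}")

groups = {s: "ALL" for s in expr.sample_ids}
expr_f = dm.variance_filter(expr, groups, q=0.25)
abund_f = dm.abundance_filter(abund, groups, min_abund=0.01, min_prev=0.10)
print(f"\nvariance filter (25% quantile): {expr.n_features} -> {expr_f.n_features} genes")
print(f"abundance filter (>=0.01 in >=10% of samples): "
      f"{abund.n_features} -> {abund_f.n_features} species")

kept_genes = set(expr_f.feature_ids)
support = {truth.gene_ids[i] for sup in truth.gene_supports for i in sup}
print(f"planted support genes surviving the filter: "
      f"{len(support & kept_genes)}/{len(support)} "
      "(signal adds variance, so planted genes pass)")
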