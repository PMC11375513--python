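"""Per-sample enrichment scores for a component's top genes, correlated with
a clinical trait.

The enrichment score (ES) summarises, per sample, whether a gene set sits
coherently toward the top or bottom of that sample's expression profile.
When the set is the top-10 genes of a component whose latent score drives
sputum neutrophilia, the ES should track the neutrophil percentage.
"""

import duomics as dm
from duomics import GeneSetCollection
from duomics.enrichment import component_gene_set

expr, abund, truth = dm.generate_paired_omics(
    n_samples=99, p_genes=300, q_species=50, k_latent=1, seed=3
)
clinical = dm.generate_clinical(
    truth,
    links={"sputum_neutrophil_pct": (0, 2.0)},
    extra_noise_vars=("sputum_eosinophil_pct",),
    seed=3,
)
X = dm.standardize(expr)
Y = dm.standardize(dm.clr_transform(abund))
comp = dm.fit_sparse_cca(
    X, Y, K=1,
    c1=dm.penalty_from_fraction(0.2, X.n_features),
    c2=dm.penalty_from_fraction(0.4, Y.n_features),
)[0]

top10 = component_gene_set(comp, rule="top_n", n=10)
sets = GeneSetCollection(sets={"C1_top10": ("", tuple(sorted(top10)))})
es = dm.gsva_scores(expr, sets)
print(f"ES matrix: {es.shape[0]} set x {es.shape[1]} samples, "
      f"range [{es.to_numpy().min():.2f}, {es.to_numpy().max():.2f}] (bounded in [-1, 1])")

tab = dm.correlate_es_clinical(
    es, clinical, ["sputum_neutrophil_pct", "sputum_eosinophil_pct"]
)
print(tab.to_string(index=False))
print("\nthe linked trait (neutrophils) shows a strong Spearman correlation; "
      "the unlinked trait (eosinophils) stays near zero")
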