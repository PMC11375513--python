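"""Pathway enrichment of component gene selections.

Each canonical component selects a sparse set of genes (by absolute weight);
those selections are tested for over-representation in named gene sets with a
one-sided Fisher's exact (hypergeometric tail) test against the universe of
genes that entered the decomposition. Pathways are then classified as shared
between the two onset phenotypes or specific to one, and species are linked
to pathways through co-membership in components.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .cca import CCAComponent
from .containers import GeneSetCollection

__all__ = [
    "EnrichmentRecord",
    "component_gene_set",
    "fisher_enrichment",
    "enrich_components",
    "classify_shared_unique",
    "species_pathway_links",
]


@dataclass
class EnrichmentRecord:
    """Result of one (component, pathway) Fisher's exact enrichment test."""

    component: str  # e.g. "LOC4", "EOC1"
    pathway: str
    n_selected: int
    n_pathway_in_universe: int
    n_overlap: int
    p_value: float
    enriched: bool
    phenotype: str  # "EO" | "LO" | other tag
    adjusted_p: float = float("nan")


def component_gene_set(
    component: CCAComponent, rule: str = "nonzero", n: int | None = None
) -> set[str]:
    """Genes a component selects, by absolute weight.

    ``rule="nonzero"`` returns every gene with a nonzero weight (the lasso has
    already selected); ``rule="top_n"`` returns the ``n`` largest by |weight|,
    ties broken toward the lexicographically smaller gene id. When fewer than
    ``n`` weights are nonzero, only the nonzero genes are returned.
    """
    pairs = [
        (gene, abs(w)) for gene, w in zip(component.gene_ids, component.u) if w != 0.0
    ]
    if not pairs:
        raise ValueError("component has an all-zero gene weight vector")
    if rule == "nonzero":
        return {g for g, _ in pairs}
    if rule == "top_n":
        if n is None or n < 1:
            raise ValueError("top_n rule requires n >= 1")
        ranked = sorted(pairs, key=lambda gw: (-gw[1], gw[0]))
        return {g for g, _ in ranked[:n]}
    raise ValueError(f"unknown rule {rule!r}")


def fisher_enrichment(
    selected: set[str], pathway: set[str], universe: set[str]
) -> tuple[int, float]:
    """One-sided enrichment test of ``selected`` against ``pathway``.

    The pathway is intersected with the universe first; the p-value is the
    hypergeometric upper tail ``P(overlap >= observed)`` for the 2x2 table of
    selection x pathway membership over the universe. Returns
    ``(n_overlap, p_value)``.
    """
    if not universe:
        raise ValueError("empty universe")
    if not selected:
        raise ValueError("empty selected set")
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    path = pathway & universe
    overlap = len(selected & path)
    # hypergeom(M=universe, n=pathway size, N=draws): P(X >= overlap)
    p = float(hypergeom.sf(overlap - 1, len(universe), len(path), len(selected)))
    return overlap, min(p, 1.0)


def enrich_components(
    components: list[CCAComponent],
    collection: GeneSetCollection,
    universe: set[str],
    phenotype: str,
    alpha: float = 0.05,
    rule: str = "nonzero",
    n: int | None = None,
    label_prefix: str | None = None,
) -> list[EnrichmentRecord]:
    """Fisher-test every (component, pathway) pair.

    The enriched flag uses the raw p < ``alpha`` threshold; BH-adjusted
    p-values (across all pairs tested here) are also reported for users who
    prefer FDR control. Component labels default to ``<phenotype>C<k>``
    (e.g. LOC1, EOC2).
    """
    prefix = label_prefix if label_prefix is not None else f"{phenotype}C"
    records: list[EnrichmentRecord] = []
    for comp in components:
        selected = component_gene_set(comp, rule=rule, n=n) & universe
        if not selected:
            continue
        for pathway_name in collection.names():
            path = set(collection.genes(pathway_name))
            overlap, p = fisher_enrichment(selected, path, universe)
            records.append(
                EnrichmentRecord(
                    component=f"{prefix}{comp.index}",
                    pathway=pathway_name,
                    n_selected=len(selected),
                    n_pathway_in_universe=len(path & universe),
                    n_overlap=overlap,
                    p_value=p,
                    enriched=p < alpha,
                    phenotype=phenotype,
                )
            )
    if records:
        adj = multipletests([r.p_value for r in records], method="fdr_bh")[1]
        for rec, a in zip(records, adj):
            rec.adjusted_p = float(a)
    return records


def classify_shared_unique(
    eo_records: list[EnrichmentRecord], lo_records: list[EnrichmentRecord]
) -> dict[str, str]:
    """Partition enriched pathways into shared / EO-only / LO-only.

    A pathway is "shared" when enriched in at least one component of each
    phenotype, and phenotype-only when enriched in exactly one. Pathways never
    enriched are absent from the output.
    """
    eo = {r.pathway for r in eo_records if r.enriched}
    lo = {r.pathway for r in lo_records if r.enriched}
    out: dict[str, str] = {}
    for pathway in sorted(eo | lo):
        if pathway in eo and pathway in lo:
            out[pathway] = "shared"
        elif pathway in eo:
            out[pathway] = "EO-only"
        else:
            out[pathway] = "LO-only"
    return out


def species_pathway_links(
    components: list[CCAComponent],
    records: list[EnrichmentRecord],
    label_prefix: str,
) -> pd.DataFrame:
    """Link species to pathways through shared component membership.

    A species with nonzero weight in component k is linked to every pathway
    enriched in component k. Returns a tidy table
    (species, pathway, component, phenotype); per-species pathway counts per
    phenotype follow by a groupby on the result.
    """
    enriched_by_comp: dict[str, list[EnrichmentRecord]] = {}
    for rec in records:
        if rec.enriched:
            enriched_by_comp.setdefault(rec.component, []).append(rec)
    rows = []
    for comp in components:
        label = f"{label_prefix}{comp.index}"
        for rec in enriched_by_comp.get(label, []):
            for species in comp.nonzero_species():
                rows.append(
                    {
                        "species": species,
                        "pathway": rec.pathway,
                        "component": label,
                        "phenotype": rec.phenotype,
                    }
                )
    return pd.DataFrame(rows, columns=["species", "pathway", "component", "phenotype"])
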