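"""End-to-end orchestration: filter -> tune -> fit -> enrich -> GSVA -> correlate.

The two onset phenotypes (early-onset EO, diagnosis before 18; late-onset LO)
are analysed fully independently — separate penalty tuning, separate component
counts — and only compared afterwards: pathway enrichments are classified as
shared or phenotype-specific, and each phenotype's component gene sets are
scored by GSVA in BOTH phenotypes' samples to ask whether a host-microbial
axis found in one group also tracks clinical traits in the other.

Every artifact is written as TSV tagged with the config hash and seed, plus a
machine-readable JSON manifest, so a run is reproducible byte-for-byte from
(config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cca import (
    CCAComponent,
    correlate_scores_clinical,
    fit_sparse_cca,
    penalty_from_fraction,
    permutation_component_test,
    tune_penalties,
)
from .containers import GeneSetCollection, OmicsMatrix
from .enrichment import (
    EnrichmentRecord,
    classify_shared_unique,
    component_gene_set,
    enrich_components,
    species_pathway_links,
)
from .gsva import correlate_es_clinical, gsva_scores
from .preprocess import (
    abundance_filter,
    clr_transform,
    differential_expression,
    select_degs,
    standardize,
    variance_filter,
)

__all__ = ["RunConfig", "GroupBundle", "ComparisonResult", "run_group_analysis", "compare_groups"]

logger = logging.getLogger("duomics")


@dataclass
class RunConfig:
    """Thresholds, model-selection settings and seeding for one analysis run."""

    alpha_deg: float = 0.05
    lfc_threshold: float = 0.5
    variance_quantile: float = 0.25
    min_abundance: float = 0.01
    min_prevalence: float = 0.10
    clr_pseudocount: float = 1e-6
    c1_fractions: list[float] = field(
        default_factory=lambda: [round(0.1 * i, 1) for i in range(1, 11)]
    )
    c2_fractions: list[float] = field(
        default_factory=lambda: [round(0.1 * i, 1) for i in range(1, 11)]
    )
    folds: int = 5
    k_max: int = 5
    n_perm: int = 99
    alpha_components: float = 0.05
    alpha_enrichment: float = 0.05
    top_n_gsva: int = 10
    onset_threshold_years: float = 18.0
    clinical_variables: list[str] = field(
        default_factory=lambda: ["sputum_neutrophil_pct", "sputum_eosinophil_pct"]
    )
    seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        if self.k_max < 1:
            raise ValueError("k_max must be at least 1")
        if self.n_perm < 19:
            raise ValueError("n_perm must be at least 19")
        if not 0 < self.alpha_deg < 1 or not 0 < self.alpha_enrichment < 1:
            raise ValueError("alpha thresholds must lie in (0, 1)")
        if not 0 <= self.variance_quantile < 1:
            raise ValueError("variance_quantile must lie in [0, 1)")
        if not 0 <= self.min_prevalence <= 1:
            raise ValueError("min_prevalence must lie in [0, 1]")
        if self.min_abundance < 0:
            raise ValueError("min_abundance must be non-negative")
        if self.folds < 2:
            raise ValueError("folds must be at least 2")
        if self.top_n_gsva < 1:
            raise ValueError("top_n_gsva must be at least 1")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass
class GroupBundle:
    """All artifacts of one phenotype's analysis."""

    group_label: str
    config: RunConfig
    expression_filtered: OmicsMatrix  # filtered, unstandardized log2 values
    abundance_filtered: OmicsMatrix
    components: list[CCAComponent]
    retained_k: int
    penalties: tuple[float, float]  # selected (c1_fraction, c2_fraction)
    enrichment: list[EnrichmentRecord]
    component_sets: GeneSetCollection  # top-N gene sets per retained component
    es: pd.DataFrame  # sets x samples
    score_clinical: pd.DataFrame
    es_clinical: pd.DataFrame


@dataclass
class ComparisonResult:
    """Cross-phenotype synthesis of two group bundles."""

    pathway_classes: dict[str, str]  # pathway -> shared | EO-only | LO-only
    cross_es: dict[tuple[str, str], pd.DataFrame]  # (set origin, sample group) -> ES
    cross_correlations: pd.DataFrame  # set, origin, sample_group, variable, rho, p
    species_links: pd.DataFrame


def _stage(label: str, t0: float, **shapes) -> None:
    desc = ", ".join(f"{k}={v}" for k, v in shapes.items())
    logger.info("[%s] %s (%.1fs)", label, desc, time.time() - t0)


def run_group_analysis(
    expression: OmicsMatrix,
    abundance: OmicsMatrix,
    clinical: pd.DataFrame,
    genesets: GeneSetCollection,
    config: RunConfig,
    group_label: str,
    control_expression: OmicsMatrix | None = None,
    output_dir: str | Path | None = None,
) -> GroupBundle:
    """Run the full single-phenotype analysis.

    ``expression``/``abundance``/``clinical`` must already be restricted to the
    group's samples (use ``clinical["group"]`` to subset beforehand). When a
    ``control_expression`` matrix (e.g. healthy sputum) is supplied, the
    differential-expression gate is applied before the variance filter;
    otherwise the DEG screen is skipped. If ``output_dir`` is given, all
    tables are materialised as TSV tagged with the config hash and seed.
    """
    config.validate()
    t0 = time.time()
    if expression.sample_ids != abundance.sample_ids:
        raise ValueError("expression and abundance must share samples in order")
    if expression.n_samples < 10:
        raise ValueError(
            f"group {group_label!r} has {expression.n_samples} samples; need >= 10"
        )
    missing = [s for s in expression.sample_ids if s not in clinical.index]
    if missing:
        raise ValueError(f"clinical table missing samples: {missing[:5]}")

    # -- stage 1: feature filtering --------------------------------------
    if control_expression is not None:
        de = differential_expression(expression, control_expression)
        degs = select_degs(de, alpha=config.alpha_deg, lfc_threshold=config.lfc_threshold)
        expression = expression.subset_features(
            [f for f in expression.feature_ids if f in degs]
        )
    single_group = {s: group_label for s in expression.sample_ids}
    expr_f = variance_filter(expression, single_group, q=config.variance_quantile)
    abund_f = abundance_filter(
        abundance,
        single_group,
        min_abund=config.min_abundance,
        min_prev=config.min_prevalence,
    )
    if expr_f.n_features < 2 or abund_f.n_features < 2:
        raise ValueError("filtering left fewer than 2 features in a block")
    _stage(
        f"{group_label}:filter",
        t0,
        genes=f"{expression.n_features}->{expr_f.n_features}",
        species=f"{abundance.n_features}->{abund_f.n_features}",
    )

    # -- stage 2: transforms ----------------------------------------------
    X = standardize(expr_f)
    Y = standardize(clr_transform(abund_f, pseudocount=config.clr_pseudocount))

    # -- stage 3: penalty tuning ------------------------------------------
    grid = tune_penalties(
        X,
        Y,
        c1_fractions=config.c1_fractions,
        c2_fractions=config.c2_fractions,
        folds=config.folds,
        seed=config.seed,
    )
    c1 = penalty_from_fraction(grid.selected[0], X.n_features)
    c2 = penalty_from_fraction(grid.selected[1], Y.n_features)
    _stage(f"{group_label}:tune", t0, selected=grid.selected)

    # -- stage 4: fit + permutation component selection -------------------
    comps_all, retained = permutation_component_test(
        X,
        Y,
        K_max=config.k_max,
        n_perm=config.n_perm,
        c1=c1,
        c2=c2,
        seed=config.seed,
        alpha=config.alpha_components,
    )
    components = comps_all[:retained]
    _stage(f"{group_label}:fit", t0, retained_k=retained)

    # -- stage 5: enrichment ----------------------------------------------
    universe = set(X.feature_ids)
    records = enrich_components(
        components,
        genesets,
        universe,
        phenotype=group_label,
        alpha=config.alpha_enrichment,
    )

    # -- stage 6: GSVA on top-N component genes ---------------------------
    comp_sets = GeneSetCollection(source=f"{group_label}-components")
    for comp in components:
        genes = component_gene_set(comp, rule="top_n", n=config.top_n_gsva)
        comp_sets.add(
            f"{group_label}C{comp.index}_top{config.top_n_gsva}",
            sorted(genes),
            description=f"top-{config.top_n_gsva} genes of {group_label}C{comp.index}",
        )
    variables = [v for v in config.clinical_variables if v in clinical.columns]
    if comp_sets.sets:
        es = gsva_scores(expr_f, comp_sets)
        es_clin = correlate_es_clinical(es, clinical, variables)
    else:
        es = pd.DataFrame()
        es_clin = pd.DataFrame(columns=["signal", "variable", "spearman_rho", "p_value"])
    score_clin = correlate_scores_clinical(components, clinical, variables)
    _stage(f"{group_label}:downstream", t0, enriched=sum(r.enriched for r in records))

    bundle = GroupBundle(
        group_label=group_label,
        config=config,
        expression_filtered=expr_f,
        abundance_filtered=abund_f,
        components=components,
        retained_k=retained,
        penalties=grid.selected,
        enrichment=records,
        component_sets=comp_sets,
        es=es,
        score_clinical=score_clin,
        es_clinical=es_clin,
    )
    if output_dir is not None:
        write_bundle(bundle, output_dir)
    return bundle


def compare_groups(
    bundle_eo: GroupBundle,
    bundle_lo: GroupBundle,
    clinical: pd.DataFrame,
) -> ComparisonResult:
    """Cross-phenotype synthesis of two independently fitted bundles.

    Classifies enriched pathways as shared/EO-only/LO-only, scores each
    phenotype's component gene sets by GSVA in both phenotypes' samples and
    correlates those scores with the clinical variables within each sample
    group, and links species to enriched pathways through components.
    """
    uni_eo = set(bundle_eo.expression_filtered.feature_ids)
    uni_lo = set(bundle_lo.expression_filtered.feature_ids)
    if not (uni_eo & uni_lo):
        raise ValueError("bundles share no gene features; universe mismatch")

    classes = classify_shared_unique(bundle_eo.enrichment, bundle_lo.enrichment)

    cross_es: dict[tuple[str, str], pd.DataFrame] = {}
    rows = []
    for origin_bundle in (bundle_eo, bundle_lo):
        for target_bundle in (bundle_eo, bundle_lo):
            if not origin_bundle.component_sets.sets:
                continue
            usable = {
                name: (desc, genes)
                for name, (desc, genes) in origin_bundle.component_sets.sets.items()
                if len(set(genes) & set(target_bundle.expression_filtered.feature_ids)) >= 2
            }
            if not usable:
                continue
            sets = GeneSetCollection(sets=usable, source=origin_bundle.component_sets.source)
            es = gsva_scores(target_bundle.expression_filtered, sets)
            key = (origin_bundle.group_label, target_bundle.group_label)
            cross_es[key] = es
            variables = [
                v
                for v in target_bundle.config.clinical_variables
                if v in clinical.columns
            ]
            tab = correlate_es_clinical(es, clinical, variables)
            tab.insert(1, "set_origin", origin_bundle.group_label)
            tab.insert(2, "sample_group", target_bundle.group_label)
            rows.append(tab)
    cross_corr = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(
            columns=["signal", "set_origin", "sample_group", "variable", "spearman_rho", "p_value"]
        )
    )

    links = pd.concat(
        [
            species_pathway_links(
                bundle_eo.components, bundle_eo.enrichment, f"{bundle_eo.group_label}C"
            ),
            species_pathway_links(
                bundle_lo.components, bundle_lo.enrichment, f"{bundle_lo.group_label}C"
            ),
        ],
        ignore_index=True,
    )
    return ComparisonResult(
        pathway_classes=classes,
        cross_es=cross_es,
        cross_correlations=cross_corr,
        species_links=links,
    )


# ---------------------------------------------------------------------------
# artifact serialisation
# ---------------------------------------------------------------------------

def _tag(config: RunConfig) -> str:
    return f"duomics config={config.config_hash()} seed={config.seed}"


def _write_df(df: pd.DataFrame, path: Path, config: RunConfig, index: bool = False, index_label=None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_tag(config)}\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label)


def write_bundle(bundle: GroupBundle, output_dir: str | Path) -> None:
    """Materialise a group bundle: weights, scores, summary, enrichment, ES."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = bundle.config
    label = bundle.group_label
    comps = bundle.components
    if comps:
        weights_u = pd.DataFrame(
            {f"component_{c.index}": c.u for c in comps},
            index=comps[0].gene_ids,
        )
        weights_v = pd.DataFrame(
            {f"component_{c.index}": c.v for c in comps},
            index=comps[0].species_ids,
        )
        scores = pd.DataFrame(
            {
                **{f"x_score_{c.index}": c.x_scores for c in comps},
                **{f"y_score_{c.index}": c.y_scores for c in comps},
            },
            index=comps[0].sample_ids,
        )
        summary = pd.DataFrame(
            {
                "component": [c.index for c in comps],
                "d": [c.d for c in comps],
                "score_correlation": [c.score_correlation for c in comps],
                "permutation_p": [c.permutation_p for c in comps],
                "c1": [c.c1 for c in comps],
                "c2": [c.c2 for c in comps],
                "converged": [c.converged for c in comps],
            }
        )
        _write_df(weights_u, out / f"{label}_gene_weights.tsv", cfg, index=True, index_label="feature_id")
        _write_df(weights_v, out / f"{label}_species_weights.tsv", cfg, index=True, index_label="feature_id")
        _write_df(scores, out / f"{label}_scores.tsv", cfg, index=True, index_label="sample_id")
        _write_df(summary, out / f"{label}_summary.tsv", cfg)
    enr = pd.DataFrame([asdict(r) for r in bundle.enrichment])
    _write_df(enr, out / f"{label}_enrichment.tsv", cfg)
    if not bundle.es.empty:
        _write_df(bundle.es, out / f"{label}_es.tsv", cfg, index=True, index_label="gene_set")
    _write_df(bundle.score_clinical, out / f"{label}_score_clinical.tsv", cfg)
    _write_df(bundle.es_clinical, out / f"{label}_es_clinical.tsv", cfg)
    if bundle.component_sets.sets:
        bundle.component_sets.to_gmt(out / f"{label}_component_sets.gmt")
    manifest = {
        "group": label,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "retained_k": bundle.retained_k,
        "penalties": list(bundle.penalties),
        "n_genes_filtered": bundle.expression_filtered.n_features,
        "n_species_filtered": bundle.abundance_filtered.n_features,
        "config": asdict(cfg),
    }
    (out / f"{label}_manifest.json").write_text(json.dumps(manifest, indent=1, default=str))


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
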