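"""Synthetic paired-omics generator with planted sparse canonical structure.

This module emulates the data a paired sputum transcriptome / sputum
metagenome integration study works with, at desk scale:

* an expression matrix on the log2 microarray scale (gene-specific baseline
  means, Gaussian noise),
* a compositional relative-abundance matrix (latent Gaussian log-abundances
  pushed through a per-sample softmax, so rows live on the unit simplex),
* K planted canonical components: shared latent sample scores ``z_k`` that
  load onto disjoint sparse gene and species supports in the two blocks,
* clinical covariates (sputum granulocyte percentages) tied to chosen latent
  scores by a rank-preserving monotone transform,
* gene-set collections (GMT) in which some sets overlap planted gene
  supports (true positives for enrichment) and the rest are decoys.

All ground truth is recorded in :class:`SyntheticTruth`, so downstream
recovery — support selection, score correlation, enrichment, per-sample
enrichment-score/clinical coupling — is scoreable exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import softmax
from scipy.stats import norm

from .containers import GeneSetCollection, OmicsMatrix

__all__ = [
    "SyntheticTruth",
    "generate_paired_omics",
    "generate_clinical",
    "generate_genesets",
    "default_group_labels",
]


@dataclass
class SyntheticTruth:
    """Ground truth of a planted paired-omics simulation."""

    k_latent: int
    gene_supports: list[list[int]]
    species_supports: list[list[int]]
    gene_weights: list[list[float]]
    species_weights: list[list[float]]
    latent_scores: np.ndarray  # n_samples x k_latent, columns uncorrelated
    signal_sd: float
    noise_sd: float
    gene_ids: list[str]
    species_ids: list[str]
    sample_ids: list[str]
    seed: int
    clinical_link: dict[str, tuple[int, float]] = field(default_factory=dict)

    def gene_support_ids(self, k: int) -> set[str]:
        return {self.gene_ids[i] for i in self.gene_supports[k]}

    def species_support_ids(self, k: int) -> set[str]:
        return {self.species_ids[i] for i in self.species_supports[k]}

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["latent_scores"] = self.latent_scores.tolist()
        payload["clinical_link"] = {k: list(v) for k, v in self.clinical_link.items()}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        payload["latent_scores"] = np.asarray(payload["latent_scores"], dtype=float)
        payload["clinical_link"] = {
            k: (int(v[0]), float(v[1])) for k, v in payload["clinical_link"].items()
        }
        return cls(**payload)


def _orthogonal_latents(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """Sample n x k latent scores; columns centered, exactly orthogonal, unit sd.

    Column-centering first keeps every QR column orthogonal to the constant
    vector, so pairwise Pearson correlations vanish to machine precision.
    """
    z = rng.standard_normal((n, k))
    z -= z.mean(axis=0, keepdims=True)
    q, r = np.linalg.qr(z)
    q = q[:, :k] * np.sign(np.diag(r))  # fix QR sign ambiguity -> deterministic
    return q * np.sqrt(n - 1)  # unit sample-sd columns


def _disjoint_supports(
    rng: np.random.Generator, n_features: int, k: int, size: int
) -> list[list[int]]:
    idx = rng.choice(n_features, size=k * size, replace=False)
    return [sorted(idx[j * size : (j + 1) * size].tolist()) for j in range(k)]


def generate_paired_omics(
    n_samples: int = 99,
    p_genes: int = 500,
    q_species: int = 60,
    k_latent: int = 2,
    gene_support_size: int = 20,
    species_support_size: int = 10,
    signal_sd: float = 3.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    sample_prefix: str = "S",
) -> tuple[OmicsMatrix, OmicsMatrix, SyntheticTruth]:
    """Generate paired expression/abundance matrices sharing planted components.

    Expression: ``x_gj = mu_g + signal_sd * sum_k z_jk w_kg + noise`` where the
    per-gene loading ``w_kg`` is +1 on the (disjoint) support of component k
    and zero elsewhere — each component drives a coherently up-regulated gene
    module (mixed-sign loadings would cancel in rank-based set scores
    downstream), and signal_sd/noise_sd is the per-feature signal-to-noise
    ratio. Abundance: the same construction with random-sign loadings on a latent
    log-abundance scale, then a per-sample softmax onto the unit simplex.
    Planted species draw their baseline log-abundance from N(1.0, 0.5) (vs
    N(0, 1.5) for decoys) so the planted taxa are detectable, moderately
    abundant species rather than vanishing rare ones.

    Returns ``(expression, abundance, truth)``. Identical seeds give
    byte-identical output.
    """
    if min(n_samples, p_genes, q_species, k_latent) <= 0:
        raise ValueError("all dimensions must be positive")
    if n_samples < 10:
        raise ValueError("need at least 10 samples")
    if signal_sd < 0 or noise_sd <= 0:
        raise ValueError("require signal_sd >= 0 and noise_sd > 0")
    if k_latent * gene_support_size > p_genes:
        raise ValueError("disjoint gene supports do not fit in p_genes")
    if k_latent * species_support_size > q_species:
        raise ValueError("disjoint species supports do not fit in q_species")

    rng = np.random.default_rng(seed)
    sample_ids = [f"{sample_prefix}{i:03d}" for i in range(n_samples)]
    gene_ids = [f"GENE{i:04d}" for i in range(p_genes)]
    species_ids = [f"sp{i:03d}" for i in range(q_species)]

    z = _orthogonal_latents(rng, n_samples, k_latent)
    gene_supports = _disjoint_supports(rng, p_genes, k_latent, gene_support_size)
    species_supports = _disjoint_supports(rng, q_species, k_latent, species_support_size)

    # expression: log2-microarray-like baseline around 7
    mu = rng.normal(7.0, 1.0, size=p_genes)
    expr = mu + noise_sd * rng.standard_normal((n_samples, p_genes))
    gene_weights: list[list[float]] = []
    for k in range(k_latent):
        w = np.ones(gene_support_size)
        gene_weights.append(w.tolist())
        expr[:, gene_supports[k]] += signal_sd * np.outer(z[:, k], w)

    # abundance: latent log scale, planted taxa moderately abundant
    alpha = rng.normal(0.0, 1.5, size=q_species)
    planted = sorted({i for sup in species_supports for i in sup})
    alpha[planted] = rng.normal(1.0, 0.5, size=len(planted))
    lat = alpha + noise_sd * rng.standard_normal((n_samples, q_species))
    species_weights: list[list[float]] = []
    for k in range(k_latent):
        w = rng.choice([-1.0, 1.0], size=species_support_size)
        species_weights.append(w.tolist())
        lat[:, species_supports[k]] += signal_sd * np.outer(z[:, k], w)
    abund = softmax(lat, axis=1)

    expression = OmicsMatrix(
        pd.DataFrame(expr, index=sample_ids, columns=gene_ids), kind="expression"
    )
    abundance = OmicsMatrix(
        pd.DataFrame(abund, index=sample_ids, columns=species_ids), kind="abundance"
    )
    truth = SyntheticTruth(
        k_latent=k_latent,
        gene_supports=gene_supports,
        species_supports=species_supports,
        gene_weights=gene_weights,
        species_weights=species_weights,
        latent_scores=z,
        signal_sd=signal_sd,
        noise_sd=noise_sd,
        gene_ids=gene_ids,
        species_ids=species_ids,
        sample_ids=sample_ids,
        seed=seed,
    )
    return expression, abundance, truth


def default_group_labels(sample_ids: list[str]) -> pd.Series:
    """Default phenotype split: first half early-onset (EO), rest late-onset (LO)."""
    n = len(sample_ids)
    n_eo = -(-n // 2)  # ceil
    return pd.Series(
        ["EO"] * n_eo + ["LO"] * (n - n_eo), index=sample_ids, name="group"
    )


def generate_clinical(
    truth: SyntheticTruth,
    links: dict[str, tuple[int, float]],
    noise_sd: float = 1.0,
    seed: int = 0,
    groups: pd.Series | None = None,
    extra_noise_vars: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Generate clinical covariates tied to planted latent scores.

    Each linked variable is ``coefficient * z_k + Gaussian noise``, then mapped
    onto the 0-100 percentage range through the Gaussian CDF of its own
    z-score — a strictly monotone (rank-preserving) transform, so Spearman
    correlations with ``z_k`` survive unchanged. ``extra_noise_vars`` are pure
    noise covariates (no latent link). A ``group`` label column (EO/LO) is
    appended; by default the first half of the samples are EO.
    """
    rng = np.random.default_rng(seed)
    n = truth.latent_scores.shape[0]
    out: dict[str, np.ndarray] = {}
    for name, (k, coef) in links.items():
        if not 0 <= k < truth.k_latent:
            raise ValueError(f"clinical link {name!r} references unknown component {k}")
        raw = coef * truth.latent_scores[:, k] + noise_sd * rng.standard_normal(n)
        out[name] = _to_percent(raw)
    for name in extra_noise_vars:
        out[name] = _to_percent(rng.standard_normal(n))
    df = pd.DataFrame(out, index=truth.sample_ids)
    if groups is None:
        groups = default_group_labels(truth.sample_ids)
    df["group"] = groups.reindex(df.index)
    truth.clinical_link.update(links)
    return df


def _to_percent(raw: np.ndarray) -> np.ndarray:
    """Monotone squash of a real vector onto (0, 100)."""
    sd = raw.std(ddof=1)
    if sd == 0:
        return np.full_like(raw, 50.0)
    return 100.0 * norm.cdf((raw - raw.mean()) / sd)


def generate_genesets(
    truth: SyntheticTruth,
    n_sets: int = 50,
    set_size: int = 15,
    overlap_fraction: float = 0.8,
    decoy_universe: int | None = None,
    seed: int = 0,
) -> GeneSetCollection:
    """Generate a GMT-writable collection mixing planted and decoy sets.

    The first ``min(k_latent, n_sets)`` sets each seed
    ``round(overlap_fraction * set_size)`` genes from one planted gene support
    (these should test enriched once selection recovers the support), topped up
    with decoy genes; the remaining sets are uniform draws from the decoy
    universe (the first ``decoy_universe`` genes, default: all genes).
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    universe_n = len(truth.gene_ids) if decoy_universe is None else decoy_universe
    if universe_n > len(truth.gene_ids):
        raise ValueError("decoy_universe exceeds number of genes")
    if set_size > universe_n:
        raise ValueError("set_size exceeds the decoy universe")
    rng = np.random.default_rng(seed)
    universe = np.array(truth.gene_ids[:universe_n])
    coll = GeneSetCollection(source="synthetic")
    n_planted = min(truth.k_latent, n_sets)
    for k in range(n_planted):
        support = [truth.gene_ids[i] for i in truth.gene_supports[k]]
        n_true = min(int(round(overlap_fraction * set_size)), set_size, len(support))
        chosen = list(rng.choice(support, size=n_true, replace=False))
        pool = np.setdiff1d(universe, np.array(support), assume_unique=False)
        fill = list(rng.choice(pool, size=set_size - n_true, replace=False))
        coll.add(
            f"PLANTED_K{k + 1}",
            sorted(chosen + fill),
            description=f"synthetic: overlaps planted component {k + 1}",
        )
    for j in range(n_sets - n_planted):
        genes = sorted(rng.choice(universe, size=set_size, replace=False))
        coll.add(f"DECOY_{j + 1:03d}", genes, description="synthetic: decoy")
    return coll
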