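"""Sample-wise gene-set enrichment scores (GSVA-style, from scratch).

The score for a gene set in one sample summarises whether the set's genes sit
coherently toward the top (or bottom) of that sample's expression profile,
relative to the gene's distribution across all samples. Three steps:

1. Kernel-ECDF statistic: for gene i in sample j,
   ``z_ij = mean_k Phi((x_ij - x_ik) / h_i)`` with Gaussian CDF Phi and
   bandwidth ``h_i = sd_i / 4`` — a smoothed within-gene ECDF, invariant to
   per-gene affine rescaling.
2. Per-sample ranking of genes by decreasing ``z`` and symmetrisation
   ``r = |N/2 - rank|`` (top gene has rank N), so both extremes of the
   profile carry large weight.
3. A weighted Kolmogorov-like random walk down the ranked list: inside-set
   steps accumulate ``r^tau`` (normalised by the set total), outside-set
   steps subtract ``1/(N - |set|)``. The enrichment score is the maximum
   positive deviation plus the minimum negative deviation of the walk
   ("max-deviation-difference" form), bounded in [-1, 1]; the alternative
   largest-|deviation| form is available via ``mx_diff=False``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cca import spearman_table
from .containers import GeneSetCollection, OmicsMatrix

__all__ = [
    "kernel_ecdf_statistic",
    "es_random_walk",
    "gsva_scores",
    "correlate_es_clinical",
]


def kernel_ecdf_statistic(X: OmicsMatrix) -> pd.DataFrame:
    """Gaussian-kernel ECDF statistic per gene and sample.

    Returns a samples x genes DataFrame. Requires >= 3 samples and strictly
    positive per-gene variance (the bandwidth is sd/4).
    """
    if X.n_samples < 3:
        raise ValueError("need at least 3 samples")
    vals = X.values.to_numpy()  # samples x genes
    sd = vals.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [f for f, s in zip(X.feature_ids, sd) if s == 0][:5]
        raise ValueError(f"zero-variance genes: {bad}")
    h = sd / 4.0
    # z[j, i] = mean_k Phi((x_ji - x_ki) / h_i); loop genes in blocks to keep
    # the n x n x block tensor small for large gene counts
    n, p = vals.shape
    out = np.empty((n, p))
    block = max(1, int(4_000_000 / (n * n)))
    for start in range(0, p, block):
        sl = slice(start, min(start + block, p))
        diff = (vals[:, None, sl] - vals[None, :, sl]) / h[sl]
        out[:, sl] = norm.cdf(diff).mean(axis=1)
    return pd.DataFrame(out, index=X.sample_ids, columns=X.feature_ids)


def _symmetric_ranks(zcol: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Order (decreasing z) and symmetric rank statistic |N/2 - rank|."""
    N = len(zcol)
    order = np.argsort(-zcol, kind="stable")
    ranks = np.empty(N)
    ranks[order] = np.arange(N, 0, -1)  # top gene gets rank N
    return order, np.abs(N / 2.0 - ranks)


def es_random_walk(
    z_statistics: np.ndarray,
    in_set: np.ndarray,
    tau: float = 1.0,
    mx_diff: bool = True,
) -> float:
    """Enrichment score of one sample from its gene statistics.

    ``z_statistics`` is the kernel-ECDF row for one sample, ``in_set`` a
    boolean mask of set membership over the same genes.
    """
    in_set = np.asarray(in_set, dtype=bool)
    if not in_set.any():
        raise ValueError("gene set does not intersect the ranked genes")
    if in_set.all():
        raise ValueError("gene set covers every ranked gene")
    order, r = _symmetric_ranks(np.asarray(z_statistics, dtype=float))
    r_ord = r[order] ** tau
    inset_ord = in_set[order]
    denom = r_ord[inset_ord].sum()
    n_out = (~in_set).sum()
    steps = np.where(inset_ord, r_ord / denom, -1.0 / n_out)
    walk = np.cumsum(steps)
    if mx_diff:
        return float(max(walk.max(), 0.0) + min(walk.min(), 0.0))
    return float(walk[np.argmax(np.abs(walk))])


def gsva_scores(
    X: OmicsMatrix,
    sets: GeneSetCollection,
    tau: float = 1.0,
    mx_diff: bool = True,
    min_intersection: int = 2,
) -> pd.DataFrame:
    """Enrichment-score matrix: gene sets (rows) x samples (columns).

    Sets intersecting fewer than ``min_intersection`` measured genes are
    skipped with a warning; if no usable set remains, raises.
    """
    z = kernel_ecdf_statistic(X).to_numpy()
    genes = np.array(X.feature_ids)
    rows: dict[str, np.ndarray] = {}
    for name in sets.names():
        in_set = np.isin(genes, list(sets.genes(name)))
        k = int(in_set.sum())
        if k < min_intersection or k >= len(genes):
            warnings.warn(
                f"gene set {name!r} intersects {k} measured genes; skipped"
            )
            continue
        rows[name] = np.array(
            [es_random_walk(z[j], in_set, tau=tau, mx_diff=mx_diff) for j in range(z.shape[0])]
        )
    if not rows:
        raise ValueError("no gene set intersects enough measured genes")
    return pd.DataFrame(rows, index=X.sample_ids).T


def correlate_es_clinical(
    es: pd.DataFrame, clinical: pd.DataFrame, variables: list[str]
) -> pd.DataFrame:
    """Spearman correlation of each set's enrichment scores with clinical traits.

    ``es`` is the sets x samples matrix from :func:`gsva_scores`; the contract
    (average ranks, pairwise NaN drop, t-approximation p, >= 4 pairs) is shared
    with the component-score correlation.
    """
    missing = [s for s in es.columns if s not in clinical.index]
    if missing:
        raise ValueError(f"clinical table does not cover samples: {missing[:5]}")
    return spearman_table(es.T, clinical, variables)
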