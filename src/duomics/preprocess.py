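"""Feature-space filtering ahead of sparse canonical correlation analysis.

Three gates define the features entering the integration:

1. a differential-expression screen (Welch's t on log2 values, Benjamini-
   Hochberg adjustment; keep adjusted p < 0.05 and |log2 FC| > 0.5),
2. a within-group variance filter (drop genes below the 25% quantile of
   per-group variances in every group),
3. an abundance/prevalence filter for species (relative abundance >= 0.01 in
   >= 10% of samples of at least one group).

Plus the numeric transforms the decomposition needs: per-feature
standardization for expression and a centered log-ratio transform for the
compositional species block.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import OmicsMatrix, as_mapping

__all__ = [
    "benjamini_hochberg",
    "differential_expression",
    "select_degs",
    "variance_filter",
    "abundance_filter",
    "standardize",
    "clr_transform",
]


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone in p-value rank)."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


def differential_expression(case: OmicsMatrix, control: OmicsMatrix) -> pd.DataFrame:
    """Per-gene Welch two-sample t-test on log2 values with BH adjustment.

    Returns a DataFrame with columns ``feature_id``, ``log2_fold_change``
    (case mean minus control mean), ``p_value`` and ``adjusted_p`` (Benjamini-
    Hochberg across all genes). Genes that are degenerate for the test (zero
    variance in both arms and equal means) receive p = 1.
    """
    if list(case.feature_ids) != list(control.feature_ids):
        raise ValueError("case and control must share the same feature set and order")
    if case.n_samples < 2 or control.n_samples < 2:
        raise ValueError("need at least 2 samples per arm")
    a = case.values.to_numpy()
    b = control.values.to_numpy()
    lfc = a.mean(axis=0) - b.mean(axis=0)
    res = stats.ttest_ind(a, b, axis=0, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    p = np.where(np.isfinite(p), p, 1.0)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    adj = benjamini_hochberg(p)
    return pd.DataFrame(
        {
            "feature_id": case.feature_ids,
            "log2_fold_change": lfc,
            "p_value": p,
            "adjusted_p": adj,
        }
    )


def select_degs(
    results: pd.DataFrame, alpha: float = 0.05, lfc_threshold: float = 0.5
) -> set[str]:
    """Features passing adjusted p < ``alpha`` and |log2 FC| > ``lfc_threshold``.

    The fold-change gate is two-sided: down-regulated genes (log2 FC < -0.5)
    are kept alongside up-regulated ones.
    """
    if results.empty:
        return set()
    keep = (results["adjusted_p"] < alpha) & (
        results["log2_fold_change"].abs() > lfc_threshold
    )
    return set(results.loc[keep, "feature_id"])


def variance_filter(X: OmicsMatrix, groups, q: float = 0.25) -> OmicsMatrix:
    """Drop features in the low-variance tail of every group.

    A feature is retained iff its within-group variance strictly exceeds the
    ``q``-quantile (linear interpolation between order statistics) of that
    group's feature variances, in at least one group.
    """
    if not 0.0 <= q < 1.0:
        raise ValueError("q must lie in [0, 1)")
    mapping = as_mapping(groups, X.sample_ids)
    keep = np.zeros(X.n_features, dtype=bool)
    for label in sorted(set(mapping.values())):
        members = [s for s in X.sample_ids if mapping[s] == label]
        if len(members) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 samples")
        var = X.values.loc[members].var(ddof=1).to_numpy()
        threshold = np.quantile(var, q)
        keep |= var > threshold
    return X.subset_features([f for f, k in zip(X.feature_ids, keep) if k])


def abundance_filter(
    Y: OmicsMatrix, groups, min_abund: float = 0.01, min_prev: float = 0.10
) -> OmicsMatrix:
    """Retain species detected at ``min_abund`` relative abundance in at least
    a ``min_prev`` fraction of samples of at least one group.

    Both comparisons use >= at the boundary (a species at exactly 0.01 in
    exactly 10% of a group's samples is retained). The surviving matrix is a
    subcomposition: rows are not renormalised.
    """
    if Y.kind != "abundance":
        raise ValueError("abundance_filter expects an abundance matrix")
    mapping = as_mapping(groups, Y.sample_ids)
    keep = np.zeros(Y.n_features, dtype=bool)
    for label in sorted(set(mapping.values())):
        members = [s for s in Y.sample_ids if mapping[s] == label]
        if not members:
            raise ValueError(f"group {label!r} is empty")
        prev = (Y.values.loc[members].to_numpy() >= min_abund).mean(axis=0)
        keep |= prev >= min_prev
    return Y.subset_features([f for f, k in zip(Y.feature_ids, keep) if k])


def standardize(X: OmicsMatrix) -> OmicsMatrix:
    """Center each feature to mean 0 and scale to unit sample variance (ddof=1)."""
    vals = X.values
    sd = vals.std(ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])[:5]
        raise ValueError(f"zero-variance features cannot be standardized: {bad}")
    out = (vals - vals.mean()) / sd
    return OmicsMatrix(out, kind="clr" if X.kind in ("abundance", "clr") else X.kind)


def clr_transform(Y: OmicsMatrix, pseudocount: float = 1e-6) -> OmicsMatrix:
    """Centered log-ratio transform of a (sub)compositional abundance matrix.

    ``clr(y)_i = log(y_i + pc) - mean_j log(y_j + pc)`` per sample. The
    pseudocount guards structural zeros created by the softmax tails and by
    filtering.
    """
    if Y.kind != "abundance":
        raise ValueError("clr_transform expects an abundance matrix")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    logs = np.log(Y.values.to_numpy() + pseudocount)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return OmicsMatrix(
        pd.DataFrame(clr, index=Y.values.index, columns=Y.values.columns), kind="clr"
    )
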