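import numpy as np
import pandas as pd
import pytest

from duomics import OmicsMatrix, generate_paired_omics, standardize


def make_gaussian_pair(n, p, q, k, sup_p, sup_q, snr, seed):
    """Paired Gaussian blocks sharing k orthogonal latents on disjoint supports.

    Unlike the package generator, the second block is NOT compositional —
    useful for checking the decomposition machinery without softmax closure.
    Supports are contiguous: component j owns genes [j*sup_p, (j+1)*sup_p) and
    features [j*sup_q, (j+1)*sup_q).
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, k))
    z -= z.mean(axis=0)
    z, _ = np.linalg.qr(z)
    z *= np.sqrt(n - 1)
    X = rng.standard_normal((n, p))
    Y = rng.standard_normal((n, q))
    for j in range(k):
        X[:, j * sup_p : (j + 1) * sup_p] += snr * np.outer(
            z[:, j], rng.choice([-1.0, 1.0], sup_p)
        )
        Y[:, j * sup_q : (j + 1) * sup_q] += snr * np.outer(
            z[:, j], rng.choice([-1.0, 1.0], sup_q)
        )
    samples = [f"S{i:03d}" for i in range(n)]
    Xm = OmicsMatrix(pd.DataFrame(X, index=samples, columns=[f"g{i}" for i in range(p)]))
    Ym = OmicsMatrix(pd.DataFrame(Y, index=samples, columns=[f"m{i}" for i in range(q)]))
    return standardize(Xm), standardize(Ym), z


@pytest.fixture(scope="session")
def small_paired():
    """Small planted dataset shared by read-only tests."""
    return generate_paired_omics(
        n_samples=60,
        p_genes=120,
        q_species=30,
        k_latent=2,
        gene_support_size=10,
        species_support_size=6,
        seed=11,
    )
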