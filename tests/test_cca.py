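"""Decomposition machinery: shrinkage operators, SVD equivalence, deflation,
tuning, permutation selection and clinical correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp
from scipy.stats import spearmanr

from duomics import (
    clr_transform,
    correlate_scores_clinical,
    fit_component,
    fit_sparse_cca,
    generate_paired_omics,
    l1_constrained_unit,
    penalty_from_fraction,
    permutation_component_test,
    soft_threshold,
    standardize,
    tune_penalties,
)
from duomics.cca import spearman_table

from conftest import make_gaussian_pair


class TestSoftThreshold:
    def test_worked_example(self):
        np.testing.assert_allclose(
            soft_threshold(np.array([3.0, -1.0, 0.5]), 1.0), [2.0, 0.0, 0.0]
        )

    def test_zero_delta_is_identity(self):
        a = np.array([1.5, -2.0, 0.0])
        np.testing.assert_array_equal(soft_threshold(a, 0.0), a)

    def test_large_delta_annihilates(self):
        a = np.array([1.5, -2.0, 0.3])
        assert not soft_threshold(a, 2.0).any()

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.ones(3), -0.1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        hnp.arrays(np.float64, 10, elements=st.floats(-5, 5)),
        st.floats(0, 4),
    )
    def test_shrinks_magnitudes_and_keeps_signs(self, a, delta):
        s = soft_threshold(a, delta)
        np.testing.assert_allclose(np.abs(s), np.maximum(np.abs(a) - delta, 0))
        assert ((np.sign(s) == np.sign(a)) | (s == 0)).all()


class TestL1ConstrainedUnit:
    def test_symmetric_case(self):
        u = l1_constrained_unit(np.array([1.0, 1.0]), np.sqrt(2))
        np.testing.assert_allclose(u, [1 / np.sqrt(2)] * 2)
        assert np.abs(u).sum() == pytest.approx(np.sqrt(2))

    def test_budget_one_forces_single_nonzero(self):
        np.testing.assert_allclose(
            l1_constrained_unit(np.array([2.0, 1.0]), 1.0), [1.0, 0.0], atol=1e-7
        )

    def test_inactive_budget_returns_normalised_input(self):
        a = np.array([3.0, -1.0, 2.0, 0.5])
        np.testing.assert_allclose(
            l1_constrained_unit(a, np.sqrt(4)), a / np.linalg.norm(a)
        )

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            l1_constrained_unit(np.zeros(4), 1.5)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        hnp.arrays(
            np.float64,
            12,
            elements=st.floats(-4, 4, exclude_min=False),
        ).filter(lambda a: np.linalg.norm(a) > 1e-3),
        st.floats(1.0, np.sqrt(12)),
    )
    def test_feasible_and_beats_delta_grid_oracle(self, a, c):
        u = l1_constrained_unit(a, c)
        assert np.linalg.norm(u) <= 1 + 1e-8
        assert np.abs(u).sum() <= c + 1e-6
        # oracle: best feasible point over a fine soft-threshold path
        best = -np.inf
        for delta in np.linspace(0, np.abs(a).max() * 0.999, 400):
            s = soft_threshold(a, delta)
            norm = np.linalg.norm(s)
            if norm == 0:
                continue
            s = s / norm
            if np.abs(s).sum() <= c + 1e-6:
                best = max(best, float(a @ s))
        assert a @ u >= best - 1e-4


class TestFitComponent:
    def test_exact_rank_one_recovery(self):
        rng = np.random.default_rng(0)
        u0 = rng.normal(size=15)
        u0 /= np.linalg.norm(u0)
        v0 = rng.normal(size=10)
        v0 /= np.linalg.norm(v0)
        Z = 4.2 * np.outer(u0, v0)
        u, v, d, ok = fit_component(Z, np.sqrt(15), np.sqrt(10))
        assert ok
        assert d == pytest.approx(4.2, abs=1e-6)
        assert min(np.abs(u - u0).max(), np.abs(u + u0).max()) < 1e-6
        assert min(np.abs(v - v0).max(), np.abs(v + v0).max()) < 1e-6

    def test_inactive_penalties_match_leading_svd_triple(self):
        rng = np.random.default_rng(1)
        Z = rng.normal(size=(30, 20))
        u, v, d, ok = fit_component(Z, np.sqrt(30), np.sqrt(20), tol=1e-10, max_iter=2000)
        U, s, Vt = np.linalg.svd(Z)
        assert d == pytest.approx(s[0], abs=1e-6)
        assert min(np.abs(u - U[:, 0]).max(), np.abs(u + U[:, 0]).max()) < 1e-6

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            fit_component(np.zeros((5, 4)), 2.0, 2.0)


class TestFitSparseCCA:
    def test_k1_equals_fit_component(self):
        X, Y, _ = make_gaussian_pair(40, 25, 15, 1, 5, 3, 2.0, 2)
        Z = X.values.to_numpy().T @ Y.values.to_numpy()
        c1, c2 = penalty_from_fraction(0.5, 25), penalty_from_fraction(0.5, 15)
        u, v, d, _ = fit_component(Z, c1, c2)
        comp = fit_sparse_cca(X, Y, K=1, c1=c1, c2=c2)[0]
        assert comp.d == pytest.approx(d)
        assert np.abs(np.abs(comp.u) - np.abs(u)).max() < 1e-12

    def test_inactive_penalties_reproduce_svd_sequence(self):
        X, Y, _ = make_gaussian_pair(50, 40, 30, 2, 8, 5, 2.0, 3)
        comps = fit_sparse_cca(
            X,
            Y,
            K=4,
            c1=np.sqrt(40),
            c2=np.sqrt(30),
            tol=1e-10,
            max_iter=5000,
        )
        Z = X.values.to_numpy().T @ Y.values.to_numpy()
        s = np.linalg.svd(Z, compute_uv=False)
        d = np.array([c.d for c in comps])
        assert (np.diff(d) <= 1e-8).all()
        np.testing.assert_allclose(d, s[:4], atol=1e-6)

    def test_deflation_reconstruction_identity(self):
        X, Y, _ = make_gaussian_pair(45, 30, 20, 2, 6, 4, 2.0, 4)
        Z1 = X.values.to_numpy().T @ Y.values.to_numpy()
        comps = fit_sparse_cca(
            X, Y, K=3, c1=penalty_from_fraction(0.4, 30), c2=penalty_from_fraction(0.5, 20)
        )
        recon = sum(c.d * np.outer(c.u, c.deflation_sign * c.v) for c in comps)
        residual = Z1 - recon
        # refit one more component on the residual: the identity holds exactly
        u, v, d, _ = fit_component(
            residual, penalty_from_fraction(0.4, 30), penalty_from_fraction(0.5, 20)
        )
        comps4 = fit_sparse_cca(
            X, Y, K=4, c1=penalty_from_fraction(0.4, 30), c2=penalty_from_fraction(0.5, 20)
        )
        assert comps4[3].d == pytest.approx(d, abs=1e-10)

    def test_component_constraints_and_sign_convention(self):
        X, Y, _ = make_gaussian_pair(40, 30, 18, 2, 6, 4, 2.5, 5)
        c1, c2 = penalty_from_fraction(0.3, 30), penalty_from_fraction(0.5, 18)
        for comp in fit_sparse_cca(X, Y, K=3, c1=c1, c2=c2):
            assert np.linalg.norm(comp.u) <= 1 + 1e-8
            assert np.linalg.norm(comp.v) <= 1 + 1e-8
            assert np.abs(comp.u).sum() <= c1 + 1e-6
            assert np.abs(comp.v).sum() <= c2 + 1e-6
            assert comp.d >= 0
            assert comp.score_correlation >= 0
            assert comp.u[np.argmax(np.abs(comp.u))] > 0

    def test_planted_components_have_decorrelated_scores(self):
        X, Y, _ = make_gaussian_pair(100, 80, 30, 2, 10, 6, 3.0, 6)
        comps = fit_sparse_cca(
            X, Y, K=2, c1=penalty_from_fraction(0.4, 80), c2=penalty_from_fraction(0.5, 30)
        )
        r = np.corrcoef(comps[0].x_scores, comps[1].x_scores)[0, 1]
        assert abs(r) < 0.2

    def test_sample_mismatch_and_bad_k_rejected(self):
        X, Y, _ = make_gaussian_pair(20, 10, 8, 1, 3, 2, 2.0, 7)
        with pytest.raises(ValueError):
            fit_sparse_cca(X, Y, K=0, c1=2.0, c2=2.0)
        Yr = Y.subset_samples(list(reversed(Y.sample_ids)))
        with pytest.raises(ValueError):
            fit_sparse_cca(X, Yr, K=1, c1=2.0, c2=2.0)


class TestTunePenalties:
    def test_single_cell_grid_returns_that_cell(self):
        X, Y, _ = make_gaussian_pair(30, 12, 8, 1, 4, 3, 2.0, 8)
        grid = tune_penalties(X, Y, c1_fractions=[0.6], c2_fractions=[0.7], seed=0)
        assert grid.selected == (0.6, 0.7)
        assert grid.criterion.shape == (1, 1)

    def test_planted_sparse_signal_selects_sparse_cell(self):
        expr, abund, _ = generate_paired_omics(
            n_samples=120, p_genes=300, q_species=50, k_latent=2, seed=13
        )
        X = standardize(expr)
        Y = standardize(clr_transform(abund))
        grid = tune_penalties(X, Y, seed=13)
        assert grid.selected[0] <= 0.5

    def test_too_few_folds_rejected(self):
        X, Y, _ = make_gaussian_pair(30, 12, 8, 1, 4, 3, 2.0, 9)
        with pytest.raises(ValueError):
            tune_penalties(X, Y, folds=1)


class TestPermutationSelection:
    def test_add_one_p_value_formula(self):
        # overwhelming signal: observed d beats all 19 permutations -> p = 1/20.
        # note 0.05 < 0.05 is false, so the minimum permutation count can
        # never retain a component under the strict threshold
        X, Y, _ = make_gaussian_pair(60, 30, 15, 1, 6, 4, 4.0, 10)
        comps, retained = permutation_component_test(
            X, Y, K_max=1, n_perm=19, c1=np.sqrt(30), c2=np.sqrt(15), seed=0
        )
        assert comps[0].permutation_p == pytest.approx(1 / 20)
        assert retained == 0
        comps, retained = permutation_component_test(
            X, Y, K_max=1, n_perm=39, c1=np.sqrt(30), c2=np.sqrt(15), seed=0
        )
        assert comps[0].permutation_p == pytest.approx(1 / 40)
        assert retained == 1

    def test_two_planted_components_retained_with_exact_deflation(self):
        # inactive penalties make the deflation exact, so the sequential rule
        # stops at the planted rank
        X, Y, _ = make_gaussian_pair(100, 60, 25, 2, 8, 5, 3.0, 11)
        _, retained = permutation_component_test(
            X, Y, K_max=4, n_perm=49, c1=np.sqrt(60), c2=np.sqrt(25), seed=1
        )
        assert retained == 2

    def test_minimum_permutations_enforced(self):
        X, Y, _ = make_gaussian_pair(20, 10, 8, 1, 3, 2, 2.0, 12)
        with pytest.raises(ValueError):
            permutation_component_test(X, Y, 1, n_perm=5, c1=2.0, c2=2.0)


class TestSpearmanCorrelation:
    def test_hand_computed_example(self):
        # x=(1..5), y=(2,1,4,3,5): d^2 = (1,1,1,1,0), rho = 1 - 6*4/120 = 0.8
        sig = pd.DataFrame({"s": [1, 2, 3, 4, 5]}, index=list("abcde"))
        clin = pd.DataFrame({"v": [2, 1, 4, 3, 5]}, index=list("abcde"))
        tab = spearman_table(sig, clin, ["v"])
        assert tab["spearman_rho"].iloc[0] == pytest.approx(0.8)

    def test_monotone_and_reversed(self):
        idx = [f"S{i}" for i in range(8)]
        sig = pd.DataFrame({"s": np.arange(8.0)}, index=idx)
        clin = pd.DataFrame(
            {"up": np.exp(np.arange(8.0)), "down": -np.arange(8.0)}, index=idx
        )
        tab = spearman_table(sig, clin, ["up", "down"])
        assert tab.set_index("variable")["spearman_rho"]["up"] == pytest.approx(1.0)
        assert tab.set_index("variable")["spearman_rho"]["down"] == pytest.approx(-1.0)

    def test_missing_values_dropped_pairwise(self):
        idx = [f"S{i}" for i in range(6)]
        sig = pd.DataFrame({"s": [1, 2, 3, 4, 5, 6]}, index=idx, dtype=float)
        clin = pd.DataFrame({"v": [2, 1, np.nan, 3, 4, 6]}, index=idx)
        tab = spearman_table(sig, clin, ["v"])
        rho, _ = spearmanr([1, 2, 4, 5, 6], [2, 1, 3, 4, 6])
        assert tab["spearman_rho"].iloc[0] == pytest.approx(rho)

    def test_too_few_pairs_rejected(self):
        idx = ["a", "b", "c"]
        sig = pd.DataFrame({"s": [1.0, 2.0, 3.0]}, index=idx)
        clin = pd.DataFrame({"v": [1.0, 2.0, 3.0]}, index=idx)
        with pytest.raises(ValueError):
            spearman_table(sig, clin, ["v"])

    def test_component_scores_against_clinical(self):
        expr, abund, truth = generate_paired_omics(
            n_samples=80, p_genes=150, q_species=40, k_latent=1, seed=21
        )
        from duomics import generate_clinical

        clin = generate_clinical(
            truth, links={"sputum_neutrophil_pct": (0, 3.0)}, noise_sd=0.3, seed=21
        )
        X = standardize(expr)
        Y = standardize(clr_transform(abund))
        comps = fit_sparse_cca(
            X, Y, K=1, c1=penalty_from_fraction(0.3, 150), c2=penalty_from_fraction(0.4, 40)
        )
        tab = correlate_scores_clinical(comps, clin, ["sputum_neutrophil_pct"])
        assert abs(tab["spearman_rho"].iloc[0]) > 0.8
        assert tab["p_value"].iloc[0] < 1e-6
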