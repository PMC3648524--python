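import numpy as np
import pytest

from angiosig import (
    compare_loadings,
    fit_pca,
    generate_cohort,
    logistic_association,
    manova_wilks,
    primary_contrast_direction,
    subset_panel,
    top_loading_genes,
)

from conftest import three_cluster_config, toy_matrix


class TestFitPca:
    def test_collinear_two_genes(self):
        m = toy_matrix(np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]))
        model, scores = fit_pca(m)
        assert np.allclose(np.abs(model.loadings[:, 0]), 1 / np.sqrt(2))
        assert model.loadings[0, 0] > 0  # sign convention
        assert model.explained_variance[1] == pytest.approx(0.0, abs=1e-12)

    def test_scores_centered_with_diagonal_covariance(self, rng):
        m = toy_matrix(rng.normal(size=(6, 40)))
        _, scores = fit_pca(m)
        s = scores.to_numpy()
        assert np.allclose(s.mean(axis=0), 0.0, atol=1e-10)
        cov = np.cov(s, rowvar=False)
        assert np.allclose(cov - np.diag(np.diag(cov)), 0.0, atol=1e-10)

    def test_matches_eigendecomposition_oracle(self, rng):
        m = toy_matrix(rng.normal(size=(5, 30)))
        model, _ = fit_pca(m)
        x = m.values.T
        cov = np.cov(x, rowvar=False, ddof=1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        assert np.allclose(model.explained_variance, evals, atol=1e-8)
        for j in range(5):
            v = evecs[:, j]
            w = model.loadings[:, j]
            assert np.allclose(np.abs(v @ w), 1.0, atol=1e-8)

    def test_reconstruction_with_all_components(self, rng):
        m = toy_matrix(rng.normal(size=(4, 25)))
        model, scores = fit_pca(m)
        xc = m.values.T - model.center
        assert np.allclose(scores.to_numpy() @ model.loadings.T, xc, atol=1e-8)

    def test_zero_variance_gene_with_scaling_rejected(self):
        m = toy_matrix(np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]]))
        with pytest.raises(ValueError, match="zero-variance"):
            fit_pca(m, scale=True)

    def test_component_labels_carry_suffix(self, rng):
        m = toy_matrix(rng.normal(size=(3, 10)))
        model, scores = fit_pca(m, label_suffix="a")
        assert model.component_labels[0] == "PC1a"
        assert list(scores.columns) == model.component_labels

    def test_planted_direction_recovery(self):
        """With one dominant planted contrast the first component's loading
        should align with the planted direction (|cos| > 0.95)."""
        from angiosig import SimulationConfig
        from angiosig.simulate import ClusterSpec

        cfg = SimulationConfig(
            n_tumor=400, n_normal=0, n_background_genes=0, noise_sd=0.8, seed=5,
            cluster_spec=[
                ClusterSpec("hi", 0.5, {"VEGFA": 2.0, "SEMA3B": -2.0, "SEMA3C": -1.5}),
                ClusterSpec("lo", 0.5, {"VEGFA": -2.0, "SEMA3B": 2.0, "SEMA3C": 1.5}),
            ],
        )
        expr, _, truth = generate_cohort(cfg)
        panel = subset_panel(expr, cfg.panel)
        model, _ = fit_pca(panel)
        explained = model.explained_variance / model.explained_variance.sum()
        assert explained[0] >= 0.30  # the contrast dominates the variance
        planted = truth.signature_direction.reindex(model.gene_symbols).to_numpy()
        cos = abs(model.loadings[:, 0] @ planted)
        assert cos > 0.95


class TestLoadingUtilities:
    def test_radius_zero_returns_all_and_large_radius_none(self, rng):
        m = toy_matrix(rng.normal(size=(6, 20)))
        model, _ = fit_pca(m)
        assert set(top_loading_genes(model, 1, 2, radius=0.0)) == set(m.gene_ids)
        assert top_loading_genes(model, 1, 2, radius=2.0) == []
        with pytest.raises(ValueError):
            top_loading_genes(model, 1, 2, radius=-0.1)

    def test_filter_matches_brute_force(self, rng):
        m = toy_matrix(rng.normal(size=(8, 30)))
        model, _ = fit_pca(m)
        norms = np.linalg.norm(model.loadings[:, [0, 2]], axis=1)
        expected = {g for g, r in zip(model.gene_symbols, norms) if r > 0.2}
        got = top_loading_genes(model, 1, 3, radius=0.2)
        assert set(got) == expected
        got_norms = [norms[model.gene_symbols.index(g)] for g in got]
        assert got_norms == sorted(got_norms, reverse=True)

    def test_compare_identical_and_negated(self, rng):
        m = toy_matrix(rng.normal(size=(5, 20)))
        model, _ = fit_pca(m)
        r, flipped = compare_loadings(model, 1, model, 1)
        assert r == pytest.approx(1.0) and not flipped
        import copy

        neg = copy.deepcopy(model)
        neg.loadings = neg.loadings.copy()
        neg.loadings[:, 0] *= -1
        # bypass orthonormality re-validation: negation preserves it
        r2, flipped2 = compare_loadings(model, 1, neg, 1)
        assert r2 == pytest.approx(-1.0) and flipped2

    def test_split_half_recovery(self):
        """Two PCAs on disjoint halves of one cohort with a strong planted
        direction recover strongly correlated leading loadings."""
        cfg = three_cluster_config(seed=9, n_tumor=600, sep=3.0, noise=0.8)
        expr, _, _ = generate_cohort(cfg)
        panel = subset_panel(expr, cfg.panel)
        half = panel.shape[1] // 2
        m1, _ = fit_pca(panel.subset_samples(panel.sample_ids[:half]))
        m2, _ = fit_pca(panel.subset_samples(panel.sample_ids[half:]))
        r, _ = compare_loadings(m1, 1, m2, 1)
        assert abs(r) > 0.9


class TestLogisticAssociation:
    def test_constructed_signal_found(self, rng):
        n = 400
        scores = rng.normal(size=(n, 8))
        import pandas as pd

        frame = pd.DataFrame(scores, columns=[f"PC{i+1}" for i in range(8)])
        outcome = (scores[:, 0] + 0.3 * rng.normal(size=n) > 0).astype(int)
        res = logistic_association(frame, outcome)
        assert res.loc["PC1", "coef"] > 1.0
        assert res.loc["PC1", "p_value"] < 1e-6
        assert res.loc["PC5", "p_value"] > 0.001

    def test_mle_matches_direct_optimization(self, rng):
        import pandas as pd
        from scipy.optimize import minimize

        x = rng.normal(size=(40, 2))
        y = (rng.random(40) < 1 / (1 + np.exp(-(0.5 + x[:, 0] - 0.7 * x[:, 1])))).astype(int)
        frame = pd.DataFrame(x, columns=["PC1", "PC2"])
        res = logistic_association(frame, y, n_components=2)

        def negll(beta):
            eta = beta[0] + x @ beta[1:]
            return np.sum(np.log1p(np.exp(eta)) - y * eta)

        opt = minimize(negll, np.zeros(3), method="BFGS", tol=1e-12)
        assert res["coef"].to_numpy() == pytest.approx(opt.x[1:], abs=1e-6)

    def test_one_class_outcome_rejected(self, rng):
        import pandas as pd

        frame = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        with pytest.raises(ValueError):
            logistic_association(frame, np.ones(30), n_components=3)

    def test_separation_flagged(self, rng):
        import pandas as pd

        x = np.concatenate([rng.normal(-3, 0.2, 25), rng.normal(3, 0.2, 25)])
        y = (x > 0).astype(int)
        frame = pd.DataFrame({"PC1": x})
        res = logistic_association(frame, y, n_components=1)
        assert res.loc["PC1", "flag"] != "ok"


class TestManovaWilks:
    def test_identical_groups_lambda_one(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.5], [2.0, 1.5], [3.0, 0.5]])
        x = np.vstack([pts, pts])
        groups = np.array([0] * 4 + [1] * 4)
        lam, chi2, df, p = manova_wilks(x, groups)
        assert lam == pytest.approx(1.0, abs=1e-12)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert df == 2

    def test_matches_hand_determinant_computation(self, rng):
        x = rng.normal(size=(20, 2))
        groups = np.array([0] * 10 + [1] * 10)
        lam, chi2, df, p = manova_wilks(x, groups)
        grand = x - x.mean(axis=0)
        t = grand.T @ grand
        w = np.zeros((2, 2))
        for g in (0, 1):
            xi = x[groups == g]
            ci = xi - xi.mean(axis=0)
            w += ci.T @ ci
        lam_hand = np.linalg.det(w) / np.linalg.det(t)
        assert lam == pytest.approx(lam_hand, abs=1e-10)
        assert chi2 == pytest.approx(-(20 - 1 - (2 + 2) / 2) * np.log(lam_hand), abs=1e-10)

    def test_null_lambda_near_one_at_large_n(self, rng):
        x = rng.normal(size=(600, 2))
        groups = rng.integers(0, 3, size=600)
        lam, _, df, p = manova_wilks(x, groups)
        assert lam > 0.97
        assert df == 4

    def test_small_group_rejected(self, rng):
        x = rng.normal(size=(10, 2))
        groups = np.array([0] * 8 + [1] * 2)
        with pytest.raises(ValueError):
            manova_wilks(x, groups)
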