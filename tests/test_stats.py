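"""Inference layer: folds, CCA, CV-CCA, permutation, bootstrap, PLS, robust fit."""

import numpy as np
import pytest

from netreconfig.stats import (
    StatsConfig,
    behavioral_pls,
    cca_fit,
    cv_cca,
    make_folds,
    partial_spearman,
    permutation_p,
    robust_regress,
    variate_loadings,
)


def small_cfg(**kw):
    base = dict(n_folds=10, n_perm=199, n_boot=199, seed=0)
    base.update(kw)
    return StatsConfig(**base)


class TestFolds:
    def test_cohort_sizes(self):
        f = make_folds(642, 10, seed=0)
        sizes = sorted(np.bincount(f))
        assert sizes == [64] * 8 + [65] * 2
        assert sorted(np.bincount(make_folds(20, 10, seed=1))) == [2] * 10

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            make_folds(5, 10, seed=0)

    def test_deterministic(self):
        assert np.array_equal(make_folds(100, 10, seed=7), make_folds(100, 10, seed=7))


class TestCcaFit:
    def test_identical_blocks_perfect_correlation(self, rng):
        X = rng.standard_normal((100, 3))
        fit = cca_fit(X, X.copy())
        assert np.allclose(fit.corrs, 1.0, atol=1e-8)

    def test_null_first_correlation_small(self):
        rng = np.random.default_rng(0)
        fit = cca_fit(rng.standard_normal((10000, 2)), rng.standard_normal((10000, 2)))
        assert fit.corrs[0] < 0.05

    def test_planted_shared_latent_recovered(self):
        rng = np.random.default_rng(1)
        n = 5000
        z = rng.standard_normal(n)
        X = np.column_stack([z + rng.standard_normal(n), rng.standard_normal(n)])
        Y = np.column_stack([z + rng.standard_normal(n), rng.standard_normal(n)])
        fit = cca_fit(X, Y)
        assert abs(fit.corrs[0] - 0.5) < 0.05

    def test_affine_invariance_of_correlations(self, rng):
        X = rng.standard_normal((200, 3))
        Y = rng.standard_normal((200, 2))
        A = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        B = rng.standard_normal((2, 2)) + 3 * np.eye(2)
        f1 = cca_fit(X, Y)
        f2 = cca_fit(X @ A + 5.0, Y @ B - 2.0)
        assert np.allclose(f1.corrs, f2.corrs, atol=1e-8)

    def test_corrs_non_increasing(self, rng):
        fit = cca_fit(rng.standard_normal((80, 4)), rng.standard_normal((80, 4)))
        assert (np.diff(fit.corrs) <= 1e-12).all()


def planted_cohort(n, r, seed, p=3, q=3):
    """Two blocks sharing one latent with population canonical correlation r."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    a = np.sqrt(1.0 / r - 1.0)  # corr(block1, block2) via shared z = 1/(1+a^2)
    X = rng.standard_normal((n, p))
    Y = rng.standard_normal((n, q))
    X[:, 0] = z + a * rng.standard_normal(n)
    Y[:, 0] = z + a * rng.standard_normal(n)
    return X, Y


class TestCvCca:
    def test_planted_latent_recovered(self):
        rs = []
        for s in range(5):
            X, Y = planted_cohort(400, 0.5, seed=s)
            res = cv_cca(X, Y, None, small_cfg(seed=s), compute_loadings=False)
            rs.append(res.r)
        assert abs(np.median(rs) - 0.5) < 0.15

    def test_no_test_fold_leakage(self):
        X, Y = planted_cohort(200, 0.5, seed=3)
        cfg = small_cfg(seed=3)
        res1 = cv_cca(X, Y, None, cfg, compute_loadings=False)
        fold = res1.folds == 0
        Y2 = Y.copy()
        Y2[fold] = Y[fold][np.random.default_rng(0).permutation(fold.sum())]
        res2 = cv_cca(X, Y2, None, cfg, compute_loadings=False)
        # fold 0's predicted X-variate depends only on training folds
        assert np.allclose(res1.pooled_u[fold], res2.pooled_u[fold])

    def test_deterministic(self):
        X, Y = planted_cohort(120, 0.5, seed=9)
        a = cv_cca(X, Y, None, small_cfg(seed=4), compute_loadings=False)
        b = cv_cca(X, Y, None, small_cfg(seed=4), compute_loadings=False)
        assert a.r == b.r and a.p == b.p


class TestPermutationP:
    def test_identical_vectors_minimum_p(self, rng):
        x = rng.standard_normal(100)
        p = permutation_p(x, x, None, n_perm=999, seed=0)
        assert p == pytest.approx(1.0 / 1000.0, abs=1e-9)

    def test_add_one_lower_bound(self, rng):
        x = rng.standard_normal(40)
        y = rng.standard_normal(40)
        p = permutation_p(x, y, None, n_perm=499, seed=1)
        assert p >= 1.0 / 500.0
        assert p <= 1.0


class TestVariateLoadings:
    def test_identity_variable(self, rng):
        u = rng.standard_normal(80)
        out = variate_loadings(u[:, None], u, None, n_boot=100, seed=0)
        assert out.loc[0, "loading"] == pytest.approx(1.0)
        assert out.loc[0, "coef"] == pytest.approx(1.0, abs=1e-8)

    def test_duplicated_variables_split_coefficient(self, rng):
        x = rng.standard_normal(150)
        u = x + 0.3 * rng.standard_normal(150)
        single = variate_loadings(x[:, None], u, None, n_boot=100, seed=1)
        dup = variate_loadings(np.column_stack([x, x + 1e-9 * rng.standard_normal(150)]),
                               u, None, n_boot=100, seed=1)
        assert dup.loc[0, "loading"] == pytest.approx(dup.loc[1, "loading"], abs=1e-4)
        assert dup["coef"].sum() == pytest.approx(single.loc[0, "coef"], abs=1e-3)

    def test_bootstrap_ci_coverage(self):
        # planted r = 0.4: the 95% BCa interval should cover it most of the time
        covered = 0
        n_seeds = 60
        for s in range(n_seeds):
            rng = np.random.default_rng(10_000 + s)
            x = rng.standard_normal(300)
            y = 0.4 * x + np.sqrt(1 - 0.16) * rng.standard_normal(300)
            out = variate_loadings(x[:, None], y, None, n_boot=400, seed=s)
            covered += out.loc[0, "loading_lo"] <= 0.4 <= out.loc[0, "loading_hi"]
        assert 0.9 * n_seeds <= covered <= n_seeds


class TestBehavioralPls:
    def test_single_behavior_saliences_equal_correlation_vector(self, rng):
        n, R = 120, 15
        B = rng.standard_normal(n)
        roi = rng.standard_normal((n, R))
        roi[:, :3] += 0.5 * B[:, None]
        res = behavioral_pls(B, roi, small_cfg(n_folds=2))
        corr = np.array([np.corrcoef(B, roi[:, j])[0, 1] for j in range(R)])
        sal = res.saliences[:, 0]
        cos = sal @ corr / (np.linalg.norm(sal) * np.linalg.norm(corr))
        assert abs(abs(cos) - 1.0) < 1e-10
        # scaled saliences equal the correlation vector up to a global sign
        sign = np.sign(sal @ corr)
        assert np.allclose(sign * sal, corr, atol=1e-10)

    def test_constant_behavior_rejected(self, rng):
        with pytest.raises(ValueError):
            behavioral_pls(np.ones(50), rng.standard_normal((50, 5)), small_cfg())

    def test_planted_rois_flagged_null_rois_spared(self):
        rng = np.random.default_rng(0)
        n, R = 300, 60
        B = rng.standard_normal(n)
        roi = rng.standard_normal((n, R))
        roi[:, :8] = 0.4 * B[:, None] + np.sqrt(1 - 0.16) * rng.standard_normal((n, 8))
        res = behavioral_pls(B, roi, small_cfg(n_perm=199, n_boot=500))
        flagged = set(res.reliable_rois(0))
        assert set(range(8)) <= flagged
        false_flags = [j for j in flagged if j >= 8]
        assert len(false_flags) <= 0.05 * (R - 8)


class TestRobustRegress:
    def test_matches_ols_on_clean_data(self, rng):
        X = rng.standard_normal((100, 2))
        y = 1.0 + 2.0 * X[:, 0] - 0.5 * X[:, 1]
        fit = robust_regress(y, X)
        assert np.allclose(fit.params, [1.0, 2.0, -0.5], atol=1e-6)

    def test_resists_gross_contamination(self):
        rng = np.random.default_rng(2)
        n = 200
        x = rng.standard_normal(n)
        y = x + 0.5 * rng.standard_normal(n)
        bad = rng.choice(n, n // 10, replace=False)
        y[bad] *= 50.0
        fit = robust_regress(y, x)
        ols = np.polyfit(x, y, 1)[0]
        assert abs(fit.params[1] - 1.0) < 0.1
        assert abs(ols - 1.0) > 0.5

    def test_constant_predictor_rejected(self, rng):
        with pytest.raises(ValueError):
            robust_regress(rng.standard_normal(30), np.ones((30, 1)))


class TestPartialSpearman:
    def test_identity_and_monotone_invariance(self, rng):
        x = rng.standard_normal(40)
        rho, _ = partial_spearman(x, x, None, n_perm=199, seed=0)
        assert rho == pytest.approx(1.0)
        y = rng.standard_normal(40)
        r1, _ = partial_spearman(x, y, None, n_perm=199, seed=0)
        r2, _ = partial_spearman(np.exp(x), y, None, n_perm=199, seed=0)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_covariate_control_removes_shared_driver(self, rng):
        c = rng.standard_normal(200)
        x = c + 0.3 * rng.standard_normal(200)
        y = c + 0.3 * rng.standard_normal(200)
        rho_raw, _ = partial_spearman(x, y, None, n_perm=199, seed=1)
        rho_ctl, _ = partial_spearman(x, y, c[:, None], n_perm=199, seed=1)
        assert rho_raw > 0.7
        assert abs(rho_ctl) < 0.25
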