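"""Inference layer: cross-validated CCA, behavioral PLS, robust regression.

CV-CCA: canonical weights are estimated on 9/10 training folds (with
fold-wise standardization from training statistics only), the left-out fold
is projected, and the pooled predicted variates are correlated (partial
Pearson, controlling covariates).  Significance comes from a permutation
test that re-runs the whole cross-validation loop on row-permuted data;
per-variable loadings and standardized coefficients carry bootstrap
confidence intervals (BCa by default).

Behavioral PLS: singular value decomposition of the behavior-by-ROI
cross-correlation matrix; latent-variable significance by row permutation
of the ROI block; salience standard errors by subject bootstrap with
Procrustes alignment; bootstrap ratio BSR = salience / SE, |BSR| >= 3
marking reliable contributors.

Robust regression: iteratively reweighted least squares with the Tukey
bisquare weight function (tuning constant 4.685, MAD scale).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.special import ndtri

from .core import logger

_PERM_CHUNK = 2000


@dataclass
class StatsConfig:
    n_folds: int = 10
    n_perm: int = 100_000
    n_boot: int = 100_000
    ci_level: float = 0.95
    pls_corr_ci: float = 0.99
    bootstrap_ci: str = "bca"  # "bca" | "percentile"
    bsr_threshold: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_perm < 100 or self.n_boot < 100:
            raise ValueError("n_perm and n_boot must be >= 100")


# ---------------------------------------------------------------------------
# helpers


def _as_cov(covariates, n: int) -> np.ndarray:
    """Covariates as an (n, c) array; c may be 0."""
    if covariates is None:
        return np.empty((n, 0))
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != n:
        raise ValueError("covariate rows must match number of subjects")
    return C


def _residualize(M: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residuals of each column of M on [intercept, covariates]."""
    M = np.asarray(M, dtype=float)
    one_d = M.ndim == 1
    if one_d:
        M = M[:, None]
    X = np.column_stack([np.ones(M.shape[0]), covariates])
    beta, *_ = np.linalg.lstsq(X, M, rcond=None)
    R = M - X @ beta
    return R[:, 0] if one_d else R


def _zscore(X: np.ndarray, mean=None, sd=None) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    if mean is None:
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd, mean, sd


def partial_pearson(x: np.ndarray, y: np.ndarray, covariates=None) -> float:
    """Pearson correlation of x and y after removing covariates from both."""
    n = len(x)
    C = _as_cov(covariates, n)
    rx = _residualize(np.asarray(x, float), C)
    ry = _residualize(np.asarray(y, float), C)
    denom = np.linalg.norm(rx) * np.linalg.norm(ry)
    if denom == 0:
        return float("nan")
    return float(rx @ ry / denom)


# ---------------------------------------------------------------------------
# folds and CCA


def make_folds(n_subjects: int, n_folds: int = 10, seed: int = 0) -> np.ndarray:
    """Fold label per subject; sizes differ by at most one."""
    if n_subjects < n_folds:
        raise ValueError("more folds than subjects")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_subjects)
    labels = np.empty(n_subjects, dtype=np.int64)
    for f, chunk in enumerate(np.array_split(perm, n_folds)):
        labels[chunk] = f
    return labels


@dataclass
class CcaFit:
    x_weights: np.ndarray  # (p, k)
    y_weights: np.ndarray  # (q, k)
    corrs: np.ndarray  # (k,), non-increasing


def cca_fit(X: np.ndarray, Y: np.ndarray) -> CcaFit:
    """Classical CCA via whitening + SVD of the cross-product.

    Weights apply to centered data; canonical correlations are the singular
    values of the whitened cross-covariance, non-increasing.  Rank-deficient
    blocks are reduced to their numerical rank with a logged warning.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have equal row counts")
    n = X.shape[0]
    if n <= X.shape[1] + Y.shape[1]:
        logger.warning("cca_fit: n (%d) not greater than p+q (%d)", n, X.shape[1] + Y.shape[1])
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)

    def whiten(M):
        U, s, Vt = np.linalg.svd(M, full_matrices=False)
        tol = max(M.shape) * np.finfo(float).eps * (s[0] if s.size else 0)
        r = int((s > tol).sum())
        if r < M.shape[1]:
            logger.warning("cca_fit: block rank reduced from %d to %d", M.shape[1], r)
        return U[:, :r], Vt[:r].T / s[:r]

    Ux, Wx = whiten(Xc)
    Uy, Wy = whiten(Yc)
    U, s, Vt = np.linalg.svd(Ux.T @ Uy, full_matrices=False)
    return CcaFit(
        x_weights=Wx @ U,
        y_weights=Wy @ Vt.T,
        corrs=np.clip(s, 0.0, 1.0),
    )


# ---------------------------------------------------------------------------
# permutation and bootstrap primitives


def permutation_p(
    pooled_u: np.ndarray,
    pooled_v: np.ndarray,
    covariates=None,
    n_perm: int = 100_000,
    seed: int = 0,
) -> float:
    """Permutation p for the partial correlation of two pooled variates.

    One variate's rows are shuffled; p = (1 + #{|r_perm| >= |r_obs|}) /
    (n_perm + 1), so p is never zero.
    """
    u = np.asarray(pooled_u, dtype=float)
    v = np.asarray(pooled_v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("variates must have equal length")
    n = u.shape[0]
    C = _as_cov(covariates, n)
    ru = _residualize(u, C)
    rv = _residualize(v, C)
    ru = (ru - ru.mean()) / (ru.std() or 1.0)
    rv = (rv - rv.mean()) / (rv.std() or 1.0)
    r_obs = abs(ru @ rv / n)
    rng = np.random.default_rng(seed)
    count = 0
    done = 0
    while done < n_perm:
        m = min(_PERM_CHUNK, n_perm - done)
        perm = np.argsort(rng.random((m, n)), axis=1)
        rs = rv[perm] @ ru / n
        count += int((np.abs(rs) >= r_obs - 1e-12).sum())
        done += m
    return (1 + count) / (n_perm + 1)


def _bca_interval(
    boot: np.ndarray, jack: np.ndarray, theta: float, level: float, method: str
) -> Tuple[float, float]:
    boot = boot[np.isfinite(boot)]
    if boot.size < 10 or not np.isfinite(theta):
        return (float("nan"), float("nan"))
    alpha = (1.0 - level) / 2.0
    if method == "percentile" or np.ptp(boot) == 0:
        return tuple(np.quantile(boot, [alpha, 1 - alpha]))
    prop = np.clip(np.mean(boot < theta), 1.0 / (boot.size + 1), boot.size / (boot.size + 1.0))
    z0 = ndtri(prop)
    jm = jack.mean()
    num = ((jm - jack) ** 3).sum()
    den = 6.0 * (((jm - jack) ** 2).sum()) ** 1.5
    a = num / den if den > 0 else 0.0
    lo_z, hi_z = ndtri(alpha), ndtri(1 - alpha)
    q_lo = sstats.norm.cdf(z0 + (z0 + lo_z) / (1 - a * (z0 + lo_z)))
    q_hi = sstats.norm.cdf(z0 + (z0 + hi_z) / (1 - a * (z0 + hi_z)))
    return tuple(np.quantile(boot, [q_lo, q_hi]))


def variate_loadings(
    observed_vars: np.ndarray,
    predicted_variate: np.ndarray,
    covariates=None,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
    method: str = "bca",
) -> pd.DataFrame:
    """Per-variable loadings and standardized coefficients with bootstrap CIs.

    Loading = partial Pearson correlation of the observed variable with the
    predicted variate (covariates removed); coefficient = the standardized
    variable's weight in the joint regression of the variate on all
    standardized variables plus covariates.  CIs resample subjects.
    """
    V = np.asarray(observed_vars, dtype=float)
    if V.ndim == 1:
        V = V[:, None]
    u = np.asarray(predicted_variate, dtype=float)
    n, p = V.shape
    C = _as_cov(covariates, n)

    def stat(idx: np.ndarray) -> np.ndarray:
        Vb, ub, Cb = V[idx], u[idx], C[idx]
        Rv = _residualize(Vb, Cb)
        ru = _residualize(ub, Cb)
        norms = np.linalg.norm(Rv, axis=0) * np.linalg.norm(ru)
        norms = np.where(norms > 0, norms, np.nan)
        loadings = (Rv.T @ ru) / norms
        Z, _, _ = _zscore(Vb)
        uz, _, _ = _zscore(ub[:, None])
        D = np.column_stack([Z, Cb, np.ones(len(idx))])
        beta, *_ = np.linalg.lstsq(D, uz[:, 0], rcond=None)
        return np.concatenate([loadings, beta[:p]])

    theta = stat(np.arange(n))
    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, 2 * p))
    for b in range(n_boot):
        boot[b] = stat(rng.integers(0, n, n))
    jack = np.empty((n, 2 * p))
    all_idx = np.arange(n)
    for i in range(n):
        jack[i] = stat(np.delete(all_idx, i))
    rows = []
    for j in range(p):
        lo_l, hi_l = _bca_interval(boot[:, j], jack[:, j], theta[j], ci_level, method)
        lo_c, hi_c = _bca_interval(boot[:, p + j], jack[:, p + j], theta[p + j], ci_level, method)
        rows.append(
            {
                "loading": theta[j],
                "loading_lo": lo_l,
                "loading_hi": hi_l,
                "coef": theta[p + j],
                "coef_lo": lo_c,
                "coef_hi": hi_c,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cross-validated CCA


@dataclass
class CvCcaResult:
    r: float
    p: float
    pooled_u: np.ndarray
    pooled_v: np.ndarray
    folds: np.ndarray
    fold_x_weights: List[np.ndarray]
    fold_y_weights: List[np.ndarray]
    x_loadings: Optional[pd.DataFrame] = None
    y_loadings: Optional[pd.DataFrame] = None


def _pooled_variates(
    X: np.ndarray, Y: np.ndarray, folds: np.ndarray, n_folds: int
) -> Tuple[np.ndarray, np.ndarray, List[np.ndarray], List[np.ndarray]]:
    """Train per-fold CCA weights and pool the held-out predicted variates."""
    n = X.shape[0]
    u = np.empty(n)
    v = np.empty(n)
    ref_wx: Optional[np.ndarray] = None
    wxs, wys = [], []
    for f in range(n_folds):
        train = folds != f
        test = folds == f
        Zx, mx, sx = _zscore(X[train])
        Zy, my, sy = _zscore(Y[train])
        fit = cca_fit(Zx, Zy)
        wx = fit.x_weights[:, 0]
        wy = fit.y_weights[:, 0]
        if ref_wx is None:
            if wx[np.argmax(np.abs(wx))] < 0:
                wx, wy = -wx, -wy
            ref_wx = wx
        elif wx @ ref_wx < 0:
            wx, wy = -wx, -wy
        wxs.append(wx)
        wys.append(wy)
        u[test] = ((X[test] - mx) / sx) @ wx
        v[test] = ((Y[test] - my) / sy) @ wy
    return u, v, wxs, wys


def cv_cca(
    X: np.ndarray,
    Y: np.ndarray,
    covariates=None,
    config: StatsConfig | None = None,
    compute_loadings: bool = True,
) -> CvCcaResult:
    """Cross-validated CCA with pooled test-fold variates.

    Training folds are standardized with their own statistics; the held-out
    fold is projected with the training weights (no leakage).  Fold weight
    signs are aligned to the first fold so pooled variates are coherent.

    The permutation test re-runs the complete cross-validation loop on each
    row-permuted Y block: fold models share training data, so pooled
    test-fold correlations are dependent across folds and a simple shuffle
    of the pooled variates would be anticonservative.
    """
    config = config or StatsConfig()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    folds = make_folds(n, config.n_folds, seed=config.seed)
    u, v, wxs, wys = _pooled_variates(X, Y, folds, config.n_folds)
    r = partial_pearson(u, v, covariates)
    rng = np.random.default_rng(config.seed + 1_000_003)
    count = 0
    for _ in range(config.n_perm):
        perm = rng.permutation(n)
        up, vp, _, _ = _pooled_variates(X, Y[perm], folds, config.n_folds)
        if abs(partial_pearson(up, vp, covariates)) >= abs(r) - 1e-12:
            count += 1
    p = (1 + count) / (config.n_perm + 1)
    res = CvCcaResult(
        r=r, p=p, pooled_u=u, pooled_v=v, folds=folds,
        fold_x_weights=wxs, fold_y_weights=wys,
    )
    if compute_loadings:
        res.x_loadings = variate_loadings(
            X, u, covariates, n_boot=config.n_boot, seed=config.seed + 11,
            ci_level=config.ci_level, method=config.bootstrap_ci,
        )
        res.y_loadings = variate_loadings(
            Y, v, covariates, n_boot=config.n_boot, seed=config.seed + 12,
            ci_level=config.ci_level, method=config.bootstrap_ci,
        )
    return res


# ---------------------------------------------------------------------------
# behavioral PLS


@dataclass
class PlsResult:
    singular_values: np.ndarray  # (L,)
    perm_p: np.ndarray  # (L,)
    saliences: np.ndarray  # (R, L) brain saliences scaled by singular value
    salience_se: np.ndarray  # (R, L)
    bsr: np.ndarray  # (R, L)
    behavior_saliences: np.ndarray  # (b, L)
    lv_behavior_corr: np.ndarray  # (b, L)
    lv_behavior_corr_ci: np.ndarray  # (b, L, 2)
    bsr_threshold: float

    def reliable_rois(self, lv: int = 0) -> np.ndarray:
        return np.flatnonzero(np.abs(self.bsr[:, lv]) >= self.bsr_threshold)


def behavioral_pls(
    behavior: np.ndarray,
    roi_part: np.ndarray,
    config: StatsConfig | None = None,
) -> PlsResult:
    """Behavioral PLS of behavior against per-ROI measures.

    SVD of the (behaviors x ROIs) cross-correlation matrix; permutation of
    ROI-block rows for LV significance; subject bootstrap with Procrustes
    alignment for salience SEs.  With one behavior column the single LV's
    scaled saliences equal the behavior-ROI correlation vector up to sign.
    """
    config = config or StatsConfig()
    B = np.asarray(behavior, dtype=float)
    if B.ndim == 1:
        B = B[:, None]
    R = np.asarray(roi_part, dtype=float)
    n = B.shape[0]
    if R.shape[0] != n:
        raise ValueError("behavior and ROI blocks must have equal rows")
    if n < 10:
        raise ValueError("need at least 10 subjects")
    if (B.std(axis=0) == 0).any():
        raise ValueError("constant behavior column")

    def cross_corr(Bm, Rm):
        Zb, _, _ = _zscore(Bm)
        Zr, _, _ = _zscore(Rm)
        return Zb.T @ Zr / (len(Bm) - 1), Zb, Zr

    Rmat, Zb, Zr = cross_corr(B, R)
    U, s, Vt = np.linalg.svd(Rmat, full_matrices=False)
    L = s.shape[0]
    sal = Vt.T * s  # (R, L) scaled brain saliences

    rng = np.random.default_rng(config.seed)
    # permutation test: reorder ROI-block rows, compare singular values
    exceed = np.zeros(L)
    for _ in range(config.n_perm):
        perm = rng.permutation(n)
        s_null = np.linalg.svd(Zb.T @ Zr[perm] / (n - 1), compute_uv=False)
        exceed += s_null >= s - 1e-12
    perm_p = (1 + exceed) / (config.n_perm + 1)

    brain_scores = Zr @ Vt.T
    lv_corr = np.empty((B.shape[1], L))
    for j in range(B.shape[1]):
        for l in range(L):
            lv_corr[j, l] = np.corrcoef(B[:, j], brain_scores[:, l])[0, 1]

    boot_sal = np.empty((config.n_boot, Vt.shape[1], L))
    boot_corr = np.empty((config.n_boot, B.shape[1], L))
    for b in range(config.n_boot):
        idx = rng.integers(0, n, n)
        while (B[idx].std(axis=0) == 0).any():  # pragma: no cover - tiny-n guard
            idx = rng.integers(0, n, n)
        Rb, Zbb, Zrb = cross_corr(B[idx], R[idx])
        Ub, sb, Vbt = np.linalg.svd(Rb, full_matrices=False)
        A, _, Bt = np.linalg.svd(Ub.T @ U)
        Q = A @ Bt  # Procrustes rotation aligning bootstrap LVs to originals
        boot_sal[b] = (Vbt.T * sb) @ Q
        scores_b = Zrb @ (Vbt.T @ Q)
        for j in range(B.shape[1]):
            for l in range(L):
                boot_corr[b, j, l] = np.corrcoef(B[idx, j], scores_b[:, l])[0, 1]
    se = boot_sal.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        bsr = np.where(se > 0, sal / se, np.inf * np.sign(sal))
    alpha = (1.0 - config.pls_corr_ci) / 2.0
    ci = np.stack(
        [
            np.quantile(boot_corr, alpha, axis=0),
            np.quantile(boot_corr, 1 - alpha, axis=0),
        ],
        axis=-1,
    )
    return PlsResult(
        singular_values=s,
        perm_p=perm_p,
        saliences=sal,
        salience_se=se,
        bsr=bsr,
        behavior_saliences=U,
        lv_behavior_corr=lv_corr,
        lv_behavior_corr_ci=ci,
        bsr_threshold=config.bsr_threshold,
    )


# ---------------------------------------------------------------------------
# robust regression and partial Spearman


@dataclass
class RobustFit:
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    names: List[str]


def robust_regress(
    y: np.ndarray, X: np.ndarray, names: Optional[List[str]] = None
) -> RobustFit:
    """Bisquare IRLS regression (tuning 4.685, MAD scale), intercept added."""
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != y.shape[0]:
        raise ValueError("row mismatch")
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError("need n > predictors + 1")
    if (np.ptp(X, axis=0) == 0).any():
        raise ValueError("constant predictor column")
    design = sm.add_constant(X)
    model = sm.RLM(y, design, M=sm.robust.norms.TukeyBiweight(c=4.685))
    res = model.fit(maxiter=200, tol=1e-8, scale_est="mad")
    cols = names or [f"x{j}" for j in range(X.shape[1])]
    return RobustFit(
        params=np.asarray(res.params),
        bse=np.asarray(res.bse),
        tvalues=np.asarray(res.tvalues),
        pvalues=np.asarray(res.pvalues),
        names=["intercept"] + cols,
    )


def partial_spearman(
    x: np.ndarray,
    y: np.ndarray,
    covariates=None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> Tuple[float, float]:
    """Partial Spearman correlation with permutation p.

    All variables are rank-transformed (average ranks); covariate ranks are
    regressed out of both x and y before the Pearson step.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    n = x.shape[0]
    C = _as_cov(covariates, n)
    rx = sstats.rankdata(x)
    ry = sstats.rankdata(y)
    RC = np.column_stack([sstats.rankdata(C[:, j]) for j in range(C.shape[1])]) if C.shape[1] else C
    ex = _residualize(rx, RC)
    ey = _residualize(ry, RC)
    denom = np.linalg.norm(ex - ex.mean()) * np.linalg.norm(ey - ey.mean())
    if denom == 0:
        return float("nan"), float("nan")
    rho = float((ex - ex.mean()) @ (ey - ey.mean()) / denom)
    p = permutation_p(ex, ey, None, n_perm=n_perm, seed=seed)
    return rho, p
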