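"""Regression GWAS: per-SNP ordinary least squares and a
spectral-decomposition linear mixed model.

The mixed model is ``y ~ N(X b, sigma_g^2 K + sigma_e^2 I)``.  With the
eigendecomposition ``K = U S U^T`` computed once, rotating ``y`` and
``X`` by ``U^T`` diagonalizes the covariance, so for any candidate
variance ratio ``delta = sigma_e^2 / sigma_g^2`` the generalized
least-squares fit reduces to weighted least squares with weights
``1 / (S_i + delta)`` and ``sigma_g^2`` profiles out analytically.
``delta`` is estimated once on the null model by maximizing the REML
log-likelihood over a 100-point log grid on [1e-5, 1e5] followed by
golden-section refinement, and is reused for every SNP by default (the
fast approximation); an exact per-SNP re-fit sits behind a flag.

Per-SNP tests are Wald chi-square with 1 df for the mixed model and
two-sided t-tests with n-2 df for plain OLS.  Zero-variance SNPs are
reported with beta 0 and p 1 so output stays row-aligned with input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

# median of the chi-square distribution with 1 df
CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))  # 0.4549364...

_TINY = 1e-12


@dataclass
class VarianceComponents:
    """REML variance components of the null mixed model.

    ``delta = sigma_e2 / sigma_g2``; pseudo-heritability
    ``h2 = sigma_g2 / (sigma_g2 + sigma_e2) = 1 / (1 + delta)``.
    """

    sigma_g2: float
    sigma_e2: float
    delta: float
    h2: float
    loglik: float


@dataclass
class LMMNull:
    """Fitted null model with the cached spectral decomposition."""

    varcomp: VarianceComponents
    eigenvalues: np.ndarray  # S, descending not required
    U: np.ndarray
    y_rot: np.ndarray  # U^T y
    X_rot: np.ndarray  # U^T X
    X: np.ndarray
    logdet_XtX: float
    reml: bool


@dataclass
class AssociationResult:
    """Per-variant association scores, row-aligned with the tested SNPs."""

    table: pd.DataFrame
    method: str
    n_samples: int

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _variant_frame(m: int, variants: pd.DataFrame | None) -> pd.DataFrame:
    if variants is not None:
        if len(variants) != m:
            raise ValueError("variant table length mismatch")
        return variants[["variant_id", "chrom", "pos"]].reset_index(drop=True)
    return pd.DataFrame(
        {"variant_id": [f"v{i}" for i in range(m)], "chrom": "0", "pos": 0}
    )


def gwas_linreg(
    g_imputed: np.ndarray, y: np.ndarray, variants: pd.DataFrame | None = None
) -> AssociationResult:
    """Single-SNP simple linear regression, ignoring relatedness.

    Per variant fits ``y = b0 + b1 g + e``; two-sided t-test on b1 with
    n-2 degrees of freedom.
    """
    X = np.asarray(g_imputed, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    if not np.isfinite(y).all():
        raise ValueError("trait vector must be finite (drop masked samples first)")
    if np.ptp(y) == 0:
        raise ValueError("trait is constant; regression is degenerate")

    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    sxx = (Xc**2).sum(axis=0)
    sxy = Xc.T @ yc
    syy = float(yc @ yc)
    ok = sxx > _TINY
    beta = np.zeros(m)
    se = np.full(m, np.nan)
    pval = np.ones(m)
    beta[ok] = sxy[ok] / sxx[ok]
    rss = np.maximum(syy - beta[ok] * sxy[ok], 0.0)
    sigma2 = rss / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        se[ok] = np.sqrt(sigma2 / sxx[ok])
        tstat = np.where(se[ok] > 0, beta[ok] / se[ok], np.inf)
    pval[ok] = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)

    table = _variant_frame(m, variants)
    table["beta"] = beta
    table["se"] = se
    table["p_value"] = np.clip(pval, np.nextafter(0, 1), 1.0)
    return AssociationResult(table, method="lm", n_samples=n)


def _reml_neg_loglik(log10_delta: float, S, y_rot, X_rot, logdet_XtX, reml=True):
    delta = 10.0**log10_delta
    w = 1.0 / (S + delta)
    Xw = X_rot * w[:, None]
    A = X_rot.T @ Xw
    b = Xw.T @ y_rot
    beta = np.linalg.solve(A, b)
    r = y_rot - X_rot @ beta
    rss = float((w * r * r).sum())
    n, p = X_rot.shape
    dof = n - p if reml else n
    sigma_g2 = max(rss / dof, 1e-300)
    ll = -0.5 * (dof * np.log(2.0 * np.pi * sigma_g2) + np.log(S + delta).sum() + dof)
    if reml:
        sign, logdet_A = np.linalg.slogdet(A)
        ll -= 0.5 * (logdet_A - logdet_XtX)
    return -ll


def fit_lmm_null(
    y: np.ndarray,
    K,
    X: np.ndarray | None = None,
    reml: bool = True,
    grid_size: int = 100,
    grid_bounds: tuple[float, float] = (1e-5, 1e5),
) -> LMMNull:
    """Estimate variance components of the null mixed model.

    ``K`` may be a :class:`~gwaskit.relatedness.KinshipMatrix` or a bare
    symmetric array; ``X`` defaults to an intercept-only design.
    """
    Kv = K.values if hasattr(K, "values") else np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if Kv.shape != (n, n):
        raise ValueError(f"kinship shape {Kv.shape} does not match n={n}")
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("covariate matrix X is rank deficient")
    if n < p + 2:
        raise ValueError("insufficient samples for the requested design")

    S, U = np.linalg.eigh((Kv + Kv.T) / 2.0)
    if S.min() < -1e-8 * max(S.max(), 1.0):
        raise np.linalg.LinAlgError(
            f"kinship is not positive semi-definite (min eigenvalue {S.min():.3g})"
        )
    S = np.clip(S, 0.0, None)
    y_rot = U.T @ y
    X_rot = U.T @ X
    _, logdet_XtX = np.linalg.slogdet(X.T @ X)

    lo, hi = np.log10(grid_bounds[0]), np.log10(grid_bounds[1])
    grid = np.linspace(lo, hi, grid_size)
    nll = np.array(
        [_reml_neg_loglik(g, S, y_rot, X_rot, logdet_XtX, reml) for g in grid]
    )
    i = int(np.argmin(nll))
    if 0 < i < grid_size - 1:
        # golden-section refinement between the best grid point's neighbors
        res = optimize.minimize_scalar(
            _reml_neg_loglik,
            bracket=(grid[i - 1], grid[i], grid[i + 1]),
            args=(S, y_rot, X_rot, logdet_XtX, reml),
            method="golden",
            options={"xtol": 1e-8},
        )
        best_log_delta = float(res.x) if res.fun <= nll[i] else grid[i]
    else:
        best_log_delta = grid[i]

    varcomp = _components_at(best_log_delta, S, y_rot, X_rot, logdet_XtX, reml)
    return LMMNull(varcomp, S, U, y_rot, X_rot, X, logdet_XtX, reml)


def _components_at(log10_delta, S, y_rot, X_rot, logdet_XtX, reml) -> VarianceComponents:
    delta = 10.0**log10_delta
    w = 1.0 / (S + delta)
    Xw = X_rot * w[:, None]
    A = X_rot.T @ Xw
    beta = np.linalg.solve(A, Xw.T @ y_rot)
    r = y_rot - X_rot @ beta
    n, p = X_rot.shape
    dof = n - p if reml else n
    sigma_g2 = float((w * r * r).sum()) / dof
    ll = -_reml_neg_loglik(log10_delta, S, y_rot, X_rot, logdet_XtX, reml)
    return VarianceComponents(
        sigma_g2=sigma_g2,
        sigma_e2=sigma_g2 * delta,
        delta=delta,
        h2=1.0 / (1.0 + delta),
        loglik=float(ll),
    )


def gwas_lmm(
    g_imputed: np.ndarray,
    y: np.ndarray,
    K,
    variants: pd.DataFrame | None = None,
    X: np.ndarray | None = None,
    refit_delta_per_snp: bool = False,
    null: LMMNull | None = None,
) -> AssociationResult:
    """Mixed-model single-SNP association.

    Each SNP enters the fixed effects alongside ``X``; with ``delta``
    fixed at the null estimate the per-SNP GLS solves are closed-form in
    the rotated space.  ``refit_delta_per_snp=True`` re-optimizes delta
    for every SNP (slow, exact).  A pre-fitted ``null`` may be supplied
    to skip the eigendecomposition.
    """
    G = np.asarray(g_imputed, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = G.shape
    if null is None:
        null = fit_lmm_null(y, K, X=X)
    S, U = null.eigenvalues, null.U
    y_rot, X_rot = null.y_rot, null.X_rot
    p = X_rot.shape[1]
    G_rot = U.T @ G

    table = _variant_frame(m, variants)
    if refit_delta_per_snp:
        beta, se, pval, loglik = _lmm_scan_refit(null, G, G_rot)
    else:
        beta, se, pval, loglik = _lmm_scan_fixed(
            null, G, G_rot, np.log10(null.varcomp.delta)
        )
    table["beta"] = beta
    table["se"] = se
    table["p_value"] = np.clip(pval, np.nextafter(0, 1), 1.0)
    table["loglik"] = loglik
    res = AssociationResult(table, method="lmm", n_samples=n)
    return res


def _lmm_scan_fixed(null: LMMNull, G: np.ndarray, G_rot: np.ndarray, log10_delta: float):
    S, y_rot, X_rot = null.eigenvalues, null.y_rot, null.X_rot
    n, p = X_rot.shape
    m = G_rot.shape[1]
    delta = 10.0**log10_delta
    w = 1.0 / (S + delta)

    Xw = X_rot * w[:, None]
    A = X_rot.T @ Xw
    Ainv = np.linalg.inv(A)
    c = Xw.T @ y_rot
    beta0 = Ainv @ c
    rss_null = float((w * y_rot**2).sum()) - float(c @ beta0)

    WG = G_rot * w[:, None]
    gtWg = np.einsum("ij,ij->j", G_rot, WG)
    B = X_rot.T @ WG  # p x m
    gtWy = WG.T @ y_rot
    AinvB = Ainv @ B
    s = gtWg - np.einsum("ij,ij->j", B, AinvB)  # Schur complement
    num = gtWy - B.T @ beta0

    # unweighted Schur complement, for the REML determinant of [X g]
    XtX_inv = np.linalg.inv(null.X.T @ null.X)
    BX = null.X.T @ G
    s0 = np.einsum("ij,ij->j", G, G) - np.einsum("ij,ij->j", BX, XtX_inv @ BX)

    ok = (s > _TINY) & (s0 > _TINY)
    beta = np.zeros(m)
    se = np.full(m, np.nan)
    pval = np.ones(m)
    loglik = np.full(m, np.nan)

    beta[ok] = num[ok] / s[ok]
    rss = np.maximum(rss_null - beta[ok] ** 2 * s[ok], 0.0)
    dof = n - p - 1 if null.reml else n
    sigma_g2 = np.maximum(rss / dof, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        se[ok] = np.sqrt(sigma_g2 / s[ok])
        chi2 = (beta[ok] / se[ok]) ** 2
    pval[ok] = stats.chi2.sf(chi2, df=1)

    ll = -0.5 * (
        dof * np.log(2.0 * np.pi * sigma_g2) + np.log(S + delta).sum() + dof
    )
    if null.reml:
        _, logdet_A = np.linalg.slogdet(A)
        logdet_A2 = logdet_A + np.log(s[ok])
        logdet_X2 = null.logdet_XtX + np.log(s0[ok])
        ll -= 0.5 * (logdet_A2 - logdet_X2)
    loglik[ok] = ll
    return beta, se, pval, loglik


def _lmm_scan_refit(null: LMMNull, G: np.ndarray, G_rot: np.ndarray):
    n, p = null.X_rot.shape
    m = G_rot.shape[1]
    S, y_rot = null.eigenvalues, null.y_rot
    beta = np.zeros(m)
    se = np.full(m, np.nan)
    pval = np.ones(m)
    loglik = np.full(m, np.nan)
    lo, hi = -5.0, 5.0
    grid = np.linspace(lo, hi, 100)
    for j in range(m):
        g = G[:, j]
        if g.var() <= _TINY:
            continue
        X2_rot = np.column_stack([null.X_rot, G_rot[:, j]])
        X2 = np.column_stack([null.X, g])
        _, logdet_X2 = np.linalg.slogdet(X2.T @ X2)
        nll = np.array(
            [_reml_neg_loglik(t, S, y_rot, X2_rot, logdet_X2, null.reml) for t in grid]
        )
        i = int(np.argmin(nll))
        best = grid[i]
        if 0 < i < len(grid) - 1:
            res = optimize.minimize_scalar(
                _reml_neg_loglik,
                bracket=(grid[i - 1], grid[i], grid[i + 1]),
                args=(S, y_rot, X2_rot, logdet_X2, null.reml),
                method="golden",
                options={"xtol": 1e-8},
            )
            if res.fun <= nll[i]:
                best = float(res.x)
        b, s_, pv, ll = _snp_stats_at(best, S, y_rot, X2_rot, null.reml, logdet_X2)
        beta[j], se[j], pval[j], loglik[j] = b, s_, pv, ll
    return beta, se, pval, loglik


def _snp_stats_at(log10_delta, S, y_rot, X2_rot, reml, logdet_X2):
    delta = 10.0**log10_delta
    w = 1.0 / (S + delta)
    Xw = X2_rot * w[:, None]
    A = X2_rot.T @ Xw
    Ainv = np.linalg.inv(A)
    betas = Ainv @ (Xw.T @ y_rot)
    r = y_rot - X2_rot @ betas
    n, p2 = X2_rot.shape
    dof = n - p2 if reml else n
    sigma_g2 = max(float((w * r * r).sum()) / dof, 1e-300)
    se = float(np.sqrt(sigma_g2 * Ainv[-1, -1]))
    chi2 = (betas[-1] / se) ** 2 if se > 0 else np.inf
    pv = float(stats.chi2.sf(chi2, df=1))
    ll = -0.5 * (dof * np.log(2.0 * np.pi * sigma_g2) + np.log(S + delta).sum() + dof)
    if reml:
        _, logdet_A = np.linalg.slogdet(A)
        ll -= 0.5 * (logdet_A - logdet_X2)
    return float(betas[-1]), se, pv, float(ll)


def genomic_inflation(p_values) -> float:
    """Genomic inflation factor lambda_GC: the median association
    chi-square statistic over the null chi-square(1) median (0.4549)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("p-value vector is empty")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_MEDIAN_1DF)
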