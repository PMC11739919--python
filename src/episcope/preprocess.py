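"""Methylation and phenotype preprocessing.

Covers the beta -> M transform, sample quantile normalization, SD-based
outlier masking, per-CpG pre-correction of M-values for age/sex/batch, and
kinship-aware phenotype residualization via a REML linear mixed model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import rankdata

from .containers import BETA, CORRECTED_M, M, MethylationMatrix

__all__ = [
    "beta_to_m",
    "m_to_beta",
    "quantile_normalize",
    "remove_outliers",
    "precorrect_m_values",
    "fit_kinship_lmm",
    "ResidualizedPhenotype",
]

_EPS = 1e-6


def beta_to_m(betas: MethylationMatrix, eps: float = _EPS) -> MethylationMatrix:
    """M = log2(beta / (1 - beta)); betas clipped to [eps, 1-eps] first.

    Missing entries stay missing.
    """
    if betas.scale != BETA:
        raise ValueError(f"expected beta-scale input, got {betas.scale!r}")
    v = np.clip(betas.values, eps, 1.0 - eps)
    v[~np.isfinite(betas.values)] = np.nan
    m = np.log2(v / (1.0 - v))
    return MethylationMatrix(m, betas.sample_ids, betas.cpg_ids, scale=M)


def m_to_beta(mat: MethylationMatrix) -> MethylationMatrix:
    """Inverse of :func:`beta_to_m`: beta = 2^M / (1 + 2^M)."""
    if mat.scale == BETA:
        raise ValueError("input is already on the beta scale")
    b = 1.0 / (1.0 + 2.0 ** (-mat.values))
    return MethylationMatrix(b, mat.sample_ids, mat.cpg_ids, scale=BETA)


def quantile_normalize(mat: MethylationMatrix) -> MethylationMatrix:
    """Force identical per-sample empirical distributions.

    Each sample's sorted values are replaced by the across-sample mean of the
    order statistics; ties receive the mean of their tied ranks.  Missing
    entries are left missing and excluded from the reference distribution
    (samples must share the same missingness count for exact exchange;
    otherwise ranks are interpolated onto the reference grid).
    """
    if mat.n_samples < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    X = mat.values
    if (~np.isfinite(X)).all(axis=1).any():
        raise ValueError("sample with all values missing")
    if np.isfinite(X).all():
        order = np.sort(X, axis=1)
        ref = order.mean(axis=0)
        ranks = rankdata(X, axis=1)  # average rank for ties
        grid = np.arange(1, X.shape[1] + 1, dtype=float)
        out = np.vstack([np.interp(ranks[i], grid, ref) for i in range(X.shape[0])])
    else:
        n_obs = np.isfinite(X).sum(axis=1)
        grid = np.linspace(0.0, 1.0, 1001)
        ref = np.mean(
            [np.quantile(X[i][np.isfinite(X[i])], grid) for i in range(X.shape[0])],
            axis=0,
        )
        out = np.full_like(X, np.nan)
        for i in range(X.shape[0]):
            obs = np.isfinite(X[i])
            r = rankdata(X[i, obs])
            q = (r - 0.5) / n_obs[i]
            out[i, obs] = np.interp(q, grid, ref)
    return MethylationMatrix(out, mat.sample_ids, mat.cpg_ids, scale=mat.scale)


def remove_outliers(values: np.ndarray, k_sd: float = 4.0, warn_cap: float = 0.01) -> np.ndarray:
    """Keep-mask: False where |x - mean| > k_sd * SD (computed once).

    Zero-variance input keeps everything.  A warning is emitted when more than
    ``warn_cap`` of the observations are masked.
    """
    if k_sd <= 0:
        raise ValueError("k_sd must be > 0")
    v = np.asarray(values, dtype=float)
    obs = np.isfinite(v)
    mask = np.ones(v.shape, dtype=bool)
    if obs.sum() < 2:
        return mask
    mu = v[obs].mean()
    sd = v[obs].std(ddof=1)
    if sd == 0 or not np.isfinite(k_sd):
        return mask
    mask[obs] = np.abs(v[obs] - mu) <= k_sd * sd
    frac = 1.0 - mask[obs].mean()
    if frac > warn_cap:
        warnings.warn(f"outlier rule removed {frac:.1%} of observations (cap {warn_cap:.0%})")
    return mask


def precorrect_m_values(
    mat: MethylationMatrix, covariates: pd.DataFrame
) -> MethylationMatrix:
    """Residualize each CpG's M-values on intercept + age + sex + batch.

    ``covariates`` must be indexed by sample ID with columns ``age``, ``sex``
    and categorical ``batch``.  Batches with a single sample are merged into
    the reference level with a warning.  Missing methylation entries are
    excluded per CpG and remain missing in the output.
    """
    if mat.scale not in (M, CORRECTED_M):
        raise ValueError("pre-correction expects M-values")
    cov = covariates.loc[mat.sample_ids]
    batch = cov["batch"].astype(str).copy()
    counts = batch.value_counts()
    singletons = counts[counts < 2].index
    if len(singletons):
        warnings.warn(f"{len(singletons)} batch(es) with a single sample merged into reference")
        ref = counts.idxmax()
        batch[batch.isin(singletons)] = ref
    dummies = pd.get_dummies(batch, drop_first=True, dtype=float)
    Z = np.column_stack(
        [
            np.ones(mat.n_samples),
            cov["age"].to_numpy(dtype=float),
            cov["sex"].to_numpy(dtype=float),
            dummies.to_numpy(),
        ]
    )
    X = mat.values
    out = np.full_like(X, np.nan)
    complete = np.isfinite(X).all(axis=0)
    if complete.any():
        coef, *_ = np.linalg.lstsq(Z, X[:, complete], rcond=None)
        out[:, complete] = X[:, complete] - Z @ coef
    for j in np.where(~complete)[0]:
        obs = np.isfinite(X[:, j])
        if obs.sum() <= Z.shape[1]:
            continue  # too few observations; stays missing
        coef, *_ = np.linalg.lstsq(Z[obs], X[obs, j], rcond=None)
        out[obs, j] = X[obs, j] - Z[obs] @ coef
    return MethylationMatrix(out, mat.sample_ids, mat.cpg_ids, scale=CORRECTED_M)


@dataclass
class ResidualizedPhenotype:
    """Phenotype residuals after fixed effects + family random effect."""

    trait_name: str
    residuals: pd.Series  # indexed by sample ID
    variance_components: dict  # sigma2_g, sigma2_e, lambda
    fixed_effects: pd.Series  # intercept, age, age2, sex coefficients


def _reml_neg_loglik(log_lam: float, d: np.ndarray, yt: np.ndarray, Xt: np.ndarray) -> float:
    lam = np.exp(log_lam)
    w = lam * d + 1.0
    Xw = Xt / w[:, None]
    XtWX = Xt.T @ Xw
    XtWy = Xw.T @ yt
    b = np.linalg.solve(XtWX, XtWy)
    r = yt - Xt @ b
    n, k = Xt.shape
    rss = float(r @ (r / w))
    sig2e = rss / (n - k)
    sign, logdet = np.linalg.slogdet(XtWX)
    return 0.5 * ((n - k) * np.log(sig2e) + np.log(w).sum() + logdet)


def fit_kinship_lmm(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    sample_ids=None,
    trait_name: str = "trait",
    residual_type: str = "conditional",
    fixed_effect_names=None,
) -> ResidualizedPhenotype:
    """REML mixed model ``y = Xb + g + e`` with ``g ~ N(0, sigma2_g * 2K)``.

    The kinship matrix is doubled so a 0.5 entry (first-degree relatives)
    yields full sharing of the family effect.  REML maximizes over
    ``lambda = sigma2_g / sigma2_e`` by Brent search on log-lambda in
    [-10, 10] after eigendecomposition of 2K.  ``residual_type`` selects
    conditional (``y - Xb - BLUP(g)``, default) or marginal (``y - Xb``)
    residuals.

    When 2K is indistinguishable from a scaled identity the variance
    components are not separately identifiable; sigma2_g is set to 0 and OLS
    residuals are returned (documented equivalence).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    K = np.asarray(K, dtype=float)
    n = y.size
    if X.shape[0] != n or K.shape != (n, n):
        raise ValueError("inconsistent shapes for y, X, K")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular fixed-effect design")
    if residual_type not in ("conditional", "marginal"):
        raise ValueError("residual_type must be 'conditional' or 'marginal'")

    A = 2.0 * K
    names = list(fixed_effect_names) if fixed_effect_names is not None else [
        f"b{i}" for i in range(X.shape[1])
    ]
    ids = list(sample_ids) if sample_ids is not None else list(range(n))

    # identity-equivalent kinship: random effect absorbed into the residual
    c = np.median(np.diag(A))
    if np.abs(A - c * np.eye(n)).max() < 1e-10:
        b, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ b
        sig2e = float(resid @ resid / (n - X.shape[1]))
        return ResidualizedPhenotype(
            trait_name,
            pd.Series(resid, index=ids, name="residual"),
            {"sigma2_g": 0.0, "sigma2_e": sig2e, "lambda": 0.0},
            pd.Series(b, index=names),
        )

    d, U = np.linalg.eigh(A)
    if d.min() < -1e-8:
        raise ValueError(f"kinship not PSD (min eigenvalue {d.min():.3g})")
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X

    res = minimize_scalar(
        _reml_neg_loglik,
        bounds=(-10.0, 10.0),
        args=(d, yt, Xt),
        method="bounded",
        options={"xatol": 1e-6},
    )
    lam = float(np.exp(res.x))
    # prefer the boundary when the optimum is flat towards lambda -> 0
    if _reml_neg_loglik(-10.0, d, yt, Xt) <= res.fun + 1e-10:
        lam = np.exp(-10.0)

    w = lam * d + 1.0
    Xw = Xt / w[:, None]
    b = np.linalg.solve(Xt.T @ Xw, Xw.T @ yt)
    rt = yt - Xt @ b
    sig2e = float(rt @ (rt / w) / (n - X.shape[1]))
    sig2g = lam * sig2e

    if residual_type == "conditional":
        resid = U @ (rt / w)  # y - Xb - BLUP(g)
    else:
        resid = U @ rt
    return ResidualizedPhenotype(
        trait_name,
        pd.Series(resid, index=ids, name="residual"),
        {"sigma2_g": sig2g, "sigma2_e": sig2e, "lambda": lam},
        pd.Series(b, index=names),
    )


def residualize_trait(
    pheno: pd.DataFrame,
    trait: str,
    kinship: np.ndarray,
    residual_type: str = "conditional",
    outlier_k_sd: float = 4.0,
) -> ResidualizedPhenotype:
    """Convenience wrapper: outlier-mask the trait, then residualize on
    intercept + centered age + centered-age^2 + sex + family structure.

    Outlier-masked samples are dropped from the fit; their residuals are NaN.
    """
    y_all = pheno[trait].to_numpy(dtype=float)
    keep = remove_outliers(y_all, k_sd=outlier_k_sd) & np.isfinite(y_all)
    age = pheno["age"].to_numpy(dtype=float)
    age_c = age - age[keep].mean()
    X = np.column_stack(
        [np.ones(len(pheno)), age_c, age_c**2, pheno["sex"].to_numpy(dtype=float)]
    )
    idx = np.where(keep)[0]
    fit = fit_kinship_lmm(
        y_all[idx],
        X[idx],
        kinship[np.ix_(idx, idx)],
        sample_ids=[pheno.index[i] for i in idx],
        trait_name=trait,
        residual_type=residual_type,
        fixed_effect_names=["intercept", "age", "age2", "sex"],
    )
    full = pd.Series(np.nan, index=pheno.index, name="residual")
    full.loc[fit.residuals.index] = fit.residuals
    fit.residuals = full
    return fit
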