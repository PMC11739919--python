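"""Marginal (per-CpG) EWAS with inflation/bias correction.

Each CpG is tested separately by OLS of the residualized trait on the
standardized CpG plus fixed covariates.  Genomic inflation is summarized by
lambda_GC; bias and inflation of the z-scores can be corrected with an
empirical-Bayes three-component Gaussian mixture fitted by Gibbs sampling
(the "bacon" approach).  Independent signals among significant CpGs are
counted as the number of principal components needed for >= 80% of their
variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MethylationMatrix
from .preprocess import ResidualizedPhenotype

__all__ = [
    "EwasResult",
    "BaconFit",
    "run_marginal_ewas",
    "call_significant",
    "fit_bacon",
    "apply_bacon",
    "count_independent_signals",
    "cross_trait_overlap",
    "annotate_cpgs",
    "lambda_gc",
]

GENOME_WIDE_P = 3.6e-8  # EWAS significance level (simulation-derived threshold)
_CHI2_NULL_MEDIAN = 0.4549364231195724  # median of chi-square with 1 df


@dataclass
class EwasResult:
    """Per-CpG summary statistics for one trait and model."""

    trait_name: str
    table: pd.DataFrame  # index cpg_id: effect, se, t, p, n_used
    model_tag: str  # base | pc_adjusted | bacon_corrected
    lambda_gc: float

    def zscores(self) -> np.ndarray:
        """Signed normal-scale z-scores derived from two-sided p-values."""
        tb = self.table
        return np.sign(tb["t"].to_numpy()) * stats.norm.isf(tb["p"].to_numpy() / 2.0)


def lambda_gc(p: np.ndarray) -> float:
    """Genomic inflation factor: median association chi-square / 0.4549."""
    p = np.asarray(p, dtype=float)
    p = p[np.isfinite(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / _CHI2_NULL_MEDIAN)


def run_marginal_ewas(
    pheno: ResidualizedPhenotype,
    mat: MethylationMatrix,
    covariates: pd.DataFrame | None = None,
    model_tag: str = "base",
) -> EwasResult:
    """OLS of the residualized trait on each standardized CpG + covariates.

    CpGs are standardized (per used samples) so effects are per SD of
    corrected-M.  Samples missing a CpG are dropped for that CpG only.
    Two-sided p-values use the Student-t reference with df = n_used minus the
    number of fitted parameters.  Covariate collinearity (condition number
    above 1e10) is rejected.
    """
    y_all = pheno.residuals.loc[mat.sample_ids].to_numpy(dtype=float)
    base_keep = np.isfinite(y_all)

    if covariates is not None:
        C = covariates.loc[mat.sample_ids].to_numpy(dtype=float)
        base_keep &= np.isfinite(C).all(axis=1)
    else:
        C = np.zeros((len(y_all), 0))

    y = y_all[base_keep]
    Z = np.column_stack([np.ones(base_keep.sum()), C[base_keep]])
    if np.linalg.cond(Z) > 1e10:
        raise ValueError("covariate design is collinear (condition number > 1e10)")
    X = mat.values[base_keep]
    n, k = Z.shape
    dfree = n - k - 1

    # hat-matrix pieces shared across CpGs (complete-case CpGs, FWL form)
    ZtZ_inv = np.linalg.inv(Z.T @ Z)
    ry = y - Z @ (ZtZ_inv @ (Z.T @ y))

    p_cpg = mat.n_cpgs
    effect = np.full(p_cpg, np.nan)
    se = np.full(p_cpg, np.nan)
    tstat = np.full(p_cpg, np.nan)
    pval = np.full(p_cpg, np.nan)
    n_used = np.zeros(p_cpg, dtype=int)

    finite = np.isfinite(X)
    complete = finite.all(axis=0)
    dropped: list[str] = []

    if complete.any():
        Xc = X[:, complete]
        mu = Xc.mean(axis=0)
        sd = Xc.std(axis=0)
        ok = sd > 0
        idx_complete = np.where(complete)[0]
        for j in idx_complete[~ok]:
            dropped.append(mat.cpg_ids[j])
        use = idx_complete[ok]
        Xs = (Xc[:, ok] - mu[ok]) / sd[ok]
        Rx = Xs - Z @ (ZtZ_inv @ (Z.T @ Xs))
        cj = (Rx * Rx).sum(axis=0)
        bj = (Rx * ry[:, None]).sum(axis=0) / cj
        rss = float(ry @ ry) - bj**2 * cj
        s2 = rss / dfree
        se_j = np.sqrt(s2 / cj)
        t_j = bj / se_j
        effect[use] = bj
        se[use] = se_j
        tstat[use] = t_j
        pval[use] = 2.0 * stats.t.sf(np.abs(t_j), dfree)
        n_used[use] = n

    for j in np.where(~complete)[0]:
        obs = finite[:, j]
        nj = int(obs.sum())
        if nj <= k + 2:
            dropped.append(mat.cpg_ids[j])
            continue
        xj = X[obs, j]
        sdj = xj.std()
        if sdj == 0:
            dropped.append(mat.cpg_ids[j])
            continue
        xs = (xj - xj.mean()) / sdj
        D = np.column_stack([Z[obs], xs])
        coef, res_ss, rank, _ = np.linalg.lstsq(D, y[obs], rcond=None)
        r = y[obs] - D @ coef
        rss_j = float(r @ r)
        dfj = nj - D.shape[1]
        XtX_inv = np.linalg.inv(D.T @ D)
        se_b = np.sqrt(rss_j / dfj * XtX_inv[-1, -1])
        effect[j] = coef[-1]
        se[j] = se_b
        tstat[j] = coef[-1] / se_b
        pval[j] = 2.0 * stats.t.sf(abs(tstat[j]), dfj)
        n_used[j] = nj

    if dropped:
        warnings.warn(f"{len(dropped)} CpGs dropped (degenerate or too few observations)")

    table = pd.DataFrame(
        {"effect": effect, "se": se, "t": tstat, "p": pval, "n_used": n_used},
        index=pd.Index(mat.cpg_ids, name="cpg_id"),
    )
    lam = lambda_gc(pval)
    return EwasResult(pheno.trait_name, table, model_tag, lam)


def call_significant(result: EwasResult, threshold: float = GENOME_WIDE_P) -> list[str]:
    """CpG IDs with p strictly below the threshold, sorted by p then ID."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    tb = result.table
    if threshold == 1.0:
        hit = tb[np.isfinite(tb["p"])]
    else:
        hit = tb[tb["p"] < threshold]
    order = hit.reset_index().sort_values(["p", "cpg_id"], kind="mergesort")
    return list(order["cpg_id"])


@dataclass
class BaconFit:
    """Three-component Gaussian mixture fit to z-scores.

    The central null component carries the bias (its mean) and inflation (its
    SD); two tail components with sign-constrained means absorb true signal.
    """

    bias_mu: float
    inflation_sigma: float
    mixture_weights: np.ndarray  # (null, negative tail, positive tail)
    tail_means: np.ndarray
    tail_sds: np.ndarray
    n_iterations: int
    seed: int
    rhat_mu: float = 1.0
    converged: bool = True


def _bacon_chain(z, rng, n_iter, burn):
    n = z.size
    mu = np.array([np.median(z), np.median(z) - 3.0, np.median(z) + 3.0])
    mad = 1.4826 * np.median(np.abs(z - mu[0]))
    sig2 = np.array([mad**2, 1.0, 1.0])
    w = np.array([0.9, 0.05, 0.05])
    # weakly informative conjugate hyperparameters
    m0 = np.array([0.0, -4.0, 4.0])
    tau2 = np.array([100.0, 4.0, 4.0])
    a0, b0 = 2.0, 1.0

    keep_mu, keep_sig, keep_w = [], [], []
    keep_tm, keep_ts = [], []
    for it in range(n_iter):
        # assignments
        logp = np.stack(
            [
                np.log(w[k] + 1e-300) - 0.5 * np.log(2 * np.pi * sig2[k])
                - 0.5 * (z - mu[k]) ** 2 / sig2[k]
                for k in range(3)
            ]
        )
        logp -= logp.max(axis=0)
        prob = np.exp(logp)
        prob /= prob.sum(axis=0)
        u = rng.random(n)
        assign = (u > prob[0]).astype(int) + (u > prob[0] + prob[1]).astype(int)

        counts = np.bincount(assign, minlength=3).astype(float)
        # null-favoring Dirichlet prior (pseudo-counts n/10, 1, 1): under a
        # pure null the tail weights must drift to ~0 or they trim the null's
        # variance; genuine signal still overwhelms the prior odds
        w = rng.dirichlet(counts + np.array([0.1 * n, 1.0, 1.0]))

        for k in range(3):
            sel = assign == k
            nk = counts[k]
            zbar = z[sel].mean() if nk else 0.0
            prec = nk / sig2[k] + 1.0 / tau2[k]
            mean = (nk * zbar / sig2[k] + m0[k] / tau2[k]) / prec
            draw = mean + rng.normal() / np.sqrt(prec)
            # tail means are kept at least 1.5 null-SDs away from the null
            # mean; without the gap the tails leak into the null under a
            # pure-null input and deflate the inflation estimate
            gap = 1.5 * np.sqrt(sig2[0])
            if k == 1:  # negative tail
                bound = mu[0] - gap
                mu[k] = bound - abs(draw - bound) if draw > bound else draw
            elif k == 2:  # positive tail
                bound = mu[0] + gap
                mu[k] = bound + abs(draw - bound) if draw < bound else draw
            else:
                mu[k] = draw
            ss = ((z[sel] - mu[k]) ** 2).sum() if nk else 0.0
            sig2[k] = 1.0 / rng.gamma(a0 + nk / 2.0, 1.0 / (b0 + 0.5 * ss))

        if it >= burn:
            keep_mu.append(mu[0])
            keep_sig.append(np.sqrt(sig2[0]))
            keep_w.append(w.copy())
            keep_tm.append(mu[1:].copy())
            keep_ts.append(np.sqrt(sig2[1:]))
    return (
        np.array(keep_mu),
        np.array(keep_sig),
        np.array(keep_w),
        np.array(keep_tm),
        np.array(keep_ts),
    )


def fit_bacon(
    z: np.ndarray, seed: int = 42, n_iterations: int = 5000, burn_in: int = 2000
) -> BaconFit:
    """Fit the bias/inflation mixture to z-scores by Gibbs sampling.

    Two chains with derived seeds are run; the potential scale reduction
    factor of the null mean across chains above 1.1 flags non-convergence
    with a warning.  Posterior means are reported over pooled post-burn-in
    draws.
    """
    z = np.asarray(z, dtype=float)
    z = z[np.isfinite(z)]
    if z.size < 1000:
        warnings.warn(f"only {z.size} z-scores; bacon fit may be unstable")
    ss = np.random.SeedSequence(seed)
    chains = [
        _bacon_chain(z, np.random.default_rng(s), n_iterations, burn_in)
        for s in ss.spawn(2)
    ]
    mus = [c[0] for c in chains]
    # split-free 2-chain PSRF on the null mean
    m = min(len(c) for c in mus)
    arr = np.stack([c[:m] for c in mus])
    W = arr.var(axis=1, ddof=1).mean()
    B = m * arr.mean(axis=1).var(ddof=1)
    rhat = float(np.sqrt(((m - 1) / m * W + B / m) / W)) if W > 0 else 1.0
    converged = rhat <= 1.1
    if not converged:
        warnings.warn(f"bacon chains not converged (R-hat {rhat:.3f} > 1.1)")

    mu_hat = float(np.mean(np.concatenate(mus)))
    sig_hat = float(np.mean(np.concatenate([c[1] for c in chains])))
    wts = np.mean(np.concatenate([c[2] for c in chains]), axis=0)
    tail_m = np.mean(np.concatenate([c[3] for c in chains]), axis=0)
    tail_s = np.mean(np.concatenate([c[4] for c in chains]), axis=0)
    return BaconFit(
        bias_mu=mu_hat,
        inflation_sigma=sig_hat,
        mixture_weights=wts,
        tail_means=tail_m,
        tail_sds=tail_s,
        n_iterations=n_iterations,
        seed=seed,
        rhat_mu=rhat,
        converged=converged,
    )


def apply_bacon(result: EwasResult, fit: BaconFit) -> EwasResult:
    """Rescale statistics: z' = (z - mu)/sigma, SE' = SE*sigma,
    effect' = effect - mu*SE; p recomputed from the normal reference."""
    tb = result.table.copy()
    z = result.zscores()
    mu, sig = fit.bias_mu, fit.inflation_sigma
    z_corr = (z - mu) / sig
    tb["effect"] = tb["effect"] - mu * tb["se"]
    tb["se"] = tb["se"] * sig
    tb["t"] = z_corr
    tb["p"] = 2.0 * stats.norm.sf(np.abs(z_corr))
    return EwasResult(result.trait_name, tb, "bacon_corrected", lambda_gc(tb["p"]))


def count_independent_signals(
    mat: MethylationMatrix, significant_ids: list[str], variance_target: float = 0.80
) -> int:
    """Number of PCs explaining >= ``variance_target`` of the significant CpGs.

    PCA is run on the standardized significant-CpG submatrix; returns the
    smallest k whose cumulative variance fraction reaches the target (small
    numerical slack so analytic ties such as 4/5 = 0.8 count as reached).
    """
    if not significant_ids:
        raise ValueError("need at least one significant CpG")
    if len(significant_ids) == 1:
        return 1
    sub = mat.subset_cpgs(significant_ids)
    X = sub.values
    if np.isnan(X).any():
        X = np.where(np.isfinite(X), X, np.nanmean(X, axis=0))
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - X.mean(axis=0)) / sd
    ev = np.linalg.svd(X, compute_uv=False) ** 2
    frac = np.cumsum(ev) / ev.sum()
    return int(np.searchsorted(frac, variance_target - 1e-9) + 1)


def cross_trait_overlap(results: dict[str, list[str]]) -> list[str]:
    """Sorted intersection of significant CpG lists across all traits."""
    if len(results) < 2:
        raise ValueError("need significant lists for >= 2 traits")
    sets = [set(v) for v in results.values()]
    return sorted(set.intersection(*sets))


def annotate_cpgs(ids: list[str], manifest: pd.DataFrame) -> pd.DataFrame:
    """Left-join CpG IDs onto an array manifest (cpg_id, chrom, position, gene).

    Positions follow the manifest's 1-based hg19 convention.  Unmapped CpGs
    get empty gene/chrom fields and ``unmapped=True``; duplicate manifest rows
    keep the first occurrence with a warning.
    """
    required = {"cpg_id", "chrom", "position", "gene"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    man = manifest.copy()
    man["cpg_id"] = man["cpg_id"].astype(str)
    if man["cpg_id"].duplicated().any():
        warnings.warn("duplicate manifest rows; keeping first occurrence per CpG")
        man = man.drop_duplicates("cpg_id", keep="first")
    out = pd.DataFrame({"cpg_id": [str(i) for i in ids]}).merge(
        man[["cpg_id", "chrom", "position", "gene"]], on="cpg_id", how="left"
    )
    out["unmapped"] = out["chrom"].isna()
    out["gene"] = out["gene"].fillna("")
    out["chrom"] = out["chrom"].fillna("")
    return out
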