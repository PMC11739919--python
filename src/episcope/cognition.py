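"""Latent growth modeling of general cognitive function and trait associations.

A per-person latent level (intercept) and per-year change (slope) of general
cognitive function are estimated from multi-test, multi-wave data with a
two-stage procedure: (1) a single common factor across tests, with loadings
taken from the first eigenvector of the pooled within-wave covariance and
fixed across waves; (2) a random-intercept random-slope linear mixed model of
the factor scores on years since baseline, giving empirical-Bayes person
estimates.  Predictors (measured traits or EpiScores) are then tested against
intercept and slope in separate OLS models with Benjamini-Hochberg FDR
control within each outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GrowthEstimates",
    "AssociationResult",
    "fit_growth_model",
    "test_associations",
    "variance_decomposition",
]


@dataclass
class GrowthEstimates:
    """Per-sample latent intercept/slope with loadings and variance components."""

    estimates: pd.DataFrame  # index sample_id: intercept_hat, slope_hat, n_waves_used
    loadings: pd.Series  # per test, mean-1 normalization
    variance_components: dict  # intercept_var, slope_var, cov, residual_var
    n_samples: int


def _factor_loadings(wide: pd.DataFrame) -> pd.Series:
    """First-eigenvector loadings from the pooled (per-wave-centered) covariance."""
    cov = wide.cov().to_numpy()
    vals, vecs = np.linalg.eigh(cov)
    lead = vecs[:, -1]
    if lead.sum() < 0:
        lead = -lead
    if np.any(lead <= 0):
        warnings.warn("non-positive loading in leading factor; check test coding")
    lam = lead / lead.mean()
    return pd.Series(lam, index=wide.columns, name="loading")


def fit_growth_model(scores: pd.DataFrame, min_tests: int = 1) -> GrowthEstimates:
    """Estimate latent intercept (baseline level) and slope (per year).

    ``scores`` is long-format with columns sample_id, wave, age, test_name,
    score.  Time is years since each sample's first observed wave.  Samples
    with a single wave contribute to the intercept only (their slope is the
    shrunk population slope).  Samples with zero observed tests are dropped.
    """
    required = {"sample_id", "wave", "age", "test_name", "score"}
    if not required.issubset(scores.columns):
        raise ValueError(f"scores needs columns {sorted(required)}")
    df = scores.dropna(subset=["score"]).copy()
    n_dropped = scores["sample_id"].nunique() - df["sample_id"].nunique()
    if n_dropped:
        warnings.warn(f"{n_dropped} sample(s) dropped with zero observed tests")
    if df["test_name"].nunique() < 2 or df["wave"].nunique() < 2:
        raise ValueError("need >= 2 tests and >= 2 waves")

    wide = df.pivot_table(
        index=["sample_id", "wave", "age"], columns="test_name", values="score"
    ).reset_index()
    tests = [c for c in wide.columns if c not in ("sample_id", "wave", "age")]
    centered = wide.copy()
    centered[tests] = wide.groupby("wave")[tests].transform(lambda g: g - g.mean())
    lam = _factor_loadings(centered[tests])

    # factor score: loading-weighted projection over available tests
    T = wide[tests].to_numpy(dtype=float)
    L = lam.to_numpy()
    obs = np.isfinite(T)
    num = np.nansum(np.where(obs, T * L, 0.0), axis=1)
    den = (obs * L**2).sum(axis=1)
    fac = pd.DataFrame(
        {
            "sample_id": wide["sample_id"],
            "age": wide["age"].astype(float),
            "f": num / np.where(den > 0, den, np.nan),
        }
    ).dropna(subset=["f"])
    baseline = fac.groupby("sample_id")["age"].transform("min")
    fac["time"] = fac["age"] - baseline

    # degenerate noiseless data: per-sample lines fit exactly; skip the LMM
    est = _per_sample_ols(fac)
    resid_max = est["max_resid"].max()
    nw = fac.groupby("sample_id")["time"].nunique()
    if resid_max < 1e-8 and (nw >= 2).all():
        out = est.rename(columns={"b0": "intercept_hat", "b1": "slope_hat"})
        out["n_waves_used"] = nw
        return GrowthEstimates(
            estimates=out[["intercept_hat", "slope_hat", "n_waves_used"]],
            loadings=lam,
            variance_components={
                "intercept_var": float(out["intercept_hat"].var()),
                "slope_var": float(out["slope_hat"].var()),
                "intercept_slope_cov": float(
                    out[["intercept_hat", "slope_hat"]].cov().iloc[0, 1]
                ),
                "residual_var": 0.0,
            },
            n_samples=len(out),
        )

    endog = fac["f"].to_numpy()
    exog = sm.add_constant(fac["time"].to_numpy())
    exog_re = exog
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(endog, exog, groups=fac["sample_id"].to_numpy(), exog_re=exog_re)
        fit = model.fit(reml=True)
        if not fit.converged:  # pragma: no cover - optimizer fallback
            fit = model.fit(reml=True, method="bfgs", maxiter=1000)

    fe_int, fe_slope = fit.fe_params
    re = fit.random_effects
    rows = []
    for sid, g in fac.groupby("sample_id"):
        r = np.asarray(re.get(sid, np.zeros(2)), dtype=float)
        rows.append((sid, fe_int + r[0], fe_slope + r[1], g["time"].nunique()))
    out = pd.DataFrame(
        rows, columns=["sample_id", "intercept_hat", "slope_hat", "n_waves_used"]
    ).set_index("sample_id")

    cov_re = np.asarray(fit.cov_re)  # already on the variance scale
    return GrowthEstimates(
        estimates=out,
        loadings=lam,
        variance_components={
            "intercept_var": float(cov_re[0, 0]),
            "slope_var": float(cov_re[1, 1]),
            "intercept_slope_cov": float(cov_re[0, 1]),
            "residual_var": float(fit.scale),
        },
        n_samples=len(out),
    )


def _per_sample_ols(fac: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for sid, g in fac.groupby("sample_id"):
        t = g["time"].to_numpy(dtype=float)
        f = g["f"].to_numpy(dtype=float)
        if np.unique(t).size >= 2:
            b1, b0 = np.polyfit(t, f, 1)
            resid = np.abs(f - (b0 + b1 * t)).max()
        else:
            b0, b1, resid = f.mean(), np.nan, np.inf
        rows.append((sid, b0, b1, resid))
    return pd.DataFrame(rows, columns=["sample_id", "b0", "b1", "max_resid"]).set_index(
        "sample_id"
    )


@dataclass
class AssociationResult:
    """Standardized predictor-outcome associations with FDR control."""

    table: pd.DataFrame  # predictor, outcome, beta, se, p, p_fdr, n, model_tag
    model_tag: str


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("constant predictor/outcome")
    return (v - v.mean()) / sd


def test_associations(
    growth: GrowthEstimates,
    predictors: pd.DataFrame,
    covariates: pd.DataFrame,
    model_tag: str = "basic",
    outcomes: tuple[str, ...] = ("intercept", "slope"),
) -> AssociationResult:
    """OLS of each (standardized) cognitive outcome on each predictor.

    One model per predictor-outcome pair with the covariates as fixed terms;
    BH FDR is applied across the predictor family within each outcome.
    """
    est = growth.estimates
    rows = []
    for outcome in outcomes:
        col = {"intercept": "intercept_hat", "slope": "slope_hat"}[outcome]
        pvals, meta = [], []
        for name in predictors.columns:
            d = pd.DataFrame({"y": est[col], "x": predictors[name]}).join(
                covariates, how="inner"
            ).dropna()
            y = _standardize(d["y"].to_numpy(dtype=float))
            x = _standardize(d["x"].to_numpy(dtype=float))
            Z = np.column_stack(
                [np.ones(len(d)), x, d[covariates.columns].to_numpy(dtype=float)]
            )
            coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
            resid = y - Z @ coef
            dfree = len(d) - Z.shape[1]
            s2 = float(resid @ resid) / dfree
            cov_b = s2 * np.linalg.inv(Z.T @ Z)
            se = float(np.sqrt(cov_b[1, 1]))
            t = coef[1] / se
            p = 2.0 * stats.t.sf(abs(t), dfree)
            pvals.append(p)
            meta.append((name, outcome, float(coef[1]), se, float(p), len(d)))
        p_fdr = multipletests(pvals, method="fdr_bh")[1] if pvals else []
        for (name, outc, b, se, p, n), q in zip(meta, p_fdr):
            rows.append((name, outc, b, se, p, float(q), n, model_tag))
    table = pd.DataFrame(
        rows,
        columns=["predictor", "outcome", "beta", "se", "p", "p_fdr", "n", "model_tag"],
    )
    return AssociationResult(table=table, model_tag=model_tag)


test_associations.__test__ = False  # a library function, not a pytest item


def variance_decomposition(
    growth: GrowthEstimates,
    measured: pd.Series,
    episcore: pd.Series,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Incremental R^2 on the cognitive intercept for measured trait,
    EpiScore, and both jointly, over an age+sex (covariates) base model."""
    d = pd.DataFrame(
        {
            "y": growth.estimates["intercept_hat"],
            "measured": measured,
            "episcore": episcore,
        }
    ).join(covariates, how="inner").dropna()
    y = d["y"].to_numpy(dtype=float)
    C = d[covariates.columns].to_numpy(dtype=float)

    def r2(X):
        Z = np.column_stack([np.ones(len(d)), X])
        coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
        r = y - Z @ coef
        tss = ((y - y.mean()) ** 2).sum()
        return float(1 - (r @ r) / tss)

    base = r2(C)
    rows = [
        ("measured_only", r2(np.column_stack([C, d["measured"]])) - base),
        ("episcore_only", r2(np.column_stack([C, d["episcore"]])) - base),
        ("combined", r2(np.column_stack([C, d[["measured", "episcore"]]])) - base),
    ]
    return pd.DataFrame(rows, columns=["model", "incremental_r2"]).assign(
        base_r2=base, n=len(d)
    )
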