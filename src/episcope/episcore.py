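"""EpiScore training, projection and evaluation.

Elastic-net methylation scores are trained on the intersected probe set of a
training and test cohort (lambda chosen by k-fold cross-validated MSE at
l1-ratio 0.5 by default), projected into test cohorts with training-mean
imputation of absent or missing CpGs, and evaluated as the incremental R^2
over an age+sex base model, overall and by subgroup.  Posterior-mean effect
sizes from the Bayesian EWAS can be projected the same way.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from .containers import MethylationMatrix
from .ewas_bayes import BayesPosterior
from .preprocess import ResidualizedPhenotype

__all__ = [
    "EpiScoreModel",
    "ProjectionResult",
    "intersect_probes",
    "train_elnet",
    "project_score",
    "bayes_score",
    "incremental_r2",
]


@dataclass
class EpiScoreModel:
    """Sparse CpG weights with training metadata.

    Weights are on the standardized-CpG scale; ``training_cpg_means`` and
    ``training_cpg_sds`` record the standardization so the score can be
    reproduced in any cohort, with mean imputation of unavailable CpGs
    (an imputed CpG contributes exactly zero).
    """

    trait_name: str
    weights: dict[str, float]  # nonzero only
    intercept: float
    training_cpg_means: dict[str, float]
    training_cpg_sds: dict[str, float]
    alpha: float  # elastic-net mixing (1 = lasso, 0 = ridge)
    lambda_selected: float
    n_folds: int
    training_n: int
    probe_universe_size: int
    probe_universe_hash: str = ""

    def __post_init__(self) -> None:
        if any(w == 0 for w in self.weights.values()):
            raise ValueError("weights must contain no zeros")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.lambda_selected <= 0:
            raise ValueError("lambda_selected must be > 0")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# trait\t{self.trait_name}\n")
            fh.write(f"# alpha\t{self.alpha}\n")
            fh.write(f"# lambda\t{self.lambda_selected}\n")
            fh.write(f"# n_train\t{self.training_n}\n")
            fh.write(f"# intercept\t{self.intercept}\n")
            fh.write(f"# probe_universe\t{self.probe_universe_size}\t{self.probe_universe_hash}\n")
            fh.write("cpg_id\tweight\ttrain_mean\ttrain_sd\n")
            for cid, w in self.weights.items():
                fh.write(
                    f"{cid}\t{w!r}\t{self.training_cpg_means[cid]!r}"
                    f"\t{self.training_cpg_sds[cid]!r}\n"
                )


@dataclass
class ProjectionResult:
    """Incremental-R^2 evaluation of a projected score."""

    scores: pd.Series
    base_r2: float
    full_r2: float
    incremental_r2: float
    n: int
    by_subgroup: dict = field(default_factory=dict)  # label -> dict
    missing_probe_count: int = 0
    imputed_fraction: float = 0.0
    flags: list = field(default_factory=list)


def _probe_hash(ids) -> str:
    h = hashlib.sha256()
    for c in ids:
        h.update(c.encode())
        h.update(b"\n")
    return h.hexdigest()[:16]


def elnet_fixed_lambda(
    X: np.ndarray, y: np.ndarray, alpha: float = 0.5, lam: float = 0.5
) -> np.ndarray:
    """Elastic-net coefficients at a fixed penalty.

    Solves ``(1/2n)||y - Xb||^2 + lam*(alpha*||b||_1 + (1-alpha)/2*||b||^2)``
    (the glmnet objective); with a single standardized predictor the solution
    is the soft threshold ``S(b_ols, lam*alpha) / (1 + lam*(1-alpha))``.
    """
    model = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=True, tol=1e-10, max_iter=100000)
    model.fit(X, y)
    return model.coef_


def intersect_probes(train: MethylationMatrix, test: MethylationMatrix) -> list[str]:
    """Sorted intersection of CpG IDs; empty intersections are an error."""
    shared = sorted(set(train.cpg_ids) & set(test.cpg_ids))
    if not shared:
        raise ValueError("no overlapping probes between cohorts")
    return shared


def train_elnet(
    pheno: ResidualizedPhenotype,
    mat: MethylationMatrix,
    probes: list[str] | None = None,
    alpha: float = 0.5,
    n_folds: int = 20,
    seed: int = 0,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-3,
) -> EpiScoreModel:
    """Cross-validated elastic net of the residualized trait on CpGs.

    ``alpha`` is the l1 mixing proportion (0.5 default); lambda runs over a
    ``n_lambdas``-point log-spaced path and is chosen to minimize the k-fold
    CV mean squared error with fold assignment derived from ``seed``.
    Columns are standardized internally; only nonzero coefficients are kept.
    """
    if probes is not None:
        mat = mat.subset_cpgs(probes)
    y_all = pheno.residuals.loc[mat.sample_ids].to_numpy(dtype=float)
    keep = np.isfinite(y_all)
    y = y_all[keep]
    if n_folds > y.size:
        raise ValueError(f"n_folds={n_folds} exceeds {y.size} training samples")
    X = mat.values[keep]
    if np.isnan(X).any():
        X = np.where(np.isfinite(X), X, np.nanmean(X, axis=0))
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / sd_safe

    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**31 - 1))
    enet = ElasticNetCV(
        l1_ratio=alpha,
        alphas=n_lambdas,  # number of points on the log-spaced lambda path
        eps=lambda_min_ratio,
        cv=cv,
        fit_intercept=True,
        max_iter=2000,
        tol=1e-4,
        random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # benign convergence chatter on the path
        enet.fit(Xs, y)

    nz = np.flatnonzero(enet.coef_)
    weights = {mat.cpg_ids[j]: float(enet.coef_[j]) for j in nz}
    return EpiScoreModel(
        trait_name=pheno.trait_name,
        weights=weights,
        intercept=float(enet.intercept_),
        training_cpg_means={mat.cpg_ids[j]: float(mu[j]) for j in nz},
        training_cpg_sds={mat.cpg_ids[j]: float(sd_safe[j]) for j in nz},
        alpha=alpha,
        lambda_selected=float(enet.alpha_),
        n_folds=n_folds,
        training_n=int(y.size),
        probe_universe_size=mat.n_cpgs,
        probe_universe_hash=_probe_hash(mat.cpg_ids),
    )


def _weighted_score(
    weights: dict[str, float],
    means: dict[str, float],
    sds: dict[str, float],
    intercept: float,
    test: MethylationMatrix,
) -> tuple[pd.Series, int, float, list]:
    lookup = {c: i for i, c in enumerate(test.cpg_ids)}
    score = np.full(test.n_samples, float(intercept))
    n_cells = test.n_samples * max(len(weights), 1)
    imputed = 0
    missing_probes = 0
    for cid, w in weights.items():
        m, s = means[cid], sds[cid]
        if cid in lookup:
            col = test.values[:, lookup[cid]].copy()
            miss = ~np.isfinite(col)
            imputed += int(miss.sum())
            col[miss] = m  # training-mean imputation -> zero contribution
            score += w * (col - m) / s
        else:
            missing_probes += 1
            imputed += test.n_samples
    flags = []
    if weights and missing_probes / len(weights) > 0.5:
        flags.append("over_half_weight_cpgs_absent")
        warnings.warn(
            f"{missing_probes}/{len(weights)} weight CpGs absent from test matrix"
        )
    return (
        pd.Series(score, index=test.sample_ids, name="episcore"),
        missing_probes,
        imputed / n_cells,
        flags,
    )


def project_score(model: EpiScoreModel, test: MethylationMatrix) -> pd.Series:
    """Project an EpiScore into a test cohort (training-mean imputation)."""
    score, _, _, _ = _weighted_score(
        model.weights, model.training_cpg_means, model.training_cpg_sds,
        model.intercept, test,
    )
    return score


def bayes_score(
    post: BayesPosterior, test: MethylationMatrix, pip_floor: float = 0.0
) -> pd.Series:
    """Score from Bayesian posterior-mean effects (same imputation contract).

    ``pip_floor`` optionally restricts to CpGs with PIP above the floor.
    """
    tb = post.table
    sel = tb[(tb["mean_effect"] != 0) & (tb["pip"] >= pip_floor)]
    weights = {c: float(w) for c, w in sel["mean_effect"].items()}
    means = {c: float(post.cpg_means[c]) for c in weights}
    sds = {c: float(post.cpg_sds[c]) for c in weights}
    score, _, _, _ = _weighted_score(weights, means, sds, 0.0, test)
    return score.rename("bayes_score")


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    Z = np.column_stack([np.ones(y.size), X])
    coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ coef
    tss = ((y - y.mean()) ** 2).sum()
    return float(1.0 - (resid @ resid) / tss) if tss > 0 else 0.0


def incremental_r2(
    trait: pd.Series,
    score: pd.Series,
    covariates: pd.DataFrame,
    subgroup: pd.Series | None = None,
    small_n: int = 30,
) -> ProjectionResult:
    """R^2 gain of trait ~ covariates + score over trait ~ covariates.

    Complete cases only.  With ``subgroup`` given, the whole-cohort models add
    subgroup dummies as covariates while per-subgroup models omit them; small
    subgroups (n < ``small_n``) are flagged.
    """
    df = pd.DataFrame({"trait": trait, "score": score}).join(covariates, how="inner")
    if subgroup is not None:
        df = df.join(subgroup.rename("subgroup"), how="inner")
    df = df.dropna()
    cov_cols = [c for c in covariates.columns]

    def _eval(d: pd.DataFrame, with_subgroup_dummies: bool) -> tuple[float, float, int]:
        Xc = d[cov_cols].to_numpy(dtype=float)
        if with_subgroup_dummies and d["subgroup"].nunique() > 1:
            Xc = np.column_stack(
                [Xc, pd.get_dummies(d["subgroup"], drop_first=True, dtype=float).to_numpy()]
            )
        y = d["trait"].to_numpy(dtype=float)
        base = _ols_r2(y, Xc)
        full = _ols_r2(y, np.column_stack([Xc, d["score"].to_numpy(dtype=float)]))
        return base, full, len(d)

    base, full, n = _eval(df, with_subgroup_dummies=subgroup is not None)
    by_sub = {}
    flags = []
    if subgroup is not None:
        for lab, d in df.groupby("subgroup"):
            b, f, ns = _eval(d, with_subgroup_dummies=False)
            entry = {
                "base_r2": b, "full_r2": f, "incremental_r2": f - b, "n": ns,
                "small_sample": ns < small_n,
            }
            if ns < small_n:
                flags.append(f"subgroup {lab}: n={ns} < {small_n}")
            by_sub[lab] = entry
    return ProjectionResult(
        scores=df["score"],
        base_r2=base,
        full_r2=full,
        incremental_r2=full - base,
        n=n,
        by_subgroup=by_sub,
        flags=flags,
    )
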