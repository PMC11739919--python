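"""EWAS covariates: weighted smoking score, reference-based cell-type
deconvolution, and methylome principal components."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.decomposition import PCA

from .containers import BETA, CORRECTED_M, MethylationMatrix

__all__ = [
    "WeightTable",
    "CellReference",
    "smoking_score",
    "deconvolve_cells",
    "methylome_pcs",
]


@dataclass
class WeightTable:
    """Fixed per-CpG weights plus an intercept (e.g. a published smoking score)."""

    cpg_ids: list[str]
    weights: np.ndarray
    intercept: float = 0.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.cpg_ids) != self.weights.size:
            raise ValueError("cpg_ids/weights length mismatch")
        if len(set(self.cpg_ids)) != len(self.cpg_ids):
            raise ValueError("duplicate CpG IDs in weight table")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    def to_tsv(self, path) -> None:
        df = pd.DataFrame({"cpg_id": self.cpg_ids, "weight": self.weights})
        with open(path, "w") as fh:
            fh.write(f"# intercept\t{self.intercept}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "WeightTable":
        intercept = 0.0
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# intercept"):
                intercept = float(first.split("\t")[1])
                df = pd.read_csv(fh, sep="\t")
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t")
        return cls(list(df["cpg_id"].astype(str)), df["weight"].to_numpy(), intercept)


@dataclass
class CellReference:
    """Per-cell-type mean beta values (CpGs x cell types) for deconvolution."""

    cpg_ids: list[str]
    profiles: np.ndarray
    cell_type_names: list[str]

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.shape != (len(self.cpg_ids), len(self.cell_type_names)):
            raise ValueError("profiles must be n_cpgs x n_cell_types")
        if len(self.cell_type_names) < 2:
            raise ValueError("need at least 2 cell types")
        if self.profiles.min() <= 0 or self.profiles.max() >= 1:
            raise ValueError("reference betas must lie in (0, 1)")


def smoking_score(
    betas: MethylationMatrix,
    weights: WeightTable,
    impute_means: Optional[dict] = None,
) -> pd.Series:
    """Weighted sum of beta values over the weight table's CpGs.

    CpGs absent from the matrix (or missing per sample) are imputed with
    ``impute_means`` (training-cohort means keyed by CpG ID) when provided,
    otherwise with the cohort's own mean beta at that CpG.  Raises when no
    weight-table CpG overlaps the matrix.
    """
    if betas.scale != BETA:
        raise ValueError("smoking score operates on the beta scale")
    present = {c: i for i, c in enumerate(betas.cpg_ids)}
    overlap = [c for c in weights.cpg_ids if c in present]
    if not overlap:
        raise ValueError("no overlap between weight-table CpGs and matrix")
    n_missing_cpgs = len(weights.cpg_ids) - len(overlap)
    if n_missing_cpgs:
        warnings.warn(f"{n_missing_cpgs} weight CpGs absent from matrix; imputed by mean")

    score = np.full(betas.n_samples, float(weights.intercept))
    for cid, w in zip(weights.cpg_ids, weights.weights):
        if cid in present:
            col = betas.values[:, present[cid]].copy()
            miss = ~np.isfinite(col)
            if miss.any():
                fill = (
                    impute_means.get(cid, np.nan) if impute_means else np.nan
                )
                if not np.isfinite(fill):
                    fill = np.nanmean(col)
                col[miss] = fill
            score += w * col
        else:
            fill = impute_means.get(cid, np.nan) if impute_means else np.nan
            if np.isfinite(fill):
                score += w * fill
    return pd.Series(score, index=betas.sample_ids, name="smoking_score")


def deconvolve_cells(betas: MethylationMatrix, ref: CellReference) -> pd.DataFrame:
    """Reference-based cell-type deconvolution by constrained least squares.

    Per sample solves ``min || beta_i - R w ||^2`` subject to ``w >= 0`` and
    ``sum(w) = 1`` (non-negative least squares with the simplex equality
    enforced through a heavily weighted augmentation row, then exact
    renormalization).  Returns fractions plus the per-sample residual norm.
    """
    if betas.scale != BETA:
        raise ValueError("deconvolution operates on the beta scale")
    present = {c: i for i, c in enumerate(betas.cpg_ids)}
    keep = [(j, present[c]) for j, c in enumerate(ref.cpg_ids) if c in present]
    if len(keep) < 10:
        raise ValueError(f"only {len(keep)} overlapping CpGs with reference; need >= 10")
    ref_rows = np.array([j for j, _ in keep])
    mat_cols = np.array([i for _, i in keep])
    R = ref.profiles[ref_rows]
    cond = np.linalg.cond(R)
    if cond > 1e8:
        warnings.warn(f"cell reference close to rank-deficient (condition number {cond:.3g})")

    rho = 1000.0
    R_aug = np.vstack([R, rho * np.ones(R.shape[1])])
    k = len(ref.cell_type_names)
    out = np.zeros((betas.n_samples, k))
    resid = np.zeros(betas.n_samples)
    for i in range(betas.n_samples):
        b = betas.values[i, mat_cols]
        obs = np.isfinite(b)
        A = np.vstack([R[obs], rho * np.ones(k)])
        w, _ = nnls(A, np.concatenate([b[obs], [rho]]))
        s = w.sum()
        w = w / s if s > 0 else np.full(k, 1.0 / k)
        out[i] = w
        resid[i] = np.linalg.norm(b[obs] - R[obs] @ w)
    df = pd.DataFrame(out, index=betas.sample_ids, columns=ref.cell_type_names)
    df["residual_norm"] = resid
    return df


def methylome_pcs(
    mat: MethylationMatrix, n_pcs: int, standardize: bool = True
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of the (column-standardized) methylation matrix.

    Computed on pre-corrected M-values so that batch/age/sex structure already
    removed upstream is not re-captured.  Constant CpGs are dropped with a
    warning.  Component signs are fixed so the loading of largest magnitude is
    positive.  Returns (scores DataFrame, variance fractions).
    """
    if mat.scale not in (CORRECTED_M, "M"):
        raise ValueError("methylome PCs expect (corrected-)M values")
    if n_pcs > min(mat.n_samples, mat.n_cpgs):
        raise ValueError("n_pcs exceeds matrix rank bound")
    X = mat.values
    if np.isnan(X).any():
        col_means = np.nanmean(X, axis=0)
        X = np.where(np.isfinite(X), X, col_means)
    if standardize:
        sd = X.std(axis=0)
        keep = sd > 0
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} constant CpGs before PCA")
            X = X[:, keep]
            sd = sd[keep]
        X = (X - X.mean(axis=0)) / sd
    else:
        X = X - X.mean(axis=0)

    pca = PCA(n_components=n_pcs, svd_solver="auto", random_state=0)
    scores = pca.fit_transform(X)
    # deterministic sign: largest-|loading| entry positive per component
    for k in range(n_pcs):
        j = np.argmax(np.abs(pca.components_[k]))
        if pca.components_[k, j] < 0:
            scores[:, k] *= -1
    frac = pca.explained_variance_ratio_
    df = pd.DataFrame(
        scores, index=mat.sample_ids, columns=[f"PC{i+1}" for i in range(n_pcs)]
    )
    return df, frac
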