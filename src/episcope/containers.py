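"""Core in-memory containers shared across the pipeline.

The central object is :class:`MethylationMatrix`, a samples x CpGs array of
methylation levels carrying its identifiers and its scale (``beta``, ``M`` or
``corrected-M``).  Missingness is represented by NaN in ``values``; every
operation in the package preserves NaNs unless it documents otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

BETA = "beta"
M = "M"
CORRECTED_M = "corrected-M"
_SCALES = (BETA, M, CORRECTED_M)


@dataclass
class MethylationMatrix:
    """Samples x CpGs methylation values with identifiers and scale.

    Parameters
    ----------
    values : ndarray, shape (n_samples, n_cpgs)
        Methylation levels; NaN marks missing entries.
    sample_ids, cpg_ids : sequences of str
        Unique identifiers for rows and columns.
    scale : {"beta", "M", "corrected-M"}
        ``beta`` values must lie in (0, 1) wherever observed.
    """

    values: np.ndarray
    sample_ids: list[str]
    cpg_ids: list[str]
    scale: str = BETA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.cpg_ids = [str(c) for c in self.cpg_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x CpGs)")
        if self.values.shape != (len(self.sample_ids), len(self.cpg_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.cpg_ids)} CpGs"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs")
        if len(set(self.cpg_ids)) != len(self.cpg_ids):
            raise ValueError("duplicate CpG IDs")
        if self.scale not in _SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == BETA:
            obs = self.values[np.isfinite(self.values)]
            if obs.size and (obs.min() <= 0.0 or obs.max() >= 1.0):
                raise ValueError("beta values must lie strictly in (0, 1)")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_cpgs(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask, True where a value is missing."""
        return ~np.isfinite(self.values)

    def cpg_index(self, ids) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cpg_ids)}
        try:
            return np.array([lookup[c] for c in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message only
            raise KeyError(f"CpG {exc.args[0]!r} not in matrix") from exc

    def subset_cpgs(self, ids) -> "MethylationMatrix":
        idx = self.cpg_index(ids)
        return MethylationMatrix(
            self.values[:, idx], self.sample_ids, [self.cpg_ids[i] for i in idx], self.scale
        )

    def subset_samples(self, ids) -> "MethylationMatrix":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([lookup[s] for s in ids], dtype=int)
        return MethylationMatrix(
            self.values[idx], [self.sample_ids[i] for i in idx], self.cpg_ids, self.scale
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.cpg_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, scale: str = BETA) -> "MethylationMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns), scale)


@dataclass
class TruthRecord:
    """Ground-truth bookkeeping for one simulated trait."""

    causal_cpg_ids: list[str]
    causal_effects: np.ndarray
    true_cell_fractions: np.ndarray  # samples x cell types, rows on the simplex
    true_variance_explained: float
    smoking_exposure: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.causal_effects = np.asarray(self.causal_effects, dtype=float)
        self.true_cell_fractions = np.asarray(self.true_cell_fractions, dtype=float)
        if len(self.causal_cpg_ids) != self.causal_effects.size:
            raise ValueError("causal ids/effects length mismatch")
        if self.true_cell_fractions.size:
            sums = self.true_cell_fractions.sum(axis=1)
            if np.any(self.true_cell_fractions < -1e-12) or np.any(np.abs(sums - 1) > 1e-8):
                raise ValueError("cell fractions must be non-negative and sum to 1")
        if not 0.0 <= self.true_variance_explained <= 1.0:
            raise ValueError("true_variance_explained must be in [0, 1]")


@dataclass
class CohortBundle:
    """Methylation + phenotypes + kinship (+ simulation truth) for one cohort.

    Sample IDs are identical and identically ordered across all components.
    The kinship matrix is symmetric with diagonal >= 0.5 and off-diagonals in
    [0, 0.5] (0.5 marks first-degree relatives).
    """

    methylation: MethylationMatrix
    phenotypes: pd.DataFrame  # indexed by sample_id
    kinship: np.ndarray
    truth: dict[str, TruthRecord] = field(default_factory=dict)
    model: object = None  # generative model (synthetic cohorts only)

    def __post_init__(self) -> None:
        ids = self.methylation.sample_ids
        if list(self.phenotypes.index.astype(str)) != ids:
            raise ValueError("phenotype sample IDs do not match methylation")
        self.kinship = np.asarray(self.kinship, dtype=float)
        n = len(ids)
        if self.kinship.shape != (n, n):
            raise ValueError("kinship must be square over the cohort samples")
        if not np.allclose(self.kinship, self.kinship.T, atol=1e-10):
            raise ValueError("kinship must be symmetric")
        d = np.diag(self.kinship)
        off = self.kinship - np.diag(d)
        if np.any(d < 0.5 - 1e-12) or off.min() < -1e-12 or off.max() > 0.5 + 1e-12:
            raise ValueError("kinship diagonal must be >= 0.5, off-diagonals in [0, 0.5]")

    @property
    def sample_ids(self) -> list[str]:
        return self.methylation.sample_ids

    @property
    def trait_names(self) -> list[str]:
        return list(self.truth) if self.truth else [
            c for c in self.phenotypes.columns
            if c not in ("age", "sex", "batch", "subgroup", "family_id")
        ]
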