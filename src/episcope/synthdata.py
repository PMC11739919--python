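"""Synthetic methylation-cohort generator.

Generates training and test cohorts with the statistical structure the
downstream analysis assumes: block-correlated CpGs, a sparse set of causal
CpGs driving each trait, cell-composition / smoking / batch / latent-factor
confounding, sibling family structure, and multi-wave cognitive follow-up.
Betas are produced as a logistic squash of Gaussian latent M-values, so the
M-value transform recovers the latent scale exactly.

Every draw is controlled by the seed in :class:`SimConfig`; identical
configurations give bit-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .containers import BETA, CohortBundle, MethylationMatrix, TruthRecord
from .covariates import CellReference, WeightTable

__all__ = [
    "SimConfig",
    "ConfounderSpec",
    "FamilySpec",
    "CognitionData",
    "simulate_cohort",
    "simulate_test_cohort",
    "simulate_cognition",
    "smoking_weight_table",
    "cell_reference",
    "write_cohort",
    "read_cohort",
]

_CELL_NAMES = ("CD4T", "CD8T", "NK", "Bcell", "Mono", "Gran")
# blood-like Dirichlet concentrations for the six-type panel
_CELL_ALPHA = np.array([0.15, 0.10, 0.05, 0.08, 0.08, 0.54]) * 60.0


@dataclass
class ConfounderSpec:
    """Confounding structure shared by methylation and phenotype."""

    cell_types: int = 6
    smoking_effect: float = 0.1  # standardized effect of smoking exposure on trait
    batch_count: int = 20
    batch_effect_sd: float = 0.1  # SD of additive per-batch M-value shifts
    n_smoking_cpgs: int = 187
    n_cell_cpgs: int = 300
    n_latent_factors: int = 3  # unmeasured global factors (picked up by DNAm PCs)
    latent_factor_variance: float = 0.08  # trait variance from latent factors


@dataclass
class FamilySpec:
    n_families: int = 200
    sibs_per_family: int = 2


@dataclass
class SimConfig:
    """Configuration of one synthetic training cohort.

    Defaults describe the desk-scale study conditions exercised throughout
    the test suite: 2,000 samples, 20,000 block-correlated CpGs, 50 causal
    CpGs explaining 40% of trait variance.
    """

    n_samples: int = 2000
    n_cpgs: int = 20000
    n_blocks: int = 1000
    within_block_corr: float = 0.6
    n_causal: int = 50
    effect_sd: float = 1.0
    confounder_spec: ConfounderSpec = field(default_factory=ConfounderSpec)
    family_spec: FamilySpec = field(default_factory=FamilySpec)
    target_variance_explained: float = 0.4
    seed: int = 0
    trait_names: tuple[str, ...] = ("trait",)
    outlier_fraction: float = 0.0  # optional gross phenotype outliers
    # trait variance fractions of the non-causal components
    v_age: float = 0.10
    v_sex: float = 0.02
    v_cells: float = 0.05
    v_batch: float = 0.05
    v_family: float = 0.15

    @classmethod
    def plain(cls, **kw) -> "SimConfig":
        """Causal signal + residual noise only: no confounding, no family
        structure, independent CpGs unless overridden.  Used for
        parameter-recovery checks where the estimand must equal the target."""
        base = dict(
            within_block_corr=0.0,
            confounder_spec=ConfounderSpec(
                smoking_effect=0.0, batch_count=1, n_latent_factors=0,
                latent_factor_variance=0.0, n_smoking_cpgs=0, n_cell_cpgs=0,
            ),
            family_spec=FamilySpec(n_families=0),
            v_age=0.0, v_sex=0.0, v_cells=0.0, v_batch=0.0, v_family=0.0,
        )
        base.update(kw)
        return cls(**base)

    def validate(self) -> None:
        counts = {
            "n_samples": self.n_samples,
            "n_cpgs": self.n_cpgs,
            "n_blocks": self.n_blocks,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if self.n_causal < 0:
            raise ValueError("n_causal must be >= 0")
        if self.n_causal * len(self.trait_names) > self.n_cpgs:
            raise ValueError(
                f"infeasible config: {self.n_causal} causal CpGs per trait x "
                f"{len(self.trait_names)} traits exceed {self.n_cpgs} CpGs"
            )
        if self.n_blocks > self.n_cpgs:
            raise ValueError("n_blocks must not exceed n_cpgs")
        if not 0.0 <= self.within_block_corr < 1.0:
            raise ValueError("within_block_corr must be in [0, 1)")
        if not 0.0 <= self.target_variance_explained <= 1.0:
            raise ValueError("target_variance_explained must be in [0, 1]")
        if self.effect_sd < 0:
            raise ValueError("effect_sd must be >= 0")


@dataclass
class _GenerativeModel:
    """Frozen latent parameters; test cohorts are re-drawn from this."""

    config: SimConfig
    cpg_ids: list[str]
    mu: np.ndarray  # per-CpG latent M mean
    s: np.ndarray  # per-CpG base latent M scale
    block_coef: np.ndarray  # per-CpG coefficient on the shared block factor
    idio_sd: np.ndarray  # per-CpG idiosyncratic SD
    block_of: np.ndarray
    causal_idx: dict  # trait -> int array
    causal_beta: dict  # trait -> effect array (per-SD of M)
    smoking_idx: np.ndarray
    smoking_eff: np.ndarray  # additive M shift per unit exposure
    cell_idx: np.ndarray
    cell_profile_beta: np.ndarray  # n_cell_cpgs x cell_types mean betas
    cell_pheno_dir: np.ndarray  # direction in cell-fraction space affecting trait
    latent_idx: list  # per factor: CpG index array
    latent_load: list  # per factor: loading array
    latent_pheno_w: np.ndarray
    var_fractions: dict


def _variance_budget(cfg: SimConfig) -> dict:
    c = cfg.confounder_spec
    v = {
        "causal": cfg.target_variance_explained,
        "age": cfg.v_age,
        "sex": cfg.v_sex,
        "cells": cfg.v_cells,
        "smoking": float(c.smoking_effect) ** 2,
        "batch": cfg.v_batch if c.batch_count > 1 else 0.0,
        "family": cfg.v_family if cfg.family_spec.n_families > 0 else 0.0,
        "latent": c.latent_factor_variance if c.n_latent_factors > 0 else 0.0,
    }
    v["residual"] = 1.0 - sum(v.values())
    if v["residual"] < 0.01:
        raise ValueError(
            "variance budget infeasible: components sum to "
            f"{1 - v['residual']:.3f}; reduce target_variance_explained or confounding"
        )
    return v


def _build_model(cfg: SimConfig, rng: np.random.Generator) -> _GenerativeModel:
    p = cfg.n_cpgs
    c = cfg.confounder_spec
    cpg_ids = [f"cg{i:08d}" for i in range(p)]
    mu = rng.uniform(-3.0, 3.0, size=p)
    s = rng.uniform(0.6, 1.4, size=p)
    block_of = rng.integers(0, cfg.n_blocks, size=p)

    # disjoint special CpG sets: causal (per trait), smoking, cell-informative;
    # the smoking/cell panels shrink proportionally on very small arrays
    n_causal_total = cfg.n_causal * len(cfg.trait_names)
    avail = p - n_causal_total
    if avail < 10:
        raise ValueError("too few CpGs left after causal sets; reduce n_causal")
    n_smoke = min(c.n_smoking_cpgs, max(avail // 5, 2)) if c.n_smoking_cpgs else 0
    n_cell = min(c.n_cell_cpgs, max(avail // 5, 2)) if c.n_cell_cpgs else 0
    c = ConfounderSpec(**{**vars(c), "n_smoking_cpgs": n_smoke, "n_cell_cpgs": n_cell})
    n_special = n_causal_total + n_smoke + n_cell
    special = rng.choice(p, size=n_special, replace=False)
    pos = 0
    causal_idx, causal_beta = {}, {}
    for t in cfg.trait_names:
        idx = np.sort(special[pos : pos + cfg.n_causal])
        pos += cfg.n_causal
        causal_idx[t] = idx
        # equal-magnitude effects with random signs: every causal CpG carries
        # the same variance share, so detection power is uniform across the
        # causal set rather than dominated by a few large draws
        causal_beta[t] = cfg.effect_sd * rng.choice([-1.0, 1.0], size=cfg.n_causal)
    smoking_idx = np.sort(special[pos : pos + c.n_smoking_cpgs])
    pos += c.n_smoking_cpgs
    cell_idx = np.sort(special[pos : pos + c.n_cell_cpgs])

    sm_mag = np.clip(rng.normal(0.8, 0.2, size=c.n_smoking_cpgs), 0.2, None)
    sm_sign = np.where(rng.random(c.n_smoking_cpgs) < 0.8, -1.0, 1.0)
    smoking_eff = sm_mag * sm_sign

    # per-cell-type beta profiles: shared base level + type-specific shifts
    base = rng.uniform(-2.0, 2.0, size=(c.n_cell_cpgs, 1))
    dev = rng.normal(0.0, 2.0, size=(c.n_cell_cpgs, c.cell_types))
    cell_profile_beta = 1.0 / (1.0 + np.exp(-(base + dev)))
    cell_profile_beta = np.clip(cell_profile_beta, 0.02, 0.98)

    dir_ = rng.normal(size=c.cell_types)
    cell_pheno_dir = dir_ - dir_.mean()  # orthogonal to the simplex constraint

    # latent (unmeasured) factors load on a random 30% of non-causal CpGs so
    # that regressing the trait on the causal columns stays an unbiased
    # variance-explained oracle
    all_causal = np.unique(np.concatenate([causal_idx[t] for t in cfg.trait_names]))\
        if cfg.n_causal else np.empty(0, dtype=int)
    non_causal = np.setdiff1d(np.arange(p), all_causal)
    latent_idx, latent_load = [], []
    for _ in range(c.n_latent_factors):
        idx = np.sort(rng.choice(non_causal, size=max(1, int(0.3 * p)), replace=False))
        latent_idx.append(idx)
        latent_load.append(rng.normal(0.0, 0.3, size=idx.size) * s[idx])
    latent_pheno_w = (
        rng.normal(size=c.n_latent_factors) if c.n_latent_factors else np.zeros(0)
    )

    # per-CpG variance budget: block factor carries exactly within_block_corr
    # of each CpG's total variance, with smoking/latent/batch extras absorbed
    # into the idiosyncratic remainder
    extras = np.zeros(p)
    extras[smoking_idx] += smoking_eff**2
    for idx, load in zip(latent_idx, latent_load):
        extras[idx] += load**2
    if c.batch_count > 1:
        extras += c.batch_effect_sd**2
    rho = cfg.within_block_corr
    total_var = np.maximum(s**2, extras / max(1.0 - rho, 1e-12) * 1.02)
    block_coef = np.sqrt(rho * total_var)
    idio_sd = np.sqrt(np.maximum(total_var * (1.0 - rho) - extras, 0.0))

    return _GenerativeModel(
        config=cfg,
        cpg_ids=cpg_ids,
        mu=mu,
        s=s,
        block_coef=block_coef,
        idio_sd=idio_sd,
        block_of=block_of,
        causal_idx=causal_idx,
        causal_beta=causal_beta,
        smoking_idx=smoking_idx,
        smoking_eff=smoking_eff,
        cell_idx=cell_idx,
        cell_profile_beta=cell_profile_beta,
        cell_pheno_dir=cell_pheno_dir,
        latent_idx=latent_idx,
        latent_load=latent_load,
        latent_pheno_w=latent_pheno_w,
        var_fractions=_variance_budget(cfg),
    )


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else v - v.mean()


def _draw_cohort(
    model: _GenerativeModel,
    n: int,
    rng: np.random.Generator,
    id_prefix: str,
    subgroups: Optional[dict] = None,
) -> CohortBundle:
    """Draw ``n`` new samples from the generative model.

    ``subgroups`` maps label -> (fraction, coupling); ``coupling`` in [0, 1]
    scales the causal CpG-trait signal within that subgroup (total trait
    variance is kept at 1 by compensating residual noise).
    """
    cfg = model.config
    c = cfg.confounder_spec
    p = cfg.n_cpgs
    v = model.var_fractions

    sample_ids = [f"{id_prefix}{i:05d}" for i in range(n)]
    age = np.clip(rng.normal(47.5, 14.9, size=n), 18.0, 95.0)
    sex = (rng.random(n) < 0.59).astype(int)
    batch = rng.integers(0, c.batch_count, size=n)

    if subgroups:
        labels = list(subgroups)
        probs = np.array([subgroups[k][0] for k in labels], dtype=float)
        probs = probs / probs.sum()
        sub = rng.choice(len(labels), size=n, p=probs)
        subgroup = np.array([labels[i] for i in sub])
        coupling = np.array([subgroups[labels[i]][1] for i in sub], dtype=float)
    else:
        subgroup = np.array(["all"] * n)
        coupling = np.ones(n)

    # sibling families over the first samples; the rest are singletons
    fam = np.arange(n)
    fs = cfg.family_spec
    n_rel = min(fs.n_families * fs.sibs_per_family, n)
    if fs.n_families > 0 and fs.sibs_per_family >= 2:
        fam[:n_rel] = np.repeat(np.arange(fs.n_families), fs.sibs_per_family)[:n_rel]
        fam[n_rel:] = fs.n_families + np.arange(n - n_rel)
    family_id = np.array([f"F{f:05d}" for f in fam])

    cells = rng.dirichlet(_CELL_ALPHA[: c.cell_types] if c.cell_types <= 6
                          else np.full(c.cell_types, 10.0), size=n)
    smoking = rng.normal(size=n)
    latent_u = rng.normal(size=(n, max(c.n_latent_factors, 1)))

    # latent M-values: block factor + idiosyncratic noise
    f_block = rng.normal(size=(n, cfg.n_blocks))
    x = model.mu + model.block_coef * f_block[:, model.block_of] + model.idio_sd * rng.normal(
        size=(n, p)
    )

    # cell-informative CpGs: mixture of per-type beta profiles on the beta scale
    cell_beta = cells @ model.cell_profile_beta.T + rng.normal(
        0.0, 0.02, size=(n, model.cell_idx.size)
    )
    cell_beta = np.clip(cell_beta, 0.005, 0.995)
    x[:, model.cell_idx] = np.log2(cell_beta / (1.0 - cell_beta))

    x[:, model.smoking_idx] += smoking[:, None] * model.smoking_eff
    for k in range(c.n_latent_factors):
        x[:, model.latent_idx[k]] += latent_u[:, k : k + 1] * model.latent_load[k]
    if c.batch_count > 1:
        shifts = rng.normal(0.0, c.batch_effect_sd, size=(c.batch_count, p))
        x += shifts[batch]

    betas = 1.0 / (1.0 + 2.0 ** (-x))

    # phenotype assembly on the unit-variance scale
    fam_effect = rng.normal(size=fam.max() + 1)[fam]
    batch_effect = rng.normal(size=c.batch_count)[batch] if c.batch_count > 1 else np.zeros(n)
    comp = {
        "age": _standardize(age),
        "sex": _standardize(sex.astype(float)),
        "cells": _standardize(cells @ model.cell_pheno_dir),
        "smoking": smoking,
        "batch": _standardize(batch_effect) if c.batch_count > 1 else np.zeros(n),
        "family": _standardize(fam_effect),
        "latent": _standardize(latent_u[:, : c.n_latent_factors] @ model.latent_pheno_w)
        if c.n_latent_factors
        else np.zeros(n),
    }

    pheno = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    truth: dict[str, TruthRecord] = {}
    T = cfg.target_variance_explained
    for t in cfg.trait_names:
        idx = model.causal_idx[t]
        if idx.size and T > 0:
            xc = x[:, idx]
            xc = (xc - xc.mean(axis=0)) / np.where(xc.std(axis=0) > 0, xc.std(axis=0), 1.0)
            g = xc @ model.causal_beta[t]
            g = _standardize(g)
        else:
            g = np.zeros(n)
        y = np.sqrt(T) * coupling * g
        # attenuated subgroups get compensating noise to keep unit variance
        y += np.sqrt(np.maximum(T * (1.0 - coupling**2), 0.0)) * rng.normal(size=n)
        for name in ("age", "sex", "cells", "smoking", "batch", "family", "latent"):
            y += np.sqrt(v[name]) * comp[name]
        y += np.sqrt(v["residual"]) * rng.normal(size=n)
        if cfg.outlier_fraction > 0:
            k = int(round(cfg.outlier_fraction * n))
            if k:
                out_i = rng.choice(n, size=k, replace=False)
                y[out_i] += rng.choice([-1, 1], size=k) * rng.uniform(6, 10, size=k)
        pheno[t] = y
        truth[t] = TruthRecord(
            causal_cpg_ids=[model.cpg_ids[i] for i in idx],
            causal_effects=model.causal_beta[t].copy(),
            true_cell_fractions=cells,
            true_variance_explained=float(T if idx.size else 0.0),
            smoking_exposure=smoking,
        )

    pheno["age"] = age
    pheno["sex"] = sex
    pheno["batch"] = [f"B{b:03d}" for b in batch]
    pheno["subgroup"] = subgroup
    pheno["family_id"] = family_id

    kin = np.zeros((n, n))
    for f in np.unique(fam):
        members = np.where(fam == f)[0]
        kin[np.ix_(members, members)] = 0.5

    mat = MethylationMatrix(betas, sample_ids, list(model.cpg_ids), scale=BETA)
    return CohortBundle(methylation=mat, phenotypes=pheno, kinship=kin, truth=truth, model=model)


def simulate_cohort(config: SimConfig) -> CohortBundle:
    """Generate a training cohort; see :class:`SimConfig` for the knobs."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    model = _build_model(config, rng)
    return _draw_cohort(model, config.n_samples, rng, id_prefix="TR")


def simulate_test_cohort(
    train: CohortBundle,
    probe_fraction: float,
    n_samples: int,
    seed: int,
    missing_rate: float = 0.02,
    subgroups: Optional[dict] = None,
    id_prefix: str = "TC",
) -> CohortBundle:
    """Draw a test cohort from the training cohort's generative model.

    Only a random ``probe_fraction`` of CpGs is retained (emulating a
    different array) and ``missing_rate`` of entries is set missing.
    ``subgroups`` maps label -> (fraction, coupling) for heterogeneous
    CpG-trait coupling across population subgroups.
    """
    if not 0.0 < probe_fraction <= 1.0:
        raise ValueError("probe_fraction must be in (0, 1]")
    if train.model is None:
        raise ValueError("training cohort has no generative model attached")
    rng = np.random.default_rng(seed)
    bundle = _draw_cohort(train.model, n_samples, rng, id_prefix=id_prefix, subgroups=subgroups)

    p = bundle.methylation.n_cpgs
    keep_n = int(round(probe_fraction * p))
    keep = np.sort(rng.choice(p, size=keep_n, replace=False)) if keep_n < p else np.arange(p)
    values = bundle.methylation.values[:, keep]
    if missing_rate > 0:
        mask = rng.random(values.shape) < missing_rate
        values = values.copy()
        values[mask] = np.nan
    mat = MethylationMatrix(
        values,
        bundle.methylation.sample_ids,
        [bundle.methylation.cpg_ids[i] for i in keep],
        scale=BETA,
    )
    return CohortBundle(
        methylation=mat,
        phenotypes=bundle.phenotypes,
        kinship=bundle.kinship,
        truth=bundle.truth,
        model=train.model,
    )


@dataclass
class CognitionData:
    """Long-format longitudinal cognitive scores plus simulation truth."""

    long: pd.DataFrame  # sample_id, wave, age, test_name, score
    truth: pd.DataFrame  # sample_id-indexed: g0, g1, baseline_age


def simulate_cognition(
    cohort: CohortBundle,
    n_tests: int,
    n_waves: int,
    intercept_assoc: float,
    slope_assoc: float,
    seed: int,
    trait: Optional[str] = None,
    loadings: Optional[np.ndarray] = None,
    noise_sd: float = 0.5,
    wave_spacing: float = 3.0,
    slope_sd: float = 0.05,
    dropout: float = 0.0,
) -> CognitionData:
    """Simulate multi-test multi-wave cognitive scores for a cohort.

    Latent intercept ``g0`` (SD 1) correlates with the chosen trait at
    standardized coefficient ``intercept_assoc``; the per-year latent slope
    ``g1`` (SD ``slope_sd``) at ``slope_assoc``.  Each test score at wave w is
    ``loading * (g0 + g1 * years_since_baseline) + noise``; waves are spaced
    ``wave_spacing`` years apart (ages ~70-82 across five triennial waves in
    the default design).  ``dropout`` applies monotone per-wave attrition.
    """
    if n_tests < 2 or n_waves < 2:
        raise ValueError("need n_tests >= 2 and n_waves >= 2")
    rng = np.random.default_rng(seed)
    trait = trait or cohort.trait_names[0]
    y = _standardize(cohort.phenotypes[trait].to_numpy(dtype=float))
    n = y.size

    ia, sa = float(intercept_assoc), float(slope_assoc)
    for name, val in (("intercept_assoc", ia), ("slope_assoc", sa)):
        if abs(val) > 1:
            raise ValueError(f"{name} must be in [-1, 1]")
    g0 = ia * y + np.sqrt(1.0 - ia**2) * rng.normal(size=n)
    g1 = slope_sd * (sa * y + np.sqrt(1.0 - sa**2) * rng.normal(size=n))

    lam = np.asarray(loadings, dtype=float) if loadings is not None else rng.uniform(
        0.6, 1.2, size=n_tests
    )
    if lam.size != n_tests:
        raise ValueError("loadings length must equal n_tests")

    baseline_age = rng.normal(70.0, 0.8, size=n)
    last_wave = np.full(n, n_waves)
    if dropout > 0:
        stay = rng.random((n, n_waves - 1)) >= dropout
        last_wave = 1 + np.cumprod(stay, axis=1).sum(axis=1)

    rows = []
    for w in range(n_waves):
        dt = wave_spacing * w
        active = w < last_wave
        latent = g0 + g1 * dt
        for t in range(n_tests):
            score = lam[t] * latent + noise_sd * rng.normal(size=n)
            for i in np.where(active)[0]:
                rows.append(
                    (cohort.sample_ids[i], w + 1, baseline_age[i] + dt, f"test_{t+1}", score[i])
                )
    long = pd.DataFrame(rows, columns=["sample_id", "wave", "age", "test_name", "score"])
    truth = pd.DataFrame(
        {"g0": g0, "g1": g1, "baseline_age": baseline_age},
        index=pd.Index(cohort.sample_ids, name="sample_id"),
    )
    return CognitionData(long=long, truth=truth)


def smoking_weight_table(model: _GenerativeModel) -> WeightTable:
    """Weight table of the generator's smoking-responsive CpGs (beta scale).

    Emulates a published fixed-weight smoking score: weights are the
    generator's per-CpG M-shifts per unit exposure, which are proportional to
    the induced beta shifts up to the local logistic slope.
    """
    ids = [model.cpg_ids[i] for i in model.smoking_idx]
    return WeightTable(cpg_ids=ids, weights=model.smoking_eff.copy(), intercept=0.0)


def cell_reference(model: _GenerativeModel) -> CellReference:
    """Per-cell-type mean-beta reference panel for the generator's cell CpGs."""
    ids = [model.cpg_ids[i] for i in model.cell_idx]
    return CellReference(
        cpg_ids=ids,
        profiles=model.cell_profile_beta.copy(),
        cell_type_names=list(_CELL_NAMES[: model.cell_profile_beta.shape[1]]),
    )


def write_cohort(bundle: CohortBundle, out_dir: str | Path) -> None:
    """Write a cohort as TSVs (methylation, phenotypes, kinship) + truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.methylation.to_dataframe().to_csv(out / "methylation.tsv", sep="\t")
    bundle.phenotypes.to_csv(out / "phenotypes.tsv", sep="\t")
    pd.DataFrame(
        bundle.kinship, index=bundle.sample_ids, columns=bundle.sample_ids
    ).to_csv(out / "kinship.tsv", sep="\t")
    truth = {
        t: {
            "causal_cpg_ids": r.causal_cpg_ids,
            "causal_effects": r.causal_effects.tolist(),
            "true_variance_explained": r.true_variance_explained,
        }
        for t, r in bundle.truth.items()
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))


def read_cohort(in_dir: str | Path, scale: str = BETA) -> CohortBundle:
    """Read a cohort written by :func:`write_cohort` (truth effects only)."""
    d = Path(in_dir)
    meth = pd.read_csv(d / "methylation.tsv", sep="\t", index_col=0)
    pheno = pd.read_csv(d / "phenotypes.tsv", sep="\t", index_col=0)
    pheno.index = pheno.index.astype(str)
    kin = pd.read_csv(d / "kinship.tsv", sep="\t", index_col=0).to_numpy(dtype=float)
    mat = MethylationMatrix.from_dataframe(meth, scale=scale)
    truth = {}
    tj = d / "truth.json"
    if tj.exists():
        raw = json.loads(tj.read_text())
        for t, r in raw.items():
            truth[t] = TruthRecord(
                causal_cpg_ids=r["causal_cpg_ids"],
                causal_effects=np.asarray(r["causal_effects"]),
                true_cell_fractions=np.zeros((0, 0)),
                true_variance_explained=r["true_variance_explained"],
            )
    return CohortBundle(methylation=mat, phenotypes=pheno, kinship=kin, truth=truth)
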