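"""End-to-end pipeline orchestration.

Runs simulate -> preprocess -> covariates -> marginal EWAS (base, PC-adjusted,
bacon) -> Bayesian EWAS -> EpiScore train/project/evaluate -> cognition from a
single config with deterministic per-stage seeds, and writes summary TSVs plus
a JSON run manifest.  Re-running with an identical config reproduces
byte-identical summary outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import MethylationMatrix
from .covariates import deconvolve_cells, methylome_pcs, smoking_score
from .episcore import (
    bayes_score,
    incremental_r2,
    intersect_probes,
    project_score,
    train_elnet,
)
from .ewas_bayes import BayesConfig, call_high_confidence, compare_marginal_bayes, run_bayes_ewas
from .ewas_marginal import (
    GENOME_WIDE_P,
    apply_bacon,
    call_significant,
    count_independent_signals,
    fit_bacon,
    run_marginal_ewas,
)
from .cognition import fit_growth_model, test_associations, variance_decomposition
from .preprocess import beta_to_m, precorrect_m_values, residualize_trait
from .synthdata import (
    SimConfig,
    ConfounderSpec,
    FamilySpec,
    cell_reference,
    simulate_cognition,
    simulate_test_cohort,
    simulate_cohort,
    smoking_weight_table,
    write_cohort,
)

__all__ = ["RunConfig", "run_pipeline", "make_table2", "stage_seed"]

_STAGES = ("simulate", "preprocess", "covariates", "ewas", "bayes", "episcore", "cognition")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed independent of stage order."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31 - 1)


@dataclass
class RunConfig:
    """Pipeline configuration (desk-scale defaults)."""

    seed: int = 1
    out_dir: str = "episcope_run"
    stages: dict = field(
        default_factory=lambda: {s: True for s in _STAGES}
    )
    # synthetic cohort
    n_samples: int = 800
    n_cpgs: int = 3000
    n_blocks: int = 150
    within_block_corr: float = 0.6
    n_causal: int = 30
    target_variance_explained: float = 0.4
    trait_names: tuple = ("trait",)
    batch_count: int = 10
    n_families: int = 80
    # test cohort
    test_n_samples: int = 400
    probe_fraction: float = 0.8
    missing_rate: float = 0.02
    subgroups: Optional[dict] = None  # label -> [fraction, coupling]
    # analysis settings
    n_pcs: int = 20
    significance_threshold: float = GENOME_WIDE_P
    run_bacon: bool = True
    bayes_iterations: int = 1200
    bayes_burn_in: int = 400
    bayes_thin: int = 2
    elnet_alpha: float = 0.5
    elnet_folds: int = 5
    # truncated lambda path: the CV optimum sits well above the glmnet-style
    # 1e-3 floor on these cohorts, and the small-lambda tail dominates runtime
    elnet_n_lambdas: int = 60
    elnet_lambda_min_ratio: float = 0.02
    # cognition
    cognition_n_tests: int = 4
    cognition_n_waves: int = 4
    cognition_intercept_assoc: float = -0.10
    cognition_slope_assoc: float = 0.0
    save_cohorts: bool = False
    threads: int = 1  # hint only; all stages currently run single-threaded

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        valid = set(cls.__dataclass_fields__)
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if "stages" in raw:
            stages = {s: False for s in _STAGES}
            stages.update(raw["stages"])
            bad = set(stages) - set(_STAGES)
            if bad:
                raise ValueError(f"unknown stages: {sorted(bad)}")
            cfg.stages = stages
        if cfg.subgroups is not None:
            cfg.subgroups = {k: tuple(v) for k, v in cfg.subgroups.items()}
        return cfg

    def sim_config(self) -> SimConfig:
        return SimConfig(
            n_samples=self.n_samples,
            n_cpgs=self.n_cpgs,
            n_blocks=self.n_blocks,
            within_block_corr=self.within_block_corr,
            n_causal=self.n_causal,
            target_variance_explained=self.target_variance_explained,
            trait_names=tuple(self.trait_names),
            confounder_spec=ConfounderSpec(batch_count=self.batch_count),
            family_spec=FamilySpec(n_families=self.n_families),
            seed=stage_seed(self.seed, "simulate"),
        )


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def make_table2(
    results: dict, mat: MethylationMatrix, threshold: float = GENOME_WIDE_P
) -> pd.DataFrame:
    """Per-trait significant-CpG counts across the three analysis modes.

    ``results[trait]`` holds ``base`` and ``pc_adjusted`` marginal results and
    the ``bayes`` posterior.  Output mirrors the canonical comparison table:
    base count, PC-adjusted count, Bayesian count with marginal overlap in
    parentheses, and the number of PCs covering >= 80% of the variance of each
    significant set.  Missing modes yield NA with a warning.
    """
    import warnings

    rows = []
    for trait, res in results.items():
        row = {"trait": trait}
        sig = {}
        for mode, col in (("base", "n_base"), ("pc_adjusted", "n_pc_adjusted")):
            if mode in res and res[mode] is not None:
                ids = call_significant(res[mode], threshold)
                sig[mode] = ids
                row[col] = len(ids)
                pc_col = f"n_pcs_80_{mode}"
                row[pc_col] = (
                    count_independent_signals(mat, ids) if ids else 0
                )
            else:
                warnings.warn(f"trait {trait}: missing {mode} results")
                row[col] = np.nan
                row[f"n_pcs_80_{mode}"] = np.nan
        if "bayes" in res and res["bayes"] is not None:
            bayes_ids = call_high_confidence(res["bayes"])
            overlap = compare_marginal_bayes(sig.get("pc_adjusted", []), bayes_ids)
            row["bayes"] = overlap["report"]
            row["n_bayes"] = len(bayes_ids)
        else:
            warnings.warn(f"trait {trait}: missing bayes results")
            row["bayes"] = "NA"
            row["n_bayes"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest.

    Later stages auto-enable their prerequisites.  Summary TSV/JSON outputs
    land under ``config.out_dir``; the manifest records versions, seeds, file
    hashes and per-stage wall time.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    requested = {s: bool(config.stages.get(s, False)) for s in _STAGES}
    # dependency closure: the stages form a linear chain, so any enabled stage
    # pulls in everything before it
    last = max((i for i, s in enumerate(_STAGES) if requested[s]), default=-1)
    enabled = {s: i <= last for i, s in enumerate(_STAGES)}

    config_echo = {k: repr(getattr(config, k)) for k in sorted(config.__dataclass_fields__)}
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config_echo,
        "config_sha256": hashlib.sha256(
            json.dumps(config_echo, sort_keys=True).encode()
        ).hexdigest()[:16],
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGES if enabled[s]},
        "stages": [],
        "outputs": {},
    }

    ctx: dict = {}

    def _record(stage: str, t0: float, outputs: dict) -> None:
        manifest["stages"].append({"stage": stage, "wall_time_s": round(time.time() - t0, 3)})
        for k, p in outputs.items():
            manifest["outputs"][k] = {"path": str(p), "sha256": _sha256_file(Path(p))}

    if enabled["simulate"]:
        t0 = time.time()
        bundle = simulate_cohort(config.sim_config())
        test = simulate_test_cohort(
            bundle,
            probe_fraction=config.probe_fraction,
            n_samples=config.test_n_samples,
            seed=stage_seed(config.seed, "simulate_test"),
            missing_rate=config.missing_rate,
            subgroups=config.subgroups,
        )
        ctx["bundle"], ctx["test"] = bundle, test
        outs = {}
        if config.save_cohorts:
            write_cohort(bundle, out / "train_cohort")
            write_cohort(test, out / "test_cohort")
            outs["train_phenotypes"] = out / "train_cohort" / "phenotypes.tsv"
        _record("simulate", t0, outs)

    if enabled["preprocess"]:
        t0 = time.time()
        bundle = ctx["bundle"]
        m = beta_to_m(bundle.methylation)
        corrected = precorrect_m_values(m, bundle.phenotypes[["age", "sex", "batch"]])
        resid = {
            t: residualize_trait(bundle.phenotypes, t, bundle.kinship)
            for t in bundle.trait_names
        }
        ctx["corrected"], ctx["resid"] = corrected, resid
        path = out / "residualized_phenotypes.tsv"
        pd.DataFrame({t: r.residuals for t, r in resid.items()}).to_csv(path, sep="\t")
        meta = {
            t: {
                "variance_components": r.variance_components,
                "fixed_effects": r.fixed_effects.to_dict(),
            }
            for t, r in resid.items()
        }
        mpath = out / "residualized_phenotypes_meta.json"
        mpath.write_text(json.dumps(meta, indent=1, sort_keys=True))
        _record("preprocess", t0, {
            "residualized_phenotypes": path, "residualized_phenotypes_meta": mpath,
        })

    if enabled["covariates"]:
        t0 = time.time()
        bundle = ctx["bundle"]
        wt = smoking_weight_table(bundle.model)
        ref = cell_reference(bundle.model)
        smoke = smoking_score(bundle.methylation, wt)
        cells = deconvolve_cells(bundle.methylation, ref)
        pcs, _ = methylome_pcs(ctx["corrected"], config.n_pcs)
        cov = pd.DataFrame({"smoking_score": smoke})
        # drop one cell type as the simplex reference level
        cov = cov.join(cells.drop(columns=["residual_norm"]).iloc[:, 1:])
        ctx["covariates"], ctx["pcs"] = cov, pcs
        ctx["weight_table"], ctx["cell_ref"] = wt, ref
        path = out / "covariates.tsv"
        cov.join(pcs).to_csv(path, sep="\t")
        _record("covariates", t0, {"covariates": path})

    if enabled["ewas"]:
        t0 = time.time()
        ewas_results: dict = {}
        outs = {}
        for t, r in ctx["resid"].items():
            base = run_marginal_ewas(r, ctx["corrected"], ctx["covariates"], model_tag="base")
            pc_adj = run_marginal_ewas(
                r, ctx["corrected"], ctx["covariates"].join(ctx["pcs"]),
                model_tag="pc_adjusted",
            )
            res = {"base": base, "pc_adjusted": pc_adj}
            if config.run_bacon:
                fit = fit_bacon(pc_adj.zscores(), seed=stage_seed(config.seed, f"bacon:{t}"))
                res["bacon"] = apply_bacon(pc_adj, fit)
                res["bacon_fit"] = fit
            ewas_results[t] = res
            for tag in ("base", "pc_adjusted", "bacon"):
                if tag in res:
                    path = out / f"ewas_{t}_{tag}.tsv"
                    tb = res[tag].table.copy()
                    tb["model_tag"] = res[tag].model_tag
                    tb.to_csv(path, sep="\t")
                    outs[f"ewas_{t}_{tag}"] = path
        ctx["ewas"] = ewas_results
        _record("ewas", t0, outs)

    if enabled["bayes"]:
        t0 = time.time()
        outs = {}
        bayes_results = {}
        for t, r in ctx["resid"].items():
            bc = BayesConfig(
                n_iterations=config.bayes_iterations,
                burn_in=config.bayes_burn_in,
                thin=config.bayes_thin,
                seed=stage_seed(config.seed, f"bayes:{t}"),
            )
            post = run_bayes_ewas(r, ctx["corrected"], ctx["covariates"], bc)
            bayes_results[t] = post
            path = out / f"bayes_{t}.tsv"
            post.table.to_csv(path, sep="\t")
            outs[f"bayes_{t}"] = path
            report = {
                "variance_explained": post.variance_explained,
                "variance_explained_ci": list(post.variance_explained_ci),
                "sigma2_e": post.sigma2_e,
                "n_kept": post.n_kept,
                "ess_variance_explained": post.ess_variance_explained,
            }
            rpath = out / f"bayes_{t}_report.json"
            rpath.write_text(json.dumps(report, indent=1, sort_keys=True))
            outs[f"bayes_{t}_report"] = rpath
        ctx["bayes"] = bayes_results
        # table-2 analogue
        table2_in = {
            t: {
                "base": ctx["ewas"][t]["base"],
                "pc_adjusted": ctx["ewas"][t]["pc_adjusted"],
                "bayes": bayes_results[t],
            }
            for t in bayes_results
        }
        t2 = make_table2(table2_in, ctx["corrected"], config.significance_threshold)
        path = out / "table2.tsv"
        t2.to_csv(path, sep="\t", index=False)
        outs["table2"] = path
        ctx["table2"] = t2
        _record("bayes", t0, outs)

    if enabled["episcore"]:
        t0 = time.time()
        bundle, test = ctx["bundle"], ctx["test"]
        outs = {}
        ctx["episcore"] = {}
        test_m = beta_to_m(test.methylation)
        for t, r in ctx["resid"].items():
            shared = intersect_probes(bundle.methylation, test.methylation)
            model = train_elnet(
                r,
                bundle.methylation,
                probes=shared,
                alpha=config.elnet_alpha,
                n_folds=config.elnet_folds,
                seed=stage_seed(config.seed, f"elnet:{t}"),
                n_lambdas=config.elnet_n_lambdas,
                lambda_min_ratio=config.elnet_lambda_min_ratio,
            )
            wpath = out / f"episcore_weights_{t}.tsv"
            model.to_tsv(wpath)
            outs[f"weights_{t}"] = wpath
            score = project_score(model, test.methylation)
            bscore = bayes_score(ctx["bayes"][t], test_m) if "bayes" in ctx else None
            proj = incremental_r2(
                test.phenotypes[t],
                score,
                test.phenotypes[["age", "sex"]],
                subgroup=test.phenotypes["subgroup"]
                if test.phenotypes["subgroup"].nunique() > 1
                else None,
            )
            ctx["episcore"][t] = {"model": model, "score": score, "projection": proj}
            report = {
                "base_r2": proj.base_r2,
                "full_r2": proj.full_r2,
                "incremental_r2": proj.incremental_r2,
                "n": proj.n,
                "by_subgroup": proj.by_subgroup,
                "n_nonzero_weights": len(model.weights),
                "lambda": model.lambda_selected,
            }
            if bscore is not None:
                bproj = incremental_r2(
                    test.phenotypes[t], bscore, test.phenotypes[["age", "sex"]]
                )
                report["bayes_incremental_r2"] = bproj.incremental_r2
                ctx["episcore"][t]["bayes_score"] = bscore
            ppath = out / f"episcore_projection_{t}.json"
            ppath.write_text(json.dumps(report, indent=1, sort_keys=True))
            outs[f"projection_{t}"] = ppath
        _record("episcore", t0, outs)

    if enabled["cognition"]:
        t0 = time.time()
        test = ctx["test"]
        cog = simulate_cognition(
            test,
            n_tests=config.cognition_n_tests,
            n_waves=config.cognition_n_waves,
            intercept_assoc=config.cognition_intercept_assoc,
            slope_assoc=config.cognition_slope_assoc,
            seed=stage_seed(config.seed, "cognition"),
        )
        growth = fit_growth_model(cog.long)
        trait = ctx["bundle"].trait_names[0]
        predictors = pd.DataFrame(
            {
                f"measured_{trait}": test.phenotypes[trait],
                f"episcore_{trait}": ctx["episcore"][trait]["score"],
            }
        )
        cov = test.phenotypes[["age", "sex"]]
        assoc = test_associations(growth, predictors, cov, model_tag="basic")
        decomp = variance_decomposition(
            growth,
            test.phenotypes[trait],
            ctx["episcore"][trait]["score"],
            cov,
        )
        apath = out / "cognition_associations.tsv"
        assoc.table.to_csv(apath, sep="\t", index=False)
        dpath = out / "cognition_variance_decomposition.tsv"
        decomp.to_csv(dpath, sep="\t", index=False)
        ctx["cognition"] = {"growth": growth, "associations": assoc, "decomposition": decomp}
        _record("cognition", t0, {"cognition_associations": apath, "cognition_decomp": dpath})

    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    manifest["context"] = ctx
    return manifest
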