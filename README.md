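# episcope

Epigenome-wide association and methylation-score analysis for quantitative
traits, exercised end to end on synthetic cohorts.

Blood DNA methylation carries broad signatures of metabolic health: body-mass
index, adiposity and blood lipids each associate with methylation at thousands
of CpG sites, and weighted sums of CpG beta-values (*EpiScores*) can proxy the
measured traits in cohorts where they were never assayed. Two statistical
problems dominate this kind of study. First, per-CpG ("marginal") regressions
ignore the strong correlation structure of the methylome, so significant-CpG
counts are inflated by correlated neighbours and unmeasured confounders;
jointly modeling all CpGs with a sparse Bayesian prior collapses each
correlated peak to its lead site. Second, scores trained in one population
must survive projection onto a different array and a different population.
`episcope` implements the full workflow for both problems, plus the
downstream question of whether metabolic EpiScores track general cognitive
function in longitudinal aging data.

Real cohorts of this kind are access-restricted, so the package includes a
generator for synthetic cohorts with the relevant structure — block-correlated
CpGs, sparse causal effects, cell-composition/smoking/batch/latent-factor
confounding, family relatedness, a reduced-probe test cohort, and multi-wave
cognitive scores — and every stage is validated against the generator's ground
truth.

## What it computes

For a trait `y` and methylation matrix (samples × CpGs, betas in (0,1),
M = log₂ β/(1−β)):

- **Residualization** — `y = Xb + g + e` with `g ~ N(0, σ²_g·2K)` for kinship
  `K`, fitted by REML over λ = σ²_g/σ²_e; M-values pre-corrected for age, sex
  and batch.
- **Marginal EWAS** — per-CpG OLS of the residuals on the standardized CpG
  plus smoking-score and cell-fraction covariates (optionally 20 methylome
  PCs), significance at p < 3.6×10⁻⁸, inflation via
  λ_GC = median(χ²₁)/0.4549, bias/inflation correction by a three-component
  Gaussian-mixture fit to the z-scores (`z' = (z−μ̂)/σ̂`), and independent
  signals counted as PCs covering ≥80% of the significant CpGs' variance.
- **Joint Bayesian EWAS** — spike-and-slab mixture prior
  (slabs {10⁻⁴,10⁻³,10⁻²}·σ²_β) sampled by Gibbs; per-CpG posterior inclusion
  probabilities (high confidence at PIP ≥ 0.95), posterior mean effects, and
  the phenotypic variance explained by genome-wide methylation,
  var(Xβ)/var(y).
- **EpiScores** — elastic net (l1-ratio 0.5, 20-fold CV) on the probe set
  intersected with the test cohort; projection with training-mean imputation;
  evaluation as incremental R² over age + sex, overall and by subgroup;
  Bayesian posterior-mean scores through the same contract.
- **Cognition** — latent intercept/slope of general cognitive function from
  multi-test multi-wave data (common factor, then a random-intercept/slope
  mixed model); standardized associations with traits and EpiScores under
  Benjamini–Hochberg FDR.

See `docs/methods.md` for models, priors, numerical choices and limitations.

## Worked example

```python
from episcope.pipeline import RunConfig, run_pipeline

cfg = RunConfig(seed=11, out_dir="demo_run",
                n_samples=800, n_cpgs=3000, n_blocks=150, n_causal=10,
                within_block_corr=0.7, test_n_samples=600,
                bayes_iterations=800, bayes_burn_in=300,
                subgroups={"X": (0.5, 1.0), "Y": (0.5, 0.3)})
manifest = run_pipeline(cfg)
print(manifest["context"]["table2"])
```

prints the per-trait significant-CpG comparison (this exact output, seeded;
~1–2 minutes on one CPU):

```
   trait  n_base  n_pcs_80_base  n_pc_adjusted  n_pcs_80_pc_adjusted    bayes  n_bayes
0  trait      79             11             52                    10  10 (10)       10
```

Reading the row: the plain marginal EWAS calls 79 CpGs at p < 3.6×10⁻⁸
(confounding plus correlated block-mates of the 10 causal CpGs), worth about
11 independent signals (PCs covering 80% of their variance); adding 20
methylome PCs as covariates removes the confounded hits, leaving 52; the joint
Bayesian model collapses each correlated block to its lead CpG — 10
high-confidence (PIP ≥ 0.95) calls, all contained in the PC-adjusted marginal
list, exactly the ground-truth causal count. The same run writes per-stage
TSV/JSON summaries (EWAS statistics, posterior tables, EpiScore weights and
projection report, cognition associations) and a manifest under `demo_run/`.
The projection report shows the EpiScore explaining 25.9% incremental R² in
the test cohort overall — 40.3% in subgroup `X` but only 15.3% in subgroup
`Y`, whose causal coupling the generator attenuated to 0.3 — and the
cognition table shows the measured trait associated with the latent cognitive
intercept (standardized β = −0.185, p_FDR < 0.001).

The same pipeline is available from the shell:

```bash
episcope all --seed 11 --out demo_run          # or a YAML config via --config
episcope simulate --out cohort/                # write a synthetic cohort
episcope ewas --seed 11 --out demo_run         # run the chain through EWAS
```

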