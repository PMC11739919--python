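# Methods

`episcope` implements a complete epigenome-wide association workflow for
quantitative traits measured alongside array-based DNA methylation: kinship-aware
phenotype residualization, marginal and joint-Bayesian per-CpG association,
test-statistic bias/inflation correction, independent-signal counting,
elastic-net methylation scores (EpiScores) with cross-cohort projection, and
latent-growth modeling of longitudinal cognitive data. Because the cohorts this
kind of analysis is normally run on are access-restricted, the package ships a
synthetic-cohort generator that reproduces the statistical structure the
analysis assumes, and every stage is tested against that generator's ground
truth.

## Synthetic cohorts

Latent M-values for CpG `j` in sample `i` are

    x_ij = mu_j + a_j * f_{b(j),i} + s~_j * e_ij  (+ confounder terms)

where `f_b` is a standard-normal factor shared by all CpGs of block `b`. The
coefficients are budgeted per CpG so that the shared factor carries exactly
`within_block_corr` of each CpG's total variance; confounder contributions
(below) are absorbed into the idiosyncratic remainder. Betas are the logistic
squash `beta = 2^x / (1 + 2^x)`, so the M-value transform
`M = log2(beta/(1-beta))` recovers the latent scale exactly.

Confounding mirrors what the analysis has to cope with in real blood-based
methylation data:

- **Cell composition** — per-sample six-cell-type fractions from a Dirichlet
  with blood-like concentrations; a panel of cell-informative CpGs is generated
  as a mixture of per-cell-type beta profiles (these CpGs are the synthetic
  deconvolution reference).
- **Smoking** — a latent exposure shifts a fixed panel of smoking-responsive
  CpGs (187 by default, mostly hypomethylating) and feeds the trait.
- **Batch** — additive per-batch M-value shifts (SD 0.1) on all CpGs plus a
  batch-level trait component; 20 batches at the desk-scale default, keeping
  roughly the per-batch sample count of large production cohorts.
- **Latent factors** — three unmeasured global factors loading on a random 30%
  of non-causal CpGs and on the trait. These are what DNAm principal
  components adjust for; without them PC adjustment would have nothing to do.

The trait is assembled on the unit-variance scale from fixed variance
fractions: causal CpGs (`target_variance_explained`, default 0.40), age 0.10,
sex 0.02, cell composition 0.05, smoking (effect² = 0.01), batch 0.05, family
0.15, latent factors 0.08, residual remainder. Causal effects have equal
magnitude and random sign, so every causal CpG carries the same variance share
and detection power is uniform across the causal set; causal, smoking and cell
CpG panels are disjoint, and latent factors avoid causal CpGs, which keeps the
ordinary-least-squares regression of the trait on the true causal M-values an
unbiased oracle for the variance-explained bookkeeping (±0.05 at n ≥ 2,000).

Families are sibling clusters: the kinship matrix `K` holds 0.5 within a
family (including the diagonal) and 0 elsewhere, so the doubled matrix `2K`
used by the mixed model is block-diagonal of ones — a family-shared random
effect.

Test cohorts are re-drawn from the same generative model with a random probe
subset (emulating a different array), ~2% missing entries, and optional
population subgroups whose causal-signal coupling is attenuated (coupling
`c < 1` scales the causal component by `c` with compensating noise), which is
the harness for subgroup heterogeneity in score performance.

The cognition simulator gives each sample a latent level `g0` (SD 1,
correlated with the chosen trait at a standardized coefficient) and per-year
slope `g1` (SD 0.05/yr); each of several test scores at wave `w` is
`loading * (g0 + g1 * Δt_w) + noise`, with triennial waves starting near age
70 and optional monotone dropout.

Desk-scale defaults (n = 2,000 samples, 20,000 CpGs in 1,000 blocks, 50
causal CpGs) are the conditions used throughout the test suite; they keep the
full pipeline within minutes on one CPU while preserving the power regimes
the methods are sensitive to.

## Preprocessing

Betas are clipped to [1e-6, 1-1e-6] before the M transform to avoid infinite
M-values at the boundaries. Sample quantile normalization replaces each
sample's order statistics with their across-sample mean (ties get the value at
their average rank). Phenotype outliers are masked once at ±4 SD (the rule and
threshold are configurable; a warning fires if more than 1% of values are
removed).

Per-CpG pre-correction regresses each CpG's M-values on intercept, age, sex
and batch dummies; residuals are the `corrected-M` scale used by both EWAS
modes and the methylome PCs. Missing entries are excluded per CpG and stay
missing. The operation is idempotent.

Phenotypes are residualized on intercept, centered age, centered age², and sex
with a family random effect: `y = Xb + g + e`, `g ~ N(0, σ²_g · 2K)`. REML
maximizes over `λ = σ²_g/σ²_e` by bounded Brent search on log λ ∈ [−10, 10]
(tolerance 1e-6) after a single eigendecomposition of `2K`. Residuals are
conditional (`y − Xb̂ − BLUP(g)`) by default, with a marginal option. When
`2K` is numerically a scaled identity the two variance components are not
separately identifiable; the fit falls back to OLS with `σ²_g = 0`, which is
the exact limit of the model. Age is mean-centered before squaring (the
quadratic term is otherwise nearly collinear with the linear one).

## Covariates

The smoking score is a fixed-weight sum of beta values over a published-style
weight panel, with mean imputation of missing or absent CpGs; the synthetic
panel is derived from the generator's smoking shifts, and the score recovers
the latent exposure at r > 0.99 under the default conditions. Cell-type
fractions solve a non-negative least-squares problem per sample with the
simplex equality enforced through a heavily weighted augmentation row and an
exact renormalization; recovery error is below 0.01 mean absolute fraction at
the default noise (beta SD 0.02). Methylome PCs are computed on the
column-standardized corrected-M matrix (standardization optional) so that
batch/age/sex structure removed upstream is not re-captured; component signs
are fixed by making the largest-magnitude loading positive.

## Marginal EWAS

Each CpG is standardized over its non-missing samples and tested by OLS of the
residualized trait on the CpG plus fixed covariates (smoking score and five of
the six cell fractions; optionally the first 20 methylome PCs). For
complete-case CpGs the per-CpG statistics come from a
Frisch–Waugh–Lovell projection shared across CpGs — verified against the full
per-CpG design to 1e-8 — and CpGs with missing entries are fit individually.
Two-sided p-values use the Student-t reference with the full model's residual
degrees of freedom. Genomic inflation is
`λ_GC = median(χ²₁)/0.4549`. The genome-wide threshold defaults to
p < 3.6e-8. Degenerate CpGs (zero variance after correction, or too few
observations) are dropped with a warning and reported as missing.

On a permuted phenotype the block-correlated methylome leaves only a couple of
thousand effectively independent tests, so a single permutation's λ wanders by
several percent; calibration checks therefore average a handful of
permutations.

### bacon-style bias/inflation correction

Z-scores are modeled as a three-component Gaussian mixture — a central null
(mean = bias, SD = inflation) and two sign-constrained tail components — fitted
by Gibbs sampling (two chains with derived seeds; the potential scale
reduction factor of the null mean above 1.1 flags non-convergence). Two
choices matter for identifiability under a pure null, where an unconstrained
mixture happily splits the null between components: tail means are kept at
least 1.5 null-SDs away from the null mean, and the mixture weights get a
null-favoring Dirichlet prior (pseudo-counts n/10, 1, 1). With those in place
the fit recovers bias and inflation on shifted/inflated null samples to within
a few percent, while a 5% signal component at |z| ≈ 4 is still absorbed by the
tails. Corrected statistics are `z' = (z − μ̂)/σ̂`, `SE' = SE·σ̂`,
`effect' = effect − μ̂·SE`, with p-values from the normal reference.

### Independent signals

The number of approximately independent signals among the significant CpGs is
the smallest number of principal components covering ≥ 80% of the variance of
the standardized significant-CpG submatrix (computed from exact singular
values, with a 1e-9 slack so analytic ties such as 4/5 = 0.80 count as
reached).

## Joint Bayesian EWAS

All standardized CpG effects are estimated simultaneously under a
spike-and-slab Gaussian-mixture prior: effect `β_j` is zero (spike) or drawn
from one of three slabs with variances {1e-4, 1e-3, 1e-2} × a common scale
σ²_β. A Gibbs sampler visits CpGs in a freshly permuted order each iteration,
samples the component assignment from the conditional marginal likelihood and
the effect from its Gaussian conditional, updating the residual vector
incrementally (the end-of-chain residual is verified against a full
recomputation to 1e-8 in the tests). Mixture proportions, σ²_β and σ²_e are
re-sampled each iteration; covariates enter as unpenalized fixed effects
re-drawn from their exact Gaussian conditional. The inner loop is numba-jitted
and fully seeded.

One prior choice departs from the flat Dirichlet(counts + 1) update on the
mixture proportions. Under the exact null the marginal likelihood ratio
between spike and any slab integrates to one, so with a flat prior the
occupancy of the smallest slab is a marginally stable random walk: null CpGs
drift in and out freely, inflating PIPs (measured null mean PIP 0.16) and the
variance explained (+0.13 at p/n = 2.5). The spike therefore carries a
Dirichlet pseudo-count of p/10 (slabs keep 1). This restores geometric drift
of null occupancy toward zero while leaving real signals untouched — their
log Bayes factors are an order of magnitude larger than the prior log-odds.
With it, a pure-null run has mean PIP < 0.005 and no PIP ≥ 0.95 calls; a
single CpG explaining 20% of variance at n = 2,000 gets PIP 1.0 with its
effect recovered within 25%; 50 causal CpGs explaining 40% recover the
variance explained within ±0.08 (the estimate sits a few points high because
`var(Xβ)/var(y)` per iteration includes posterior draw noise); and the
empirical false discovery rate of PIP ≥ 0.95 calls stays at or below 5% over
20 replicates.

Under confounding, the joint model legitimately recruits three kinds of CpGs
beyond the marginal threshold's reach: causal CpGs with sub-threshold marginal
evidence, correlated block-mates acting as conditional (suppressor) terms, and
latent-factor-loaded CpGs serving as proxies for the unmeasured confounder —
the advertised "controls for unknown confounders" behavior of joint penalized
regression.

Defaults are 10,000 iterations, 5,000 burn-in, thinning 5; the reduced preset
(1,000–1,500 iterations, 400–500 burn-in, thinning 2) is used throughout the
tests and the pipeline, where the posterior summaries of interest (PIPs,
variance explained) are stable across seeds to within 0.03.

### Desk-scale power and the count hierarchy

The qualitative comparison-table pattern — marginal counts ≫ PC-adjusted
counts ≫ PIP ≥ 0.95 counts, with the Bayesian calls largely contained in the
PC-adjusted calls — is a power phenomenon. At n = 2,000 a CpG passes
p < 3.6e-8 only at |z| ≳ 5.5, and a whole correlated block tags along only
when the lead CpG reaches |z| ≳ 9. The confounded demonstration cohort
therefore concentrates the causal variance in 10 CpGs within tightly
correlated blocks (ρ = 0.7), the regime where the marginal EWAS calls whole
blocks genome-wide while the joint model collapses each block to its lead CpG.
With 50 equal causal effects (per-CpG z ≈ 4) the hierarchy inverts at this
sample size — the joint model out-calls the marginal threshold — which is a
fact about desk-scale power, not about the methods.

## EpiScores

Scores are trained on the residualized trait (the same files the EWAS uses)
with the elastic net at l1-ratio 0.5, lambda chosen to minimize k-fold
cross-validated MSE (20 folds by default; fold assignment from the seed) on
the probe set intersected with the target cohort *before* fitting. Training
runs through scikit-learn's coordinate descent; a hand-rolled coordinate
descent solver serves as the independent oracle in the tests (agreement to
1e-4), and the single-standardized-predictor solution
`S(b, λα)/(1 + λ(1−α))` is exercised exactly. The library default lambda path
(100 points down to 1e-3 of λ_max) is retained in the API; the pipeline
truncates to 60 points down to 0.02 because the CV optimum sits well above the
floor on these cohorts and the small-λ tail of the path dominates runtime on
correlated designs. Fold assignment ignores family structure — at the default
relatedness (400 of 2,000 samples in sibling pairs) this slightly flatters CV
error, a known limitation.

Projection is the weighted sum over the model's CpGs on the training
standardization, with training-mean imputation of absent or per-sample-missing
CpGs (an imputed CpG contributes exactly zero); a warning flags projections
with more than half the weight CpGs absent. Bayesian posterior-mean effects
project through the identical contract. Evaluation is the incremental R²:
R²(trait ~ age + sex + score) − R²(trait ~ age + sex), on the whole cohort
(plus subgroup dummies when subgroups exist) and per subgroup (without the
dummies); subgroups under 30 samples are flagged. A constructed score carrying
20% of trait variance evaluates to incremental R² 0.20 ± 0.04 at n = 2,000,
and a subgroup with coupling 0.4 shows roughly (0.4)² ≈ one-sixth of the
strong subgroups' incremental R², the analogue of heterogeneous score
transportability across populations.

## Cognitive growth model

The latent growth model is deliberately two-stage rather than a simultaneous
structural equation model (whose exact specification would add many knobs this
package cannot validate): (1) a single common factor across tests, loadings
taken from the first eigenvector of the pooled within-wave covariance (fixed
across waves, normalized to mean 1) and factor scores computed as the
loading-weighted projection over each sample's available tests; (2) a
random-intercept random-slope mixed model of factor scores on years since
baseline, fitted by REML (statsmodels MixedLM), giving empirical-Bayes
per-person intercepts and slopes. Samples with one wave inform the intercept
only. Noiseless data with unit loadings reproduce the latent values exactly
(the degenerate zero-residual case bypasses the mixed model, whose likelihood
is singular there). The two-stage estimator targets the same estimands as the
SEM formulation; with four tests at noise SD 0.5 it recovers true intercepts
at r > 0.98 and a simulated standardized intercept-association of −0.10 within
±0.07 at n = 861.

Associations regress each standardized cognitive outcome (intercept, slope) on
each standardized predictor with age and sex (basic model; the full model adds
a configurable covariate set), with Benjamini–Hochberg FDR across the
predictor family within each outcome. The variance decomposition reports
incremental R² on the intercept for the measured trait alone, the EpiScore
alone, and both.

## Pipeline and reproducibility

`run_pipeline` executes the stage chain
simulate → preprocess → covariates → ewas → bayes → episcore → cognition from
one `RunConfig` (YAML-loadable), with per-stage seeds derived as
`sha256(global_seed:stage) mod 2^31` so stage reproducibility is independent of
stage order. The manifest records versions, seeds, output hashes and wall
times; identical configs give byte-identical summary TSV/JSON outputs,
including all stochastic stages. The `episcope` CLI exposes each stage (stage
commands run their prerequisites; `train`/`project`/`evaluate` map onto the
episcore stage) plus `simulate` and `all`.

`scripts/acceptance.py` regenerates everything from scratch at desk scale —
two confounded 2,000 × 20,000 cohorts (default conditions for calibration,
concentrated-signal conditions for the count hierarchy), clean recovery
cohorts for the Bayesian and elastic-net checks, and the cognition cohort —
and writes the computed quantities as JSON. The full run takes a few minutes
on one CPU.

## Known limitations

- Starts from post-QC beta matrices: no raw-intensity processing, detection-p
  or bead-count QC, and no probe-type-aware normalization.
- The generator does not emulate probe chemistry, genotype-methylation
  (meQTL) structure, or realistic linkage between blocks; passing tests show
  the statistics behave correctly under the assumed structure, not that the
  structure matches any particular cohort.
- Known covariates are modeled as unpenalized fixed effects in the joint
  model; latent-component estimation inside the sampler is not implemented
  (the marginal pipeline's PC adjustment covers that role).
- Cross-validation folds ignore relatedness.
- The cognitive model has no practice effects, no early-life ability
  adjustment, and no informative-dropout correction.
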