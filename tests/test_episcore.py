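"""EpiScore tests: probe intersection, elastic-net closed form and
independent-solver agreement, projection/imputation contracts, and
incremental-R^2 evaluation."""

import numpy as np
import pandas as pd
import pytest

from episcope.containers import BETA, MethylationMatrix
from episcope.episcore import (
    EpiScoreModel,
    elnet_fixed_lambda,
    incremental_r2,
    intersect_probes,
    project_score,
    train_elnet,
)
from episcope.preprocess import ResidualizedPhenotype


def _pheno(y, ids):
    return ResidualizedPhenotype(
        "trait", pd.Series(y, index=ids),
        {"sigma2_g": 0.0, "sigma2_e": 1.0, "lambda": 0.0},
        pd.Series([0.0], index=["intercept"]),
    )


def _beta_mat(values, ids=None, cpgs=None):
    values = np.asarray(values, dtype=float)
    return MethylationMatrix(
        values,
        ids or [f"s{i}" for i in range(values.shape[0])],
        cpgs or [f"cg{j:04d}" for j in range(values.shape[1])],
        scale=BETA,
    )


def _coordinate_descent_oracle(X, y, alpha, lam, n_iter=5000):
    """Independent coordinate-descent elastic net (glmnet objective)."""
    n, p = X.shape
    ybar = y.mean()
    xbar = X.mean(axis=0)
    Xc, yc = X - xbar, y - ybar
    b = np.zeros(p)
    col_ss = (Xc**2).sum(axis=0) / n
    for _ in range(n_iter):
        b_old = b.copy()
        for j in range(p):
            r_j = yc - Xc @ b + Xc[:, j] * b[j]
            rho = Xc[:, j] @ r_j / n
            b[j] = np.sign(rho) * max(abs(rho) - lam * alpha, 0.0) / (
                col_ss[j] + lam * (1 - alpha)
            )
        if np.abs(b - b_old).max() < 1e-12:
            break
    return b


class TestIntersectProbes:
    def test_identical_sets(self, rng):
        a = _beta_mat(rng.uniform(0.1, 0.9, (3, 5)))
        assert intersect_probes(a, a) == sorted(a.cpg_ids)

    def test_partial_overlap(self, rng):
        a = _beta_mat(rng.uniform(0.1, 0.9, (3, 3)), cpgs=["a", "b", "c"])
        b = _beta_mat(rng.uniform(0.1, 0.9, (3, 3)), cpgs=["b", "c", "d"])
        assert intersect_probes(a, b) == ["b", "c"]

    def test_disjoint_rejected(self, rng):
        a = _beta_mat(rng.uniform(0.1, 0.9, (3, 2)), cpgs=["a", "b"])
        b = _beta_mat(rng.uniform(0.1, 0.9, (3, 2)), cpgs=["c", "d"])
        with pytest.raises(ValueError):
            intersect_probes(a, b)


class TestElasticNet:
    def test_single_predictor_closed_form(self, rng):
        # standardized predictor with OLS coefficient 1.0 at lam=0.5,
        # alpha=0.5: soft-threshold solution S(1, 0.25)/1.25 = 0.6
        n = 400
        x = rng.normal(size=n)
        x = (x - x.mean()) / x.std()
        y = x.copy()  # OLS coefficient exactly 1
        coef = elnet_fixed_lambda(x[:, None], y, alpha=0.5, lam=0.5)
        assert coef[0] == pytest.approx(0.6, abs=1e-6)

    def test_matches_coordinate_descent_oracle(self, rng):
        n, p = 200, 50
        X = rng.normal(size=(n, p))
        y = X[:, :5] @ np.array([1.0, -0.8, 0.6, 0.4, -0.3]) + rng.normal(size=n)
        for lam in (0.05, 0.2, 1.0):
            ours = elnet_fixed_lambda(X, y, alpha=0.5, lam=lam)
            oracle = _coordinate_descent_oracle(X, y, alpha=0.5, lam=lam)
            assert np.abs(ours - oracle).max() < 1e-4

    def test_lasso_sparsity_monotone_in_lambda(self, rng):
        n, p = 150, 40
        X = rng.normal(size=(n, p))
        y = X[:, :3].sum(axis=1) + rng.normal(size=n)
        nnz = [
            int((elnet_fixed_lambda(X, y, alpha=1.0, lam=l) != 0).sum())
            for l in (0.01, 0.05, 0.2, 0.8)
        ]
        assert nnz == sorted(nnz, reverse=True)

    def test_null_phenotype_selects_near_empty_model(self, rng):
        n, p = 300, 1000
        X = rng.uniform(0.05, 0.95, size=(n, p))
        mat = _beta_mat(X)
        nnz = []
        for seed in range(5):
            y = np.random.default_rng(seed).normal(size=n)
            m = train_elnet(_pheno(y, mat.sample_ids), mat, n_folds=5, seed=seed)
            nnz.append(len(m.weights))
        assert np.median(nnz) <= 5

    def test_causal_recovery(self, bundle_plain, resid_plain):
        # every causal CpG carries an equal, detectable variance share here
        model = train_elnet(
            resid_plain, bundle_plain.methylation, n_folds=10, seed=1,
            n_lambdas=60, lambda_min_ratio=0.02,
        )
        causal = set(bundle_plain.truth["trait"].causal_cpg_ids)
        assert len(causal & set(model.weights)) / len(causal) >= 0.9

    def test_fold_validation(self, rng):
        mat = _beta_mat(rng.uniform(0.1, 0.9, (10, 5)))
        with pytest.raises(ValueError, match="n_folds"):
            train_elnet(_pheno(rng.normal(size=10), mat.sample_ids), mat, n_folds=20)


class TestProjection:
    @staticmethod
    def _model():
        return EpiScoreModel(
            trait_name="trait",
            weights={"cgA": 0.5, "cgB": -0.3},
            intercept=2.0,
            training_cpg_means={"cgA": 0.6, "cgB": 0.4},
            training_cpg_sds={"cgA": 0.1, "cgB": 0.2},
            alpha=0.5,
            lambda_selected=0.1,
            n_folds=5,
            training_n=100,
            probe_universe_size=2,
        )

    def test_training_means_give_intercept(self):
        model = self._model()
        test = _beta_mat(np.array([[0.6, 0.4]]), cpgs=["cgA", "cgB"])
        assert project_score(model, test).iloc[0] == pytest.approx(2.0)

    def test_all_weight_cpgs_absent_all_imputed(self):
        model = self._model()
        test = _beta_mat(np.array([[0.5]]), cpgs=["other"])
        with pytest.warns(UserWarning, match="absent"):
            score = project_score(model, test)
        assert np.allclose(score, 2.0)

    def test_invariant_to_column_order(self, rng):
        model = self._model()
        v = rng.uniform(0.1, 0.9, size=(4, 2))
        a = project_score(model, _beta_mat(v, cpgs=["cgA", "cgB"]))
        b = project_score(model, _beta_mat(v[:, ::-1], cpgs=["cgB", "cgA"]))
        assert np.allclose(a, b)

    def test_heldout_correlation_matches_holdout_estimate(self, bundle_plain):
        # two out-of-sample estimates of the same quantity agree: a held-out
        # slice of the training cohort vs a freshly drawn test cohort
        from episcope.preprocess import residualize_trait
        from episcope.synthdata import simulate_test_cohort

        train = bundle_plain.methylation.subset_samples(bundle_plain.sample_ids[:700])
        holdout = bundle_plain.methylation.subset_samples(bundle_plain.sample_ids[700:])
        pheno = residualize_trait(
            bundle_plain.phenotypes.iloc[:700], "trait", bundle_plain.kinship[:700, :700]
        )
        model = train_elnet(pheno, train, n_folds=10, seed=2,
                            n_lambdas=60, lambda_min_ratio=0.02)
        test = simulate_test_cohort(bundle_plain, 1.0, 1000, seed=3, missing_rate=0.0)
        r_hold = np.corrcoef(
            project_score(model, holdout), bundle_plain.phenotypes["trait"].iloc[700:]
        )[0, 1]
        r_test = np.corrcoef(
            project_score(model, test.methylation), test.phenotypes["trait"]
        )[0, 1]
        assert r_test == pytest.approx(r_hold, abs=0.1)
        assert r_test > 0.4


class TestIncrementalR2:
    @staticmethod
    def _data(rng, n=2000):
        ids = [f"s{i}" for i in range(n)]
        cov = pd.DataFrame(
            {"age": rng.uniform(20, 80, n), "sex": rng.integers(0, 2, n)}, index=ids
        )
        return ids, cov

    def test_orthogonal_score_near_zero(self, rng):
        # averaged over replicates the null incremental R^2 is ~ 1/n
        ids, cov = self._data(rng)
        vals = []
        for _ in range(20):
            trait = pd.Series(rng.normal(size=2000), index=ids)
            score = pd.Series(rng.normal(size=2000), index=ids)
            vals.append(incremental_r2(trait, score, cov).incremental_r2)
        assert abs(np.mean(vals)) < 2 / 2000

    def test_score_equal_trait(self, rng):
        ids, cov = self._data(rng, n=300)
        trait = pd.Series(rng.normal(size=300) + 0.01 * cov["age"], index=ids)
        res = incremental_r2(trait, trait.copy(), cov)
        assert res.full_r2 == pytest.approx(1.0, abs=1e-10)
        assert res.incremental_r2 == pytest.approx(1.0 - res.base_r2, abs=1e-10)

    def test_constructed_twenty_percent_score(self, rng):
        ids, cov = self._data(rng)
        latent = rng.normal(size=2000)
        trait = pd.Series(
            np.sqrt(0.2) * latent + np.sqrt(0.8) * rng.normal(size=2000), index=ids
        )
        score = pd.Series(latent, index=ids)
        res = incremental_r2(trait, score, cov)
        assert res.incremental_r2 == pytest.approx(0.20, abs=0.04)

    def test_affine_rescaling_invariance(self, rng):
        ids, cov = self._data(rng, n=500)
        trait = pd.Series(rng.normal(size=500), index=ids)
        score = pd.Series(rng.normal(size=500) + 0.3 * trait, index=ids)
        a = incremental_r2(trait, score, cov)
        b = incremental_r2(trait, 5.0 * score - 7.0, cov)
        assert a.incremental_r2 == pytest.approx(b.incremental_r2, abs=1e-12)

    def test_subgroup_models_and_small_sample_flag(self, rng):
        ids, cov = self._data(rng, n=400)
        latent = rng.normal(size=400)
        sub = pd.Series(["A"] * 380 + ["B"] * 20, index=ids)
        trait = pd.Series(np.sqrt(0.3) * latent + rng.normal(size=400), index=ids)
        score = pd.Series(latent, index=ids)
        res = incremental_r2(trait, score, cov, subgroup=sub)
        assert set(res.by_subgroup) == {"A", "B"}
        assert res.by_subgroup["B"]["small_sample"] is True
        assert any("n=20" in f for f in res.flags)

    def test_weak_coupling_subgroup_has_lower_r2(self, bundle_plain, resid_plain):
        from episcope.synthdata import simulate_test_cohort

        model = train_elnet(
            resid_plain, bundle_plain.methylation, n_folds=10, seed=4,
            n_lambdas=60, lambda_min_ratio=0.02,
        )
        test = simulate_test_cohort(
            bundle_plain, 1.0, 1500, seed=5, missing_rate=0.0,
            subgroups={"strong": (0.5, 1.0), "weak": (0.5, 0.35)},
        )
        score = project_score(model, test.methylation)
        res = incremental_r2(
            test.phenotypes["trait"], score, test.phenotypes[["age", "sex"]],
            subgroup=test.phenotypes["subgroup"],
        )
        strong = res.by_subgroup["strong"]["incremental_r2"]
        weak = res.by_subgroup["weak"]["incremental_r2"]
        assert strong > weak + 0.05
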