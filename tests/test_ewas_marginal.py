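"""Marginal EWAS tests: closed-form OLS oracle equivalence, type-I error,
power, significance calling, bacon bias/inflation recovery, independent-signal
counting and set operations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from episcope.containers import CORRECTED_M, MethylationMatrix
from episcope.ewas_marginal import (
    BaconFit,
    annotate_cpgs,
    apply_bacon,
    call_significant,
    count_independent_signals,
    cross_trait_overlap,
    fit_bacon,
    lambda_gc,
    run_marginal_ewas,
)
from episcope.preprocess import ResidualizedPhenotype


def _pheno(y, ids):
    return ResidualizedPhenotype(
        "trait",
        pd.Series(y, index=ids),
        {"sigma2_g": 0.0, "sigma2_e": 1.0, "lambda": 0.0},
        pd.Series([0.0], index=["intercept"]),
    )


def _mat(values):
    values = np.asarray(values, dtype=float)
    return MethylationMatrix(
        values,
        [f"s{i}" for i in range(values.shape[0])],
        [f"cg{j:05d}" for j in range(values.shape[1])],
        scale=CORRECTED_M,
    )


class TestMarginalOls:
    def test_six_point_hand_computed_t(self):
        # one CpG, no covariates: t from the closed-form simple-regression
        # formula t = r * sqrt(df / (1 - r^2)) on six fixed points
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([1.2, 1.9, 3.4, 3.6, 5.5, 5.9])
        mat = _mat(x[:, None])
        res = run_marginal_ewas(_pheno(y, mat.sample_ids), mat)
        r = np.corrcoef(x, y)[0, 1]
        t_oracle = r * np.sqrt(4 / (1 - r**2))
        assert res.table["t"].iloc[0] == pytest.approx(t_oracle, abs=1e-10)
        assert res.table["p"].iloc[0] == pytest.approx(
            2 * stats.t.sf(abs(t_oracle), 4), abs=1e-12
        )

    def test_matches_full_ols_oracle_with_covariates(self, rng):
        n, p, k = 150, 100, 3
        X = rng.normal(size=(n, p))
        C = rng.normal(size=(n, k))
        y = X[:, 0] * 0.3 + C @ [0.5, -0.2, 0.1] + rng.normal(size=n)
        mat = _mat(X)
        cov = pd.DataFrame(C, index=mat.sample_ids, columns=list("abc"))
        res = run_marginal_ewas(_pheno(y, mat.sample_ids), mat, cov)
        Xs = (X - X.mean(axis=0)) / X.std(axis=0)
        for j in range(p):
            D = np.column_stack([np.ones(n), C, Xs[:, j]])
            coef, *_ = np.linalg.lstsq(D, y, rcond=None)
            resid = y - D @ coef
            dfree = n - D.shape[1]
            se = np.sqrt(
                resid @ resid / dfree * np.linalg.inv(D.T @ D)[-1, -1]
            )
            assert res.table["effect"].iloc[j] == pytest.approx(coef[-1], abs=1e-8)
            assert res.table["se"].iloc[j] == pytest.approx(se, abs=1e-8)

    def test_p_consistent_with_t_and_df(self, resid_small, corrected_small):
        res = run_marginal_ewas(resid_small, corrected_small)
        tb = res.table.dropna()
        dfree = tb["n_used"] - 2
        p_expected = 2 * stats.t.sf(np.abs(tb["t"]), dfree)
        assert np.abs(tb["p"] - p_expected).max() < 1e-10

    def test_per_cpg_missing_samples_dropped(self, rng):
        n = 80
        X = rng.normal(size=(n, 3))
        X[:10, 1] = np.nan
        y = rng.normal(size=n)
        mat = _mat(X)
        res = run_marginal_ewas(_pheno(y, mat.sample_ids), mat)
        assert res.table["n_used"].tolist() == [n, n - 10, n]
        obs = np.isfinite(X[:, 1])
        xs = (X[obs, 1] - X[obs, 1].mean()) / X[obs, 1].std()
        D = np.column_stack([np.ones(obs.sum()), xs])
        coef, *_ = np.linalg.lstsq(D, y[obs], rcond=None)
        assert res.table["effect"].iloc[1] == pytest.approx(coef[-1], abs=1e-10)

    def test_power_standardized_effect(self, rng):
        # standardized effect 0.1 at n=2000 gives expected t ~ 4.5
        n = 2000
        x = rng.normal(size=n)
        xs = (x - x.mean()) / x.std()
        y = 0.1 * xs + np.sqrt(1 - 0.01) * rng.normal(size=n)
        mat = _mat(x[:, None])
        res = run_marginal_ewas(_pheno(y, mat.sample_ids), mat)
        assert res.table["t"].iloc[0] == pytest.approx(0.1 * np.sqrt(n), abs=1.5)

    def test_collinear_covariates_rejected(self, rng):
        n = 50
        C = rng.normal(size=(n, 1))
        cov = pd.DataFrame(
            np.column_stack([C, 2 * C]), index=[f"s{i}" for i in range(n)],
            columns=["a", "b"],
        )
        mat = _mat(rng.normal(size=(n, 2)))
        with pytest.raises(ValueError, match="collinear"):
            run_marginal_ewas(_pheno(rng.normal(size=n), mat.sample_ids), mat, cov)

    def test_pc_adjustment_reduces_confounded_false_positives(
        self, bundle_small, resid_small, corrected_small
    ):
        from episcope.covariates import methylome_pcs

        pcs, _ = methylome_pcs(corrected_small, 20)
        base = run_marginal_ewas(resid_small, corrected_small)
        adj = run_marginal_ewas(resid_small, corrected_small, pcs, model_tag="pc_adjusted")
        causal = set(bundle_small.truth["trait"].causal_cpg_ids)
        null_ids = [c for c in corrected_small.cpg_ids if c not in causal]
        fp_base = (base.table.loc[null_ids, "p"] < 1e-5).sum()
        fp_adj = (adj.table.loc[null_ids, "p"] < 1e-5).sum()
        assert fp_adj < fp_base
        assert adj.table["n_used"].max() <= base.table["n_used"].max()


class TestCallSignificant:
    def test_default_threshold_count(self):
        tb = pd.DataFrame(
            {"effect": [1, 1], "se": [1, 1], "t": [1, 1], "p": [1e-9, 1e-7],
             "n_used": [10, 10]},
            index=pd.Index(["cgA", "cgB"], name="cpg_id"),
        )
        res_obj = type("R", (), {"table": tb})()
        assert call_significant(res_obj) == ["cgA"]

    def test_threshold_one_returns_all_sorted(self, resid_small, corrected_small):
        res = run_marginal_ewas(resid_small, corrected_small)
        ids = call_significant(res, 1.0)
        assert len(ids) == res.table["p"].notna().sum()
        ps = res.table.loc[ids, "p"].to_numpy()
        assert np.all(np.diff(ps) >= 0)

    def test_monotone_in_threshold(self, resid_small, corrected_small):
        res = run_marginal_ewas(resid_small, corrected_small)
        loose = set(call_significant(res, 1e-3))
        strict = set(call_significant(res, 1e-6))
        assert strict <= loose


class TestBacon:
    def test_standard_null_recovered(self, rng):
        z = rng.normal(0, 1, 10000)
        fit = fit_bacon(z, seed=1, n_iterations=1500, burn_in=500)
        assert fit.bias_mu == pytest.approx(0.0, abs=0.03)
        assert fit.inflation_sigma == pytest.approx(1.0, abs=0.03)

    def test_shifted_inflated_null_recovered(self, rng):
        z = rng.normal(0.5, 1.5, 10000)
        fit = fit_bacon(z, seed=2, n_iterations=1500, burn_in=500)
        assert fit.bias_mu == pytest.approx(0.5, abs=0.05)
        assert fit.inflation_sigma == pytest.approx(1.5, abs=0.05)

    def test_signal_absorbed_by_tail_component(self, rng):
        z = np.concatenate([rng.normal(0, 1.3, 9500), rng.normal(4, 1, 500)])
        fit = fit_bacon(z, seed=3, n_iterations=1500, burn_in=500)
        assert fit.inflation_sigma == pytest.approx(1.3, abs=0.1)

    def test_two_seeds_agree(self, rng):
        z = rng.normal(0, 1, 10000)
        f1 = fit_bacon(z, seed=10, n_iterations=1500, burn_in=500)
        f2 = fit_bacon(z, seed=20, n_iterations=1500, burn_in=500)
        assert abs(f1.bias_mu - f2.bias_mu) < 0.02
        assert abs(f1.inflation_sigma - f2.inflation_sigma) < 0.02

    def test_apply_identity_fit_is_noop(self, resid_small, corrected_small):
        res = run_marginal_ewas(resid_small, corrected_small)
        fit = BaconFit(0.0, 1.0, np.array([1, 0, 0]), np.zeros(2), np.ones(2), 0, 0)
        out = apply_bacon(res, fit)
        assert np.allclose(out.table["effect"], res.table["effect"])
        assert np.allclose(out.table["se"], res.table["se"])

    def test_apply_halves_z_at_sigma_two(self, resid_small, corrected_small):
        res = run_marginal_ewas(resid_small, corrected_small)
        fit = BaconFit(0.0, 2.0, np.array([1, 0, 0]), np.zeros(2), np.ones(2), 0, 0)
        out = apply_bacon(res, fit)
        assert np.allclose(out.table["t"], res.zscores() / 2.0)

    def test_correction_restores_null_lambda(self, rng):
        z = rng.normal(0.4, 1.6, 10000)
        p = 2 * stats.norm.sf(np.abs(z))
        assert lambda_gc(p) > 2.0
        fit = fit_bacon(z, seed=4, n_iterations=1500, burn_in=500)
        z_corr = (z - fit.bias_mu) / fit.inflation_sigma
        p_corr = 2 * stats.norm.sf(np.abs(z_corr))
        assert lambda_gc(p_corr) == pytest.approx(1.0, abs=0.05)


class TestIndependentSignals:
    def test_ten_orthogonal_cpgs_need_eight_pcs(self, rng):
        n = 40
        raw = np.column_stack([np.ones(n), rng.normal(size=(n, 10))])
        Q, _ = np.linalg.qr(raw)
        X = Q[:, 1:11]  # orthonormal, zero-mean -> sample correlation is I
        mat = _mat(X)
        assert count_independent_signals(mat, mat.cpg_ids) == 8

    def test_five_perfect_blocks_need_four_pcs(self, rng):
        n = 30
        raw = np.column_stack([np.ones(n), rng.normal(size=(n, 5))])
        Q, _ = np.linalg.qr(raw)
        base = Q[:, 1:6]
        X = np.repeat(base, 4, axis=1)  # 5 blocks x 4 perfectly correlated
        mat = _mat(X)
        assert count_independent_signals(mat, mat.cpg_ids) == 4

    def test_single_cpg(self, corrected_small):
        assert count_independent_signals(corrected_small, [corrected_small.cpg_ids[0]]) == 1

    def test_empty_rejected(self, corrected_small):
        with pytest.raises(ValueError):
            count_independent_signals(corrected_small, [])


class TestSetOps:
    def test_cross_trait_overlap(self):
        assert cross_trait_overlap({"a": ["x"], "b": ["y"]}) == []
        assert cross_trait_overlap({"a": ["x", "y"], "b": ["x", "y"]}) == ["x", "y"]
        assert cross_trait_overlap(
            {"t1": ["A", "B", "C"], "t2": ["B", "C"], "t3": ["C"]}
        ) == ["C"]

    def test_annotate_join_semantics(self):
        man = pd.DataFrame(
            {
                "cpg_id": ["cg1", "cg2"],
                "chrom": ["chr1", "chr2"],
                "position": [100, 200],
                "gene": ["GENE1", ""],
            }
        )
        out = annotate_cpgs(["cg1", "cg2", "cg3"], man)
        assert len(out) == 3
        assert out.loc[out.cpg_id == "cg1", "gene"].iloc[0] == "GENE1"
        assert out["unmapped"].tolist() == [False, False, True]

    def test_annotate_duplicate_manifest_warns(self):
        man = pd.DataFrame(
            {
                "cpg_id": ["cg1", "cg1"],
                "chrom": ["chr1", "chr9"],
                "position": [1, 2],
                "gene": ["A", "B"],
            }
        )
        with pytest.warns(UserWarning, match="duplicate"):
            out = annotate_cpgs(["cg1"], man)
        assert out["gene"].iloc[0] == "A"
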