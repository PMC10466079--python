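"""Linear model fits, empirical-Bayes shrinkage, moderated tests, BH."""


import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from conftest import make_qm, two_group_design
from proteoflow.diffstats import (
    DifferentialModel,
    ShrinkageParams,
    add_rejections,
    adjust_bh,
    fit_linear_models,
    moderated_test,
    squeeze_var,
    trigamma_inverse,
)
from proteoflow.synthetic import simulate_null_dataset


class TestFitLinearModels:
    def test_hand_ols_example(self):
        qm = make_qm(np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]]))
        fit = fit_linear_models(qm, ["A_vs_B"])
        assert fit.beta.iloc[0, 0] == pytest.approx(-3.0)
        assert fit.s2.iloc[0] == pytest.approx(1.0)
        assert fit.df_resid.iloc[0] == 4.0
        assert fit.u.iloc[0, 0] == pytest.approx(np.sqrt(2 / 3))

    def test_constant_feature_zero_variance(self):
        qm = make_qm(np.full((1, 6), 7.0))
        fit = fit_linear_models(qm, ["A_vs_B"])
        assert fit.s2.iloc[0] == 0.0

    def test_matches_generic_lstsq_oracle(self, rng):
        X = rng.normal(20, 2, (500, 6))
        qm = make_qm(X)
        fit = fit_linear_models(qm, ["B_vs_A"])
        # independent oracle: design-matrix least squares per feature
        D = np.zeros((6, 2)); D[:3, 0] = 1; D[3:, 1] = 1
        for i in range(0, 500, 17):
            coef, res_ss, *_ = np.linalg.lstsq(D, X[i], rcond=None)
            assert fit.beta.iloc[i, 0] == pytest.approx(coef[1] - coef[0], abs=1e-10)
            assert fit.s2.iloc[i] == pytest.approx(float(res_ss[0]) / 4, abs=1e-10)

    def test_unknown_condition_errors(self):
        qm = make_qm(np.ones((1, 6)))
        with pytest.raises(ValueError, match="unknown condition"):
            fit_linear_models(qm, ["A_vs_C"])


class TestSqueezeVar:
    def test_identical_variances_give_infinite_prior_df(self):
        pr = squeeze_var(np.full(1000, 0.25), np.full(1000, 4.0))
        assert np.isinf(pr.d0)
        assert pr.s0_2 == pytest.approx(0.25, rel=1e-9)

    def test_recovers_prior_from_simulated_variances(self):
        # s2_g drawn from the scaled inverse-chi-squared hierarchy with
        # d0 = 4, s0^2 = 0.05, residual df 4
        rng = np.random.default_rng(42)
        d0, s02, d, n = 4.0, 0.05, 4.0, 5000
        sigma2 = d0 * s02 / rng.chisquare(d0, n)
        s2 = sigma2 * rng.chisquare(d, n) / d
        pr = squeeze_var(s2, np.full(n, d))
        assert 3.2 <= pr.d0 <= 4.8
        assert pr.s0_2 == pytest.approx(s02, rel=0.10)

    def test_trigamma_inverse_vs_bisection_oracle(self):
        from scipy.optimize import brentq

        for x in np.logspace(-5, 6, 23):
            y = trigamma_inverse(x)
            y_b = brentq(lambda z: special.polygamma(1, z) - x, 1e-9, 1e10,
                         xtol=1e-14, rtol=8.9e-16)
            assert y == pytest.approx(y_b, rel=1e-8)

    def test_all_zero_df_errors(self):
        with pytest.raises(ValueError):
            squeeze_var(np.ones(20), np.zeros(20))


class TestModeratedTest:
    def _fit(self, rng, n=50):
        return fit_linear_models(make_qm(rng.normal(20, 1, (n, 6))), ["A_vs_B"])

    def test_d0_zero_equals_ordinary_t(self, rng):
        fit = self._fit(rng)
        tab = moderated_test(fit, ShrinkageParams(d0=0.0, s0_2=1.0))
        t_ord = fit.beta.iloc[:, 0] / (fit.u.iloc[:, 0] * np.sqrt(fit.s2))
        assert np.allclose(tab["t_mod"], t_ord, atol=1e-12)
        assert (tab["df_total"] == 4.0).all()

    def test_d0_infinite_uses_normal_reference_with_prior_variance(self, rng):
        fit = self._fit(rng)
        s02 = 0.5
        tab = moderated_test(fit, ShrinkageParams(d0=np.inf, s0_2=s02))
        t_exp = fit.beta.iloc[:, 0] / (fit.u.iloc[:, 0] * np.sqrt(s02))
        assert np.allclose(tab["t_mod"], t_exp, atol=1e-12)
        assert np.allclose(tab["p"], 2 * stats.norm.sf(np.abs(t_exp)), atol=1e-12)

    def test_formula_oracle_example(self):
        # beta=0.6, u=sqrt(0.5), s2=0.04, d=4, s0^2=0.01, d0=2
        from proteoflow.diffstats import FitResult

        idx = pd.Index(["g"])
        fr = FitResult(
            beta=pd.DataFrame({"A_vs_B": [0.6]}, index=idx),
            s2=pd.Series([0.04], index=idx),
            df_resid=pd.Series([4.0], index=idx),
            u=pd.DataFrame({"A_vs_B": [np.sqrt(0.5)]}, index=idx),
            contrast_names=["A_vs_B"],
        )
        tab = moderated_test(fr, ShrinkageParams(d0=2.0, s0_2=0.01))
        s2_post = (2 * 0.01 + 4 * 0.04) / 6
        assert s2_post == pytest.approx(0.03)
        t_exp = 0.6 / (np.sqrt(0.5) * np.sqrt(s2_post))
        assert tab["t_mod"].iloc[0] == pytest.approx(t_exp, abs=1e-12)
        assert tab["df_total"].iloc[0] == 6.0
        assert tab["p"].iloc[0] == pytest.approx(2 * stats.t.sf(t_exp, 6), abs=1e-12)

    def test_posterior_variance_between_s2_and_prior(self, rng):
        fit = self._fit(rng, n=200)
        prior = squeeze_var(fit.s2, fit.df_resid)
        if np.isinf(prior.d0):
            pytest.skip("degenerate draw: no spread in variances")
        post = (prior.d0 * prior.s0_2 + fit.df_resid * fit.s2) / (prior.d0 + fit.df_resid)
        lo = np.minimum(fit.s2, prior.s0_2)
        hi = np.maximum(fit.s2, prior.s0_2)
        assert ((post >= lo - 1e-12) & (post <= hi + 1e-12)).all()


class TestAdjustBH:
    def test_single_p_unchanged(self):
        assert adjust_bh(np.array([0.3]))[0] == pytest.approx(0.3)

    def test_stepup_example(self):
        assert np.allclose(adjust_bh(np.array([0.01, 0.02, 0.03, 0.04])), 0.04)

    def test_matches_bruteforce_min_over_tails(self, rng):
        for _ in range(30):
            p = rng.uniform(0, 1, int(rng.integers(1, 40)))
            adj = adjust_bh(p)
            n = len(p)
            order = np.argsort(p, kind="stable")
            brute = np.empty(n)
            for rank_i, idx in enumerate(order):
                brute[idx] = min(
                    min(p[order[j]] * n / (j + 1) for j in range(rank_i, n)), 1.0
                )
            assert np.allclose(adj, brute, atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 200)
        assert np.allclose(adjust_bh(p), multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            adjust_bh(np.array([0.5, 1.5]))


class TestAddRejections:
    def test_gating_examples(self):
        tab = pd.DataFrame({"padj": [0.04, 0.04], "log2fc": [1.5, 0.5]})
        out = add_rejections(tab, alpha=0.05, lfc=1.0)
        assert list(out["significant"]) == [True, False]

    def test_flag_count_matches_bruteforce_conjunction(self, rng):
        tab = pd.DataFrame({"padj": rng.uniform(0, 1, 300), "log2fc": rng.normal(0, 1.2, 300)})
        out = add_rejections(tab, alpha=0.1, lfc=0.8)
        expected = int(((tab["padj"] <= 0.1) & (tab["log2fc"].abs() >= 0.8)).sum())
        assert int(out["significant"].sum()) == expected


class TestModelResultsInterface:
    def test_fit_returns_results_with_summary(self, rng):
        X, design = simulate_null_dataset(200, 3, 0.3, seed=4)
        res = DifferentialModel.from_dataframe(X, design, ["B_vs_A"]).fit()
        assert res.contrast_names == ["B_vs_A"]
        tab = res.contrast_table("B_vs_A")
        assert set(tab.columns) >= {"feature_id", "log2fc", "t_mod", "p", "padj", "significant"}
        text = res.summary()
        assert "prior df" in text and "B_vs_A" in text

    def test_padj_preserves_p_order_within_contrast(self, rng):
        X, design = simulate_null_dataset(300, 3, 0.3, seed=9)
        res = DifferentialModel.from_dataframe(X, design, ["B_vs_A"]).fit()
        tab = res.contrast_table("B_vs_A").sort_values("p")
        assert (tab["padj"].diff().dropna() >= -1e-15).all()

    def test_raw_scale_rejected(self, rng):
        qm = make_qm(np.exp2(rng.normal(25, 2, (40, 6))), scale="raw")
        with pytest.raises(ValueError, match="log-scale"):
            DifferentialModel(qm, ["A_vs_B"])


def test_moderated_chain_matches_limma_oracle(tmp_path, rng):
    """Independent cross-check of the full shrinkage + moderated-t chain
    against the reference empirical-Bayes implementation."""
    X = rng.normal(20, 1, (200, 6))
    X[:20, 3:] += 1.0
    ids = [f"g{i}" for i in range(200)]
    design = two_group_design(3)
    mat = pd.DataFrame(X, index=ids, columns=list(design["sample"]))
    mat.to_csv(tmp_path / "mat.tsv", sep="\t")
    script = tmp_path / "oracle.R"
    script.write_text(
        """
suppressMessages(library(limma))
args <- commandArgs(trailingOnly=TRUE)
m <- as.matrix(read.delim(args[1], row.names=1))
cond <- factor(rep(c("A","B"), each=3))
design <- model.matrix(~0+cond)
colnames(design) <- levels(cond)
fit <- lmFit(m, design)
fit2 <- contrasts.fit(fit, makeContrasts(B-A, levels=design))
fit2 <- eBayes(fit2)
out <- data.frame(logFC=fit2$coefficients[,1], t=fit2$t[,1], p=fit2$p.value[,1])
out$d0 <- fit2$df.prior
out$s02 <- fit2$s2.prior
write.table(out, args[2], sep="\t", quote=FALSE)
"""
    )
    res = subprocess.run(
        ["Rscript", str(script), str(tmp_path / "mat.tsv"), str(tmp_path / "out.tsv")],
        capture_output=True, text=True,
    )
    assert res.returncode == 0, res.stderr
    oracle = pd.read_csv(tmp_path / "out.tsv", sep="\t")

    mine = DifferentialModel.from_dataframe(mat, design, ["B_vs_A"]).fit(lfc=0.0)
    tab = mine.contrast_table("B_vs_A").set_index("feature_id")
    assert mine.prior.d0 == pytest.approx(oracle["d0"].iloc[0], rel=1e-4)
    assert mine.prior.s0_2 == pytest.approx(oracle["s02"].iloc[0], rel=1e-4)
    assert np.allclose(tab.loc[ids, "log2fc"], oracle["logFC"], atol=1e-8)
    assert np.allclose(tab.loc[ids, "t_mod"], oracle["t"], atol=1e-5)
    assert np.allclose(tab.loc[ids, "p"], oracle["p"], atol=1e-8)
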