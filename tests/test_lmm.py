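"""The mixed-model core: likelihood, fitting, inference, likelihood-ratio
machinery — each checked against an independent oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import multivariate_normal

from conftest import ri_dataset
from phenolmm.exceptions import DataError, NumericError, UnsupportedModelError
from phenolmm.lmm import (
    LmmSpec,
    fit_lmm,
    loglik_lmm,
    lrt,
    marginal_r2_f2,
    satterthwaite_df,
    wald_t_test,
)


def dense_mvn_loglik(df, spec, vp, beta):
    """Brute-force oracle: explicit per-group covariance, scipy's MVN density."""
    ll = 0.0
    for _, sub in df.groupby("patient_id"):
        sub = sub.sort_values("month_index")
        n = len(sub)
        X = np.column_stack([np.ones(n)] + [sub[t] for t in spec.fixed_terms])
        if spec.has_slope:
            Z = np.column_stack([np.ones(n), sub[spec.slope_term]])
            G = np.array(
                [
                    [vp["sigma2_intercept"], vp["cov_intercept_slope"]],
                    [vp["cov_intercept_slope"], vp["sigma2_slope"]],
                ]
            )
        else:
            Z = np.ones((n, 1))
            G = np.array([[vp["sigma2_intercept"]]])
        rho = vp.get("rho") or 0.0
        idx = np.arange(n)
        V = Z @ G @ Z.T + vp["sigma2_resid"] * rho ** np.abs(idx[:, None] - idx[None, :])
        ll += multivariate_normal.logpdf(sub[spec.outcome], X @ np.asarray(beta), V)
    return ll


def _tiny_dataset(rng):
    n_groups = int(rng.integers(2, 6))
    sizes = rng.integers(1, 7, size=n_groups)
    pid = np.repeat(np.arange(n_groups), sizes)
    n = pid.size
    return pd.DataFrame(
        {
            "patient_id": pid,
            "month_index": np.concatenate([np.arange(s) for s in sizes]),
            "x": rng.normal(size=n),
            "y": rng.normal(size=n),
        }
    )


class TestLoglik:
    @pytest.mark.parametrize("structure", ["RI", "RI_AR1", "RI_RS", "RI_RS_AR1"])
    def test_matches_dense_mvn_oracle(self, structure):
        rng = np.random.default_rng(42)
        spec = LmmSpec("y", ("x",), structure)
        for _ in range(25):
            df = _tiny_dataset(rng)
            vp = {
                "sigma2_resid": float(rng.uniform(0.2, 2.0)),
                "sigma2_intercept": float(rng.uniform(0.0, 2.0)),
                "sigma2_slope": float(rng.uniform(0.0, 1.0)),
                "rho": float(rng.uniform(-0.8, 0.8)) if spec.has_ar1 else None,
            }
            vp["cov_intercept_slope"] = (
                float(rng.uniform(-0.9, 0.9)) * np.sqrt(vp["sigma2_intercept"] * vp["sigma2_slope"])
            )
            beta = rng.normal(size=2)
            assert loglik_lmm(spec, df, vp, beta) == pytest.approx(
                dense_mvn_loglik(df, spec, vp, beta), abs=1e-8
            )

    def test_single_standard_normal_observation(self):
        df = pd.DataFrame({"patient_id": [0, 1], "month_index": [0, 0], "y": [0.0, 0.0]})
        ll = loglik_lmm(LmmSpec("y", ()), df, {"sigma2_resid": 1.0, "sigma2_intercept": 0.0}, [0.0])
        assert ll == pytest.approx(2 * (-0.5 * np.log(2 * np.pi)))

    def test_ar1_with_zero_rho_reduces_to_ri(self):
        df = ri_dataset(seed=9)
        vp = {"sigma2_resid": 1.1, "sigma2_intercept": 0.9, "rho": 0.0}
        beta = [1.8, 0.6]
        ll_ar1 = loglik_lmm(LmmSpec("y", ("x",), "RI_AR1"), df, vp, beta)
        ll_ri = loglik_lmm(LmmSpec("y", ("x",), "RI"), df, {k: vp[k] for k in ("sigma2_resid", "sigma2_intercept")}, beta)
        assert ll_ar1 == pytest.approx(ll_ri, abs=1e-8)

    def test_nonpsd_covariance_reported(self):
        df = ri_dataset(seed=1, n_groups=3, n_per=3)
        spec = LmmSpec("y", ("x",), "RI_RS")
        vp = {"sigma2_resid": 1e-12, "sigma2_intercept": 1.0, "sigma2_slope": 1.0,
              "cov_intercept_slope": 1.5}  # |cov| > sqrt(v0 v1): not PSD
        with pytest.raises(NumericError):
            loglik_lmm(spec, df, vp, [0.0, 0.0])


class TestFit:
    def test_noise_free_beta_recovery(self):
        rng = np.random.default_rng(0)
        pid = np.repeat(np.arange(5), 6)
        x = rng.normal(size=30)
        df = pd.DataFrame({"patient_id": pid, "month_index": np.tile(np.arange(6), 5),
                           "x": x, "y": 1.25 - 0.5 * x})
        fit = fit_lmm(LmmSpec("y", ("x",)), df)
        assert fit.beta == pytest.approx([1.25, -0.5], abs=1e-6)

    def test_balanced_closed_form_ml_oracle(self):
        rng = np.random.default_rng(3)
        G, n = 15, 7
        pid = np.repeat(np.arange(G), n)
        y = 3 + np.repeat(rng.normal(0, 1.3, G), n) + rng.normal(0, 0.9, G * n)
        df = pd.DataFrame({"patient_id": pid, "month_index": np.tile(np.arange(n), G), "y": y})
        fit = fit_lmm(LmmSpec("y", ()), df)
        ybar = np.array([y[pid == g].mean() for g in range(G)])
        ssw = sum(((y[pid == g] - ybar[g]) ** 2).sum() for g in range(G))
        s2e = ssw / (G * (n - 1))
        s2b = ((ybar - y.mean()) ** 2).mean() - s2e / n
        assert fit.beta[0] == pytest.approx(y.mean(), rel=1e-6)
        assert fit.var_params["sigma2_resid"] == pytest.approx(s2e, rel=1e-5)
        assert fit.var_params["sigma2_intercept"] == pytest.approx(s2b, rel=1e-4)

    @pytest.mark.parametrize("structure", ["RI", "RI_RS"])
    def test_cross_validated_against_statsmodels(self, structure):
        import statsmodels.formula.api as smf

        df = ri_dataset(seed=21, n_groups=20, n_per=10)
        if structure == "RI_RS":
            rng = np.random.default_rng(2)
            b1 = rng.normal(0, 0.6, 20)
            df["y"] = df["y"] + b1[df["patient_id"]] * df["x"]
        fit = fit_lmm(LmmSpec("y", ("x",), structure), df)
        re_formula = "~x" if structure == "RI_RS" else None
        sm = smf.mixedlm("y ~ x", df, groups=df["patient_id"], re_formula=re_formula).fit(reml=False)
        assert fit.beta == pytest.approx(sm.params.values[:2], rel=1e-3)
        assert fit.minus2_loglik == pytest.approx(-2 * sm.llf, rel=1e-6)
        assert fit.var_params["sigma2_resid"] == pytest.approx(sm.scale, rel=1e-3)
        assert fit.var_params["sigma2_intercept"] == pytest.approx(float(sm.cov_re.iloc[0, 0]), rel=2e-3)
        if structure == "RI_RS":
            assert fit.var_params["sigma2_slope"] == pytest.approx(float(sm.cov_re.iloc[1, 1]), rel=5e-3)

    def test_nesting_never_hurts_the_larger_model(self):
        df = ri_dataset(seed=13, n_groups=15, n_per=9)
        f_ri = fit_lmm(LmmSpec("y", ("x",), "RI"), df)
        f_ar = fit_lmm(LmmSpec("y", ("x",), "RI_AR1"), df, extra_starts=[[float(f_ri._theta[0]), 0.0]])
        f_rs = fit_lmm(LmmSpec("y", ("x",), "RI_RS"), df, extra_starts=[[float(f_ri._theta[0]), -12.0, 0.0]])
        tol = 1e-4
        assert f_ri.minus2_loglik >= f_ar.minus2_loglik - tol
        assert f_ri.minus2_loglik >= f_rs.minus2_loglik - tol

    def test_underdetermined_design_raises(self):
        df = pd.DataFrame({"patient_id": [0, 1], "month_index": [0, 0],
                           "x": [1.0, 2.0], "z": [0.3, 0.1], "y": [1.0, 2.0]})
        with pytest.raises(DataError):
            fit_lmm(LmmSpec("y", ("x", "z", "x")), df.iloc[:2])

    def test_single_group_raises(self):
        df = ri_dataset(seed=1, n_groups=1, n_per=8)
        with pytest.raises(DataError):
            fit_lmm(LmmSpec("y", ("x",)), df)


class TestSatterthwaite:
    def test_balanced_intercept_contrast_matches_between_groups_df(self):
        rng = np.random.default_rng(4)
        G, n = 38, 8
        pid = np.repeat(np.arange(G), n)
        y = 5 + np.repeat(rng.normal(0, 2, G), n) + rng.normal(0, 1, G * n)
        df = pd.DataFrame({"patient_id": pid, "month_index": np.tile(np.arange(n), G), "y": y})
        fit = fit_lmm(LmmSpec("y", ()), df)
        assert fit.satterthwaite_df[0] == pytest.approx(G - 1, rel=0.05)

    def test_degenerate_random_effects_give_residual_df(self):
        rng = np.random.default_rng(5)
        G, n = 20, 6
        pid = np.repeat(np.arange(G), n)
        x = rng.normal(size=G * n)
        df = pd.DataFrame({"patient_id": pid, "month_index": np.tile(np.arange(n), G),
                           "x": x, "y": 1 + 0.5 * x + rng.normal(0, 1, G * n)})
        fit = fit_lmm(LmmSpec("y", ("x",)), df)
        assert fit.satterthwaite_df[1] == pytest.approx(G * n - 2, rel=0.02)

    def test_clamped_to_valid_range_on_fuzzed_fits(self):
        rng = np.random.default_rng(6)
        for seed in range(5):
            df = ri_dataset(seed=seed, n_groups=int(rng.integers(4, 10)), n_per=int(rng.integers(3, 7)))
            fit = fit_lmm(LmmSpec("y", ("x",)), df)
            for j, c in enumerate(np.eye(2)):
                d = satterthwaite_df(fit, c)
                assert 1.0 <= d <= fit.n_obs - 2


class TestWaldT:
    def test_table_row_acc_sleep_sd(self):
        t, _ = wald_t_test(0.548, 0.172, 469.7)
        assert round(t, 1) == 3.2

    def test_table_row_p_value(self):
        _, p = wald_t_test(-2.4 * 1.0, 1.0, 20)
        assert round(p, 2) == 0.03

    def test_zero_estimate_p_one(self):
        _, p = wald_t_test(0.0, 1.0, 57)
        assert p == pytest.approx(1.0)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(NumericError):
            wald_t_test(1.0, 0.0, 10)


class TestEffectSize:
    def test_null_fixed_effect_gives_zero(self):
        rng = np.random.default_rng(8)
        G, n = 30, 8
        pid = np.repeat(np.arange(G), n)
        df = pd.DataFrame({"patient_id": pid, "month_index": np.tile(np.arange(n), G),
                           "y": 5 + np.repeat(rng.normal(0, 2, G), n) + rng.normal(0, 1, G * n)})
        fit = fit_lmm(LmmSpec("y", ()), df)
        Rm, f2 = marginal_r2_f2(fit)
        assert Rm == pytest.approx(0.0, abs=1e-10)
        assert f2 == pytest.approx(0.0, abs=1e-10)

    def test_formula_identity_rm_half_gives_f2_one(self):
        # planted 50% fixed-effect variance share
        rng = np.random.default_rng(9)
        G, n = 200, 10
        pid = np.repeat(np.arange(G), n)
        x = rng.normal(size=G * n)
        df = pd.DataFrame({"patient_id": pid, "month_index": np.tile(np.arange(n), G),
                           "x": x, "y": x + np.repeat(rng.normal(0, np.sqrt(0.5), G), n)
                           + rng.normal(0, np.sqrt(0.5), G * n)})
        fit = fit_lmm(LmmSpec("y", ("x",)), df)
        Rm, f2 = marginal_r2_f2(fit)
        assert Rm == pytest.approx(0.5, abs=0.03)
        assert f2 == pytest.approx(Rm / (1 - Rm), rel=1e-12)

    def test_variance_share_recovery(self):
        # fixed share 0.2: var(Xb)=0.2, sigma_b2+sigma_e2=0.8
        rng = np.random.default_rng(10)
        reps = []
        for r in range(40):
            G, n = 38, 10
            pid = np.repeat(np.arange(G), n)
            x = rng.normal(size=G * n)
            y = np.sqrt(0.2) * x + np.repeat(rng.normal(0, np.sqrt(0.4), G), n) + rng.normal(0, np.sqrt(0.4), G * n)
            df = pd.DataFrame({"patient_id": pid, "month_index": np.tile(np.arange(n), G), "x": x, "y": y})
            reps.append(fit_lmm(LmmSpec("y", ("x",)), df).Rm)
        assert np.mean(reps) == pytest.approx(0.2, abs=0.02)

    def test_unsupported_for_ar1_structures(self):
        df = ri_dataset(seed=11)
        fit = fit_lmm(LmmSpec("y", ("x",), "RI_AR1"), df)
        with pytest.raises(UnsupportedModelError):
            marginal_r2_f2(fit)


class TestLrt:
    def test_chi2_arithmetic_from_printed_comparison(self):
        assert round(stats.chi2.sf(0.4, 1), 2) == 0.53

    def test_mixture_arithmetic_from_printed_comparison(self):
        p = 0.5 * stats.chi2.sf(3.7, 1) + 0.5 * stats.chi2.sf(3.7, 2)
        assert round(p, 2) == 0.11

    def test_lrt_objects(self):
        df = ri_dataset(seed=12)
        f1 = fit_lmm(LmmSpec("y", ("x",), "RI"), df)
        f2 = fit_lmm(LmmSpec("y", ("x",), "RI_AR1"), df, extra_starts=[[float(f1._theta[0]), 0.0]])
        res = lrt(f2, f1, "chi2_1")
        assert res.statistic >= 0
        assert res.p_value == pytest.approx(stats.chi2.sf(res.statistic, 1))

    def test_zero_statistic_gives_p_one(self):
        df = ri_dataset(seed=14)
        f1 = fit_lmm(LmmSpec("y", ("x",), "RI"), df)
        res = lrt(f1, f1, "mix_half_chi2_1_chi2_2")
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_worse_larger_model_is_diagnosed(self):
        df = ri_dataset(seed=15)
        f1 = fit_lmm(LmmSpec("y", ("x",), "RI"), df)
        f2 = fit_lmm(LmmSpec("y", ("x",), "RI_AR1"), df, extra_starts=[[float(f1._theta[0]), 0.0]])
        f2.minus2_loglik = f1.minus2_loglik + 1.0  # simulate an optimizer failure
        with pytest.raises(NumericError, match="restarts"):
            lrt(f2, f1, "chi2_1")
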