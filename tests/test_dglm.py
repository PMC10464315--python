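import subprocess
import textwrap

import numpy as np
import pytest
from scipy import stats

from xvar.dglm import build_design, fit_dglm, scan
from xvar.preprocess import rin_transform_frame
from xvar.synth import SimConfig, plant_truth, simulate_cohort


class TestFitDglm:
    def test_intercept_only_dispersion_reduces_to_ols(self, null_design, rng):
        X, _ = null_design
        y = X @ rng.normal(size=X.shape[1]) + rng.normal(size=X.shape[0])
        fit = fit_dglm(y, X, np.ones((X.shape[0], 1)))
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(fit.mean_coefs, ols, rtol=0, atol=1e-12)

    def test_parameter_recovery_unbiased(self, null_design, rng):
        X, _ = null_design
        beta = np.array([0.0, 0.02, 0.1, -0.1, 0.05, 0.0])
        gamma = np.array([-1.0, 0.03, 0.0, 0.0, 0.0, 0.0])
        n_rep = 150
        b1 = np.empty(n_rep)
        g1 = np.empty(n_rep)
        for r in range(n_rep):
            y = X @ beta + rng.normal(size=X.shape[0]) * np.exp(0.5 * (X @ gamma))
            f = fit_dglm(y, X, X, assume_full_rank=True)
            b1[r], g1[r] = f.mean_coefs[1], f.disp_coefs[1]
        assert abs(b1.mean() - 0.02) < 2 * b1.std() / np.sqrt(n_rep)
        assert abs(g1.mean() - 0.03) < 2 * g1.std() / np.sqrt(n_rep)

    def test_scale_equivariance_of_dispersion_test(self, null_design, rng):
        X, _ = null_design
        y = rng.normal(size=X.shape[0]) * np.exp(0.01 * X[:, 1])
        f1 = fit_dglm(y, X, X, assume_full_rank=True)
        f2 = fit_dglm(5.0 * y, X, X, assume_full_rank=True)
        z1 = f1.disp_coefs[1] / f1.disp_se[1]
        z2 = f2.disp_coefs[1] / f2.disp_se[1]
        # exact at the optimum; finite stopping leaves O(1e-4) residuals
        assert abs(z1 - z2) < 1e-3
        # only the dispersion intercept moves, by 2 log c
        assert abs((f2.disp_coefs[0] - f1.disp_coefs[0]) - 2 * np.log(5.0)) < 1e-3
        np.testing.assert_allclose(f1.disp_coefs[1:], f2.disp_coefs[1:], atol=1e-4)

    def test_matches_reference_reml_scoring(self, tmp_path):
        """Independent oracle: statmod::remlscore (R) on identical data."""
        r = np.random.default_rng(3)
        n = 300
        age = r.uniform(18, 85, n)
        X = np.column_stack([np.ones(n), age, r.normal(size=(n, 2))])
        Y = r.normal(size=(6, n)) * np.exp(0.01 * (age - 50))[None, :]
        np.savetxt(tmp_path / "X.txt", X)
        np.savetxt(tmp_path / "Y.txt", Y)
        ours = []
        for i in range(Y.shape[0]):
            f = fit_dglm(Y[i], X, X, assume_full_rank=True)
            ours.append([f.mean_coefs[1], f.disp_coefs[1],
                         f.disp_coefs[1] / f.disp_se[1]])
        script = textwrap.dedent("""
            library(statmod)
            X <- as.matrix(read.table("X.txt")); Y <- as.matrix(read.table("Y.txt"))
            res <- t(apply(Y, 1, function(y) {
              f <- remlscore(y, X, X)
              c(f$beta[2], f$gamma[2], f$gamma[2] / f$se.gam[2])
            }))
            write.table(res, "ref.txt", row.names=FALSE, col.names=FALSE)
        """)
        (tmp_path / "oracle.R").write_text(script)
        subprocess.run(["Rscript", "oracle.R"], cwd=tmp_path, check=True,
                       capture_output=True)
        ref = np.loadtxt(tmp_path / "ref.txt")
        np.testing.assert_allclose(np.array(ours), ref, rtol=2e-3, atol=2e-5)

    def test_mean_effects_match_plain_linear_model(self, planted_study):
        """Across a simulated chromosome the DGLM mean slopes and an OLS fit
        on the identical covariates are virtually identical."""
        land, truth = planted_study
        meth, samples = simulate_cohort(land, truth, 300, 0, seed=61)
        rin = rin_transform_frame(meth, samples)
        fem = samples[samples.sex == "F"]
        X, cols = build_design(fem, ["age", "cohort"])
        ai = cols.index("age")
        sub = rin.loc[rin.index[:150], fem.index].to_numpy()
        dglm_b = np.empty(sub.shape[0])
        ols_b = np.empty(sub.shape[0])
        for i in range(sub.shape[0]):
            f = fit_dglm(sub[i], X, X, assume_full_rank=True)
            dglm_b[i] = f.mean_coefs[ai]
            ols_b[i] = np.linalg.lstsq(X, sub[i], rcond=None)[0][ai]
        r2 = np.corrcoef(dglm_b, ols_b)[0, 1] ** 2
        assert r2 > 0.99

    def test_aliased_columns_dropped_deterministically(self, rng):
        n = 100
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x, 2 * x])  # third column aliased
        y = x + rng.normal(size=n)
        f = fit_dglm(y, X, np.ones((n, 1)))
        assert np.isnan(f.mean_coefs[2]) and not np.isnan(f.mean_coefs[1])

    def test_input_validation(self, rng):
        y = rng.normal(size=10)
        with pytest.raises(ValueError):
            fit_dglm(y, np.ones((9, 1)), np.ones((10, 1)))
        y[0] = np.nan
        with pytest.raises(ValueError):
            fit_dglm(y, np.ones((10, 1)), np.ones((10, 1)))


class TestScan:
    @pytest.fixture(scope="class")
    def power_study(self):
        """600 females, 2000 CpGs, 20 planted variance CpGs (gamma=0.03/yr)."""
        from xvar.synth import generate_landscape

        land = generate_landscape(2000, seed=21)
        land, truth = plant_truth(
            land, n_var_xi=20, n_var_xa=0, n_mean_xa=0, n_mean_xi=0,
            n_composition=0, gamma1=0.03, seed=22,
        )
        cfg = SimConfig(confounding=False)
        meth, samples = simulate_cohort(land, truth, 600, 100, config=cfg, seed=23)
        rin = rin_transform_frame(meth, samples)
        res_f = scan(rin, samples, sex="F")
        return rin, samples, truth, res_f

    def test_planted_variance_cpgs_rank_top_with_power(self, power_study):
        rin, samples, truth, res = power_study
        planted = truth.index[truth["effect_type"] == "variance"]
        thr = stats.norm.isf(0.05 / len(res) / 2)  # Bonferroni two-sided
        power = (res.loc[planted, "z_disp"].abs() > thr).mean()
        assert power >= 0.8
        # planted CpGs dominate the extreme dispersion statistics
        top = res["z_disp"].abs().nlargest(20).index
        assert len(set(top) & set(planted)) >= 14

    def test_null_mean_model_calibrated(self, power_study):
        rin, samples, truth, res = power_study
        nulls = truth.index[truth["effect_type"] == "none"]
        frac = (res.loc[nulls, "p_mean"] < 0.05).mean()
        assert 0.03 < frac < 0.08

    def test_female_only_effect_absent_in_males(self, power_study):
        rin, samples, truth, _ = power_study
        res_m = scan(rin, samples, sex="M")
        planted = truth.index[truth["effect_type"] == "variance"]
        z = res_m.loc[planted, "z_disp"]
        # centred at zero: mean within 3 MC-SE, spread near 1
        assert abs(z.mean()) < 3 / np.sqrt(len(z))
        assert z.abs().max() < 4.5

    def test_empty_sex_subset_rejected(self, small_cohort):
        meth, samples = small_cohort
        only_f = samples[samples.sex == "F"]
        with pytest.raises(ValueError):
            scan(meth, only_f, sex="M")
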