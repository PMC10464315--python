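import numpy as np
import pandas as pd
import pytest

from xvar.synth import (
    SimConfig,
    dilution_experiment,
    generate_landscape,
    plant_truth,
    simulate_cohort,
)

CELLS = ["cd8t", "cd4t", "nk", "bcell", "mono"]


class TestLandscape:
    def test_degenerate_single_cpg(self):
        land = generate_landscape(1, seed=0)
        cp = land.cpgs
        assert len(cp) == 1
        assert 0 <= cp.baseline_xa.iloc[0] <= 1
        assert 0 <= cp.baseline_xi.iloc[0] <= 1

    def test_determinism_under_fixed_seed(self):
        a = generate_landscape(200, seed=42)
        b = generate_landscape(200, seed=42)
        pd.testing.assert_frame_equal(a.cpgs, b.cpgs)
        np.testing.assert_array_equal(a.cgi_intervals, b.cgi_intervals)
        pd.testing.assert_frame_equal(a.tss, b.tss)

    def test_positions_sorted_unique_and_betas_bounded(self, small_landscape):
        cp = small_landscape.cpgs
        assert cp.pos.is_monotonic_increasing and cp.pos.is_unique
        assert cp.baseline_xa.between(0, 1).all()
        assert cp.baseline_xi.between(0, 1).all()

    def test_xci_composition_tracks_mix(self):
        land = generate_landscape(4000, xci_mix=(0.75, 0.15, 0.10), seed=3)
        ann = land.cpgs[land.cpgs.xci_status != "unannotated"]
        frac = ann.xci_status.value_counts(normalize=True)
        assert frac["subject"] == pytest.approx(0.75, abs=0.06)
        assert frac["escape"] == pytest.approx(0.15, abs=0.05)
        assert frac["variable"] == pytest.approx(0.10, abs=0.05)

    def test_xci_status_implies_xi_baseline_level(self, small_landscape):
        cp = small_landscape.cpgs
        esc = cp[cp.xci_status == "escape"]
        sub = cp[cp.xci_status == "subject"]
        assert (esc.baseline_xi < 0.3).all()
        assert (sub.baseline_xi > 0.55).all()

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            generate_landscape(0)
        with pytest.raises(ValueError):
            generate_landscape(10, xci_mix=(0.7, 0.2, 0.2))

    def test_female_trimodal_male_bimodal_by_bic(self):
        from sklearn.mixture import GaussianMixture

        land = generate_landscape(2000, seed=1)
        land, truth = plant_truth(land, seed=2)
        meth, samp = simulate_cohort(land, truth, 300, 250,
                                     cohorts=("B1", "B2"), seed=3)
        fem = meth.loc[:, samp.sex == "F"].mean(axis=1).to_numpy().reshape(-1, 1)
        mal = meth.loc[:, samp.sex == "M"].mean(axis=1).to_numpy().reshape(-1, 1)
        bic = {
            name: {k: GaussianMixture(k, random_state=0, n_init=5).fit(x).bic(x)
                   for k in (2, 3)}
            for name, x in (("F", fem), ("M", mal))
        }
        assert bic["F"][3] < bic["F"][2]
        assert bic["M"][2] < bic["M"][3]


class TestSimulateCohort:
    def test_beta_range_and_fraction_simplex(self, small_cohort):
        meth, samples = small_cohort
        v = meth.to_numpy()
        assert v.min() >= 0 and v.max() <= 1
        total = samples[CELLS].sum(axis=1)
        assert (samples[CELLS] >= 0).all().all()
        assert (total <= 1).all()  # granulocyte remainder non-negative

    def test_determinism(self, planted_study):
        land, truth = planted_study
        a = simulate_cohort(land, truth, 20, 20, seed=9)
        b = simulate_cohort(land, truth, 20, 20, seed=9)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_invalid_inputs_rejected(self, planted_study):
        land, truth = planted_study
        with pytest.raises(ValueError):
            simulate_cohort(land, truth, 0, 0)
        with pytest.raises(ValueError):
            simulate_cohort(land, truth, 5, 5, age_range=(80, 20))
        with pytest.raises(ValueError):
            simulate_cohort(land, truth.iloc[:10], 5, 5)

    def test_monocyte_cohort_reports_purity_not_fractions(self, planted_study):
        land, truth = planted_study
        _, samples = simulate_cohort(land, truth, 10, 10, kind="monocyte", seed=5)
        assert "purity" in samples.columns
        assert not set(CELLS) <= set(samples.columns)
        assert samples["purity"].between(0.7, 1.0).all()

    def test_null_cohort_has_no_variance_age_trend(self, small_landscape):
        """With no planted effects and confounding off, per-CpG squared
        residuals regressed on age reject at roughly the nominal rate."""
        land = small_landscape
        _, truth = plant_truth(land, n_var_xi=0, n_var_xa=0, n_mean_xa=0,
                               n_mean_xi=0, n_composition=0, seed=1)
        cfg = SimConfig(confounding=False, batch_sd=0.0, cohort_sd=0.0)
        meth, samples = simulate_cohort(land, truth, 250, 0, config=cfg, seed=8)
        age = samples.age.to_numpy()
        X = np.column_stack([np.ones(len(age)), age])
        hits = 0
        from scipy import stats as st
        for i in range(len(meth)):
            y = meth.iloc[i].to_numpy()
            e = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
            r = st.linregress(age, np.log(e * e + 1e-12))
            hits += r.pvalue < 0.05
        assert hits / len(meth) == pytest.approx(0.05, abs=0.035)

    def test_xi_variance_effect_recovered_in_females_only(self):
        """Moment oracle: the expected log-variance age slope follows from
        the allele model; simulated females match it, males show none."""
        land = generate_landscape(1, seed=4)
        cp = land.cpgs.copy()
        cp.loc[:, ["baseline_xa", "baseline_xi"]] = [[0.35, 0.6]]
        from dataclasses import replace
        land = replace(land, cpgs=cp)
        g = 0.04
        truth = pd.DataFrame(
            {"effect_type": ["variance"], "beta1_true": [0.0],
             "gamma1_true": [g], "xa_specific": [False], "mechanism": ["allele"]},
            index=cp.index,
        )
        cfg = SimConfig(confounding=False, batch_sd=0.0, cohort_sd=0.0,
                        sd_xi=0.08, sd_xa=0.01, sd_meas=0.005)
        meth, samples = simulate_cohort(land, truth, 5000, 5000, config=cfg, seed=6)
        from scipy import stats as st

        slopes = {}
        for sex in ("F", "M"):
            sub = samples[samples.sex == sex]
            y = meth.loc[:, sub.index].to_numpy()[0]
            age = sub.age.to_numpy()
            e = y - np.polyval(np.polyfit(age, y, 1), age)
            slopes[sex] = st.linregress(age, np.log(e * e + 1e-300)).slope
        # oracle: female measured variance = (sd_xi^2 exp(g da) + sd_xa^2)/4
        # + sd_meas^2; regress its log on age over the age grid
        ages = np.linspace(18, 85, 200)
        da = ages - cfg.age_mid
        var_f = (cfg.sd_xi**2 * np.exp(g * da) + cfg.sd_xa**2) / 4 + cfg.sd_meas**2
        expected_f = st.linregress(ages, np.log(var_f)).slope
        assert slopes["F"] == pytest.approx(expected_f, abs=0.006)
        assert abs(slopes["M"]) < 0.004

    def test_composition_axis_absent_from_monocyte_cohort(self, planted_study):
        land, truth = planted_study
        comp = truth.index[truth.mechanism == "composition"]
        cfg = SimConfig(batch_sd=0.0, cohort_sd=0.0)
        blood, sb = simulate_cohort(land, truth, 400, 0, config=cfg, seed=31)
        mono, sm = simulate_cohort(land, truth, 400, 0, config=cfg,
                                   kind="monocyte", seed=31)
        from scipy import stats as st

        slopes_blood = [st.linregress(sb.age, blood.loc[c]).slope for c in comp]
        slopes_mono = [st.linregress(sm.age, mono.loc[c]).slope for c in comp]
        sens = land.cpgs.loc[comp, "sens_latent"].to_numpy()
        expected = sens * cfg.drift_per_year
        # blood slopes track sens * drift; monocyte slopes do not
        r_blood = np.corrcoef(slopes_blood, expected)[0, 1]
        assert r_blood > 0.8
        assert np.abs(slopes_mono).mean() < np.abs(slopes_blood).mean() / 2


class TestDilution:
    def test_xa_specific_slope_halved_in_females(self):
        res = dilution_experiment(n_per_sex=4000, n_replicates=12, seed=77)
        assert res["ratio_mean"] == pytest.approx(2.0, abs=0.15)
        assert res["slope_m"] == pytest.approx(2 * res["slope_f"], rel=0.15)
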