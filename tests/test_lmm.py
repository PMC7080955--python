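import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from flowtoj import (
    FlowModerationModel,
    FlowModerationResults,
    StudyConfig,
    fit_lmm,
    fit_moderation_models,
    generate_study,
    lrt_compare,
    score_table,
    variance_partition,
)
from conftest import model_tables


def one_way_table(rng, n_groups=8, n_per=6, var_b=25.0, var_w=4.0):
    """Balanced one-way random-intercept data in the model-table schema."""
    u = rng.normal(0, np.sqrt(var_b), n_groups)
    rows = []
    for g in range(n_groups):
        for j in range(n_per):
            rows.append(dict(participant=g + 1, session=1, prepost=j % 2,
                             condition=0, flow=3.0, flow_c=0.0,
                             value=50 + u[g] + rng.normal(0, np.sqrt(var_w))))
    return pd.DataFrame(rows)


class TestFitLmm:
    def test_balanced_random_intercept_matches_anova_closed_form(self, rng):
        df = one_way_table(rng)
        res = fit_lmm(df, kind="pss", terms=(), reml=True, random_slope=False)
        # REML on balanced one-way data equals the ANOVA moment estimators
        m = df.groupby("participant")["value"].mean()
        n_per = 6
        msb = n_per * m.var(ddof=1)
        ssw = ((df["value"] - df["participant"].map(m)) ** 2).sum()
        msw = ssw / (len(df) - len(m))
        assert res.params["Intercept"] == pytest.approx(df["value"].mean(), abs=1e-6)
        assert res.vcomp["sigma2"] == pytest.approx(msw, rel=1e-6)
        assert res.vcomp["Var: subject"] == pytest.approx((msb - msw) / n_per, rel=1e-5)

    def test_reml_and_ml_fixed_effects_agree_on_balanced_design(self, rng):
        df = one_way_table(rng)
        a = fit_lmm(df, kind="pss", terms=("prepost",), reml=True, random_slope=False)
        b = fit_lmm(df, kind="pss", terms=("prepost",), reml=False, random_slope=False)
        assert np.allclose(a.params, b.params, atol=1e-6)

    def test_agrees_with_lme4_reference(self, tmp_path):
        study = generate_study(StudyConfig(seed=42, n_participants=12),
                               simulate_trials=False)
        est = study.true_estimates()
        scores = score_table(study.questionnaire)
        jnd_tab, _ = model_tables(study, est, scores)
        res = fit_lmm(jnd_tab, kind="jnd", reml=True)
        csv = tmp_path / "jnd.csv"
        jnd_tab.to_csv(csv, index=False)
        rscript = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv('{csv}')
            m <- lmer(value ~ condition + flow_c + prepost + prepost:flow_c
                      + (1|participant) + (1|participant:session), data=d, REML=TRUE)
            fe <- fixef(m)
            vc <- as.data.frame(VarCorr(m))
            cat(fe['(Intercept)'], fe['condition'], fe['flow_c'], fe['prepost'],
                fe['flow_c:prepost'],
                vc$vcov[vc$grp=='participant:session'],
                vc$vcov[vc$grp=='participant'],
                vc$vcov[vc$grp=='Residual'], sep='\\n')
        """)
        out = subprocess.run(["Rscript", "-"], input=rscript, text=True,
                             capture_output=True, timeout=300)
        assert out.returncode == 0, out.stderr
        ref = [float(v) for v in out.stdout.split()]
        ours = [res.params["Intercept"], res.params["condition"],
                res.params["flow_c"], res.params["prepost"],
                res.params["prepost:flow_c"],
                res.vcomp["Var: session:subject"], res.vcomp["Var: subject"],
                res.vcomp["sigma2"]]
        assert np.allclose(ours, ref, rtol=1e-3)

    def test_centering_flow_moves_intercept_not_interaction(self, default_study_estimates):
        study, est, scores = default_study_estimates
        jnd_tab, _ = model_tables(study, est, scores)
        centred = fit_lmm(jnd_tab, kind="jnd")
        raw = jnd_tab.copy()
        raw["flow_c"] = raw["flow"]  # uncentred coding
        shifted = fit_lmm(raw, kind="jnd")
        assert shifted.params["prepost:flow_c"] == pytest.approx(
            centred.params["prepost:flow_c"], abs=1e-5)
        assert shifted.params["Intercept"] != pytest.approx(
            centred.params["Intercept"], abs=0.5)

    def test_too_few_subjects_rejected(self):
        df = one_way_table(np.random.default_rng(0), n_groups=1)
        with pytest.raises(ValueError):
            FlowModerationModel(df, kind="jnd")

    def test_moderation_models_report_expected_structure(self, default_study_estimates):
        study, est, scores = default_study_estimates
        jnd_tab, pss_tab = model_tables(study, est, scores)
        models = fit_moderation_models(jnd_tab, pss_tab)
        jnd, pss = models["jnd"], models["pss"]
        assert list(jnd.params.index) == [
            "Intercept", "condition", "flow_c", "prepost", "prepost:flow_c"]
        assert set(jnd.vcomp) == {"Var: subject", "Var: session:subject", "sigma2"}
        assert set(pss.vcomp) == {"Var: subject (Intercept)", "Var: subject condition",
                                  "Cov: subject (Intercept) condition", "sigma2"}
        assert jnd.group_counts["subject"] == 27
        # Wald CI convention
        name = "prepost:flow_c"
        assert jnd.conf_int.loc[name, "lower"] == pytest.approx(
            jnd.params[name] - 1.96 * jnd.bse[name], abs=1e-6)
        assert "Flow moderation model" in jnd.summary()


class TestLrt:
    def test_identical_models_give_zero_statistic(self, default_study_estimates):
        study, est, scores = default_study_estimates
        jnd_tab, _ = model_tables(study, est, scores)
        a = fit_lmm(jnd_tab, kind="jnd", reml=False)
        b = fit_lmm(jnd_tab, kind="jnd", reml=False)
        with pytest.raises(ValueError):
            lrt_compare(a, b)  # identical parameter counts are not a test

    def test_one_added_fixed_term_gives_df_1_and_exact_statistic(
            self, default_study_estimates):
        study, est, scores = default_study_estimates
        jnd_tab, _ = model_tables(study, est, scores)
        m0 = fit_lmm(jnd_tab, kind="jnd",
                     terms=("condition", "flow", "prepost"), reml=False)
        m1 = fit_lmm(jnd_tab, kind="jnd", reml=False)
        out = lrt_compare(m0, m1)
        assert out["df"] == 1
        assert out["chi2"] == pytest.approx(max(0.0, 2 * (m1.llf - m0.llf)), abs=1e-10)
        assert 0.0 <= out["p"] <= 1.0

    def test_reml_fits_rejected(self, default_study_estimates):
        study, est, scores = default_study_estimates
        jnd_tab, _ = model_tables(study, est, scores)
        m0 = fit_lmm(jnd_tab, kind="jnd", terms=("condition",), reml=True)
        m1 = fit_lmm(jnd_tab, kind="jnd", reml=True)
        with pytest.raises(ValueError):
            lrt_compare(m0, m1)


class TestVariancePartition:
    def test_arithmetic_on_known_components(self):
        res = FlowModerationResults(
            model=None, params=pd.Series(dtype=float), bse=pd.Series(dtype=float),
            tvalues=pd.Series(dtype=float), pvalues=pd.Series(dtype=float),
            conf_int=pd.DataFrame(), llf=0.0, n_obs=0, n_params=0,
            group_counts={}, reml=True, converged=True, singular=False,
            df_resid=0,
            vcomp={"Var: subject": 331.62, "Var: session:subject": 152.93,
                   "sigma2": 343.18})
        shares = variance_partition(res)
        assert shares["subject"] == pytest.approx(0.4005, abs=1e-3)
        assert shares["session:subject"] == pytest.approx(0.1847, abs=1e-3)
        assert shares["residual"] == pytest.approx(0.4145, abs=1e-3)

    def test_generator_shares_recovered_from_unconditional_fit(self):
        # plant the variance decomposition reported for the unconditional
        # JND model: 15% subject, 38% session, rest residual
        total = 800.0
        cfg = StudyConfig(seed=606, var_subject=0.15 * total,
                          var_session=0.38 * total, var_residual=0.47 * total,
                          gamma_jnd=0.0, delta_prepost_jnd=0.0,
                          cond_offset_jnd=0.0, dropout_rate=0.0)
        import dataclasses

        shares = np.zeros(3)
        reps = 30
        for r in range(reps):
            study = generate_study(dataclasses.replace(cfg, seed=606 + r),
                                   simulate_trials=False)
            est = study.true_estimates()
            scores = score_table(study.questionnaire)
            tab, _ = model_tables(study, est, scores)
            res = fit_lmm(tab, kind="jnd", terms=())
            s = variance_partition(res)
            shares += np.array([s["subject"], s["session:subject"], s["residual"]])
        shares /= reps
        assert shares[0] == pytest.approx(0.15, abs=0.05)
        assert shares[1] == pytest.approx(0.38, abs=0.05)
        assert shares[2] == pytest.approx(0.47, abs=0.05)

    def test_zero_total_variance_signalled(self):
        res = FlowModerationResults(
            model=None, params=pd.Series(dtype=float), bse=pd.Series(dtype=float),
            tvalues=pd.Series(dtype=float), pvalues=pd.Series(dtype=float),
            conf_int=pd.DataFrame(), llf=0.0, n_obs=0, n_params=0,
            group_counts={}, reml=True, converged=True, singular=True,
            df_resid=0, vcomp={"Var: subject": 0.0, "sigma2": 0.0})
        with pytest.raises(ValueError):
            variance_partition(res)


def test_null_interaction_pvalues_are_uniform(null_simulation):
    """Under gamma = 0 the moderation p-values should be U(0,1)."""
    from scipy.stats import kstest

    _, pvalues = null_simulation
    assert kstest(pvalues, "uniform").pvalue > 0.01


def test_moderation_plot_renders(default_study_estimates):
    import matplotlib.pyplot as plt

    study, est, scores = default_study_estimates
    jnd_tab, _ = model_tables(study, est, scores)
    res = fit_lmm(jnd_tab, kind="jnd")
    ax = res.plot_moderation()
    assert len(ax.lines) == 2
    plt.close("all")
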