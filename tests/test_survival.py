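"""Survival models: stage coding, GMM groups, log-rank, Cox, stepwise AIC."""

import numpy as np
import pandas as pd
import pytest

from immunets import synthetic as syn
from immunets.survival import (
    CoxModel,
    encode_stage,
    fit_cox,
    gmm_risk_groups,
    logrank_test,
    ph_check,
    risk_split,
    stepwise_aic,
    stratified_split,
    univariate_screen,
)
from oracles import cox_mle_bruteforce, logrank_bruteforce


class TestEncodeStage:
    @pytest.mark.parametrize(
        "label,code",
        [
            ("I", 1), ("Ia", 1), ("Ib", 1), ("Ic", 1),
            ("II", 2), ("IIa", 2), ("IIb", 2), ("IIc", 2),
            ("III", 3), ("IIIa", 3), ("IIIb", 3), ("IIIc", 3),
            ("IV", 4),
            ("iiib", 3), ("Stage IIIB", 3), ("stage iv", 4),
        ],
    )
    def test_mapping(self, label, code):
        assert encode_stage(label) == code

    @pytest.mark.parametrize("label", ["X", "IVa", "0", "", "V"])
    def test_unmapped_label_is_error(self, label):
        with pytest.raises(ValueError, match="unmapped"):
            encode_stage(label)


class TestGMMRiskGroups:
    def test_well_separated_mixture_recovered(self):
        rng = np.random.default_rng(3)
        truth = np.repeat([0, 1], 100)
        x = np.where(truth == 0, rng.normal(0, 1, 200), rng.normal(10, 1, 200))
        fit = gmm_risk_groups(x, seed=3)
        assert fit.k == 2
        # label-permutation-invariant accuracy
        acc = max(
            (fit.labels == truth).mean(), (fit.labels == 1 - truth).mean()
        )
        assert acc >= 0.99

    def test_single_component_selected_on_unimodal_data(self):
        chosen = []
        for seed in range(20):
            x = np.random.default_rng(100 + seed).normal(0, 1, 200)
            chosen.append(gmm_risk_groups(x, seed=seed).k)
        assert sum(k == 1 for k in chosen) >= 18

    def test_zero_variance_unstratifiable(self):
        fit = gmm_risk_groups(np.full(50, 3.0))
        assert fit.k == 1 and not fit.stratifiable

    def test_needs_ten_values(self):
        with pytest.raises(ValueError, match="at least 10"):
            gmm_risk_groups(np.arange(5.0))


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        time = np.array([1.0, 2, 3, 1, 2, 3])
        event = np.ones(6, bool)
        stat, p = logrank_test([0, 0, 0, 1, 1, 1], time, event)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_bruteforce_tables(self):
        # group A events at 1, 2, 3; group B events at 4, 5, 6
        time = np.array([1.0, 2, 3, 4, 5, 6])
        event = np.ones(6, bool)
        groups = np.array([0, 0, 0, 1, 1, 1])
        stat, p = logrank_test(groups, time, event)
        stat_o, p_o = logrank_bruteforce(time, event, groups)
        assert stat == pytest.approx(stat_o, rel=1e-10)
        assert p == pytest.approx(p_o, rel=1e-10)

    def test_matches_bruteforce_with_censoring(self):
        rng = np.random.default_rng(4)
        time = rng.exponential(10, 30).round(3)
        event = rng.random(30) < 0.7
        groups = rng.integers(0, 2, 30)
        if event.any() and len(np.unique(groups)) == 2:
            stat, p = logrank_test(groups, time, event)
            stat_o, p_o = logrank_bruteforce(time, event, groups)
            assert stat == pytest.approx(stat_o, rel=1e-8)

    def test_all_censored_reports_p_one(self):
        with pytest.warns(UserWarning, match="no events"):
            stat, p = logrank_test([0, 0, 1, 1], [1.0, 2, 3, 4], [False] * 4)
        assert p == 1.0


class TestUnivariateScreen:
    def test_planted_bimodal_prognostic_gene_significant(self):
        hits = 0
        for seed in range(10):
            spec = syn.SurvivalCohortSpec(
                n_patients=300,
                betas=(("PROG", np.log(3)),),
                n_noise_genes=2,
                bimodal=(("PROG", 4.0),),
                censor_rate=0.005,
                seed=seed,
            )
            df, _ = syn.simulate_survival_cohort(spec)
            screen = univariate_screen(df, ["PROG", "N0001", "N0002"], seed=seed)
            hits += screen.loc["PROG", "q"] < 0.05
        assert hits >= 9

    def test_single_gene_panel_q_equals_p(self):
        spec = syn.SurvivalCohortSpec(
            n_patients=100, betas=(("G", 0.5),), bimodal=(("G", 5.0),), seed=1
        )
        df, _ = syn.simulate_survival_cohort(spec)
        screen = univariate_screen(df, ["G"], seed=1)
        assert screen.loc["G", "q"] == pytest.approx(screen.loc["G", "p"])

    def test_unstratifiable_gene_gets_p_one(self):
        spec = syn.SurvivalCohortSpec(n_patients=60, betas=(("G", 0.0),), seed=2)
        df, _ = syn.simulate_survival_cohort(spec)
        df["FLAT"] = 1.0
        df["FLAT"] = df["FLAT"] + 0  # constant column
        screen = univariate_screen(df, ["FLAT", "G"], seed=2)
        assert screen.loc["FLAT", "p"] == 1.0

    def test_missing_gene_is_error(self):
        spec = syn.SurvivalCohortSpec(n_patients=60, seed=0)
        df, _ = syn.simulate_survival_cohort(spec)
        with pytest.raises(ValueError, match="absent"):
            univariate_screen(df, ["NOT_THERE"])


class TestStratifiedSplit:
    def make_cohort(self, n=100, seed=0):
        spec = syn.SurvivalCohortSpec(
            n_patients=n, stage_probs=(0.25, 0.25, 0.25, 0.25), seed=seed
        )
        df, _ = syn.simulate_survival_cohort(spec)
        return df

    def test_disjoint_and_exhaustive(self):
        df = self.make_cohort()
        train, valid = stratified_split(df, fraction=0.65, seed=1)
        assert set(train.index).isdisjoint(valid.index)
        assert set(train.index) | set(valid.index) == set(df.index)

    def test_per_stratum_rounding(self):
        df = self.make_cohort()
        train, valid = stratified_split(df, fraction=0.65, seed=2)
        for stage, block in df.groupby("stage_code"):
            n_train = (train["stage_code"] == stage).sum()
            assert n_train == round(0.65 * len(block))

    def test_seeds_change_membership_not_sizes(self):
        df = self.make_cohort()
        t1, _ = stratified_split(df, fraction=0.65, seed=1)
        t2, _ = stratified_split(df, fraction=0.65, seed=2)
        assert len(t1) == len(t2)
        assert set(t1.index) != set(t2.index)

    def test_fraction_one_rejected(self):
        df = self.make_cohort()
        with pytest.raises(ValueError, match="fraction"):
            stratified_split(df, fraction=1.0)

    def test_singleton_stratum_goes_to_train(self):
        df = self.make_cohort(n=40, seed=3)
        df = pd.concat([df[df["stage_code"] != 4], df[df["stage_code"] == 4].head(1)])
        if (df["stage_code"] == 4).sum() == 1:
            with pytest.warns(UserWarning, match="size 1"):
                train, _ = stratified_split(df, fraction=0.6, seed=0)
            singleton = df.index[df["stage_code"] == 4][0]
            assert singleton in train.index


class TestFitCox:
    def test_matches_bruteforce_partial_likelihood(self):
        # 6 patients, binary covariate, no ties
        df = pd.DataFrame(
            {
                "time": [1.0, 2.5, 3.0, 4.5, 6.0, 7.5],
                "event": [True, True, False, True, True, True],
                "x": [1.0, 0.0, 1.0, 0.0, 1.0, 0.0],
            }
        )
        model = fit_cox(df, ["x"])
        beta_oracle = cox_mle_bruteforce(df["time"], df["event"], df["x"])
        assert model.summary.loc["x", "coef"] == pytest.approx(beta_oracle, abs=1e-4)

    def test_bruteforce_agreement_on_random_small_fixtures(self):
        rng = np.random.default_rng(5)
        for rep in range(4):
            n = 8
            df = pd.DataFrame(
                {
                    "time": rng.permutation(np.arange(1.0, n + 1)),
                    "event": rng.random(n) < 0.8,
                    "x": rng.normal(size=n),
                }
            )
            if df["event"].sum() < 2:
                continue
            model = fit_cox(df, ["x"])
            beta_oracle = cox_mle_bruteforce(df["time"], df["event"], df["x"])
            assert model.summary.loc["x", "coef"] == pytest.approx(beta_oracle, abs=1e-4)

    def test_planted_beta_recovered(self):
        spec = syn.SurvivalCohortSpec(
            n_patients=1000, betas=(("G1", np.log(2)),), censor_rate=0.005, seed=0
        )
        df, _ = syn.simulate_survival_cohort(spec)
        model = fit_cox(df, ["G1"])
        assert model.summary.loc["G1", "coef"] == pytest.approx(np.log(2), abs=0.1)

    def test_null_covariate_hr_near_one(self):
        within = 0
        for seed in range(10):
            spec = syn.SurvivalCohortSpec(
                n_patients=400, betas=(("G1", 0.0),), seed=seed
            )
            df, _ = syn.simulate_survival_cohort(spec)
            model = fit_cox(df, ["G1"])
            lo = model.summary.loc["G1", "ci_lower"]
            hi = model.summary.loc["G1", "ci_upper"]
            within += lo <= 1.0 <= hi
        assert within >= 9

    def test_hr_is_exp_coef_and_ci_brackets(self):
        spec = syn.SurvivalCohortSpec(n_patients=200, betas=(("G1", 0.4),), seed=1)
        df, _ = syn.simulate_survival_cohort(spec)
        model = fit_cox(df, ["G1", "age"])
        s = model.summary
        np.testing.assert_allclose(s["hr"], np.exp(s["coef"]), rtol=1e-12)
        assert ((s["ci_lower"] <= s["hr"]) & (s["hr"] <= s["ci_upper"])).all()

    def test_constant_covariate_rejected(self):
        spec = syn.SurvivalCohortSpec(n_patients=50, seed=2)
        df, _ = syn.simulate_survival_cohort(spec)
        df["flat"] = 2.0
        with pytest.raises(ValueError, match="constant"):
            fit_cox(df, ["flat"])


class TestStepwiseAIC:
    def test_noise_covariate_usually_eliminated(self):
        # a 1-df null covariate survives backwards AIC elimination with
        # probability P(chi2_1 >= 2) ~ 0.157; over 50 seeds the expected
        # elimination count is ~42, lower 3-sigma bound 34
        eliminated = 0
        for seed in range(50):
            spec = syn.SurvivalCohortSpec(
                n_patients=300, betas=(("INF", 0.7), ("NOISE", 0.0)), seed=seed
            )
            df, _ = syn.simulate_survival_cohort(spec)
            model, _ = stepwise_aic(df, ["INF", "NOISE"])
            eliminated += "NOISE" not in model.covariates
        assert eliminated >= 34

    def test_aic_never_above_full_model(self):
        for seed in range(5):
            spec = syn.SurvivalCohortSpec(
                n_patients=150,
                betas=(("A", 0.0), ("B", 0.0), ("C", 0.0)),
                seed=seed,
            )
            df, _ = syn.simulate_survival_cohort(spec)
            full = fit_cox(df, ["A", "B", "C"])
            reduced, trace = stepwise_aic(df, ["A", "B", "C"])
            assert reduced.aic <= full.aic + 1e-9
            aics = [step["aic"] for step in trace]
            assert all(np.diff(aics) < 0)  # every recorded step improved

    def test_never_drop_honoured(self):
        spec = syn.SurvivalCohortSpec(
            n_patients=200, betas=(("G", 0.6),), beta_age=0.0, beta_stage=0.0, seed=3
        )
        df, _ = syn.simulate_survival_cohort(spec)
        model, _ = stepwise_aic(
            df, ["age", "stage_code", "G"], never_drop=("age", "stage_code")
        )
        assert {"age", "stage_code"} <= set(model.covariates)


class TestPHCheck:
    def test_single_covariate_global_equals_percovariate(self):
        spec = syn.SurvivalCohortSpec(n_patients=150, betas=(("G", 0.5),), seed=4)
        df, _ = syn.simulate_survival_cohort(spec)
        model = fit_cox(df, ["G"])
        ph = ph_check(model, df)
        assert ph.loc["G", "p"] == pytest.approx(ph.loc["GLOBAL", "p"], rel=1e-9)

    def test_percovariate_agrees_with_lifelines(self):
        from lifelines.statistics import proportional_hazard_test

        spec = syn.SurvivalCohortSpec(
            n_patients=250, betas=(("G1", 0.5), ("G2", -0.3)), beta_age=0.02, seed=5
        )
        df, _ = syn.simulate_survival_cohort(spec)
        model = fit_cox(df, ["G1", "G2", "age"])
        ph = ph_check(model, df)
        ref = proportional_hazard_test(
            model.fitter, df[["time", "event", "G1", "G2", "age"]], time_transform="km"
        ).summary
        for cov in ("G1", "G2", "age"):
            assert ph.loc[cov, "p"] == pytest.approx(float(ref.loc[cov, "p"]), abs=0.01)

    def test_too_few_events_warns(self):
        df = pd.DataFrame(
            {
                "time": [1.0, 2, 3, 4, 5, 6, 7, 8, 9, 10],
                "event": [True, True] + [False] * 8,
                "x": np.arange(10.0),
            }
        )
        model = fit_cox(df, ["x"])
        with pytest.warns(UserWarning, match="fewer than 3 events"):
            ph = ph_check(model, df)
        assert np.isnan(ph.loc["GLOBAL", "p"])


class TestRiskSplit:
    def fitted_model(self, n, seed=0):
        spec = syn.SurvivalCohortSpec(
            n_patients=n, betas=(("G", 0.8),), censor_rate=0.005, seed=seed
        )
        df, _ = syn.simulate_survival_cohort(spec)
        return fit_cox(df, ["G"]), df

    def test_255_distinct_scores_split_128_127(self):
        model, df = self.fitted_model(255)
        assert model.linear_predictor(df).nunique() == 255
        strat = risk_split(model, df, df)
        assert strat.train_sizes == (128, 127)

    def test_256_distinct_scores_split_evenly(self):
        model, df = self.fitted_model(256)
        strat = risk_split(model, df, df)
        assert strat.train_sizes == (128, 128)

    def test_high_risk_group_has_shorter_survival(self):
        model, train = self.fitted_model(300, seed=6)
        spec = syn.SurvivalCohortSpec(
            n_patients=200, betas=(("G", 0.8),), censor_rate=0.005, seed=7
        )
        valid, _ = syn.simulate_survival_cohort(spec)
        strat = risk_split(model, train, valid)
        assert strat.p < 0.05
        high = valid.loc[strat.labels == "high", "time"].median()
        low = valid.loc[strat.labels == "low", "time"].median()
        assert high < low

    def test_all_equal_scores_rejected(self):
        model, df = self.fitted_model(100, seed=8)
        clone = df.copy()
        clone["G"] = 0.0
        frozen = CoxModel(
            ["G"], model.summary, model.log_likelihood, model.aic, model.lr_p,
            model.n, model.n_events, model.fitter,
        )
        with pytest.raises(ValueError, match="all training scores equal"):
            risk_split(frozen, clone, clone)
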