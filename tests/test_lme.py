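import warnings

import numpy as np
import pandas as pd
import patsy
import pytest
from scipy import stats

import priortime as pt
from priortime import lme


@pytest.fixture(scope="module")
def design_level1(small_cohort_trials):
    trials, covariates, _ = small_cohort_trials
    return pt.build_design(trials, level=1)


@pytest.fixture(scope="module")
def ladder_fits(small_cohort_trials):
    trials, _, _ = small_cohort_trials
    return pt.fit_ladder(trials, levels=(1, 2, 4, 8))


class TestConditionSlopes:
    def test_perfect_reproduction_gives_unit_slope(self):
        ts = np.tile(np.linspace(0.7, 1.1, 11), 6)
        df = pd.DataFrame(
            {
                "subject_id": "s",
                "condition": "NM",
                "sample_s": ts,
                "production_s": ts,
            }
        )
        out = pt.condition_slopes(df)
        assert out["slope"].iloc[0] == pytest.approx(1.0)
        assert out["central_tendency"].iloc[0] == pytest.approx(0.0)

    def test_constant_response_gives_zero_slope(self):
        ts = np.tile(np.linspace(0.7, 1.1, 11), 6)
        df = pd.DataFrame(
            {
                "subject_id": "s",
                "condition": "NM",
                "sample_s": ts,
                "production_s": 0.9,
            }
        )
        assert pt.condition_slopes(df)["slope"].iloc[0] == pytest.approx(0.0)

    def test_group_mean_slopes_follow_prior_predictions(self, small_cohort_trials):
        trials, _, _ = small_cohort_trials
        group = pt.condition_slopes(trials).groupby("condition")["slope"].mean()
        assert group["NS"] > group["NL"]
        assert group["WM"] > group["NM"]

    def test_sparse_condition_skipped_with_warning(self):
        df = pd.DataFrame(
            {
                "subject_id": "s",
                "condition": "NM",
                "sample_s": [0.7, 0.9, 1.1] * 2,
                "production_s": [0.8, 0.9, 1.0] * 2,
            }
        )
        with pytest.warns(UserWarning, match="skipped"):
            out = pt.condition_slopes(df)
        assert out.empty

    def test_agrees_with_ideal_observer_curve_slopes(self, standard_conditions):
        obs = pt.ObserverParams(wm=0.1, wp=0.1)
        prof = pt.SubjectProfile(subject_id="big", observer=obs)
        frames = [
            pt.simulate_session(prof, pt.plan_session(s), seed=100 + s)
            for s in range(8)
        ]
        trials = pd.concat(frames, ignore_index=True)
        emp = pt.condition_slopes(trials).groupby("condition")["slope"].mean()
        for name, cond in standard_conditions.items():
            curve = pt.simulate_condition_curve(
                obs, cond.prior, n_sims=1000, rng=np.random.default_rng(5)
            )
            assert emp[name] == pytest.approx(curve.slope, abs=0.05)


class TestBuildDesign:
    def test_level1_contains_exactly_base_terms(self, design_level1):
        spec, _ = design_level1
        assert set(spec.terms) == {
            "Intercept",
            "sample_z",
            "length_medium",
            "length_long",
            "width_wide",
            "sample_z:length_medium",
            "sample_z:length_long",
            "sample_z:width_wide",
        }

    def test_level8_matches_full_formula(self, small_cohort_trials):
        trials, _, _ = small_cohort_trials
        spec, _ = pt.build_design(trials, level=8)
        for name in (
            "start",
            "length_transition",
            "width_transition_ntow",
            "width_transition_wton",
            "global_mean_z",
        ):
            assert name in spec.terms
        for name in (
            "sample_z:start",
            "sample_z:length_transition",
            "sample_z:width_transition_ntow",
            "sample_z:width_transition_wton",
        ):
            assert name in spec.terms
        assert "sample_z:global_mean_z" not in spec.terms

    def test_zscored_sample_has_mean_zero_sd_one(self, design_level1):
        _, data = design_level1
        assert abs(data["sample_z"].mean()) < 1e-10
        assert data["sample_z"].std(ddof=0) == pytest.approx(1.0, abs=1e-10)

    def test_transition_indicator_marks_first_block_only(self, small_cohort_trials):
        trials, _, _ = small_cohort_trials
        _, data = pt.build_design(trials, level=8)
        for sid, grp in data.groupby("subject_id"):
            order = grp.sort_values("trial_index")["condition"].drop_duplicates().tolist()
            wm_pos = order.index("WM")
            if wm_pos == 0:
                after = order[1]  # first narrow condition after the wide one
                rows = grp[grp["condition"] == after]
                assert (rows.loc[rows["block"] == 1, "width_transition_wton"] == 1).all()
                assert (rows.loc[rows["block"] > 1, "width_transition_wton"] == 0).all()
            else:
                rows = grp[grp["condition"] == "WM"]
                assert (rows.loc[rows["block"] == 1, "width_transition_ntow"] == 1).all()
                assert (rows.loc[rows["block"] > 1, "width_transition_ntow"] == 0).all()

    def test_global_mean_is_running_mean_of_preceding_samples(self, small_cohort_trials):
        trials, _, _ = small_cohort_trials
        _, data = pt.build_design(trials, level=4)
        one = data[data["subject_id"] == data["subject_id"].iloc[0]].sort_values(
            "trial_index"
        )
        s = one["sample_s"].to_numpy()
        expected = np.concatenate([[s[0]], np.cumsum(s)[:-1] / np.arange(1, len(s))])
        np.testing.assert_allclose(one["global_mean"].to_numpy(), expected, atol=1e-12)

    def test_rank_deficient_design_raises(self, small_cohort_trials):
        trials, _, _ = small_cohort_trials
        # keep only NM and WM: the medium-length dummy becomes the intercept
        sub = trials[trials["condition"].isin(["NM", "WM"])]
        with pytest.raises(ValueError, match="aliased|rank"):
            pt.build_design(sub, level=1)

    def test_missing_covariates_listed(self, small_cohort_trials):
        trials, covariates, _ = small_cohort_trials
        with pytest.raises(ValueError, match="S000|missing"):
            pt.build_design(trials, 1, covariates=covariates.iloc[2:])


class TestFitLme:
    def test_recovers_known_fixed_effects(self, design_level1):
        spec, data = design_level1
        data = data.copy()
        # split each session into two pseudo-subjects: ML variance components
        # are biased low with very few groups, which would distort coverage
        data["subject_id"] = (
            data["subject_id"] + "_" + (data["trial_index"] % 4).astype(str)
        )
        X = patsy.dmatrix(spec.formula.split("~", 1)[1], data, return_type="dataframe")
        beta = np.array([0.9, 0.1, 0.05, 0.1, 0.0, -0.02, -0.04, 0.05])
        subjects = data["subject_id"].to_numpy()
        ids = pd.unique(subjects)
        rng_master = np.random.default_rng(77)
        covered = 0
        n_rep = 100
        for rep in range(n_rep):
            rng = np.random.default_rng(rng_master.integers(2**31))
            re = {s: rng.normal(0, 0.1, 2) for s in ids}
            re_int = np.array([re[s][0] for s in subjects])
            re_slo = np.array([re[s][1] for s in subjects])
            y = (
                X.to_numpy() @ beta
                + re_int
                + re_slo * data["sample_z"].to_numpy()
                + rng.normal(0, 0.1, len(data))
            )
            sim = data.copy()
            sim["production_s"] = y
            fit = pt.fit_lme(spec, sim)
            c = fit.coef("sample_z")
            # 95% interval using the fit's own Satterthwaite df
            crit = stats.t.ppf(0.975, c["df"])
            covered += abs(c["estimate"] - 0.1) <= crit * c["se"]
        assert covered / n_rep >= 0.90

    def test_degenerate_random_effects_match_pooled_ols(self, design_level1):
        import statsmodels.api as sm

        spec, data = design_level1
        X = patsy.dmatrix(spec.formula.split("~", 1)[1], data, return_type="dataframe")
        rng = np.random.default_rng(3)
        beta = np.array([0.9, 0.12, 0.0, 0.05, 0.01, -0.01, -0.03, 0.04])
        sim = data.copy()
        sim["production_s"] = X.to_numpy() @ beta + rng.normal(0, 0.1, len(data))
        fit = pt.fit_lme(spec, sim)
        ols = sm.OLS(sim["production_s"], X).fit()
        np.testing.assert_allclose(
            fit.coefficients["estimate"].to_numpy(), ols.params.to_numpy(), atol=1e-4
        )

    def test_prior_manipulation_effects_have_predicted_signs(self, ladder_fits):
        fit = ladder_fits[1]
        assert fit.coef("sample_z:width_wide")["estimate"] > 0
        assert fit.coef("sample_z:length_long")["estimate"] < 0
        assert fit.coef("sample_z:width_wide")["p"] < 0.05

    def test_information_criteria_identities(self, ladder_fits):
        for fit in ladder_fits.values():
            assert fit.aic == pytest.approx(2 * fit.k_params - 2 * fit.loglik, rel=1e-12)
            assert fit.bic == pytest.approx(
                fit.k_params * np.log(fit.n_obs) - 2 * fit.loglik, rel=1e-12
            )

    def test_satterthwaite_dfs_are_reported_and_bounded(self, ladder_fits):
        fit = ladder_fits[1]
        assert (fit.coefficients["df_method"] == "satterthwaite").all()
        assert (fit.coefficients["df"] >= 1).all()
        assert (fit.coefficients["df"] <= fit.n_obs - len(fit.coefficients)).all()
        # the random-slope-bearing Sample term has far fewer effective dfs
        # than purely within-subject terms
        df_sample = fit.coef("sample_z")["df"]
        df_within = fit.coef("length_long")["df"]
        assert df_sample < df_within / 2


class TestModelComparison:
    def test_lrt_statistics_nonnegative_and_chi2_calibrated(self, ladder_fits):
        comp = pt.compare_models(ladder_fits)
        lrt = comp.table["lrt_stat"].dropna()
        assert (lrt >= 0).all()
        # oracle: chi-square survival at a canonical point
        assert stats.chi2.sf(10, 2) == pytest.approx(0.00674, abs=1e-5)

    def test_aic_bic_closed_forms(self):
        fits = {
            1: lme.LMEFit(
                level=1, formula="", coefficients=pd.DataFrame({"term": []}),
                cov_re=np.eye(2), scale=1.0, loglik=-100.0,
                aic=2 * 5 + 200, bic=5 * np.log(100) + 200,
                n_obs=100, n_subjects=10, k_params=5, converged=True,
            )
        }
        f = fits[1]
        assert f.aic == pytest.approx(210.0)
        assert f.bic == pytest.approx(5 * np.log(100) + 200, abs=1e-9)
        assert f.bic == pytest.approx(223.0259, abs=1e-3)

    def test_mismatched_rows_raise(self, ladder_fits):
        import dataclasses

        bad = dict(ladder_fits)
        some = bad[1]
        bad[1] = dataclasses.replace(some, n_obs=some.n_obs - 1)
        with pytest.raises(ValueError, match="identical rows"):
            pt.compare_models(bad)

    def test_winner_requires_three_way_consensus(self, ladder_fits):
        comp = pt.compare_models(ladder_fits)
        if comp.consensus:
            row = comp.table[comp.table["level"] == comp.winner].iloc[0]
            assert row["aic"] == comp.table["aic"].min()
            assert row["bic"] == comp.table["bic"].min()
        else:
            assert comp.winner is None


class TestVif:
    def test_orthogonal_columns_have_unit_vif(self):
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(np.column_stack([np.ones(100), rng.normal(size=(100, 3))]))
        df = pd.DataFrame(q[:, 1:], columns=["a", "b", "c"])  # centered, orthogonal
        assert pt.vif(df).max() == pytest.approx(1.0, abs=1e-9)

    def test_known_correlation_gives_closed_form_vif(self):
        rng = np.random.default_rng(1)
        q, _ = np.linalg.qr(
            np.column_stack([np.ones(200), rng.normal(size=(200, 2))])
        )
        v1, v2 = q[:, 1], q[:, 2]  # centered, orthonormal
        df = pd.DataFrame({"x1": v1, "x2": 0.8 * v1 + 0.6 * v2})
        out = pt.vif(df)
        assert out["x1"] == pytest.approx(1 / (1 - 0.64), rel=1e-9)
        assert out["x2"] == pytest.approx(2.778, abs=1e-3)

    def test_duplicated_column_is_flagged_infinite(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        df = pd.DataFrame({"x1": x, "x2": x})
        assert np.isinf(pt.vif(df)).all()

    def test_fixed_design_vifs_finite_and_flaggable(self, design_level1):
        # dummy x continuous interaction codings inflate some VIFs by
        # construction; the diagnostic must stay finite and identify them
        spec, data = design_level1
        X = patsy.dmatrix(spec.formula.split("~", 1)[1], data, return_type="dataframe")
        out = pt.vif(X)
        assert np.isfinite(out).all()
        assert (out >= 1 - 1e-9).all()
        assert "Intercept" not in out.index


class TestInterindividual:
    def test_model_contains_six_trait_modulation_terms(self, small_cohort_trials):
        trials, covariates, _ = small_cohort_trials
        fit = pt.interindividual_model(trials, covariates, level=1)
        for factors in [
            ("sample_z", "caps_z"),
            ("sample_z", "wf_z"),
            ("sample_z", "length_long", "caps_z"),
            ("sample_z", "length_long", "wf_z"),
            ("sample_z", "width_wide", "caps_z"),
            ("sample_z", "width_wide", "wf_z"),
        ]:
            assert fit.find_term(*factors) is not None

    def test_weber_variation_lowers_slopes(self):
        # population varying only in wm: higher WF -> more central tendency,
        # i.e. a negative Sample x WF coefficient
        hyper = pt.PopulationHyper(gamma_max=0.0)
        profiles = pt.generate_population(14, hyper, seed=8)
        conds = pt.standard_conditions(reps_per_bin_per_block=2)
        rng = np.random.default_rng(15)
        frames = [
            pt.simulate_session(p, pt.plan_session(rng), rng, conditions=conds)
            for p in profiles
        ]
        trials = pd.concat(frames, ignore_index=True)
        cov = pd.DataFrame(
            {
                "subject_id": [p.subject_id for p in profiles],
                "wf": [p.observer.wm for p in profiles],
                "caps": [p.caps_score for p in profiles],
            }
        )
        fit = pt.interindividual_model(trials, cov, level=1)
        assert fit.find_term("sample_z", "wf_z")["estimate"] < 0


class TestLastBlocksSensitivity:
    def test_subset_drops_first_blocks_and_start(self, small_cohort_trials):
        trials, _, _ = small_cohort_trials
        per_subject_full = trials.groupby("subject_id").size().iloc[0]
        with pytest.warns(UserWarning, match="constant"):
            fits = pt.last_blocks_sensitivity(trials, levels=(8,))
        fit = fits[8]
        n_subj = trials["subject_id"].nunique()
        # two of three blocks survive
        assert fit.n_obs == n_subj * per_subject_full * 2 // 3
        assert "start" not in [t for t in fit.coefficients["term"]]

    def test_full_session_subset_row_count(self, single_session):
        df, _ = single_session
        subset = df[df["block"] > 1]
        assert len(subset) == 648

    def test_width_effect_stable_without_first_blocks(self, small_cohort_trials):
        trials, _, _ = small_cohort_trials
        full = pt.fit_ladder(trials, levels=(1,))[1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sub = pt.last_blocks_sensitivity(trials, levels=(1,))[1]
        a = full.coef("sample_z:width_wide")
        b = sub.coef("sample_z:width_wide")
        assert abs(a["estimate"] - b["estimate"]) <= 2 * max(a["se"], b["se"])
        assert np.sign(a["estimate"]) == np.sign(b["estimate"])
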