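import numpy as np
import pandas as pd
import pytest

import crowdcontext as cc
from crowdcontext.empirical_pipeline import MIN_ESTIMATES_FOR_R

from conftest import make_trials, trial_rows


class TestLoadTrials:
    def test_round_trip_with_generator_output(self, tmp_path, small_corpus):
        trials, _ = small_corpus
        path = tmp_path / "trials.csv"
        trials.to_csv(path, index=False)
        loaded = cc.load_trials(path)
        assert len(loaded) == len(trials)
        pd.testing.assert_frame_equal(
            loaded.reset_index(drop=True), trials[list(loaded.columns)], check_dtype=False)

    def test_missing_truth_column(self, tmp_path, toy_trials):
        path = tmp_path / "bad.csv"
        toy_trials.drop(columns=["truth"]).to_csv(path, index=False)
        with pytest.raises(cc.SchemaError, match="truth"):
            cc.load_trials(path)

    def test_non_numeric_estimate_reported_with_location(self, tmp_path, toy_trials):
        bad = toy_trials.copy()
        bad["estimate"] = bad["estimate"].astype(object)
        bad.loc[3, "estimate"] = "twelve-ish"
        path = tmp_path / "bad.csv"
        bad.to_csv(path, index=False)
        with pytest.raises(cc.SchemaError, match=r"non-numeric.*\[3\]"):
            cc.load_trials(path)

    def test_column_mapping(self, tmp_path, toy_trials):
        renamed = toy_trials.rename(columns={"estimate": "guess", "truth": "answer"})
        path = tmp_path / "dialect.csv"
        renamed.to_csv(path, index=False)
        loaded = cc.load_trials(path, mapping={"estimate": "guess", "truth": "answer"})
        assert "estimate" in loaded.columns

    def test_duplicate_stage_record_rejected(self, toy_trials):
        dup = pd.concat([toy_trials, toy_trials.iloc[[0]]], ignore_index=True)
        with pytest.raises(cc.SchemaError, match="exactly one initial"):
            cc.validate_trials(dup)

    def test_two_row_toy_file(self, tmp_path):
        df = make_trials(trial_rows("s1", "t1", "g1", [100], [10], truth=12))
        path = tmp_path / "tiny.csv"
        df.to_csv(path, index=False)
        out = cc.summarize_trials(cc.load_trials(path))
        assert len(out) == 1


class TestFilterPositiveTasks:
    def test_no_negatives_unchanged(self, small_corpus):
        trials, _ = small_corpus
        assert len(cc.filter_positive_tasks(trials)) == len(trials)

    def test_task_level_omission(self, toy_trials):
        out = cc.filter_positive_tasks(toy_trials)
        # t3 held the single -5 estimate: all its records go, t1/t2 stay whole
        assert set(out["task_id"]) == {"t1", "t2"}

    def test_zero_estimates_survive_this_filter(self):
        df = make_trials(trial_rows("s1", "t1", "g1", [0.0, 2.0], [1.0, 1.0], truth=1))
        assert len(cc.filter_positive_tasks(df)) == len(df)


class TestSummarize:
    def test_hand_arithmetic(self, toy_trials):
        out = cc.summarize_trials(toy_trials).set_index(["task_id", "group_id"])
        t1g1 = out.loc[("t1", "g1")]
        assert t1g1["collective_initial"] == 20.0
        assert t1g1["collective_revised"] == 20.0
        assert t1g1["abs_err_initial"] == 1.0 and t1g1["abs_err_revised"] == 1.0
        assert t1g1["improved"] == 0  # tie is not improvement

        t1g2 = out.loc[("t1", "g2")]
        assert t1g2["abs_err_initial"] == 19.0 and t1g2["abs_err_revised"] == 19.0
        assert t1g2["improved"] == 0

        t2g1 = out.loc[("t2", "g1")]  # single-subject trial
        assert t2g1["abs_err_initial"] == 88.0 and t2g1["abs_err_revised"] == 2.0
        assert t2g1["improved"] == 1

    def test_exact_tie_at_zero_error(self):
        df = make_trials(trial_rows("s1", "t1", "g1", [1, 3], [2, 2], truth=2))
        row = cc.summarize_trial(df)
        assert row["abs_err_initial"] == 0.0 == row["abs_err_revised"]
        assert row["improved"] == 0

    def test_missing_revised_records(self):
        df = make_trials(trial_rows("s1", "t1", "g1", [1, 3], [2, 2], truth=2))
        with pytest.raises(cc.SchemaError):
            cc.summarize_trials(cc.validate_trials(df[df["stage"] == "initial"]))

    def test_condition_indicator(self, toy_trials):
        out = cc.summarize_trials(toy_trials)
        assert set(out.loc[out["condition"] == "control", "I"]) == {0}
        assert set(out.loc[out["condition"] == "interactive", "I"]) == {1}


class TestTaskFeatures:
    def test_constant_within_task(self, small_corpus):
        trials, _ = small_corpus
        out = cc.attach_task_features(trials, cc.summarize_trials(trials))
        assert (out.groupby(["study_id", "task_id"])["R"].nunique() == 1).all()

    def test_lognormal_task_has_high_R(self):
        rng = np.random.default_rng(0)
        rows = []
        for g in range(5):
            a = np.exp(rng.normal(2, 1, 20))
            rows += trial_rows("s1", "t1", f"g{g}", a, a, truth=10)
        trials = make_trials(rows)
        feats = cc.compute_task_features(trials)
        assert feats.loc[0, "R"] > 0.5
        assert feats.loc[0, "n_obs"] == 100  # pooled across groups

    def test_small_pool_excluded(self):
        trials = make_trials(trial_rows("s1", "t1", "g1", [1, 2, 3], [1, 2, 3], truth=2))
        assert 3 < MIN_ESTIMATES_FOR_R
        feats = cc.compute_task_features(trials)
        assert np.isnan(feats.loc[0, "R"])
        out = cc.attach_task_features(trials, cc.summarize_trials(trials))
        assert len(out) == 0


class TestStandardizeErrors:
    def test_two_trial_task(self):
        rows = trial_rows("s1", "t1", "g1", [8], [8], truth=10)  # err 2
        rows += trial_rows("s1", "t1", "g2", [6], [6], truth=10)  # err 4
        out = cc.standardize_errors(cc.summarize_trials(make_trials(rows)))
        np.testing.assert_allclose(
            np.sort(out["z_err"]), [-np.sqrt(0.5), np.sqrt(0.5)], rtol=1e-12)

    def test_normalization_identity(self, small_outcomes):
        grp = small_outcomes.groupby(["study_id", "task_id"])["z_err"]
        np.testing.assert_allclose(grp.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(grp.std(ddof=1), 1.0, rtol=1e-12)

    def test_zero_sd_task_excluded(self):
        rows = trial_rows("s1", "t1", "g1", [8], [8], truth=10)
        rows += trial_rows("s1", "t1", "g2", [12], [12], truth=10)  # same |err|
        out = cc.standardize_errors(cc.summarize_trials(make_trials(rows)))
        assert len(out) == 0


class TestMixedModels:
    def test_constant_R_is_singular(self, small_outcomes):
        d = small_outcomes.copy()
        d["R"] = 0.7
        with pytest.raises(cc.SingularDesignError):
            cc.fit_improvement_model(d)

    def test_single_condition_rejected(self, small_outcomes):
        d = small_outcomes[small_outcomes["I"] == 1]
        with pytest.raises(cc.DesignError):
            cc.fit_error_model(d)

    def test_constant_outcome_rejected(self, small_outcomes):
        d = small_outcomes.copy()
        d["improved"] = 1
        with pytest.raises(cc.DesignError, match="constant"):
            cc.fit_improvement_model(d)

    def test_counting_consistency(self, small_outcomes):
        logit = cc.fit_improvement_model(small_outcomes)
        linear = cc.fit_error_model(small_outcomes)
        n_interactive = int(small_outcomes["I"].sum())
        n_control = int((1 - small_outcomes["I"]).sum())
        assert logit.n_obs == n_interactive
        assert linear.n_obs == n_interactive + n_control
        assert linear.n_obs - logit.n_obs == n_control

    def test_statistic_is_estimate_over_se(self, small_outcomes):
        for res in (cc.fit_improvement_model(small_outcomes),
                    cc.fit_error_model(small_outcomes)):
            for coef in res.coefficients.values():
                assert coef.stat == pytest.approx(coef.estimate / coef.se, abs=1e-6)

    def test_result_serializes(self, small_outcomes):
        import json
        blob = json.dumps(cc.fit_error_model(small_outcomes).to_dict())
        assert "coefficients" in blob

    def test_pipeline_determinism(self, small_corpus):
        trials, _ = small_corpus
        def run():
            out = cc.attach_task_features(trials, cc.summarize_trials(trials))
            return cc.standardize_errors(out)
        a, b = run(), run()
        pd.testing.assert_frame_equal(a, b)
        fa = cc.fit_error_model(a)
        fb = cc.fit_error_model(b)
        assert fa.coefficients == fb.coefficients


class TestMarginalEffects:
    def test_surface_and_crossing(self, small_outcomes):
        res = cc.fit_error_model(small_outcomes)
        me = cc.marginal_effects(res, r_grid=np.linspace(0, 1, 11))
        assert len(me) == 22
        b = {k: v.estimate for k, v in res.coefficients.items()}
        ctrl0 = me[(me["condition"] == "control") & (me["R"] == 0)]["predicted_z_err"].iloc[0]
        assert ctrl0 == pytest.approx(b["Intercept"])
        inter1 = me[(me["condition"] == "interactive") & (me["R"] == 1)]["predicted_z_err"].iloc[0]
        assert inter1 == pytest.approx(b["Intercept"] + b["R"] + b["I"] + b["R:I"])
        assert (me["ci_low"] <= me["predicted_z_err"]).all()

    def test_requires_linear_model(self, small_outcomes):
        logit = cc.fit_improvement_model(small_outcomes)
        with pytest.raises(ValueError, match="linear"):
            cc.marginal_effects(logit)
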