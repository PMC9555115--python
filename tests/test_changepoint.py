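"""Episode splitting, the extended (change-point) Cox fit, AIC threshold
search and two-regime survival prediction."""

import numpy as np
import pandas as pd
import pytest

from extcox.changepoint import (
    ChangePointModel,
    EXTENDED_COLUMNS,
    extended_design,
    fit_extended,
    group_hazard_ratios,
    level_hazard_ratios,
    predict_survival,
    select_threshold,
    split_at_threshold,
)
from extcox.cohort import SimulationConfig, TRUE_COEFFICIENTS, generate_cohort
from extcox.coxph import newton_cox
from extcox.evaluate import kaplan_meier
from .conftest import threshold_recovery_config


def _episodes(cohort, tau):
    X, x8 = extended_design(cohort)
    return split_at_threshold(
        cohort["time_weeks"].to_numpy(), cohort["event"].to_numpy(), X, x8, tau
    ), X, x8


class TestSplit:
    def test_single_patient_arithmetic(self):
        X = np.array([[1.0]])
        ep = split_at_threshold([200.0], [1.0], X, [1.0], 164.0, names=["z"])
        assert ep.start.tolist() == [0.0, 164.0]
        assert ep.stop.tolist() == [164.0, 200.0]
        assert ep.event.tolist() == [0.0, 1.0]
        assert ep.x8.tolist() == [0.0, 1.0]

    def test_exposure_conserved(self, fixture_cohort):
        ep, _, _ = _episodes(fixture_cohort, 164.0)
        assert ep.exposure == pytest.approx(fixture_cohort["time_weeks"].sum())

    def test_event_only_in_final_episode(self, small_cohort):
        ep, _, _ = _episodes(small_cohort, 164.0)
        df = pd.DataFrame({"pid": ep.patient_idx, "stop": ep.stop, "e": ep.event})
        last = df.sort_values("stop").groupby("pid").tail(1)
        assert df["e"].sum() == last["e"].sum()

    def test_interaction_inactive_at_exactly_tau(self):
        X = np.array([[1.0]])
        ep = split_at_threshold([164.0], [1.0], X, [1.0], 164.0, names=["z"])
        assert len(ep.stop) == 1 and ep.x8.tolist() == [0.0]

    def test_tau_beyond_follow_up_reduces_to_plain_cox(self, small_cohort):
        t = small_cohort["time_weeks"].to_numpy()
        e = small_cohort["event"].to_numpy()
        ep, X, _ = _episodes(small_cohort, float(t.max()) + 1.0)
        with pytest.warns(UserWarning, match="all-zero"):
            m = fit_extended(ep)
        plain = newton_cox(X, t, e)
        assert abs(m.loglik - plain.loglik) < 1e-10


class TestFitExtended:
    def test_coefficient_recovery_two_se(self):
        """Fits on cohorts generated from the change-point truth recover
        each coefficient within two standard errors (pooled over three
        seeded replicates to stabilize the point estimate)."""
        ests, ses = [], []
        for seed in (0, 1, 2):
            df = generate_cohort(SimulationConfig(n_patients=5000, seed=seed))
            ep, _, _ = _episodes(df, 164.0)
            m = fit_extended(ep)
            ests.append([m.coef[k] for k in TRUE_COEFFICIENTS])
            ses.append([m.se[k] for k in TRUE_COEFFICIENTS])
        pooled = np.mean(ests, axis=0)
        se = np.mean(ses, axis=0)
        truth = np.array(list(TRUE_COEFFICIENTS.values()))
        assert np.all(np.abs(pooled - truth) <= 2.0 * se)

    def test_post_threshold_hr_is_exp_beta8(self, small_cohort):
        ep, _, _ = _episodes(small_cohort, 164.0)
        m = fit_extended(ep)
        hr = group_hazard_ratios(m).set_index(["period", "pr_status", "age_group"])
        pre = hr.loc[("pre", "high", "middle"), "coef"]
        post = hr.loc[("post", "high", "middle"), "coef"]
        assert post - pre == pytest.approx(m.beta_post)

    def test_group_table_reproduces_published_arithmetic(self):
        m = ChangePointModel.from_coefficients(dict(TRUE_COEFFICIENTS), tau=164.0)
        g = group_hazard_ratios(m).set_index(["period", "pr_status", "age_group"])["hr"]
        assert g[("pre", "high", "young")] == pytest.approx(0.165, abs=5e-4)
        assert g[("pre", "low", "middle")] == pytest.approx(0.210, abs=5e-4)
        assert g[("pre", "low", "elderly")] == pytest.approx(0.83, abs=5e-3)
        assert g[("post", "high", "middle")] == pytest.approx(0.17, abs=5e-3)
        assert g[("post", "high", "elderly")] == pytest.approx(0.68, abs=5e-3)

    def test_level_table_ordinal_arithmetic(self):
        m = ChangePointModel.from_coefficients(dict(TRUE_COEFFICIENTS))
        lv = level_hazard_ratios(m).set_index(["factor", "level"])["hr"]
        assert lv[("grade", "III")] == pytest.approx(np.exp(2 * 1.329))
        assert lv[("n_stage", "2")] == pytest.approx(np.exp(2 * 0.972))


class TestSelectThreshold:
    def test_profile_invariant_under_reordering(self, small_cohort):
        t = small_cohort["time_weeks"].to_numpy()
        e = small_cohort["event"].to_numpy()
        X, x8 = extended_design(small_cohort)
        cands = [100.0, 150.0, 200.0, 250.0]
        _, prof1 = select_threshold(t, e, X, x8, candidates=cands)
        _, prof2 = select_threshold(t, e, X, x8, candidates=cands[::-1])
        pd.testing.assert_frame_equal(prof1, prof2)

    def test_profile_length_and_tie_break(self, small_cohort):
        t = small_cohort["time_weeks"].to_numpy()
        e = small_cohort["event"].to_numpy()
        X, x8 = extended_design(small_cohort)
        cands = [120.0, 180.0, 240.0]
        best, prof = select_threshold(t, e, X, x8, candidates=cands)
        assert len(prof) == 3
        assert best.tau == prof.loc[prof["aic"].idxmin(), "tau"]

    def test_needs_two_candidates(self, small_cohort):
        t = small_cohort["time_weeks"].to_numpy()
        e = small_cohort["event"].to_numpy()
        X, x8 = extended_design(small_cohort)
        with pytest.raises(ValueError, match="two admissible"):
            select_threshold(t, e, X, x8, candidates=[164.0])

    def test_null_interaction_aic_favors_base_model(self):
        """With the interaction coefficient zero in truth, the fixed-
        threshold extended model offers no AIC improvement over the
        no-interaction model on average, and the fitted interaction term is
        not significant (averaged over replicates)."""
        gaps, zs = [], []
        for seed in (20, 21, 22, 23, 24):
            cfg = threshold_recovery_config(seed, n=2000)
            cfg.coefficients = dict(cfg.coefficients, pr_age_post=0.0)
            df = generate_cohort(cfg)
            t = df["time_weeks"].to_numpy()
            e = df["event"].to_numpy()
            X, x8 = extended_design(df)
            ep = split_at_threshold(t, e, X, x8, 164.0)
            m = fit_extended(ep)
            base = newton_cox(X, t, e)
            base_aic = -2 * base.loglik + 2 * X.shape[1]
            gaps.append(base_aic - m.aic)
            zs.append(abs(m.coef["pr_age_post"] / m.se["pr_age_post"]))
        assert np.mean(gaps) <= 2.0
        assert np.mean(zs) < 3.0


class TestPredictSurvival:
    @pytest.fixture(scope="class")
    def fitted(self):
        df = generate_cohort(SimulationConfig(n_patients=3000, seed=8,
                                              baseline_rates=(4e-4, 4e-4)))
        ep, X, x8 = _episodes(df, 164.0)
        return fit_extended(ep), df, X, x8

    def test_reference_patient_gets_baseline_survival(self, fitted):
        m, df, X, x8 = fitted
        ref = np.zeros((1, X.shape[1]))
        s = predict_survival(m, ref, [0.0], [100.0, 200.0])[0]
        idx = np.searchsorted(m.baseline_times, [100.0, 200.0], side="right") - 1
        base = np.exp(-m.baseline_cumhaz[idx])
        assert np.allclose(s, base)

    def test_monotone_and_continuous_at_tau(self, fitted):
        m, df, X, x8 = fitted
        ts = np.array([50.0, 120.0, 163.9, 164.0, 164.1, 220.0, 300.0])
        s = predict_survival(m, X[:5], x8[:5], ts)
        assert np.all(np.diff(s, axis=1) <= 1e-12)
        # continuity at the threshold: no jump bigger than the local step
        assert np.all(np.abs(s[:, 3] - s[:, 2]) < 0.01)

    def test_horizon_beyond_support_rejected(self, fitted):
        m, df, X, x8 = fitted
        with pytest.raises(ValueError, match="beyond baseline support"):
            predict_survival(m, X[:1], x8[:1], [m.max_time + 10.0])

    def test_agrees_with_km_on_one_stratum(self):
        """Model survival matches the Kaplan-Meier estimate on a cohort with
        a single covariate pattern (within simulation error)."""
        marg = None
        cfg = SimulationConfig(n_patients=6000, seed=14, baseline_rates=(4e-4, 4e-4))
        df = generate_cohort(cfg)
        stratum = (
            (df["grade"] == 2) & (df["n_stage"] == 0) & (df["ki67_pct"] < 60)
            & (df["pr_pct"] >= 20) & (df["age"] >= 55)
        )
        sub = df[stratum]
        ep, X, x8 = _episodes(df, 164.0)
        m = fit_extended(ep)
        km = kaplan_meier(sub["time_weeks"].to_numpy(), sub["event"].to_numpy())
        Xs, x8s = extended_design(sub)
        for t in (100.0, 250.0):
            s_model = predict_survival(m, Xs[:1], x8s[:1], [t])[0, 0]
            s_km = float(np.atleast_1d(km.survival_at(t))[0])
            assert s_model == pytest.approx(s_km, abs=0.03)
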