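"""Synthetic-cohort module: fixture marginals, generator distributional
properties, summaries and I/O."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from extcox.cohort import (
    CohortSchemaError,
    SimulationConfig,
    TRUE_COEFFICIENTS,
    generate_cohort,
    linear_predictor,
    make_fixture,
    read_cohort_csv,
    table_one,
    validate_cohort,
    write_cohort_csv,
)
from extcox.coxph import newton_cox


FIXTURE_MARGINALS = [
    ("grade", {"1": 22, "2": 267, "3": 46}),
    ("t_stage", {"1": 206, "2": 126, "3": 3, "4": 0}),
    ("n_stage", {"0": 180, "1": 98, "2": 41, "3": 16}),
    ("lvi", {"0": 220, "1": 115}),
    ("tnm_stage", {"1": 133, "2": 142, "3": 60}),
    ("p53", {"0": 176, "1": 159}),
    ("age_group", {"<41": 27, "41-54": 159, ">=55": 149}),
    ("pr_group", {"<20": 72, ">=20": 263}),
    ("ki67_group", {"<60": 292, ">=60": 43}),
]


class TestFixture:
    def test_size_and_event_split(self, fixture_cohort):
        assert len(fixture_cohort) == 335
        assert int(fixture_cohort["event"].sum()) == 28
        assert int((fixture_cohort["event"] == 0).sum()) == 307

    @pytest.mark.parametrize("characteristic,expected", FIXTURE_MARGINALS)
    def test_marginals_exact(self, fixture_cohort, characteristic, expected):
        t1 = table_one(fixture_cohort)
        for category, count in expected.items():
            assert t1.loc[(characteristic, category), "full"] == count

    def test_died_subgroup_marginals(self, fixture_cohort):
        t1 = table_one(fixture_cohort)
        assert t1.loc[("grade", "1"), "died"] == 0
        assert t1.loc[("grade", "3"), "died"] == 12
        assert t1.loc[("n_stage", "3"), "died"] == 10
        assert t1.loc[("ki67_group", ">=60"), "died"] == 10
        assert t1.loc[("age_group", ">=55"), "died"] == 18

    def test_determinism(self):
        a, b = make_fixture(), make_fixture()
        pd.testing.assert_frame_equal(a, b)

    def test_age_range_and_median(self, fixture_cohort):
        assert fixture_cohort["age"].min() == 26
        assert fixture_cohort["age"].max() == 89
        assert fixture_cohort["age"].median() == 53

    def test_longest_death_time(self, fixture_cohort):
        died = fixture_cohort[fixture_cohort["event"] == 1]
        assert died["time_weeks"].max() == 341.0


class TestTableOne:
    def test_counts_sum_to_n(self, fixture_cohort):
        t1 = table_one(fixture_cohort)
        grade = t1.loc["grade"]
        assert grade["full"].sum() == 335
        assert (grade["censored"] + grade["died"]).equals(grade["full"])

    def test_single_row_cohort(self, fixture_cohort):
        t1 = table_one(fixture_cohort.iloc[[0]])
        counts = t1.loc["grade", "full"]
        assert set(counts) <= {0, 1}
        assert counts.sum() == 1


class TestGenerator:
    def test_same_seed_identical(self):
        cfg = SimulationConfig(n_patients=200, seed=42)
        pd.testing.assert_frame_equal(generate_cohort(cfg), generate_cohort(cfg))

    def test_different_seed_differs(self):
        a = generate_cohort(SimulationConfig(n_patients=200, seed=1))
        b = generate_cohort(SimulationConfig(n_patients=200, seed=2))
        assert not a["time_weeks"].equals(b["time_weeks"])

    def test_null_effects_times_follow_baseline(self):
        """With all coefficients zero and no censoring, event times follow
        the piecewise-exponential baseline distribution (KS test)."""
        r1, r2 = 2e-3, 1e-3
        cfg = SimulationConfig(
            n_patients=5000,
            seed=9,
            coefficients={k: 0.0 for k in TRUE_COEFFICIENTS},
            baseline_rates=(r1, r2),
            admin_window=(1e9, 1e9 + 1),
            loss_rate=0.0,
        )
        df = generate_cohort(cfg)
        assert df["event"].all()

        def cdf(t):
            t = np.asarray(t, dtype=float)
            H = np.where(t <= 164.0, r1 * t, r1 * 164.0 + r2 * (t - 164.0))
            return 1.0 - np.exp(-H)

        ks = stats.kstest(df["time_weeks"], cdf)
        assert ks.pvalue > 0.01

    def test_censoring_rate_near_default_target(self):
        """Default conditions give ~91.6% censoring (within 5 points)."""
        df = generate_cohort(SimulationConfig(n_patients=335, seed=0))
        cens = 100.0 * (df["event"] == 0).mean()
        assert abs(cens - 91.6) <= 5.0

    def test_parameter_recovery_standard_cox(self):
        """Without the change point, a standard Cox fit on the generating
        columns recovers every coefficient within 2 SE (n=10000)."""
        coef = dict(TRUE_COEFFICIENTS, pr_age_post=0.0)
        cfg = SimulationConfig(
            n_patients=10000, seed=4, coefficients=coef, baseline_rates=(2e-4, 2e-4)
        )
        df = generate_cohort(cfg)
        A, _ = linear_predictor(df, coef, cfg.cutoffs)
        X = np.column_stack(
            [
                df["grade"] - 1,
                df["n_stage"],
                (df["ki67_pct"] >= 60).astype(float),
                (df["pr_pct"] >= 20).astype(float),
                (df["age"] >= 55).astype(float),
                (df["age"] >= 41).astype(float),
            ]
        )
        fit = newton_cox(X, df["time_weeks"].to_numpy(), df["event"].to_numpy())
        truth = [coef[k] for k in
                 ["grade", "n_stage", "ki67_high", "pr_high", "age_ge55", "age_ge41"]]
        z = (fit.coef - np.array(truth)) / fit.se
        assert np.all(np.abs(z) <= 2.0)

    def test_copula_correlation_orders_continuous_factors(self):
        cfg = SimulationConfig(n_patients=4000, seed=7, correlation=0.8)
        df = generate_cohort(cfg)
        rho = stats.spearmanr(df["er_pct"], df["pr_pct"]).statistic
        base = generate_cohort(SimulationConfig(n_patients=4000, seed=7))
        rho0 = stats.spearmanr(base["er_pct"], base["pr_pct"]).statistic
        assert rho > 0.5 > abs(rho0) + 0.4

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_patients": 0},
            {"n_patients": 10, "baseline_rates": (0.0, 1e-4)},
            {"n_patients": 10, "baseline_rates": (1e-4,)},
            {"n_patients": 10, "threshold_weeks": -1.0},
            {"n_patients": 10, "correlation": 1.5},
        ],
    )
    def test_configuration_errors(self, kwargs):
        with pytest.raises(ValueError, match="configuration error"):
            generate_cohort(SimulationConfig(seed=0, **kwargs))

    def test_bad_marginal_rejected(self):
        from extcox.cohort import _default_marginals

        marg = _default_marginals()
        marg["grade"] = (np.array([1, 2, 3]), np.array([0.5, 0.2, 0.2]))
        with pytest.raises(ValueError, match="sum to 1"):
            generate_cohort(SimulationConfig(n_patients=10, seed=0, marginals=marg))


class TestIO:
    def test_csv_round_trip(self, tmp_path, small_cohort):
        path = tmp_path / "cohort.csv"
        write_cohort_csv(small_cohort, path)
        back = read_cohort_csv(path)
        pd.testing.assert_frame_equal(
            back.reset_index(drop=True), small_cohort.reset_index(drop=True),
            check_dtype=False,
        )

    def test_missing_column_named(self, tmp_path, small_cohort):
        bad = small_cohort.drop(columns=["pr_pct"])
        with pytest.raises(CohortSchemaError, match="pr_pct") as exc:
            validate_cohort(bad)
        assert exc.value.column == "pr_pct"

    def test_domain_violation_named(self, small_cohort):
        bad = small_cohort.copy()
        bad.loc[bad.index[0], "er_pct"] = 0  # ER+ cohorts require >= 1%
        with pytest.raises(CohortSchemaError, match="er_pct"):
            validate_cohort(bad)
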