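"""Cox partial-likelihood numerics against closed forms, a brute-force
risk-set oracle, and the independent lifelines implementation."""

import numpy as np
import pytest

from extcox.coxph import (
    NonIdentifiableError,
    cox_loglik,
    cox_loglik_grad_hess,
    newton_cox,
)
from .conftest import random_survival_data


def brute_force_loglik(start, stop, event, X, beta, ties="breslow"):
    """Direct double-loop Breslow/Efron log partial likelihood."""
    X = np.atleast_2d(X)
    eta = X @ np.asarray(beta, dtype=float)
    ll = 0.0
    for t in np.unique(stop[event > 0]):
        tied = np.flatnonzero((stop == t) & (event > 0))
        at_risk = np.flatnonzero((start < t) & (t <= stop))
        s0 = np.exp(eta[at_risk]).sum()
        d0 = np.exp(eta[tied]).sum()
        d = len(tied)
        ll += eta[tied].sum()
        for l in range(d):
            ll -= np.log(s0 - (l / d) * d0 if ties == "efron" else s0)
    return ll


class TestLoglikClosedForms:
    def test_null_value_three_subjects(self):
        X = np.array([[1.0], [0.0], [0.0]])
        ll = cox_loglik(None, [1, 2, 3], [1, 1, 1], X, [0.0])
        assert ll == pytest.approx(-np.log(3) - np.log(2) - np.log(1))

    def test_hand_computed_risk_sets_at_beta_one(self):
        X = np.array([[1.0], [0.0], [0.0]])
        ll = cox_loglik(None, [1, 2, 3], [1, 1, 1], X, [1.0])
        assert ll == pytest.approx(1.0 - np.log(np.e + 2.0) - np.log(2.0))

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            cox_loglik(None, [1.0, 2.0], [0, 0], np.ones((2, 1)), [0.0])

    @pytest.mark.parametrize("ties", ["breslow", "efron"])
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_oracle(self, seed, ties):
        X, t, e = random_survival_data(seed, n=50, p=2, ties=True)
        rng = np.random.default_rng(seed + 100)
        beta = rng.normal(scale=0.5, size=2)
        ours = cox_loglik(None, t, e, X, beta, ties=ties)
        brute = brute_force_loglik(np.zeros_like(t), t, e, X, beta, ties=ties)
        assert ours == pytest.approx(brute, abs=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_counting_process_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        X = rng.normal(size=(n, 2))
        start = rng.uniform(0, 1, n)
        stop = start + rng.exponential(1.0, n)
        event = rng.integers(0, 2, n).astype(float)
        event[0] = 1
        beta = rng.normal(scale=0.5, size=2)
        ours = cox_loglik(start, stop, event, X, beta)
        brute = brute_force_loglik(start, stop, event, X, beta)
        assert ours == pytest.approx(brute, abs=1e-10)

    def test_gradient_matches_finite_differences(self):
        X, t, e = random_survival_data(3, n=60, p=3)
        beta = np.array([0.3, -0.2, 0.1])
        _, grad, info = cox_loglik_grad_hess(None, t, e, X, beta)
        eps = 1e-6
        for j in range(3):
            db = np.zeros(3)
            db[j] = eps
            num = (cox_loglik(None, t, e, X, beta + db)
                   - cox_loglik(None, t, e, X, beta - db)) / (2 * eps)
            assert grad[j] == pytest.approx(num, abs=1e-4)
        assert np.allclose(info, info.T)


class TestNewtonAgainstLifelines:
    def test_tie_free_fit_matches(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        X, t, e = random_survival_data(7, n=150, p=3, ties=False)
        fit = newton_cox(X, t, e)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["t"], df["e"] = t, e
        cph = CoxPHFitter().fit(df, "t", "e")
        assert np.allclose(fit.coef, cph.params_.to_numpy(), atol=1e-5)
        assert np.allclose(fit.se, cph.standard_errors_.to_numpy(), atol=1e-5)

    def test_efron_ties_match_lifelines(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        X, t, e = random_survival_data(8, n=120, p=2, ties=True)
        fit = newton_cox(X, t, e, ties="efron")
        df = pd.DataFrame(X, columns=["a", "b"])
        df["t"], df["e"] = t, e
        cph = CoxPHFitter().fit(df, "t", "e")
        assert np.allclose(fit.coef, cph.params_.to_numpy(), atol=1e-5)

    def test_counting_process_matches_time_varying_fitter(self):
        import pandas as pd
        from lifelines import CoxTimeVaryingFitter

        rng = np.random.default_rng(12)
        n = 120
        X = rng.normal(size=(n, 2))
        T = rng.exponential(np.exp(-X @ np.array([0.6, -0.4])))
        C = rng.exponential(2.0, n)
        t = np.minimum(T, C)
        e = (T <= C).astype(float)
        # split each subject at an arbitrary interior point
        cut = t * 0.4
        df = pd.DataFrame(
            {
                "id": np.concatenate([np.arange(n), np.arange(n)]),
                "start": np.concatenate([np.zeros(n), cut]),
                "stop": np.concatenate([cut, t]),
                "e": np.concatenate([np.zeros(n), e]),
                "a": np.concatenate([X[:, 0], X[:, 0]]),
                "b": np.concatenate([X[:, 1], X[:, 1]]),
            }
        )
        ctv = CoxTimeVaryingFitter().fit(df, id_col="id", start_col="start",
                                         stop_col="stop", event_col="e")
        fit = newton_cox(
            df[["a", "b"]].to_numpy(),
            start=df["start"].to_numpy(),
            stop=df["stop"].to_numpy(),
            event=df["e"].to_numpy(),
        )
        assert np.allclose(fit.coef, ctv.params_.to_numpy(), atol=1e-5)

    def test_separation_names_offending_column(self):
        t = np.arange(1.0, 41.0)
        e = np.ones(40)
        x = (t > 20).astype(float)  # perfectly orders the events
        with pytest.raises(NonIdentifiableError) as exc:
            newton_cox(x[:, None], t, e, names=["sep_col"])
        assert exc.value.column == "sep_col"

    def test_baseline_hazard_breslow_identity(self):
        """With beta=0 the Breslow increments are d_k / n_at_risk."""
        from extcox.coxph import breslow_baseline

        t = np.array([1.0, 2.0, 2.0, 3.0, 4.0])
        e = np.array([1.0, 1, 1, 0, 1])
        x = np.zeros((5, 1))
        times, dh = breslow_baseline(None, t, e, x, np.zeros(1))
        assert np.allclose(times, [1.0, 2.0, 4.0])
        assert np.allclose(dh, [1 / 5, 2 / 4, 1 / 1])
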