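"""Core Cox proportional-hazards numerics.

Partial likelihood (Breslow or Efron tie handling) for right-censored and
counting-process ``(start, stop]`` data, a Newton-Raphson fitter with
step-halving, and the Breslow baseline cumulative-hazard estimator.  These
primitives back the penalized fitter, the change-point model and the
univariate cutoff screens; external survival packages are used only as
independent cross-checks in the test suite.

All routines accept plain numpy arrays.  Times may carry heavy ties (the
motivating data are follow-up weeks), which is why Breslow is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CoxFit",
    "NonIdentifiableError",
    "cox_loglik",
    "cox_loglik_grad_hess",
    "diag_working_quantities",
    "newton_cox",
]


class NonIdentifiableError(RuntimeError):
    """Raised when a Cox fit diverges or the information matrix is singular.

    ``column`` names the offending covariate when it can be identified.
    """

    def __init__(self, message: str, column: str | None = None):
        super().__init__(message)
        self.column = column


def _as_counting(start, stop, event):
    stop = np.asarray(stop, dtype=float)
    event = np.asarray(event, dtype=float)
    if start is None:
        start = np.zeros_like(stop)
    else:
        start = np.asarray(start, dtype=float)
    if event.sum() < 1:
        raise ValueError("at least one event is required")
    if np.any(stop <= start):
        raise ValueError("episodes must satisfy start < stop")
    return start, stop, event


def _suffix_sums(keys, values, query):
    """sum of values[i] over i with keys[i] >= q, for each q in query."""
    order = np.argsort(keys, kind="stable")
    vals = values[order]
    if vals.ndim == 1:
        suffix = np.concatenate([np.cumsum(vals[::-1])[::-1], [0.0]])
    else:
        rev = np.cumsum(vals[::-1], axis=0)[::-1]
        suffix = np.concatenate([rev, np.zeros((1,) + vals.shape[1:])], axis=0)
    idx = np.searchsorted(keys[order], query, side="left")
    return suffix[idx]


def _risk_sets(start, stop, event, eta, X=None, order=0, ties="breslow"):
    """Breslow/Efron risk-set aggregates at each distinct event time.

    Returns ``(times, d, S0, S1, S2, shift)`` where ``S0`` etc. are computed
    with ``exp(eta - shift)`` for numerical stability; for Efron ties the
    within-tie sums ``D0, D1, D2`` are folded into the log-likelihood and
    derivative formulas by the callers via the returned tie corrections.
    """
    shift = float(np.max(eta))
    w = np.exp(eta - shift)
    et, d = np.unique(stop[event > 0], return_counts=True)
    d = d.astype(float)

    def sums(vals):
        a = _suffix_sums(stop, vals, et)
        if np.any(start > 0):
            a = a - _suffix_sums(start, vals, et)
        return a

    S0 = sums(w)
    S1 = S2 = None
    if order >= 1:
        S1 = sums(w[:, None] * X)
    if order >= 2:
        S2 = sums(w[:, None, None] * (X[:, :, None] * X[:, None, :]))

    tie = None
    if ties == "efron":
        # sums of w (and wX, wXX) over the events *at* each event time
        ev = event > 0
        keys = stop[ev]
        srt = np.argsort(keys, kind="stable")
        keys_s = keys[srt]
        pos = np.searchsorted(keys_s, et, side="left")
        end = np.searchsorted(keys_s, et, side="right")
        tie = {}
        c = np.concatenate([[0.0], np.cumsum(w[ev][srt])])
        tie["D0"] = c[end] - c[pos]
        if order >= 1:
            v = (w[:, None] * X)[ev][srt]
            c = np.concatenate([np.zeros((1, X.shape[1])), np.cumsum(v, axis=0)])
            tie["D1"] = c[end] - c[pos]
        if order >= 2:
            v = (w[:, None, None] * (X[:, :, None] * X[:, None, :]))[ev][srt]
            c = np.concatenate([np.zeros((1,) + v.shape[1:]), np.cumsum(v, axis=0)])
            tie["D2"] = c[end] - c[pos]
    return et, d, S0, S1, S2, shift, tie


def cox_loglik(start, stop, event, X, beta, ties="breslow"):
    """Log partial likelihood at ``beta`` (Breslow or Efron ties)."""
    start, stop, event = _as_counting(start, stop, event)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    eta = X @ np.asarray(beta, dtype=float)
    et, d, S0, _, _, shift, tie = _risk_sets(start, stop, event, eta, ties=ties)
    ll = float(eta[event > 0].sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        if ties == "breslow":
            ll -= float(np.sum(d * (np.log(S0) + shift)))
        else:
            for k in range(len(et)):
                dk = int(d[k])
                l = np.arange(dk)
                ll -= float(np.sum(np.log(S0[k] - l / dk * tie["D0"][k]) + shift))
    return ll


def cox_loglik_grad_hess(start, stop, event, X, beta, ties="breslow"):
    """Log partial likelihood, score vector and observed information matrix."""
    start, stop, event = _as_counting(start, stop, event)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    beta = np.asarray(beta, dtype=float)
    eta = X @ beta
    et, d, S0, S1, S2, shift, tie = _risk_sets(
        start, stop, event, eta, X=X, order=2, ties=ties
    )
    ll = float(eta[event > 0].sum())
    grad = X[event > 0].sum(axis=0)
    info = np.zeros((p, p))
    if ties == "breslow":
        with np.errstate(divide="ignore", invalid="ignore"):
            ll -= float(np.sum(d * (np.log(S0) + shift)))
            r1 = S1 / S0[:, None]
            grad -= (d[:, None] * r1).sum(axis=0)
            info = np.einsum("k,kij->ij", d, S2 / S0[:, None, None]) - np.einsum(
                "k,ki,kj->ij", d, r1, r1
            )
    else:
        for k in range(len(et)):
            dk = int(d[k])
            for l in range(dk):
                f = l / dk
                s0 = S0[k] - f * tie["D0"][k]
                s1 = S1[k] - f * tie["D1"][k]
                s2 = S2[k] - f * tie["D2"][k]
                ll -= float(np.log(s0) + shift)
                r1 = s1 / s0
                grad -= r1
                info += s2 / s0 - np.outer(r1, r1)
    return ll, grad, info


def diag_working_quantities(time, event, eta):
    """Per-subject score ``g`` and diagonal Hessian weight ``w`` of the
    Breslow partial likelihood for right-censored data, used by the
    coordinate-descent penalized fitter.

    ``g_i = d_i - exp(eta_i) * r_i`` and ``w_i = exp(eta_i) r_i -
    exp(2 eta_i) q_i`` with ``r_i = sum_{t_k <= t_i} d_k / S0_k`` and ``q_i``
    the analogous sum with ``S0_k**2``.  Also returns the log partial
    likelihood at ``eta``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    shift = float(np.max(eta))
    w = np.exp(eta - shift)
    et, d = np.unique(time[event > 0], return_counts=True)
    d = d.astype(float)
    S0 = _suffix_sums(time, w, et)  # scaled by exp(-shift)
    ll = float(eta[event > 0].sum() - np.sum(d * (np.log(S0) + shift)))
    # cumulative d/S0 and d/S0^2 up to each subject's time (true scale)
    inc_r = d / S0 * np.exp(-shift)
    inc_q = d / S0**2 * np.exp(-2.0 * shift)
    pos = np.searchsorted(et, time, side="right")
    cr = np.concatenate([[0.0], np.cumsum(inc_r)])
    cq = np.concatenate([[0.0], np.cumsum(inc_q)])
    r = cr[pos]
    q = cq[pos]
    ew = np.exp(np.clip(eta, -250.0, 250.0))
    g = event - ew * r
    wdiag = ew * r - ew**2 * q
    return g, np.maximum(np.nan_to_num(wdiag), 1e-10), ll


def breslow_baseline(start, stop, event, X, beta):
    """Breslow increments of the baseline cumulative hazard at event times."""
    start, stop, event = _as_counting(start, stop, event)
    X = np.asarray(X, dtype=float)
    eta = X @ np.asarray(beta, dtype=float)
    et, d, S0, _, _, shift, _ = _risk_sets(start, stop, event, eta)
    dH = d / (S0 * np.exp(shift))
    return et, dH


@dataclass
class CoxFit:
    """An unpenalized Cox fit on (possibly counting-process) data."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    baseline_times: np.ndarray
    baseline_dhazard: np.ndarray
    ties: str = "breslow"
    iterations: int = 0

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci(self) -> np.ndarray:
        with np.errstate(over="ignore"):
            lo = np.exp(self.coef - 1.959963984540054 * self.se)
            hi = np.exp(self.coef + 1.959963984540054 * self.se)
        return np.column_stack([lo, hi])

    @property
    def z(self) -> np.ndarray:
        return self.coef / self.se

    @property
    def p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * len(self.coef)

    def summary(self):
        import pandas as pd

        ci = self.ci
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "hr": self.hr,
                "ci_lower": ci[:, 0],
                "ci_upper": ci[:, 1],
                "z": self.z,
                "p": self.p,
            },
            index=self.names,
        )


def newton_cox(
    X,
    time=None,
    event=None,
    *,
    start=None,
    stop=None,
    names=None,
    ties="breslow",
    max_iter=60,
    tol=1e-11,
    init=None,
):
    """Maximum partial-likelihood Cox fit by Newton-Raphson with step halving.

    Right-censored data may be passed as ``(X, time, event)``; counting-process
    data as ``(X, start=..., stop=..., event=...)``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if stop is None:
        stop = time
    start_, stop_, event_ = _as_counting(start, stop, event)
    if names is None:
        names = [f"x{j + 1}" for j in range(p)]

    beta = np.zeros(p) if init is None else np.asarray(init, dtype=float).copy()
    ll, grad, info = cox_loglik_grad_hess(start_, stop_, event_, X, beta, ties=ties)
    ll_null = ll if init is None else cox_loglik(start_, stop_, event_, X, np.zeros(p), ties=ties)
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            j = int(np.argmin(np.linalg.eigvalsh(info)))
            raise NonIdentifiableError(
                f"singular information matrix (column {names[j]!r} suspected)",
                column=names[j],
            ) from None
        # step-halving line search on the log partial likelihood
        scale = 1.0
        accepted = False
        for _ in range(40):
            cand = beta + scale * step
            ll_new = cox_loglik(start_, stop_, event_, X, cand, ties=ties)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                accepted = True
                break
            scale *= 0.5
        if not accepted:
            break  # no ascent direction within machine precision
        beta = cand
        if np.max(np.abs(beta)) > 25:
            j = int(np.argmax(np.abs(beta)))
            raise NonIdentifiableError(
                f"coefficient for column {names[j]!r} diverged (monotone "
                "likelihood / separation)",
                column=names[j],
            )
        improved = ll_new - ll
        ll, grad, info = cox_loglik_grad_hess(start_, stop_, event_, X, beta, ties=ties)
        if abs(improved) < tol * (abs(ll) + 1.0) and np.max(np.abs(grad)) < 1e-6:
            break
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        raise NonIdentifiableError("information matrix singular at optimum") from None
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    bt, bdh = breslow_baseline(start_, stop_, event_, X, beta)
    return CoxFit(
        names=list(names),
        coef=beta,
        se=se,
        cov=cov,
        loglik=ll,
        loglik_null=ll_null,
        n=n,
        n_events=int(event_.sum()),
        baseline_times=bt,
        baseline_dhazard=bdh,
        ties=ties,
        iterations=it,
    )
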