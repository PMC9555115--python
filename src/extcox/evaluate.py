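"""Discrimination and calibration of fitted survival models.

* :func:`kaplan_meier` -- product-limit survival estimate with Greenwood
  variance and log-scale 95% confidence bands.
* :func:`td_auc` -- time-dependent (cumulative-case / dynamic-control) ROC
  and AUC at a fixed horizon with inverse-probability-of-censoring (IPCW)
  Kaplan-Meier weights; reduces exactly to the usual concordance-pair AUC of
  the binary outcome "event by the horizon" when there is no censoring.
* :func:`gof_chi_square` -- risk-decile goodness-of-fit: observed versus
  model-expected deaths by a horizon across risk-score groups, compared to a
  chi-square with (groups - 1) degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationReport",
    "SurvivalCurve",
    "TdAucResult",
    "gof_chi_square",
    "kaplan_meier",
    "td_auc",
]


@dataclass
class SurvivalCurve:
    """Kaplan-Meier estimate with Greenwood standard errors."""

    times: np.ndarray
    survival: np.ndarray
    se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t):
        """Step-function lookup S(t); S = 1 before the first event time."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if len(self.times) == 0:
            out = np.ones_like(t)
        else:
            idx = np.searchsorted(self.times, t, side="right") - 1
            out = np.where(idx >= 0, self.survival[np.maximum(idx, 0)], 1.0)
        return float(out[0]) if len(out) == 1 else out


def kaplan_meier(time, event) -> SurvivalCurve:
    """Product-limit estimator.

    Confidence bands are computed on the log-survival scale,
    ``S * exp(+-1.96 * se(log S))`` with the Greenwood sum, and clipped to
    [0, 1].  With no events the curve is identically 1.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    et = np.unique(time[event > 0])
    if len(et) == 0:
        z = np.array([])
        return SurvivalCurve(z, z, z, z, z, z, z)
    n_at = np.array([(time >= t).sum() for t in et], dtype=float)
    d = np.array([((time == t) & (event > 0)).sum() for t in et], dtype=float)
    frac = 1.0 - d / n_at
    S = np.cumprod(frac)
    gw = np.cumsum(d / (n_at * (n_at - d).clip(min=0.5)))  # Greenwood sum
    se_logS = np.sqrt(gw)
    se = S * se_logS
    z = 1.959963984540054
    lo = np.clip(S * np.exp(-z * se_logS), 0.0, 1.0)
    hi = np.clip(S * np.exp(z * se_logS), 0.0, 1.0)
    return SurvivalCurve(
        times=et, survival=S, se=se, ci_lower=lo, ci_upper=hi,
        at_risk=n_at, n_events=d,
    )


def _censoring_survival(time, event):
    """KM of the censoring distribution G (events are censorings)."""
    return kaplan_meier(time, 1.0 - np.asarray(event, dtype=float))


def _ipcw_weights(time, event, horizon):
    """Case/control masks and IPCW weights at a fixed horizon.

    Cases: event by the horizon, weighted by 1/G(t-); controls: still at
    risk past the horizon, weighted by 1/G(horizon)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    G = _censoring_survival(time, event)

    def G_at(t):
        return np.atleast_1d(G.survival_at(t))

    def G_minus(t):
        return np.atleast_1d(G.survival_at(np.asarray(t) - 1e-9))

    cases = (event > 0) & (time <= horizon)
    controls = time > horizon
    w = np.zeros(len(time))
    gmin = np.clip(G_minus(time[cases]), 1e-10, None)
    w[cases] = 1.0 / gmin
    ghor = float(np.clip(G_at(horizon), 1e-10, None)[0])
    w[controls] = 1.0 / ghor
    return cases, controls, w


@dataclass
class TdAucResult:
    """Time-dependent ROC at one horizon."""

    horizon: float
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    ci_lower: float
    ci_upper: float
    n_cases: int
    n_controls: int


def _weighted_auc(marker, cases, controls, w):
    """Weighted probability that a case outranks a control (ties count 1/2),
    computed by sorting rather than pairwise enumeration."""
    m_case, w_case = marker[cases], w[cases]
    m_ctrl, w_ctrl = marker[controls], w[controls]
    order = np.argsort(m_ctrl, kind="stable")
    mc, wc = m_ctrl[order], w_ctrl[order]
    cum = np.concatenate([[0.0], np.cumsum(wc)])
    lo = np.searchsorted(mc, m_case, side="left")
    hi = np.searchsorted(mc, m_case, side="right")
    below = cum[lo]
    ties = cum[hi] - cum[lo]
    num = float(np.sum(w_case * (below + 0.5 * ties)))
    den = float(w_case.sum() * wc.sum())
    return num / den


def td_auc(marker, time, event, horizon, n_boot: int = 0, seed: int = 0) -> TdAucResult:
    """Cumulative-case / dynamic-control AUC at ``horizon`` with IPCW
    Kaplan-Meier censoring weights; higher marker = higher risk.

    The ROC staircase is swept over all marker thresholds; the AUC is the
    weighted concordance (equivalently the trapezoid area).  A seeded
    bootstrap over patients supplies the optional 95% CI (``n_boot`` > 0).
    """
    marker = np.asarray(marker, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    cases, controls, w = _ipcw_weights(time, event, horizon)
    if cases.sum() == 0 or controls.sum() == 0:
        raise ValueError("AUC undefined: need at least one case and one control by horizon")

    thresholds = np.unique(marker)[::-1]
    wc_tot = w[cases].sum()
    wn_tot = w[controls].sum()
    tpr = [0.0]
    fpr = [0.0]
    for c in thresholds:
        sel = marker >= c
        tpr.append(float(w[cases & sel].sum() / wc_tot))
        fpr.append(float(w[controls & sel].sum() / wn_tot))
    tpr, fpr = np.asarray(tpr), np.asarray(fpr)
    auc = _weighted_auc(marker, cases, controls, w)

    lo = hi = np.nan
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = len(time)
        vals = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            try:
                cs, ct, wb = _ipcw_weights(time[idx], event[idx], horizon)
                if cs.sum() and ct.sum():
                    vals.append(_weighted_auc(marker[idx], cs, ct, wb))
            except ValueError:
                continue
        if vals:
            lo, hi = np.percentile(vals, [2.5, 97.5])
    return TdAucResult(
        horizon=float(horizon), fpr=fpr, tpr=tpr, auc=float(auc),
        ci_lower=float(lo), ci_upper=float(hi),
        n_cases=int(cases.sum()), n_controls=int(controls.sum()),
    )


@dataclass
class CalibrationReport:
    """Observed vs expected deaths across risk-score groups."""

    table: pd.DataFrame  # per group: n, observed, expected
    statistic: float
    df: int
    p_value: float
    horizon: float
    n_groups: int


def gof_chi_square(
    event_prob,
    time,
    event,
    horizon,
    n_groups: int = 10,
    observed: str = "km",
    standardized: bool = False,
) -> CalibrationReport:
    """Risk-group goodness-of-fit chi-square at a fixed horizon.

    ``event_prob`` are model-predicted event probabilities by the horizon
    (the risk scores).  Patients are split into ``n_groups`` near-equal
    groups by score; expected deaths are the within-group sums of
    ``event_prob``; observed deaths are ``n_g * (1 - KM_g(horizon))``
    (``observed='km'``, robust to censoring) or the raw event count
    (``observed='count'``).  Statistic: sum of ``(O - E)^2 / E`` (or the
    variance-standardized ``(O - E)^2 / (E (1 - E / n_g))`` when
    ``standardized``), df = groups - 1 after merging zero-expectation
    groups.
    """
    p = np.asarray(event_prob, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if n_groups < 2:
        raise ValueError("need at least two risk groups")
    n = len(p)
    order = np.argsort(p, kind="stable")
    bounds = np.linspace(0, n, n_groups + 1).round().astype(int)
    rows = []
    for g in range(n_groups):
        idx = order[bounds[g]:bounds[g + 1]]
        if len(idx) == 0:
            continue
        E = float(p[idx].sum())
        if observed == "km":
            km = kaplan_meier(time[idx], event[idx])
            O = len(idx) * (1.0 - float(np.atleast_1d(km.survival_at(horizon))[0])) \
                if len(km.times) else 0.0
        elif observed == "count":
            O = float(((time[idx] <= horizon) & (event[idx] > 0)).sum())
        else:
            raise ValueError("observed must be 'km' or 'count'")
        rows.append({"group": g + 1, "n": len(idx), "observed": O, "expected": E,
                     "mean_score": float(p[idx].mean())})
    table = pd.DataFrame(rows)

    # merge groups with (near-)zero expectation into their neighbor
    merged = []
    carry = None
    for _, r in table.iterrows():
        r = r.copy()
        if carry is not None:
            r["n"] += carry["n"]
            r["observed"] += carry["observed"]
            r["expected"] += carry["expected"]
            carry = None
        if r["expected"] < 1e-8:
            carry = r
        else:
            merged.append(r)
    if carry is not None:
        if merged:
            merged[-1]["n"] += carry["n"]
            merged[-1]["observed"] += carry["observed"]
            merged[-1]["expected"] += carry["expected"]
        else:
            raise ValueError("all groups have zero expected deaths")
    mt = pd.DataFrame(merged)
    if len(mt) < len(table):
        warnings.warn(
            f"merged {len(table) - len(mt)} zero-expectation risk group(s)",
            stacklevel=2,
        )
    O = mt["observed"].to_numpy()
    E = mt["expected"].to_numpy()
    if standardized:
        denom = E * np.clip(1.0 - E / mt["n"].to_numpy(), 1e-10, None)
    else:
        denom = E
    statistic = float(np.sum((O - E) ** 2 / denom))
    df = max(len(mt) - 1, 1)
    return CalibrationReport(
        table=table,
        statistic=statistic,
        df=df,
        p_value=float(stats.chi2.sf(statistic, df)),
        horizon=float(horizon),
        n_groups=n_groups,
    )
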