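"""Change-point (extended) Cox model.

A proportional-hazards model in which the age-PR interaction coefficient is
zero up to a time threshold tau and constant afterwards:

    h(t | x) = h0(t) * exp(A),                 t <= tau
    h(t | x) = h0(t) * exp(A + beta8 * x8),    t >  tau

where ``A`` is the ordinary linear predictor and ``x8`` indicates patients
aged >= 41 with PR >= 20%.  Fitting uses the counting-process trick: each
patient's follow-up is split into ``(start, stop]`` episodes at tau, the
switchable column is zero in pre-threshold episodes, and a standard Cox fit
on the episode table maximizes the correct partial likelihood.  The
threshold itself is chosen by minimizing the AIC over a candidate grid of
observed times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coxph import CoxFit, newton_cox

__all__ = [
    "ChangePointModel",
    "EpisodeTable",
    "fit_extended",
    "group_hazard_ratios",
    "level_hazard_ratios",
    "predict_survival",
    "select_threshold",
    "split_at_threshold",
]

#: canonical covariate columns of the extended model, in report order
EXTENDED_COLUMNS = ["grade", "n_stage", "ki67_high", "pr_high", "age_ge55", "age_ge41"]
POST_COLUMN = "pr_age_post"


def extended_design(cohort: pd.DataFrame):
    """The six pre-threshold covariates of the extended model plus the
    age>=41 & PR>=20% interaction indicator, from a cohort table."""
    X = np.column_stack(
        [
            cohort["grade"].to_numpy(dtype=float) - 1.0,
            cohort["n_stage"].to_numpy(dtype=float),
            (cohort["ki67_pct"].to_numpy(dtype=float) >= 60).astype(float),
            (cohort["pr_pct"].to_numpy(dtype=float) >= 20).astype(float),
            (cohort["age"].to_numpy(dtype=float) >= 55).astype(float),
            (cohort["age"].to_numpy(dtype=float) >= 41).astype(float),
        ]
    )
    x8 = (
        (cohort["age"].to_numpy(dtype=float) >= 41)
        & (cohort["pr_pct"].to_numpy(dtype=float) >= 20)
    ).astype(float)
    return X, x8


@dataclass
class EpisodeTable:
    """Counting-process episodes ``(start, stop]`` with the switchable
    interaction column active only in post-threshold episodes."""

    patient_idx: np.ndarray
    start: np.ndarray
    stop: np.ndarray
    event: np.ndarray
    X: np.ndarray              # base covariates replicated per episode
    x8: np.ndarray             # switchable column (0 pre-threshold)
    tau: float
    names: list = field(default_factory=list)

    @property
    def exposure(self) -> float:
        return float(np.sum(self.stop - self.start))


def split_at_threshold(time, event, X, x8_indicator, tau: float,
                       names=None) -> EpisodeTable:
    """Split follow-up at ``tau``.

    Patients with ``time <= tau`` contribute a single episode (the
    interaction is inactive at exactly t = tau); longer follow-up is split
    into ``(0, tau]`` (event 0, x8 = 0) and ``(tau, time]`` with x8 equal to
    the patient's interaction indicator.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    X = np.asarray(X, dtype=float)
    x8_indicator = np.asarray(x8_indicator, dtype=float)
    n = len(time)
    pre = time <= tau
    idx_pre = np.flatnonzero(pre)
    idx_post = np.flatnonzero(~pre)

    patient_idx = np.concatenate([idx_pre, idx_post, idx_post])
    start = np.concatenate(
        [np.zeros(len(idx_pre)), np.zeros(len(idx_post)), np.full(len(idx_post), tau)]
    )
    stop = np.concatenate([time[idx_pre], np.full(len(idx_post), tau), time[idx_post]])
    ev = np.concatenate(
        [event[idx_pre], np.zeros(len(idx_post)), event[idx_post]]
    )
    x8 = np.concatenate(
        [np.zeros(len(idx_pre)), np.zeros(len(idx_post)), x8_indicator[idx_post]]
    )
    return EpisodeTable(
        patient_idx=patient_idx,
        start=start,
        stop=stop,
        event=ev,
        X=X[patient_idx],
        x8=x8,
        tau=float(tau),
        names=list(names) if names is not None else list(EXTENDED_COLUMNS),
    )


@dataclass
class ChangePointModel:
    """Fitted extended Cox model: coefficients, threshold and baseline."""

    tau: float
    names: list                      # base covariate names (A terms)
    coef: dict                       # name -> coefficient, incl. post column
    se: dict
    loglik: float
    aic: float
    n: int
    n_events: int
    baseline_times: np.ndarray | None = None
    baseline_cumhaz: np.ndarray | None = None
    max_time: float = np.inf
    has_post_term: bool = True
    fit: CoxFit | None = None

    @classmethod
    def from_coefficients(cls, coefficients: dict, tau: float = 164.0):
        """Build a model object from known coefficients (no data, no
        baseline); hazard-ratio arithmetic works, survival prediction does
        not."""
        names = [k for k in coefficients if k != POST_COLUMN]
        return cls(
            tau=float(tau),
            names=names,
            coef=dict(coefficients),
            se={k: np.nan for k in coefficients},
            loglik=np.nan,
            aic=np.nan,
            n=0,
            n_events=0,
            has_post_term=POST_COLUMN in coefficients,
        )

    @property
    def beta_post(self) -> float:
        return self.coef.get(POST_COLUMN, 0.0)

    def linear_predictor(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        b = np.array([self.coef[nm] for nm in self.names])
        return X @ b

    def summary(self) -> pd.DataFrame:
        rows = []
        for nm in list(self.names) + ([POST_COLUMN] if self.has_post_term else []):
            b, s = self.coef[nm], self.se[nm]
            from scipy import stats as _st

            rows.append(
                {
                    "variable": nm,
                    "coef": b,
                    "se": s,
                    "hr": np.exp(b),
                    "ci_lower": np.exp(b - 1.959963984540054 * s),
                    "ci_upper": np.exp(b + 1.959963984540054 * s),
                    "p": 2 * _st.norm.sf(abs(b / s)) if s > 0 else np.nan,
                }
            )
        return pd.DataFrame(rows).set_index("variable")


def fit_extended(episodes: EpisodeTable, ties: str = "breslow",
                 init=None) -> ChangePointModel:
    """Counting-process Cox fit of the extended model on an episode table.

    The switchable column is appended unless it is identically zero (then it
    is dropped with a warning and the fit is the ordinary no-interaction
    model)."""
    has_post = bool(np.any(episodes.x8 != 0))
    if not has_post:
        warnings.warn(
            "interaction column is all-zero after the split; fitting without it",
            stacklevel=2,
        )
        Xfit = episodes.X
        names = list(episodes.names)
    else:
        Xfit = np.column_stack([episodes.X, episodes.x8])
        names = list(episodes.names) + [POST_COLUMN]
    if init is not None and len(init) != Xfit.shape[1]:
        init = None
    fit = newton_cox(
        Xfit,
        start=episodes.start,
        stop=episodes.stop,
        event=episodes.event,
        names=names,
        ties=ties,
        init=init,
    )
    cumhaz = np.cumsum(fit.baseline_dhazard)
    return ChangePointModel(
        tau=episodes.tau,
        names=list(episodes.names),
        coef=dict(zip(names, fit.coef)),
        se=dict(zip(names, fit.se)),
        loglik=fit.loglik,
        aic=fit.aic,
        n=int(len(np.unique(episodes.patient_idx))),
        n_events=fit.n_events,
        baseline_times=fit.baseline_times,
        baseline_cumhaz=cumhaz,
        max_time=float(episodes.stop.max()),
        has_post_term=has_post,
        fit=fit,
    )


def candidate_thresholds(time, event, min_events_side: int = 1,
                         min_at_risk: int = 10, max_candidates: int | None = None):
    """Candidate thresholds: distinct observed times (deaths and censorings)
    leaving at least ``min_events_side`` events and ``min_at_risk`` subjects
    on each side; optionally thinned evenly to ``max_candidates``."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    out = []
    for c in np.unique(time):
        ev_le = event[time <= c].sum()
        ev_gt = event[time > c].sum()
        if (
            ev_le >= min_events_side
            and ev_gt >= min_events_side
            and (time <= c).sum() >= min_at_risk
            and (time > c).sum() >= min_at_risk
        ):
            out.append(c)
    out = np.asarray(out)
    if max_candidates is not None and len(out) > max_candidates:
        pick = np.unique(np.linspace(0, len(out) - 1, max_candidates).round().astype(int))
        out = out[pick]
    return out


def select_threshold(
    time,
    event,
    X,
    x8_indicator,
    candidates=None,
    names=None,
    ties: str = "breslow",
    max_candidates: int | None = None,
):
    """AIC-minimizing threshold search for the extended model.

    Fits the change-point model at every candidate tau and returns
    ``(best_model, profile)`` where ``profile`` is the (tau, AIC) table;
    ties break to the smallest tau.  The AIC counts the interaction
    coefficient as one parameter; tau itself is not counted (the comparison
    is between fixed-threshold fits, a deliberately anti-conservative
    convention).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if candidates is None:
        candidates = candidate_thresholds(time, event, max_candidates=max_candidates)
    candidates = np.asarray(candidates, dtype=float)
    if len(candidates) < 2:
        raise ValueError("need at least two admissible threshold candidates")

    rows = []
    fits = {}
    errors = {}
    warm = None
    for tau in candidates:
        try:
            ep = split_at_threshold(time, event, X, x8_indicator, tau, names=names)
            m = fit_extended(ep, ties=ties, init=warm)
            if m.fit is not None:
                warm = m.fit.coef  # nearby thresholds give nearby solutions
            rows.append({"tau": float(tau), "aic": m.aic, "loglik": m.loglik,
                         "k": len(m.coef)})
            fits[float(tau)] = m
        except Exception as exc:  # noqa: BLE001 - per-candidate diagnostics
            rows.append({"tau": float(tau), "aic": np.nan, "loglik": np.nan, "k": 0})
            errors[float(tau)] = repr(exc)
    profile = pd.DataFrame(rows).sort_values("tau").reset_index(drop=True)
    if profile["aic"].isna().all():
        raise RuntimeError(f"all threshold fits failed: {errors}")
    ok = profile.dropna(subset=["aic"])
    best_aic = ok["aic"].min()
    best_tau = float(ok.loc[ok["aic"] == best_aic, "tau"].min())
    return fits[best_tau], profile


def predict_survival(model: ChangePointModel, X, x8_indicator, horizons):
    """Survival probability S(t | x) under the two-regime model.

    The cumulative hazard integrates the baseline piecewise:
    ``H(t|x) = H0(min(t, tau)) e^A + (H0(t) - H0(tau))_+ e^(A + beta8 x8)``,
    which is continuous in t at the threshold.
    """
    if model.baseline_times is None:
        raise ValueError("model carries no baseline hazard (built from coefficients only)")
    horizons = np.atleast_1d(np.asarray(horizons, dtype=float))
    if np.any(horizons > model.max_time):
        raise ValueError(
            f"horizon beyond baseline support (max observed time {model.max_time})"
        )
    X = np.atleast_2d(np.asarray(X, dtype=float))
    x8 = np.atleast_1d(np.asarray(x8_indicator, dtype=float))
    A = model.linear_predictor(X)

    def H0(t):
        idx = np.searchsorted(model.baseline_times, t, side="right") - 1
        return np.where(idx >= 0, model.baseline_cumhaz[np.maximum(idx, 0)], 0.0)

    H0_tau = H0(np.array([model.tau]))[0]
    out = np.empty((X.shape[0], len(horizons)))
    for k, t in enumerate(horizons):
        h0t = H0(np.array([t]))[0]
        pre = min(h0t, H0_tau)
        post = max(h0t - H0_tau, 0.0)
        out[:, k] = np.exp(
            -(pre * np.exp(A) + post * np.exp(A + model.beta_post * x8))
        )
    return out


def level_hazard_ratios(model: ChangePointModel) -> pd.DataFrame:
    """Per-level hazard ratios implied by the fitted coefficients.

    Ordinal factors contribute linearly (grade III is exp(2 * beta_grade)),
    age enters through the two nested indicators (middle aged = age>=41,
    elderly = both), and the interaction row applies after the threshold.
    """
    c = model.coef
    rows = [
        ("grade", "I", 0.0),
        ("grade", "II", c.get("grade", 0.0)),
        ("grade", "III", 2.0 * c.get("grade", 0.0)),
        ("n_stage", "0", 0.0),
        ("n_stage", "1", c.get("n_stage", 0.0)),
        ("n_stage", "2", 2.0 * c.get("n_stage", 0.0)),
        ("n_stage", "3", 3.0 * c.get("n_stage", 0.0)),
        ("ki67", "low", 0.0),
        ("ki67", "high", c.get("ki67_high", 0.0)),
        ("pr", "low", 0.0),
        ("pr", "high", c.get("pr_high", 0.0)),
        ("age", "young", 0.0),
        ("age", "middle", c.get("age_ge41", 0.0)),
        ("age", "elderly", c.get("age_ge41", 0.0) + c.get("age_ge55", 0.0)),
        ("pr_age_post", "0", 0.0),
        ("pr_age_post", "1", c.get(POST_COLUMN, 0.0)),
    ]
    return pd.DataFrame(
        [
            {"factor": f, "level": lv, "coef": b, "hr": float(np.exp(b))}
            for f, lv, b in rows
        ]
    )


def group_hazard_ratios(model: ChangePointModel) -> pd.DataFrame:
    """Joint age x PR hazard ratios before and after the threshold.

    Within each period the reference is a young (< 41), PR-low patient;
    all other covariates are held fixed.  After the threshold the
    interaction term enters for PR-high patients aged >= 41.
    """
    c = model.coef
    b_pr = c.get("pr_high", 0.0)
    b55 = c.get("age_ge55", 0.0)
    b41 = c.get("age_ge41", 0.0)
    b8 = c.get(POST_COLUMN, 0.0)
    rows = []
    for period, post in [("pre", 0.0), ("post", 1.0)]:
        for pr_label, pr in [("low", 0.0), ("high", 1.0)]:
            for age_label, ge41, ge55 in [("young", 0.0, 0.0),
                                          ("middle", 1.0, 0.0),
                                          ("elderly", 1.0, 1.0)]:
                lp = b_pr * pr + b41 * ge41 + b55 * ge55 + b8 * post * pr * ge41
                rows.append(
                    {
                        "period": period,
                        "pr_status": pr_label,
                        "age_group": age_label,
                        "coef": lp,
                        "hr": float(np.exp(lp)),
                    }
                )
    return pd.DataFrame(rows)
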