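"""Synthetic cohorts for hormone-receptor-positive, HER2-negative breast cancer.

The analysis pipeline needs patient-level data: one row per patient with
clinicopathological covariates (histological grade, nodal stage, Ki67/ER/PR
percentages, age, ...), breast-cancer-specific-mortality follow-up in weeks
and an event flag.  Because the motivating cohort is not publicly deposited,
this module provides

* :func:`make_fixture` -- a deterministic 335-patient cohort whose univariate
  marginals (both overall and split by vital status) reproduce the published
  characteristics table exactly.  The joint distribution is an independent
  coupling: a documented convention, not a claim about the real data.
* :func:`generate_cohort` -- cohorts of arbitrary size drawn from a
  change-point proportional-hazards truth: covariates sampled from the
  fixture marginals, event times by inversion from a piecewise-constant
  baseline hazard whose linear predictor gains the age-PR interaction term
  after a time threshold (default 164 weeks), administrative plus
  loss-to-follow-up censoring.
* :func:`table_one` -- the frequency / mean (SD) summary keyed like a
  clinical characteristics table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "COHORT_COLUMNS",
    "HISTOTYPES",
    "TRUE_COEFFICIENTS",
    "CohortSchemaError",
    "SimulationConfig",
    "generate_cohort",
    "make_fixture",
    "read_cohort_csv",
    "table_one",
    "validate_cohort",
    "write_cohort_csv",
]

COHORT_COLUMNS = [
    "patient_id",
    "age",
    "grade",
    "histotype",
    "tnm_stage",
    "t_stage",
    "n_stage",
    "lvi",
    "p53",
    "ki67_pct",
    "er_pct",
    "pr_pct",
    "time_weeks",
    "event",
]

HISTOTYPES = [
    "invasive carcinoma of no special type",
    "invasive lobular carcinoma",
    "mixed carcinoma",
    "micropapillary carcinoma",
    "invasive papillary carcinoma",
    "neuroendocrine carcinoma",
    "metaplastic carcinoma",
    "microinvasive carcinoma",
]

#: Generating coefficients of the change-point truth (log hazard ratios).
#: grade and n_stage act linearly on their 0-based ordinal scores; the
#: remaining terms are indicators.  ``pr_age_post`` is the age>=41 & PR>=20%
#: interaction that switches on after the time threshold.
TRUE_COEFFICIENTS = {
    "grade": 1.329,
    "n_stage": 0.972,
    "ki67_high": 1.650,
    "pr_high": -1.802,
    "age_ge55": 1.378,
    "age_ge41": -1.563,
    "pr_age_post": 1.594,
}

# ---------------------------------------------------------------------------
# Fixture marginals: per category (full-cohort count, died count); censored
# counts follow by subtraction.  These are the published characteristics of
# the 335-patient cohort (307 censored / 28 breast-cancer deaths).
# ---------------------------------------------------------------------------

_GRADE = {1: (22, 0), 2: (267, 16), 3: (46, 12)}
_HISTO = {
    HISTOTYPES[0]: (270, 23),
    HISTOTYPES[1]: (15, 1),
    HISTOTYPES[2]: (14, 0),
    HISTOTYPES[3]: (15, 3),
    HISTOTYPES[4]: (5, 1),
    HISTOTYPES[5]: (5, 0),
    HISTOTYPES[6]: (1, 0),
    HISTOTYPES[7]: (10, 0),
}
_T = {1: (206, 15), 2: (126, 13), 3: (3, 0), 4: (0, 0)}
_N = {0: (180, 7), 1: (98, 8), 2: (41, 3), 3: (16, 10)}
_LVI = {0: (220, 15), 1: (115, 13)}
_TNM = {1: (133, 6), 2: (142, 9), 3: (60, 13)}
_P53 = {0: (176, 13), 1: (159, 15)}

# Continuous factors: full-cohort value counts (chosen on the observed
# support: integer ages, a coarse percentage grid for Ki67/ER/PR) plus an
# explicit died sub-multiset.  The age multiset is built so that data-driven
# partition enumeration with minimum group size 10 yields exactly the 40
# canonical age cutoffs {37..75, 77}.
_AGE_COUNTS = {
    26: 1, 28: 1, 30: 1, 31: 1, 32: 1, 33: 1, 34: 1, 35: 1, 36: 2,
    37: 3, 38: 4, 39: 5, 40: 5,
    41: 5, 42: 6, 43: 7, 44: 8, 45: 9, 46: 10, 47: 11, 48: 12, 49: 13,
    50: 14, 51: 15, 52: 16, 53: 17, 54: 16,
    55: 14, 56: 13, 57: 12, 58: 11, 59: 10, 60: 9, 61: 8, 62: 8, 63: 7,
    64: 7, 65: 6, 66: 6, 67: 5, 68: 5, 69: 4, 70: 4, 71: 3, 72: 3, 73: 2,
    74: 1, 75: 1,
    77: 2, 78: 2, 80: 2, 82: 1, 84: 1, 86: 1, 89: 1,
}
_AGE_DIED = [34, 36, 39, 40, 44, 47, 50, 52, 53, 54,
             55, 55, 56, 56, 57, 57, 58, 58, 59, 59,
             60, 60, 61, 62, 63, 65, 70, 80]

_KI67_COUNTS = {1: 10, 5: 30, 10: 50, 15: 45, 20: 40, 25: 30, 30: 25,
                35: 20, 40: 16, 45: 14, 50: 12, 60: 25, 70: 12, 80: 6}
_KI67_DIED = [1, 5, 10, 15, 20, 20, 25, 25, 30, 30, 35, 35, 40, 40,
              45, 45, 50, 50, 60, 60, 60, 60, 60, 70, 70, 70, 80, 80]

_PR_COUNTS = {1: 12, 5: 20, 10: 20, 15: 20, 20: 15, 25: 10, 30: 12, 40: 15,
              50: 20, 60: 25, 65: 10, 70: 20, 75: 10, 80: 30, 85: 15,
              90: 30, 95: 21, 100: 30}
_PR_DIED = [1, 1, 5, 5, 5, 10, 10, 10, 15, 15, 15, 15,
            20, 20, 25, 30, 40, 50, 50, 60, 70, 80, 80, 90, 90, 95, 100, 100]

_ER_COUNTS = {5: 3, 10: 4, 15: 4, 20: 5, 25: 5, 30: 6, 40: 8, 50: 12,
              60: 20, 65: 15, 70: 25, 75: 30, 80: 45, 85: 40, 90: 50,
              95: 40, 98: 23}
_ER_DIED = [5, 10, 15, 20, 25, 30, 30, 40, 40, 50, 50, 50, 60, 60,
            65, 70, 70, 75, 75, 80, 80, 85, 85, 90, 90, 95, 95, 98]

_DEATH_TIMES = [20.0, 35.0, 50.0, 62.0, 75.0, 88.0, 100.0, 112.0, 125.0,
                138.0, 150.0, 160.0, 170.0, 182.0, 195.0, 208.0, 220.0,
                232.0, 245.0, 258.0, 270.0, 282.0, 295.0, 305.0, 315.0,
                325.0, 333.0, 341.0]

_N_FULL, _N_DIED = 335, 28


class CohortSchemaError(ValueError):
    """A cohort table violates the input schema; ``column`` names the field."""

    def __init__(self, message: str, column: str | None = None):
        super().__init__(message)
        self.column = column


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort table against the input schema, returning it.

    Checks column presence, missingness and the domain invariants
    (positive follow-up, ER >= 1% by cohort definition, binary event flag).
    """
    for col in COHORT_COLUMNS:
        if col not in df.columns:
            raise CohortSchemaError(f"missing required column {col!r}", column=col)
    checks = {
        "age": lambda s: (s >= 18).all(),
        "grade": lambda s: s.isin([1, 2, 3]).all(),
        "tnm_stage": lambda s: s.isin([1, 2, 3]).all(),
        "t_stage": lambda s: s.isin([1, 2, 3, 4]).all(),
        "n_stage": lambda s: s.isin([0, 1, 2, 3]).all(),
        "lvi": lambda s: s.isin([0, 1]).all(),
        "p53": lambda s: s.isin([0, 1]).all(),
        "ki67_pct": lambda s: s.between(1, 100).all(),
        "er_pct": lambda s: s.between(1, 100).all(),
        "pr_pct": lambda s: s.between(1, 100).all(),
        "time_weeks": lambda s: (s > 0).all(),
        "event": lambda s: s.isin([0, 1]).all(),
    }
    for col in COHORT_COLUMNS:
        if df[col].isna().any():
            raise CohortSchemaError(f"column {col!r} contains missing values", column=col)
    for col, ok in checks.items():
        if not ok(df[col]):
            raise CohortSchemaError(f"column {col!r} violates its domain", column=col)
    return df


def _expand_counts(counts: dict) -> list:
    out = []
    for value, c in counts.items():
        out.extend([value] * int(c))
    return out


def _multiset_difference(full: list, sub: list) -> list:
    remaining = list(full)
    for v in sub:
        remaining.remove(v)
    return remaining


def _fill_groups(rng, died_values, censored_values, n_died=_N_DIED):
    died = np.asarray(died_values)
    cens = np.asarray(censored_values)
    return np.concatenate([rng.permutation(died), rng.permutation(cens)])


def make_fixture() -> pd.DataFrame:
    """Deterministic 335-row cohort matching the published marginal counts.

    Marginals hold exactly both overall and within the censored (n=307) and
    died (n=28) groups; covariates are coupled independently within each
    vital-status group via a fixed pseudo-random permutation (seeded), so the
    joint structure carries no information.  Deaths occur at fixed times up
    to 341 weeks; 24 censored patients are "lost to follow-up" before study
    end and the rest carry administrative censoring times of 352-402 weeks.
    """
    rng = np.random.default_rng(20090915)
    event = np.concatenate([np.ones(_N_DIED, int), np.zeros(_N_FULL - _N_DIED, int)])

    def categorical(table):
        died, cens = [], []
        for cat, (n_full, n_died) in table.items():
            died.extend([cat] * n_died)
            cens.extend([cat] * (n_full - n_died))
        return _fill_groups(rng, died, cens)

    def continuous(counts, died_values):
        cens = _multiset_difference(_expand_counts(counts), died_values)
        return _fill_groups(rng, died_values, cens)

    lost = np.round(np.linspace(30.0, 345.0, 24), 1)
    admin = np.round(np.linspace(352.0, 402.0, _N_FULL - _N_DIED - 24), 1)
    censored_times = rng.permutation(np.concatenate([lost, admin]))

    df = pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:04d}" for i in range(_N_FULL)],
            "age": continuous(_AGE_COUNTS, _AGE_DIED).astype(int),
            "grade": categorical(_GRADE).astype(int),
            "histotype": categorical(_HISTO),
            "tnm_stage": categorical(_TNM).astype(int),
            "t_stage": categorical(_T).astype(int),
            "n_stage": categorical(_N).astype(int),
            "lvi": categorical(_LVI).astype(int),
            "p53": categorical(_P53).astype(int),
            "ki67_pct": continuous(_KI67_COUNTS, _KI67_DIED).astype(int),
            "er_pct": continuous(_ER_COUNTS, _ER_DIED).astype(int),
            "pr_pct": continuous(_PR_COUNTS, _PR_DIED).astype(int),
            "time_weeks": np.concatenate([np.asarray(_DEATH_TIMES), censored_times]),
            "event": event,
        }
    )
    return validate_cohort(df)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _default_marginals() -> dict:
    def probs(counts):
        vals = np.array(list(counts))
        n = np.array([counts[v][0] if isinstance(counts[v], tuple) else counts[v]
                      for v in counts], dtype=float)
        return vals, n / n.sum()

    marg = {}
    for name, table in [
        ("grade", {k: v[0] for k, v in _GRADE.items()}),
        ("tnm_stage", {k: v[0] for k, v in _TNM.items()}),
        ("t_stage", {k: v[0] for k, v in _T.items()}),
        ("n_stage", {k: v[0] for k, v in _N.items()}),
        ("lvi", {k: v[0] for k, v in _LVI.items()}),
        ("p53", {k: v[0] for k, v in _P53.items()}),
        ("age", _AGE_COUNTS),
        ("ki67_pct", _KI67_COUNTS),
        ("er_pct", _ER_COUNTS),
        ("pr_pct", _PR_COUNTS),
    ]:
        vals, p = probs(table)
        marg[name] = (vals, p)
    hv = list(_HISTO)
    hp = np.array([_HISTO[h][0] for h in hv], dtype=float)
    marg["histotype"] = (np.array(hv, dtype=object), hp / hp.sum())
    return marg


@dataclass
class SimulationConfig:
    """Generative truth for synthetic cohorts.

    Parameters
    ----------
    n_patients, seed
        Cohort size and the seed that fully determines the output.
    coefficients
        Log hazard ratios of the change-point truth; keys as in
        :data:`TRUE_COEFFICIENTS`.
    threshold_weeks
        Time after which the age-PR interaction coefficient applies.
    baseline_breaks, baseline_rates
        Piecewise-constant baseline hazard: ``rates[k]`` (per week) applies on
        ``[breaks[k-1], breaks[k])`` with breaks[-1] extending to infinity.
        Defaults put one break at the interaction threshold and are calibrated
        so that, under the default coefficients and marginals, roughly 8% of
        patients die of breast cancer by study end (censoring near 91.6%).
    admin_window
        Administrative censoring horizon drawn uniformly over this interval
        (weeks), emulating a one-year accrual window with a fixed study end.
    loss_rate
        Exponential loss-to-follow-up hazard per week (about 7% lost by study
        end at the default).
    cutoffs
        True dichotomization points used in the linear predictor.
    correlation
        Optional exchangeable Gaussian-copula correlation across the four
        continuous factors, for stress tests (0 = independent sampling).
    marginals
        ``{factor: (values, probabilities)}``; defaults to the fixture
        marginals.
    """

    n_patients: int
    seed: int = 0
    coefficients: dict = field(default_factory=lambda: dict(TRUE_COEFFICIENTS))
    threshold_weeks: float = 164.0
    baseline_breaks: tuple = (164.0,)
    baseline_rates: tuple = (4.4e-05, 4.4e-05)
    admin_window: tuple = (350.0, 402.0)
    loss_rate: float = 2.0e-4
    cutoffs: dict = field(
        default_factory=lambda: {"ki67": 60.0, "pr": 20.0, "age_low": 41.0, "age_high": 55.0}
    )
    correlation: float = 0.0
    marginals: dict | None = None

    def validate(self) -> "SimulationConfig":
        if self.n_patients < 1:
            raise ValueError("configuration error: n_patients must be positive")
        if len(self.baseline_rates) != len(self.baseline_breaks) + 1:
            raise ValueError(
                "configuration error: need len(baseline_rates) == len(baseline_breaks) + 1"
            )
        if any(r <= 0 for r in self.baseline_rates):
            raise ValueError("configuration error: baseline rates must be positive")
        if list(self.baseline_breaks) != sorted(self.baseline_breaks):
            raise ValueError("configuration error: baseline breaks must be increasing")
        if self.loss_rate < 0 or self.threshold_weeks <= 0:
            raise ValueError("configuration error: rates/threshold must be nonnegative")
        if not (0 <= self.correlation < 1):
            raise ValueError("configuration error: correlation must be in [0, 1)")
        marg = self.marginals if self.marginals is not None else _default_marginals()
        for fac, (vals, p) in marg.items():
            p = np.asarray(p, dtype=float)
            if len(vals) == 0 or len(vals) != len(p):
                raise ValueError(f"configuration error: empty marginal for {fac!r}")
            if not np.isclose(p.sum(), 1.0):
                raise ValueError(
                    f"configuration error: marginal for {fac!r} does not sum to 1"
                )
        return self


def _sample_marginal(rng, vals, p, n):
    return rng.choice(vals, size=n, p=np.asarray(p, dtype=float))


def linear_predictor(df: pd.DataFrame, coefficients: dict, cutoffs: dict):
    """Pre-threshold linear predictor A and the interaction indicator.

    Returns ``(A, x8_indicator)`` where the post-threshold log hazard is
    ``A + coefficients['pr_age_post'] * x8_indicator``.
    """
    c = coefficients
    age = df["age"].to_numpy(dtype=float)
    pr = df["pr_pct"].to_numpy(dtype=float)
    ki = df["ki67_pct"].to_numpy(dtype=float)
    a_lo, a_hi = cutoffs["age_low"], cutoffs["age_high"]
    A = (
        c.get("grade", 0.0) * (df["grade"].to_numpy(dtype=float) - 1.0)
        + c.get("n_stage", 0.0) * df["n_stage"].to_numpy(dtype=float)
        + c.get("ki67_high", 0.0) * (ki >= cutoffs["ki67"])
        + c.get("pr_high", 0.0) * (pr >= cutoffs["pr"])
        + c.get("age_ge55", 0.0) * (age >= a_hi)
        + c.get("age_ge41", 0.0) * (age >= a_lo)
    )
    x8 = ((age >= a_lo) & (pr >= cutoffs["pr"])).astype(float)
    return A, x8


def _invert_piecewise(rng, bounds, rates):
    """Draw event times by inversion from per-subject piecewise-constant
    hazards.  ``bounds`` are the shared segment starts (first must be 0);
    ``rates`` is (n, k) with the last segment extending to infinity."""
    n, k = rates.shape
    widths = np.diff(np.append(bounds, np.inf))
    Hcum = np.concatenate(
        [np.zeros((n, 1)), np.cumsum(rates[:, :-1] * widths[:-1], axis=1)], axis=1
    )
    E = rng.exponential(size=n)
    seg = np.sum(E[:, None] >= Hcum, axis=1) - 1  # last segment with Hcum <= E
    seg = np.clip(seg, 0, k - 1)
    rows = np.arange(n)
    return bounds[seg] + (E - Hcum[rows, seg]) / rates[rows, seg]


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a cohort under the change-point proportional-hazards truth."""
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    marg = cfg.marginals if cfg.marginals is not None else _default_marginals()

    cols = {}
    continuous = ["age", "ki67_pct", "er_pct", "pr_pct"]
    if cfg.correlation > 0:
        # exchangeable Gaussian copula across the continuous factors
        from scipy import stats as _st

        rho = cfg.correlation
        cov = np.full((4, 4), rho)
        np.fill_diagonal(cov, 1.0)
        z = rng.multivariate_normal(np.zeros(4), cov, size=n)
        u = _st.norm.cdf(z)
        for j, fac in enumerate(continuous):
            vals, p = marg[fac]
            cdf = np.cumsum(np.asarray(p, dtype=float))
            idx = np.searchsorted(cdf, u[:, j], side="left")
            cols[fac] = np.asarray(vals)[np.clip(idx, 0, len(vals) - 1)]
    else:
        for fac in continuous:
            vals, p = marg[fac]
            cols[fac] = _sample_marginal(rng, vals, p, n)
    for fac in ["grade", "histotype", "tnm_stage", "t_stage", "n_stage", "lvi", "p53"]:
        vals, p = marg[fac]
        cols[fac] = _sample_marginal(rng, vals, p, n)

    df = pd.DataFrame(cols)
    df.insert(0, "patient_id", [f"S{i + 1:05d}" for i in range(n)])

    A, x8 = linear_predictor(df, cfg.coefficients, cfg.cutoffs)
    beta8 = cfg.coefficients.get("pr_age_post", 0.0)
    tau = cfg.threshold_weeks

    bounds = np.array(sorted(set([0.0] + list(cfg.baseline_breaks) + [tau])))
    base = np.zeros(len(bounds))
    for k, b in enumerate(bounds):
        seg = np.searchsorted(cfg.baseline_breaks, b, side="right")
        base[k] = cfg.baseline_rates[seg]
    post = bounds >= tau  # x8 active on segments starting at/after the threshold
    lp = A[:, None] + beta8 * np.outer(x8, post.astype(float))
    rates = base[None, :] * np.exp(lp)
    T = _invert_piecewise(rng, bounds, rates)

    C = rng.uniform(cfg.admin_window[0], cfg.admin_window[1], size=n)
    if cfg.loss_rate > 0:
        C = np.minimum(C, rng.exponential(1.0 / cfg.loss_rate, size=n))
    df["time_weeks"] = np.minimum(T, C)
    df["event"] = (T <= C).astype(int)
    for c in ["age", "grade", "tnm_stage", "t_stage", "n_stage", "lvi", "p53",
              "ki67_pct", "er_pct", "pr_pct"]:
        df[c] = df[c].astype(int)
    return validate_cohort(df[COHORT_COLUMNS])


# ---------------------------------------------------------------------------
# Summaries and I/O
# ---------------------------------------------------------------------------


def table_one(cohort: pd.DataFrame) -> pd.DataFrame:
    """Characteristics summary: counts per category and mean (SD) of the
    percentage markers, overall and split by vital status."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    df = cohort
    died = df[df["event"] == 1]
    cens = df[df["event"] == 0]
    rows = []

    def count_rows(char, series, categories, fmt=lambda c: str(c)):
        for cat in categories:
            rows.append(
                {
                    "characteristic": char,
                    "category": fmt(cat),
                    "full": int((series == cat).sum()),
                    "censored": int((series[df["event"] == 0] == cat).sum()),
                    "died": int((series[df["event"] == 1] == cat).sum()),
                }
            )

    age = df["age"]
    for label, mask in [
        ("<41", age < 41),
        ("41-54", (age >= 41) & (age < 55)),
        (">=55", age >= 55),
    ]:
        rows.append(
            {
                "characteristic": "age_group",
                "category": label,
                "full": int(mask.sum()),
                "censored": int((mask & (df["event"] == 0)).sum()),
                "died": int((mask & (df["event"] == 1)).sum()),
            }
        )
    count_rows("grade", df["grade"], [1, 2, 3])
    count_rows("histotype", df["histotype"], HISTOTYPES)
    count_rows("t_stage", df["t_stage"], [1, 2, 3, 4])
    count_rows("n_stage", df["n_stage"], [0, 1, 2, 3])
    count_rows("lvi", df["lvi"], [0, 1])
    count_rows("tnm_stage", df["tnm_stage"], [1, 2, 3])
    count_rows("p53", df["p53"], [0, 1])
    for label, mask in [("<20", df["pr_pct"] < 20), (">=20", df["pr_pct"] >= 20)]:
        rows.append(
            {
                "characteristic": "pr_group",
                "category": label,
                "full": int(mask.sum()),
                "censored": int((mask & (df["event"] == 0)).sum()),
                "died": int((mask & (df["event"] == 1)).sum()),
            }
        )
    for label, mask in [("<60", df["ki67_pct"] < 60), (">=60", df["ki67_pct"] >= 60)]:
        rows.append(
            {
                "characteristic": "ki67_group",
                "category": label,
                "full": int(mask.sum()),
                "censored": int((mask & (df["event"] == 0)).sum()),
                "died": int((mask & (df["event"] == 1)).sum()),
            }
        )
    out = pd.DataFrame(rows).set_index(["characteristic", "category"])

    stats_rows = {}
    for col in ["er_pct", "pr_pct", "ki67_pct"]:
        stats_rows[(col, "mean")] = [df[col].mean(), cens[col].mean(),
                                     died[col].mean() if len(died) else np.nan]
        stats_rows[(col, "sd")] = [df[col].std(ddof=1), cens[col].std(ddof=1),
                                   died[col].std(ddof=1) if len(died) > 1 else np.nan]
    stats_rows[("age", "median")] = [df["age"].median(), cens["age"].median(),
                                     died["age"].median() if len(died) else np.nan]
    stats_rows[("age", "min")] = [df["age"].min(), cens["age"].min(),
                                  died["age"].min() if len(died) else np.nan]
    stats_rows[("age", "max")] = [df["age"].max(), cens["age"].max(),
                                  died["age"].max() if len(died) else np.nan]
    cont = pd.DataFrame(stats_rows, index=["full", "censored", "died"]).T
    cont.index.names = ["characteristic", "category"]
    return pd.concat([out, cont])


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    validate_cohort(cohort)[COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_cohort(df)
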