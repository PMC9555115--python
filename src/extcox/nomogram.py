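"""Nomogram construction from a fitted change-point Cox model.

A nomogram converts a multivariable model into a printable scoring device: each
predictor row maps its levels onto a shared 0-100 point axis (the variable
with the largest coefficient-times-range spans the full axis), the summed
points map affinely back to the linear predictor, and probability rows read
off model survival at fixed horizons.  The default build has eleven rows:
the points axis, six predictor rows (grade, N stage, Ki67 status, PR status,
age group and the post-threshold age-PR interaction), the total-points axis
and three survival-probability rows.

Because the interaction coefficient acts only after the model threshold,
survival lookup tables at post-threshold horizons are tabulated per
interaction status; :func:`score_patient` resolves the branch from the
patient's covariates, keeping the round trip against direct model
prediction exact up to point rounding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .changepoint import ChangePointModel, POST_COLUMN, predict_survival

__all__ = ["NomogramSpec", "build_nomogram", "score_patient"]

#: nomogram predictor rows: (row label, model term(s), levels)
#: level entries are (level label, multiplier on each term)
_ROWS = [
    ("grade", ("grade",), [("I", (0.0,)), ("II", (1.0,)), ("III", (2.0,))]),
    ("n_stage", ("n_stage",), [("0", (0.0,)), ("1", (1.0,)), ("2", (2.0,)), ("3", (3.0,))]),
    ("ki67", ("ki67_high",), [("low", (0.0,)), ("high", (1.0,))]),
    ("pr", ("pr_high",), [("low", (0.0,)), ("high", (1.0,))]),
    ("age", ("age_ge41", "age_ge55"),
     [("young", (0.0, 0.0)), ("middle", (1.0, 0.0)), ("elderly", (1.0, 1.0))]),
    ("pr_age", (POST_COLUMN,), [("0", (0.0,)), ("1", (1.0,))]),
]


@dataclass
class NomogramSpec:
    """Point tables and survival lookup tables of a built nomogram."""

    points: dict                 # row -> {level label: points}
    ref_levels: dict             # row -> reference level label
    scale: float                 # points per unit log hazard
    offset: float                # lp = total/scale + offset (non-interaction rows)
    horizons: np.ndarray
    tau: float
    # horizon -> {x8 status: (total grid, survival grid)}
    survival_tables: dict
    max_points: float
    model: ChangePointModel
    row_order: list = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        """points row + predictor rows + total points + one row per horizon."""
        return 1 + len(self.points) + 1 + len(self.horizons)


def _row_contributions(model: ChangePointModel):
    """Per row: {level: lp contribution} from the fitted coefficients."""
    contribs = {}
    for row, terms, levels in _ROWS:
        if terms == (POST_COLUMN,) and not model.has_post_term:
            continue
        vals = {}
        for label, mult in levels:
            vals[label] = float(sum(m * model.coef.get(t, 0.0) for m, t in zip(mult, terms)))
        contribs[row] = vals
    return contribs


def build_nomogram(model: ChangePointModel, horizons=(52.0, 156.0, 260.0),
                   n_grid: int = 200, round_decimals: int = 1) -> NomogramSpec:
    """Build point tables and survival lookups from a fitted model.

    The reference level of each row is the level with the smallest linear-
    predictor contribution (so points are nonnegative); the row with the
    largest contribution range spans 0-100 points.  Survival rows tabulate
    model-predicted survival on an ``n_grid``-step total-points grid via the
    two-regime cumulative hazard; the interaction row contributes to the
    hazard only beyond the model threshold.
    """
    horizons = np.asarray(horizons, dtype=float)
    contribs = _row_contributions(model)
    ranges = {row: max(v.values()) - min(v.values()) for row, v in contribs.items()}
    dropped = [row for row, r in ranges.items() if r == 0.0]
    for row in dropped:
        warnings.warn(f"nomogram row {row!r} has zero coefficient range; dropped",
                      stacklevel=2)
        del contribs[row], ranges[row]
    if not contribs:
        raise ValueError("no nomogram rows with nonzero coefficient range")
    max_range = max(ranges.values())
    scale = 100.0 / max_range  # points per unit log hazard

    points = {}
    ref_levels = {}
    offset = 0.0
    for row, vals in contribs.items():
        ref = min(vals, key=vals.get)
        ref_levels[row] = ref
        points[row] = {
            label: round((v - vals[ref]) * scale, round_decimals)
            for label, v in vals.items()
        }
        if row != "pr_age":
            offset += vals[ref]

    inter_pts = points.get("pr_age", {}).get("1", 0.0)
    max_points = float(sum(max(v.values()) for v in points.values()))

    if model.baseline_times is None:
        raise ValueError("model carries no baseline hazard; cannot tabulate survival")

    survival_tables = {}
    base_max = float(sum(max(v.values()) for r, v in points.items() if r != "pr_age"))
    for h in horizons:
        tables = {}
        for x8 in (0.0, 1.0):
            grid = np.linspace(0.0, base_max, n_grid)
            lp = grid / scale + offset
            # survival under the two-regime hazard at linear predictor lp
            surv = _survival_from_lp(model, lp, x8, h)
            total_grid = grid + (inter_pts if x8 else 0.0)
            tables[x8] = (total_grid, surv)
        survival_tables[float(h)] = tables

    return NomogramSpec(
        points=points,
        ref_levels=ref_levels,
        scale=scale,
        offset=offset,
        horizons=horizons,
        tau=model.tau,
        survival_tables=survival_tables,
        max_points=max_points,
        model=model,
        row_order=["points", *points.keys(), "total_points",
                   *[f"survival_{int(h)}wk" for h in horizons]],
    )


def _survival_from_lp(model: ChangePointModel, lp, x8, horizon):
    """S(horizon) for given pre-threshold linear predictor(s) and
    interaction status, using the model baseline."""
    lp = np.atleast_1d(np.asarray(lp, dtype=float))

    def H0(t):
        idx = np.searchsorted(model.baseline_times, t, side="right") - 1
        if idx < 0:
            return 0.0
        return float(model.baseline_cumhaz[idx])

    H_tau = H0(model.tau)
    H_t = H0(horizon)
    pre = min(H_t, H_tau)
    post = max(H_t - H_tau, 0.0)
    return np.exp(-(pre * np.exp(lp) + post * np.exp(lp + model.beta_post * x8)))


def score_patient(spec: NomogramSpec, covariates: dict):
    """Total points and survival probabilities for one patient.

    ``covariates`` maps each predictor row to a level label, e.g.
    ``{"grade": "II", "n_stage": "1", "ki67": "low", "pr": "high",
    "age": "middle", "pr_age": "1"}``.  Probabilities are linear
    interpolations of the spec's survival tables on the appropriate
    interaction branch.
    """
    total = 0.0
    for row, table in spec.points.items():
        if row not in covariates:
            raise KeyError(f"missing covariate for nomogram row {row!r}")
        level = str(covariates[row])
        if level not in table:
            raise KeyError(f"level {level!r} outside table for row {row!r}")
        total += table[level]
    x8 = 1.0 if str(covariates.get("pr_age", "0")) == "1" else 0.0
    surv = {}
    for h in spec.horizons:
        grid, s = spec.survival_tables[float(h)][x8]
        surv[float(h)] = float(np.interp(total, grid, s))
    return total, surv
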