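"""Exhaustive dichotomization of continuous prognostic factors.

The modelling strategy converts each continuous factor (Ki67, ER, PR, age)
into a *series* of >=-cutoff indicator variables, one per admissible
partition point, and lets a sparse penalized Cox fit choose among them --
turning "where is the optimal cutoff?" into a variable-selection problem.
This module builds those candidate design matrices:

* without interactions: 7 single-column categorical factors + 4 raw
  continuous columns + every cutoff indicator (95 columns with the canonical
  reference partitions);
* with interactions: additionally T x N (product of the ordinal scores) and,
  for each of the families (ER, PR), (age, ER), (age, PR), every pairwise
  product of {raw column, its cutoff indicators} from both parents
  (1664 columns with the reference partitions).

Every column carries metadata sufficient to rebuild it from a cohort table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import HISTOTYPES
from .coxph import NonIdentifiableError, newton_cox

__all__ = [
    "ColumnMeta",
    "DesignMatrix",
    "PartitionSpec",
    "REFERENCE_PARTITIONS",
    "binarize",
    "build_design",
    "enumerate_partitions",
    "rebuild_column",
    "univariate_hr_series",
]

#: Canonical partition grids for replication mode.  These are fixed inputs
#: (they cannot be re-derived without the original raw data): 14 Ki67, 15 ER,
#: 15 PR and 40 age cutoffs.
REFERENCE_PARTITIONS = {
    "ki67_pct": [1, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50, 60, 70, 80],
    "er_pct": [10, 15, 20, 30, 40, 50, 60, 65, 70, 75, 80, 85, 90, 95, 98],
    "pr_pct": [5, 10, 15, 20, 25, 30, 40, 50, 60, 65, 70, 80, 85, 90, 95],
    "age": list(range(37, 76)) + [77],
}

_CONTINUOUS = ["ki67_pct", "er_pct", "pr_pct", "age"]
_CATEGORICAL = ["grade", "histotype", "tnm_stage", "t_stage", "n_stage", "lvi", "p53"]
#: interaction families: (parent factor, parent factor); T x N is the single
#: product of the two ordinal scores and is handled separately.
_INTERACTION_FAMILIES = [("er_pct", "pr_pct"), ("age", "er_pct"), ("age", "pr_pct")]


@dataclass
class PartitionSpec:
    """Admissible cutoffs for one continuous factor."""

    factor: str
    cutoffs: np.ndarray
    min_group_size: int = 10

    def __post_init__(self):
        self.cutoffs = np.asarray(self.cutoffs, dtype=float)
        if np.any(np.diff(self.cutoffs) <= 0):
            raise ValueError(f"cutoffs for {self.factor!r} must be strictly increasing")


def enumerate_partitions(values, min_group_size: int = 10, factor: str = "") -> PartitionSpec:
    """Admissible partition points of ``values``: every distinct observed
    value ``c`` with at least ``min_group_size`` observations on each side of
    the ``>= c`` split, sorted ascending."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2 * min_group_size:
        warnings.warn(
            f"too few observations ({len(v)}) for factor {factor!r}; empty partition",
            stacklevel=2,
        )
        return PartitionSpec(factor, np.array([]), min_group_size)
    distinct = np.unique(v)
    keep = [
        c
        for c in distinct
        if (v >= c).sum() >= min_group_size and (v < c).sum() >= min_group_size
    ]
    return PartitionSpec(factor, np.asarray(keep), min_group_size)


def binarize(values, cutoff) -> np.ndarray:
    """Indicator of ``value >= cutoff`` as a float 0/1 column."""
    return (np.asarray(values, dtype=float) >= float(cutoff)).astype(float)


@dataclass(frozen=True)
class ColumnMeta:
    """Reconstruction rule for one design column.

    ``kind`` is one of ``categorical-ordinal``, ``continuous``,
    ``binary-cutoff`` or ``interaction``.  ``factors`` holds the source
    factor(s) and ``cutoffs`` the matching cutoff(s), with ``None`` marking a
    raw (non-dichotomized) parent.
    """

    name: str
    kind: str
    factors: tuple
    cutoffs: tuple = (None,)


def _base_column(cohort: pd.DataFrame, factor: str, cutoff):
    if factor == "grade":
        return cohort["grade"].to_numpy(dtype=float) - 1.0
    if factor == "tnm_stage":
        return cohort["tnm_stage"].to_numpy(dtype=float) - 1.0
    if factor == "t_stage":
        return cohort["t_stage"].to_numpy(dtype=float) - 1.0
    if factor == "histotype":
        codes = {h: i for i, h in enumerate(HISTOTYPES)}
        return cohort["histotype"].map(codes).to_numpy(dtype=float)
    if factor in ("n_stage", "lvi", "p53"):
        return cohort[factor].to_numpy(dtype=float)
    if factor in _CONTINUOUS:
        raw = cohort[factor].to_numpy(dtype=float)
        return raw if cutoff is None else binarize(raw, cutoff)
    raise KeyError(f"unknown factor {factor!r}")


def rebuild_column(cohort: pd.DataFrame, meta: ColumnMeta) -> np.ndarray:
    """Recompute a design column from a cohort table and its metadata."""
    cols = [
        _base_column(cohort, f, c) for f, c in zip(meta.factors, meta.cutoffs)
    ]
    out = cols[0]
    for c in cols[1:]:
        out = out * c
    return out


@dataclass
class DesignMatrix:
    """Candidate design: an (n, p) value matrix plus per-column metadata."""

    X: np.ndarray
    columns: list

    @property
    def names(self) -> list:
        return [m.name for m in self.columns]

    @property
    def shape(self):
        return self.X.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.names)

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [m.name for m in self.columns],
                "kind": [m.kind for m in self.columns],
                "factors": ["*".join(m.factors) for m in self.columns],
                "cutoffs": [
                    "*".join("raw" if c is None else repr(float(c)) for c in m.cutoffs)
                    for m in self.columns
                ],
            }
        )


def _short(factor: str) -> str:
    return {"ki67_pct": "ki67", "er_pct": "er", "pr_pct": "pr", "age": "age"}[factor]


def _fmt_cut(c) -> str:
    c = float(c)
    return str(int(c)) if c == int(c) else str(c).replace(".", "p")


def resolve_partitions(cohort: pd.DataFrame, partitions="reference",
                       min_group_size: int = 10) -> dict:
    """Resolve a partition request into ``{factor: PartitionSpec}``.

    ``partitions`` may be ``"reference"`` (the canonical printed grids),
    ``"auto"`` (data-driven enumeration with the minimum-group-size rule) or
    an explicit mapping of factor name to cutoff list / PartitionSpec.
    """
    if partitions == "reference":
        return {
            f: PartitionSpec(f, np.asarray(c, dtype=float), min_group_size)
            for f, c in REFERENCE_PARTITIONS.items()
        }
    if partitions == "auto":
        return {
            f: enumerate_partitions(cohort[f].to_numpy(), min_group_size, factor=f)
            for f in _CONTINUOUS
        }
    out = {}
    for f, spec in partitions.items():
        if f not in _CONTINUOUS:
            raise KeyError(f"unknown factor {f!r} in partitions")
        out[f] = (
            spec
            if isinstance(spec, PartitionSpec)
            else PartitionSpec(f, np.asarray(spec, dtype=float), min_group_size)
        )
    missing = [f for f in _CONTINUOUS if f not in out]
    if missing:
        raise KeyError(f"partitions missing for factors {missing}")
    return out


def build_design(
    cohort: pd.DataFrame,
    partitions="reference",
    with_interactions: bool = False,
    min_group_size: int = 10,
) -> DesignMatrix:
    """Expand a cohort into the candidate design matrix.

    Column order: the 7 single-column categorical factors (ordinal scores;
    histotype as an integer category code), the 4 raw continuous factors,
    all ``>=``-cutoff indicators, then (optionally) the interaction columns.
    """
    for col in _CATEGORICAL + _CONTINUOUS:
        if col not in cohort.columns:
            raise KeyError(f"cohort is missing column {col!r}")
    specs = resolve_partitions(cohort, partitions, min_group_size)

    metas: list[ColumnMeta] = []
    cols: list[np.ndarray] = []

    for f in _CATEGORICAL:
        metas.append(ColumnMeta(f, "categorical-ordinal", (f,)))
        cols.append(_base_column(cohort, f, None))
    for f in _CONTINUOUS:
        metas.append(ColumnMeta(f, "continuous", (f,)))
        cols.append(_base_column(cohort, f, None))
    for f in _CONTINUOUS:
        for c in specs[f].cutoffs:
            metas.append(
                ColumnMeta(f"{_short(f)}_ge{_fmt_cut(c)}", "binary-cutoff", (f,), (float(c),))
            )
            cols.append(binarize(cohort[f].to_numpy(), c))

    if with_interactions:
        metas.append(
            ColumnMeta("t_stage*n_stage", "interaction", ("t_stage", "n_stage"), (None, None))
        )
        cols.append(_base_column(cohort, "t_stage", None) * _base_column(cohort, "n_stage", None))
        for fa, fb in _INTERACTION_FAMILIES:
            parents_a = [(None, _base_column(cohort, fa, None))] + [
                (float(c), binarize(cohort[fa].to_numpy(), c)) for c in specs[fa].cutoffs
            ]
            parents_b = [(None, _base_column(cohort, fb, None))] + [
                (float(c), binarize(cohort[fb].to_numpy(), c)) for c in specs[fb].cutoffs
            ]
            for ca, va in parents_a:
                na = _short(fa) if ca is None else f"{_short(fa)}_ge{_fmt_cut(ca)}"
                for cb, vb in parents_b:
                    nb = _short(fb) if cb is None else f"{_short(fb)}_ge{_fmt_cut(cb)}"
                    metas.append(
                        ColumnMeta(f"{na}*{nb}", "interaction", (fa, fb), (ca, cb))
                    )
                    cols.append(va * vb)

    return DesignMatrix(X=np.column_stack(cols), columns=metas)


def univariate_hr_series(
    cohort: pd.DataFrame,
    factor: str,
    partitions=None,
    min_group_size: int = 10,
) -> pd.DataFrame:
    """Univariate Cox hazard ratio (with 95% confidence limits and Wald p)
    for every ``>=``-cutoff indicator of one continuous factor.

    Cutoffs whose fit is degenerate (no events in a stratum, separation) are
    flagged ``estimable = False`` rather than dropped.
    """
    if factor not in _CONTINUOUS:
        raise KeyError(f"{factor!r} is not a continuous factor")
    if partitions is None:
        spec = enumerate_partitions(cohort[factor].to_numpy(), min_group_size, factor=factor)
    elif isinstance(partitions, PartitionSpec):
        spec = partitions
    else:
        spec = PartitionSpec(factor, np.asarray(partitions, dtype=float), min_group_size)

    time = cohort["time_weeks"].to_numpy(dtype=float)
    event = cohort["event"].to_numpy(dtype=float)
    rows = []
    for c in spec.cutoffs:
        x = binarize(cohort[factor].to_numpy(), c)
        events_hi = event[x == 1].sum()
        events_lo = event[x == 0].sum()
        rec = {"cutoff": float(c), "events_above": int(events_hi),
               "events_below": int(events_lo)}
        if event.sum() < 1 or events_hi == 0 or events_lo == 0 or x.std() == 0:
            rec.update(coef=np.nan, hr=np.nan, ci_lower=np.nan, ci_upper=np.nan,
                       p=np.nan, estimable=False)
        else:
            try:
                fit = newton_cox(x[:, None], time, event, names=[f"{factor}>={c}"])
                ci = fit.ci[0]
                rec.update(
                    coef=fit.coef[0], hr=fit.hr[0], ci_lower=ci[0], ci_upper=ci[1],
                    p=fit.p[0], estimable=True,
                )
            except NonIdentifiableError:
                rec.update(coef=np.nan, hr=np.nan, ci_lower=np.nan,
                           ci_upper=np.nan, p=np.nan, estimable=False)
        rows.append(rec)
    return pd.DataFrame(rows)
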