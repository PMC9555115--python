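"""SCAD-penalized Cox proportional-hazards fitting.

The smoothly clipped absolute deviation (SCAD) penalty is folded-concave:
it behaves like the lasso near zero (producing exact zeros) but levels off,
so large coefficients are nearly unbiased -- which is what lets a single
penalized fit pick one cutoff indicator out of a correlated series without
over-shrinking it.

The optimizer follows the standard local linear approximation (LLA)
scheme: at each outer step the SCAD penalty is majorized by a weighted L1
penalty with weights ``p'_lambda(|beta_j|)``, and the weighted-lasso Cox
subproblem is solved by iteratively reweighted least squares with
coordinate descent (glmnet-style, using the diagonal Hessian of the Breslow
partial likelihood).  Columns are standardized internally; coefficients are
reported on the original scale.  The penalty level is chosen by BIC
(``-2 logPL + k log(#events)``) over a log-spaced grid descending from the
smallest lambda that zeroes every coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coxph import NonIdentifiableError, diag_working_quantities, newton_cox

__all__ = [
    "PenalizedCoxFit",
    "fit_scad_cox",
    "refit_selected",
    "scad_penalty",
    "scad_penalty_deriv",
]


def scad_penalty(theta, lam, a: float = 3.7):
    """SCAD penalty value at ``theta >= 0``.

    Linear (``lam * theta``) up to ``lam``, quadratically clipped on
    ``(lam, a*lam]`` and constant at ``lam**2 * (a + 1) / 2`` beyond
    ``a * lam``.
    """
    if a <= 2:
        raise ValueError("SCAD shape parameter a must exceed 2")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    th = np.abs(np.asarray(theta, dtype=float))
    out = np.where(
        th <= lam,
        lam * th,
        np.where(
            th <= a * lam,
            -(th**2 - 2.0 * a * lam * th + lam**2) / (2.0 * (a - 1.0)),
            lam**2 * (a + 1.0) / 2.0,
        ),
    )
    return out if out.ndim else float(out)


def scad_penalty_deriv(theta, lam, a: float = 3.7):
    """Derivative ``p'_lambda(theta)`` for ``theta >= 0``:
    ``lam`` on [0, lam], ``(a*lam - theta)_+ / (a - 1)`` beyond."""
    if a <= 2:
        raise ValueError("SCAD shape parameter a must exceed 2")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    th = np.abs(np.asarray(theta, dtype=float))
    out = np.where(th <= lam, lam, np.maximum(a * lam - th, 0.0) / (a - 1.0))
    return out if out.ndim else float(out)


@dataclass
class PenalizedCoxFit:
    """Solution of the SCAD-penalized Cox fit at the criterion-optimal lambda."""

    names: list
    coef: np.ndarray            # original scale; exact zeros off-support
    selected: np.ndarray        # indices of nonzero coefficients
    lam: float
    a: float
    loglik: float               # unpenalized log partial likelihood at solution
    criterion: str
    path: pd.DataFrame          # per-lambda: n_selected, loglik, bic, converged
    screened_out: np.ndarray    # columns excluded by the group-size guard
    n: int
    n_events: int
    convergence: dict = field(default_factory=dict)

    @property
    def selected_names(self) -> list:
        return [self.names[j] for j in self.selected]


def _admissible_mask(X: np.ndarray, min_group_size: int) -> np.ndarray:
    """Group-size guard: exclude constant columns and 0/1 columns with fewer
    than ``min_group_size`` ones or zeros."""
    n, p = X.shape
    mask = np.ones(p, dtype=bool)
    for j in range(p):
        col = X[:, j]
        if np.ptp(col) == 0:
            mask[j] = False
            continue
        vals = np.unique(col)
        if len(vals) == 2 and set(vals) <= {0.0, 1.0}:
            ones = int(col.sum())
            if min(ones, n - ones) < min_group_size:
                mask[j] = False
    return mask


def _weighted_lasso_cox(
    Xs, time, event, beta, penalty_weights, *, max_irls, max_sweeps, tol, cd_tol
):
    """Solve the weighted-L1 Cox subproblem by IRLS + coordinate descent.

    ``Xs`` is standardized; ``penalty_weights`` are per-coordinate L1 levels
    on the standardized scale.  Objective: ``-logPL/n + sum w_j |beta_j|``.
    Returns ``(beta, loglik, converged)``.
    """
    n, p = Xs.shape
    beta = beta.copy()
    eta = Xs @ beta
    g, w, ll = diag_working_quantities(time, event, eta)
    obj_prev = -ll / n + float(penalty_weights @ np.abs(beta))
    converged = False
    for _ in range(max_irls):
        # working response z = eta + g/w; CD operates on wres = w*(z - Xs beta)
        wres = g.copy()  # w * (z - eta) = g at the current beta
        Wx = w[:, None] * Xs
        wx2 = (Wx * Xs).sum(axis=0) / n
        active = np.ones(p, dtype=bool)
        need_full = True
        for sweep in range(max_sweeps):
            max_delta = 0.0
            full = need_full
            idx = np.arange(p) if full else np.flatnonzero(active)
            for j in idx:
                bj = beta[j]
                rho = float(Xs[:, j] @ wres) / n + wx2[j] * bj
                pen = penalty_weights[j]
                if abs(rho) <= pen:
                    bnew = 0.0
                else:
                    bnew = (rho - np.sign(rho) * pen) / wx2[j]
                if bnew != bj:
                    wres -= Wx[:, j] * (bnew - bj)
                    beta[j] = bnew
                    max_delta = max(max_delta, abs(bnew - bj))
                active[j] = beta[j] != 0.0
            if max_delta < cd_tol:
                if full:
                    break
                need_full = True  # active set stable; verify with a full sweep
            else:
                need_full = False
        eta = Xs @ beta
        g, w, ll = diag_working_quantities(time, event, eta)
        obj = -ll / n + float(penalty_weights @ np.abs(beta))
        if abs(obj_prev - obj) < tol * (abs(obj_prev) + 1e-3):
            converged = True
            obj_prev = obj
            break
        obj_prev = obj
    return beta, ll, converged


def fit_scad_cox(
    X,
    time,
    event,
    *,
    lam_grid=None,
    n_lambda: int = 50,
    lam_min_ratio: float = 1e-3,
    a: float = 3.7,
    min_group_size: int = 10,
    criterion: str = "bic",
    names=None,
    max_lla: int = 5,
    max_irls: int = 40,
    max_sweeps: int = 500,
    tol: float = 1e-8,
    cd_tol: float = 1e-6,
    max_selected: int | None = None,
) -> PenalizedCoxFit:
    """Fit the SCAD-penalized Cox model over a lambda path and return the
    BIC-optimal solution.

    Lambdas at which the LLA iterations fail to decrease the penalized
    objective are flagged and excluded from model selection; the path
    continues.  ``lam_grid`` overrides the automatic grid (useful for
    ``lam_grid=[0.0]``, which reduces to the unpenalized fit).  The path
    stops early once the active set exceeds ``max_selected`` (default: the
    number of events) -- denser fits are unidentifiable and cannot win the
    BIC comparison.
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    n, p = X.shape
    if names is None:
        names = [f"x{j + 1}" for j in range(p)]
    n_events = int(event.sum())
    if n_events < 1:
        raise ValueError("at least one event is required")

    mask = _admissible_mask(X, min_group_size)
    screened_out = np.flatnonzero(~mask)
    Xa = X[:, mask]
    mu = Xa.mean(axis=0)
    sd = Xa.std(axis=0)
    Xs = (Xa - mu) / sd
    pa = Xs.shape[1]

    if lam_grid is None:
        g0, _, _ = diag_working_quantities(time, event, np.zeros(n))
        score = np.abs(Xs.T @ g0) / n
        lam_max = float(score.max()) * 1.001
        lam_grid = np.geomspace(lam_max, lam_max * lam_min_ratio, n_lambda)
    lam_grid = np.asarray(lam_grid, dtype=float)

    beta = np.zeros(pa)
    records = []
    solutions = {}
    for li, lam in enumerate(lam_grid):
        pen_obj_trace = []
        beta_l = beta.copy()
        ll = None
        ok = True
        if lam == 0.0:
            # no penalty: the LLA subproblem is the plain partial-likelihood
            # maximization, solved exactly by Newton-Raphson
            nf = newton_cox(Xs, time, event, init=beta_l)
            beta_l, ll = nf.coef, nf.loglik
            pen_obj_trace.append(-ll / n)
        else:
            for it in range(max_lla):
                pw = scad_penalty_deriv(np.abs(beta_l), lam, a)
                beta_l, ll, inner_ok = _weighted_lasso_cox(
                    Xs, time, event, beta_l, pw,
                    max_irls=max_irls, max_sweeps=max_sweeps, tol=tol, cd_tol=cd_tol,
                )
                pen_obj = -ll / n + float(np.sum(scad_penalty(np.abs(beta_l), lam, a)))
                pen_obj_trace.append(pen_obj)
                if it > 0 and pen_obj > pen_obj_trace[-2] + 1e-6 * (abs(pen_obj_trace[-2]) + 1.0):
                    ok = False
                    break
                if it > 0 and abs(pen_obj_trace[-2] - pen_obj) < tol * (abs(pen_obj) + 1e-3):
                    break
        k = int(np.count_nonzero(beta_l))
        bic = -2.0 * ll + k * np.log(max(n_events, 2))
        records.append(
            {"lam": float(lam), "n_selected": k, "loglik": float(ll),
             "bic": float(bic), "converged": bool(ok),
             "penalized_objective": pen_obj_trace}
        )
        solutions[li] = beta_l.copy()
        beta = beta_l  # warm start for the next (smaller) lambda
        if not ok:
            warnings.warn(
                f"LLA did not converge at lambda={lam:.4g}; excluded from selection",
                stacklevel=2,
            )
        cap = max_selected if max_selected is not None else n_events
        if lam > 0 and k >= min(cap, pa):
            break

    path = pd.DataFrame(records)
    usable = path[path["converged"]]
    if usable.empty:
        raise RuntimeError("no lambda converged; cannot select a model")
    best = int(usable["bic"].idxmin())
    beta_std = solutions[best]
    coef = np.zeros(p)
    coef[mask] = beta_std / sd
    selected = np.flatnonzero(coef != 0.0)
    return PenalizedCoxFit(
        names=list(names),
        coef=coef,
        selected=selected,
        lam=float(path.loc[best, "lam"]),
        a=a,
        loglik=float(path.loc[best, "loglik"]),
        criterion=criterion,
        path=path,
        screened_out=screened_out,
        n=n,
        n_events=n_events,
        convergence={"lambda_index": best, "n_lambda": len(lam_grid)},
    )


def refit_selected(X, time, event, selected, names=None, ties: str = "breslow"):
    """Unpenalized Cox refit on the selected columns.

    Returns a :class:`extcox.coxph.CoxFit`; its ``summary()`` carries the
    coefficient, hazard ratio ``exp(coef)``, Wald 95% CI and p-value per
    variable, and ``aic = -2 logPL + 2k``.
    """
    selected = np.asarray(selected, dtype=int)
    if selected.size == 0:
        raise ValueError("selected set is empty")
    X = np.asarray(X, dtype=float)
    if names is None:
        names = [f"x{j + 1}" for j in range(X.shape[1])]
    sub_names = [names[j] for j in selected]
    return newton_cox(X[:, selected], time, event, names=sub_names, ties=ties)
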