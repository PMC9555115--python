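"""End-to-end orchestration of the extended Cox modelling workflow.

``run_pipeline`` executes the full three-stage strategy on a cohort (loaded,
simulated, or the built-in fixture): candidate-design expansion, SCAD-
penalized selection without and with interaction terms (models 1 and 2),
the change-point extended model with AIC threshold search, evaluation
(Kaplan-Meier, time-dependent AUC, risk-decile goodness of fit) and the
nomogram.  Every run writes deterministic JSON/CSV artifacts plus a manifest
with SHA-256 checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .changepoint import (
    extended_design,
    group_hazard_ratios,
    level_hazard_ratios,
    predict_survival,
    select_threshold,
)
from .cohort import (
    SimulationConfig,
    generate_cohort,
    make_fixture,
    read_cohort_csv,
    table_one,
    write_cohort_csv,
)
from .design import build_design, univariate_hr_series
from .evaluate import gof_chi_square, kaplan_meier, td_auc
from .nomogram import build_nomogram
from .scad import fit_scad_cox, refit_selected

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (YAML-serializable)."""

    outdir: str = "extcox_run"
    cohort: str = "simulate"          # "simulate", "fixture", or a CSV path
    n_patients: int = 1000
    seed: int = 0
    partition_mode: str = "reference"  # "reference" or "auto"
    min_group_size: int = 10
    scad_a: float = 3.7
    n_lambda: int = 50
    ties: str = "breslow"
    threshold_grid: str = "auto"
    max_threshold_candidates: int | None = 40
    horizons: tuple = (52.0, 156.0, 260.0)
    gof_horizon: float = 260.0
    n_boot: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "horizons" in raw:
            raw["horizons"] = tuple(float(h) for h in raw["horizons"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["horizons"] = list(self.horizons)
        d.pop("outdir", None)  # environment detail; keeps artifacts reproducible
        return d


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(_jsonify(payload), indent=1, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_cohort(cfg: PipelineConfig) -> pd.DataFrame:
    if cfg.cohort == "simulate":
        return generate_cohort(SimulationConfig(n_patients=cfg.n_patients, seed=cfg.seed))
    if cfg.cohort == "fixture":
        return make_fixture()
    return read_cohort_csv(cfg.cohort)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages; returns the output directory.

    Stage failures propagate as ``RuntimeError`` naming the stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return deco

    @stage("cohort")
    def cohort():
        df = _load_cohort(config)
        write_cohort_csv(df, out / "cohort.csv")
        table_one(df).to_csv(out / "table_one.csv")
        artifacts["cohort"] = out / "cohort.csv"
        artifacts["table_one"] = out / "table_one.csv"
        return df

    time = cohort["time_weeks"].to_numpy(dtype=float)
    event = cohort["event"].to_numpy(dtype=float)

    @stage("design")
    def designs():
        d_plain = build_design(cohort, config.partition_mode,
                               with_interactions=False,
                               min_group_size=config.min_group_size)
        d_inter = build_design(cohort, config.partition_mode,
                               with_interactions=True,
                               min_group_size=config.min_group_size)
        d_inter.metadata_frame().to_csv(out / "design_metadata.csv", index=False)
        artifacts["design_metadata"] = out / "design_metadata.csv"
        return d_plain, d_inter

    d_plain, d_inter = designs

    @stage("univariate_screen")
    def screen():
        frames = []
        for factor in ["ki67_pct", "er_pct", "pr_pct", "age"]:
            s = univariate_hr_series(cohort, factor,
                                     min_group_size=config.min_group_size)
            s.insert(0, "factor", factor)
            frames.append(s)
        tbl = pd.concat(frames, ignore_index=True)
        tbl.to_csv(out / "univariate_hr.csv", index=False)
        artifacts["univariate_hr"] = out / "univariate_hr.csv"
        return tbl

    def scad_stage(design, label):
        fit = fit_scad_cox(design.X, time, event, names=design.names,
                           a=config.scad_a, n_lambda=config.n_lambda,
                           min_group_size=config.min_group_size)
        payload = {
            "lambda": fit.lam, "a": fit.a, "criterion": fit.criterion,
            "loglik": fit.loglik, "n": fit.n, "n_events": fit.n_events,
            "selected": fit.selected_names,
            "coefficients": {nm: c for nm, c in zip(fit.names, fit.coef) if c != 0.0},
            "path": fit.path.drop(columns=["penalized_objective"]).to_dict("records"),
            "seed": config.seed,
        }
        if len(fit.selected):
            from .coxph import NonIdentifiableError

            try:
                refit = refit_selected(design.X, time, event, fit.selected,
                                       names=design.names, ties=config.ties)
                payload["refit"] = refit.summary().reset_index(names="variable").to_dict("records")
                payload["refit_aic"] = refit.aic
            except NonIdentifiableError as exc:
                payload["refit_error"] = str(exc)
        _write_json(out / f"{label}.json", payload)
        artifacts[label] = out / f"{label}.json"
        return fit

    model1 = stage("model1_scad")(lambda: scad_stage(d_plain, "model1"))
    model2 = stage("model2_scad")(lambda: scad_stage(d_inter, "model2"))

    @stage("extended_model")
    def extended():
        X, x8 = extended_design(cohort)
        from .changepoint import EXTENDED_COLUMNS

        best, profile = select_threshold(
            time, event, X, x8, names=EXTENDED_COLUMNS,
            ties=config.ties,
            max_candidates=config.max_threshold_candidates,
        )
        payload = {
            "tau": best.tau,
            "aic": best.aic,
            "loglik": best.loglik,
            "coefficients": best.coef,
            "se": best.se,
            "summary": best.summary().reset_index().to_dict("records"),
            "profile": profile.to_dict("records"),
            "level_hazard_ratios": level_hazard_ratios(best).to_dict("records"),
            "group_hazard_ratios": group_hazard_ratios(best).to_dict("records"),
            "baseline": {
                "times": best.baseline_times,
                "cumhaz": best.baseline_cumhaz,
            },
        }
        _write_json(out / "extended_model.json", payload)
        artifacts["extended_model"] = out / "extended_model.json"
        return best, X, x8

    best, X, x8 = extended

    @stage("evaluation")
    def evaluation():
        km = kaplan_meier(time, event)
        horizons = [h for h in config.horizons if h <= best.max_time]
        risk = {
            h: 1.0 - predict_survival(best, X, x8, [h])[:, 0] for h in horizons
        }
        aucs = {}
        for h in horizons:
            try:
                r = td_auc(risk[h], time, event, h, n_boot=config.n_boot,
                           seed=config.seed)
                aucs[h] = {"auc": r.auc, "ci": [r.ci_lower, r.ci_upper],
                           "n_cases": r.n_cases, "n_controls": r.n_controls}
            except ValueError as exc:
                aucs[h] = {"auc": None, "error": str(exc)}
        gof_h = min(config.gof_horizon, best.max_time)
        gof = gof_chi_square(risk.get(gof_h, 1.0 - predict_survival(best, X, x8, [gof_h])[:, 0]),
                             time, event, gof_h)
        payload = {
            "km": {
                "times": km.times, "survival": km.survival,
                "ci_lower": km.ci_lower, "ci_upper": km.ci_upper,
            },
            "td_auc": aucs,
            "gof": {
                "statistic": gof.statistic, "df": gof.df, "p_value": gof.p_value,
                "horizon": gof.horizon,
                "table": gof.table.to_dict("records"),
            },
        }
        _write_json(out / "evaluation.json", payload)
        artifacts["evaluation"] = out / "evaluation.json"
        return payload

    @stage("nomogram")
    def nomogram():
        horizons = [h for h in config.horizons if h <= best.max_time]
        spec = build_nomogram(best, horizons=horizons)
        payload = {
            "row_order": spec.row_order,
            "points": spec.points,
            "ref_levels": spec.ref_levels,
            "scale": spec.scale,
            "offset": spec.offset,
            "tau": spec.tau,
            "max_points": spec.max_points,
            "survival_tables": {
                str(int(h)): {
                    str(int(x8v)): {"total": grid, "survival": surv}
                    for x8v, (grid, surv) in tables.items()
                }
                for h, tables in spec.survival_tables.items()
            },
        }
        _write_json(out / "nomogram.json", payload)
        artifacts["nomogram"] = out / "nomogram.json"
        return spec

    config_path = out / "config.yaml"
    config_path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    artifacts["config"] = config_path

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": _sha256(config_path),
        "files": {
            name: {"path": p.name, "sha256": _sha256(p)}
            for name, p in sorted(artifacts.items())
        },
    }
    _write_json(out / "manifest.json", manifest)
    return out
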