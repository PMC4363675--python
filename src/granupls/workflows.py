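"""Calibration workflows: local per-granularity models and the pooled
granularity-hybrid (GH) model.

Both experiments share the same per-class preparation: replicate
averaging, an outlier screen on the reference concentrations, and a
deterministic Kennard-Stone calibration/validation split. Local models
are then fitted per sieve-mesh class and evaluated on their own
validation set (and, for robustness analysis, on every other class's
validation set); the GH model pools all classes' calibration subsets into
one training set and is evaluated against each class's validation set
separately. Preprocessing pipelines are ranked by minimum PRESS under
cross-validation — never by test-set error — and the latent-variable
count follows the PRESS minimum with an optional RMSECV-close-to-RMSEP
overfit guard.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .pls import (MetricsReport, PressCurve, evaluate, fit_pls, predict,
                  predict_per_lv, press_curve, rmse, select_lv)
from .preprocess import (TABLE_PIPELINES, PipelineParams, PreprocessPipeline,
                         apply_pipeline)
from .sampling import average_replicates, dixon_outlier_screen, kennard_stone_split
from .spectra import SpectraSet

__all__ = [
    "ExperimentConfig",
    "EvaluationReport",
    "run_local_models",
    "run_gh_model",
    "grid_search_preprocessing",
    "gh_vs_local_mean_rmsep",
    "render_report",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExperimentConfig:
    """Settings shared by the calibration experiments.

    ``n_cal`` is the per-class calibration size (the pooled GH training
    set has ``n_cal`` x number of classes rows). ``split_on`` selects the
    features used for Kennard-Stone distances: ``"raw"`` (default, one
    split reused across the whole pipeline grid) or a pipeline label.
    """

    pipelines: tuple[str, ...] = TABLE_PIPELINES
    n_cal: int = 60
    split_on: str = "raw"
    max_lv: int = 10
    cv: object = "loo"
    lv_tolerance: float = 0.10
    use_overfit_guard: bool = True
    outlier_alpha: float = 0.05
    outlier_max_removals: int = 1
    outlier_variant: str = "dixon"
    params: PipelineParams = field(default_factory=PipelineParams)
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.pipelines) < 1:
            raise ValueError("need at least one pipeline label")
        if self.max_lv < 1:
            raise ValueError("max_lv must be >= 1")


@dataclass
class EvaluationReport:
    """Tabular results of one experiment plus the data behind them."""

    kind: str                      # "local" | "gh" | "grid"
    table: pd.DataFrame
    predictions: dict[str, pd.DataFrame] = field(default_factory=dict)
    best_pipeline: str | None = None
    extras: dict = field(default_factory=dict)


def _dedup_pipelines(labels) -> list[str]:
    seen, out = set(), []
    for lab in labels:
        canon = PreprocessPipeline.parse(lab).label
        if canon in seen:
            log.warning("duplicate pipeline label %r ignored", lab)
            continue
        seen.add(canon)
        out.append(canon)
    return out


def _prepare_class(data: SpectraSet, mesh: int, cfg: ExperimentConfig):
    """Screen outliers and KS-split one granularity class.

    Returns ``(subset, cal_idx, val_idx)`` or ``None`` when the class is
    too small for the requested split.
    """
    sub = data.select_mesh(mesh)
    screen = dixon_outlier_screen(
        sub.concentrations, alpha=cfg.outlier_alpha,
        max_removals=cfg.outlier_max_removals, variant=cfg.outlier_variant,
    )
    if screen.outliers:
        log.info("mesh %d: removed outliers %s", mesh, screen.outliers)
    sub = sub.subset(screen.retained)
    if not (2 <= cfg.n_cal < len(sub)):
        log.warning("mesh %d: %d samples cannot support n_cal=%d; skipped",
                    mesh, len(sub), cfg.n_cal)
        return None
    if cfg.split_on == "raw":
        feats = sub.intensities
    else:
        feats, _, _ = apply_pipeline(cfg.split_on, sub.intensities, None,
                                     sub.grid, cfg.params)
    split = kennard_stone_split(feats, cfg.n_cal)
    return sub, split.calibration, split.validation


def _fit_one(label: str, X_cal, y_cal, X_val, y_val, grid, cfg: ExperimentConfig):
    """Fit one pipeline + PLS model; returns a result dict or raises."""
    cal_t, val_t, fitted = apply_pipeline(label, X_cal, X_val, grid, cfg.params)
    max_lv = min(cfg.max_lv, cal_t.shape[0] - 2, cal_t.shape[1])
    curve = press_curve(cal_t, y_cal, max_lv, cv=cfg.cv, seed=cfg.seed)

    rmsep_per_lv = None
    if cfg.use_overfit_guard and X_val is not None and len(y_val) >= 2:
        probe = fit_pls(cal_t, y_cal, curve.max_lv)
        per_lv = predict_per_lv(probe, val_t)
        if probe.n_lv < curve.max_lv:
            per_lv = np.hstack([per_lv,
                                np.repeat(per_lv[:, -1:],
                                          curve.max_lv - probe.n_lv, axis=1)])
        rmsep_per_lv = np.array([rmse(y_val, per_lv[:, k])
                                 for k in range(curve.max_lv)])
    n_lv = select_lv(curve, rmsep_per_lv, tolerance=cfg.lv_tolerance)
    model = fit_pls(cal_t, y_cal, n_lv)
    rep = MetricsReport(n_lv=model.n_lv)
    rep.rmsec = rmse(y_cal, predict(model, cal_t))
    rep.rmsecv = float(curve.rmsecv[n_lv - 1])
    rep.r_cv = curve.r_cv(y_cal, n_lv)
    rep.press = curve.press
    if X_val is not None:
        val_rep = evaluate(model, val_t, y_val)
        rep.rmsep, rep.r_p, rep.rpd = val_rep.rmsep, val_rep.r_p, val_rep.rpd
        rep.flags = val_rep.flags
    return dict(label=label, fitted=fitted, model=model, curve=curve,
                metrics=rep, min_press=float(curve.press.min()))


def grid_search_preprocessing(X_cal, y_cal, grid, cfg: ExperimentConfig,
                              X_val=None, y_val=None) -> EvaluationReport:
    """Rank preprocessing pipelines by minimum PRESS on the calibration set.

    Failing pipelines (e.g. SNV on a constant spectrum) are recorded as
    failed rows rather than aborting the grid. The full table is retained.
    """
    rows, fits = [], {}
    for label in _dedup_pipelines(cfg.pipelines):
        try:
            res = _fit_one(label, X_cal, y_cal, X_val, y_val, grid, cfg)
        except (ValueError, RuntimeError) as exc:
            log.warning("pipeline %r failed: %s", label, exc)
            rows.append(dict(pipeline=label, status=f"failed: {exc}",
                             min_press=np.nan, LVs=np.nan, RMSECV=np.nan))
            continue
        m = res["metrics"]
        rows.append(dict(pipeline=label, status="ok",
                         min_press=res["min_press"], LVs=m.n_lv,
                         RMSECV=m.rmsecv, R_CV=m.r_cv,
                         RMSEP=m.rmsep, R_P=m.r_p, RPD=m.rpd))
        fits[label] = res
    table = pd.DataFrame(rows).sort_values(
        "min_press", na_position="last").reset_index(drop=True)
    ok = table[table["status"] == "ok"]
    best = None if ok.empty else str(ok.iloc[0]["pipeline"])
    return EvaluationReport(kind="grid", table=table, best_pipeline=best,
                            extras={"fits": fits})


_METRIC_COLS = ["LVs", "RMSECV", "R_CV", "RMSEP", "R_P", "RPD"]


def run_local_models(data: SpectraSet, cfg: ExperimentConfig) -> EvaluationReport:
    """Per-granularity local PLS models.

    For each mesh class: outlier screen, KS split, preprocessing grid
    (best pipeline by minimum PRESS), LV selection, test-set validation.
    The report table mirrors the local-model layout (one row per class,
    columns LVs / RMSECV / R_CV / RMSEP / R_P / RPD); the cross-class
    RMSEP matrix of every local model applied to every class's validation
    set is stored in ``extras["cross_rmsep"]``.
    """
    data = average_replicates(data)
    prep = {}
    for mesh in data.mesh_classes:
        out = _prepare_class(data, int(mesh), cfg)
        if out is not None:
            prep[int(mesh)] = out

    rows, predictions, chosen = [], {}, {}
    for mesh, (sub, cal, val) in prep.items():
        grid_rep = grid_search_preprocessing(
            sub.intensities[cal], sub.concentrations[cal], sub.grid, cfg,
            sub.intensities[val], sub.concentrations[val])
        if grid_rep.best_pipeline is None:
            log.warning("mesh %d: every pipeline failed; skipped", mesh)
            continue
        res = grid_rep.extras["fits"][grid_rep.best_pipeline]
        m = res["metrics"]
        rows.append(dict(mesh=mesh, pipeline=res["label"], LVs=m.n_lv,
                         RMSECV=m.rmsecv, R_CV=m.r_cv, RMSEP=m.rmsep,
                         R_P=m.r_p, RPD=m.rpd))
        y_val = sub.concentrations[val]
        yhat = predict(res["model"], res["fitted"].transform(sub.intensities[val]))
        predictions[f"mesh{mesh}"] = pd.DataFrame(
            dict(reference=y_val, predicted=yhat))
        chosen[mesh] = res

    cross = pd.DataFrame(index=sorted(chosen), columns=sorted(prep), dtype=float)
    for m_mesh, res in chosen.items():
        for v_mesh, (vsub, _, vval) in prep.items():
            Xv = res["fitted"].transform(vsub.intensities[vval])
            cross.loc[m_mesh, v_mesh] = rmse(vsub.concentrations[vval],
                                             predict(res["model"], Xv))
    table = pd.DataFrame(rows)
    return EvaluationReport(kind="local", table=table, predictions=predictions,
                            extras={"cross_rmsep": cross,
                                    "models": {m: r["model"] for m, r in chosen.items()},
                                    "splits": {m: (p[1], p[2]) for m, p in prep.items()}})


def run_gh_model(data: SpectraSet, cfg: ExperimentConfig) -> EvaluationReport:
    """Granularity-hybrid calibration: pool every class's calibration set.

    One model per pipeline is trained on the pooled calibration rows
    (per-class screening and KS splitting happen before pooling) and
    evaluated against each class's validation set separately, giving one
    row per pipeline with per-class RMSEP / R_P / RPD columns. The best
    pipeline is the one with the lowest minimum PRESS (equivalently the
    lowest RMSECV at its optimum).
    """
    data = average_replicates(data)
    prep = {}
    for mesh in data.mesh_classes:
        out = _prepare_class(data, int(mesh), cfg)
        if out is not None:
            prep[int(mesh)] = out
    if not prep:
        return EvaluationReport(kind="gh", table=pd.DataFrame())

    X_cal = np.vstack([sub.intensities[cal] for sub, cal, _ in prep.values()])
    y_cal = np.concatenate([sub.concentrations[cal] for sub, cal, _ in prep.values()])
    X_val = np.vstack([sub.intensities[val] for sub, _, val in prep.values()])
    y_val = np.concatenate([sub.concentrations[val] for sub, _, val in prep.values()])
    grid = next(iter(prep.values()))[0].grid

    rows, predictions, fits = [], {}, {}
    for label in _dedup_pipelines(cfg.pipelines):
        try:
            res = _fit_one(label, X_cal, y_cal, X_val, y_val, grid, cfg)
        except (ValueError, RuntimeError) as exc:
            log.warning("GH pipeline %r failed: %s", label, exc)
            rows.append(dict(pipeline=label, status=f"failed: {exc}"))
            continue
        m = res["metrics"]
        row = dict(pipeline=label, status="ok", LVs=m.n_lv,
                   RMSECV=m.rmsecv, R_CV=m.r_cv, min_press=res["min_press"])
        for mesh, (sub, _, val) in prep.items():
            Xv = res["fitted"].transform(sub.intensities[val])
            rep = evaluate(res["model"], Xv, sub.concentrations[val])
            row[f"RMSEP_{mesh}"] = rep.rmsep
            row[f"R_P_{mesh}"] = rep.r_p
            row[f"RPD_{mesh}"] = rep.rpd
            predictions[f"{label}|mesh{mesh}"] = pd.DataFrame(dict(
                reference=sub.concentrations[val],
                predicted=predict(res["model"], Xv)))
        rows.append(row)
        fits[label] = res

    table = pd.DataFrame(rows)
    best = None
    ok = table[table.get("status", pd.Series(dtype=str)) == "ok"]
    if not ok.empty:
        best = str(ok.loc[ok["min_press"].idxmin(), "pipeline"])
        table = table.assign(best=table["pipeline"] == best)
    return EvaluationReport(kind="gh", table=table, predictions=predictions,
                            best_pipeline=best,
                            extras={"fits": fits,
                                    "splits": {m: (p[1], p[2]) for m, p in prep.items()},
                                    "n_cal_pooled": len(y_cal)})


def gh_vs_local_mean_rmsep(data: SpectraSet, cfg: ExperimentConfig,
                           pipeline: str = "RAW") -> dict:
    """Head-to-head robustness comparison on one fixed pipeline.

    Returns the GH model's mean RMSEP across the per-class validation
    sets and, for each local model, its mean RMSEP across *all* classes'
    validation sets (matched and mismatched granularity alike).
    """
    one = replace(cfg, pipelines=(pipeline,))
    local = run_local_models(data, one)
    gh = run_gh_model(data, one)
    cross = local.extras["cross_rmsep"]
    row = gh.table[gh.table["pipeline"] == PreprocessPipeline.parse(pipeline).label]
    gh_mean = float(np.mean([row.iloc[0][f"RMSEP_{m}"] for m in cross.columns]))
    local_means = {int(m): float(cross.loc[m].mean()) for m in cross.index}
    return dict(gh_mean_rmsep=gh_mean, local_mean_rmsep=local_means,
                cross_rmsep=cross, gh_report=gh, local_report=local)


def _rounded(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    for col in out.columns:
        name = str(col)
        if name.startswith("RMSE") or name == "rmsec":
            out[col] = out[col].round(3)
        elif name.startswith("R_"):
            out[col] = out[col].round(4)
        elif name.startswith("RPD"):
            out[col] = out[col].round(2)
    return out


def render_report(report: EvaluationReport, outdir, prefix: str | None = None,
                  rounded: bool = False) -> list[Path]:
    """Write CSV and JSON mirrors of a report plus prediction pairs.

    Full precision by default so a CSV round-trip reproduces every cell;
    ``rounded=True`` applies the conventional display rounding (RMSE to 3
    decimals, correlations to 4, RPD to 2). Empty reports yield valid
    files with headers only.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prefix = prefix or report.kind
    table = _rounded(report.table) if rounded else report.table
    written = []

    csv_path = outdir / f"{prefix}_table.csv"
    table.to_csv(csv_path, index=False, float_format="%.12g")
    written.append(csv_path)

    json_path = outdir / f"{prefix}_table.json"
    doc = {"kind": report.kind, "best_pipeline": report.best_pipeline,
           "rows": json.loads(table.to_json(orient="records"))}
    json_path.write_text(json.dumps(doc, indent=1))
    written.append(json_path)

    for key, pairs in report.predictions.items():
        safe = key.replace(" ", "").replace("|", "_").replace("+", "")
        p = outdir / f"{prefix}_predictions_{safe}.csv"
        pairs.to_csv(p, index=False, float_format="%.12g")
        written.append(p)
    return written
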