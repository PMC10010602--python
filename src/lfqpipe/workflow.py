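"""Pipeline orchestration: analysis and modeling runs with manifests.

``run_analysis`` executes read -> filter -> (average tech reps) ->
group-missingness filter -> imputation/normalization (configurable order)
-> differential expression, writing stage TSVs, QC figures and a manifest
JSON (parameters, seeds, per-stage row counts, output hashes).

``run_modeling`` continues from a DE result and complete matrix:
feature selection -> stratified split -> repeated-CV training -> held-out
probabilities -> ROC/AUC, persisting a run-report JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import Design, IntensityMatrix
from .de import DEResult, find_dep, write_de_result
from .impute import ImputeParams, impute_minprob, write_impute_record
from .io import (
    read_design,
    read_intensity_matrix,
    read_protein_groups,
    write_intensity_matrix,
)
from .modeling import (
    DEFAULT_ALGORITHMS,
    roc_auc,
    select_features,
    split_data,
    test_models,
    train_models,
)
from .normalize import quantile_normalize
from .plots import FigureSpec, render_figure
from .preprocess import (
    FilterParams,
    average_tech_reps,
    create_intensity_frame,
    filter_by_group_na,
)

logger = logging.getLogger("lfqpipe.workflow")

__all__ = ["RunConfig", "run_analysis", "run_modeling"]

ORDERS = ("impute_first", "normalize_first", "skip_normalization")


@dataclass
class RunConfig:
    """Flat configuration for a full run; CLI flags override config files."""

    protein_groups: str | None = None
    generic_matrix: str | None = None
    design: str | None = None
    outdir: str = "lfqpipe_run"
    intensity_type: str = "LFQ"
    uniq_pep_min: int = 3
    max_group_na: float = 0.34
    impute_q: float = 0.01
    tune_sigma: float = 1.0
    order: str = "impute_first"
    lfc_cut: float = 1.0
    adj_p_cut: float = 0.05
    top_n: int = 20
    corr_cut: float = 0.90
    train_frac: float = 0.7
    algorithms: tuple[str, ...] = DEFAULT_ALGORITHMS
    k: int = 10
    repeats: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.order not in ORDERS:
            raise ValueError(f"order must be one of {ORDERS}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


class _Manifest:
    """Incrementally persisted run manifest; survives mid-run aborts."""

    def __init__(self, outdir: Path, cfg: RunConfig, kind: str):
        self.path = outdir / f"{kind}_manifest.json"
        self.data = {
            "tool": "lfqpipe",
            "version": __version__,
            "kind": kind,
            "config": asdict(cfg),
            "stages": [],
            "outputs": {},
        }
        self.flush()

    def stage(self, name: str, **info) -> None:
        self.data["stages"].append({"stage": name, **info})
        self.flush()

    def output(self, name: str, path: Path) -> None:
        self.data["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}
        self.flush()

    def flush(self) -> None:
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=2, default=_jsonable)


def run_analysis(cfg: RunConfig) -> dict:
    """Execute the analysis pipeline; returns the artifact dict.

    The returned dict carries the in-memory objects (``design``, stage
    matrices, ``de``) plus the paths of everything written.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cfg.design is None:
        raise ValueError("config lacks a design file")
    for label, p in (("design", cfg.design), ("input table", cfg.protein_groups or cfg.generic_matrix)):
        if p is None:
            raise ValueError("config names neither a protein-groups table nor a generic matrix")
        if not Path(p).exists():
            raise FileNotFoundError(f"{label} not found: {p}")

    manifest = _Manifest(outdir, cfg, "analysis")
    filt = FilterParams(uniq_pep_min=cfg.uniq_pep_min, max_group_na=cfg.max_group_na)

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            manifest.stage(name, error=str(exc))
            raise RuntimeError(f"analysis aborted at stage {name!r}: {exc}") from exc

    if cfg.protein_groups:
        table = _stage("read", lambda: read_protein_groups(cfg.protein_groups, cfg.intensity_type))
    else:
        table = _stage("read", lambda: read_intensity_matrix(cfg.generic_matrix))
    design = _stage("design", lambda: read_design(cfg.design, table))
    manifest.stage("read", proteins=table.n_proteins, columns=len(table.column_labels),
                   groups=design.groups)

    raw = _stage("create_intensity_frame", lambda: create_intensity_frame(table, design, filt))
    manifest.stage("create_intensity_frame", retained=len(raw.values),
                   removed=table.n_proteins - len(raw.values))

    figures: dict[str, Path] = {}
    if design.has_tech_reps:
        figures["corr_plot"] = render_figure(FigureSpec(
            kind="corr_plot", inputs={"matrix": raw, "design": design},
            path=outdir / "corr_plot.png"))
        averaged = _stage("average_tech_reps", lambda: average_tech_reps(raw, design))
        manifest.stage("average_tech_reps", samples=len(averaged.sample_ids))
    else:
        averaged = raw

    figures["heatmap_na"] = render_figure(FigureSpec(
        kind="heatmap_na", inputs={"matrix": averaged}, path=outdir / "heatmap_na.png"))

    filtered = _stage("filter_by_group_na", lambda: filter_by_group_na(averaged, filt))
    manifest.stage("filter_by_group_na", retained=len(filtered.values),
                   removed=len(averaged.values) - len(filtered.values))
    raw_path = outdir / "raw_matrix.tsv"
    write_intensity_matrix(filtered, raw_path)
    manifest.output("raw_matrix", raw_path)

    imp_params = ImputeParams(q=cfg.impute_q, tune_sigma=cfg.tune_sigma, seed=cfg.seed)
    if cfg.order == "normalize_first":
        normalized = _stage("quantile_normalize", lambda: quantile_normalize(filtered))
        final = _stage("impute_minprob", lambda: impute_minprob(normalized, imp_params))
        pre_norm, post_norm = filtered, normalized
    elif cfg.order == "impute_first":
        imputed = _stage("impute_minprob", lambda: impute_minprob(filtered, imp_params))
        final = _stage("quantile_normalize", lambda: quantile_normalize(imputed))
        pre_norm, post_norm = imputed, final
    else:  # skip_normalization
        final = _stage("impute_minprob", lambda: impute_minprob(filtered, imp_params))
        pre_norm = post_norm = None
    manifest.stage("impute_normalize", order=cfg.order, missing_before=filtered.n_missing)

    figures["impute_plot"] = render_figure(FigureSpec(
        kind="impute_plot", inputs={"before": filtered, "after": final},
        path=outdir / "impute_plot.png"))
    if post_norm is not None:
        figures["norm_plot"] = render_figure(FigureSpec(
            kind="norm_plot", inputs={"before": pre_norm, "after": post_norm},
            path=outdir / "norm_plot.png"))

    final_path = outdir / "final_matrix.tsv"
    write_intensity_matrix(final, final_path)
    manifest.output("final_matrix", final_path)
    impute_json = outdir / "impute_record.json"
    write_impute_record(final if final.meta.get("impute") else final, impute_json)
    manifest.output("impute_record", impute_json)

    de = _stage("find_dep", lambda: find_dep(final, design, cfg.lfc_cut, cfg.adj_p_cut))
    de_path = outdir / "de_result.tsv"
    write_de_result(de, de_path)
    manifest.output("de_result", de_path)
    manifest.stage("find_dep", significant=de.n_significant, tested=len(de.table))

    figures["volcano_plot"] = render_figure(FigureSpec(
        kind="volcano_plot", inputs={"de": de}, path=outdir / "volcano_plot.png"))
    figures["heatmap_de"] = render_figure(FigureSpec(
        kind="heatmap_de", inputs={"matrix": final, "de": de}, path=outdir / "heatmap_de.png"))
    for name, p in figures.items():
        manifest.output(name, p)

    return {
        "design": design,
        "raw": filtered,
        "final": final,
        "de": de,
        "figures": figures,
        "manifest": manifest.path,
        "outdir": outdir,
    }


def run_modeling(cfg: RunConfig, de: DEResult, m: IntensityMatrix) -> dict:
    """Execute the modeling pipeline from a DE result and complete matrix."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir, cfg, "modeling")

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            manifest.stage(name, error=str(exc))
            raise RuntimeError(f"modeling aborted at stage {name!r}: {exc}") from exc

    mf = _stage("select_features", lambda: select_features(de, m, cfg.top_n, cfg.corr_cut))
    manifest.stage("select_features", features=list(mf.features.columns))
    split = _stage("split_data", lambda: split_data(mf, cfg.train_frac, cfg.seed))
    manifest.stage("split_data", train=len(split.train_ids), test=len(split.test_ids))
    ms = _stage("train_models", lambda: train_models(
        split, mf, cfg.algorithms, cfg.k, cfg.repeats, cfg.seed))
    probs = _stage("test_models", lambda: test_models(ms, split, mf))

    positive = mf.classes[-1]
    report = {
        "features": list(mf.features.columns),
        "classes": mf.classes,
        "positive_class": positive,
        "split": {"train": split.train_ids, "test": split.test_ids,
                  "train_frac": cfg.train_frac, "seed": cfg.seed},
        "grids": ms.grids,
        "best_settings": ms.best,
        "cv": {"k": cfg.k, "repeats": cfg.repeats},
        "algorithms": {},
    }
    truth = mf.labels.loc[split.test_ids]
    for algo in ms.models:
        frame = probs.probabilities[algo]
        curve, auc = roc_auc(frame[positive].to_numpy(), truth.to_numpy(), positive)
        pred = probs.predicted[algo]
        confusion = pd.crosstab(truth, pred).reindex(
            index=mf.classes, columns=mf.classes, fill_value=0)
        report["algorithms"][algo] = {
            "mean_cv_accuracy": ms.mean_cv_accuracy(algo),
            "test_accuracy": probs.accuracy(algo, truth),
            "auc": auc,
            "confusion": confusion.to_dict(),
            "roc": {"fpr": curve["fpr"].tolist(), "tpr": curve["tpr"].tolist()},
            "probabilities": frame.round(6).to_dict(orient="index"),
        }
    report_path = outdir / "model_report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    manifest.output("model_report", report_path)

    resamples_path = outdir / "resamples.tsv"
    ms.resamples.to_csv(resamples_path, sep="\t", index=False, lineterminator="\n")
    manifest.output("resamples", resamples_path)

    figures = {}
    figures["feature_plot"] = render_figure(FigureSpec(
        kind="feature_plot", inputs={"model_frame": mf}, path=outdir / "feature_plot.png"))
    figures["performance_plot"] = render_figure(FigureSpec(
        kind="performance_plot", inputs={"model_set": ms}, path=outdir / "performance_plot.png"))
    figures["varimp_plot"] = render_figure(FigureSpec(
        kind="varimp_plot", inputs={"model_set": ms, "split": split, "model_frame": mf},
        path=outdir / "varimp_plot.png", seed=cfg.seed))
    figures["roc_plot"] = render_figure(FigureSpec(
        kind="roc_plot", inputs={"probabilities": probs, "labels": mf.labels},
        path=outdir / "roc_plot.png"))
    for name, p in figures.items():
        manifest.output(name, p)

    return {
        "model_frame": mf,
        "split": split,
        "model_set": ms,
        "probabilities": probs,
        "report": report,
        "figures": figures,
        "manifest": manifest.path,
        "outdir": outdir,
    }
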