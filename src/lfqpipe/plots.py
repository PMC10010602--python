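"""Figure suite for the analysis and modeling workflows.

Every figure writes, next to the image, a plain-text data export (TSV)
holding exactly the numbers plotted, so figure content can be asserted
without image diffing.  The default palette is the 8-colour Okabe-Ito
set, which is safe for the common forms of colour-vision deficiency.

Kinds
-----
corr_plot          technical-replicate scatter with Pearson r
heatmap_na         missing-value mask
impute_plot        intensity density before/after imputation
norm_plot          per-sample boxplots before/after normalization
heatmap_de         intensities of the top differential proteins
volcano_plot       log2FC vs -log10 p, significant proteins highlighted
feature_plot       per-feature intensity boxplots by class
varimp_plot        permutation feature importances per algorithm
performance_plot   resampled accuracy/kappa per algorithm
roc_plot           ROC curve per algorithm with AUC in the legend
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats as sstats

from .modeling import roc_auc

__all__ = ["PALETTES", "FigureSpec", "render_figure"]

PALETTES = {
    "okabe_ito": [
        "#E69F00", "#56B4E9", "#009E73", "#F0E442",
        "#0072B2", "#D55E00", "#CC79A7", "#000000",
    ],
}


@dataclass
class FigureSpec:
    """Description of one figure: what to draw, from what, to where."""

    kind: str
    inputs: dict
    path: str | Path
    palette: str = "okabe_ito"
    seed: int = 0


def _require(spec: FigureSpec, *names: str) -> list:
    missing = [n for n in names if n not in spec.inputs]
    if missing:
        raise ValueError(f"{spec.kind} needs input(s): {missing}")
    return [spec.inputs[n] for n in names]


def _export_path(path: Path) -> Path:
    return path.with_name(path.stem + "_data.tsv")


def _corr_plot(spec, colors):
    m, design = _require(spec, "matrix", "design")
    rows = []
    pairs = []
    for sample in dict.fromkeys(design.entries["sample_id"]):
        labels = list(design.entries.loc[design.entries["sample_id"] == sample, "label"])
        labels = [l for l in labels if l in m.values.columns]
        for i in range(len(labels) - 1):
            x, y = m.values[labels[i]], m.values[labels[i + 1]]
            ok = x.notna() & y.notna()
            r = float(np.corrcoef(x[ok], y[ok])[0, 1]) if ok.sum() > 2 else np.nan
            pairs.append((sample, labels[i], labels[i + 1], x[ok], y[ok], r))
            rows.append(pd.DataFrame({
                "sample_id": sample, "rep_x": labels[i], "rep_y": labels[i + 1],
                "protein_id": x[ok].index, "x": x[ok].to_numpy(), "y": y[ok].to_numpy(),
                "pearson_r": r,
            }))
    if not pairs:
        raise ValueError("corr_plot needs technical replicates")
    n = len(pairs)
    ncol = min(n, 3)
    nrow = int(np.ceil(n / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 3.0 * nrow), squeeze=False)
    for ax, (sample, lx, ly, x, y, r) in zip(axes.ravel(), pairs):
        ax.scatter(x, y, s=6, alpha=0.5, color=colors[0])
        ax.set_title(f"{sample}: r={r:.3f}", fontsize=9)
        ax.set_xlabel(lx, fontsize=8)
        ax.set_ylabel(ly, fontsize=8)
    for ax in axes.ravel()[n:]:
        ax.set_visible(False)
    return fig, pd.concat(rows, ignore_index=True)


def _heatmap_na(spec, colors):
    (m,) = _require(spec, "matrix")
    mask = m.values.isna()
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.imshow(mask.to_numpy(), aspect="auto", cmap="Greys", interpolation="nearest")
    ax.set_xticks(range(len(mask.columns)))
    ax.set_xticklabels(mask.columns, rotation=90, fontsize=7)
    ax.set_ylabel("proteins")
    ax.set_title(f"missing values: {int(mask.to_numpy().sum())} cells")
    export = mask.astype(int).rename_axis("protein_id").reset_index()
    return fig, export


def _density(ax, values, label, color):
    values = values[np.isfinite(values)]
    if len(values) > 1 and np.std(values) > 0:
        grid = np.linspace(values.min(), values.max(), 200)
        ax.plot(grid, sstats.gaussian_kde(values)(grid), label=label, color=color)


def _impute_plot(spec, colors):
    before, after = _require(spec, "before", "after")
    fig, ax = plt.subplots(figsize=(6, 4))
    pooled_b = before.values.to_numpy().ravel()
    pooled_a = after.values.to_numpy().ravel()
    _density(ax, pooled_b, "before imputation", colors[0])
    _density(ax, pooled_a, "after imputation", colors[5])
    ax.set_xlabel("log2 intensity")
    ax.set_ylabel("density")
    ax.legend()
    export = pd.concat([
        pd.DataFrame({"stage": "before", "value": pooled_b[np.isfinite(pooled_b)]}),
        pd.DataFrame({"stage": "after", "value": pooled_a[np.isfinite(pooled_a)]}),
    ], ignore_index=True)
    return fig, export


def _norm_plot(spec, colors):
    before, after = _require(spec, "before", "after")
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    rows = []
    for ax, (stage, m) in zip(axes, (("before", before), ("after", after))):
        data = [m.values[c].dropna().to_numpy() for c in m.values.columns]
        ax.boxplot(data, tick_labels=list(m.values.columns))
        ax.set_title(f"{stage} normalization")
        ax.tick_params(axis="x", rotation=90, labelsize=7)
        for c in m.values.columns:
            sub = m.values[c].dropna()
            rows.append(pd.DataFrame({"stage": stage, "sample": c,
                                      "protein_id": sub.index, "value": sub.to_numpy()}))
    return fig, pd.concat(rows, ignore_index=True)


def _heatmap_de(spec, colors):
    m, de = _require(spec, "matrix", "de")
    top = de.table.head(20)["protein_id"]
    top = [p for p in top if p in m.values.index]
    block = m.values.loc[top]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(block.to_numpy(), aspect="auto", cmap="viridis", interpolation="nearest")
    fig.colorbar(im, ax=ax, label="log2 intensity")
    ax.set_yticks(range(len(top)))
    ax.set_yticklabels(top, fontsize=6)
    ax.set_xticks(range(len(block.columns)))
    ax.set_xticklabels(block.columns, rotation=90, fontsize=7)
    ax.set_title("top differential proteins")
    return fig, block.reset_index()


def _volcano_plot(spec, colors):
    (de,) = _require(spec, "de")
    t = de.table.copy()
    with np.errstate(divide="ignore"):
        t["neg_log10_p"] = -np.log10(t["adj_p_value"])
    fig, ax = plt.subplots(figsize=(6, 5))
    bg = t[~t["significant"]]
    hi = t[t["significant"]]
    ax.scatter(bg["log2FC"], bg["neg_log10_p"], s=8, color="#999999", alpha=0.5, label="ns")
    ax.scatter(hi["log2FC"], hi["neg_log10_p"], s=12, color=colors[5], label="significant")
    ax.axvline(de.lfc_cut, ls="--", lw=0.7, color="k")
    ax.axvline(-de.lfc_cut, ls="--", lw=0.7, color="k")
    ax.axhline(-np.log10(de.adj_p_cut), ls="--", lw=0.7, color="k")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 adjusted p")
    ax.legend()
    return fig, t[["protein_id", "log2FC", "adj_p_value", "neg_log10_p", "significant"]]


def _feature_plot(spec, colors):
    (mf,) = _require(spec, "model_frame")
    feats = list(mf.features.columns)
    n = len(feats)
    ncol = min(n, 5)
    nrow = int(np.ceil(n / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(2.4 * ncol, 2.4 * nrow), squeeze=False)
    rows = []
    for ax, f in zip(axes.ravel(), feats):
        data = [mf.features.loc[mf.labels == c, f].to_numpy() for c in mf.classes]
        ax.boxplot(data, tick_labels=mf.classes)
        ax.set_title(f, fontsize=7)
        for c in mf.classes:
            vals = mf.features.loc[mf.labels == c, f]
            rows.append(pd.DataFrame({"feature": f, "class": c,
                                      "sample": vals.index, "value": vals.to_numpy()}))
    for ax in axes.ravel()[n:]:
        ax.set_visible(False)
    return fig, pd.concat(rows, ignore_index=True)


def _varimp_plot(spec, colors):
    from sklearn.inspection import permutation_importance

    ms, split, mf = _require(spec, "model_set", "split", "model_frame")
    x = mf.features.loc[split.train_ids].to_numpy()
    codes = mf.labels.loc[split.train_ids].map({c: i for i, c in enumerate(mf.classes)}).to_numpy()
    rows = []
    algos = list(ms.models)
    fig, axes = plt.subplots(1, len(algos), figsize=(3.0 * len(algos), 4), squeeze=False)
    for ax, algo in zip(axes.ravel(), algos):
        imp = permutation_importance(
            ms.models[algo], x, codes, n_repeats=10, random_state=spec.seed
        )
        order = np.argsort(imp.importances_mean)
        names = [ms.feature_names[i] for i in order]
        means = imp.importances_mean[order]
        ax.hlines(range(len(names)), 0, means, color=colors[4])
        ax.plot(means, range(len(names)), "o", color=colors[4])
        ax.set_yticks(range(len(names)))
        ax.set_yticklabels(names, fontsize=6)
        ax.set_title(algo, fontsize=9)
        ax.set_xlabel("permutation importance")
        rows.append(pd.DataFrame({"algorithm": algo, "feature": ms.feature_names,
                                  "importance": imp.importances_mean}))
    return fig, pd.concat(rows, ignore_index=True)


def _performance_plot(spec, colors):
    (ms,) = _require(spec, "model_set")
    best_rows = []
    for algo, gi in ms.best.items():
        sub = ms.resamples[(ms.resamples["algorithm"] == algo) & (ms.resamples["setting"] == gi)]
        best_rows.append(sub)
    best = pd.concat(best_rows, ignore_index=True)
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, metric in zip(axes, ("accuracy", "kappa")):
        data = [best.loc[best["algorithm"] == a, metric].to_numpy() for a in ms.best]
        ax.boxplot(data, tick_labels=list(ms.best))
        ax.set_title(metric)
        ax.tick_params(axis="x", rotation=45)
    return fig, best


def _roc_plot(spec, colors):
    probs, labels = _require(spec, "probabilities", "labels")
    positive = spec.inputs.get("positive_class") or probs.classes[-1]
    fig, ax = plt.subplots(figsize=(5, 5))
    rows = []
    for i, (algo, frame) in enumerate(probs.probabilities.items()):
        scores = frame[positive].to_numpy()
        truth = labels.loc[frame.index].to_numpy()
        curve, auc = roc_auc(scores, truth, positive)
        ax.plot(curve["fpr"], curve["tpr"], label=f"{algo} (AUC={auc:.3f})",
                color=colors[i % len(colors)])
        curve = curve.assign(algorithm=algo, auc=auc)
        rows.append(curve)
    ax.plot([0, 1], [0, 1], ls=":", color="#888888")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=8)
    return fig, pd.concat(rows, ignore_index=True)


_RENDERERS = {
    "corr_plot": _corr_plot,
    "heatmap_na": _heatmap_na,
    "impute_plot": _impute_plot,
    "norm_plot": _norm_plot,
    "heatmap_de": _heatmap_de,
    "volcano_plot": _volcano_plot,
    "feature_plot": _feature_plot,
    "varimp_plot": _varimp_plot,
    "performance_plot": _performance_plot,
    "roc_plot": _roc_plot,
}


def render_figure(spec: FigureSpec) -> Path:
    """Render one figure and its sidecar TSV data export.

    Returns the image path; the export lands at ``<stem>_data.tsv`` next
    to it.  Rendering the same spec twice produces byte-identical exports.
    """
    if spec.kind not in _RENDERERS:
        raise ValueError(f"unknown figure kind {spec.kind!r}; known: {sorted(_RENDERERS)}")
    colors = PALETTES[spec.palette]
    path = Path(spec.path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig, export = _RENDERERS[spec.kind](spec, colors)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    export.to_csv(_export_path(path), sep="\t", index=False, lineterminator="\n")
    return path
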