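"""Classifier panels from top differential proteins.

Workflow: take the top differentially abundant proteins (smallest adjusted
p), prune highly correlated features, split samples into stratified
train/test partitions, train several classifier families with repeated
stratified k-fold cross-validation over small fixed hyperparameter grids,
then evaluate held-out class probabilities and ROC/AUC.

Algorithm registry (field-standard names -> native estimators)::

    rf           random forest
    svmRadial    support vector machine, RBF kernel
    svmLinear    support vector machine, linear kernel
    glm          logistic regression
    xgbLinear    gradient boosting with linear base learners
    naive_bayes  Gaussian naive Bayes
    knn          k-nearest neighbours

DEFAULT_ALGORITHMS reproduces the conventional five-algorithm panel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, cohen_kappa_score
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .data import IntensityMatrix
from .de import DEResult

logger = logging.getLogger("lfqpipe.modeling")

def _quiet_fit(est, x, y):
    # SVC(probability=True) is the stable way to get class probabilities for
    # the SVM panel members; silence the advisory about its future renaming.
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="The `probability` parameter", category=FutureWarning
        )
        est.fit(x, y)
    return est

__all__ = [
    "ModelFrame",
    "Split",
    "ModelSet",
    "ProbabilitySet",
    "DEFAULT_ALGORITHMS",
    "greedy_prune",
    "select_features",
    "split_data",
    "train_models",
    "test_models",
    "roc_auc",
]

DEFAULT_ALGORITHMS = ("svmRadial", "glm", "rf", "xgbLinear", "naive_bayes")


@dataclass
class ModelFrame:
    """samples x features matrix with class labels, ready for modeling."""

    features: pd.DataFrame  # samples x selected proteins, complete
    labels: pd.Series  # class label per sample
    classes: list[str]  # class order (design order)
    provenance: pd.DataFrame  # protein_id, adj_p_value of selected features

    def __post_init__(self) -> None:
        if self.features.isna().any().any():
            raise ValueError("model frame must be complete")
        if len(set(self.labels)) < 2:
            raise ValueError("model frame needs >=2 classes")


@dataclass
class Split:
    """Stratified train/test partition of a ModelFrame's samples."""

    train_ids: list[str]
    test_ids: list[str]
    train_frac: float
    seed: int


@dataclass
class ModelSet:
    """Per-algorithm fitted models with resampling records.

    ``resamples`` has one row per (algorithm, setting, repeat, fold) with
    accuracy and Cohen's kappa; ``best`` maps algorithm -> chosen grid
    index; ``models`` holds the final estimators refit on the full
    training partition.
    """

    models: dict[str, object]
    grids: dict[str, list[dict]]
    best: dict[str, int]
    resamples: pd.DataFrame
    feature_names: list[str]
    classes: list[str]
    k: int
    repeats: int

    def mean_cv_accuracy(self, algorithm: str) -> float:
        sub = self.resamples
        sel = sub[(sub["algorithm"] == algorithm) & (sub["setting"] == self.best[algorithm])]
        return float(sel["accuracy"].mean())


@dataclass
class ProbabilitySet:
    """Held-out class probabilities per algorithm."""

    probabilities: dict[str, pd.DataFrame]  # algorithm -> test samples x classes
    predicted: dict[str, pd.Series]
    classes: list[str]

    def accuracy(self, algorithm: str, truth: pd.Series) -> float:
        pred = self.predicted[algorithm]
        return float((pred == truth.loc[pred.index]).mean())


def greedy_prune(corr: pd.DataFrame, order: list, corr_cut: float) -> list:
    """Greedy correlation-based feature elimination.

    While any pair of remaining features has |r| > ``corr_cut``: take the
    worst (largest |r|) pair and drop the member with the larger mean
    absolute correlation to all remaining features; on a tie, drop the one
    appearing later in ``order``.  Returns the kept features in ``order``.
    """
    rank = {f: i for i, f in enumerate(order)}
    chosen = list(order)
    while len(chosen) > 1:
        sub = corr.loc[chosen, chosen].abs()
        np.fill_diagonal(sub.values, 0.0)
        f1, f2 = sub.stack().idxmax()
        if sub.loc[f1, f2] <= corr_cut:
            break
        if len(chosen) > 2:
            mean_abs = {f: sub.loc[f].drop(f).mean() for f in (f1, f2)}
        else:
            mean_abs = {f1: 0.0, f2: 0.0}
        if mean_abs[f1] > mean_abs[f2]:
            drop = f1
        elif mean_abs[f2] > mean_abs[f1]:
            drop = f2
        else:
            drop = f1 if rank[f1] > rank[f2] else f2
        logger.info("pruning %s (|r|=%.3f with %s)", drop, sub.loc[f1, f2],
                    f1 if drop == f2 else f2)
        chosen.remove(drop)
    return chosen


def select_features(
    de: DEResult,
    m: IntensityMatrix,
    top_n: int = 20,
    corr_cut: float = 0.90,
) -> ModelFrame:
    """Pick the top differential proteins and prune correlated ones.

    Up to ``top_n`` significant proteins (smallest adjusted p, the
    DEResult sort order) are taken; features with zero variance are
    dropped with a warning; then, while any pair of remaining features has
    |Pearson r| > ``corr_cut``, the member of the worst pair with the
    larger mean absolute correlation to all remaining features is removed
    (ties: the one later in the sort order).
    """
    if m.values.isna().any().any():
        raise ValueError("matrix must be complete before modeling")
    sig = de.table[de.table["significant"]]
    if len(sig) == 0:
        raise ValueError("nothing to model: no significant proteins")
    chosen = [pid for pid in sig["protein_id"] if pid in m.values.index][:top_n]
    feats = m.values.loc[chosen].T  # samples x features

    variances = feats.var(axis=0, ddof=0)
    flat = list(variances[variances == 0].index)
    if flat:
        logger.warning("dropping %d zero-variance feature(s): %s", len(flat), flat)
        feats = feats.drop(columns=flat)
        chosen = [c for c in chosen if c not in flat]

    chosen = greedy_prune(feats[chosen].corr(), chosen, corr_cut)
    feats = feats[chosen]
    labels = m.groups.loc[feats.index]
    classes = list(dict.fromkeys(m.groups))
    prov = de.table.set_index("protein_id").loc[chosen, ["adj_p_value"]].reset_index()
    return ModelFrame(features=feats, labels=labels, classes=classes, provenance=prov)


def split_data(mf: ModelFrame, train_frac: float = 0.7, seed: int = 0) -> Split:
    """Stratified train/test split preserving class proportions.

    Per class with n_c samples the training partition receives
    round-half-up(train_frac * n_c) samples, floored so both partitions
    keep at least one sample of every class; membership is drawn uniformly
    without replacement under ``seed``.
    """
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for cls in mf.classes:
        ids = [s for s in mf.features.index if mf.labels[s] == cls]
        n_c = len(ids)
        if n_c < 2:
            raise ValueError(f"class {cls!r} has {n_c} sample(s); need >=2 to split")
        n_train = int(np.floor(train_frac * n_c + 0.5))  # round half up
        n_train = min(max(n_train, 1), n_c - 1)
        picked = rng.choice(n_c, size=n_train, replace=False)
        picked_set = set(picked.tolist())
        train += [ids[i] for i in sorted(picked_set)]
        test += [ids[i] for i in range(n_c) if i not in picked_set]
    return Split(train_ids=train, test_ids=test, train_frac=train_frac, seed=seed)


def _registry(seed: int) -> dict[str, tuple[object, list[dict]]]:
    """Estimator prototypes and small fixed hyperparameter grids."""
    return {
        "rf": (
            RandomForestClassifier(n_estimators=100, random_state=seed),
            [{"max_features": v} for v in ("sqrt", 0.5, 1.0)],
        ),
        "svmRadial": (
            SVC(kernel="rbf", gamma="scale", probability=True, random_state=seed),
            [{"C": v} for v in (0.25, 0.5, 1.0)],
        ),
        "svmLinear": (
            SVC(kernel="linear", probability=True, random_state=seed),
            [{"C": v} for v in (0.25, 0.5, 1.0)],
        ),
        "glm": (
            LogisticRegression(max_iter=2000),
            [{"C": v} for v in (0.1, 1.0, 10.0)],
        ),
        "xgbLinear": (
            XGBClassifier(
                booster="gblinear",
                updater="coord_descent",
                n_estimators=30,
                n_jobs=1,
                random_state=seed,
                verbosity=0,
            ),
            [{"reg_lambda": v} for v in (0.0, 1e-4, 1e-2)],
        ),
        "naive_bayes": (
            GaussianNB(),
            [{"var_smoothing": v} for v in (1e-9, 1e-6, 1e-3)],
        ),
        "knn": (
            KNeighborsClassifier(),
            [{"n_neighbors": v} for v in (3, 5, 7)],
        ),
    }


def train_models(
    split: Split,
    mf: ModelFrame,
    algorithms: tuple[str, ...] = DEFAULT_ALGORITHMS,
    k: int = 10,
    repeats: int = 3,
    seed: int = 0,
) -> ModelSet:
    """Train each algorithm with repeated stratified k-fold CV.

    For every algorithm and every grid setting, ``k`` x ``repeats``
    resampling measurements (accuracy and Cohen's kappa) are recorded; the
    best setting is the one with the highest mean accuracy (ties -> the
    smallest grid index, i.e. the simplest setting); the final model is
    refit on the full training partition.
    """
    registry = _registry(seed)
    unknown = [a for a in algorithms if a not in registry]
    if unknown:
        raise ValueError(f"unknown algorithm(s) {unknown}; registry: {sorted(registry)}")

    x = mf.features.loc[split.train_ids]
    y = mf.labels.loc[split.train_ids]
    class_counts = y.value_counts()
    if k > class_counts.min():
        raise ValueError(
            f"k={k} exceeds the smallest training class count "
            f"({class_counts.min()}); choose a smaller k"
        )
    # one label encoding shared by all estimators: design class order
    codes = y.map({c: i for i, c in enumerate(mf.classes)}).to_numpy()
    xv = x.to_numpy()

    cv = RepeatedStratifiedKFold(n_splits=k, n_repeats=repeats, random_state=seed)
    folds = list(cv.split(xv, codes))

    records = []
    models: dict[str, object] = {}
    grids: dict[str, list[dict]] = {}
    best: dict[str, int] = {}
    for algo in algorithms:
        proto, grid = registry[algo]
        grids[algo] = grid
        means = []
        for gi, params in enumerate(grid):
            accs = []
            for ri, (tr, te) in enumerate(folds):
                est = clone(proto).set_params(**params)
                _quiet_fit(est, xv[tr], codes[tr])
                pred = est.predict(xv[te])
                acc = accuracy_score(codes[te], pred)
                kappa = cohen_kappa_score(codes[te], pred)
                records.append(
                    {
                        "algorithm": algo,
                        "setting": gi,
                        "repeat": ri // k,
                        "fold": ri % k,
                        "accuracy": acc,
                        "kappa": kappa,
                    }
                )
                accs.append(acc)
            means.append(float(np.mean(accs)))
        best_gi = int(np.argmax(means))  # argmax takes the first max: simplest setting
        best[algo] = best_gi
        final = clone(proto).set_params(**grid[best_gi])
        _quiet_fit(final, xv, codes)
        models[algo] = final
        logger.info("%s: best setting %s (mean CV accuracy %.3f)", algo, grid[best_gi], means[best_gi])

    return ModelSet(
        models=models,
        grids=grids,
        best=best,
        resamples=pd.DataFrame(records),
        feature_names=list(mf.features.columns),
        classes=mf.classes,
        k=k,
        repeats=repeats,
    )


def test_models(ms: ModelSet, split: Split, mf: ModelFrame) -> ProbabilitySet:
    """Predict class probabilities for the held-out test partition.

    Predicted labels are the argmax class; exact probability ties resolve
    to the first class in design order.
    """
    if list(mf.features.columns) != ms.feature_names:
        raise ValueError("feature mismatch between ModelFrame and ModelSet")
    if not split.test_ids:
        raise ValueError("test partition is empty")
    xt = mf.features.loc[split.test_ids].to_numpy()
    probabilities = {}
    predicted = {}
    for algo, model in ms.models.items():
        prob = model.predict_proba(xt)
        # model class codes are indices into ms.classes; re-order defensively
        cols = [ms.classes[int(c)] for c in model.classes_]
        frame = pd.DataFrame(prob, index=split.test_ids, columns=cols)[ms.classes]
        frame = frame.div(frame.sum(axis=1), axis=0)  # guard tiny numeric drift
        probabilities[algo] = frame
        predicted[algo] = frame.idxmax(axis=1)  # idxmax: first class wins ties
    return ProbabilitySet(probabilities=probabilities, predicted=predicted, classes=ms.classes)


def roc_auc(
    scores: np.ndarray,
    labels: np.ndarray,
    positive_class,
) -> tuple[pd.DataFrame, float]:
    """ROC curve and AUC for one score vector.

    The curve holds (FPR, TPR) at every distinct threshold with endpoints
    (0,0) and (1,1).  AUC is the Mann-Whitney pair statistic: the fraction
    of (positive, negative) pairs ranked correctly, ties counting 1/2 —
    equal to the trapezoidal area under the curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive_class
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute ROC")

    order = np.argsort(-scores, kind="mergesort")
    sorted_pos = pos[order]
    sorted_scores = scores[order]
    tps = np.cumsum(sorted_pos)
    fps = np.cumsum(~sorted_pos)
    distinct = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr})

    # pair counting via mid-ranks of the positive scores
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return curve, float(auc)
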