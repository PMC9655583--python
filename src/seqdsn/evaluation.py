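"""Metrics, 36-fold cross-validation orchestration and classical baselines.

Threshold metrics (accuracy, specificity, precision, recall, F1) use a
0.5 cutoff on the positive-class probability. Ranking metrics are the
area under the ROC curve (trapezoid over score-sorted thresholds, which
equals the Mann-Whitney pair statistic with ties counted 1/2) and
average precision (step-wise, no interpolation) — AP is the headline
number at 1:10 class imbalance, where AUC saturates easily.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .datasets import CVPlan, DomainDataset
from .model import LossWeights, ModelConfig, init_model

__all__ = [
    "ConfusionCounts", "MetricsReport", "compute_metrics", "roc_auc",
    "average_precision", "run_cross_validation", "run_baseline",
    "BASELINE_NAMES",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    acc: float
    spe: float
    pre: float
    rec: float
    f1: float
    auc: float | None
    ap: float | None
    threshold: float
    counts: ConfusionCounts

    def as_dict(self) -> dict:
        d = asdict(self)
        d["counts"] = asdict(self.counts)
        return d


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def roc_auc(labels, scores) -> float | None:
    """AUC by trapezoid over the ROC curve; tied scores contribute 1/2.

    Returns None (with a warning) for single-class label vectors.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        warnings.warn("AUC undefined for single-class labels", stacklevel=2)
        return None
    order = np.argsort(-scores, kind="mergesort")
    y = labels[order]
    s = scores[order]
    # cumulative TP/FP at each distinct threshold
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(1 - y)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    return float(np.trapezoid(tpr, fpr))


def average_precision(labels, scores) -> float | None:
    """Step-wise average precision: AP = sum (R_k - R_{k-1}) * P_k over
    distinct thresholds. Equals the mean of precision at each positive's
    rank when scores are untied."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        warnings.warn("AP undefined for single-class labels", stacklevel=2)
        return None
    order = np.argsort(-scores, kind="mergesort")
    y = labels[order]
    s = scores[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(1 - y)[distinct]
    precision = tps / (tps + fps)
    recall = tps / n_pos
    recall_prev = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - recall_prev) * precision))


def compute_metrics(scores, labels, threshold: float = 0.5) -> MetricsReport:
    """Full metric suite from positive-class scores and 0/1 labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(scores) != len(labels):
        raise ValueError("scores/labels length mismatch")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    counts = ConfusionCounts(tp, tn, fp, fn)
    pre = _safe_div(tp, tp + fp)
    rec = _safe_div(tp, tp + fn)
    return MetricsReport(
        acc=_safe_div(tn + tp, counts.total),
        spe=_safe_div(tn, tn + fp),
        pre=pre,
        rec=rec,
        f1=_safe_div(2 * pre * rec, pre + rec),
        auc=roc_auc(labels, scores),
        ap=average_precision(labels, scores),
        threshold=threshold,
        counts=counts,
    )


# -- cross-validation --------------------------------------------------


def run_cross_validation(source: DomainDataset, target: DomainDataset,
                         plan: CVPlan, train_config, model_config=None,
                         weights: LossWeights = LossWeights(),
                         classifier: str = "auto"):
    """Run the full (groups x groups)-fold plan over the target domain.

    The source domain participates fully in every fold's training; the
    plan partitions the target domain. Per fold the model is trained
    from scratch with a fold-derived seed (master seed + fold index),
    scored on the fold's test records, and the unweighted arithmetic
    mean report over folds is returned alongside the per-fold reports.
    """
    from .training import train
    from dataclasses import replace

    model_config = model_config or ModelConfig(
        window_length=target.encoded.shape[1])
    keys = [r.key for r in target.provenance]
    key_to_idx = {k: i for i, k in enumerate(keys)}
    if set(plan.pos_groups) | set(plan.neg_groups) != set(keys):
        raise ValueError("CV plan ids do not match target dataset records")

    fold_reports = []
    for fold_index, fold in enumerate(plan.folds):
        test_keys = plan.test_keys(fold)
        train_keys = plan.train_keys(fold)
        assert not (test_keys & train_keys), "fold leakage"
        test_idx = np.array(sorted(key_to_idx[k] for k in test_keys))
        train_idx = np.array(sorted(key_to_idx[k] for k in train_keys))
        tgt_train = target.subset(train_idx)
        tgt_test = target.subset(test_idx)
        if tgt_test.labels.sum() in (0, len(tgt_test)):
            warnings.warn(f"fold {fold}: single-class test set, skipped",
                          stacklevel=2)
            continue
        fold_seed = train_config.seed + fold_index
        cfg = replace(train_config, seed=fold_seed)
        if cfg.mode in ("source_only_classifier", 1):
            tgt_train = tgt_train.subset(
                np.flatnonzero(tgt_train.labels == 0))
        model = init_model(model_config, mode=cfg.mode, seed=fold_seed)
        model, _ = train(model, source, tgt_train, cfg, weights)
        scores = model.predict_scores(tgt_test.encoded, classifier=classifier)
        report = compute_metrics(scores, tgt_test.labels)
        fold_reports.append((fold, report))
    if not fold_reports:
        raise ValueError("no fold produced a report")
    mean = _mean_report([r for _, r in fold_reports])
    return fold_reports, mean


def _mean_report(reports: list[MetricsReport]) -> dict:
    out = {}
    for key in ("acc", "spe", "pre", "rec", "f1", "auc", "ap"):
        vals = [getattr(r, key) for r in reports if getattr(r, key) is not None]
        out[key] = float(np.mean(vals)) if vals else None
    out["n_folds"] = len(reports)
    return out


# -- classical baselines ----------------------------------------------

BASELINE_NAMES = ("naive_bayes", "logistic", "knn", "svm",
                  "random_forest", "xgboost")


def _make_baseline(name: str, seed: int):
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import BernoulliNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC

    if name == "naive_bayes":
        return BernoulliNB()
    if name == "logistic":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=15)
    if name == "svm":
        return SVC(probability=True, random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    if name == "xgboost":
        from xgboost import XGBClassifier
        return XGBClassifier(n_estimators=200, max_depth=4,
                             learning_rate=0.1, random_state=seed,
                             eval_metric="logloss", verbosity=0)
    raise ValueError(
        f"unknown baseline {name!r}; options: {', '.join(BASELINE_NAMES)}")


def run_baseline(name: str, train: DomainDataset, test: DomainDataset,
                 seed: int = 0) -> MetricsReport:
    """Fit a classical classifier on flattened one-hot windows and score
    the test set (the "source only" transfer scenario when train is the
    source domain and test the target)."""
    clf = _make_baseline(name, seed)
    clf.fit(train.flat_features, train.labels)
    scores = clf.predict_proba(test.flat_features)[:, 1]
    return compute_metrics(scores, test.labels)
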