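"""Supervised behavior classification and ethogram quantification.

Per-frame manual labels are aggregated into one label per analysis window
with a prominence-aware rule: with L1 and L2 the two most frequent labels in
the window (L1 the more frequent), the window is labeled L2 when L2 is the
more prominent behavior and L1's count does not exceed three times L2's
count; otherwise L1.  Short bursts of salient behaviors (a 1-s contraction
inside 4 s of stillness) therefore win the window.

Windows encoded as Fisher vectors are classified with a one-vs-rest-style
multiclass RBF SVM: PCA to 90% retained variance, class weights
w_i = (sum_j N_j) / N_i to counter class imbalance, and a 5-fold
cross-validated grid search over cost and kernel width with
log2 C, log2 gamma in {-5, -3, ..., 15}.  Predictions are either hard (the
class with the highest calibrated probability) or soft: up to three labels,
adding the runner-up while its probability exceeds 50% of the one above it.

Evaluation reports per-class accuracy, precision and recall, a confusion
matrix, and ROC/AUC computed by trapezoid integration of the TPR-FPR curve.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .classes import NONE_CODE, prominence
from .config import PipelineConfig


def aggregate_window_label(frame_labels) -> int:
    """One behavior code for a window of per-frame codes.

    None-class frames are ignored unless the window is entirely none.
    """
    labels = [int(l) for l in frame_labels]
    if not labels:
        raise ValueError("empty window")
    informative = [l for l in labels if l != NONE_CODE]
    if not informative:
        return NONE_CODE
    counts = Counter(informative)
    # order by count, prominence as tie-break
    ranked = sorted(counts, key=lambda c: (counts[c], prominence(c)),
                    reverse=True)
    l1 = ranked[0]
    if len(ranked) == 1:
        return l1
    l2 = ranked[1]
    if prominence(l2) > prominence(l1) and counts[l1] <= 3 * counts[l2]:
        return l2
    return l1


def class_weights(labels) -> dict[int, float]:
    """w_i = (sum_j N_j) / N_i from training counts."""
    counts = Counter(int(l) for l in labels)
    total = sum(counts.values())
    return {c: total / n for c, n in counts.items()}


@dataclass
class ClassifierModel:
    """Trained PCA + class-weighted RBF SVM with probability estimates."""

    pca: PCA
    svc: SVC
    classes: np.ndarray
    weights: dict[int, float]
    best_params: dict
    cv_results: pd.DataFrame | None = None


def train(vectors: np.ndarray, labels, config: PipelineConfig | None = None,
          seed: int | None = None) -> ClassifierModel:
    """Grid-search CV and fit the window classifier."""
    config = config or PipelineConfig()
    seed = config.seed if seed is None else seed
    X = np.asarray(vectors, float)
    y = np.asarray(labels, int)
    if np.unique(y).size < 2:
        raise ValueError("need at least two classes to train")

    pca = PCA(n_components=config.pca_variance, svd_solver="full")
    Xp = pca.fit_transform(X)

    weights = class_weights(y)
    grid = {"C": [2.0**e for e in config.log2_c_grid],
            "gamma": [2.0**e for e in config.log2_g_grid]}
    n_per_class = min(Counter(y.tolist()).values())
    folds = min(config.cv_folds, n_per_class)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    # the deployed predictor is argmax of the calibrated probabilities, so
    # model selection scores the probability estimates themselves
    search = GridSearchCV(
        SVC(kernel="rbf", class_weight=weights, probability=True,
            random_state=seed),
        grid, cv=cv, scoring="neg_log_loss", n_jobs=1)
    search.fit(Xp, y)
    best = search.best_estimator_
    return ClassifierModel(pca, best, best.classes_, weights,
                           dict(search.best_params_),
                           pd.DataFrame(search.cv_results_))


@dataclass
class Ethogram:
    """Predicted labels (1-3 per window, probabilities non-increasing)."""

    window_ids: list[str]
    labels: list[list[int]]           # per window, most probable first
    probabilities: list[list[float]]
    frame_rate_hz: float
    window_s: float

    def hard_labels(self) -> np.ndarray:
        return np.array([l[0] for l in self.labels])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, wid in enumerate(self.window_ids):
            row = {"window_id": wid, "t_start_s": i * self.window_s}
            for j in range(3):
                row[f"label{j+1}"] = (self.labels[i][j]
                                      if j < len(self.labels[i]) else "")
                row[f"prob{j+1}"] = (self.probabilities[i][j]
                                     if j < len(self.probabilities[i]) else "")
            rows.append(row)
        return pd.DataFrame(rows)


def _ranked_probs(model: ClassifierModel, vectors: np.ndarray):
    X = model.pca.transform(np.asarray(vectors, float))
    probs = model.svc.predict_proba(X)
    classes = model.classes
    ranked = []
    for p in probs:
        # ties broken toward the more prominent behavior
        order = sorted(range(len(classes)),
                       key=lambda i: (p[i], prominence(int(classes[i]))),
                       reverse=True)
        ranked.append([(int(classes[i]), float(p[i])) for i in order])
    return ranked


def predict_hard(model: ClassifierModel, vectors: np.ndarray,
                 window_ids=None, config: PipelineConfig | None = None
                 ) -> Ethogram:
    """One label per window: the class with the highest probability."""
    config = config or PipelineConfig()
    ranked = _ranked_probs(model, vectors)
    ids = list(window_ids) if window_ids is not None else [
        str(i) for i in range(len(ranked))]
    return Ethogram(ids, [[r[0][0]] for r in ranked],
                    [[r[0][1]] for r in ranked],
                    config.frame_rate_hz, config.window_s)


def predict_soft(model: ClassifierModel, vectors: np.ndarray,
                 window_ids=None, config: PipelineConfig | None = None
                 ) -> Ethogram:
    """Up to three labels per window via the strict 50% probability cascade."""
    config = config or PipelineConfig()
    ranked = _ranked_probs(model, vectors)
    ids = list(window_ids) if window_ids is not None else [
        str(i) for i in range(len(ranked))]
    labels, probs = [], []
    for r in ranked:
        keep = [r[0]]
        if len(r) > 1 and r[1][1] > 0.5 * r[0][1]:
            keep.append(r[1])
            if len(r) > 2 and r[2][1] > 0.5 * r[1][1]:
                keep.append(r[2])
        labels.append([c for c, _ in keep])
        probs.append([p for _, p in keep])
    return Ethogram(ids, labels, probs, config.frame_rate_hz, config.window_s)


def roc_curve_points(scores: np.ndarray, truth: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """ROC (FPR, TPR) points from binary truth and continuous scores."""
    scores = np.asarray(scores, float)
    truth = np.asarray(truth, bool)
    order = np.argsort(-scores, kind="stable")
    truth = truth[order]
    tp = np.concatenate([[0], np.cumsum(truth)])
    fp = np.concatenate([[0], np.cumsum(~truth)])
    n_pos, n_neg = max(tp[-1], 1), max(fp[-1], 1)
    return fp / n_neg, tp / n_pos


def auc_trapezoid(fpr: np.ndarray, tpr: np.ndarray) -> float:
    return float(np.trapezoid(tpr, fpr))


def evaluate(ethogram: Ethogram, truth_labels,
             probabilities: dict[int, np.ndarray] | None = None) -> dict:
    """Per-class one-vs-rest metrics plus confusion matrix and ROC/AUC.

    A window counts as a true positive for a class when the truth label is
    in the predicted label set (so soft predictions get credit for any of
    their 1-3 labels).  ``probabilities`` optionally maps class code ->
    per-window score for the ROC; without it AUC is skipped.
    """
    truth = np.asarray(truth_labels, int)
    pred_sets = [set(l) for l in ethogram.labels]
    hard = ethogram.hard_labels()
    classes = sorted(set(truth.tolist()) | {c for s in pred_sets for c in s})

    per_class = {}
    for c in classes:
        is_c = truth == c
        pred_c = np.array([c in s for s in pred_sets])
        tp = int(np.sum(is_c & pred_c))
        fp = int(np.sum(~is_c & pred_c))
        fn = int(np.sum(is_c & ~pred_c))
        tn = int(np.sum(~is_c & ~pred_c))
        if not is_c.any():
            per_class[c] = {"accuracy": np.nan, "precision": np.nan,
                            "recall": np.nan, "auc": np.nan,
                            "tp": tp, "fp": fp, "fn": fn, "tn": tn}
            continue
        entry = {
            "accuracy": (tp + tn) / max(tp + tn + fp + fn, 1),
            "precision": tp / (tp + fp) if tp + fp else np.nan,
            "recall": tp / (tp + fn) if tp + fn else np.nan,
            "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        }
        if probabilities is not None and c in probabilities:
            fpr, tpr = roc_curve_points(probabilities[c], is_c)
            entry["roc"] = (fpr, tpr)
            entry["auc"] = auc_trapezoid(fpr, tpr)
        per_class[c] = entry

    cm = pd.DataFrame(0, index=classes, columns=classes)
    for t, p in zip(truth, hard):
        cm.loc[t, p] += 1
    overall = float(np.mean([t in s for t, s in zip(truth, pred_sets)]))
    return {"per_class": per_class, "confusion_matrix": cm,
            "overall_accuracy": overall}


def summarize_ethogram(ethogram: Ethogram, block_minutes: float = 30.0
                       ) -> pd.DataFrame:
    """Fraction of time per behavior plus its across-block variability.

    Returns one row per behavior with the overall fraction of windows whose
    top label is that behavior and the standard deviation of that fraction
    computed over consecutive ``block_minutes`` blocks.
    """
    hard = ethogram.hard_labels()
    n = hard.size
    if n == 0:
        raise ValueError("empty ethogram")
    per_block = max(1, int(round(block_minutes * 60.0 / ethogram.window_s)))
    classes = sorted(set(hard.tolist()))
    blocks = [hard[i:i + per_block] for i in range(0, n, per_block)]
    rows = []
    for c in classes:
        frac = float(np.mean(hard == c))
        block_fracs = [float(np.mean(b == c)) for b in blocks]
        sd = float(np.std(block_fracs)) if len(block_fracs) > 1 else 0.0
        rows.append({"behavior": c, "fraction": frac, "block_sd": sd,
                     "n_blocks": len(blocks)})
    return pd.DataFrame(rows)
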