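"""Nearest-shrunken-centroid (PAMR-style) validation of a gene signature.

The classifier shrinks standardized class-centroid deviations toward zero by a
soft threshold delta, zeroing uninformative genes, and classifies samples by
shrunken-centroid distance with class priors. The threshold is chosen by
stratified cross-validation (largest delta at minimal CV error) and the
signature is evaluated by repeated stratified 10-fold cross-validation with
sensitivity, specificity, precision and accuracy.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .data_io import ExpressionMatrix, GroupLabels

logger = logging.getLogger(__name__)

_CLASSES = ("control", "case")


@dataclass
class NSCModel:
    """Fitted nearest-shrunken-centroid state for a two-class problem.

    d_ik = (centroid_ik - overall_i) / (m_k (s_i + s0)) is the standardized
    centroid deviation; the shrunken deviation soft-thresholds it at delta:
    d'_ik = sign(d_ik) max(|d_ik| - delta, 0).
    """

    classes: tuple[str, str]
    class_centroids: np.ndarray   # genes x 2
    overall_centroid: np.ndarray  # genes
    pooled_sd: np.ndarray         # genes
    s0: float
    m_k: np.ndarray               # 2
    delta: float
    d: np.ndarray                 # genes x 2, unshrunken
    d_shrunk: np.ndarray          # genes x 2
    shrunken_centroids: np.ndarray  # genes x 2
    priors: np.ndarray            # 2, sums to 1

    @property
    def n_active_genes(self) -> int:
        return int(np.any(self.d_shrunk != 0, axis=1).sum())


def _class_arrays(X: ExpressionMatrix, y: GroupLabels) -> tuple[np.ndarray, np.ndarray]:
    labels = y.labels_for(X.sample_ids)
    return X.values, labels


def fit_nsc(X: ExpressionMatrix, y: GroupLabels, delta: float = 0.0) -> NSCModel:
    """Fit the shrunken-centroid model on training data at threshold delta.

    Pooled within-class variance uses n - 2 degrees of freedom; s0 is the
    median pooled sd across genes; m_k = sqrt(1/n_k - 1/n); priors are the
    empirical class frequencies. delta = 0 reproduces the plain class
    centroids.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    V, lab = _class_arrays(X, y)
    n = V.shape[1]
    n_k = np.array([(lab == 0).sum(), (lab == 1).sum()])
    if n_k.min() < 2:
        raise ValueError(
            f"each class needs >= 2 training samples (got control={n_k[0]}, "
            f"case={n_k[1]})"
        )
    centroids = np.stack(
        [V[:, lab == 0].mean(axis=1), V[:, lab == 1].mean(axis=1)], axis=1
    )
    overall = V.mean(axis=1)
    ss = sum(
        ((V[:, lab == k] - centroids[:, [k]]) ** 2).sum(axis=1) for k in (0, 1)
    )
    pooled_sd = np.sqrt(ss / (n - 2))
    s0 = float(np.median(pooled_sd))
    m_k = np.sqrt(1.0 / n_k - 1.0 / n)
    denom = m_k[None, :] * (pooled_sd + s0)[:, None]
    d = (centroids - overall[:, None]) / denom
    d_shrunk = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
    shrunken = overall[:, None] + denom * d_shrunk
    return NSCModel(
        classes=_CLASSES,
        class_centroids=centroids,
        overall_centroid=overall,
        pooled_sd=pooled_sd,
        s0=s0,
        m_k=m_k,
        delta=float(delta),
        d=d,
        d_shrunk=d_shrunk,
        shrunken_centroids=shrunken,
        priors=n_k / n,
    )


def _discriminant(model: NSCModel, V: np.ndarray) -> np.ndarray:
    """delta_k(x) = sum_i (x_i - centroid'_ik)^2/(s_i+s0)^2 - 2 log pi_k.

    ``V`` is genes x samples; returns samples x 2 scores (smaller is better).
    """
    scale = (model.pooled_sd + model.s0)[:, None]
    scores = np.empty((V.shape[1], 2))
    for k in (0, 1):
        resid = (V - model.shrunken_centroids[:, [k]]) / scale
        scores[:, k] = (resid ** 2).sum(axis=0) - 2.0 * np.log(model.priors[k])
    return scores


def predict_nsc(model: NSCModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Classify samples (columns of a genes x samples array).

    Returns (labels, scores): labels 0 = control / 1 = case (argmin of the
    discriminant; exact ties go to control), scores the samples x 2
    discriminant values.
    """
    V = np.atleast_2d(np.asarray(X, dtype=float))
    if V.ndim == 2 and V.shape[0] != model.overall_centroid.size:
        if V.shape[1] == model.overall_centroid.size and V.shape[0] != V.shape[1]:
            V = V.T  # accept a single sample given as a row vector
        else:
            raise ValueError("sample dimension does not match model gene count")
    scores = _discriminant(model, V)
    labels = np.where(scores[:, 1] < scores[:, 0], 1, 0)
    return labels, scores


def _delta_grid(X: ExpressionMatrix, y: GroupLabels, n_points: int = 30) -> np.ndarray:
    full = fit_nsc(X, y, delta=0.0)
    return np.linspace(0.0, float(np.abs(full.d).max()), n_points)


def _sorted_by_id(X: ExpressionMatrix, y: GroupLabels) -> tuple[ExpressionMatrix, GroupLabels]:
    """Canonical sample order (sorted IDs) so CV folds attach to IDs, not positions."""
    order = sorted(X.sample_ids)
    return X.subset_samples(order), y


def cv_select_delta(
    X: ExpressionMatrix,
    y: GroupLabels,
    delta_grid: np.ndarray | None = None,
    folds: int = 10,
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Choose the shrinkage threshold by stratified k-fold cross-validation.

    The CV misclassification error is computed for each delta on a common
    fold split; the returned delta_star is the LARGEST delta achieving the
    minimal error (the most parsimonious model at equal error).
    """
    X, y = _sorted_by_id(X, y)
    lab = y.labels_for(X.sample_ids)
    if min((lab == 0).sum(), (lab == 1).sum()) < 2:
        raise ValueError("minority class smaller than 2: cannot cross-validate")
    if delta_grid is None:
        delta_grid = _delta_grid(X, y)
    delta_grid = np.asarray(delta_grid, dtype=float)
    n_splits = min(folds, int(min((lab == 0).sum(), (lab == 1).sum())))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed % (2**32))
    errors = np.zeros(delta_grid.size)
    for train_idx, test_idx in skf.split(np.zeros(len(lab)), lab):
        X_tr = X.subset_samples([X.sample_ids[i] for i in train_idx])
        base = fit_nsc(X_tr, y, delta=0.0)
        V_te = X.values[:, test_idx]
        truth = lab[test_idx]
        denom = base.m_k[None, :] * (base.pooled_sd + base.s0)[:, None]
        for j, delta in enumerate(delta_grid):
            d_shrunk = np.sign(base.d) * np.maximum(np.abs(base.d) - delta, 0.0)
            model = NSCModel(
                classes=base.classes, class_centroids=base.class_centroids,
                overall_centroid=base.overall_centroid, pooled_sd=base.pooled_sd,
                s0=base.s0, m_k=base.m_k, delta=float(delta), d=base.d,
                d_shrunk=d_shrunk,
                shrunken_centroids=base.overall_centroid[:, None] + denom * d_shrunk,
                priors=base.priors,
            )
            pred, _ = predict_nsc(model, V_te)
            errors[j] += int((pred != truth).sum())
    errors /= len(lab)
    best = errors.min()
    delta_star = float(delta_grid[np.where(errors == best)[0].max()])
    curve = pd.DataFrame({"delta": delta_grid, "cv_error": errors})
    return delta_star, curve


@dataclass
class CVReport:
    """Repeated cross-validation performance of a signature.

    ``per_repeat`` has one row per repeat with the pooled confusion matrix
    (positive class = the declared positive group) and the four metrics;
    ``summary`` holds their means and standard deviations across repeats.
    """

    per_repeat: pd.DataFrame
    summary: pd.DataFrame

    def to_json(self, path) -> None:
        payload = {
            "per_repeat": self.per_repeat.to_dict(orient="records"),
            "summary": {
                m: {"mean": float(self.summary.loc[m, "mean"]),
                    "sd": float(self.summary.loc[m, "sd"])}
                for m in self.summary.index
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def to_tsv(self, path) -> None:
        rows = self.per_repeat.copy()
        rows.to_csv(path, sep="\t", index=False)


def _metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    def safe(a, b):
        return a / b if b else 0.0

    return {
        "sensitivity": safe(tp, tp + fn),
        "specificity": safe(tn, tn + fp),
        "precision": safe(tp, tp + fp),
        "accuracy": safe(tp + tn, tp + fp + tn + fn),
    }


def evaluate_signature(
    X: ExpressionMatrix,
    y: GroupLabels,
    repeats: int = 10,
    folds: int = 10,
    seed: int = 0,
) -> CVReport:
    """Repeated stratified k-fold cross-validation of the signature classifier.

    Per repeat r: samples are split into stratified folds (seeded by
    seed + r); for each split the shrinkage threshold is chosen by an inner
    cross-validation on the training portion, the model refit at that
    threshold, and the held-out fold predicted; the repeat's test predictions
    pool into one confusion matrix. Metrics use the declared positive group
    (default: case) as positive.
    """
    X, y = _sorted_by_id(X, y)
    lab = y.labels_for(X.sample_ids)
    positive = 1 if y.positive_group == "case" else 0
    rows = []
    for r in range(repeats):
        rep_seed = (seed + r) % (2**31)
        n_splits = min(folds, int(min((lab == 0).sum(), (lab == 1).sum())))
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=rep_seed)
        tp = fp = tn = fn = 0
        deltas = []
        for train_idx, test_idx in skf.split(np.zeros(len(lab)), lab):
            train_ids = [X.sample_ids[i] for i in train_idx]
            X_tr = X.subset_samples(train_ids)
            delta_star, _ = cv_select_delta(X_tr, y, folds=folds, seed=rep_seed)
            deltas.append(delta_star)
            model = fit_nsc(X_tr, y, delta=delta_star)
            pred, _ = predict_nsc(model, X.values[:, test_idx])
            truth = lab[test_idx]
            tp += int(((pred == positive) & (truth == positive)).sum())
            fp += int(((pred == positive) & (truth != positive)).sum())
            tn += int(((pred != positive) & (truth != positive)).sum())
            fn += int(((pred != positive) & (truth == positive)).sum())
        m = _metrics(tp, fp, tn, fn)
        rows.append(
            {"repeat": r, "TP": tp, "FP": fp, "TN": tn, "FN": fn,
             "chosen_delta": float(np.median(deltas)), **m}
        )
        logger.info("CV repeat %d: accuracy %.3f", r, m["accuracy"])
    per_repeat = pd.DataFrame(rows)
    metrics = ["sensitivity", "specificity", "precision", "accuracy"]
    summary = pd.DataFrame(
        {"mean": per_repeat[metrics].mean(), "sd": per_repeat[metrics].std(ddof=1)}
    )
    summary.index.name = "metric"
    return CVReport(per_repeat=per_repeat, summary=summary)
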