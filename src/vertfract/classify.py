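"""Normal-vs-fractured classification: k-nearest neighbors and linear
soft-margin SVM, plus the train/test-split grid-search protocol.

KNN votes among the k Euclidean-nearest training rows; the posterior for a
class is its fraction among those neighbors, and distance ties are broken by
lower training-row index so predictions are deterministic.  The SVM
minimizes the standard primal 1/2 ||w||^2 + C sum_i hinge(y_i (w.x_i + b));
the decision rule is sign(w.x + b) with 0 mapped to the positive class.

Both classifiers are scale sensitive, so the grid search z-scores every
feature using training-partition statistics only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .balance import LabeledDataset, smote
from .evaluate import cls_metrics, confusion

__all__ = [
    "KnnConfig", "SvmModel", "knn_predict", "svm_train", "svm_predict",
    "grid_search", "evaluate_split", "stratified_split", "Standardizer", "select_C",
]


@dataclass(frozen=True)
class KnnConfig:
    k: int = 3

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class SvmModel:
    """Trained linear soft-margin SVM in standardized feature space."""

    w: np.ndarray
    b: float
    C_reg: float
    support_flags: np.ndarray    # training rows with |w.x + b| <= 1 + tol
    objective: float             # primal value at the solution


@dataclass
class Standardizer:
    """Per-feature z-scoring with statistics frozen on the training split."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        sd = X.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        return cls(mean=X.mean(axis=0), sd=sd)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd


def knn_predict(train: LabeledDataset, query_vectors: np.ndarray,
                config: KnnConfig) -> tuple[np.ndarray, np.ndarray]:
    """Majority vote among the k nearest training rows.

    Returns predicted labels and the posterior P(fractured | x) as the
    fraction of fractured neighbors.  Label ties (even k) go to the lower
    class index; distance ties prefer the lower training-row index.
    """
    X = train.features
    y = train.labels
    if len(train) == 0:
        raise ValueError("empty training set")
    if config.k > len(train):
        raise ValueError("k exceeds training-set size")
    Q = np.atleast_2d(np.asarray(query_vectors, dtype=float))
    if Q.shape[1] != X.shape[1]:
        raise ValueError(f"dimension mismatch: train d={X.shape[1]}, query d={Q.shape[1]}")
    d2 = np.sum((Q[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    # stable argsort keeps lower row index first on exact distance ties
    order = np.argsort(d2, axis=1, kind="stable")[:, :config.k]
    votes = y[order]
    posterior = votes.mean(axis=1)
    labels = (posterior > 0.5).astype(int)
    return labels, posterior


def svm_train(train: LabeledDataset, C_reg: float = 1.0, tol: float = 1e-6,
              max_iter: int = 100_000, seed: int = 0) -> SvmModel:
    """Fit the linear soft-margin SVM primal.

    The quadratic program is solved through its dual (libsvm's SMO); the
    returned model carries the primal objective so independent solvers can
    check it.  Deterministic for a fixed training set.
    """
    X = train.features
    y = train.labels
    if len(np.unique(y)) < 2:
        raise ValueError("SVM needs both classes present in training data")
    clf = SVC(kernel="linear", C=C_reg, tol=tol, max_iter=max_iter,
              random_state=seed)
    clf.fit(X, y)
    w = clf.coef_.ravel().copy()
    b = float(clf.intercept_[0])
    margins = X @ w + b
    y_signed = np.where(y == 1, 1.0, -1.0)
    hinge = np.maximum(0.0, 1.0 - y_signed * margins)
    objective = 0.5 * float(w @ w) + C_reg * float(hinge.sum())
    support = np.abs(margins) <= 1.0 + 1e-6
    return SvmModel(w=w, b=b, C_reg=C_reg, support_flags=support, objective=objective)


def svm_predict(model: SvmModel, query_vectors: np.ndarray) -> np.ndarray:
    """sign(w.x + b); a point exactly on the hyperplane goes to class 1."""
    Q = np.atleast_2d(np.asarray(query_vectors, dtype=float))
    return (Q @ model.w + model.b >= 0).astype(int)


def stratified_split(dataset: LabeledDataset, train_fraction: float,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified train/test index split."""
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in np.unique(dataset.labels):
        idx = np.flatnonzero(dataset.labels == cls)
        rng.shuffle(idx)
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    tr = np.sort(np.concatenate(train_idx))
    te = np.sort(np.concatenate(test_idx))
    if len(np.unique(dataset.labels[tr])) < 2 or len(np.unique(dataset.labels[te])) < 2:
        raise ValueError("split leaves a class empty")
    return tr, te


def select_C(train: LabeledDataset, C_grid=(0.01, 0.1, 1.0, 10.0, 100.0),
             n_folds: int = 5, seed: int = 0) -> float:
    """Pick the regularization weight by stratified k-fold CV accuracy on the
    training split; ties go to the smaller C."""
    rng = np.random.default_rng(seed)
    y = train.labels
    folds = np.zeros(len(train), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % n_folds
    best_C, best_acc = C_grid[0], -1.0
    for C in C_grid:
        correct = total = 0
        for f in range(n_folds):
            tr, te = np.flatnonzero(folds != f), np.flatnonzero(folds == f)
            if len(np.unique(y[tr])) < 2 or te.size == 0:
                continue
            model = svm_train(train.subset(tr), C_reg=C)
            pred = svm_predict(model, train.features[te])
            correct += int(np.sum(pred == y[te]))
            total += te.size
        acc = correct / total if total else 0.0
        if acc > best_acc + 1e-12:
            best_C, best_acc = C, acc
    return best_C


SPLIT_FRACTIONS = (0.3, 0.4, 0.5, 0.6, 0.7, 0.8)
K_VALUES = (3, 5, 7, 9, 11)


def evaluate_split(dataset: LabeledDataset, train_fraction: float, seed: int,
                   smote_ratio: float | None = 1.0, k_values=K_VALUES,
                   C_grid=(0.01, 0.1, 1.0, 10.0, 100.0)):
    """Evaluate one seeded stratified split: SMOTE-balanced training side,
    z-scored features, KNN per k plus the CV-tuned linear SVM.

    Returns ``[(classifier, hyperparameter, ClsMetrics), ...]``."""
    tr_idx, te_idx = stratified_split(dataset, train_fraction, seed=seed)
    train, test = dataset.subset(tr_idx), dataset.subset(te_idx)
    std = Standardizer.fit(train.features)
    train_s = LabeledDataset(std.transform(train.features), train.labels,
                             train.case_ids, list(train.provenance))
    if smote_ratio is not None:
        counts = np.bincount(train_s.labels, minlength=2)
        k_sm = min(5, counts.min() - 1)
        if counts.min() / counts.max() < smote_ratio and k_sm >= 1:
            train_s = smote(train_s, k_neighbors=k_sm, target_ratio=smote_ratio, seed=seed)
    Xte = std.transform(test.features)
    rows = []
    for k in k_values:
        pred, _ = knn_predict(train_s, Xte, KnnConfig(k=k))
        m = cls_metrics(confusion(pred, test.labels))
        rows.append(("knn", k, m))
    C = select_C(train_s, C_grid=C_grid, seed=seed)
    model = svm_train(train_s, C_reg=C)
    pred = svm_predict(model, Xte)
    m = cls_metrics(confusion(pred, test.labels))
    rows.append(("svm", "linear", m))
    return rows


def grid_search(dataset: LabeledDataset, k_values=K_VALUES,
                split_fractions=SPLIT_FRACTIONS,
                C_grid=(0.01, 0.1, 1.0, 10.0, 100.0),
                n_seeds: int = 1, seed: int = 0,
                smote_ratio: float | None = 1.0) -> pd.DataFrame:
    """Run every (classifier, hyperparameter, train fraction) cell.

    Each cell draws a seeded stratified split at the stated fraction,
    balances the training side with SMOTE, z-scores with training statistics,
    and reports accuracy / precision / recall / F-measure in percent.  With
    ``n_seeds > 1`` cells are averaged over seeds and the dispersion (sd over
    seeds) is reported.  An ``Average`` row per classifier arm is the
    arithmetic mean over split fractions.
    """
    records: list[dict] = []
    for frac in split_fractions:
        per_seed: dict[tuple, list] = {}
        for s in range(n_seeds):
            for clf, hp, m in evaluate_split(dataset, frac, seed + s,
                                             smote_ratio, k_values, C_grid):
                per_seed.setdefault((clf, hp), []).append(m)
        for (clf, hp), ms in per_seed.items():
            acc = np.array([m.accuracy for m in ms])
            records.append({
                "classifier": clf, "hyperparameter": hp,
                "split": f"{int(frac * 100)}-{int(100 - frac * 100)}",
                "train_fraction": frac,
                "accuracy": float(np.mean(acc)),
                "precision": float(np.mean([m.precision for m in ms])),
                "recall": float(np.mean([m.recall for m in ms])),
                "f_measure": float(np.mean([m.f1 for m in ms])),
                "accuracy_sd": float(np.std(acc, ddof=1)) if len(acc) > 1 else 0.0,
            })
    df = pd.DataFrame(records)
    avg_rows = []
    for (clf, hp), grp in df.groupby(["classifier", "hyperparameter"]):
        avg_rows.append({
            "classifier": clf, "hyperparameter": hp, "split": "Average",
            "train_fraction": np.nan,
            "accuracy": grp["accuracy"].mean(),
            "precision": grp["precision"].mean(),
            "recall": grp["recall"].mean(),
            "f_measure": grp["f_measure"].mean(),
            "accuracy_sd": np.nan,
        })
    return pd.concat([df, pd.DataFrame(avg_rows)], ignore_index=True)
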