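"""SVM recursive feature elimination with a cross-validated error curve.

Features (genes) are repeatedly ranked by the squared weights |w|² of a
linear max-margin classifier; the lowest-weight features are discarded
and the model refitted until none remain. The elimination order defines
the importance ranking (rank 1 = removed last = most informative). A
stratified k-fold cross-validation error curve over the top-k feature
prefixes selects the optimal feature count k* (smallest k at the minimum
mean error), and the key genes are the top k* of the ranking.

Ranking uses a linear kernel — the weight vector w only exists for linear
decision functions — while the cross-validation classifier kernel is
configurable (linear default, RBF available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = ["RFERanking", "CVCurve", "rfe_rank", "cv_error_curve", "select_key_features"]


@dataclass
class RFERanking:
    """Backward-elimination record: first-removed … last-removed."""

    elimination_order: list[str]
    rank: pd.Series  # feature -> 1-based rank; 1 = most informative (last removed)
    criteria: dict[str, float]  # feature -> w² at its removal iteration


@dataclass
class CVCurve:
    k: list[int]
    mean_error: list[float]
    fold_errors: list[list[float]]
    k_star: int

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"k": self.k, "mean_error": self.mean_error})
        for i in range(len(self.fold_errors[0])):
            frame[f"fold_{i}"] = [fe[i] for fe in self.fold_errors]
        return frame


def _standardize(train: np.ndarray, other: np.ndarray | None = None):
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    z_train = (train - mu) / sd_safe
    if other is None:
        return z_train, sd
    return z_train, (other - mu) / sd_safe, sd


def _binary_labels(y: np.ndarray) -> np.ndarray:
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    return (y == classes[1]).astype(int)


def rfe_rank(
    X: pd.DataFrame,
    y: np.ndarray,
    step: int = 1,
    C: float = 1.0,
    seed: int = 0,
) -> RFERanking:
    """Rank features by backward elimination on linear-SVM squared weights.

    At each iteration the surviving features are standardized (training
    mean/sd), a linear SVM is fitted, and the ``step`` features with the
    smallest w² are removed (ties: larger column index removed first).
    Constant features get criterion 0 and therefore leave earliest.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    y01 = _binary_labels(np.asarray(y))
    if min(np.bincount(y01)) < 2:
        raise ValueError("need at least 2 samples per class")
    features = list(X.columns)
    values = X.to_numpy(dtype=float)
    surviving = list(range(len(features)))
    eliminated: list[int] = []
    criteria: dict[str, float] = {}
    while surviving:
        if len(surviving) == 1:
            criteria.setdefault(features[surviving[0]], 0.0)
            eliminated.append(surviving.pop())
            break
        sub = values[:, surviving]
        z, sd = _standardize(sub)
        model = SVC(kernel="linear", C=C, random_state=seed)
        model.fit(z, y01)
        w2 = np.asarray(model.coef_).ravel() ** 2
        w2 = np.where(sd > 0, w2, 0.0)  # constant features carry no signal
        # remove the `step` smallest-criterion features; ties -> larger index first
        order = sorted(range(len(surviving)), key=lambda j: (w2[j], -j))
        to_remove = sorted(order[: min(step, len(surviving))], key=lambda j: -j)
        for j in to_remove:
            col = surviving[j]
            criteria[features[col]] = float(w2[j])
            eliminated.append(col)
            surviving.pop(j)
    order_names = [features[i] for i in eliminated]
    n = len(order_names)
    rank = pd.Series(
        {name: n - pos for pos, name in enumerate(order_names)}, name="rank"
    ).loc[features]
    return RFERanking(order_names, rank, criteria)


def cv_error_curve(
    X: pd.DataFrame,
    y: np.ndarray,
    ranking: RFERanking,
    n_folds: int = 5,
    kernel: str = "linear",
    C: float = 1.0,
    seed: int = 0,
) -> CVCurve:
    """Stratified k-fold misclassification error of the top-k feature prefixes.

    Standardization parameters are estimated inside each training fold only.
    k* is the smallest k attaining the minimum mean error.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    y01 = _binary_labels(np.asarray(y))
    if min(np.bincount(y01)) < n_folds:
        raise ValueError("each class needs at least n_folds samples for stratified CV")
    ordered = ranking.rank.sort_values().index.tolist()  # rank 1 first
    values = X[ordered].to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(values, y01))
    ks = list(range(1, len(ordered) + 1))
    mean_err, fold_errs = [], []
    for k in ks:
        errs = []
        for train_idx, test_idx in folds:
            z_train, z_test, _ = _standardize(
                values[np.ix_(train_idx, range(k))], values[np.ix_(test_idx, range(k))]
            )
            model = SVC(kernel=kernel, C=C, random_state=seed)
            model.fit(z_train, y01[train_idx])
            pred = model.predict(z_test)
            errs.append(float(np.mean(pred != y01[test_idx])))
        fold_errs.append(errs)
        mean_err.append(float(np.mean(errs)))
    k_star = ks[int(np.argmin(mean_err))]  # argmin takes the first (smallest k) on ties
    return CVCurve(ks, mean_err, fold_errs, k_star)


def select_key_features(
    X: pd.DataFrame,
    y: np.ndarray,
    curve: CVCurve,
    ranking: RFERanking,
    kernel: str = "linear",
    C: float = 1.0,
    seed: int = 0,
) -> tuple[list[str], dict]:
    """Top-k* features plus a final whole-data refit summary.

    Returns (key feature list, summary) where the summary reports the
    training accuracy of the refitted classifier and the cross-validated
    accuracy at k* from the curve.
    """
    ordered = ranking.rank.sort_values().index.tolist()
    keys = ordered[: curve.k_star]
    y01 = _binary_labels(np.asarray(y))
    z, _ = _standardize(X[keys].to_numpy(dtype=float))
    model = SVC(kernel=kernel, C=C, random_state=seed)
    model.fit(z, y01)
    train_acc = float(np.mean(model.predict(z) == y01))
    cv_acc = 1.0 - curve.mean_error[curve.k.index(curve.k_star)]
    summary = {
        "k_star": curve.k_star,
        "train_accuracy": train_acc,
        "cv_accuracy": float(cv_acc),
        "min_cv_error": float(min(curve.mean_error)),
    }
    return keys, summary
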