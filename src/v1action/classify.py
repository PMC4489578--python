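"""SVM classification of action codes under subject-safe protocols.

Three evaluation protocols mirror common action-recognition practice:
leave-one-subject-out cross-validation; repeated random subject splits;
and a small fixed number of random-split trials.  Splits always
partition *subjects* — no subject's sequences may straddle train and
test.  The classifier is a Gaussian-kernel (RBF) SVM, one-vs-rest, with
the kernel width set by the median pairwise-distance heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.svm import SVC

__all__ = ["EvalProtocol", "ClassifyResult", "fit_predict", "median_gamma"]


@dataclass
class EvalProtocol:
    """mode: 'loocv' (leave-one-subject-out), 'random_split', 'trials'.

    train_fraction and n_trials apply to the random modes; seed makes
    every split reproducible."""

    mode: str = "loocv"
    train_fraction: float = 0.64
    n_trials: int = 100
    seed: int = 0


@dataclass
class ClassifyResult:
    arr: float                    # average recognition rate over trials, %
    confusion: np.ndarray         # rows = predicted class, cols = true
    classes: list[str]
    per_trial: list[float]


def median_gamma(X: np.ndarray) -> float:
    """RBF gamma from the median heuristic: 1 / (2 * median^2) of pairwise
    Euclidean distances."""
    d = pdist(X)
    med = float(np.median(d[d > 0])) if np.any(d > 0) else 1.0
    return 1.0 / (2.0 * med * med)


def _splits(subjects: np.ndarray, protocol: EvalProtocol):
    uniq = np.unique(subjects)
    if uniq.size < 2:
        raise ValueError("need at least 2 subjects to form a split")
    if protocol.mode == "loocv":
        for s in uniq:
            yield subjects != s, subjects == s
    elif protocol.mode in ("random_split", "trials"):
        rng = np.random.default_rng(protocol.seed)
        n_train = max(int(round(protocol.train_fraction * uniq.size)), 1)
        n_train = min(n_train, uniq.size - 1)
        for _ in range(protocol.n_trials):
            train_subj = rng.choice(uniq, size=n_train, replace=False)
            tr = np.isin(subjects, train_subj)
            yield tr, ~tr
    else:
        raise ValueError(f"unknown protocol mode {protocol.mode!r}")


def fit_predict(X: np.ndarray, labels: list[str], subjects: list[str],
                protocol: EvalProtocol | None = None, C: float = 10.0,
                gamma: float | str = "median") -> ClassifyResult:
    """Train/evaluate the RBF SVM under a subject-partitioned protocol.

    Returns the average recognition rate (percent) and a confusion matrix
    whose rows are the predicted class and columns the true class,
    accumulated over all trials.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(labels)
    subj = np.asarray(subjects)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    protocol = protocol or EvalProtocol()
    if gamma == "median":
        gamma = median_gamma(X)
    idx = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=np.int64)
    per_trial = []
    for tr, te in _splits(subj, protocol):
        if set(subj[tr]) & set(subj[te]):
            raise RuntimeError("subject leakage between train and test")
        if len(set(y[tr])) < 2:
            continue
        clf = SVC(kernel="rbf", C=C, gamma=gamma,
                  decision_function_shape="ovr")
        clf.fit(X[tr], y[tr])
        pred = clf.predict(X[te])
        per_trial.append(100.0 * float(np.mean(pred == y[te])))
        for p, t in zip(pred, y[te]):
            confusion[idx[p], idx[t]] += 1
    if not per_trial:
        raise ValueError("no valid trial produced a score")
    return ClassifyResult(arr=float(np.mean(per_trial)), confusion=confusion,
                          classes=classes, per_trial=per_trial)
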