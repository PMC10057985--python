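"""Soft-margin SVM classification, delegated to scikit-learn's SVC.

The contract here is the decision-function semantics — a deterministic
kernel classifier fitted on preprocessed training spectra — not a bespoke
quadratic-programming solver.  Defaults are an RBF kernel with C = 1 and
gamma = 1/(P·var(X)) (scikit-learn's "scale"), since the field rarely
reports kernel choices; a small grid-search helper is provided but off by
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from ..errors import ParameterError
from ..spectra import SpectrumSet


@dataclass
class SVMModel:
    kernel: str
    C: float
    gamma: object
    classes: list
    _clf: SVC


def _matrix(X) -> np.ndarray:
    return X.absorbance if isinstance(X, SpectrumSet) else np.asarray(X, float)


def fit_svm(X: SpectrumSet | np.ndarray, labels, kernel: str = "rbf",
            C: float = 1.0, gamma="scale") -> SVMModel:
    if kernel not in ("rbf", "linear"):
        raise ParameterError(f"kernel must be rbf or linear, got {kernel!r}")
    if C <= 0:
        raise ParameterError("C must be positive")
    if isinstance(gamma, (int, float)) and gamma <= 0:
        raise ParameterError("gamma must be positive")
    labels = np.asarray(labels, dtype=object)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ParameterError("SVM training requires exactly two classes")
    clf = SVC(kernel=kernel, C=C, gamma=gamma)
    clf.fit(_matrix(X), labels.astype(str))
    return SVMModel(kernel, C, gamma, classes, clf)


def predict_svm(m: SVMModel, X: SpectrumSet | np.ndarray) -> np.ndarray:
    return m._clf.predict(_matrix(X)).astype(object)


def grid_search_svm(X, labels, Cs=(0.1, 1.0, 10.0, 100.0),
                    gammas=("scale", 0.01, 0.001), kernel: str = "rbf",
                    n_folds: int = 5, seed: int = 0) -> dict:
    """Small CV grid search over (C, gamma); returns the best settings."""
    Xm = _matrix(X)
    labels = np.asarray(labels, dtype=object)
    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(Xm.shape[0]), n_folds)
    best = {"C": None, "gamma": None, "cv_accuracy": -1.0}
    for C in Cs:
        for g in gammas:
            correct = total = 0
            for fold in folds:
                mask = np.ones(Xm.shape[0], bool)
                mask[fold] = False
                if len(set(labels[mask].tolist())) < 2:
                    continue
                m = fit_svm(Xm[mask], labels[mask], kernel=kernel, C=C, gamma=g)
                correct += int(np.sum(predict_svm(m, Xm[fold]) == labels[fold]))
                total += fold.size
            acc = correct / total if total else 0.0
            if acc > best["cv_accuracy"]:
                best = {"C": C, "gamma": g, "cv_accuracy": acc}
    return best
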