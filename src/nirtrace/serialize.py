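"""JSON serialization of fitted models and pipelines.

Every fitted object round-trips through a documented, human-readable JSON
file: a ``type`` tag plus the object's numeric state as nested lists.
Loaded models reproduce their predictions exactly (the SVM is restored from
its decision-function state — support vectors, dual coefficients, bias —
not by refitting).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .models.plsr import PLSRModel
from .models.simca import ClassSubmodel, SIMCAModel
from .models.svm import SVMModel
from .outliers import PCAOutlierModel
from .preprocess import Preprocessor, TransformStep


def _arr(x) -> list:
    return np.asarray(x).tolist()


def _encode(obj) -> dict:
    if isinstance(obj, Preprocessor):
        return {"type": "preprocessor",
                "steps": [{"kind": st.kind, "params": st.params,
                           "fitted_state": {k: _arr(v) for k, v in
                                            st.fitted_state.items()}}
                          for st in obj.steps]}
    if isinstance(obj, PLSRModel):
        return {"type": "plsr", "n_components": obj.n_components,
                "weights": _arr(obj.weights), "x_loadings": _arr(obj.x_loadings),
                "y_loadings": _arr(obj.y_loadings), "x_scores": _arr(obj.x_scores),
                "coefficients": _arr(obj.coefficients),
                "x_center": _arr(obj.x_center), "y_center": obj.y_center}
    if isinstance(obj, SIMCAModel):
        return {"type": "simca", "alpha": obj.alpha,
                "submodels": {str(c): {
                    "label": str(c), "center": _arr(sub.center),
                    "loadings": _arr(sub.loadings),
                    "score_variances": _arr(sub.score_variances),
                    "k": sub.k, "n_train": sub.n_train,
                    "s0_sq": sub.s0_sq, "f_limit": sub.f_limit}
                    for c, sub in obj.submodels.items()}}
    if isinstance(obj, PCAOutlierModel):
        return {"type": "pca_outlier", "loadings": _arr(obj.loadings),
                "center": _arr(obj.center),
                "score_variances": _arr(obj.score_variances),
                "residual_eigenvalues": _arr(obj.residual_eigenvalues),
                "k": obj.k, "alpha": obj.alpha, "t2_limit": obj.t2_limit,
                "q_limit": obj.q_limit, "n_train": obj.n_train}
    if isinstance(obj, SVMModel):
        clf = obj._clf
        return {"type": "svm", "kernel": obj.kernel, "C": obj.C,
                "gamma_setting": obj.gamma if isinstance(obj.gamma, str)
                else float(obj.gamma),
                "gamma_value": float(clf._gamma),
                "classes": [str(c) for c in clf.classes_],
                "support_vectors": _arr(clf.support_vectors_),
                "dual_coef": _arr(clf.dual_coef_),
                "intercept": _arr(clf.intercept_)}
    raise ParameterError(f"cannot serialize object of type {type(obj).__name__}")


def save_model(obj, path) -> None:
    Path(path).write_text(json.dumps(_encode(obj), indent=1))


class _RestoredSVM:
    """Kernel decision function rebuilt from stored state."""

    def __init__(self, d: dict):
        self.kernel = d["kernel"]
        self.gamma = d["gamma_value"]
        self.sv = np.asarray(d["support_vectors"])
        self.dual = np.asarray(d["dual_coef"])[0]
        self.b = float(np.asarray(d["intercept"])[0])
        self.classes_ = np.array(d["classes"], dtype=object)

    def _kernel(self, X: np.ndarray) -> np.ndarray:
        if self.kernel == "linear":
            return X @ self.sv.T
        d2 = (np.sum(X**2, axis=1)[:, None] + np.sum(self.sv**2, axis=1)
              - 2 * X @ self.sv.T)
        return np.exp(-self.gamma * d2)

    def predict(self, X) -> np.ndarray:
        dec = self._kernel(np.asarray(X, float)) @ self.dual + self.b
        return np.where(dec > 0, self.classes_[1], self.classes_[0])


def load_model(path):
    d = json.loads(Path(path).read_text())
    t = d["type"]
    if t == "preprocessor":
        return Preprocessor([
            TransformStep(st["kind"], st["params"],
                          {k: np.asarray(v) for k, v in
                           st["fitted_state"].items()})
            for st in d["steps"]])
    if t == "plsr":
        return PLSRModel(d["n_components"], np.asarray(d["weights"]),
                         np.asarray(d["x_loadings"]),
                         np.asarray(d["y_loadings"]),
                         np.asarray(d["x_scores"]),
                         np.asarray(d["coefficients"]),
                         np.asarray(d["x_center"]), d["y_center"])
    if t == "simca":
        subs = {c: ClassSubmodel(
            v["label"], np.asarray(v["center"]), np.asarray(v["loadings"]),
            np.asarray(v["score_variances"]), v["k"], v["n_train"],
            v["s0_sq"], v["f_limit"]) for c, v in d["submodels"].items()}
        return SIMCAModel(subs, d["alpha"])
    if t == "pca_outlier":
        return PCAOutlierModel(
            np.asarray(d["loadings"]), np.asarray(d["center"]),
            np.asarray(d["score_variances"]),
            np.asarray(d["residual_eigenvalues"]), d["k"], d["alpha"],
            d["t2_limit"], d["q_limit"], d["n_train"])
    if t == "svm":
        return _RestoredSVM(d)
    raise ParameterError(f"unknown model type tag {t!r}")
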