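"""Partial least squares regression by NIPALS, used as PLS-DA for two-class
origin discrimination.

Each factor maximizes the covariance between an X-score t = Xw (‖w‖ = 1) and
the response, followed by deflation of X with the factor's loading.  With a
single dummy-coded response (y ∈ {0, 1}) the NIPALS inner loop closes in one
pass per factor, but the general iteration is kept for robustness.  The
fitted factors collapse to a single regression vector B, and at full rank
PLSR predictions coincide with ordinary least squares.

Model quality is reported as R² and RMSE; a report flag marks the
conventional R² > 0.91 adequacy gate used in NIR origin modeling.  For
classification the continuous prediction is thresholded at 0.5 (PLS-DA).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ConvergenceError, GridError, ParameterError
from ..spectra import SpectrumSet

#: conventional adequacy gate for origin-tracing PLSR models
R2_REQUIREMENT = 0.91


@dataclass
class PLSRModel:
    n_components: int
    weights: np.ndarray      # P × A
    x_loadings: np.ndarray   # P × A
    y_loadings: np.ndarray   # A
    x_scores: np.ndarray     # N × A (training scores)
    coefficients: np.ndarray  # length P
    x_center: np.ndarray
    y_center: float


@dataclass
class RegressionReport:
    r2: float
    rmse: float

    @property
    def meets_requirement(self) -> bool:
        """Adequacy gate: R² above 0.91."""
        return self.r2 > R2_REQUIREMENT


def fit_plsr(X: SpectrumSet | np.ndarray, y, n_components: int,
             max_iter: int = 500, tol: float = 1e-12) -> PLSRModel:
    """Fit a NIPALS PLSR model with ``n_components`` latent factors."""
    Xm = X.absorbance if isinstance(X, SpectrumSet) else np.asarray(X, float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = Xm.shape
    if y.shape[0] != n:
        raise ParameterError("y length must match number of spectra")
    if not (1 <= n_components <= min(n - 1, p)):
        raise ParameterError(
            f"n_components must be in [1, min(N-1, P)] = [1, {min(n - 1, p)}]")

    x_center = Xm.mean(axis=0)
    y_center = float(y.mean())
    E = Xm - x_center
    f = y - y_center

    W = np.zeros((p, n_components))
    P_mat = np.zeros((p, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))

    for a in range(n_components):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw < 1e-300:
            raise ConvergenceError(
                f"residual X carries no covariance with y at component {a + 1}")
        w /= nw
        for _ in range(max_iter):
            t = E @ w
            tt = t @ t
            if tt == 0:
                raise ConvergenceError("zero score vector in NIPALS")
            qa = (f @ t) / tt
            u = f * qa  # univariate y: u proportional to f
            w_new = E.T @ u
            nw = np.linalg.norm(w_new)
            if nw == 0:
                break
            w_new /= nw
            if np.linalg.norm(w_new - np.sign(w_new @ w) * w) < tol:
                w = w_new
                break
            w = w_new
        t = E @ w
        tt = t @ t
        p_vec = E.T @ t / tt
        qa = (f @ t) / tt
        E = E - np.outer(t, p_vec)
        f = f - t * qa
        W[:, a], P_mat[:, a], q[a], T[:, a] = w, p_vec, qa, t

    # B = W (PᵀW)⁻¹ q  — closed form equivalent of the factor expansion
    B = W @ np.linalg.solve(P_mat.T @ W, q)
    return PLSRModel(n_components, W, P_mat, q, T, B, x_center, y_center)


def predict_plsr(m: PLSRModel, X: SpectrumSet | np.ndarray) -> np.ndarray:
    """ŷ = (X − x̄)·B + ȳ."""
    Xm = X.absorbance if isinstance(X, SpectrumSet) else np.asarray(X, float)
    if Xm.shape[1] != m.coefficients.shape[0]:
        raise GridError("spectra do not match the fitted model grid")
    return (Xm - m.x_center) @ m.coefficients + m.y_center


def predict_plsda(m: PLSRModel, X, threshold: float = 0.5) -> np.ndarray:
    """Class codes {0, 1} by thresholding the continuous prediction."""
    return (predict_plsr(m, X) >= threshold).astype(int)


def evaluate_regression(y_true, y_pred) -> RegressionReport:
    """R² = 1 − SSE/SST and RMSE, in the units of y."""
    y_true = np.asarray(y_true, float).ravel()
    y_pred = np.asarray(y_pred, float).ravel()
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ParameterError("y_true and y_pred must be equal-length, non-empty")
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    if sst == 0:
        raise ParameterError("R² undefined: y_true is constant")
    sse = float(np.sum((y_true - y_pred) ** 2))
    return RegressionReport(r2=1.0 - sse / sst,
                            rmse=float(np.sqrt(np.mean((y_true - y_pred) ** 2))))


def select_plsr_components(X, y, max_components: int = 15, n_folds: int = 10,
                           seed: int = 0) -> int:
    """Pick the component count minimizing k-fold RMSECV."""
    Xm = X.absorbance if isinstance(X, SpectrumSet) else np.asarray(X, float)
    y = np.asarray(y, dtype=float).ravel()
    n = Xm.shape[0]
    max_components = min(max_components, Xm.shape[1],
                         n - int(np.ceil(n / n_folds)) - 1)
    if max_components < 1:
        raise ParameterError("too few samples for CV component selection")
    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(n), n_folds)
    press = np.zeros(max_components)
    for fold in folds:
        if fold.size == 0:
            continue
        mask = np.ones(n, bool)
        mask[fold] = False
        m = fit_plsr(Xm[mask], y[mask], max_components)
        Ec = Xm[fold] - m.x_center
        # accumulate predictions component-by-component via the factor expansion
        t_test = np.zeros((fold.size, max_components))
        E = Ec.copy()
        for a in range(max_components):
            t_test[:, a] = E @ m.weights[:, a]
            E -= np.outer(t_test[:, a], m.x_loadings[:, a])
        pred = m.y_center + np.cumsum(t_test * m.y_loadings, axis=1)
        press += np.sum((pred - y[fold, None]) ** 2, axis=0)
    return int(np.argmin(press)) + 1
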