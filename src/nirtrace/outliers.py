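"""PCA-based outlier screening via Hotelling T² and Q residuals.

A PCA model with k components is fitted to the mean-centered absorbance
matrix.  Each sample gets two statistics: the leverage in score space
(Hotelling T², each score squared over its variance) and the squared norm of
its reconstruction residual off the PCA subspace (Q, also called SPE).  A
sample is flagged when either statistic exceeds its critical limit at
significance α (default 5%): high leverage and high residual are different
ways of being abnormal, and the screening treats them as alternatives.

Critical limits follow the classical chemometric forms: the T² limit from
the F distribution, T²_crit = k(N−1)/(N−k) · F₁₋α(k, N−k), and the Q limit
from the Jackson–Mudholkar normal approximation built on the residual
eigenvalue moments (a χ²-matching alternative is available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import GridError, ParameterError
from .spectra import SpectrumSet

logger = logging.getLogger(__name__)


@dataclass
class PCAOutlierModel:
    loadings: np.ndarray          # P × k, orthonormal columns
    center: np.ndarray            # length-P training mean spectrum
    score_variances: np.ndarray   # length-k, per-component score variance
    residual_eigenvalues: np.ndarray  # eigenvalues beyond k (for Q limit)
    k: int
    alpha: float
    t2_limit: float
    q_limit: float
    n_train: int

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ParameterError("alpha must be in (0, 1)")


def choose_k(eigenvalues: np.ndarray, cumvar: float = 0.95,
             k_max: int | None = None) -> int:
    """Smallest k whose cumulative explained variance reaches ``cumvar``."""
    ev = np.asarray(eigenvalues, dtype=float)
    total = ev.sum()
    if total <= 0:
        return 1
    frac = np.cumsum(ev) / total
    k = int(np.searchsorted(frac, cumvar) + 1)
    k = min(k, ev.size)
    if k_max is not None:
        k = min(k, k_max)
    return max(k, 1)


def _pca(a: np.ndarray):
    """Thin SVD of the centered matrix -> (center, loadings, eigenvalues)."""
    center = a.mean(axis=0)
    xc = a - center
    _, sv, vt = np.linalg.svd(xc, full_matrices=False)
    eig = sv ** 2 / (a.shape[0] - 1)   # covariance eigenvalues
    return center, vt, eig


def fit_outlier_model(s: SpectrumSet, k: int | None = None,
                      alpha: float = 0.05, cumvar: float = 0.95,
                      q_method: str = "jackson-mudholkar") -> PCAOutlierModel:
    """Fit the PCA screening model and its T²/Q critical limits.

    ``k=None`` selects the smallest k reaching ``cumvar`` cumulative
    explained variance (capped at N−2 so a residual space exists).
    """
    n = s.n_samples
    center, vt, eig = _pca(s.absorbance)
    if k is None:
        k = choose_k(eig, cumvar=cumvar, k_max=max(n - 2, 1))
    if k < 1 or k >= n:
        raise ParameterError(f"need N > k >= 1 (N={n}, k={k})")

    loadings = vt[:k].T
    score_var = eig[:k]
    resid_eig = eig[k:]

    t2_limit = k * (n - 1) / (n - k) * stats.f.ppf(1 - alpha, k, n - k)
    q_limit = _q_limit(resid_eig, alpha, q_method, total_var=float(eig.sum()))
    return PCAOutlierModel(loadings, center, score_var, resid_eig, k, alpha,
                           float(t2_limit), float(q_limit), n)


def _q_limit(resid_eig: np.ndarray, alpha: float, method: str,
             total_var: float = 0.0) -> float:
    th1 = float(np.sum(resid_eig))
    th2 = float(np.sum(resid_eig ** 2))
    th3 = float(np.sum(resid_eig ** 3))
    if th1 <= 0 or th2 <= 0 or (total_var > 0 and th1 < 1e-12 * total_var):
        # data lie exactly in the k-dim subspace: no residual variation, so
        # no sample can meaningfully exceed Q
        logger.warning("residual eigenvalue moments are zero; Q limit disabled")
        return float(np.inf)
    if method == "chi2":
        g, h = th2 / th1, th1 ** 2 / th2
        return float(g * stats.chi2.ppf(1 - alpha, h))
    if method != "jackson-mudholkar":
        raise ParameterError(f"unknown Q-limit method {method!r}")
    h0 = 1.0 - 2.0 * th1 * th3 / (3.0 * th2 ** 2)
    if h0 <= 0:
        h0 = 1e-3  # degenerate spectrum of residual eigenvalues
    c = stats.norm.ppf(1 - alpha)
    inner = (c * np.sqrt(2.0 * th2 * h0 ** 2) / th1
             + 1.0 + th2 * h0 * (h0 - 1.0) / th1 ** 2)
    if inner <= 0:
        return float(np.inf)
    return float(th1 * inner ** (1.0 / h0))


def score_samples(m: PCAOutlierModel, s: SpectrumSet
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample (T², Q).  T² sums squared scores over their training
    variances; Q is the squared reconstruction residual norm."""
    if s.n_points != m.center.shape[0]:
        raise GridError("spectra do not match the fitted model grid")
    xc = s.absorbance - m.center
    t = xc @ m.loadings
    sv = np.where(m.score_variances > 0, m.score_variances, np.inf)
    t2 = np.sum(t ** 2 / sv, axis=1)
    resid = xc - t @ m.loadings.T
    q = np.sum(resid ** 2, axis=1)
    return t2, q


def detect_outliers(s: SpectrumSet, k: int | None = None, alpha: float = 0.05,
                    cumvar: float = 0.95, q_method: str = "jackson-mudholkar"
                    ) -> tuple[np.ndarray, pd.DataFrame]:
    """Flag samples whose T² or Q exceeds its limit at significance α.

    Returns the sorted flagged indices and a per-sample report with the
    statistics and limits (written out as CSV by the drivers).
    """
    m = fit_outlier_model(s, k=k, alpha=alpha, cumvar=cumvar, q_method=q_method)
    t2, q = score_samples(m, s)
    flagged = (t2 > m.t2_limit) | (q > m.q_limit)
    report = pd.DataFrame({
        "id": s.ids,
        "t2": t2,
        "q": q,
        "t2_limit": m.t2_limit,
        "q_limit": m.q_limit,
        "flagged": flagged,
    })
    return np.flatnonzero(flagged), report
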