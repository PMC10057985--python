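"""Soft independent modeling of class analogies (SIMCA).

Each class gets its own PCA model (center, k_c orthonormal loadings, score
variances) fitted on that class's training spectra only.  A sample's
similarity to a class is its residual variance after projection onto the
class model, s² = ‖r‖²/(P − k_c), compared against the class's pooled
training residual variance s₀²_c through an F test:

    s₀²_c = Σ residuals² / ((N_c − k_c − 1)(P − k_c))
    member  ⇔  s²/s₀²_c ≤ F₁₋α(P − k_c, (N_c − k_c − 1)(P − k_c))

"Soft" means a sample may be accepted by several classes or by none; for
accuracy bookkeeping a forced-choice assignment (smallest residual ratio,
ties broken by sorted label order) is reported alongside the membership
flags.

The separability of two fitted class models is summarized by the SIMCA
model distance

    D(r, g) = sqrt[ (S²_{r→g} + S²_{g→r}) / (S²_{r→r} + S²_{g→g}) ]

where S²_{a→b} is the mean residual variance of class-a training samples
fitted to class-b's model (every term normalized per sample by P − k_b, so
D of a model against itself is exactly 1).  By convention D > 3 indicates
well-separated classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ..errors import GridError, ParameterError
from ..spectra import SpectrumSet
from ..outliers import choose_k

#: conventional model-distance threshold for "well separated"
DISTANCE_THRESHOLD = 3.0

#: cap on per-class components; after scatter correction the within-class
#: covariance is near-isotropic and an uncapped variance rule would absorb
#: most of the sample rank, leaving no residual degrees of freedom
K_CAP = 10


@dataclass
class ClassSubmodel:
    label: object
    center: np.ndarray          # length P
    loadings: np.ndarray        # P × k, orthonormal
    score_variances: np.ndarray
    k: int
    n_train: int
    s0_sq: float                # pooled training residual variance
    f_limit: float              # critical residual ratio at alpha


@dataclass
class SIMCAModel:
    submodels: dict             # label -> ClassSubmodel
    alpha: float

    @property
    def classes(self) -> list:
        return sorted(self.submodels)


def _fit_class(X: np.ndarray, label, alpha: float, k_rule) -> ClassSubmodel:
    n, p = X.shape
    center = X.mean(axis=0)
    xc = X - center
    _, sv, vt = np.linalg.svd(xc, full_matrices=False)
    eig = sv ** 2 / max(n - 1, 1)
    if isinstance(k_rule, int):
        k = k_rule
    else:  # default cumulative-variance rule with cap
        k = choose_k(eig, cumvar=0.95, k_max=min(K_CAP, n - 2))
    if not (1 <= k <= n - 2):
        raise ParameterError(
            f"class {label!r}: need N_c > k + 1 (N_c={n}, k={k})")
    if k >= p:
        raise ParameterError(f"class {label!r}: k={k} must be < P={p}")
    loadings = vt[:k].T
    scores = xc @ loadings
    resid = xc - scores @ loadings.T
    dof = (n - k - 1) * (p - k)
    s0_sq = float(np.sum(resid ** 2) / dof)
    f_limit = float(stats.f.ppf(1 - alpha, p - k, dof))
    return ClassSubmodel(label, center, loadings, sv[:k] ** 2 / max(n - 1, 1),
                         k, n, s0_sq, f_limit)


def fit_simca(X: SpectrumSet, labels=None, alpha: float = 0.05,
              k_rule="cumvar") -> SIMCAModel:
    """Fit one PCA class model per label.

    ``k_rule`` is either the string ``"cumvar"`` (default: smallest k with
    ≥ 95% cumulative explained variance, capped at min(10, N_c − 2)) or a
    fixed integer k applied to every class.
    """
    if labels is None:
        labels = X.labels
    labels = np.asarray(labels, dtype=object)
    if not (0 < alpha < 1):
        raise ParameterError("alpha must be in (0, 1)")
    submodels = {}
    for c in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == c)
        if idx.size < 4:
            raise ParameterError(f"class {c!r} too small for SIMCA (N_c={idx.size})")
        submodels[c] = _fit_class(X.absorbance[idx], c, alpha,
                                  k_rule if k_rule != "cumvar" else None)
    return SIMCAModel(submodels, alpha)


def residual_ratio(sub: ClassSubmodel, X: SpectrumSet | np.ndarray) -> np.ndarray:
    """Per-sample residual variance ratio s²/s₀² against one class model."""
    Xm = X.absorbance if isinstance(X, SpectrumSet) else np.asarray(X, float)
    if Xm.shape[1] != sub.center.shape[0]:
        raise GridError("spectra do not match the fitted class-model grid")
    xc = Xm - sub.center
    resid = xc - (xc @ sub.loadings) @ sub.loadings.T
    s_sq = np.sum(resid ** 2, axis=1) / (Xm.shape[1] - sub.k)
    return s_sq / sub.s0_sq if sub.s0_sq > 0 else np.where(s_sq > 0, np.inf, 0.0)


def simca_classify(m: SIMCAModel, X: SpectrumSet
                   ) -> tuple[np.ndarray, dict, np.ndarray]:
    """Forced-choice labels, per-class membership flags, and the ratio matrix.

    Assigned label = class with the smallest residual ratio (first class in
    sorted order on exact ties); membership flag = ratio ≤ class F limit.
    """
    classes = m.classes
    ratios = np.column_stack([residual_ratio(m.submodels[c], X) for c in classes])
    best = np.argmin(ratios, axis=1)  # argmin takes the first minimum: tie-break
    assigned = np.array([classes[i] for i in best], dtype=object)
    membership = {c: ratios[:, j] <= m.submodels[c].f_limit
                  for j, c in enumerate(classes)}
    return assigned, membership, ratios


def _mean_residual_variance(sub: ClassSubmodel, X: np.ndarray) -> float:
    xc = X - sub.center
    resid = xc - (xc @ sub.loadings) @ sub.loadings.T
    return float(np.mean(np.sum(resid ** 2, axis=1)) / (X.shape[1] - sub.k))


def simca_model_distance(sub_r: ClassSubmodel, sub_g: ClassSubmodel,
                         X_r: SpectrumSet | np.ndarray,
                         X_g: SpectrumSet | np.ndarray) -> float:
    """Inter-model distance D(r, g); symmetric, D = 1 for identical
    data/models, and > 3 conventionally flags well-separated classes.

    Kept as the single authoritative definition so an alternative reading of
    the distance can be swapped in one place.
    """
    Xr = X_r.absorbance if isinstance(X_r, SpectrumSet) else np.asarray(X_r, float)
    Xg = X_g.absorbance if isinstance(X_g, SpectrumSet) else np.asarray(X_g, float)
    if Xr.shape[1] != sub_r.center.shape[0] or Xg.shape[1] != sub_g.center.shape[0]:
        raise GridError("class data do not match the fitted model grids")
    s_rg = _mean_residual_variance(sub_g, Xr)   # class r fitted to model g
    s_gr = _mean_residual_variance(sub_r, Xg)   # class g fitted to model r
    s_rr = _mean_residual_variance(sub_r, Xr)
    s_gg = _mean_residual_variance(sub_g, Xg)
    denom = s_rr + s_gg
    if denom <= 0:
        raise ParameterError(
            "both class models fit their data exactly; distance undefined")
    return float(np.sqrt((s_rg + s_gr) / denom))


def is_separable(distance: float) -> bool:
    """The conventional D > 3 separability flag."""
    return distance > DISTANCE_THRESHOLD
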