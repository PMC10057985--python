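"""Spectral pretreatment operators and ordered pipelines.

The suite covers the nine classical single pretreatments used in NIR
chemometrics — mean centering, area normalization, first and second
derivative, Savitzky–Golay smoothing, MSC, SNV, OSC and baseline
correction — plus polynomial detrending for use in combinations such as
``SNV + detrend``.  Order matters and is taken literally: ``snv`` then
``detrend`` is a different operator than ``detrend`` then ``snv``.

Operators split into two families:

* **stateless** (snv, derivatives, S-G smoothing, baseline, detrend,
  area normalization) act row-by-row with no learned quantities;
* **stateful** (msc, osc, mean_center) learn statistics on the training
  set and replay them on test spectra, so no information flows from test
  to train.

The :class:`Preprocessor` chains fitted steps and guarantees exact replay:
applying a fitted pipeline to its own training data reproduces the matrix
produced during fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import numpy as np
from scipy.signal import savgol_filter

from .errors import (ConvergenceError, DegenerateFitError,
                     DegenerateSpectrumError, ParameterError,
                     PipelineStepError)
from .spectra import SpectrumSet

STATEFUL_KINDS = {"msc", "osc", "mean_center"}
STATELESS_KINDS = {"snv", "deriv1", "deriv2", "sg_smooth", "baseline",
                   "detrend", "area_norm"}
ALL_KINDS = STATEFUL_KINDS | STATELESS_KINDS


# ---------------------------------------------------------------- stateless

def snv(s: SpectrumSet) -> SpectrumSet:
    """Standard normal variate: per-spectrum centering and unit scaling.

    Each row x becomes (x − mean(x)) / sd(x) with the sample standard
    deviation (denominator P − 1), removing multiplicative scatter gain and
    additive offset.  A zero-variance spectrum cannot be scaled.
    """
    a = s.absorbance
    mu = a.mean(axis=1, keepdims=True)
    sd = a.std(axis=1, ddof=1, keepdims=True)
    flat = np.where(sd[:, 0] == 0)[0]
    if flat.size:
        raise DegenerateSpectrumError(
            f"zero-variance spectrum, id={s.ids[flat[0]]!r}")
    return s.with_absorbance((a - mu) / sd)


def baseline_correct(s: SpectrumSet) -> SpectrumSet:
    """Two-point linear baseline: subtract the chord through the first and
    last point of each spectrum, so both endpoints become exactly zero."""
    a = s.absorbance
    n = a.shape[1]
    t = np.linspace(0.0, 1.0, n)
    base = a[:, [0]] * (1 - t) + a[:, [-1]] * t
    out = a - base
    out[:, 0] = 0.0
    out[:, -1] = 0.0
    return s.with_absorbance(out)


def detrend(s: SpectrumSet, degree: int = 2) -> SpectrumSet:
    """Subtract the per-row least-squares polynomial of ``degree`` in
    wavenumber (degree 0 is mean removal).  The wavenumber axis is mapped to
    [−1, 1] before building the Vandermonde basis for conditioning."""
    if degree < 0 or degree >= s.n_points:
        raise ParameterError(f"detrend degree {degree} invalid for P={s.n_points}")
    v = s.grid.values
    x = 2 * (v - v.min()) / (v.max() - v.min()) - 1
    basis = np.polynomial.polynomial.polyvander(x, degree)  # P × (deg+1)
    coef, *_ = np.linalg.lstsq(basis, s.absorbance.T, rcond=None)
    return s.with_absorbance(s.absorbance - (basis @ coef).T)


def sg_smooth(s: SpectrumSet, window: int = 15, polyorder: int = 2) -> SpectrumSet:
    """Savitzky–Golay least-squares smoothing with polynomial edge handling."""
    _check_sg(s.n_points, window, polyorder)
    return s.with_absorbance(
        savgol_filter(s.absorbance, window, polyorder, axis=1, mode="interp"))


def derivative(s: SpectrumSet, order: int = 1, window: int = 15,
               polyorder: Optional[int] = None) -> SpectrumSet:
    """Savitzky–Golay derivative with respect to wavenumber.

    The signed grid step is respected: on the instrument's descending grid a
    rising absorbance toward low wavenumber has a negative derivative.  First
    order removes additive offsets exactly; second order also removes linear
    baselines.
    """
    if order not in (1, 2):
        raise ParameterError("derivative order must be 1 or 2")
    if polyorder is None:
        polyorder = 2 if order == 1 else 3
    if polyorder < order:
        raise ParameterError("polyorder must be >= derivative order")
    _check_sg(s.n_points, window, polyorder)
    step = s.grid.step
    d = savgol_filter(s.absorbance, window, polyorder, deriv=order,
                      delta=abs(step), axis=1, mode="interp")
    if step < 0:
        d = d * ((-1.0) ** order)
    return s.with_absorbance(d)


def area_normalize(s: SpectrumSet, method: str = "abs_sum") -> SpectrumSet:
    """Scale each row so its absolute area is one.

    ``abs_sum`` (default) divides by Σ|x|, robust to the sign changes
    derivative spectra introduce; ``trapezoid`` divides by ∫|x| dν over the
    wavenumber axis instead.
    """
    a = s.absorbance
    if method == "abs_sum":
        area = np.abs(a).sum(axis=1)
    elif method == "trapezoid":
        area = np.abs(np.trapezoid(np.abs(a), x=s.grid.values, axis=1))
    else:
        raise ParameterError(f"unknown area method {method!r}")
    zero = np.where(area == 0)[0]
    if zero.size:
        raise DegenerateSpectrumError(
            f"all-zero spectrum cannot be area-normalized, id={s.ids[zero[0]]!r}")
    return s.with_absorbance(a / area[:, None])


def _check_sg(n_points: int, window: int, polyorder: int) -> None:
    if window < 3 or window % 2 == 0:
        raise ParameterError(f"window must be odd and >= 3, got {window}")
    if polyorder >= window:
        raise ParameterError(f"polyorder {polyorder} must be < window {window}")
    if n_points < window:
        raise ParameterError(f"window {window} exceeds spectrum length {n_points}")


# ----------------------------------------------------------------- stateful

@dataclass
class TransformStep:
    """One fitted pipeline stage: a kind, its parameters, and any state
    learned on the training set (empty for stateless kinds)."""

    kind: str
    params: dict = field(default_factory=dict)
    fitted_state: dict = field(default_factory=dict)

    def spec(self) -> dict:
        """Serializable {kind, params} record (fitted state excluded)."""
        return {"kind": self.kind, "params": dict(self.params)}


def msc_fit(s_train: SpectrumSet) -> TransformStep:
    """Fit multiplicative scatter correction: the reference is the training
    column-mean spectrum."""
    if s_train.n_samples < 2:
        raise ParameterError("MSC needs at least 2 training spectra")
    ref = s_train.absorbance.mean(axis=0)
    return TransformStep("msc", fitted_state={"reference": ref})


def msc_apply(step: TransformStep, s: SpectrumSet) -> SpectrumSet:
    """Regress each spectrum on the reference (x = a + b·ref over wavenumbers)
    and return (x − a) / b."""
    ref = step.fitted_state["reference"]
    if ref.shape[0] != s.n_points:
        raise ParameterError("MSC reference length does not match spectra")
    refc = ref - ref.mean()
    denom = float(refc @ refc)
    a = s.absorbance
    b = (a - a.mean(axis=1, keepdims=True)) @ refc / denom
    if np.any(np.abs(b) < 1e-12):
        i = int(np.argmin(np.abs(b)))
        raise DegenerateFitError(
            f"MSC slope ~ 0 for id={s.ids[i]!r}; spectrum uncorrelated with reference")
    intercept = a.mean(axis=1) - b * ref.mean()
    return s.with_absorbance((a - intercept[:, None]) / b[:, None])


def mean_center_fit(s_train: SpectrumSet) -> TransformStep:
    if s_train.n_samples < 1:
        raise ParameterError("mean centering needs at least 1 training spectrum")
    return TransformStep("mean_center",
                         fitted_state={"column_means": s_train.absorbance.mean(axis=0)})


def mean_center_apply(step: TransformStep, s: SpectrumSet) -> SpectrumSet:
    mu = step.fitted_state["column_means"]
    if mu.shape[0] != s.n_points:
        raise ParameterError("column means length does not match spectra")
    return s.with_absorbance(s.absorbance - mu)


def osc_fit(s_train: SpectrumSet, y_train: np.ndarray, n_components: int = 1,
            max_iter: int = 500, tol: float = 1e-8) -> TransformStep:
    """Orthogonal signal correction, Wold-style.

    Per component: start from the first principal-component score of the
    (deflated) training matrix, orthogonalize it against the span of
    ``[1, y]``, regress it back onto X to get a weight vector, and iterate to
    a fixed point.  X is then deflated by the rank-one term t·pᵀ.  The weight
    and loading vectors are stored so test spectra are deflated with
    train-fitted directions only.
    """
    y = np.asarray(y_train, dtype=float).ravel()
    X = s_train.absorbance.copy()
    n = X.shape[0]
    if y.shape[0] != n:
        raise ParameterError("y_train length must match training samples")
    if n_components < 0:
        raise ParameterError("n_components must be >= 0")
    if n_components and n <= n_components + 1:
        raise ParameterError("need N > n_components + 1 for OSC")
    if n_components and len(set(y.tolist())) < 2:
        raise ParameterError("OSC needs both classes in y_train")

    # orthonormal basis of [1, y] for projecting response variation out
    M = np.column_stack([np.ones(n), y])
    Qm, _ = np.linalg.qr(M)

    weights, loadings = [], []
    for _ in range(n_components):
        u, sv, vt = np.linalg.svd(X, full_matrices=False)
        t = u[:, 0] * sv[0]                       # first PC score
        w = vt[0].copy()
        for it in range(max_iter):
            t_orth = t - Qm @ (Qm.T @ t)
            w_new, *_ = np.linalg.lstsq(X, t_orth, rcond=None)
            nw = np.linalg.norm(w_new)
            if nw == 0:
                raise ConvergenceError("OSC weight vector collapsed to zero")
            w_new /= nw
            delta = np.linalg.norm(w_new - np.sign(w_new @ w) * w)
            w = w_new
            t = X @ w
            if delta < tol:
                break
        else:
            raise ConvergenceError(
                f"OSC did not converge in {max_iter} iterations "
                f"(last relative change {delta:.3e})")
        # at the fixed point t = Xw equals its own orthogonalized version
        # (exactly so when X has full row rank), so deflating with t keeps
        # fit and apply identical operations and the replay contract exact
        t = X @ w
        p = X.T @ t / (t @ t)
        X = X - np.outer(t, p)
        weights.append(w)
        loadings.append(p)

    p_dim = X.shape[1]
    return TransformStep(
        "osc", params={"n_components": n_components},
        fitted_state={
            "weights": (np.array(weights) if weights
                        else np.zeros((0, p_dim))),
            "loadings": (np.array(loadings) if loadings
                         else np.zeros((0, p_dim)))})


def osc_apply(step: TransformStep, s: SpectrumSet) -> SpectrumSet:
    """Deflate spectra with the train-fitted OSC weight/loading pairs."""
    W = step.fitted_state["weights"]
    P = step.fitted_state["loadings"]
    X = s.absorbance.copy()
    for w, p in zip(W, P):
        t = X @ w
        X = X - np.outer(t, p)
    return s.with_absorbance(X)


# ----------------------------------------------------------------- pipeline

_STATELESS_FUNCS = {
    "snv": snv,
    "baseline": baseline_correct,
    "detrend": detrend,
    "sg_smooth": sg_smooth,
    "area_norm": area_normalize,
}


def _apply_stateless(kind: str, s: SpectrumSet, params: dict) -> SpectrumSet:
    if kind == "deriv1":
        return derivative(s, order=1, **params)
    if kind == "deriv2":
        return derivative(s, order=2, **params)
    return _STATELESS_FUNCS[kind](s, **params)


@dataclass
class Preprocessor:
    """An ordered chain of fitted transform steps.

    Built by :func:`fit_pipeline`; application replays the identical fitted
    chain, so test spectra are transformed with training-set statistics only.
    """

    steps: list  # list[TransformStep]

    def spec(self) -> list:
        return [st.spec() for st in self.steps]

    @property
    def name(self) -> str:
        return "+".join(st.kind for st in self.steps) if self.steps else "raw"


def fit_pipeline(steps_spec: Sequence, s_train: SpectrumSet,
                 y_train: Optional[np.ndarray] = None
                 ) -> tuple[Preprocessor, SpectrumSet]:
    """Fit an ordered pipeline on training data.

    ``steps_spec`` is a sequence of kinds or ``(kind, params)`` pairs; an
    empty sequence is the identity ("raw") pipeline.  Stateful steps are
    fitted on the progressively-transformed training data, matching how the
    chain will be replayed.  Returns the fitted :class:`Preprocessor` and the
    transformed training set (the fit-time matrix, byte-identical to what
    :func:`apply_pipeline` reproduces).
    """
    steps: list[TransformStep] = []
    cur = s_train
    for i, item in enumerate(steps_spec):
        kind, params = (item, {}) if isinstance(item, str) else (item[0], dict(item[1]))
        if kind not in ALL_KINDS:
            raise ParameterError(f"unknown preprocessing kind {kind!r}")
        try:
            if kind == "msc":
                step = msc_fit(cur)
                cur = msc_apply(step, cur)
            elif kind == "mean_center":
                step = mean_center_fit(cur)
                cur = mean_center_apply(step, cur)
            elif kind == "osc":
                if y_train is None:
                    raise ParameterError("OSC step requires y_train")
                step = osc_fit(cur, y_train, **params)
                cur = osc_apply(step, cur)
            else:
                step = TransformStep(kind, params=params)
                cur = _apply_stateless(kind, cur, params)
        except PipelineStepError:
            raise
        except Exception as e:  # attach step position for grid drivers
            raise PipelineStepError(i, kind, e) from e
        steps.append(step)
    return Preprocessor(steps), cur


def apply_pipeline(p: Preprocessor, s: SpectrumSet) -> SpectrumSet:
    """Replay a fitted chain on new spectra, in declared order."""
    cur = s
    for i, step in enumerate(p.steps):
        try:
            if step.kind == "msc":
                cur = msc_apply(step, cur)
            elif step.kind == "mean_center":
                cur = mean_center_apply(step, cur)
            elif step.kind == "osc":
                cur = osc_apply(step, cur)
            else:
                cur = _apply_stateless(step.kind, cur, step.params)
        except PipelineStepError:
            raise
        except Exception as e:
            raise PipelineStepError(i, step.kind, e) from e
    return cur
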