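"""Unit-variance-scaled PCA and PLS-DA with cross-validated predictive power.

Both decompositions are computed with the NIPALS algorithm, the iterative
scheme conventional in chemometrics software: it extracts one latent
component at a time by alternating score/loading regressions and deflating
the data matrix, which makes cumulative R²X / R²Y bookkeeping natural.

PLS-DA is PLS1 against a 0/1 class response. Goodness of fit is
R²Y = 1 − RSS/TSS on the training response; predictive ability is
Q²Y = 1 − PRESS/TSS estimated by seven-round internal cross-validation,
with samples assigned to the seven folds round-robin in a seed-fixed
shuffled order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ExpressionMatrix

__all__ = [
    "ScalingParams",
    "LatentModel",
    "uv_scale",
    "pca_nipals",
    "plsda",
    "q2y_crossval",
]

_TOL = 1e-12
_MAX_ITER = 2000


@dataclass
class ScalingParams:
    """Per-variable centring means and unit-variance divisors S_k."""

    mean: pd.Series
    sd: pd.Series
    dropped: list[str] = field(default_factory=list)


@dataclass
class LatentModel:
    n_components: int
    scores: np.ndarray        # samples × components (T)
    loadings: np.ndarray      # variables × components (P)
    r2x: np.ndarray           # per-component fraction of X variance
    weights: np.ndarray | None = None   # PLS W, variables × components
    y_loadings: np.ndarray | None = None  # PLS c, per component
    r2y: np.ndarray | None = None       # cumulative, PLS only
    q2y: np.ndarray | None = None       # cumulative, PLS only
    x_mean: np.ndarray | None = None
    y_mean: float | None = None


def uv_scale(m: ExpressionMatrix | pd.DataFrame) -> tuple[pd.DataFrame, ScalingParams]:
    """Centre each variable and divide by its standard deviation S_k.

    Constant variables (S_k = 0) carry no discriminatory information and are
    dropped with a warning. Requires at least two samples.
    """
    x = m.values if isinstance(m, ExpressionMatrix) else m
    if len(x) < 2:
        raise ValueError("unit-variance scaling needs >= 2 samples")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    constant = list(sd.index[sd == 0])
    if constant:
        warnings.warn(f"dropping constant variable(s): {constant}", stacklevel=2)
    keep = [c for c in x.columns if c not in constant]
    scaled = (x[keep] - mean[keep]) / sd[keep]
    return scaled, ScalingParams(mean=mean[keep], sd=sd[keep], dropped=constant)


def _as_array(m) -> np.ndarray:
    if isinstance(m, ExpressionMatrix):
        m = m.values
    if isinstance(m, pd.DataFrame):
        m = m.to_numpy()
    return np.asarray(m, dtype=float)


def pca_nipals(m, n_components: int, *, tol: float = _TOL,
               max_iter: int = _MAX_ITER) -> LatentModel:
    """NIPALS principal component analysis of a scaled matrix.

    Components equal, up to sign, the leading singular vectors of the input.
    """
    x = _as_array(m).copy()
    n, p = x.shape
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(samples-1, variables)"
        )
    ss_total = float((x ** 2).sum())
    scores = np.empty((n, n_components))
    loadings = np.empty((p, n_components))
    r2x = np.empty(n_components)
    for a in range(n_components):
        t = x[:, np.argmax(np.var(x, axis=0))].copy()
        if not np.any(t):
            t = x[:, 0].copy()
        for it in range(max_iter):
            pv = x.T @ t / float(t @ t)
            pv /= np.linalg.norm(pv)
            t_new = x @ pv
            if np.linalg.norm(t_new - t) <= tol * max(1.0, np.linalg.norm(t_new)):
                t = t_new
                break
            t = t_new
        else:
            raise RuntimeError(f"NIPALS failed to converge on component {a + 1}")
        scores[:, a] = t
        loadings[:, a] = pv
        x -= np.outer(t, pv)
        r2x[a] = float(t @ t) / ss_total if ss_total > 0 else 0.0
    return LatentModel(n_components=n_components, scores=scores,
                       loadings=loadings, r2x=r2x)


def _pls1_fit(x: np.ndarray, y: np.ndarray, n_components: int):
    """PLS1 NIPALS on (internally centred) x, y. Returns the pieces needed
    for prediction: weights W, loadings P, y-loadings c, and the means."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x_mean = x.mean(axis=0)
    y_mean = float(y.mean())
    xc = x - x_mean
    yc = y - y_mean
    n, p = xc.shape
    W = np.empty((p, n_components))
    P = np.empty((p, n_components))
    C = np.empty(n_components)
    T = np.empty((n, n_components))
    for a in range(n_components):
        w = xc.T @ yc
        nrm = np.linalg.norm(w)
        if nrm == 0:
            # response orthogonal to the residual X: pad with zero components
            W[:, a:] = 0.0
            P[:, a:] = 0.0
            C[a:] = 0.0
            T[:, a:] = 0.0
            break
        w /= nrm
        t = xc @ w
        tt = float(t @ t)
        c = float(t @ yc) / tt
        pv = xc.T @ t / tt
        xc = xc - np.outer(t, pv)
        yc = yc - c * t
        W[:, a], P[:, a], C[a], T[:, a] = w, pv, c, t
    return W, P, C, T, x_mean, y_mean


def _pls1_predict(x_new: np.ndarray, W, P, C, x_mean, y_mean,
                  n_components: int) -> np.ndarray:
    """Predicted response using the first ``n_components`` components."""
    Wa, Pa, Ca = W[:, :n_components], P[:, :n_components], C[:n_components]
    if n_components == 0 or not np.any(Wa):
        return np.full(len(x_new), y_mean)
    # regression vector B = W (P'W)^-1 c
    b = Wa @ np.linalg.solve(Pa.T @ Wa, Ca)
    return y_mean + (np.asarray(x_new, dtype=float) - x_mean) @ b


def plsda(m, labels, n_components: int = 2) -> LatentModel:
    """PLS discriminant analysis of a scaled matrix against two classes.

    ``labels`` may be any two-level vector; it is coded 0/1 internally.
    R²Y is cumulative over components: 1 − RSS/TSS on the training response.
    """
    x = _as_array(m)
    y = _encode_labels(labels)
    W, P, C, T, x_mean, y_mean = _pls1_fit(x, y, n_components)
    ss_x = float(((x - x.mean(axis=0)) ** 2).sum())
    r2x = np.array([float(T[:, a] @ T[:, a]) * float(P[:, a] @ P[:, a]) / ss_x
                    if ss_x > 0 else 0.0 for a in range(n_components)])
    tss = float(((y - y.mean()) ** 2).sum())
    r2y = np.empty(n_components)
    for a in range(1, n_components + 1):
        pred = _pls1_predict(x, W, P, C, x_mean, y_mean, a)
        r2y[a - 1] = 1.0 - float(((y - pred) ** 2).sum()) / tss
    return LatentModel(n_components=n_components, scores=T, loadings=P,
                       weights=W, y_loadings=C, r2x=r2x, r2y=r2y,
                       x_mean=x_mean, y_mean=y_mean)


def _encode_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    return (labels == classes[1]).astype(float)


def q2y_crossval(m, labels, n_components: int = 2, *, n_folds: int = 7,
                 seed: int = 0, assignment: str = "round_robin") -> np.ndarray:
    """Cumulative Q²Y per component by internal cross-validation.

    Samples are assigned to ``n_folds`` folds round-robin after a seed-fixed
    shuffle (``assignment='venetian'`` keeps the original sample order, the
    deterministic venetian-blind scheme). Each fold is predicted from a PLS
    model fit on the remaining samples; Q²Y = 1 − PRESS/TSS.
    """
    x = _as_array(m)
    y = _encode_labels(labels)
    n = len(y)
    if n < n_folds:
        raise ValueError(f"need >= {n_folds} samples, got {n}")
    order = np.arange(n)
    if assignment == "round_robin":
        order = np.random.default_rng(seed).permutation(n)
    elif assignment != "venetian":
        raise ValueError(f"unknown assignment {assignment!r}")
    fold_of = np.empty(n, dtype=int)
    fold_of[order] = np.arange(n) % n_folds
    press = np.zeros(n_components)
    for f in range(n_folds):
        test = fold_of == f
        W, P, C, T, x_mean, y_mean = _pls1_fit(x[~test], y[~test], n_components)
        for a in range(1, n_components + 1):
            pred = _pls1_predict(x[test], W, P, C, x_mean, y_mean, a)
            press[a - 1] += float(((y[test] - pred) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / tss
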