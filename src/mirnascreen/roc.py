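"""ROC-based biomarker screening: curves, AUC, specificity at 100% detection
rate with an exact binomial confidence interval, and multi-marker panels.

A screening test for preterm-birth risk must not miss cases, so the
operating point of interest is the threshold at which every case is
screen-positive (100% detection rate); the useful quantity is then the
specificity retained at that threshold, reported with an exact
Clopper–Pearson 95% interval on the control count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as _skm
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "Direction",
    "RocCurve",
    "ScreenThreshold",
    "roc_curve",
    "auc_p_value",
    "clopper_pearson",
    "specificity_at_full_sensitivity",
    "combine_markers",
]


def clopper_pearson(count: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact two-sided binomial (Clopper–Pearson) confidence interval.

    Returns (lower, upper) proportions for ``count`` successes out of ``n``,
    from beta-distribution quantiles.
    """
    if not 0 <= count <= n:
        raise ValueError(f"count {count} outside [0, {n}]")
    lo, hi = proportion_confint(count, n, alpha=alpha, method="beta")
    return float(0.0 if count == 0 else lo), float(1.0 if count == n else hi)


class Direction(Enum):
    UP_IN_CASES = "UP_IN_CASES"
    DOWN_IN_CASES = "DOWN_IN_CASES"
    AUTO = "AUTO"


@dataclass
class RocCurve:
    thresholds: np.ndarray  # descending on the oriented score
    fpr: np.ndarray         # non-decreasing, (0, 0) → (1, 1)
    dr: np.ndarray          # detection rate (sensitivity), same shape
    auc: float
    direction: Direction    # resolved orientation (never AUTO)
    case_n: int
    control_n: int


@dataclass
class ScreenThreshold:
    threshold: float
    direction: Direction
    specificity_at_full_sensitivity: float  # proportion in [0, 1]
    ci95: tuple[float, float]
    control_n: int
    controls_negative: int


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("need both cases and controls")
    return scores[y], scores[~y]


def roc_curve(scores, labels, direction: Direction = Direction.AUTO) -> RocCurve:
    """ROC curve of a per-sample marker score against case/control labels.

    ``labels`` is truthy for cases. ``direction`` states whether cases score
    high or low on the marker; AUTO orients so that AUC ≥ 0.5. The AUC
    equals both the trapezoidal area and the Mann-Whitney concordance
    probability with ties counted one half.
    """
    cases, controls = _split(scores, labels)
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if direction is Direction.AUTO:
        direction = (Direction.UP_IN_CASES
                     if _skm.roc_auc_score(y, s) >= 0.5
                     else Direction.DOWN_IN_CASES)
    oriented = s if direction is Direction.UP_IN_CASES else -s
    fpr, tpr, thr = _skm.roc_curve(y, oriented, drop_intermediate=False)
    return RocCurve(thresholds=thr, fpr=fpr, dr=tpr,
                    auc=float(_skm.auc(fpr, tpr)), direction=direction,
                    case_n=len(cases), control_n=len(controls))


def auc_p_value(scores, labels) -> float:
    """Two-sided Mann-Whitney p-value for AUC ≠ 0.5."""
    cases, controls = _split(scores, labels)
    if np.ptp(np.concatenate([cases, controls])) == 0:
        return 1.0
    return float(stats.mannwhitneyu(cases, controls,
                                    alternative="two-sided").pvalue)


def specificity_at_full_sensitivity(
    scores, labels, direction: Direction = Direction.AUTO,
    *, ci_alpha: float = 0.05,
) -> ScreenThreshold:
    """Specificity at the screen-positive cut-off that captures every case.

    For an UP_IN_CASES marker the threshold is the minimum case score and a
    sample is screen-positive when its score is ≥ the threshold, so all
    cases are positive by construction; a control exactly at the threshold
    counts as screen-positive. Specificity is the fraction of controls
    strictly on the negative side, with an exact Clopper–Pearson two-sided
    binomial interval.
    """
    cases, controls = _split(scores, labels)
    if direction is Direction.AUTO:
        y = np.asarray(labels).astype(int)
        direction = (Direction.UP_IN_CASES
                     if _skm.roc_auc_score(y, np.asarray(scores, float)) >= 0.5
                     else Direction.DOWN_IN_CASES)
    if direction is Direction.UP_IN_CASES:
        threshold = float(cases.min())
        negative = int((controls < threshold).sum())
    else:
        threshold = float(cases.max())
        negative = int((controls > threshold).sum())
    n = len(controls)
    return ScreenThreshold(
        threshold=threshold, direction=direction,
        specificity_at_full_sensitivity=negative / n,
        ci95=clopper_pearson(negative, n, ci_alpha), control_n=n,
        controls_negative=negative,
    )


def combine_markers(values: pd.DataFrame, labels, *, method: str = "logistic",
                    ridge_c: float = 1.0) -> tuple[pd.Series, RocCurve, pd.Series]:
    """Combine a marker panel into a single per-sample score.

    ``values`` holds per-marker log2 relative expression (samples × panel).
    The default combination is a two-class maximum-likelihood logistic
    model fitted in-sample; under perfect separation the MLE diverges and an
    L2-penalised (ridge) fit is used instead with a warning.
    ``method='rank'`` combines by the mean of per-marker ranks instead.

    Returns (combined score per sample, ROC of the score, coefficients).
    """
    if values.shape[1] < 1:
        raise ValueError("panel must contain at least one marker")
    y = np.asarray(labels).astype(int)
    if method == "rank":
        ranks = values.rank(axis=0)
        score = ranks.mean(axis=1)
        coef = pd.Series(1.0 / values.shape[1], index=values.columns)
    elif method == "logistic":
        import statsmodels.api as sm
        x = sm.add_constant(values.to_numpy(), has_constant="add")
        coef_arr = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.Logit(y, x).fit(disp=0, maxiter=200)
                if (fit.mle_retvals.get("converged", False)
                        and np.isfinite(fit.params).all()):
                    coef_arr = fit.params
            except Exception:
                coef_arr = None
        if coef_arr is None:
            warnings.warn("perfect separation: falling back to an L2 (ridge) "
                          "logistic fit", stacklevel=2)
            from sklearn.linear_model import LogisticRegression
            lr = LogisticRegression(C=ridge_c, max_iter=5000)
            lr.fit(values.to_numpy(), y)
            coef_arr = np.concatenate([lr.intercept_, lr.coef_.ravel()])
        score = pd.Series(
            coef_arr[0] + values.to_numpy() @ coef_arr[1:], index=values.index)
        coef = pd.Series(coef_arr[1:], index=values.columns)
    else:
        raise ValueError(f"unknown combination method {method!r}")
    curve = roc_curve(score.to_numpy(), y, Direction.UP_IN_CASES)
    return score, curve, coef
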