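"""Univariate and longitudinal differential-expression statistics.

Cross-sectional group comparisons are gated on the D'Agostino–Pearson
omnibus normality test: when both groups look Gaussian an unpaired Student
t-test is used, otherwise a two-sided Mann-Whitney test (exact for small
tie-free samples). Count profiles can alternatively be compared on
log-transformed geometric means with a Welch unequal-variance t-test.

Longitudinal (three-time-point) profiles are tested per subject with either
repeated-measures ANOVA under the Greenhouse–Geisser sphericity correction
followed by a linear-trend contrast, or — for non-Gaussian data — the
Friedman rank test followed by Dunn's pairwise comparisons with Bonferroni
adjustment over the three time-point pairs.

Multiplicity over a marker set is controlled with Benjamini–Hochberg
step-up adjusted q-values.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestUsed",
    "LongitudinalTestUsed",
    "DEResult",
    "LongitudinalResult",
    "dagostino_pearson",
    "group_compare",
    "welch_log_geomean_test",
    "gg_epsilon",
    "longitudinal_test",
    "bh_fdr",
]


class TestUsed(Enum):
    T_TEST = "T_TEST"
    MANN_WHITNEY = "MANN_WHITNEY"
    WELCH_LOG_GEOMEAN = "WELCH_LOG_GEOMEAN"


class LongitudinalTestUsed(Enum):
    RM_ANOVA_GG = "RM_ANOVA_GG"
    FRIEDMAN = "FRIEDMAN"


@dataclass
class DEResult:
    marker_id: str | None
    time_point: str | None
    group_pair: tuple[str, str] | None
    test_used: TestUsed
    statistic: float
    p_value: float
    q_value: float | None = None


@dataclass
class LongitudinalResult:
    test_used: LongitudinalTestUsed
    statistic: float
    p_value: float
    epsilon_gg: float | None = None          # RM-ANOVA branch only
    trend_statistic: float | None = None     # linear-trend contrast t
    trend_p: float | None = None
    pairwise_p: dict[tuple[int, int], float] | None = None  # Friedman branch
    n_subjects: int = 0
    marker_id: str | None = None


def dagostino_pearson(x: Sequence[float]) -> float:
    """D'Agostino–Pearson omnibus normality p-value (K² against χ²₂).

    Requires n ≥ 8 and a non-constant sample; callers needing a normality
    gate at smaller n fall back to a nonparametric test instead.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise ValueError(f"normality test needs n >= 8, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("normality test undefined for a constant sample")
    return float(stats.normaltest(x).pvalue)


def group_compare(x: Sequence[float], y: Sequence[float],
                  alpha: float = 0.05) -> DEResult:
    """Two-sided unpaired comparison with a normality gate.

    Student's t when both groups pass the omnibus normality test at
    ``alpha``; otherwise a two-sided Mann-Whitney test — exact when the
    smaller group has n < 8 and there are no ties, normal approximation with
    tie correction otherwise. Groups of n < 8 cannot be normality-tested and
    route to Mann-Whitney.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if min(x.size, y.size) < 2:
        raise ValueError("both groups need >= 2 observations")
    gaussian = False
    if min(x.size, y.size) >= 8 and np.ptp(x) > 0 and np.ptp(y) > 0:
        gaussian = (dagostino_pearson(x) > alpha and dagostino_pearson(y) > alpha)
    if gaussian:
        res = stats.ttest_ind(x, y, equal_var=True)
        return DEResult(None, None, None, TestUsed.T_TEST,
                        float(res.statistic), float(res.pvalue))
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) < 8 and not has_ties) else "asymptotic"
    if np.ptp(pooled) == 0:
        return DEResult(None, None, None, TestUsed.MANN_WHITNEY,
                        float(x.size * y.size / 2.0), 1.0)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return DEResult(None, None, None, TestUsed.MANN_WHITNEY,
                    float(res.statistic), float(min(res.pvalue, 1.0)))


def welch_log_geomean_test(x_counts: Sequence[float],
                           y_counts: Sequence[float],
                           *, offset: float = 1.0) -> DEResult:
    """Welch t-test on log2(count + offset) — i.e. on log geometric means.

    The unequal-variance form is used; ``offset`` (default 1) keeps
    background-subtracted zero counts finite on the log scale.
    """
    x = np.asarray(x_counts, dtype=float)
    y = np.asarray(y_counts, dtype=float)
    if (x == 0).all() or (y == 0).all():
        raise ValueError("all-zero group: log-geometric-mean test undefined")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("counts must be non-negative")
    lx, ly = np.log2(x + offset), np.log2(y + offset)
    if np.ptp(np.concatenate([lx, ly])) == 0:
        return DEResult(None, None, None, TestUsed.WELCH_LOG_GEOMEAN, 0.0, 1.0)
    res = stats.ttest_ind(lx, ly, equal_var=False)
    return DEResult(None, None, None, TestUsed.WELCH_LOG_GEOMEAN,
                    float(res.statistic), float(res.pvalue))


def gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse–Geisser sphericity correction ε for subjects × k data.

    ε = (Σλ)² / ((k−1)·Σλ²) over the eigenvalues λ of the double-centred
    sample covariance of the time-point columns; bounded in [1/(k−1), 1].
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    s = np.cov(data, rowvar=False, ddof=1)
    c = np.eye(k) - np.ones((k, k)) / k
    sc = c @ s @ c
    lam = np.linalg.eigvalsh(sc)
    lam = np.clip(lam, 0.0, None)
    denom = (k - 1) * float((lam ** 2).sum())
    if denom == 0:
        return 1.0
    eps = float(lam.sum()) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def _rm_anova_gg(data: np.ndarray) -> tuple[float, float, float]:
    """One-way repeated-measures ANOVA F, GG-corrected p, and ε."""
    n, k = data.shape
    grand = data.mean()
    subj_means = data.mean(axis=1)
    time_means = data.mean(axis=0)
    ss_time = n * float(((time_means - grand) ** 2).sum())
    ss_err = float(((data - subj_means[:, None] - time_means[None, :] + grand) ** 2).sum())
    df_time, df_err = k - 1, (k - 1) * (n - 1)
    ms_time = ss_time / df_time
    ms_err = ss_err / df_err if df_err > 0 else np.nan
    if not np.isfinite(ms_err) or ms_err == 0:
        return (np.inf if ss_time > 0 else 0.0,
                0.0 if ss_time > 0 else 1.0, 1.0)
    f = ms_time / ms_err
    eps = gg_epsilon(data)
    p = float(stats.f.sf(f, df_time * eps, df_err * eps))
    return float(f), p, eps


def _linear_trend(data: np.ndarray) -> tuple[float, float]:
    """Per-subject linear contrast (−1, 0, +1) tested against zero mean."""
    k = data.shape[1]
    w = np.linspace(-1.0, 1.0, k)
    scores = data @ w
    if np.ptp(scores) == 0:
        return 0.0 if scores.mean() == 0 else np.inf, 1.0 if scores.mean() == 0 else 0.0
    res = stats.ttest_1samp(scores, 0.0)
    return float(res.statistic), float(res.pvalue)


#: Exact Friedman null distribution is used up to this many subjects.
_FRIEDMAN_EXACT_MAX_N = 15


def _friedman_statistic(data: np.ndarray) -> float:
    n, k = data.shape
    ranks = stats.rankdata(data, axis=1)
    col_sums = ranks.sum(axis=0)
    return float(12.0 / (n * k * (k + 1)) * (col_sums ** 2).sum()
                 - 3.0 * n * (k + 1))


def _friedman_exact_p(data: np.ndarray) -> float:
    """Exact Friedman p by dynamic programming over per-subject rank
    permutations (valid for tie-free rows).

    The statistic depends on the data only through the column rank sums, so
    the null distribution of Σ_j R_j² is the n-fold convolution of the
    uniform distribution over the k! permutations of (1..k), tracked exactly
    over the (R_1, …, R_{k−1}) lattice.
    """
    import itertools

    n, k = data.shape
    perms = list(itertools.permutations(range(1, k + 1)))
    dist: dict[tuple[int, ...], float] = {tuple([0] * (k - 1)): 1.0}
    for _ in range(n):
        new: dict[tuple[int, ...], float] = {}
        for state, w in dist.items():
            for perm in perms:
                key = tuple(s + r for s, r in zip(state, perm[:-1]))
                new[key] = new.get(key, 0.0) + w
        dist = new
    total_rank = n * k * (k + 1) // 2
    obs = _friedman_statistic(data)
    coef = 12.0 / (n * k * (k + 1))
    hits = 0.0
    denom = float(len(perms)) ** n
    for state, w in dist.items():
        sums = list(state) + [total_rank - sum(state)]
        chi2 = coef * sum(s * s for s in sums) - 3.0 * n * (k + 1)
        if chi2 >= obs - 1e-9:
            hits += w
    return hits / denom


def _friedman(data: np.ndarray) -> tuple[float, float]:
    """Friedman test; exact null distribution for small tie-free designs,
    chi-square approximation otherwise."""
    n, k = data.shape
    if np.all(np.ptp(data, axis=1) == 0):
        return 0.0, 1.0
    no_ties = all(np.unique(row).size == k for row in data)
    if no_ties and n <= _FRIEDMAN_EXACT_MAX_N:
        return _friedman_statistic(data), _friedman_exact_p(data)
    return tuple(map(float, stats.friedmanchisquare(*data.T)))


def _dunn_pairs(data: np.ndarray) -> dict[tuple[int, int], float]:
    """Dunn's post-hoc z-tests on within-subject rank sums, Bonferroni over
    the k(k−1)/2 pairs."""
    n, k = data.shape
    ranks = stats.rankdata(data, axis=1)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    n_pairs = k * (k - 1) // 2
    out = {}
    for i, j in itertools.combinations(range(k), 2):
        z = abs(mean_ranks[i] - mean_ranks[j]) / se
        out[(i, j)] = float(min(1.0, 2.0 * stats.norm.sf(z) * n_pairs))
    return out


def longitudinal_test(values: np.ndarray | pd.DataFrame,
                      alpha: float = 0.05,
                      marker_id: str | None = None) -> LongitudinalResult:
    """Test a subjects × time-points profile for a gestational-age effect.

    Subjects with missing time points are dropped with a warning; at least
    three complete subjects are required. When every time point passes the
    omnibus normality test at ``alpha`` (possible only for n ≥ 8), the
    Gaussian branch runs RM-ANOVA with the Greenhouse–Geisser correction and
    a linear-trend contrast; otherwise the Friedman test with Dunn's
    Bonferroni-adjusted pairwise comparisons.
    """
    data = np.asarray(values, dtype=float)
    if data.ndim != 2:
        raise ValueError("expected a subjects × time-points array")
    complete = ~np.isnan(data).any(axis=1)
    if not complete.all():
        warnings.warn(
            f"dropping {int((~complete).sum())} subject(s) with missing "
            "time points", stacklevel=2)
        data = data[complete]
    n, k = data.shape
    if n < 3:
        raise ValueError(f"need >= 3 complete subjects, got {n}")
    gaussian = False
    if n >= 8:
        try:
            gaussian = all(dagostino_pearson(data[:, j]) > alpha for j in range(k))
        except ValueError:
            gaussian = False
    if gaussian:
        f, p, eps = _rm_anova_gg(data)
        t, tp = _linear_trend(data)
        return LongitudinalResult(LongitudinalTestUsed.RM_ANOVA_GG, f, p,
                                  epsilon_gg=eps, trend_statistic=t,
                                  trend_p=tp, n_subjects=n, marker_id=marker_id)
    chi2, p = _friedman(data)
    return LongitudinalResult(LongitudinalTestUsed.FRIEDMAN, chi2, p,
                              pairwise_p=_dunn_pairs(data), n_subjects=n,
                              marker_id=marker_id)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
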