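"""Threshold-based ASPECTS and the comparative outcome statistics.

Covers the patient-level analyses: the threshold-based ASPECTS score
(10 minus the number of regions predicted to infarct), Spearman rank
correlation with a percentile-bootstrap confidence interval, Wilcox's
percentile-bootstrap comparison of two overlapping dependent correlations
(two predictors sharing one outcome), and DeLong's covariance-based test
for paired ROC AUCs.

Bootstrap CIs are used instead of Fisher-z normal theory because integer
ASPECTS scores carry heavy ties. All bootstraps resample patients, use a
caller-supplied seed, and default to 2000 replicates. All p-values are
two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CorrelationResult",
    "AucComparison",
    "threshold_aspects",
    "spearman_ci",
    "compare_dependent_correlations",
    "delong_auc_variance",
    "delong_test",
    "outcome_auc",
]

DEFAULT_BOOTSTRAP_REPS = 2000


@dataclass(frozen=True)
class CorrelationResult:
    r_s: float
    ci_low: float
    ci_high: float
    n: int
    p_value: float


@dataclass(frozen=True)
class AucComparison:
    """Paired-AUC comparison: per-score AUC with DeLong 95% CI, delta, p."""

    auc_a: float
    auc_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    delta: float
    z: float
    p_value: float


def threshold_aspects(predicted_infarcted) -> int:
    """ASPECTS from region predictions: 10 minus predicted-infarcted count."""
    pred = list(predicted_infarcted)
    if len(pred) != 10:
        raise ValueError(f"expected 10 region predictions, got {len(pred)}")
    return 10 - sum(bool(p) for p in pred)


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be paired 1-D vectors")
    return x, y


def _rowwise_spearman(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spearman r for each row of two equal-shape 2-D arrays (average ranks)."""
    rx = stats.rankdata(x, axis=1)
    ry = stats.rankdata(y, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (rx * ry).sum(axis=1) / denom


def spearman_ci(
    x,
    y,
    bootstrap_reps: int = DEFAULT_BOOTSTRAP_REPS,
    seed: int | None = None,
) -> CorrelationResult:
    """Spearman correlation with a 95% percentile-bootstrap CI.

    Ranks use the average-rank convention for ties; the CI resamples
    patients with replacement. Replicates where either resampled vector is
    constant (undefined correlation) are dropped.
    """
    x, y = _paired(x, y)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input vector: correlation undefined")
    r, p = stats.spearmanr(x, y)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(bootstrap_reps, n))
    reps = _rowwise_spearman(x[idx], y[idx])
    reps = reps[~np.isnan(reps)]
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return CorrelationResult(
        r_s=float(r), ci_low=float(lo), ci_high=float(hi), n=n, p_value=float(p)
    )


def compare_dependent_correlations(
    x1,
    x2,
    y,
    bootstrap_reps: int = DEFAULT_BOOTSTRAP_REPS,
    seed: int | None = None,
) -> float:
    """Percentile-bootstrap p for H0: rho(x1, y) = rho(x2, y).

    The two predictors share the outcome vector (overlapping dependent
    correlations). Patients are resampled with replacement; each replicate
    yields delta* = r_s(x1*, y*) - r_s(x2*, y*). The two-sided p-value is
    2 * min(P(delta* > 0), P(delta* < 0)), with replicates at exactly zero
    split evenly between the sides; identical predictors therefore give
    p = 1 rather than an artefactual rejection.
    """
    x1, y = _paired(x1, y)
    x2, _ = _paired(x2, y)
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 pairs")
    for name, v in (("x1", x1), ("x2", x2), ("y", y)):
        if np.all(v == v[0]):
            raise ValueError(f"constant input vector {name}: correlation undefined")
    if bootstrap_reps < 1000:
        warnings.warn(
            f"bootstrap_reps={bootstrap_reps} < 1000; p-value resolution is coarse",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(bootstrap_reps, n))
    ys = y[idx]
    delta = _rowwise_spearman(x1[idx], ys) - _rowwise_spearman(x2[idx], ys)
    delta = delta[~np.isnan(delta)]
    if delta.size == 0:
        raise ValueError("all bootstrap replicates degenerate")
    p_hat = (np.sum(delta > 0) + 0.5 * np.sum(delta == 0)) / delta.size
    return float(2.0 * min(p_hat, 1.0 - p_hat))


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong placement values (higher score = positive orientation).

    Returns per-positive placements V10, per-negative placements V01, and
    the AUC (their common mean).
    """
    m, n = pos.size, neg.size
    combined = np.concatenate([pos, neg])
    rank_all = stats.rankdata(combined)
    rank_pos = stats.rankdata(pos)
    rank_neg = stats.rankdata(neg)
    v10 = (rank_all[:m] - rank_pos) / n
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m
    return v10, v01, float(v10.mean())


def delong_auc_variance(scores, labels) -> tuple[float, float]:
    """AUC (higher score = positive) and its DeLong variance estimate."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if not y.any() or y.all():
        raise ValueError("both outcome classes are required")
    v10, v01, a = _placements(s[y], s[~y])
    var = np.var(v10, ddof=1) / v10.size + np.var(v01, ddof=1) / v01.size
    return a, float(var)


def delong_test(scores_a, scores_b, labels) -> AucComparison:
    """DeLong's test for the difference of two paired ROC AUCs.

    ``scores_a`` and ``scores_b`` are risk scores on the same patients;
    higher score means higher predicted risk of the positive outcome. Uses
    the placement-value covariance estimate and a two-sided normal test.
    When the variance of the difference is zero and the difference itself
    is zero (e.g. identical score vectors), p = 1 by convention.
    """
    sa, sb = _paired(scores_a, scores_b)
    y = np.asarray(labels, dtype=bool)
    if y.shape != sa.shape:
        raise ValueError("labels must pair with the scores")
    if not y.any() or y.all():
        raise ValueError("both outcome classes are required")
    v10a, v01a, auc_a = _placements(sa[y], sa[~y])
    v10b, v01b, auc_b = _placements(sb[y], sb[~y])
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var_delta = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )
    delta = auc_a - auc_b
    if var_delta <= 0:
        z = 0.0 if delta == 0 else np.inf * np.sign(delta)
        p = 1.0 if delta == 0 else 0.0
    else:
        z = delta / np.sqrt(var_delta)
        p = 2.0 * stats.norm.sf(abs(z))
    za = stats.norm.ppf(0.975)
    ci_a = _auc_ci(auc_a, s10[0, 0] / m + s01[0, 0] / n, za)
    ci_b = _auc_ci(auc_b, s10[1, 1] / m + s01[1, 1] / n, za)
    return AucComparison(
        auc_a=float(auc_a),
        auc_b=float(auc_b),
        ci_a=ci_a,
        ci_b=ci_b,
        delta=float(delta),
        z=float(z),
        p_value=float(p),
    )


def _auc_ci(a: float, var: float, z: float) -> tuple[float, float]:
    half = z * np.sqrt(max(var, 0.0))
    return (float(max(a - half, 0.0)), float(min(a + half, 1.0)))


def outcome_auc(aspects, poor_outcome) -> tuple[float, tuple[float, float]]:
    """AUC of ASPECTS for poor functional outcome, with DeLong 95% CI.

    The risk score is 10 - ASPECTS (a lower score flags more extensive
    early ischemic change, hence higher risk); ties are counted half.
    """
    a = np.asarray(aspects, dtype=float)
    y = np.asarray(poor_outcome, dtype=bool)
    if a.shape != y.shape:
        raise ValueError("paired vectors required")
    if not y.any() or y.all():
        raise ValueError("both outcome classes are required")
    risk = 10.0 - a
    auc_val, var = delong_auc_variance(risk, y)
    return auc_val, _auc_ci(auc_val, var, stats.norm.ppf(0.975))
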