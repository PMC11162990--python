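"""Model evaluation: ROC/AUC with DeLong variance, paired AUC comparison,
the Youden operating point, decision-curve analysis, Hosmer-Lemeshow
calibration, bootstrap calibration error, and cohort-balance tests.

The AUC is the Mann-Whitney pairwise-comparison estimate (ties counted
half).  Its variance and the covariance between two markers scored on the
same subjects use the DeLong structural components, giving the usual normal
confidence interval and the paired z-test for correlated ROC curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ROCResult", "OperatingPoint", "DecisionCurve", "CalibrationResult",
           "auc", "delong_ci", "delong_paired_test", "youden_operating_point",
           "decision_curve", "hosmer_lemeshow", "calibration_mae_bootstrap",
           "cohort_balance_tests"]


@dataclass(frozen=True)
class ROCResult:
    auc: float
    n_pos: int
    n_neg: int
    fpr: np.ndarray
    tpr: np.ndarray
    ci95: tuple | None = None


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    accuracy: float
    sensitivity: float
    specificity: float
    youden_j: float
    degenerate: bool = False


@dataclass(frozen=True)
class DecisionCurve:
    thresholds: np.ndarray
    net_benefit_model: np.ndarray
    net_benefit_all: np.ndarray

    @property
    def net_benefit_none(self):
        return np.zeros_like(self.thresholds)


@dataclass(frozen=True)
class CalibrationResult:
    hl_statistic: float
    hl_df: int
    hl_p: float
    n_groups: int


def _check_binary(labels):
    labels = np.asarray(labels, int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    return labels


def _structural_components(scores, labels):
    """DeLong placement values: per-positive V10 and per-negative V01."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    m, n = len(pos), len(neg)
    # midranks via average ranking
    all_s = np.concatenate([pos, neg])
    r_all = stats.rankdata(all_s)
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    a = float((np.sum(r_all[:m]) - m * (m + 1) / 2.0) / (m * n))
    return a, v10, v01


def auc(scores, labels) -> ROCResult:
    """Mann-Whitney AUC with the empirical ROC curve."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, float)
    a, _, _ = _structural_components(scores, labels)
    m = int(labels.sum())
    n = int(len(labels) - m)
    # empirical curve over descending unique thresholds
    order = np.argsort(-scores, kind="stable")
    y_sorted = labels[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    distinct = np.r_[np.flatnonzero(np.diff(scores[order])), len(scores) - 1]
    tpr = np.r_[0.0, tps[distinct] / m]
    fpr = np.r_[0.0, fps[distinct] / n]
    return ROCResult(a, m, n, fpr, tpr)


def delong_ci(scores, labels, level: float = 0.95) -> tuple:
    """DeLong normal-approximation confidence interval on the AUC scale,
    clipped to [0, 1].  Degenerate (zero-variance) data give a zero-width
    interval with a warning."""
    labels = _check_binary(labels)
    a, v10, v01 = _structural_components(scores, labels)
    m, n = len(v10), len(v01)
    if m < 2 or n < 2:
        raise ValueError("need at least 2 observations per class")
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    if var <= 0:
        warnings.warn("degenerate DeLong variance; zero-width interval")
        return (a, a)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return (float(np.clip(a - half, 0, 1)), float(np.clip(a + half, 0, 1)))


def delong_paired_test(scores1, scores2, labels):
    """DeLong paired z-test for two correlated AUCs on the same subjects.

    Returns ``(z, p)`` two-sided.  If the variance of the AUC difference is
    zero the AUCs are either identical (p = 1) or the comparison is
    ill-posed (error).
    """
    labels = _check_binary(labels)
    a1, v10_1, v01_1 = _structural_components(scores1, labels)
    a2, v10_2, v01_2 = _structural_components(scores2, labels)
    m, n = len(v10_1), len(v01_1)
    var1 = v10_1.var(ddof=1) / m + v01_1.var(ddof=1) / n
    var2 = v10_2.var(ddof=1) / m + v01_2.var(ddof=1) / n
    cov = (np.cov(v10_1, v10_2, ddof=1)[0, 1] / m
           + np.cov(v01_1, v01_2, ddof=1)[0, 1] / n)
    var_diff = var1 + var2 - 2 * cov
    if var_diff <= 1e-16:
        if abs(a1 - a2) < 1e-12:
            return 0.0, 1.0
        raise ValueError("zero variance of AUC difference with unequal AUCs")
    z = (a1 - a2) / np.sqrt(var_diff)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def youden_operating_point(probs, labels) -> OperatingPoint:
    """Operating point maximizing Youden's J = sensitivity + specificity − 1.

    The threshold is chosen from the observed score set (predicted positive
    when prob ≥ threshold); ties in J are broken toward higher sensitivity.
    """
    labels = _check_binary(labels)
    probs = np.asarray(probs, float)
    m = labels.sum()
    n = len(labels) - m
    best = None
    for t in np.unique(probs):
        pred = probs >= t
        sens = float(np.sum(pred & (labels == 1)) / m)
        spec = float(np.sum(~pred & (labels == 0)) / n)
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12 or (
                abs(j - best[0]) <= 1e-12 and sens > best[1]):
            acc = float(np.mean(pred == (labels == 1)))
            best = (j, sens, spec, acc, float(t))
    j, sens, spec, acc, t = best
    return OperatingPoint(t, acc, sens, spec, j, degenerate=(j <= 1e-12))


def decision_curve(probs, labels, thresholds=None) -> DecisionCurve:
    """Decision-curve analysis: net benefit of the model, of treating all,
    and of treating none across threshold probabilities."""
    labels = _check_binary(labels)
    probs = np.asarray(probs, float)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probs must be in [0, 1]")
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    N = len(labels)
    prev = labels.mean()
    odds = thresholds / (1.0 - thresholds)
    nb_model = np.empty_like(thresholds)
    for i, pt in enumerate(thresholds):
        pred = probs >= pt
        tp = np.sum(pred & (labels == 1))
        fp = np.sum(pred & (labels == 0))
        nb_model[i] = tp / N - (fp / N) * odds[i]
    nb_all = prev - (1 - prev) * odds
    return DecisionCurve(thresholds, nb_model, nb_all)


def hosmer_lemeshow(probs, labels, n_groups: int = 10) -> CalibrationResult:
    """Hosmer-Lemeshow goodness-of-fit over deciles of predicted risk.

    Groups are equal-count deciles of the predicted probability (adjacent
    groups sharing a boundary value are merged); the statistic is
    Σ (O − E)² / (n_g·p̄_g·(1 − p̄_g)) with df = groups − 2.
    """
    labels = _check_binary(labels)
    probs = np.asarray(probs, float)
    if len(labels) < 2 * n_groups:
        raise ValueError("need at least 2 observations per group")
    order = np.argsort(probs, kind="stable")
    splits = np.array_split(order, n_groups)
    # merge groups whose probability ranges collide entirely (mass ties)
    groups, current = [], list(splits[0])
    for s in splits[1:]:
        if len(s) == 0:
            continue
        if probs[current[-1]] == probs[s[0]] and np.all(probs[s] == probs[current[-1]]):
            current.extend(s)
        else:
            groups.append(current)
            current = list(s)
    groups.append(current)
    g = len(groups)
    if g < 3:
        warnings.warn("fewer than 3 distinct risk groups; H-L test unstable")
    stat = 0.0
    for grp in groups:
        o = labels[grp].sum()
        pbar = probs[grp].mean()
        e = len(grp) * pbar
        denom = len(grp) * pbar * (1 - pbar)
        if denom <= 0:
            if abs(o - e) > 1e-12:
                stat = float("inf")
            continue
        stat += (o - e) ** 2 / denom
    df = max(g - 2, 1)
    p = float(stats.chi2.sf(stat, df))
    return CalibrationResult(float(stat), df, p, g)


def calibration_mae_bootstrap(probs, labels, B: int = 1000, seed: int = 0,
                              n_bins: int = 10) -> float:
    """Bootstrap mean absolute calibration error.

    For each bootstrap resample the observed-frequency curve is estimated by
    equal-count binning of the predicted probabilities (bin mean probability
    vs bin event rate, linearly interpolated) and evaluated on the original
    predicted probabilities; the MAE between that curve and the identity is
    averaged over ``B`` resamples.  Deterministic given ``seed``.
    """
    labels = np.asarray(labels, int)
    probs = np.asarray(probs, float)
    if B < 100:
        raise ValueError("B must be at least 100")
    if np.ptp(probs) == 0:
        # the smoother degenerates to a single point: the calibration error
        # is just the gap between the event rate and the constant prediction
        warnings.warn("constant predicted probabilities; calibration "
                      "smoother degenerates to a point estimate")
        return float(abs(labels.mean() - probs[0]))
    rng = np.random.default_rng(seed)
    n = len(probs)
    grid = np.sort(probs)
    maes = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, n)
        p_b, y_b = probs[idx], labels[idx]
        order = np.argsort(p_b, kind="stable")
        splits = np.array_split(order, n_bins)
        xs = np.array([p_b[s].mean() for s in splits if len(s)])
        ys = np.array([y_b[s].mean() for s in splits if len(s)])
        ux, uidx = np.unique(xs, return_index=True)
        maes[b] = np.mean(np.abs(np.interp(grid, ux, ys[uidx]) - grid))
    return float(maes.mean())


def cohort_balance_tests(group_a, group_b, variable_type: str) -> float:
    """Two-group comparison p-value.

    ``variable_type='continuous'`` uses the Mann-Whitney U test with the
    tie-corrected normal approximation (no continuity correction);
    ``'categorical'`` uses the chi-square test without continuity
    correction, switching to Fisher's exact test when any expected cell
    count is below 5 (2×2 tables).
    """
    a = np.asarray(group_a)
    b = np.asarray(group_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if variable_type == "continuous":
        if np.ptp(np.concatenate([a.astype(float), b.astype(float)])) == 0:
            return 1.0
        res = stats.mannwhitneyu(a.astype(float), b.astype(float),
                                 alternative="two-sided",
                                 use_continuity=False, method="asymptotic")
        return float(res.pvalue)
    if variable_type == "categorical":
        cats = np.unique(np.concatenate([a, b]))
        if cats.size < 2:
            return 1.0
        table = np.array([[np.sum(g == c) for c in cats] for g in (a, b)])
        expected = stats.contingency.expected_freq(table)
        if np.any(expected < 5) and table.shape == (2, 2):
            return float(stats.fisher_exact(table)[1])
        return float(stats.chi2_contingency(table, correction=False)[1])
    raise ValueError("variable_type must be 'continuous' or 'categorical'")
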