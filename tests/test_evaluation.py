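import numpy as np
import pytest
from scipy import stats

from ngdwi.evaluation import (auc, calibration_mae_bootstrap,
                              cohort_balance_tests, decision_curve,
                              delong_ci, delong_paired_test,
                              hosmer_lemeshow, youden_operating_point)


def _auc_bruteforce(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_auc_examples():
    assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]).auc == 1.0
    assert auc([0.5] * 6, [1, 1, 1, 0, 0, 0]).auc == 0.5
    # pair count: (0.9>0.5)+(0.9>0.3)+(0.4<0.5)+(0.4>0.3) = 3/4
    assert auc([0.9, 0.4, 0.5, 0.3], [1, 1, 0, 0]).auc == 0.75


def test_auc_equals_bruteforce_pair_counting(rng):
    """Exact agreement with O(n²) pair counting on all n ≤ 30 instances."""
    for seed in range(25):
        r = np.random.default_rng(seed)
        n = r.integers(4, 31)
        labels = np.zeros(n, int)
        labels[: max(1, int(n * r.random()))] = 1
        r.shuffle(labels)
        if labels.sum() in (0, n):
            labels[0], labels[-1] = 0, 1
        scores = np.round(r.random(n), 1)    # force ties
        assert auc(scores, labels).auc == pytest.approx(
            _auc_bruteforce(scores, labels), abs=1e-12)


def test_auc_invariant_under_monotone_transform(rng):
    scores = rng.random(50)
    labels = (rng.random(50) < 0.4).astype(int)
    a1 = auc(scores, labels).auc
    a2 = auc(np.exp(3 * scores), labels).auc
    assert a1 == pytest.approx(a2, abs=1e-12)


def test_auc_single_class_rejected():
    with pytest.raises(ValueError):
        auc([0.1, 0.2], [1, 1])


def test_delong_duplicated_dataset_halves_variance(rng):
    """Doubling every observation roughly halves the DeLong variance, i.e.
    shrinks the CI width by √2 (structural-components property)."""
    scores = rng.normal(size=60)
    labels = (rng.random(60) < 0.5).astype(int)
    lo1, hi1 = delong_ci(scores, labels)
    lo2, hi2 = delong_ci(np.tile(scores, 2), np.tile(labels, 2))
    ratio = (hi1 - lo1) / (hi2 - lo2)
    assert ratio == pytest.approx(np.sqrt(2), rel=0.06)


def test_delong_separated_data_zero_width():
    with pytest.warns(UserWarning, match="degenerate"):
        ci = delong_ci([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
    assert ci == (1.0, 1.0)


def test_delong_ci_moderate_coverage(rng):
    """Binormal simulation: the 95% CI covers the true AUC at roughly the
    nominal rate (quick check; the full 500-replicate study runs in the
    acceptance suite)."""
    mu = 1.0
    true_auc = stats.norm.cdf(mu / np.sqrt(2))
    cover = 0
    reps = 120
    for s in range(reps):
        r = np.random.default_rng(1000 + s)
        scores = np.concatenate([r.normal(0, 1, 100), r.normal(mu, 1, 100)])
        labels = np.repeat([0, 1], 100)
        lo, hi = delong_ci(scores, labels)
        cover += lo <= true_auc <= hi
    assert 0.88 <= cover / reps <= 0.99


def test_delong_paired_self_comparison():
    scores = np.array([0.1, 0.4, 0.35, 0.8, 0.7, 0.2])
    labels = np.array([0, 1, 0, 1, 1, 0])
    z, p = delong_paired_test(scores, scores, labels)
    assert z == 0.0 and p == 1.0
    # strictly monotone transform preserves ranks → identical AUCs
    z, p = delong_paired_test(scores, np.exp(scores), labels)
    assert p == 1.0


def test_delong_paired_against_bootstrap_reference(rng):
    """Small paired example: the DeLong p-value agrees with a subject-level
    bootstrap reference of the AUC difference."""
    r = np.random.default_rng(5)
    n = 12
    labels = np.array([0, 1] * 6)
    s1 = labels + r.normal(0, 0.8, n)
    s2 = labels + r.normal(0, 1.6, n)
    _z, p = delong_paired_test(s1, s2, labels)

    B = 20000
    diffs = np.empty(B)
    kept = 0
    for b in range(B):
        idx = r.integers(0, n, n)
        lab = labels[idx]
        if lab.sum() in (0, n):
            continue
        diffs[kept] = (_auc_bruteforce(s1[idx], lab)
                       - _auc_bruteforce(s2[idx], lab))
        kept += 1
    diffs = diffs[:kept]
    d0 = _auc_bruteforce(s1, labels) - _auc_bruteforce(s2, labels)
    se = diffs.std(ddof=1)
    p_boot = 2 * stats.norm.sf(abs(d0) / se)
    assert p == pytest.approx(p_boot, abs=0.02)


def test_youden_point_examples():
    op = youden_operating_point([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert op.sensitivity == op.specificity == op.accuracy == 1.0
    op = youden_operating_point([0.5] * 4, [1, 1, 0, 0])
    assert op.youden_j == 0.0 and op.degenerate


def test_youden_matches_exhaustive_sweep(rng):
    probs = rng.random(40)
    labels = (rng.random(40) < 0.5).astype(int)
    if labels.sum() in (0, 40):
        labels[0] = 1 - labels[0]
    op = youden_operating_point(probs, labels)
    best_j = max(
        (np.mean(probs[labels == 1] >= t) + np.mean(probs[labels == 0] < t)
         - 1.0) for t in np.unique(probs))
    assert op.youden_j == pytest.approx(best_j, abs=1e-12)


def test_decision_curve_closed_forms():
    rng = np.random.default_rng(3)
    labels = (rng.random(400) < 0.3).astype(int)
    prev = labels.mean()
    probs = np.clip(labels * 0.9 + 0.05, 0, 1)
    dc = decision_curve(probs, labels, thresholds=np.array([prev]))
    # treat-all at pt = prevalence has zero net benefit
    assert dc.net_benefit_all[0] == pytest.approx(0.0, abs=1e-12)
    # perfect classifier: NB = prevalence below the minimum positive prob
    dc2 = decision_curve(probs, labels, thresholds=np.array([0.5]))
    assert dc2.net_benefit_model[0] == pytest.approx(prev)
    assert np.all(dc2.net_benefit_none == 0.0)


def test_decision_curve_hand_count():
    probs = np.array([0.9, 0.8, 0.7, 0.4, 0.35, 0.3, 0.2, 0.15, 0.1, 0.05])
    labels = np.array([1, 1, 0, 1, 0, 0, 0, 0, 0, 0])
    dc = decision_curve(probs, labels, thresholds=np.array([0.25, 0.5]))
    # pt=0.25: predicted positive = probs >= 0.25 → TP=3, FP=3
    assert dc.net_benefit_model[0] == pytest.approx(
        3 / 10 - (3 / 10) * 0.25 / 0.75)
    # pt=0.5: TP=2, FP=1
    assert dc.net_benefit_model[1] == pytest.approx(
        2 / 10 - (1 / 10) * 0.5 / 0.5)


def test_decision_curve_bounded_by_perfect_classifier(rng):
    probs = rng.random(200)
    labels = (rng.random(200) < 0.35).astype(int)
    dc = decision_curve(probs, labels)
    assert np.all(dc.net_benefit_model <= labels.mean() + 1e-12)


def test_hosmer_lemeshow_perfect_grouping():
    # observed frequency in each group equals the group mean probability
    probs = np.repeat([0.2, 0.8], 50)
    labels = np.concatenate([
        np.r_[np.ones(10), np.zeros(40)],      # 20% events at p=0.2
        np.r_[np.ones(40), np.zeros(10)],      # 80% events at p=0.8
    ]).astype(int)
    res = hosmer_lemeshow(probs, labels, n_groups=2)
    assert res.hl_statistic == pytest.approx(0.0, abs=1e-12)
    assert res.hl_p == pytest.approx(1.0, abs=1e-12)


def test_hosmer_lemeshow_hand_computation():
    probs = np.repeat([0.3, 0.6], 20)
    labels = np.concatenate([np.r_[np.ones(9), np.zeros(11)],
                             np.r_[np.ones(10), np.zeros(10)]]).astype(int)
    res = hosmer_lemeshow(probs, labels, n_groups=2)
    expected = ((9 - 6.0) ** 2 / (20 * 0.3 * 0.7)
                + (10 - 12.0) ** 2 / (20 * 0.6 * 0.4))
    assert res.hl_statistic == pytest.approx(expected, rel=1e-12)


def test_calibration_mae_well_calibrated(rng):
    n = 5000
    probs = rng.random(n)
    labels = (rng.random(n) < probs).astype(int)
    mae = calibration_mae_bootstrap(probs, labels, B=200, seed=0)
    assert mae < 0.03


def test_calibration_mae_determinism(rng):
    probs = rng.random(300)
    labels = (rng.random(300) < probs).astype(int)
    m1 = calibration_mae_bootstrap(probs, labels, B=150, seed=9)
    m2 = calibration_mae_bootstrap(probs, labels, B=150, seed=9)
    assert m1 == m2
    with pytest.raises(ValueError):
        calibration_mae_bootstrap(probs, labels, B=10)


def test_calibration_mae_constant_probs_flagged():
    """Constant predictions degrade the smoother to a point: flagged with a
    warning; perfectly confident correct predictions give MAE 0."""
    with pytest.warns(UserWarning, match="constant"):
        mae = calibration_mae_bootstrap(np.ones(50), np.ones(50, int), B=100)
    assert mae == pytest.approx(0.0)
    with pytest.warns(UserWarning, match="constant"):
        mae = calibration_mae_bootstrap(np.full(50, 0.5),
                                        np.ones(50, int), B=100)
    assert mae == pytest.approx(0.5)


def test_balance_continuous():
    a = np.arange(20.0)
    assert cohort_balance_tests(a, a.copy(), "continuous") == pytest.approx(
        1.0)
    p = cohort_balance_tests(np.arange(20.0), np.arange(20.0) + 100.0,
                             "continuous")
    assert p < 1e-3


def test_balance_categorical_chi_square_hand_formula():
    a = np.array(["x"] * 20 + ["y"] * 10)
    b = np.array(["x"] * 10 + ["y"] * 20)
    p = cohort_balance_tests(a, b, "categorical")
    # expected counts all 15; statistic = 4·25/15
    stat = 4 * 25 / 15
    assert p == pytest.approx(stats.chi2.sf(stat, 1), rel=1e-10)


def test_balance_small_cells_use_fisher():
    a = np.array(["x"] * 2 + ["y"] * 4)     # expected x-count 3.75 < 5
    b = np.array(["x"] * 8 + ["y"] * 2)
    p = cohort_balance_tests(a, b, "categorical")
    table = [[2, 4], [8, 2]]
    assert p == pytest.approx(stats.fisher_exact(table)[1], rel=1e-10)
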