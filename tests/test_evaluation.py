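"""c-statistic, ROC, Hosmer-Lemeshow, and derivation/validation reporting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from casemix.evaluation import (
    c_statistic,
    evaluate_model,
    hosmer_lemeshow,
    roc_curve,
)
from casemix.modeling import fit_linear, fit_logistic


def brute_force_concordance(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def test_c_statistic_examples():
    assert c_statistic([0.3, 0.3, 0.3, 0.3], [0, 1, 0, 1]) == 0.5
    assert c_statistic([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
    assert c_statistic([0.2, 0.4, 0.4, 0.9], [0, 0, 1, 1]) == pytest.approx(0.875)
    with pytest.raises(ValueError, match="single class"):
        c_statistic([0.1, 0.2], [1, 1])


@given(st.integers(0, 2**30 - 1), st.integers(10, 120))
def test_c_statistic_equals_bruteforce_pairs(seed, n):
    rng = np.random.default_rng(seed)
    scores = rng.integers(0, 10, size=n) / 10.0  # heavy ties
    labels = rng.integers(0, 2, size=n)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    assert c_statistic(scores, labels) == pytest.approx(
        brute_force_concordance(scores, labels), abs=1e-12)


@given(st.integers(0, 2**30 - 1))
def test_c_statistic_invariant_under_increasing_transforms(seed):
    rng = np.random.default_rng(seed)
    scores = rng.random(60)
    labels = rng.integers(0, 2, size=60)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    base = c_statistic(scores, labels)
    assert c_statistic(3.0 * scores + 1.0, labels) == pytest.approx(base, abs=1e-12)
    assert c_statistic(np.exp(scores), labels) == pytest.approx(base, abs=1e-12)


def test_roc_endpoints_and_area():
    fpr, tpr = roc_curve([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
    assert (fpr[0], tpr[0]) == (0.0, 0.0) and (fpr[-1], tpr[-1]) == (1.0, 1.0)
    assert any(f == 0.0 and t == 1.0 for f, t in zip(fpr, tpr))  # perfect separator
    assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)

    single = roc_curve([0.4, 0.4, 0.4, 0.4], [0, 1, 0, 1])
    assert len(single[0]) == 2 or len(single[0]) == 3  # one threshold

    rng = np.random.default_rng(9)
    scores = rng.random(500)
    labels = rng.integers(0, 2, size=500)
    fpr, tpr = roc_curve(scores, labels)
    assert np.trapezoid(tpr, fpr) == pytest.approx(
        c_statistic(scores, labels), abs=1e-12)


def test_random_scores_give_null_auc():
    rng = np.random.default_rng(17)
    labels = np.repeat([0, 1], 500)
    scores = rng.random(1000)
    n1 = n0 = 500
    se = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
    assert abs(c_statistic(scores, labels) - 0.5) < 3 * se


def test_hosmer_lemeshow_zero_statistic_when_groups_calibrated():
    probs = np.repeat([0.1, 0.3], 50)
    labels = np.concatenate([np.ones(5), np.zeros(45), np.ones(15), np.zeros(35)])
    result = hosmer_lemeshow(probs, labels, groups=2)
    assert result.statistic == pytest.approx(0.0, abs=1e-9)
    assert result.p_value == 1.0
    assert [g.size for g in result.groups] == [50, 50]
    assert result.groups[0].observed == 5
    assert result.groups[0].expected == pytest.approx(5.0)


def test_hosmer_lemeshow_accounting_identities(rng):
    n = 2000
    probs = np.clip(rng.beta(2, 8, size=n), 1e-6, 1 - 1e-6)
    labels = (rng.random(n) < probs).astype(float)
    result = hosmer_lemeshow(probs, labels)
    assert sum(g.size for g in result.groups) == n
    assert sum(g.observed for g in result.groups) == labels.sum()
    assert sum(g.expected for g in result.groups) == pytest.approx(probs.sum(), abs=1e-9)
    assert result.df == len(result.groups) - 2
    assert 0.0 <= result.p_value <= 1.0


def test_hosmer_lemeshow_keeps_probability_ties_together():
    probs = np.array([0.1] * 70 + [0.5] * 30)  # 10% cut falls inside the tie block
    labels = (np.arange(100) % 5 == 0).astype(float)
    result = hosmer_lemeshow(probs, labels, groups=10)
    assert [g.size for g in result.groups] == [70, 30]


def test_hosmer_lemeshow_input_validation():
    with pytest.raises(ValueError, match="strictly in"):
        hosmer_lemeshow([0.0, 0.5] * 10, [0, 1] * 10, groups=2)
    with pytest.raises(ValueError, match="at least as many"):
        hosmer_lemeshow([0.2] * 5, [0] * 5, groups=10)


def _toy_fit(rng, n=600):
    X = pd.DataFrame((rng.random((n, 3)) < 0.4).astype(int), columns=list("abc"))
    from scipy.special import expit
    eta = -1.5 + X.to_numpy() @ np.array([0.9, 0.5, -0.4])
    y = (rng.random(n) < expit(eta)).astype(float)
    return X, y


def test_evaluate_model_identity_when_sets_coincide(rng):
    X, y = _toy_fit(rng)
    model = fit_logistic(X, y)
    report = evaluate_model(model, (X, y), (X, y))
    assert report.c_derivation == report.c_validation
    assert 0.5 < report.c_derivation < 1.0
    assert report.hl is not None and report.hl.df >= 1
    assert report.r2_derivation is None


def test_evaluate_model_linear_dispatch(rng):
    n = 500
    X = pd.DataFrame((rng.random((n, 2)) < 0.4).astype(int), columns=list("ab"))
    y = 1.0 + 0.4 * X["a"].to_numpy() + rng.normal(0, 0.5, n)
    model = fit_linear(X, y)
    half = n // 2
    report = evaluate_model(model, (X[:half], y[:half]), (X[half:], y[half:]))
    assert report.c_derivation is None and report.hl is None
    assert report.r2_derivation is not None and report.r2_validation is not None
    assert abs(report.r2_derivation - report.r2_validation) < 0.2
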