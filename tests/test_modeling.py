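"""Split-sample assignment and logistic/OLS fitting against oracles."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from casemix.modeling import (
    coefficient_table,
    fit_linear,
    fit_logistic,
    predict,
    significance_stars,
    split_sample,
)
from casemix.synthetic import MORTALITY_OR, generate_profiles


def test_split_sizes_and_determinism():
    ids = [f"h{i}" for i in range(10)]
    split = split_sample(ids, 0.7, seed=3)
    assert len(split.derivation_ids) == 7 and len(split.validation_ids) == 3
    assert split.derivation_ids | split.validation_ids == set(ids)
    assert not split.derivation_ids & split.validation_ids
    again = split_sample(ids, 0.7, seed=3)
    assert again.derivation_ids == split.derivation_ids
    other = split_sample(ids, 0.7, seed=4)
    assert other.derivation_ids != split.derivation_ids  # seed actually matters


def test_split_rejects_degenerate_fractions():
    with pytest.raises(ValueError):
        split_sample(["a", "b"], 0.2, seed=0)  # derivation would be empty
    with pytest.raises(ValueError):
        split_sample(["a"], 0.5, seed=0)


def test_logistic_recovers_closed_form_odds_ratio():
    # single binary predictor, saturated model: OR = cross-product ratio
    x = np.repeat([1, 1, 0, 0], [20, 80, 10, 90])
    y = np.concatenate([np.ones(20), np.zeros(80), np.ones(10), np.zeros(90)])
    model = fit_logistic(pd.DataFrame({"flag": x}), y)
    assert math.exp(model.coefficients["flag"]) == pytest.approx(2.25, abs=1e-8)
    assert model.converged


def test_logistic_requires_both_classes():
    X = pd.DataFrame({"flag": [0, 1, 0, 1]})
    with pytest.raises(ValueError, match="both classes"):
        fit_logistic(X, np.ones(4))


def test_logistic_matches_direct_likelihood_maximization(rng):
    """Newton IRLS solution equals a generic optimizer's MLE to 1e-6."""
    n, k = 400, 4
    X = pd.DataFrame(rng.random((n, k)) < 0.3, dtype=float,
                     columns=[f"c{j}" for j in range(k)])
    eta = -1.0 + X.to_numpy() @ np.array([0.8, -0.5, 0.3, 0.0])
    y = (rng.random(n) < expit(eta)).astype(float)
    model = fit_logistic(X, y)

    X1 = np.column_stack([np.ones(n), X.to_numpy()])

    def nll(beta):
        z = X1 @ beta
        return -(y * z - np.logaddexp(0.0, z)).sum()

    def grad(beta):
        return X1.T @ (expit(X1 @ beta) - y)

    res = minimize(nll, np.zeros(k + 1), jac=grad, method="BFGS",
                   options={"gtol": 1e-12, "maxiter": 500})
    fitted = np.array([model.intercept] + [model.coefficients[c] for c in X.columns])
    assert np.allclose(fitted, res.x, atol=1e-6)


def test_logistic_flags_quasi_separation_by_column():
    rng = np.random.default_rng(0)
    n = 200
    X = pd.DataFrame({
        "common": (rng.random(n) < 0.4).astype(int),
        "rare": np.zeros(n, dtype=int),
    })
    X.loc[:4, "rare"] = 1
    y = (rng.random(n) < 0.3).astype(float)
    y[:5] = 1.0  # every carrier of `rare` has the event -> zero cell
    with pytest.warns(UserWarning, match="rare"):
        model = fit_logistic(X, y)
    assert not model.converged
    assert model.separation_flags == ("rare",)


def test_linear_exact_fit_and_rank_deficiency(rng):
    x = (rng.random(200) < 0.5).astype(float)
    X = pd.DataFrame({"flag": x})
    y = 1.5 + 0.7 * x
    model = fit_linear(X, y)
    assert model.coefficients["flag"] == pytest.approx(0.7)
    assert model.r_squared == pytest.approx(1.0)
    dup = pd.DataFrame({"a": x, "b": x})
    with pytest.raises(ValueError, match="rank deficient"):
        fit_linear(dup, y)


def test_linear_null_model_r_squared_is_tiny(rng):
    flags = generate_profiles(50_000, rng=rng)
    X = flags.drop(columns="blood_loss_anemia").astype(float)
    y = rng.normal(size=len(X))
    model = fit_linear(X, y)
    assert model.r_squared <= 0.01


def test_predict_hand_computed_rows():
    x = np.repeat([1, 0], [50, 50])
    y = np.concatenate([np.ones(20), np.zeros(30), np.ones(10), np.zeros(40)])
    rng = np.random.default_rng(1)
    X = pd.DataFrame({
        "a": x, "b": (rng.random(100) < 0.5).astype(int),
        "c": (rng.random(100) < 0.5).astype(int),
    })
    model = fit_logistic(X, y)
    rows = pd.DataFrame({"a": [0, 1, 1], "b": [0, 0, 1], "c": [0, 0, 1]})
    scores = predict(model, rows)
    b = model.coefficients
    assert scores[0] == pytest.approx(expit(model.intercept), abs=1e-12)
    assert scores[1] == pytest.approx(expit(model.intercept + b["a"]), abs=1e-12)
    manual = 1.0 / (1.0 + math.exp(-(model.intercept + b["a"] + b["b"] + b["c"])))
    assert scores[2] == pytest.approx(manual, abs=1e-12)
    with pytest.raises(ValueError, match="column mismatch"):
        predict(model, rows[["b", "a", "c"]])


def test_fitted_logistic_reproduces_event_rate():
    # score equation: mean fitted probability equals the observed rate
    rng = np.random.default_rng(2)
    X = pd.DataFrame((rng.random((1000, 3)) < 0.3).astype(int), columns=list("abc"))
    y = (rng.random(1000) < 0.2).astype(float)
    model = fit_logistic(X, y)
    assert predict(model, X).mean() == pytest.approx(y.mean(), abs=1e-8)


def test_coefficient_table_stars_and_odds_ratio_scale():
    x = np.repeat([1, 1, 0, 0], [20, 80, 10, 90])
    y = np.concatenate([np.ones(20), np.zeros(80), np.ones(10), np.zeros(90)])
    model = fit_logistic(pd.DataFrame({"flag": x}), y)
    table = coefficient_table(model, {"flag": "Test condition"})
    row = table.iloc[0]
    assert row["estimate"] == pytest.approx(2.25, abs=1e-6)
    assert row["display_name"] == "Test condition"
    assert row["ci_low"] < 2.25 < row["ci_high"]
    assert significance_stars(0.0001) == "***"
    assert significance_stars(0.005) == "**"
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.5) == ""


def test_wald_intervals_cover_true_coefficients():
    """Simulation at cohort scale: pooled 95% CI coverage lands near nominal."""
    truth = {k: math.log(v) for k, v in MORTALITY_OR.items()}
    n = 39_162
    covered = total = 0
    est_sum = {k: 0.0 for k in truth}
    se_sum = {k: 0.0 for k in truth}
    n_seeds = 20
    for seed in range(n_seeds):
        rng = np.random.default_rng(900 + seed)
        flags = generate_profiles(n, rng=rng)
        xb = np.zeros(n)
        for k, b in truth.items():
            xb += b * flags[k].to_numpy(float)
        y = (rng.random(n) < expit(-3.0 + xb)).astype(float)
        X = flags[list(truth)].astype(np.int8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_logistic(X, y)
        for k in truth:
            lo, hi = model.ci_95[k]
            covered += lo <= truth[k] <= hi
            total += 1
            est_sum[k] += model.coefficients[k]
            se_sum[k] += model.standard_errors[k]
    assert 0.90 <= covered / total <= 0.99
    # no gross bias for conditions common enough to estimate stably
    from casemix.synthetic import DEFAULT_PREVALENCES
    for k in truth:
        if DEFAULT_PREVALENCES[k] >= 0.01:
            bias = est_sum[k] / n_seeds - truth[k]
            assert abs(bias) < 2 * se_sum[k] / n_seeds, k
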