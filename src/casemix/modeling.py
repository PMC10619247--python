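"""Split-sample derivation/validation and per-outcome model fitting.

The cohort is randomly divided (default 70/30, by hospitalization) into a
derivation set, on which coefficients are estimated, and a validation set,
onto which the frozen derivation coefficients are forced.  Each of the three
binary outcomes gets a logistic model on the 0/1 comorbidity design matrix;
log length-of-stay gets an ordinary least squares model.  Coefficients are
reported with Wald standard errors and 95% CIs (odds-ratio scale for the
logistic family); no regularization or multiple-testing adjustment is applied.

Complete or quasi-complete separation (a zero cell in a predictor's 2x2 table
with the outcome, plausible for very rare conditions) is detected and reported:
the model is returned with ``converged=False`` and a warning naming the
offending columns rather than silently dropping them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

__all__ = [
    "SplitAssignment",
    "FittedModel",
    "split_sample",
    "fit_logistic",
    "fit_linear",
    "predict",
    "coefficient_table",
    "significance_stars",
]

_Z95 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass(frozen=True)
class SplitAssignment:
    derivation_ids: frozenset[str]
    validation_ids: frozenset[str]
    fraction: float
    seed: int


def split_sample(ids: Sequence[str], fraction: float = 0.7, seed: int = 0) -> SplitAssignment:
    """Uniform random split without replacement; |derivation| = floor(fraction*n).

    Deterministic given the seed.  Degenerate splits (either side empty) are
    errors.
    """
    n = len(ids)
    if n < 2:
        raise ValueError("need at least two ids to split")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n_der = math.floor(fraction * n)
    if n_der == 0 or n_der == n:
        raise ValueError(f"degenerate split: {n_der}/{n - n_der}")
    rng = np.random.default_rng(seed)
    ids_arr = np.asarray(ids, dtype=object)
    picked = rng.choice(n, size=n_der, replace=False)
    mask = np.zeros(n, dtype=bool)
    mask[picked] = True
    return SplitAssignment(
        derivation_ids=frozenset(ids_arr[mask]),
        validation_ids=frozenset(ids_arr[~mask]),
        fraction=fraction,
        seed=seed,
    )


@dataclass
class FittedModel:
    """Intercept + per-condition coefficients for one outcome.

    Coefficients are on the log-odds scale for the logistic family and the
    log-days scale for the linear family.  ``ci_95`` bounds are on the same
    scale; odds ratios are ``exp(coefficient)``.
    """

    outcome: str
    family: str  # "logistic" | "linear"
    intercept: float
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    ci_95: dict[str, tuple[float, float]]
    p_values: dict[str, float]
    intercept_se: float
    n_obs: int
    converged: bool
    separation_flags: tuple[str, ...] = ()
    r_squared: Optional[float] = None
    adj_r_squared: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "family": self.family,
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "coefficients": self.coefficients,
            "standard_errors": self.standard_errors,
            "ci_95": {k: list(v) for k, v in self.ci_95.items()},
            "p_values": self.p_values,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "separation_flags": list(self.separation_flags),
            "r_squared": self.r_squared,
            "adj_r_squared": self.adj_r_squared,
        }


def _checked_xy(X: pd.DataFrame, y) -> tuple[np.ndarray, np.ndarray]:
    y_arr = np.asarray(y, dtype=float)
    if len(y_arr) != len(X):
        raise ValueError("X and y lengths differ")
    if len(X) <= X.shape[1]:
        raise ValueError("need more observations than predictors")
    return np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)]), y_arr


def _separation_scan(X: pd.DataFrame, y: np.ndarray) -> tuple[str, ...]:
    """Binary predictors with a zero cell in their 2x2 table against y."""
    suspects = []
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        if set(np.unique(x)) - {0.0, 1.0}:
            continue
        on = x == 1
        cells = [
            (y[on] == 1).sum(), (y[on] == 0).sum(),
            (y[~on] == 1).sum(), (y[~on] == 0).sum(),
        ]
        if 0 in cells:
            suspects.append(col)
    return tuple(suspects)


def fit_logistic(X: pd.DataFrame, y, outcome: str = "outcome") -> FittedModel:
    """Maximum-likelihood logistic fit with intercept and Wald inference.

    ``y`` must contain both classes.  Separation is reported, not repaired:
    affected columns keep their (unstable) estimates, ``converged`` is False,
    and a warning names them.
    """
    exog, y_arr = _checked_xy(X, y)
    classes = np.unique(y_arr)
    if not np.isin(classes, [0.0, 1.0]).all() or len(classes) < 2:
        raise ValueError("y must be binary with both classes present")
    suspects = _separation_scan(X, y_arr)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y_arr, exog).fit(disp=0, maxiter=200, method="newton", tol=1e-10)
        except Exception:
            res = sm.Logit(y_arr, exog).fit(disp=0, maxiter=1000, method="lbfgs")
    converged = bool(res.mle_retvals.get("converged", False)) and not suspects
    if suspects:
        warnings.warn(
            f"{outcome}: possible complete/quasi-complete separation in column(s) "
            f"{list(suspects)}; coefficients for these are unstable",
            stacklevel=2,
        )
    return _wrap_result(res, X, outcome, "logistic", converged, suspects, len(y_arr))


def fit_linear(X: pd.DataFrame, y, outcome: str = "log_los") -> FittedModel:
    """Ordinary least squares with intercept, R-squared, and t-interval CIs."""
    exog, y_arr = _checked_xy(X, y)
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        diag = np.abs(np.diag(np.linalg.qr(exog, mode="r")))
        bad = [X.columns[j - 1] for j in range(1, exog.shape[1])
               if diag[j] < 1e-8 * diag.max()]
        raise ValueError(f"design matrix is rank deficient; collinear column(s): {bad}")
    res = sm.OLS(y_arr, exog).fit()
    model = _wrap_result(res, X, outcome, "linear", True, (), len(y_arr))
    model.r_squared = float(res.rsquared)
    model.adj_r_squared = float(res.rsquared_adj)
    return model


def _wrap_result(res, X, outcome, family, converged, suspects, n_obs) -> FittedModel:
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    conf = np.asarray(res.conf_int(), dtype=float)
    pvals = np.asarray(res.pvalues, dtype=float)
    cols = list(X.columns)
    return FittedModel(
        outcome=outcome,
        family=family,
        intercept=float(params[0]),
        coefficients={c: float(params[j + 1]) for j, c in enumerate(cols)},
        standard_errors={c: float(bse[j + 1]) for j, c in enumerate(cols)},
        ci_95={c: (float(conf[j + 1, 0]), float(conf[j + 1, 1])) for j, c in enumerate(cols)},
        p_values={c: float(pvals[j + 1]) for j, c in enumerate(cols)},
        intercept_se=float(bse[0]),
        n_obs=n_obs,
        converged=converged,
        separation_flags=suspects,
    )


def predict(model: FittedModel, X: pd.DataFrame) -> np.ndarray:
    """Per-row score: probability (logistic) or fitted value (linear).

    ``X`` columns must match the model's coefficients exactly and in order —
    no silent reindexing.
    """
    if list(X.columns) != list(model.coefficients):
        raise ValueError(
            f"column mismatch: model has {list(model.coefficients)}, X has {list(X.columns)}"
        )
    beta = np.array([model.coefficients[c] for c in X.columns])
    eta = model.intercept + X.to_numpy(dtype=float) @ beta
    return expit(eta) if model.family == "logistic" else eta


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def coefficient_table(
    model: FittedModel, names: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Publication-style coefficient rows, in the model's condition order.

    Logistic models report odds ratios with exponentiated CI bounds; linear
    models report raw coefficients.  Stars mark Wald p-value thresholds
    0.05 / 0.01 / 0.001.
    """
    def safe_exp(v: float) -> float:
        # separation can push CI bounds beyond the exp() range
        try:
            return math.exp(v)
        except OverflowError:
            return math.inf

    rows = []
    logistic = model.family == "logistic"
    for cond, coef in model.coefficients.items():
        lo, hi = model.ci_95[cond]
        p = model.p_values[cond]
        est, lo_r, hi_r = (safe_exp(coef), safe_exp(lo), safe_exp(hi)) if logistic else (coef, lo, hi)
        rows.append({
            "condition": cond,
            "display_name": (names or {}).get(cond, cond),
            "estimate": est,
            "ci_low": lo_r,
            "ci_high": hi_r,
            "p_value": p,
            "stars": significance_stars(p),
        })
    return pd.DataFrame(rows)
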