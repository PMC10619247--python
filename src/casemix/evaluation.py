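"""Discrimination and calibration of the fitted risk models.

Discrimination of the binary-outcome models is the c-statistic: the
probability that a randomly chosen event receives a higher score than a
randomly chosen non-event, with ties credited 1/2.  It equals the trapezoidal
area under the ROC curve.  The linear (log length-of-stay) model is summarized
by R-squared; on the validation set R-squared is computed against the frozen
derivation coefficients, 1 - SSE/SST with SST about the validation mean.

Calibration uses the Hosmer-Lemeshow grouped chi-square: observations are
sorted by predicted probability and cut at group quantiles (default deciles),
with tied probabilities never split across groups — group sizes may therefore
be unequal.  The statistic is

    H = sum_g (O_g - E_g)^2 / (E_g * (1 - E_g / n_g))

compared to a chi-square with (groups - 2) degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .modeling import FittedModel, predict

__all__ = [
    "HLGroup",
    "HLResult",
    "EvaluationReport",
    "c_statistic",
    "roc_curve",
    "hosmer_lemeshow",
    "evaluate_model",
    "plot_roc",
]


@dataclass(frozen=True)
class HLGroup:
    group_index: int  # 1-based, low risk -> high risk
    size: int
    observed: int
    expected: float

    @property
    def observed_pct(self) -> float:
        return 100.0 * self.observed / self.size

    @property
    def expected_pct(self) -> float:
        return 100.0 * self.expected / self.size


@dataclass(frozen=True)
class HLResult:
    groups: tuple[HLGroup, ...]
    statistic: float
    df: int
    p_value: float

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": [g.group_index for g in self.groups],
                "size": [g.size for g in self.groups],
                "observed": [g.observed for g in self.groups],
                "observed_pct": [g.observed_pct for g in self.groups],
                "expected": [g.expected for g in self.groups],
                "expected_pct": [g.expected_pct for g in self.groups],
            }
        )


def _check_labels(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("labels contain a single class; discrimination undefined")


def c_statistic(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Concordance probability (AUROC) with half credit for score ties.

    Computed from midranks (Mann-Whitney form), so it is exact under ties and
    invariant to any strictly increasing transform of the scores.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    _check_labels(y)
    n1 = int((y == 1).sum())
    n0 = len(y) - n1
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """ROC points over all distinct thresholds: (FPR, TPR), (0,0) to (1,1).

    The trapezoidal area under the returned polyline equals
    :func:`c_statistic` up to floating-point rounding.
    """
    y = np.asarray(labels)
    _check_labels(y)
    fpr, tpr, _ = _sk_roc_curve(y, np.asarray(scores, dtype=float), drop_intermediate=False)
    return fpr, tpr


def hosmer_lemeshow(
    probs: Sequence[float], labels: Sequence[int], groups: int = 10
) -> HLResult:
    """Hosmer-Lemeshow grouped calibration test.

    Rows are cut at quantiles of predicted probability; tied probabilities at
    a cut all fall in the lower group, and duplicate cut values are collapsed,
    so the effective group count (hence df) can drop below ``groups``.  A
    group with expected events equal to 0 or to its size makes the variance
    term degenerate and raises, with the suggestion to use fewer groups.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError("probs and labels differ in length")
    if len(p) < groups:
        raise ValueError("need at least as many observations as groups")
    if (p <= 0).any() or (p >= 1).any():
        raise ValueError("probabilities must lie strictly in (0, 1)")
    cuts = np.quantile(p, [i / groups for i in range(1, groups)])
    cuts = np.unique(cuts)
    # value equal to a cut -> count of cuts strictly below it -> lower group
    assignment = np.searchsorted(cuts, p, side="left")
    out: list[HLGroup] = []
    statistic = 0.0
    for gi in range(len(cuts) + 1):
        in_g = assignment == gi
        n_g = int(in_g.sum())
        if n_g == 0:
            continue
        o_g = int(y[in_g].sum())
        e_g = float(p[in_g].sum())
        if e_g <= 0 or e_g >= n_g:
            raise ValueError(
                f"group {gi + 1} has degenerate expected count {e_g:.3g} of {n_g}; "
                "try fewer groups"
            )
        statistic += (o_g - e_g) ** 2 / (e_g * (1 - e_g / n_g))
        out.append(HLGroup(len(out) + 1, n_g, o_g, e_g))
    df = len(out) - 2
    if df <= 0:
        p_value = 1.0 if statistic < 1e-12 else 0.0
    else:
        p_value = float(chi2.sf(statistic, df))
    return HLResult(tuple(out), float(statistic), df, p_value)


@dataclass
class EvaluationReport:
    """Side-by-side derivation/validation fit summary for one outcome."""

    outcome: str
    family: str
    c_derivation: Optional[float] = None
    c_validation: Optional[float] = None
    r2_derivation: Optional[float] = None
    r2_validation: Optional[float] = None
    hl: Optional[HLResult] = None

    def to_dict(self) -> dict:
        out = {
            "outcome": self.outcome,
            "family": self.family,
            "c_derivation": self.c_derivation,
            "c_validation": self.c_validation,
            "r2_derivation": self.r2_derivation,
            "r2_validation": self.r2_validation,
        }
        if self.hl is not None:
            out["hosmer_lemeshow"] = {
                "statistic": self.hl.statistic,
                "df": self.hl.df,
                "p_value": self.hl.p_value,
                "groups": self.hl.table().to_dict(orient="records"),
            }
        return out


def evaluate_model(
    model: FittedModel,
    derivation: tuple[pd.DataFrame, Sequence[float]],
    validation: tuple[pd.DataFrame, Sequence[float]],
    hl_groups: int = 10,
) -> EvaluationReport:
    """Score the derivation fit and the frozen coefficients on validation.

    Derivation metrics use the model's own predictions on the derivation set;
    validation metrics force the derivation coefficients onto the validation
    set unchanged (the overfitting check).  Calibration (Hosmer-Lemeshow) is
    reported on the validation predictions of logistic models.
    """
    X_der, y_der = derivation
    X_val, y_val = validation
    s_der = predict(model, X_der)
    s_val = predict(model, X_val)
    y_der = np.asarray(y_der, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    report = EvaluationReport(outcome=model.outcome, family=model.family)
    if model.family == "logistic":
        report.c_derivation = c_statistic(s_der, y_der)
        report.c_validation = c_statistic(s_val, y_val)
        report.hl = hosmer_lemeshow(s_val, y_val, groups=hl_groups)
    else:
        report.r2_derivation = _r_squared(y_der, s_der)
        report.r2_validation = _r_squared(y_val, s_val)
    return report


def _r_squared(y: np.ndarray, fitted: np.ndarray) -> float:
    sse = float(((y - fitted) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    return 1.0 - sse / sst


def plot_roc(
    panels: dict[str, tuple[Sequence[float], Sequence[int]]], path: str
) -> None:
    """One ROC panel per named (scores, labels) pair, written to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(panels)
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 4), squeeze=False)
    for ax, (name, (scores, labels)) in zip(axes[0], panels.items()):
        fpr, tpr = roc_curve(scores, labels)
        ax.plot(fpr, tpr, lw=1.5)
        ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
        ax.set_title(f"{name} (c = {c_statistic(scores, labels):.3f})")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
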