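"""Diagnostic accuracy of the parent report against direct assessment.

The direct-assessment risk label is the truth ("gold standard"); the
parent-report label is the index test; "positive" means At risk.  From the
2x2 cross-classification the module derives sensitivity, specificity,
accuracy, prevalence, predictive values, likelihood ratios and the Youden
index, with 95% confidence intervals (Wilson score for proportions,
log-method for likelihood ratios), plus Bayes pre-test -> post-test
probability updating (the computation behind a Fagan nomogram).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from statsmodels.stats.proportion import proportion_confint

from .classification import RiskLabel

_Z95 = 1.959963984540054


class UndefinedStatisticError(ValueError):
    """A confusion-table margin is empty so the statistic does not exist."""


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 cross-classification: truth = direct label, test = parent label."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty confusion table")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class DiagnosticSummary:
    sensitivity: float
    specificity: float
    accuracy: float
    prevalence: float
    ppv: float
    npv: float
    lr_pos: float  # +inf when fp == 0
    lr_neg: float
    youden_j: float
    lr_pos_infinite: bool = False
    ci_95: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass(frozen=True)
class PosttestResult:
    pretest_prob: float
    likelihood_ratio: float
    posttest_prob: float


def confusion(truth_labels: list[RiskLabel | str], test_labels: list[RiskLabel | str]) -> ConfusionTable:
    """Cross-classify paired risk labels, positive = at_risk."""
    if len(truth_labels) != len(test_labels):
        raise ValueError(
            f"paired label vectors differ in length: {len(truth_labels)} vs {len(test_labels)}"
        )
    if not truth_labels:
        raise ValueError("empty label vectors")

    def _pos(label: RiskLabel | str) -> bool:
        value = label.value if isinstance(label, RiskLabel) else label
        if value not in ("at_risk", "not_at_risk"):
            raise ValueError(f"unknown risk label {value!r}")
        return value == "at_risk"

    tp = fn = fp = tn = 0
    for t, d in zip(truth_labels, test_labels):
        if _pos(t):
            if _pos(d):
                tp += 1
            else:
                fn += 1
        else:
            if _pos(d):
                fp += 1
            else:
                tn += 1
    return ConfusionTable(tp, fn, fp, tn)


def _wilson(count: int, nobs: int) -> tuple[float, float]:
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def _lr_ci(lr: float, se_log: float) -> tuple[float, float]:
    if lr == 0 or math.isinf(lr):
        return (lr, lr)
    return (lr * math.exp(-_Z95 * se_log), lr * math.exp(_Z95 * se_log))


def diagnostic_summary(t: ConfusionTable) -> DiagnosticSummary:
    """Full diagnostic battery from a 2x2 table.

    With fp == 0 the positive likelihood ratio is reported as +inf with the
    ``lr_pos_infinite`` flag rather than raising.
    """
    n_pos = t.tp + t.fn
    n_neg = t.fp + t.tn
    if n_pos == 0 or n_neg == 0:
        raise UndefinedStatisticError(
            "both truth classes must be present to compute sensitivity/specificity"
        )
    sens = t.tp / n_pos
    spec = t.tn / n_neg
    acc = (t.tp + t.tn) / t.total
    prev = n_pos / t.total
    ppv = t.tp / (t.tp + t.fp) if (t.tp + t.fp) else float("nan")
    npv = t.tn / (t.tn + t.fn) if (t.tn + t.fn) else float("nan")

    infinite = t.fp == 0
    lr_pos = float("inf") if infinite else sens / (1 - spec)
    lr_neg = (1 - sens) / spec if spec > 0 else float("inf")

    ci: dict[str, tuple[float, float]] = {
        "sensitivity": _wilson(t.tp, n_pos),
        "specificity": _wilson(t.tn, n_neg),
        "accuracy": _wilson(t.tp + t.tn, t.total),
        "ppv": _wilson(t.tp, t.tp + t.fp) if (t.tp + t.fp) else (float("nan"),) * 2,
        "npv": _wilson(t.tn, t.tn + t.fn) if (t.tn + t.fn) else (float("nan"),) * 2,
    }
    # Simel-Samsa-Matchar log-method SEs; degenerate cells fall back to a
    # point interval, flagged by lr_pos_infinite where relevant.
    if not infinite and t.tp > 0:
        se = math.sqrt(1 / t.tp - 1 / n_pos + 1 / t.fp - 1 / n_neg)
        ci["lr_pos"] = _lr_ci(lr_pos, se)
    else:
        ci["lr_pos"] = (lr_pos, lr_pos)
    if t.fn > 0 and t.tn > 0:
        se = math.sqrt(1 / t.fn - 1 / n_pos + 1 / t.tn - 1 / n_neg)
        ci["lr_neg"] = _lr_ci(lr_neg, se)
    else:
        ci["lr_neg"] = (lr_neg, lr_neg)

    return DiagnosticSummary(
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        prevalence=prev,
        ppv=ppv,
        npv=npv,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        youden_j=sens + spec - 1,
        lr_pos_infinite=infinite,
        ci_95=ci,
    )


def posttest_probability(pretest_prob: float, lr: float) -> PosttestResult:
    """Update a pre-test probability through a likelihood ratio.

    posttest odds = pretest odds x LR; probabilities strictly inside (0, 1).
    """
    if not 0 < pretest_prob < 1:
        raise ValueError(f"pretest probability must lie in (0, 1), got {pretest_prob}")
    if lr < 0:
        raise ValueError(f"likelihood ratio must be non-negative, got {lr}")
    odds = pretest_prob / (1 - pretest_prob)
    post_odds = odds * lr
    post = 1.0 if math.isinf(post_odds) else post_odds / (1 + post_odds)
    return PosttestResult(pretest_prob, lr, post)


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal rounding used for printed percentages (0.5 always rounds up)."""
    if not math.isfinite(x):
        return x
    factor = 10 ** decimals
    return math.floor(x * factor + 0.5) / factor
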