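"""Empirical and binormal ROC analysis of a screening score.

The empirical curve sweeps every distinct score threshold; its trapezoidal
area equals the Mann-Whitney concordance probability (ties counted one
half).  The binormal model assumes a latent normal score in each class
(negatives N(0,1), positives N(mu, sigma)); with a = mu/sigma and
b = 1/sigma the area under the fitted curve is Az = Phi(a / sqrt(1 + b^2)).
Parameters are estimated by Dorfman-Alf maximum likelihood on rating
categories obtained by quantile binning, with the category thresholds
treated as free parameters.

Score polarity: screening scores are mean item coefficients where LOWER
values mean more Caution/Delay, i.e. higher risk.  All entry points take a
``low_is_risk`` flag (default True) and orient the score internally so
that higher oriented scores mean higher risk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


class DegenerateCurveError(ValueError):
    """Both classes are required for any ROC quantity."""


class FitNotIdentifiableError(ValueError):
    """Fewer than two distinct cutpoints: the binormal fit has no solution."""


@dataclass
class ROCCurve:
    points: np.ndarray  # (k, 2) array of (fpf, tpf), from (0,0) to (1,1)
    thresholds: np.ndarray  # oriented-score threshold per interior point
    auc_trapezoidal: float
    n_pos: int
    n_neg: int


@dataclass
class BinormalFit:
    a: float
    b: float
    az: float
    converged: bool
    n_cutpoints: int
    log_likelihood: float
    thresholds: np.ndarray


@dataclass
class YoudenScan:
    best_cutoff: float
    best_j: float
    table: np.ndarray  # (k, 4): cutoff, sensitivity, specificity, J


def _oriented(scores, truth, low_is_risk: bool) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(
        [t if isinstance(t, (bool, np.bool_, int, np.integer)) else t.at_risk if hasattr(t, "at_risk") else t == "at_risk" for t in truth],
        dtype=bool,
    )
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and truth must be paired 1-d sequences")
    if y.all() or not y.any():
        raise DegenerateCurveError("both at-risk and not-at-risk children are required")
    return (-s if low_is_risk else s), y


def empirical_roc(scores, truth, low_is_risk: bool = True) -> ROCCurve:
    """ROC curve over all distinct thresholds of the oriented score.

    A child is called positive when the oriented score is >= the threshold;
    the trapezoidal area equals the concordance probability
    P(oriented positive score > oriented negative score) + P(tie)/2.
    """
    s, y = _oriented(scores, truth, low_is_risk)
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    n_pos, n_neg = int(y.sum()), int((~y).sum())

    distinct = np.r_[True, np.diff(s_sorted) != 0]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    # curve points at the end of each tie-block of thresholds
    block_ends = np.r_[np.nonzero(distinct)[0][1:] - 1, s_sorted.size - 1]
    tpf = tp[block_ends] / n_pos
    fpf = fp[block_ends] / n_neg
    points = np.vstack([[0.0, 0.0], np.column_stack([fpf, tpf])])
    if points[-1, 0] != 1.0 or points[-1, 1] != 1.0:
        points = np.vstack([points, [1.0, 1.0]])
    auc = float(np.trapezoid(points[:, 1], points[:, 0]))
    return ROCCurve(
        points=points,
        thresholds=s_sorted[block_ends],
        auc_trapezoidal=auc,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def _bin_ratings(s: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign pooled scores to at most ``n_bins`` ordinal categories."""
    uniq = np.unique(s)
    if uniq.size <= n_bins:
        return np.searchsorted(uniq, s)
    edges = np.unique(np.quantile(s, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, s, side="right")


def _binormal_nll(params: np.ndarray, n_neg_k: np.ndarray, n_pos_k: np.ndarray) -> float:
    k = n_neg_k.size
    mu, log_sigma = params[0], params[1]
    sigma = math.exp(log_sigma)
    cuts = np.empty(k - 1)
    cuts[0] = params[2]
    if k > 2:
        cuts[1:] = cuts[0] + np.cumsum(np.exp(params[3:]))
    lo = np.r_[-np.inf, cuts]
    hi = np.r_[cuts, np.inf]
    p_neg = stats.norm.cdf(hi) - stats.norm.cdf(lo)
    p_pos = stats.norm.cdf((hi - mu) / sigma) - stats.norm.cdf((lo - mu) / sigma)
    eps = 1e-300
    return -float(
        n_neg_k @ np.log(np.maximum(p_neg, eps)) + n_pos_k @ np.log(np.maximum(p_pos, eps))
    )


def binormal_fit(scores, truth, n_bins: int = 10, low_is_risk: bool = True) -> BinormalFit:
    """Dorfman-Alf maximum-likelihood binormal fit on binned rating data.

    Continuous scores are discretised into at most ``n_bins`` quantile
    categories; the fit needs at least two distinct cutpoints (three
    occupied categories).  b is kept in (0.05, 20) by bounding log(sigma).
    """
    s, y = _oriented(scores, truth, low_is_risk)
    cat = _bin_ratings(s, n_bins)
    cats, cat = np.unique(cat, return_inverse=True)
    k = cats.size
    if k < 3:
        raise FitNotIdentifiableError(
            f"only {k - 1} distinct cutpoint(s) after binning; need at least 2"
        )
    n_pos_k = np.bincount(cat[y], minlength=k).astype(float)
    n_neg_k = np.bincount(cat[~y], minlength=k).astype(float)

    # moment start: standardise by the negative class
    m0, sd0 = s[~y].mean(), max(s[~y].std(ddof=1), 1e-6)
    mu0 = (s[y].mean() - m0) / sd0
    sigma0 = min(max(s[y].std(ddof=1) / sd0, 0.06), 19.0)
    # starting thresholds from pooled category frequencies on the probit scale
    pooled = (n_pos_k + n_neg_k) / (n_pos_k + n_neg_k).sum()
    cum = np.cumsum(pooled)[:-1]
    t0 = stats.norm.ppf(np.clip(cum, 1e-4, 1 - 1e-4))
    t0 = np.maximum.accumulate(t0)
    t0 += np.arange(k - 1) * 1e-6  # keep increments strictly positive
    x0 = np.r_[mu0, math.log(sigma0), t0[0], np.log(np.maximum(np.diff(t0), 1e-4))]

    bounds = [(-30, 30), (math.log(1 / 20), math.log(1 / 0.05)), (-10, 10)]
    bounds += [(-12, 5)] * (k - 2)
    res = optimize.minimize(
        _binormal_nll,
        x0,
        args=(n_neg_k, n_pos_k),
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-10},
    )
    mu, sigma = res.x[0], math.exp(res.x[1])
    a, b = mu / sigma, 1 / sigma
    cuts = np.empty(k - 1)
    cuts[0] = res.x[2]
    if k > 2:
        cuts[1:] = cuts[0] + np.cumsum(np.exp(res.x[3:]))
    return BinormalFit(
        a=a,
        b=b,
        az=binormal_az(a, b),
        converged=bool(res.success),
        n_cutpoints=k - 1,
        log_likelihood=-float(res.fun),
        thresholds=cuts,
    )


def binormal_az(a: float, b: float) -> float:
    """Closed-form area under the binormal curve, Phi(a / sqrt(1 + b^2))."""
    return float(stats.norm.cdf(a / math.sqrt(1 + b * b)))


def youden_scan(scores=None, truth=None, curve: ROCCurve | None = None, low_is_risk: bool = True) -> YoudenScan:
    """J = sensitivity + specificity - 1 at every cutoff; argmax reported.

    Ties in J are broken toward the cutoff with higher sensitivity.
    """
    if curve is None:
        if scores is None or truth is None:
            raise ValueError("provide either a curve or scores and truth")
        curve = empirical_roc(scores, truth, low_is_risk=low_is_risk)
    interior = curve.points[1:curve.thresholds.size + 1]
    fpf, tpf = interior[:, 0], interior[:, 1]
    sens = tpf
    spec = 1 - fpf
    j = sens + spec - 1
    # argmax with ties toward higher sensitivity
    best = max(range(j.size), key=lambda i: (j[i], sens[i]))
    table = np.column_stack([curve.thresholds, sens, spec, j])
    return YoudenScan(
        best_cutoff=float(curve.thresholds[best]),
        best_j=float(j[best]),
        table=table,
    )
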