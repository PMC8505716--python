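"""Individual-change indices and group-comparison tests.

The per-child net percentage change index (NET) expresses the parent-report
score relative to the direct-assessment score, 100 x (CARE - HLL) / HLL;
negative values mean the parent underrated the child.  The standardized
individual difference (SID) divides the raw difference by the baseline SD,
and the reliable change index (RCI) follows the Jacobson-Truax convention,
dividing by the standard error of the difference
SD_baseline x sqrt(2) x sqrt(1 - reliability); |RCI| >= 1.96 flags a
reliable change at the 5% level.

Group tests mirror the usual screening-study battery: Mann-Whitney U with
tie-corrected normal approximation and the z-based effect size r = |z|/sqrt(N),
Kruskal-Wallis, one-way ANOVA with eta^2 / omega^2 and Bonferroni post hoc
t-tests with Cohen's d, and the two-level mixed-design ANOVA (source as the
within factor, risk group between).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

RELIABLE_CHANGE_Z = 1.959963984540054


class UndefinedNetError(ValueError):
    """NET index is undefined when the direct-assessment score is zero."""


@dataclass
class NETRecord:
    child_id: str
    scope: str  # "overall" or a domain name
    hll_score: float
    care_score: float
    net: float | None
    sid: float | None = None
    rci: float | None = None
    flagged: bool = False  # True when net undefined (hll_score == 0)


@dataclass
class RankTestResult:
    u_statistic: float
    z: float
    p_value: float
    effect_r: float
    n1: int
    n2: int
    median1: float
    median2: float
    iqr1: float
    iqr2: float


@dataclass
class PairwiseResult:
    groups: tuple[int, int]
    t_statistic: float
    df: float
    p_value: float  # Bonferroni-adjusted, capped at 1
    cohens_d: float


@dataclass
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    eta_squared: float
    omega_squared: float
    posthoc: list[PairwiseResult] = field(default_factory=list)


@dataclass
class MixedAnovaResult:
    f_within: float
    df_within: tuple[int, int]
    p_within: float
    f_between: float
    df_between: tuple[int, int]
    p_between: float
    f_interaction: float
    df_interaction: tuple[int, int]
    p_interaction: float
    ss: dict[str, float] = field(default_factory=dict)


def net_index(care_score: float, hll_score: float) -> float:
    """Percent change of the parent-report score relative to direct score."""
    if hll_score == 0:
        raise UndefinedNetError("NET undefined for a zero direct-assessment score")
    return 100.0 * (care_score - hll_score) / hll_score


def sid(x_care: float, x_hll: float, sd_baseline: float) -> float:
    """Standardized individual difference: (CARE - HLL) / baseline SD."""
    if sd_baseline <= 0:
        raise ValueError(f"sd_baseline must be positive, got {sd_baseline}")
    return (x_care - x_hll) / sd_baseline


def reliable_change(x_care: float, x_hll: float, sd_baseline: float, reliability: float) -> float:
    """Jacobson-Truax RCI: difference over SD x sqrt(2) x sqrt(1 - reliability)."""
    if sd_baseline <= 0:
        raise ValueError(f"sd_baseline must be positive, got {sd_baseline}")
    if not 0 < reliability < 1:
        raise ValueError(f"reliability must lie in (0, 1), got {reliability}")
    s_diff = sd_baseline * math.sqrt(2.0) * math.sqrt(1.0 - reliability)
    return (x_care - x_hll) / s_diff


def net_records(
    child_ids,
    care_scores,
    hll_scores,
    scope: str = "overall",
    reliability: float | None = None,
) -> list[NETRecord]:
    """Per-child NET/SID/RCI records; zero-HLL children flagged and excluded
    from aggregate summaries by the caller."""
    care = np.asarray(care_scores, dtype=float)
    hll = np.asarray(hll_scores, dtype=float)
    sd_base = float(np.std(hll, ddof=1)) if hll.size > 1 else float("nan")
    out = []
    for cid, c, h in zip(child_ids, care, hll):
        rec = NETRecord(child_id=str(cid), scope=scope, hll_score=float(h), care_score=float(c), net=None)
        if h == 0:
            rec.flagged = True
        else:
            rec.net = net_index(c, h)
        if sd_base > 0:
            rec.sid = sid(c, h, sd_base)
            if reliability is not None:
                rec.rci = reliable_change(c, h, sd_base, reliability)
        out.append(rec)
    return out


def _iqr(x: np.ndarray) -> float:
    q75, q25 = np.percentile(x, [75, 25])
    return float(q75 - q25)


def mann_whitney(x, y) -> RankTestResult:
    """Mann-Whitney U from midrank sums with tie-corrected normal z.

    U is counted for the first sample; effect size r = |z| / sqrt(n1 + n2),
    the convention that pairs the test with a correlation-like magnitude.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    ranks = stats.rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0

    mu = n1 * n2 / 2.0
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        z, p = 0.0, 1.0
    else:
        z = (u1 - mu) / math.sqrt(var)
        p = 2 * stats.norm.sf(abs(z))
    return RankTestResult(
        u_statistic=float(u1),
        z=float(z),
        p_value=float(p),
        effect_r=float(abs(z) / math.sqrt(n)),
        n1=n1,
        n2=n2,
        median1=float(np.median(x)),
        median2=float(np.median(y)),
        iqr1=_iqr(x),
        iqr2=_iqr(y),
    )


def kruskal_wallis(groups) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p on k-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("at least two groups required")
    if any(g.size == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    if all(np.all(g == groups[0][0]) for g in groups):
        return 0.0, len(groups) - 1, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), len(groups) - 1, float(p)


def _cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.size, b.size
    sp = math.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if sp == 0:
        return 0.0
    return float((a.mean() - b.mean()) / sp)


def one_way_anova(groups, posthoc: bool = True) -> AnovaResult:
    """One-way ANOVA with eta^2, omega^2 and Bonferroni pairwise t-tests.

    eta^2 = SSb / SStotal; omega^2 = (SSb - (k-1) MSw) / (SStotal + MSw),
    truncated at 0.  Post hoc comparisons use pooled-variance t-tests with
    p multiplied by the number of comparisons (capped at 1) and Cohen's d.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("at least two groups required")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    k = len(groups)
    n = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    sst = ssb + ssw
    df_b, df_w = k - 1, n - k
    if ssw == 0:
        raise ValueError("zero within-group variance everywhere: F undefined")
    msb, msw = ssb / df_b, ssw / df_w
    f = msb / msw
    p = float(stats.f.sf(f, df_b, df_w))
    eta2 = ssb / sst if sst > 0 else 0.0
    omega2 = max((ssb - df_b * msw) / (sst + msw), 0.0)

    pairs: list[PairwiseResult] = []
    if posthoc:
        combos = list(itertools.combinations(range(k), 2))
        for i, j in combos:
            a, b = groups[i], groups[j]
            t, praw = stats.ttest_ind(a, b, equal_var=True)
            pairs.append(
                PairwiseResult(
                    groups=(i, j),
                    t_statistic=float(t),
                    df=a.size + b.size - 2,
                    p_value=min(float(praw) * len(combos), 1.0),
                    cohens_d=_cohens_d(a, b),
                )
            )
    return AnovaResult(
        f_statistic=float(f),
        df_between=df_b,
        df_within=df_w,
        p_value=p,
        eta_squared=float(eta2),
        omega_squared=float(omega2),
        posthoc=pairs,
    )


def mixed_anova(scores, between) -> MixedAnovaResult:
    """Two-level mixed-design ANOVA from a full subjects x sources table.

    ``scores`` is an (n_subjects, 2) array — each child measured under both
    sources (direct, parent report) — and ``between`` assigns each child to
    one risk group.  Sums of squares follow the classic split-plot
    partition: the group effect is tested against the between-subjects
    error (subjects within groups), the source effect and the
    source-by-group interaction against the subject-by-source error.  With
    only two within levels sphericity holds trivially.
    """
    y = np.asarray(scores, dtype=float)
    if y.ndim != 2 or y.shape[1] != 2:
        raise ValueError("scores must be an (n_subjects, 2) array")
    if np.isnan(y).any():
        raise ValueError("missing cell: every child needs both source values")
    groups = np.asarray(between)
    if groups.shape[0] != y.shape[0]:
        raise ValueError("one group label per child required")
    levels = np.unique(groups)
    if levels.size < 2:
        raise ValueError("at least two between-subject groups required")

    n, s = y.shape
    grand = y.mean()
    subj_means = y.mean(axis=1)
    src_means = y.mean(axis=0)
    grp_sizes = np.array([(groups == g).sum() for g in levels])
    grp_means = np.array([y[groups == g].mean() for g in levels])
    cell_means = np.array([y[groups == g].mean(axis=0) for g in levels])  # (k, 2)

    ss_total = ((y - grand) ** 2).sum()
    ss_between_subj = s * ((subj_means - grand) ** 2).sum()
    ss_group = s * (grp_sizes * (grp_means - grand) ** 2).sum()
    ss_subj_within = ss_between_subj - ss_group
    ss_source = n * ((src_means - grand) ** 2).sum()
    ss_cells = (grp_sizes[:, None] * (cell_means - grand) ** 2).sum()
    ss_interaction = ss_cells - ss_group - ss_source
    ss_within_subj = ss_total - ss_between_subj
    ss_error_within = ss_within_subj - ss_source - ss_interaction

    k = levels.size
    df_group, df_subj = k - 1, n - k
    df_source = s - 1
    df_inter = (s - 1) * (k - 1)
    df_err_w = (s - 1) * (n - k)

    ms = lambda ssq, df: ssq / df if df > 0 else float("nan")
    mse_b = ms(ss_subj_within, df_subj)
    mse_w = ms(ss_error_within, df_err_w)

    def _f(ssq, df, mse, dfe):
        if mse <= 0:
            return 0.0, 1.0
        f = (ssq / df) / mse
        return float(f), float(stats.f.sf(f, df, dfe))

    f_g, p_g = _f(ss_group, df_group, mse_b, df_subj)
    f_s, p_s = _f(ss_source, df_source, mse_w, df_err_w)
    f_i, p_i = _f(ss_interaction, df_inter, mse_w, df_err_w)

    return MixedAnovaResult(
        f_within=f_s,
        df_within=(df_source, df_err_w),
        p_within=p_s,
        f_between=f_g,
        df_between=(df_group, df_subj),
        p_between=p_g,
        f_interaction=f_i,
        df_interaction=(df_inter, df_err_w),
        p_interaction=p_i,
        ss={
            "total": float(ss_total),
            "group": float(ss_group),
            "subjects_within_groups": float(ss_subj_within),
            "source": float(ss_source),
            "interaction": float(ss_interaction),
            "error_within": float(ss_error_within),
        },
    )
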