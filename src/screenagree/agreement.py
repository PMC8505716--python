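"""Inter-source agreement: Cohen's kappa, chi-square/Fisher tests, phi/Cramer's V.

Overall agreement between the two risk classifications is summarised with
Cohen's kappa and its Landis-Koch interpretation band.  Item-level
agreement cross-tabulates pass/fail per milestone item between parent
report and direct assessment, testing association with Pearson chi-square
or, when any observed cell falls below five, Fisher's exact test, and
reporting phi (2x2) or Cramer's V as effect size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

_Z95 = 1.959963984540054

# Landis-Koch interpretation bands: (upper bound inclusive, band name).
KAPPA_BANDS = [
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost_perfect"),
]


class DegenerateTableError(ValueError):
    """Marginals make the requested statistic undefined."""


@dataclass
class AgreementSummary:
    kappa: float
    se_kappa: float
    ci_95: tuple[float, float]
    observed_agreement: float
    chance_agreement: float
    band: str


@dataclass
class ItemAgreement:
    item_id: str
    table: np.ndarray  # 2x2: rows parent report (pass/fail), cols direct
    n: int
    test_used: str  # chi_square | fisher_exact
    statistic: float
    p_value: float
    effect_size: float  # phi for 2x2
    kappa: float | None
    undefined: bool = False


def cohens_kappa(table) -> AgreementSummary:
    """Cohen's kappa for an r x r cross-classification of two raters.

    Standard error is the Fleiss-Cohen-Everitt asymptotic form; the 95% CI
    is kappa +/- 1.96 SE truncated to [-1, 1].
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError(f"square table required, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("negative cell counts")
    n = t.sum()
    if n == 0:
        raise DegenerateTableError("empty table")
    p = t / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = float(np.trace(p))
    pe = float(row @ col)
    if pe >= 1.0 - 1e-15:
        raise DegenerateTableError("degenerate marginals: chance agreement is 1")
    kappa = (po - pe) / (1 - pe)

    k = t.shape[0]
    a = sum(
        p[i, i] * ((1 - pe) - (row[i] + col[i]) * (1 - po)) ** 2 for i in range(k)
    )
    b = (1 - po) ** 2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2 for i in range(k) for j in range(k) if i != j
    )
    c = (po * pe - 2 * pe + po) ** 2
    var = max((a + b - c), 0.0) / (n * (1 - pe) ** 4)
    se = math.sqrt(var)
    lo = max(-1.0, kappa - _Z95 * se)
    hi = min(1.0, kappa + _Z95 * se)
    return AgreementSummary(
        kappa=kappa,
        se_kappa=se,
        ci_95=(lo, hi),
        observed_agreement=po,
        chance_agreement=pe,
        band=interpret_kappa(kappa),
    )


def interpret_kappa(kappa: float) -> str:
    """Landis-Koch band for a kappa in [-1, 1]; negative kappa = disagreement."""
    if not -1 <= kappa <= 1:
        raise ValueError(f"kappa must lie in [-1, 1], got {kappa}")
    if kappa < 0:
        return "disagreement"
    for upper, band in KAPPA_BANDS:
        if kappa <= upper:
            return band
    return "almost_perfect"


def phi_coefficient(table) -> float:
    """Signed phi for a 2x2 table: (ad - bc) / sqrt of marginal products."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("phi requires a 2x2 table")
    a, b = t[0]
    c, d = t[1]
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise DegenerateTableError("a zero marginal makes phi undefined")
    return float((a * d - b * c) / math.sqrt(denom))


def cramers_v(table) -> float:
    """Cramer's V = sqrt(chi2 / (N * (min(r, c) - 1))); equals |phi| on 2x2."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("Cramer's V requires at least a 2x2 table")
    n = t.sum()
    if n == 0 or (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DegenerateTableError("zero marginal makes Cramer's V undefined")
    chi2 = stats.chi2_contingency(t, correction=False).statistic
    return float(math.sqrt(chi2 / (n * (min(t.shape) - 1))))


def item_agreement(
    parent_pass,
    direct_pass,
    item_id: str = "",
    fisher_trigger: str = "observed",
    yates: bool = False,
) -> ItemAgreement:
    """Association between parent-reported and directly observed pass/fail.

    ``parent_pass`` and ``direct_pass`` are paired boolean sequences over
    the children who have the item from both sources.  Fisher's exact test
    replaces the chi-square when any observed (default) or expected cell is
    below five.
    """
    p = np.asarray(parent_pass, dtype=bool)
    d = np.asarray(direct_pass, dtype=bool)
    if p.shape != d.shape or p.ndim != 1:
        raise ValueError("paired 1-d pass/fail vectors required")
    if p.size == 0:
        raise ValueError("no paired observations")
    if fisher_trigger not in ("observed", "expected"):
        raise ValueError(f"unknown fisher trigger {fisher_trigger!r}")

    # rows: parent pass/fail; cols: direct pass/fail
    table = np.array(
        [
            [int((p & d).sum()), int((p & ~d).sum())],
            [int((~p & d).sum()), int((~p & ~d).sum())],
        ]
    )
    n = int(table.sum())

    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        # one source never varies: association is undefined, report the
        # raw observed-agreement kappa only when it exists
        try:
            kap = cohens_kappa(table).kappa
        except DegenerateTableError:
            kap = None
        return ItemAgreement(
            item_id=item_id, table=table, n=n, test_used="none",
            statistic=float("nan"), p_value=float("nan"),
            effect_size=float("nan"), kappa=kap, undefined=True,
        )

    if fisher_trigger == "observed":
        use_fisher = (table < 5).any()
    else:
        expected = stats.contingency.expected_freq(table)
        use_fisher = (expected < 5).any()

    if use_fisher:
        res = stats.fisher_exact(table)
        test_used, statistic, p_value = "fisher_exact", float(res.statistic), float(res.pvalue)
    else:
        res = stats.chi2_contingency(table, correction=yates)
        test_used, statistic, p_value = "chi_square", float(res.statistic), float(res.pvalue)

    return ItemAgreement(
        item_id=item_id,
        table=table,
        n=n,
        test_used=test_used,
        statistic=statistic,
        p_value=p_value,
        effect_size=phi_coefficient(table),
        kappa=cohens_kappa(table).kappa,
    )
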