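"""Count-based risk classification rules.

Both sources share the Denver-style rule: a child is "At risk" with at
least one Delay item or at least two Cautions.  The parent-report rule adds
one clause for booklets the family could not complete: at least four
unanswered ("couldn't observe / believe they can't do it") items also flag
risk.  "Not at risk" is the logical complement of the at-risk disjunction.
"""

from __future__ import annotations

from dataclasses import dataclass

AT_RISK = "at_risk"
NOT_AT_RISK = "not_at_risk"

DELAY_THRESHOLD = 1
CAUTION_THRESHOLD = 2
UNANSWERED_THRESHOLD = 4


@dataclass(frozen=True)
class RiskLabel:
    value: str  # at_risk | not_at_risk
    rule: str  # hll | care
    trigger: str  # delay_clause | caution_clause | unanswered_clause | none

    def __post_init__(self) -> None:
        if (self.trigger == "none") != (self.value == NOT_AT_RISK):
            raise ValueError("trigger 'none' must coincide with not_at_risk")

    @property
    def at_risk(self) -> bool:
        return self.value == AT_RISK


def _check_counts(**counts: int) -> None:
    for name, n in counts.items():
        if n < 0:
            raise ValueError(f"{name} must be non-negative, got {n}")


def classify_hll(n_delay: int, n_caution: int) -> RiskLabel:
    """Direct-assessment rule: at risk iff >=1 Delay or >=2 Cautions."""
    _check_counts(n_delay=n_delay, n_caution=n_caution)
    if n_delay >= DELAY_THRESHOLD:
        return RiskLabel(AT_RISK, "hll", "delay_clause")
    if n_caution >= CAUTION_THRESHOLD:
        return RiskLabel(AT_RISK, "hll", "caution_clause")
    return RiskLabel(NOT_AT_RISK, "hll", "none")


def classify_care(n_delay: int, n_caution: int, n_unanswered: int) -> RiskLabel:
    """Parent-report rule: HLL clauses plus >=4 unanswered items.

    The unanswered threshold is counted over the whole booklet, not per
    domain.
    """
    _check_counts(n_delay=n_delay, n_caution=n_caution, n_unanswered=n_unanswered)
    if n_delay >= DELAY_THRESHOLD:
        return RiskLabel(AT_RISK, "care", "delay_clause")
    if n_caution >= CAUTION_THRESHOLD:
        return RiskLabel(AT_RISK, "care", "caution_clause")
    if n_unanswered >= UNANSWERED_THRESHOLD:
        return RiskLabel(AT_RISK, "care", "unanswered_clause")
    return RiskLabel(NOT_AT_RISK, "care", "none")
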