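"""Screening instruments and age-norm item scoring.

A milestone item carries two norm ages on the month scale: ``p50_age``, the
age at which half the norm population passes it, and ``p95_limit_age``, the
age by which 95% pass.  A failed age-appropriate item is a *Caution* while
the child is still at or below the 95% limit age, and a *Delay* once the
child is strictly older.  Marks map to the quantitative coefficients used
for continuous analysis: Positive = +1, Caution = 0, Delay = -1; items the
parent could not observe stay unanswered and carry no coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

DOMAINS = (
    "personal_social",
    "language_logico_math",
    "fine_motor_adaptive",
    "gross_motor",
)

AGE_MIN = 24
AGE_MAX = 59

COEFFICIENTS = {"positive": 1, "caution": 0, "delay": -1}


class ApplicabilityError(ValueError):
    """Raised when an item is marked outside its administration window."""


class AgeRangeError(ValueError):
    """Raised for ages outside the instrument's 24-59 month range."""


@dataclass(frozen=True)
class InstrumentItem:
    """One milestone with its domain and month-scale age norms."""

    item_id: str
    domain: str
    admin_min_age: int
    admin_max_age: int
    p50_age: float
    p95_limit_age: float
    text: str = ""

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")
        if not (self.admin_min_age <= self.p50_age <= self.p95_limit_age):
            raise ValueError(
                f"item {self.item_id}: require admin_min_age <= p50_age <= "
                f"p95_limit_age, got {self.admin_min_age}, {self.p50_age}, "
                f"{self.p95_limit_age}"
            )
        if self.admin_min_age < AGE_MIN or self.admin_max_age > AGE_MAX:
            raise ValueError(
                f"item {self.item_id}: administration window "
                f"[{self.admin_min_age}, {self.admin_max_age}] outside "
                f"[{AGE_MIN}, {AGE_MAX}]"
            )
        if self.admin_min_age > self.admin_max_age:
            raise ValueError(f"item {self.item_id}: empty administration window")


@dataclass
class Instrument:
    """A named set of milestone items, directly administered or parent-reported.

    Parent-report instruments are organised as age-group booklets: the child
    receives every item of the booklet for their age group, regardless of the
    per-item administration windows.
    """

    name: str
    kind: str  # "direct" | "parent_report"
    items: list[InstrumentItem]
    age_groups: list[tuple[int, int]] = field(default_factory=lambda: [(24, 35), (36, 59)])

    def __post_init__(self) -> None:
        if self.kind not in ("direct", "parent_report"):
            raise ValueError(f"unknown instrument kind {self.kind!r}")
        ids = [it.item_id for it in self.items]
        if len(ids) != len(set(ids)):
            raise ValueError(f"instrument {self.name}: duplicate item ids")
        if self.kind == "parent_report" and sorted(self.age_groups) != [(24, 35), (36, 59)]:
            raise ValueError(
                "parent-report instruments must define exactly the age groups "
                "24-35 and 36-59 months"
            )

    def age_group_of(self, age: int) -> tuple[int, int]:
        for lo, hi in self.age_groups:
            if lo <= age <= hi:
                return (lo, hi)
        raise AgeRangeError(f"age {age} not in any age group of {self.name}")


@dataclass(frozen=True)
class ItemResponse:
    """One child's outcome on one item: pass, fail or (parent only) not_observed."""

    child_id: str
    item_id: str
    outcome: str

    def __post_init__(self) -> None:
        if self.outcome not in ("pass", "fail", "not_observed"):
            raise ValueError(f"unknown outcome {self.outcome!r}")


@dataclass(frozen=True)
class ScoredItem:
    item_id: str
    mark: str  # positive | caution | delay | unanswered
    coefficient: int | None

    def __post_init__(self) -> None:
        expected = COEFFICIENTS.get(self.mark)
        if self.mark == "unanswered":
            if self.coefficient is not None:
                raise ValueError("unanswered items carry no coefficient")
        elif expected is None or self.coefficient != expected:
            raise ValueError(f"mark {self.mark!r} incompatible with coefficient {self.coefficient}")


@dataclass
class AssessmentResult:
    """Scored assessment of one child from one source.

    ``overall_score`` is the mean coefficient over answered applicable items,
    so it lives in [-1, +1]; ``domain_scores`` restrict the mean to each
    domain with at least one answered item.  ``risk`` is filled by the
    classification module.
    """

    child_id: str
    source: str
    scored: list[ScoredItem]
    n_positive: int
    n_caution: int
    n_delay: int
    n_unanswered: int
    domain_scores: dict[str, float]
    overall_score: float | None
    risk: str | None = None


def applicable_items(instrument: Instrument, age: int) -> list[InstrumentItem]:
    """Items administered to a child of ``age`` months.

    Direct instruments administer the items whose window contains the age;
    parent-report instruments hand the family the whole booklet for the
    child's age group.
    """
    if not (AGE_MIN <= age <= AGE_MAX):
        raise AgeRangeError(f"age {age} outside [{AGE_MIN}, {AGE_MAX}] months")
    if instrument.kind == "parent_report":
        lo, hi = instrument.age_group_of(age)
        return [
            it for it in instrument.items
            if lo <= it.admin_min_age and it.admin_max_age <= hi
        ]
    return [it for it in instrument.items if it.admin_min_age <= age <= it.admin_max_age]


def mark_item(response: ItemResponse, item: InstrumentItem, age: int) -> str:
    """Mark one response against the item's age norms.

    A fail at exactly the 95% limit age is still a Caution; Delay requires
    the child to be strictly older than the limit age.
    """
    if response.item_id != item.item_id:
        raise ApplicabilityError(
            f"response for {response.item_id!r} marked against item {item.item_id!r}"
        )
    if response.outcome == "pass":
        return "positive"
    if response.outcome == "not_observed":
        return "unanswered"
    return "delay" if age > item.p95_limit_age else "caution"


def score_assessment(
    responses: list[ItemResponse],
    instrument: Instrument,
    age: int,
    child_id: str | None = None,
) -> AssessmentResult:
    """Score one child's responses on one instrument.

    Every applicable item needs exactly one response.  A missing response is
    an error for direct instruments (the assessor sees every item) and is
    coerced to ``not_observed`` with a warning for parent reports.
    ``not_observed`` outcomes are rejected on direct instruments.
    """
    items = applicable_items(instrument, age)
    by_id = {it.item_id: it for it in items}

    seen: dict[str, ItemResponse] = {}
    for r in responses:
        if child_id is None:
            child_id = r.child_id
        elif r.child_id != child_id:
            raise ValueError(f"responses mix children {child_id!r} and {r.child_id!r}")
        if r.item_id not in by_id:
            raise ApplicabilityError(
                f"item {r.item_id!r} is not applicable at age {age} on {instrument.name}"
            )
        if r.item_id in seen:
            raise ValueError(f"duplicate response for item {r.item_id!r}")
        if r.outcome == "not_observed" and instrument.kind != "parent_report":
            raise ValueError(
                f"not_observed is only valid on parent-report instruments "
                f"(item {r.item_id!r})"
            )
        seen[r.item_id] = r

    missing = [iid for iid in by_id if iid not in seen]
    if missing:
        if instrument.kind != "parent_report":
            raise ValueError(
                f"missing direct-assessment responses for items {sorted(missing)}"
            )
        log.warning(
            "child %s: %d parent-report items missing, coerced to not_observed",
            child_id, len(missing),
        )
        for iid in missing:
            seen[iid] = ItemResponse(child_id or "", iid, "not_observed")

    scored: list[ScoredItem] = []
    counts = {"positive": 0, "caution": 0, "delay": 0, "unanswered": 0}
    by_domain: dict[str, list[int]] = {}
    for it in items:
        mark = mark_item(seen[it.item_id], it, age)
        counts[mark] += 1
        coef = COEFFICIENTS.get(mark)
        scored.append(ScoredItem(it.item_id, mark, coef))
        if coef is not None:
            by_domain.setdefault(it.domain, []).append(coef)

    answered = [c for coeffs in by_domain.values() for c in coeffs]
    return AssessmentResult(
        child_id=child_id or "",
        source=instrument.kind,
        scored=scored,
        n_positive=counts["positive"],
        n_caution=counts["caution"],
        n_delay=counts["delay"],
        n_unanswered=counts["unanswered"],
        domain_scores={d: sum(v) / len(v) for d, v in by_domain.items()},
        overall_score=sum(answered) / len(answered) if answered else None,
    )
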