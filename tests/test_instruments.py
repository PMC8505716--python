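"""Item applicability, Caution/Delay marking and assessment scoring."""

import pytest
from hypothesis import given, settings, strategies as st

from screenagree.instruments import (
    AgeRangeError,
    ApplicabilityError,
    Instrument,
    InstrumentItem,
    ItemResponse,
    applicable_items,
    mark_item,
    score_assessment,
)


class TestApplicableItems:
    def test_direct_uses_window_containment(self, tiny_direct):
        ids = {it.item_id for it in applicable_items(tiny_direct, 40)}
        assert ids == {"ps_a", "ps_b", "lg_a", "fm_a", "gm_a"}
        ids = {it.item_id for it in applicable_items(tiny_direct, 25)}
        assert ids == {"ps_a", "lg_a", "gm_a"}

    def test_window_bounds_inclusive(self):
        item = InstrumentItem("x", "gross_motor", 36, 47, 40.0, 45.0)
        inst = Instrument("i", "direct", [item])
        assert applicable_items(inst, 36) == [item]
        assert applicable_items(inst, 47) == [item]
        assert applicable_items(inst, 40) == [item]
        assert applicable_items(inst, 35) == []

    def test_parent_report_returns_full_booklet(self, tiny_parent):
        young = {it.item_id for it in applicable_items(tiny_parent, 30)}
        assert young == {"ps_a", "lg_a"}
        old = {it.item_id for it in applicable_items(tiny_parent, 40)}
        assert old == {"ps_b", "fm_a", "gm_a"}
        # booklet membership ignores the child's exact age within the group
        assert old == {it.item_id for it in applicable_items(tiny_parent, 59)}

    @pytest.mark.parametrize("age", [23, 60, 100])
    def test_age_out_of_range_rejected(self, tiny_direct, age):
        with pytest.raises(AgeRangeError):
            applicable_items(tiny_direct, age)

    def test_empty_instrument_gives_empty_list(self):
        inst = Instrument("empty", "direct", [])
        assert applicable_items(inst, 24) == []


class TestMarkItem:
    def test_fail_before_limit_age_is_caution(self, colors_item):
        r = ItemResponse("c1", "lang_colors", "fail")
        assert mark_item(r, colors_item, 40) == "caution"

    def test_fail_after_limit_age_is_delay(self, colors_item):
        r = ItemResponse("c1", "lang_colors", "fail")
        assert mark_item(r, colors_item, 45) == "delay"

    def test_fail_at_exact_limit_age_is_still_caution(self, colors_item):
        r = ItemResponse("c1", "lang_colors", "fail")
        assert mark_item(r, colors_item, 44) == "caution"

    def test_pass_is_positive_and_not_observed_unanswered(self, colors_item):
        assert mark_item(ItemResponse("c", "lang_colors", "pass"), colors_item, 50) == "positive"
        assert mark_item(ItemResponse("c", "lang_colors", "not_observed"), colors_item, 40) == "unanswered"

    def test_mismatched_item_rejected(self, colors_item):
        with pytest.raises(ApplicabilityError):
            mark_item(ItemResponse("c", "other", "pass"), colors_item, 40)

    @given(age=st.integers(24, 59), later=st.integers(0, 20))
    @settings(max_examples=50, deadline=None)
    def test_fail_mark_monotone_in_age(self, age, later):
        """A fail can move caution -> delay with age, never the reverse."""
        item = InstrumentItem("m", "gross_motor", 24, 59, 30.0, 40.0)
        r = ItemResponse("c", "m", "fail")
        first = mark_item(r, item, age)
        second = mark_item(r, item, min(age + later, 59))
        assert (first, second) != ("delay", "caution")


class TestScoreAssessment:
    def _responses(self, outcomes):
        return [ItemResponse("c1", iid, out) for iid, out in outcomes.items()]

    def test_all_pass_scores_one(self, tiny_direct):
        resp = self._responses({i.item_id: "pass" for i in applicable_items(tiny_direct, 40)})
        res = score_assessment(resp, tiny_direct, 40)
        assert res.overall_score == 1.0
        assert (res.n_delay, res.n_caution, res.n_unanswered, res.n_positive) == (0, 0, 0, 5)

    def test_mean_coefficient_arithmetic(self, tiny_direct):
        # age 40: ps_a fail past its 33-month limit -> delay; rest pass
        resp = self._responses(
            {"ps_a": "fail", "ps_b": "pass", "lg_a": "pass", "fm_a": "pass", "gm_a": "pass"}
        )
        res = score_assessment(resp, tiny_direct, 40)
        assert res.n_delay == 1 and res.n_positive == 4
        assert res.overall_score == pytest.approx((4 - 1) / 5)

    def test_not_observed_excluded_from_denominator(self, tiny_parent):
        resp = self._responses({"ps_b": "pass", "fm_a": "not_observed", "gm_a": "not_observed"})
        res = score_assessment(resp, tiny_parent, 40)
        assert res.n_unanswered == 2
        assert res.overall_score == 1.0  # only the answered item counts
        assert set(res.domain_scores) == {"personal_social"}

    def test_counts_partition_applicable_items(self, tiny_direct):
        resp = self._responses(
            {"ps_a": "fail", "ps_b": "fail", "lg_a": "pass", "fm_a": "pass", "gm_a": "fail"}
        )
        res = score_assessment(resp, tiny_direct, 40)
        total = res.n_positive + res.n_caution + res.n_delay + res.n_unanswered
        assert total == len(applicable_items(tiny_direct, 40))

    def test_score_invariant_to_item_order(self, tiny_direct):
        outcomes = {"ps_a": "fail", "ps_b": "pass", "lg_a": "fail", "fm_a": "pass", "gm_a": "pass"}
        resp = self._responses(outcomes)
        a = score_assessment(resp, tiny_direct, 40)
        b = score_assessment(list(reversed(resp)), tiny_direct, 40)
        assert a.overall_score == b.overall_score
        assert a.domain_scores == b.domain_scores

    def test_missing_direct_response_is_error(self, tiny_direct):
        resp = self._responses({"ps_a": "pass"})
        with pytest.raises(ValueError, match="missing direct-assessment"):
            score_assessment(resp, tiny_direct, 40)

    def test_missing_parent_response_coerced_to_not_observed(self, tiny_parent, caplog):
        res = score_assessment(self._responses({"ps_b": "pass"}), tiny_parent, 40)
        assert res.n_unanswered == 2

    def test_not_observed_rejected_on_direct(self, tiny_direct):
        resp = self._responses({i.item_id: "pass" for i in applicable_items(tiny_direct, 40)})
        resp[0] = ItemResponse("c1", resp[0].item_id, "not_observed")
        with pytest.raises(ValueError, match="not_observed"):
            score_assessment(resp, tiny_direct, 40)

    def test_duplicate_response_rejected(self, tiny_direct):
        resp = self._responses({i.item_id: "pass" for i in applicable_items(tiny_direct, 40)})
        with pytest.raises(ValueError, match="duplicate"):
            score_assessment(resp + [resp[0]], tiny_direct, 40)


class TestInvariants:
    def test_item_norm_ordering_enforced(self):
        with pytest.raises(ValueError):
            InstrumentItem("bad", "gross_motor", 30, 40, 28.0, 35.0)  # admin_min > p50
        with pytest.raises(ValueError):
            InstrumentItem("bad", "gross_motor", 24, 40, 38.0, 35.0)  # p50 > p95

    def test_window_outside_24_59_rejected(self):
        with pytest.raises(ValueError):
            InstrumentItem("bad", "gross_motor", 20, 40, 30.0, 35.0)

    def test_parent_instrument_needs_canonical_age_groups(self):
        item = InstrumentItem("x", "gross_motor", 24, 35, 30.0, 33.0)
        with pytest.raises(ValueError, match="age groups"):
            Instrument("p", "parent_report", [item], age_groups=[(24, 40), (41, 59)])

    def test_duplicate_item_ids_rejected(self):
        item = InstrumentItem("x", "gross_motor", 24, 35, 30.0, 33.0)
        with pytest.raises(ValueError, match="duplicate"):
            Instrument("d", "direct", [item, item])
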