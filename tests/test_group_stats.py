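"""NET/SID/RCI indices, rank tests, ANOVA and the mixed-design partition."""

import math

import numpy as np
import pingouin as pg
import pandas as pd
import pytest
from scipy import stats

from screenagree.group_stats import (
    UndefinedNetError,
    kruskal_wallis,
    mann_whitney,
    mixed_anova,
    net_index,
    net_records,
    one_way_anova,
    reliable_change,
    sid,
)


class TestNetIndex:
    def test_percent_change_arithmetic(self):
        assert net_index(0.6, 0.5) == pytest.approx(20.0)

    def test_equal_scores_give_zero(self):
        assert net_index(0.73, 0.73) == 0.0

    def test_negative_means_parental_underrating(self):
        assert net_index(0.5, 0.8) < 0

    def test_zero_direct_score_rejected(self):
        with pytest.raises(UndefinedNetError):
            net_index(0.5, 0.0)

    def test_records_flag_zero_baseline_children(self):
        recs = net_records(["a", "b", "c"], [0.6, 0.5, 0.4], [0.5, 0.0, 0.8])
        assert [r.flagged for r in recs] == [False, True, False]
        assert recs[0].net == pytest.approx(20.0)
        assert recs[1].net is None


class TestIndividualChange:
    def test_sid_standardizes_by_baseline_sd(self):
        assert sid(0.8, 0.6, 0.1) == pytest.approx(2.0)

    def test_equal_scores_give_zero_change(self):
        assert sid(0.5, 0.5, 0.2) == 0.0
        assert reliable_change(0.5, 0.5, 0.2, 0.9) == 0.0

    def test_rci_uses_jacobson_truax_denominator(self):
        rci = reliable_change(0.8, 0.6, 0.1, 0.9)
        assert rci == pytest.approx(0.2 / (0.1 * math.sqrt(2) * math.sqrt(0.1)))
        # this difference exceeds the 1.96 reliable-change criterion
        assert abs(rci) >= 1.96

    @pytest.mark.parametrize("sd, rel", [(0.0, 0.9), (-1.0, 0.9), (0.1, 0.0), (0.1, 1.0)])
    def test_invalid_inputs_rejected(self, sd, rel):
        with pytest.raises(ValueError):
            reliable_change(0.5, 0.4, sd, rel)


def u_pair_enumeration(x, y):
    """Brute-force U for the first sample: pairs won + half per tie."""
    u = 0.0
    for xi in x:
        for yj in y:
            u += 1.0 if xi > yj else 0.5 if xi == yj else 0.0
    return u


class TestMannWhitney:
    def test_complete_separation_gives_zero_u(self):
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.u_statistic == 0.0

    def test_identical_samples(self):
        r = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert r.u_statistic == pytest.approx(8.0)  # n1*n2/2
        assert r.z == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_u_matches_pair_enumeration_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 5, size=7).astype(float)
        y = rng.integers(0, 5, size=8).astype(float)
        r = mann_whitney(x, y)
        assert r.u_statistic == pytest.approx(u_pair_enumeration(x, y))
        u_scipy = stats.mannwhitneyu(x, y, alternative="two-sided").statistic
        assert r.u_statistic == pytest.approx(float(u_scipy))

    def test_p_matches_scipy_normal_approximation(self, rng):
        x = rng.normal(0, 1, 25)
        y = rng.normal(0.8, 1, 20)
        r = mann_whitney(x, y)
        p_scipy = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                                     use_continuity=False).pvalue
        assert r.p_value == pytest.approx(float(p_scipy), rel=1e-9)

    def test_effect_r_is_z_over_sqrt_n(self, rng):
        x = rng.normal(0, 1, 15)
        y = rng.normal(1, 1, 12)
        r = mann_whitney(x, y)
        assert r.effect_r == pytest.approx(abs(r.z) / math.sqrt(27))

    def test_effect_r_convention_reproduces_reported_magnitude(self):
        """With group sizes 39 and 13 and U = 66, the |z|/sqrt(N) effect size
        lands near 0.55 — the magnitude convention used alongside U tests in
        screening studies (1 - 2U/(n1 n2) would give 0.74 instead)."""
        # tie-free samples with U = 5*13 + 1 = 66
        x = [float(v) for v in range(-33, 0)] + [2.5] + [20.0, 21.0, 22.0, 23.0, 24.0]
        y = [float(v) for v in range(2, 15)]
        r = mann_whitney(x, y)
        assert r.u_statistic == pytest.approx(66.0)
        assert 0.5 <= r.effect_r <= 0.6

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestKruskalWallis:
    def test_identical_groups_give_zero(self):
        h, df, p = kruskal_wallis([[2, 2, 2], [2, 2], [2, 2, 2, 2]])
        assert h == 0.0 and df == 2 and p == 1.0

    def test_two_groups_consistent_with_mann_whitney(self, rng):
        x = rng.normal(0, 1, 20)
        y = rng.normal(1, 1, 20)
        h, df, p_kw = kruskal_wallis([x, y])
        r = mann_whitney(x, y)
        assert df == 1
        # H = z^2 without ties, so the chi-square p equals the normal p
        assert p_kw == pytest.approx(r.p_value, rel=1e-6)

    def test_shifted_groups_match_hand_computed_rank_sums(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        # rank sums 6, 15, 24 over N=9 -> H = 12/(9*10) * sum(R^2/n) - 3*10
        h_hand = 12 / 90 * (36 / 3 + 225 / 3 + 576 / 3) - 30
        h, df, _ = kruskal_wallis(groups)
        assert h == pytest.approx(h_hand)
        assert df == 2

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


class TestOneWayAnova:
    def test_equal_means_give_negligible_f(self, rng):
        g = [rng.normal(0, 1, 30) for _ in range(3)]
        shifted = [x - x.mean() for x in g]
        res = one_way_anova(shifted)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.eta_squared == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_f_equals_t_squared(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(1, 1, 15)
        res = one_way_anova([a, b])
        t, _ = stats.ttest_ind(a, b, equal_var=True)
        assert res.f_statistic == pytest.approx(t * t)

    def test_matches_scipy_f_oneway(self, rng):
        groups = [rng.normal(m, 1, 20) for m in (0, 0.5, 1.2)]
        res = one_way_anova(groups)
        f, p = stats.f_oneway(*groups)
        assert res.f_statistic == pytest.approx(float(f))
        assert res.p_value == pytest.approx(float(p))

    def test_textbook_fixture(self):
        """Three groups of three with between-group SS 24 and within SS 6."""
        groups = [[1, 2, 3], [3, 4, 5], [5, 6, 7]]
        res = one_way_anova(groups)
        # grand mean 4; SSb = 3*(4+0+4) = 24; SSw = 2+2+2 = 6; F = 12/1 = 12
        assert res.f_statistic == pytest.approx(12.0)
        assert res.eta_squared == pytest.approx(24 / 30)
        assert res.omega_squared == pytest.approx((24 - 2 * 1) / (30 + 1))

    def test_effect_sizes_ordered_and_bounded(self, rng):
        groups = [rng.normal(m, 1, 15) for m in (0, 0.7, 1.5)]
        res = one_way_anova(groups)
        assert 0 <= res.omega_squared <= res.eta_squared <= 1

    def test_bonferroni_posthoc_with_cohens_d(self, rng):
        groups = [rng.normal(m, 1, 20) for m in (0, 1.0, 2.0)]
        res = one_way_anova(groups)
        assert len(res.posthoc) == 3
        raw = stats.ttest_ind(groups[0], groups[1], equal_var=True).pvalue
        pair = next(p for p in res.posthoc if p.groups == (0, 1))
        assert pair.p_value == pytest.approx(min(raw * 3, 1.0))
        assert abs(pair.cohens_d) > 0.5


class TestMixedAnova:
    def _fixture(self):
        scores = np.array(
            [
                [0.2, 0.3], [0.4, 0.5], [0.1, 0.4], [0.5, 0.5],
                [0.7, 0.9], [0.8, 0.8], [0.9, 1.0], [0.6, 0.9],
            ]
        )
        groups = np.array(["at_risk"] * 4 + ["not_at_risk"] * 4)
        return scores, groups

    def test_no_source_effect_when_sources_identical(self, rng):
        base = rng.normal(0, 1, 12)
        scores = np.column_stack([base, base])
        groups = np.array(["a"] * 6 + ["b"] * 6)
        res = mixed_anova(scores, groups)
        assert res.f_within == pytest.approx(0.0, abs=1e-12)

    def test_sums_of_squares_partition_total(self):
        scores, groups = self._fixture()
        res = mixed_anova(scores, groups)
        parts = (
            res.ss["group"] + res.ss["subjects_within_groups"]
            + res.ss["source"] + res.ss["interaction"] + res.ss["error_within"]
        )
        assert parts == pytest.approx(res.ss["total"])

    def test_matches_pingouin(self):
        scores, groups = self._fixture()
        res = mixed_anova(scores, groups)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(8), 2),
                "source": ["direct", "parent"] * 8,
                "group": np.repeat(groups, 2),
                "score": scores.ravel(),
            }
        )
        ref = pg.mixed_anova(long, dv="score", within="source", between="group",
                             subject="subject")
        f = dict(zip(ref["Source"], ref["F"]))
        assert res.f_between == pytest.approx(f["group"], rel=1e-9)
        assert res.f_within == pytest.approx(f["source"], rel=1e-9)
        assert res.f_interaction == pytest.approx(f["Interaction"], rel=1e-9)

    def test_invariant_to_child_permutation(self, rng):
        scores, groups = self._fixture()
        perm = rng.permutation(len(groups))
        a = mixed_anova(scores, groups)
        b = mixed_anova(scores[perm], groups[perm])
        for attr in ("f_within", "f_between", "f_interaction"):
            assert getattr(a, attr) == pytest.approx(getattr(b, attr))

    def test_missing_cell_rejected(self):
        scores = np.array([[0.1, np.nan], [0.2, 0.3]])
        with pytest.raises(ValueError, match="missing cell"):
            mixed_anova(scores, np.array(["a", "b"]))
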