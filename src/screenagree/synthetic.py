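"""Synthetic parent-report / direct-assessment dyads.

The generator emulates the statistical structure a milestone-screening
agreement study assumes, so the whole pipeline is testable without any
real cohort:

* children aged 24-59 months (uniform integer months), four developmental
  domains, item pass probability increasing with age on a probit scale:
  P(skill) = Phi((age - a50) / s + ability), where a50 is the item's
  50%-pass age and s its slope in months;
* per-child, per-domain latent ability ~ Normal(0, 1), with a "delayed"
  subpopulation of fraction pi shifted by -delta;
* a direct-assessment channel that observes the true skill with assessor
  sensitivity/specificity, and a parental reporting channel with report
  sensitivity/specificity, a not-observed probability nu, and an additive
  SES-dependent reporting bias;
* 95%-limit ages derived from the norm model: the age at which an
  average (ability 0) child passes with probability 0.95.

Probit (rather than logistic) age curves make the binormal ROC model
exactly correct in one simulator limit, giving the ROC module a
closed-form oracle.

`exact_channel_operating_point` computes the sensitivity and specificity
of the parent-report classification against the direct classification by
exhaustive integration (dynamic programming over truncated mark counts,
Gauss-Hermite quadrature over ability), independent of the simulation
path — the oracle used to validate parameter recovery on small item banks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .classification import classify_care, classify_hll
from .instruments import Instrument, InstrumentItem, ItemResponse

_Z95_NORM = 1.6448536269514722  # Phi^-1(0.95)

DOMAIN_ITEM_COUNTS = {
    "personal_social": 11,
    "language_logico_math": 20,
    "fine_motor_adaptive": 9,
    "gross_motor": 7,
}


class CalibrationError(RuntimeError):
    """The target prevalence is not reachable under the configured model."""


def _phi(x: float) -> float:
    """Standard normal CDF (scalar, via erf: much faster than scipy here)."""
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


@dataclass(frozen=True)
class SimConfig:
    """Full generative model for synthetic dyads.

    Defaults mirror the study conditions: 52 dyads aged 24-59 months and
    the 11/20/9/7 items-per-domain booklet structure.  ``delay_shift`` and
    ``delayed_fraction`` are the severity and size of the delayed
    subpopulation; `calibrate_to_paper` tunes them to the reported 75%
    direct-assessment at-risk prevalence.
    """

    n_children: int = 52
    age_min: int = 24
    age_max: int = 59
    n_items_per_domain: tuple[int, int, int, int] = (11, 20, 9, 7)
    slope_months: float = 1.5
    a50_min: float = 24.0
    a50_max: float = 52.0
    admin_tail_months: float = 2.0  # window end past the 95% limit age
    delayed_fraction: float = 0.6  # pi
    delay_shift: float = 2.0  # delta, probit units
    assess_sensitivity: float = 0.97
    assess_specificity: float = 0.97
    report_sensitivity: float = 0.98  # rho_s
    report_specificity: float = 0.85  # rho_c
    p_not_observed: float = 0.05  # nu
    ses_probs: tuple[float, float, float] = (0.28, 0.41, 0.31)
    ses_bias: tuple[float, float, float] = (0.0, 0.04, -0.04)  # beta(SES) on yes-prob
    p_male: float = 0.558
    p_mother_employed: float = 0.74
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (
            self.assess_sensitivity, self.assess_specificity,
            self.report_sensitivity, self.report_specificity,
            self.p_not_observed, self.delayed_fraction,
            self.p_male, self.p_mother_employed, *self.ses_probs,
        )
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.delay_shift < 0:
            raise ValueError("delay_shift must be non-negative")
        if abs(sum(self.ses_probs) - 1) > 1e-9:
            raise ValueError("ses_probs must sum to 1")
        if len(self.n_items_per_domain) != 4 or any(m < 1 for m in self.n_items_per_domain):
            raise ValueError("need at least one item in each of the four domains")
        if not (self.age_min < self.age_max):
            raise ValueError("empty age range")
        if self.slope_months <= 0:
            raise ValueError("slope must be positive")


@dataclass
class DyadDataset:
    demographics: pd.DataFrame
    direct_responses: pd.DataFrame  # child_id, item_id, outcome
    parent_responses: pd.DataFrame
    truth: pd.DataFrame  # child_id, delayed, ability per domain
    direct_instrument: Instrument
    parent_instrument: Instrument
    config: SimConfig


def _p95_limit(a50: float, slope: float) -> float:
    """Age where an average child's pass probability reaches 0.95."""
    return a50 + _Z95_NORM * slope


def generate_item_bank(config: SimConfig) -> tuple[Instrument, Instrument]:
    """Matched direct + parent-report instruments from the norm model.

    Item 50%-pass ages are spread evenly within each domain over
    [a50_min, a50_max] (monotone within domain); every parent item matches
    one direct item (same id and norms).  Parent items belong to the
    24-35 or 36-59 month booklet that contains their 50%-pass age, with
    the booklet window as administration window; direct items get a
    window around their norm ages clipped to [24, 59].
    """
    domains = list(DOMAIN_ITEM_COUNTS)
    direct_items: list[InstrumentItem] = []
    parent_items: list[InstrumentItem] = []
    for d_idx, (domain, m) in enumerate(zip(domains, config.n_items_per_domain)):
        if m == 1:
            a50s = [0.5 * (config.a50_min + config.a50_max)]
        else:
            a50s = list(np.linspace(config.a50_min, config.a50_max, m))
        for j, a50 in enumerate(a50s):
            p95 = _p95_limit(a50, config.slope_months)
            iid = f"{domain[:2]}{d_idx}_{j:02d}"
            # administration starts at the 50%-pass age (never after it) and
            # ends shortly past the 95% limit, like an age-line screening table
            lo = int(np.clip(math.floor(a50), 24, 59))
            hi = int(np.clip(math.ceil(p95 + config.admin_tail_months), lo, 59))
            direct_items.append(
                InstrumentItem(iid, domain, lo, hi, a50, p95, text=f"{domain} milestone {j}")
            )
            glo, ghi = (24, 35) if a50 <= 35 else (36, 59)
            parent_items.append(
                InstrumentItem(iid, domain, glo, ghi, max(a50, glo), p95,
                               text=f"{domain} milestone {j} (parent report)")
            )
    direct = Instrument("HLL-like direct screening (synthetic)", "direct", direct_items)
    parent = Instrument("CARE-like parent booklet (synthetic)", "parent_report", parent_items)
    return direct, parent


def _clip01(x: float) -> float:
    return min(max(x, 0.0), 1.0)


def simulate_dyads(config: SimConfig) -> DyadDataset:
    """Simulate one dataset of dyads under the configured model.

    All randomness flows from ``config.seed``; equal seeds give identical
    tables.  True skill per child x item is shared between the two
    observation channels, so parent-direct agreement reflects exactly the
    channel noise plus applicability differences.
    """
    rng = np.random.default_rng(config.seed)
    direct, parent = generate_item_bank(config)
    domains = list(DOMAIN_ITEM_COUNTS)
    dom_index = {d: i for i, d in enumerate(domains)}

    n = config.n_children
    ages = rng.integers(config.age_min, config.age_max + 1, size=n)
    sexes = np.where(rng.random(n) < config.p_male, "male", "female")
    ses = rng.choice([1, 2, 3], size=n, p=config.ses_probs)
    employed = np.where(rng.random(n) < config.p_mother_employed, "employed", "unemployed")
    caregiver = rng.choice(["mother", "relative", "non_relative"], size=n, p=[0.65, 0.25, 0.10])
    delayed = rng.random(n) < config.delayed_fraction
    ability = rng.normal(0.0, 1.0, size=(n, 4))
    ability[delayed] -= config.delay_shift

    child_ids = [f"c{i:04d}" for i in range(n)]
    items_by_id = {it.item_id: it for it in direct.items}

    direct_rows, parent_rows = [], []
    for i, cid in enumerate(child_ids):
        age = int(ages[i])
        bias = config.ses_bias[int(ses[i]) - 1]
        # true skill for every item potentially observed by either source
        direct_set = {it.item_id for it in direct.items if it.admin_min_age <= age <= it.admin_max_age}
        glo, ghi = (24, 35) if age <= 35 else (36, 59)
        parent_set = {it.item_id for it in parent.items if (it.admin_min_age, it.admin_max_age) == (glo, ghi)}
        for iid in sorted(direct_set | parent_set):
            it = items_by_id[iid]
            abil = ability[i, dom_index[it.domain]]
            p_skill = _phi((age - it.p50_age) / config.slope_months + abil)
            skill = rng.random() < p_skill
            if iid in direct_set:
                p_pass = config.assess_sensitivity if skill else 1 - config.assess_specificity
                outcome = "pass" if rng.random() < p_pass else "fail"
                direct_rows.append((cid, iid, outcome))
            if iid in parent_set:
                if rng.random() < config.p_not_observed:
                    outcome = "not_observed"
                else:
                    p_yes = _clip01(
                        (config.report_sensitivity if skill else 1 - config.report_specificity) + bias
                    )
                    outcome = "pass" if rng.random() < p_yes else "fail"
                parent_rows.append((cid, iid, outcome))

    demographics = pd.DataFrame(
        {
            "child_id": child_ids,
            "age_months": ages,
            "sex": sexes,
            "ses_level": ses,
            "maternal_employment": employed,
            "caregiver": caregiver,
        }
    )
    truth = pd.DataFrame(
        {
            "child_id": child_ids,
            "delayed": delayed,
            **{f"ability_{d}": ability[:, j] for j, d in enumerate(domains)},
        }
    )
    cols = ["child_id", "item_id", "outcome"]
    return DyadDataset(
        demographics=demographics,
        direct_responses=pd.DataFrame(direct_rows, columns=cols),
        parent_responses=pd.DataFrame(parent_rows, columns=cols),
        truth=truth,
        direct_instrument=direct,
        parent_instrument=parent,
        config=config,
    )


def responses_as_objects(frame: pd.DataFrame) -> dict[str, list[ItemResponse]]:
    """Group a response table into per-child ItemResponse lists."""
    out: dict[str, list[ItemResponse]] = {}
    for row in frame.itertuples(index=False):
        out.setdefault(str(row.child_id), []).append(
            ItemResponse(str(row.child_id), str(row.item_id), str(row.outcome))
        )
    return out


# --------------------------------------------------------------------------
# fast vectorised direct-assessment prevalence, used by the calibrator

def _hll_prevalence(config: SimConfig, n: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    direct, _ = generate_item_bank(config)
    a50 = np.array([it.p50_age for it in direct.items])
    p95 = np.array([it.p95_limit_age for it in direct.items])
    lo = np.array([it.admin_min_age for it in direct.items])
    hi = np.array([it.admin_max_age for it in direct.items])
    dom = np.array([list(DOMAIN_ITEM_COUNTS).index(it.domain) for it in direct.items])

    ages = rng.integers(config.age_min, config.age_max + 1, size=n)
    delayed = rng.random(n) < config.delayed_fraction
    ability = rng.normal(0.0, 1.0, size=(n, 4)) - config.delay_shift * delayed[:, None]

    applicable = (ages[:, None] >= lo) & (ages[:, None] <= hi)
    p_skill = stats.norm.cdf((ages[:, None] - a50) / config.slope_months + ability[:, dom])
    skill = rng.random(p_skill.shape) < p_skill
    p_pass = np.where(skill, config.assess_sensitivity, 1 - config.assess_specificity)
    passed = rng.random(p_pass.shape) < p_pass
    fail = applicable & ~passed
    delay = fail & (ages[:, None] > p95)
    caution = fail & ~delay
    at_risk = (delay.sum(axis=1) >= 1) | (caution.sum(axis=1) >= 2)
    return float(at_risk.mean())


def calibrate_to_paper(
    config: SimConfig,
    target_prevalence: float = 0.75,
    tol: float = 0.03,
    n: int = 5000,
    max_delta: float = 6.0,
) -> SimConfig:
    """Tune the delayed subpopulation to a target direct-screening at-risk rate.

    Bisects the severity ``delay_shift`` at the configured delayed fraction;
    if the target exceeds what severity alone can reach, bisects the
    delayed fraction at maximum severity (both directions are monotone).
    Monte-Carlo prevalence uses common random numbers so the objective is
    deterministic in the bisection variable.
    """
    if not 0 <= target_prevalence <= 1:
        raise CalibrationError(f"target prevalence {target_prevalence} outside [0, 1]")
    seed = config.seed + 10_007

    def prev(delta: float, pi: float) -> float:
        c = replace(config, delay_shift=delta, delayed_fraction=pi)
        return _hll_prevalence(c, n=n, seed=seed)

    pi0 = config.delayed_fraction
    f_lo, f_hi = prev(0.0, pi0), prev(max_delta, pi0)
    if f_lo <= target_prevalence <= f_hi:
        lo, hi = 0.0, max_delta
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            f = prev(mid, pi0)
            if abs(f - target_prevalence) <= tol / 2:
                return replace(config, delay_shift=mid)
            if f < target_prevalence:
                lo = mid
            else:
                hi = mid
        return replace(config, delay_shift=0.5 * (lo + hi))
    if target_prevalence > f_hi:
        if prev(max_delta, 1.0) < target_prevalence - tol:
            raise CalibrationError(
                f"target prevalence {target_prevalence} unreachable even with "
                f"delayed_fraction=1 at delta={max_delta}"
            )
        lo, hi = pi0, 1.0
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            f = prev(max_delta, mid)
            if abs(f - target_prevalence) <= tol / 2:
                return replace(config, delay_shift=max_delta, delayed_fraction=mid)
            if f < target_prevalence:
                lo = mid
            else:
                hi = mid
        return replace(config, delay_shift=max_delta, delayed_fraction=0.5 * (lo + hi))
    # target below the no-delay baseline: nothing to bisect
    raise CalibrationError(
        f"target prevalence {target_prevalence} below the baseline rate "
        f"{f_lo:.3f} of the undelayed population"
    )


# --------------------------------------------------------------------------
# exact channel operating point: DP over truncated mark counts

# state axes: (hll_delay flag 0-1, hll_caution 0-2 capped,
#              care_delay flag 0-1, care_caution 0-2 capped, care_unansw 0-4 capped)
_STATE_SHAPE = (2, 3, 2, 3, 5)


def _shift_capped(dist: np.ndarray, axis: int, inc: int) -> np.ndarray:
    """Add ``inc`` to a capped counter axis, mass above the cap piles at the cap."""
    if inc == 0:
        return dist
    out = np.zeros_like(dist)
    m = dist.shape[axis]
    src = np.moveaxis(dist, axis, 0)
    dst = np.moveaxis(out, axis, 0)
    for i in range(m):
        dst[min(i + inc, m - 1)] += src[i]
    return out


def exact_channel_operating_point(config: SimConfig) -> dict[str, float]:
    """Sensitivity/specificity of the parent-report classification vs the
    direct classification, by exhaustive integration.

    Loops over integer ages, delayed status, and SES level; integrates the
    per-domain latent ability with Gauss-Hermite quadrature; propagates a
    joint distribution over truncated (Delay, Caution, unanswered) counts
    through every item with dynamic programming; convolves the four
    domains.  Exact up to the ability quadrature (21 nodes per domain).
    Intended for small item banks, where it is fast.
    """
    direct, parent = generate_item_bank(config)
    domains = list(DOMAIN_ITEM_COUNTS)
    nodes, weights = np.polynomial.hermite_e.hermegauss(21)
    weights = weights / weights.sum()

    ages = range(config.age_min, config.age_max + 1)
    age_w = 1.0 / len(ages)
    joint = np.zeros((2, 2))  # [hll at-risk, care at-risk]

    items_by_domain: dict[str, list[tuple[InstrumentItem, InstrumentItem]]] = {
        d: [] for d in domains
    }
    parent_by_id = {it.item_id: it for it in parent.items}
    for it in direct.items:
        items_by_domain[it.domain].append((it, parent_by_id[it.item_id]))

    for age in ages:
        glo, ghi = (24, 35) if age <= 35 else (36, 59)
        for g, g_w in ((0, 1 - config.delayed_fraction), (1, config.delayed_fraction)):
            if g_w == 0:
                continue
            mu_abil = -config.delay_shift * g
            for ses_idx, ses_w in enumerate(config.ses_probs):
                if ses_w == 0:
                    continue
                bias = config.ses_bias[ses_idx]
                total = np.zeros(_STATE_SHAPE)
                total[0, 0, 0, 0, 0] = 1.0
                for d in domains:
                    dom_dist = np.zeros(_STATE_SHAPE)
                    for node, w in zip(nodes, weights):
                        abil = mu_abil + node
                        dist = np.zeros(_STATE_SHAPE)
                        dist[0, 0, 0, 0, 0] = 1.0
                        for it_d, it_p in items_by_domain[d]:
                            in_direct = it_d.admin_min_age <= age <= it_d.admin_max_age
                            in_parent = (it_p.admin_min_age, it_p.admin_max_age) == (glo, ghi)
                            if not (in_direct or in_parent):
                                continue
                            p_skill = _phi(
                                (age - it_d.p50_age) / config.slope_months + abil
                            )
                            events = _item_events(
                                p_skill, age, it_d, in_direct, in_parent, config, bias
                            )
                            new = np.zeros(_STATE_SHAPE)
                            for prob, incs in events:
                                if prob == 0:
                                    continue
                                shifted = dist
                                for axis, inc in incs:
                                    shifted = _shift_capped(shifted, axis, inc)
                                new += prob * shifted
                            dist = new
                        dom_dist += w * dist
                    total = _convolve_states(total, dom_dist)
                joint += (age_w * g_w * ses_w) * _joint_risk(total)

    sens = joint[1, 1] / joint[1].sum()
    spec = joint[0, 0] / joint[0].sum()
    return {
        "sensitivity": float(sens),
        "specificity": float(spec),
        "hll_prevalence": float(joint[1].sum()),
        "care_positive_rate": float(joint[:, 1].sum()),
    }


def _item_events(
    p_skill: float,
    age: int,
    item: InstrumentItem,
    in_direct: bool,
    in_parent: bool,
    config: SimConfig,
    bias: float,
) -> list[tuple[float, list[tuple[int, int]]]]:
    """Joint (direct mark, parent mark) outcome probabilities for one item,
    marginalised over the latent skill; marks encoded as capped-axis shifts."""
    delay_direct = age > item.p95_limit_age
    d_fail_axis = 0 if delay_direct else 1  # hll delay flag vs caution counter
    p_fail_axis = 0 + 2 if delay_direct else 1 + 2  # care axes offset by 2

    events: dict[tuple[tuple[int, int], ...], float] = {}
    for skill, p_s in ((True, p_skill), (False, 1 - p_skill)):
        if p_s == 0:
            continue
        if in_direct:
            p_pass_d = config.assess_sensitivity if skill else 1 - config.assess_specificity
            d_outcomes = [((), p_pass_d), (((d_fail_axis, 1),), 1 - p_pass_d)]
        else:
            d_outcomes = [((), 1.0)]
        if in_parent:
            p_yes = _clip01(
                (config.report_sensitivity if skill else 1 - config.report_specificity) + bias
            )
            nu = config.p_not_observed
            p_outcomes = [
                ((), (1 - nu) * p_yes),
                (((p_fail_axis, 1),), (1 - nu) * (1 - p_yes)),
                (((4, 1),), nu),
            ]
        else:
            p_outcomes = [((), 1.0)]
        for d_inc, pd_ in d_outcomes:
            for p_inc, pp in p_outcomes:
                key = tuple(d_inc) + tuple(p_inc)
                events[key] = events.get(key, 0.0) + p_s * pd_ * pp
    return [(p, list(k)) for k, p in events.items()]


def _convolve_states(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Sum two independent capped-count states."""
    out = np.zeros(_STATE_SHAPE)
    nz = np.argwhere(b > 0)
    for idx in nz:
        shifted = a
        for axis, inc in enumerate(idx):
            if inc:
                shifted = _shift_capped(shifted, axis, int(inc))
        out += b[tuple(idx)] * shifted
    return out


def _joint_risk(dist: np.ndarray) -> np.ndarray:
    """Collapse the state distribution to the 2x2 (hll risk, care risk) table."""
    hd = np.arange(2)[:, None, None, None, None]
    hc = np.arange(3)[None, :, None, None, None]
    cd = np.arange(2)[None, None, :, None, None]
    cc = np.arange(3)[None, None, None, :, None]
    cu = np.arange(5)[None, None, None, None, :]
    hll_risk = np.broadcast_to((hd >= 1) | (hc >= 2), dist.shape)
    care_risk = np.broadcast_to((cd >= 1) | (cc >= 2) | (cu >= 4), dist.shape)
    out = np.zeros((2, 2))
    for i in (0, 1):
        for j in (0, 1):
            out[i, j] = dist[(hll_risk == bool(i)) & (care_risk == bool(j))].sum()
    return out


def pipeline_operating_point(config: SimConfig, n: int | None = None) -> dict[str, float]:
    """Monte-Carlo sensitivity/specificity of the parent report, computed by
    running the real scoring + classification pipeline on a simulated cohort."""
    from .instruments import score_assessment

    c = config if n is None else replace(config, n_children=n)
    data = simulate_dyads(c)
    ages = dict(zip(data.demographics.child_id, data.demographics.age_months))
    direct_by_child = responses_as_objects(data.direct_responses)
    parent_by_child = responses_as_objects(data.parent_responses)

    joint = np.zeros((2, 2))
    for cid, age in ages.items():
        res_d = score_assessment(direct_by_child.get(cid, []), data.direct_instrument, int(age), child_id=cid)
        res_p = score_assessment(parent_by_child.get(cid, []), data.parent_instrument, int(age), child_id=cid)
        hll = classify_hll(res_d.n_delay, res_d.n_caution)
        care = classify_care(res_p.n_delay, res_p.n_caution, res_p.n_unanswered)
        joint[int(hll.at_risk), int(care.at_risk)] += 1
    return {
        "sensitivity": float(joint[1, 1] / joint[1].sum()),
        "specificity": float(joint[0, 0] / joint[0].sum()),
        "hll_prevalence": float(joint[1].sum() / joint.sum()),
        "care_positive_rate": float(joint[:, 1].sum() / joint.sum()),
    }
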