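"""File formats, run configuration and the end-to-end analysis driver.

All tables are comma-separated UTF-8 text with a mandatory header row and
decimal points.  The driver `run_full_analysis` executes the complete
battery — score, classify, confusion/diagnostics, kappa, item agreement,
ROC (empirical + binormal + Youden), NET/demographic effects, group
tests — and writes CSV tables, plain-text per-child feedback reports and
a machine-readable JSON run summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agreement, diagnostics, group_stats, roc
from .classification import classify_care, classify_hll
from .instruments import Instrument, InstrumentItem, ItemResponse, score_assessment

log = logging.getLogger(__name__)

RESPONSE_COLUMNS = ["child_id", "item_id", "outcome"]
INSTRUMENT_COLUMNS = [
    "item_id", "domain", "admin_min_age", "admin_max_age", "p50_age", "p95_limit_age", "text",
]
DEMOGRAPHIC_COLUMNS = ["child_id", "age_months", "sex", "ses_level", "maternal_employment"]

OUTCOMES = {"pass", "fail", "not_observed"}


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


class AnalysisError(RuntimeError):
    """A pipeline stage failed; message names the stage."""


@dataclass
class RunConfig:
    direct_instrument: str
    parent_instrument: str
    direct_responses: str
    parent_responses: str
    demographics: str
    out_dir: str = "screenagree_out"
    alpha: float = 0.05
    seed: int = 0
    fisher_trigger: str = "observed"  # observed | expected
    roc_bins: int = 10
    score_polarity: str = "low-is-risk"  # low-is-risk | high-is-risk
    sid_reliability: float = 0.9

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.score_polarity not in ("low-is-risk", "high-is-risk"):
            raise ValueError(f"unknown score polarity {self.score_polarity!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    @property
    def low_is_risk(self) -> bool:
        return self.score_polarity == "low-is-risk"


def read_instrument(path: str | Path, name: str | None = None, kind: str = "direct") -> Instrument:
    """Load an instrument definition from CSV (or YAML/JSON with the same fields)."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml", ".json"):
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        name = raw.get("name", name or path.stem)
        kind = raw.get("kind", kind)
        rows = raw["items"]
        frame = pd.DataFrame(rows)
    else:
        frame = pd.read_csv(path)
    missing = [c for c in INSTRUMENT_COLUMNS[:-1] if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing instrument columns {missing}")
    items = []
    for line, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            items.append(
                InstrumentItem(
                    item_id=str(row.item_id),
                    domain=str(row.domain),
                    admin_min_age=int(row.admin_min_age),
                    admin_max_age=int(row.admin_max_age),
                    p50_age=float(row.p50_age),
                    p95_limit_age=float(row.p95_limit_age),
                    text=str(getattr(row, "text", "")),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path} line {line}: {exc}") from exc
    return Instrument(name or path.stem, kind, items)


def read_responses(path: str | Path, known_items: set[str] | None = None) -> list[ItemResponse]:
    """Read a response CSV; rejects unknown outcomes and duplicate pairs
    with the offending line number."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        log.warning("%s: empty response file", path)
        return []
    missing = [c for c in RESPONSE_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing response columns {missing}")
    if frame.empty:
        log.warning("%s: no response rows", path)
        return []
    out: list[ItemResponse] = []
    seen: set[tuple[str, str]] = set()
    for line, row in enumerate(frame.itertuples(index=False), start=2):
        outcome = str(row.outcome)
        if outcome not in OUTCOMES:
            raise ParseError(f"{path} line {line}: unknown outcome {outcome!r}")
        if known_items is not None and str(row.item_id) not in known_items:
            raise ParseError(f"{path} line {line}: unknown item_id {row.item_id!r}")
        key = (str(row.child_id), str(row.item_id))
        if key in seen:
            raise ParseError(f"{path} line {line}: duplicate response for {key}")
        seen.add(key)
        out.append(ItemResponse(str(row.child_id), str(row.item_id), outcome))
    return out


def read_demographics(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in DEMOGRAPHIC_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing demographic columns {missing}")
    frame["child_id"] = frame["child_id"].astype(str)
    return frame


def write_dataset(data, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated DyadDataset in the formats the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for label, inst in (("direct", data.direct_instrument), ("parent", data.parent_instrument)):
        frame = pd.DataFrame(
            [
                {
                    "item_id": it.item_id,
                    "domain": it.domain,
                    "admin_min_age": it.admin_min_age,
                    "admin_max_age": it.admin_max_age,
                    "p50_age": round(it.p50_age, 4),
                    "p95_limit_age": round(it.p95_limit_age, 4),
                    "text": it.text,
                }
                for it in inst.items
            ]
        )
        paths[f"{label}_instrument"] = p = out / f"{label}_instrument.csv"
        frame.to_csv(p, index=False)
    for label, frame in (
        ("direct_responses", data.direct_responses),
        ("parent_responses", data.parent_responses),
        ("demographics", data.demographics),
        ("truth", data.truth),
    ):
        paths[label] = p = out / f"{label}.csv"
        frame.to_csv(p, index=False)
    return paths


# --------------------------------------------------------------------------
# full analysis driver

def _group_by_child(responses: list[ItemResponse]) -> dict[str, list[ItemResponse]]:
    out: dict[str, list[ItemResponse]] = {}
    for r in responses:
        out.setdefault(r.child_id, []).append(r)
    return out


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the whole agreement battery and write the report bundle."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:
                raise AnalysisError(f"stage {name!r} failed: {exc}") from exc
        return deco

    direct_inst = read_instrument(config.direct_instrument, kind="direct")
    parent_inst = read_instrument(config.parent_instrument, kind="parent_report")
    direct_resp = _group_by_child(
        read_responses(config.direct_responses, {i.item_id for i in direct_inst.items})
    )
    parent_resp = _group_by_child(
        read_responses(config.parent_responses, {i.item_id for i in parent_inst.items})
    )
    demo = read_demographics(config.demographics)
    ages = dict(zip(demo.child_id, demo.age_months))

    # children with an empty direct-assessment item set (very young ages on a
    # sparse bank) still score: empty marks, never at risk
    children = sorted(set(parent_resp) & set(ages))
    if not children:
        raise AnalysisError("stage 'score' failed: no children present in all tables")

    # 1-2: score and classify
    @stage("score")
    def scored():
        rows = {}
        for cid in children:
            age = int(ages[cid])
            rd = score_assessment(direct_resp.get(cid, []), direct_inst, age, child_id=cid)
            rp = score_assessment(parent_resp[cid], parent_inst, age, child_id=cid)
            rd.risk = classify_hll(rd.n_delay, rd.n_caution).value
            lab_p = classify_care(rp.n_delay, rp.n_caution, rp.n_unanswered)
            rp.risk = lab_p.value
            rows[cid] = (rd, rp, lab_p.trigger)
        return rows

    hll_labels = [scored[cid][0].risk for cid in children]
    care_labels = [scored[cid][1].risk for cid in children]

    # 3: confusion and diagnostics
    @stage("diagnostics")
    def diag():
        table = diagnostics.confusion(hll_labels, care_labels)
        summ = diagnostics.diagnostic_summary(table)
        post_pos = diagnostics.posttest_probability(summ.prevalence, summ.lr_pos) \
            if not summ.lr_pos_infinite else None
        post_neg = diagnostics.posttest_probability(summ.prevalence, summ.lr_neg)
        return table, summ, post_pos, post_neg

    table, summ, post_pos, post_neg = diag

    # 4: overall kappa
    @stage("kappa")
    def kap():
        return agreement.cohens_kappa([[table.tp, table.fn], [table.fp, table.tn]])

    # 5: item-level agreement
    @stage("item_agreement")
    def item_rows():
        rows = []
        for it in direct_inst.items:
            pairs = []
            for cid in children:
                age = int(ages[cid])
                in_d = any(s.item_id == it.item_id for s in scored[cid][0].scored)
                sp = next((s for s in scored[cid][1].scored if s.item_id == it.item_id), None)
                sd = next((s for s in scored[cid][0].scored if s.item_id == it.item_id), None)
                if sd is None or sp is None or sp.mark == "unanswered":
                    continue
                pairs.append((sp.mark == "positive", sd.mark == "positive"))
            if not pairs:
                continue
            res = agreement.item_agreement(
                [p for p, _ in pairs], [d for _, d in pairs],
                item_id=it.item_id, fisher_trigger=config.fisher_trigger,
            )
            rows.append((it, res))
        return rows

    # 6: ROC on the parent-report overall score
    @stage("roc")
    def roc_res():
        scores = [scored[cid][1].overall_score for cid in children]
        if any(s is None for s in scores):
            usable = [(s, t) for s, t in zip(scores, hll_labels) if s is not None]
            scores, truth = [s for s, _ in usable], [t for _, t in usable]
        else:
            truth = hll_labels
        curve = roc.empirical_roc(scores, truth, low_is_risk=config.low_is_risk)
        scan = roc.youden_scan(curve=curve)
        try:
            fit = roc.binormal_fit(scores, truth, n_bins=config.roc_bins,
                                   low_is_risk=config.low_is_risk)
        except roc.FitNotIdentifiableError as exc:
            log.warning("binormal fit skipped: %s", exc)
            fit = None
        return curve, scan, fit

    curve, scan, fit = roc_res

    # 7: NET indices and demographic group tests
    @stage("group_stats")
    def net_and_groups():
        both = [
            cid for cid in children
            if scored[cid][0].overall_score is not None
            and scored[cid][1].overall_score is not None
        ]
        care_scores = [scored[cid][1].overall_score for cid in both]
        hll_scores = [scored[cid][0].overall_score for cid in both]
        recs = group_stats.net_records(
            both, care_scores, hll_scores, reliability=config.sid_reliability
        )
        demo_idx = demo.set_index("child_id")
        nets = {r.child_id: r.net for r in recs if not r.flagged}

        def groups_by(column):
            vals: dict[str, list[float]] = {}
            for cid, nv in nets.items():
                key = demo_idx.loc[cid, column]
                if pd.isna(key):
                    continue
                vals.setdefault(str(key), []).append(nv)
            return vals

        tests = {}

        def try_test(name, fn, *args):
            try:
                tests[name] = fn(*args)
            except ValueError as exc:  # degenerate split (constant scores, tiny cell)
                log.warning("group test %s skipped: %s", name, exc)

        ses_groups = groups_by("ses_level")
        if len(ses_groups) >= 2 and all(len(v) >= 2 for v in ses_groups.values()):
            try_test("net_by_ses_anova", group_stats.one_way_anova, list(ses_groups.values()))
            if len(ses_groups) >= 3:
                try_test("net_by_ses_kruskal", group_stats.kruskal_wallis, list(ses_groups.values()))
        emp = groups_by("maternal_employment")
        if len(emp) == 2:
            a, b = emp.values()
            try_test("net_by_employment_mw", group_stats.mann_whitney, a, b)
        sex = groups_by("sex")
        if len(sex) == 2:
            a, b = sex.values()
            try_test("net_by_sex_mw", group_stats.mann_whitney, a, b)

        pairs = np.array([[h, c] for h, c in zip(hll_scores, care_scores)], dtype=float)
        labels = np.array([scored[cid][0].risk for cid in both])
        mixed = group_stats.mixed_anova(pairs, labels) if len(set(labels)) >= 2 else None
        return recs, tests, mixed

    recs, tests, mixed = net_and_groups

    bundle = _assemble_bundle(
        config, children, ages, scored, table, summ, post_pos, post_neg,
        kap, item_rows, curve, scan, fit, recs, tests, mixed, direct_inst,
    )
    _write_bundle(bundle, scored, children, out_dir, item_rows, curve)
    return bundle


def _assemble_bundle(config, children, ages, scored, table, summ, post_pos,
                     post_neg, kap, item_rows, curve, scan, fit, recs, tests, mixed,
                     direct_inst) -> dict:
    pct = lambda x: diagnostics.round_half_up(100 * x)
    bundle = {
        "config": {k: v for k, v in asdict(config).items()},
        "n_children": len(children),
        "classification": {
            "hll_at_risk": table.tp + table.fn,
            "care_at_risk": table.tp + table.fp,
            "confusion": {"tp": table.tp, "fn": table.fn, "fp": table.fp, "tn": table.tn},
        },
        "diagnostics": {
            "sensitivity_pct": pct(summ.sensitivity),
            "specificity_pct": pct(summ.specificity),
            "accuracy_pct": pct(summ.accuracy),
            "prevalence_pct": pct(summ.prevalence),
            "ppv_pct": pct(summ.ppv),
            "npv_pct": pct(summ.npv),
            "lr_pos": None if summ.lr_pos_infinite else diagnostics.round_half_up(summ.lr_pos, 2),
            "lr_pos_infinite": summ.lr_pos_infinite,
            "lr_neg": diagnostics.round_half_up(summ.lr_neg, 2),
            "youden_j": round(summ.youden_j, 4),
            "ci_95": {k: [round(v[0], 4), round(v[1], 4)] for k, v in summ.ci_95.items()},
            "posttest_prob_positive": None if post_pos is None else round(post_pos.posttest_prob, 4),
            "posttest_prob_negative": round(post_neg.posttest_prob, 4),
        },
        "agreement": {
            "kappa": round(kap.kappa, 4),
            "se_kappa": round(kap.se_kappa, 4),
            "ci_95": [round(kap.ci_95[0], 4), round(kap.ci_95[1], 4)],
            "observed_agreement": round(kap.observed_agreement, 4),
            "chance_agreement": round(kap.chance_agreement, 4),
            "band": kap.band,
        },
        "item_agreement": {
            "n_items": len(item_rows),
            "n_significant": sum(
                1 for _, r in item_rows if not r.undefined and r.p_value < config.alpha
            ),
        },
        "roc": {
            "auc_trapezoidal": round(curve.auc_trapezoidal, 4),
            "youden_best_j": round(scan.best_j, 4),
            "youden_best_cutoff": round(scan.best_cutoff, 4),
            "binormal": None if fit is None else {
                "a": round(fit.a, 4), "b": round(fit.b, 4), "az": round(fit.az, 4),
                "converged": fit.converged, "n_cutpoints": fit.n_cutpoints,
            },
        },
        "net": {
            "n": sum(1 for r in recs if not r.flagged),
            "n_flagged_zero_hll": sum(1 for r in recs if r.flagged),
            "mean": round(float(np.mean([r.net for r in recs if not r.flagged])), 4)
            if any(not r.flagged for r in recs) else None,
            "median": round(float(np.median([r.net for r in recs if not r.flagged])), 4)
            if any(not r.flagged for r in recs) else None,
        },
        "group_tests": {
            name: _testdict(res) for name, res in tests.items()
        },
        "mixed_anova": None if mixed is None else {
            "f_source": round(mixed.f_within, 4), "p_source": round(mixed.p_within, 4),
            "f_group": round(mixed.f_between, 4), "p_group": round(mixed.p_between, 4),
            "f_interaction": round(mixed.f_interaction, 4),
            "p_interaction": round(mixed.p_interaction, 4),
        },
    }
    return bundle


def _testdict(res) -> dict:
    if isinstance(res, group_stats.RankTestResult):
        return {
            "u": res.u_statistic, "z": round(res.z, 4), "p": round(res.p_value, 4),
            "r": round(res.effect_r, 4),
            "medians": [res.median1, res.median2], "iqr": [res.iqr1, res.iqr2],
        }
    if isinstance(res, group_stats.AnovaResult):
        return {
            "f": round(res.f_statistic, 4),
            "df": [res.df_between, res.df_within],
            "p": round(res.p_value, 4),
            "eta_squared": round(res.eta_squared, 4),
            "omega_squared": round(res.omega_squared, 4),
            "posthoc": [
                {"groups": list(p.groups), "t": round(p.t_statistic, 4),
                 "p_bonferroni": round(p.p_value, 4), "d": round(p.cohens_d, 4)}
                for p in res.posthoc
            ],
        }
    h, df, p = res
    return {"h": round(h, 4), "df": df, "p": round(p, 4)}


def _write_bundle(bundle, scored, children, out_dir: Path, item_rows, curve) -> None:
    with open(out_dir / "run_summary.json", "w", encoding="utf-8") as fh:
        json.dump(bundle, fh, indent=2)

    # per-child scores table; scores are mean item coefficients in [-1, 1]
    rows = []
    for cid in children:
        rd, rp, trigger = scored[cid]
        rows.append(
            {
                "child_id": cid,
                "hll_overall_score_mean_coeff": rd.overall_score,
                "care_overall_score_mean_coeff": rp.overall_score,
                "hll_n_delay": rd.n_delay, "hll_n_caution": rd.n_caution,
                "care_n_delay": rp.n_delay, "care_n_caution": rp.n_caution,
                "care_n_unanswered": rp.n_unanswered,
                "hll_risk": rd.risk, "care_risk": rp.risk,
                "care_trigger": trigger,
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "scores.csv", index=False)

    item_frame = pd.DataFrame(
        [
            {
                "item_id": it.item_id, "domain": it.domain, "n_pairs": r.n,
                "test_used": r.test_used, "statistic": r.statistic,
                "p_value": r.p_value, "phi": r.effect_size, "kappa": r.kappa,
                "undefined": r.undefined,
            }
            for it, r in item_rows
        ]
    )
    item_frame.to_csv(out_dir / "item_agreement.csv", index=False)

    pd.DataFrame(curve.points, columns=["false_positive_fraction", "true_positive_fraction"]) \
        .to_csv(out_dir / "roc_curve.csv", index=False)

    report_dir = out_dir / "child_reports"
    report_dir.mkdir(exist_ok=True)
    for cid in children:
        rd, rp, trigger = scored[cid]
        lines = [
            f"Screening feedback for child {cid}",
            "=" * 40,
            f"Direct assessment : {rd.n_positive} positive, {rd.n_caution} caution, "
            f"{rd.n_delay} delay -> {rd.risk}",
            f"Parent report     : {rp.n_positive} positive, {rp.n_caution} caution, "
            f"{rp.n_delay} delay, {rp.n_unanswered} unanswered -> {rp.risk}",
            f"Parent-report rule clause fired: {trigger}",
            "Scores are mean item coefficients (+1 positive, 0 caution, -1 delay).",
            f"Direct overall score: {rd.overall_score:.3f}"
            if rd.overall_score is not None else "Direct overall score: undefined",
            f"Parent overall score: {rp.overall_score:.3f}"
            if rp.overall_score is not None else "Parent overall score: undefined",
        ]
        (report_dir / f"{cid}.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
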