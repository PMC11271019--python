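"""Data products behind the interactive figures.

Every figure in the report is coupled with the flat table of records
behind it; the series a chart displays must be reconstructible from
that backing table alone. The builders here therefore work in two
steps: assemble the backing table from the domain data, then derive
the plotted series from the backing table with a pure function
(:func:`series_from_backing`), which makes the coupled-table contract
checkable rather than aspirational.

Covered products: subjects-by-visit bars, the adverse-event
SOC/PT hierarchy shared by treemap and sunburst, the hepatotoxicity
eDish scatter (peak ALT vs peak bilirubin in ULN multiples), lab
spaghetti lines with optional per-arm aggregation, and baseline ->
worst post-baseline shift cross-tabs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .datamodel import DomainTable
from .derivations import (
    DEFAULT_SEVERITY_ORDER,
    classify_partial_date,
    derive_study_day,
    rank_severity,
)
from .summary import MISSING_LABEL, _numeric

__all__ = [
    "ChartPayload",
    "AeTreeNode",
    "visit_attendance",
    "ae_hierarchy",
    "edish",
    "spaghetti_data",
    "shift_data",
    "series_from_backing",
]

#: eDish reference thresholds in ULN multiples (standard Hy's-law
#: quadrant boundaries: ALT at 3x, total bilirubin at 2x).
EDISH_ALT_THRESHOLD = 3.0
EDISH_BILI_THRESHOLD = 2.0


@dataclass
class ChartPayload:
    chart_kind: str
    series: dict
    backing_table: list[dict]
    links: dict[str, str | None] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def rebuild_series(self) -> dict:
        """Recompute the series from the backing table alone."""
        return series_from_backing(self.chart_kind, self.backing_table, self.meta)


@dataclass
class AeTreeNode:
    level: str  # "SOC" | "PT"
    label: str
    parent: str | None
    n_subjects: int
    pct: float | None
    n_events: int
    worst_severity_rank: int
    subjects: list[str] = field(default_factory=list)


def _attach_links(payload: ChartPayload, link_index: Mapping[str, str] | None) -> None:
    link_index = link_index or {}
    subjects = {r["subject_id"] for r in payload.backing_table if r.get("subject_id")}
    payload.links = {s: link_index.get(s) for s in sorted(subjects)}


# ------------------------------------------------------------- builders


def visit_attendance(
    sv: DomainTable,
    dm: DomainTable,
    groups: Mapping[str, str],
    link_index: Mapping[str, str] | None = None,
) -> ChartPayload:
    """Distinct subjects per visit per arm (the study snapshot bars)."""
    backing = []
    seen = set()
    for rec in sv.records():
        sid = rec[sv.subject_id_var]
        if sid not in groups:
            continue
        visitnum = _numeric(rec.get("VISITNUM"))
        key = (sid, visitnum)
        if key in seen:  # duplicate visit rows count once
            continue
        seen.add(key)
        backing.append(
            {
                "subject_id": sid,
                "group": groups[sid],
                "visit": rec.get("VISIT") or f"VISIT {visitnum:g}",
                "visit_order": visitnum,
            }
        )
    payload = ChartPayload("visit_bar", {}, backing)
    payload.series = payload.rebuild_series()
    _attach_links(payload, link_index)
    return payload


def ae_hierarchy(
    ae: DomainTable,
    population: Sequence[str],
    severity_order: Sequence[str] = DEFAULT_SEVERITY_ORDER,
    soc_var: str = "AEBODSYS",
    pt_var: str = "AEDECOD",
    severity_var: str = "AESEV",
) -> list[AeTreeNode]:
    """SOC/PT tree shared by the treemap and sunburst figures.

    Preferred-term nodes aggregate their events; each system-organ-class
    node's subject count is the union of its PTs' subject sets while its
    event count is the sum. Node shading is driven by the worst severity
    rank among the node's events.
    """
    popset = set(population)
    events = []
    for rec in ae.records():
        sid = rec[ae.subject_id_var]
        if sid not in popset:
            continue
        events.append(
            {
                "sid": sid,
                "soc": rec.get(soc_var) or MISSING_LABEL,
                "pt": rec.get(pt_var) or MISSING_LABEL,
                "rank": rank_severity(rec.get(severity_var), severity_order),
            }
        )
    denom = len(set(popset))
    nodes: list[AeTreeNode] = []
    for soc in sorted({e["soc"] for e in events}):
        soc_events = [e for e in events if e["soc"] == soc]
        soc_subjects = sorted({e["sid"] for e in soc_events})
        nodes.append(
            AeTreeNode(
                "SOC", soc, None,
                n_subjects=len(soc_subjects),
                pct=100.0 * len(soc_subjects) / denom if denom else None,
                n_events=len(soc_events),
                worst_severity_rank=max(e["rank"] for e in soc_events),
                subjects=soc_subjects,
            )
        )
        for pt in sorted({e["pt"] for e in soc_events}):
            pt_events = [e for e in soc_events if e["pt"] == pt]
            pt_subjects = sorted({e["sid"] for e in pt_events})
            nodes.append(
                AeTreeNode(
                    "PT", pt, soc,
                    n_subjects=len(pt_subjects),
                    pct=100.0 * len(pt_subjects) / denom if denom else None,
                    n_events=len(pt_events),
                    worst_severity_rank=max(e["rank"] for e in pt_events),
                    subjects=pt_subjects,
                )
            )
    return nodes


def ae_hierarchy_payload(
    ae: DomainTable,
    population: Sequence[str],
    severity_order: Sequence[str] = DEFAULT_SEVERITY_ORDER,
    link_index: Mapping[str, str] | None = None,
    **kwargs,
) -> ChartPayload:
    """The AE tree as a chart payload with its backing record table."""
    soc_var = kwargs.get("soc_var", "AEBODSYS")
    pt_var = kwargs.get("pt_var", "AEDECOD")
    severity_var = kwargs.get("severity_var", "AESEV")
    popset = set(population)
    backing = [
        {
            "subject_id": rec[ae.subject_id_var],
            "soc": rec.get(soc_var) or MISSING_LABEL,
            "pt": rec.get(pt_var) or MISSING_LABEL,
            "severity_rank": rank_severity(rec.get(severity_var), severity_order),
            "severity": rec.get(severity_var),
        }
        for rec in ae.records()
        if rec[ae.subject_id_var] in popset
    ]
    payload = ChartPayload(
        "treemap", {}, backing, meta={"denominator": len(popset)}
    )
    payload.series = payload.rebuild_series()
    _attach_links(payload, link_index)
    return payload


def _subject_reference_dates(dm: DomainTable, ref_var: str = "RFSTDTC") -> dict:
    refs = {}
    for rec in dm.records():
        status = classify_partial_date(rec.get(ref_var))
        refs[rec[dm.subject_id_var]] = status.date
    return refs


def _lab_points(
    lb: DomainTable,
    dm: DomainTable,
    testcd: str,
    uln: Mapping[str, float] | None,
    testcd_var: str = "LBTESTCD",
    result_var: str = "LBORRES",
    date_var: str = "LBDTC",
) -> list[dict]:
    refs = _subject_reference_dates(dm)
    points = []
    for rec in lb.records():
        if rec.get(testcd_var) != testcd:
            continue
        sid = rec[lb.subject_id_var]
        value = _numeric(rec.get(result_var))
        if value is None:
            continue
        ref = refs.get(sid)
        date = classify_partial_date(rec.get(date_var)).date
        day = derive_study_day(date, ref) if ref and date else None
        limit = _numeric(rec.get("LBORNRHI"))
        if limit is None and uln:
            limit = uln.get(testcd)
        points.append(
            {
                "subject_id": sid,
                "parameter": testcd,
                "study_day": day,
                "value": value,
                "uln": limit,
                "visit": rec.get("VISIT"),
            }
        )
    return points


def edish(
    lb: DomainTable,
    dm: DomainTable,
    uln: Mapping[str, float] | None = None,
    alt_code: str = "ALT",
    bili_code: str = "BILI",
    link_index: Mapping[str, str] | None = None,
) -> ChartPayload:
    """Hepatotoxicity eDish scatter: peak post-baseline ALT vs bilirubin.

    Per subject, x is the maximum post-baseline ALT in ULN multiples
    and y the maximum post-baseline total bilirubin in ULN multiples
    (independent per-parameter maxima). Reference lines sit at 3x
    (ALT) and 2x (bilirubin); subjects beyond both fall in the
    potential Hy's-law quadrant. The backing table keeps every
    visit-level measurement so selecting a subject can highlight all
    their visits. Subjects lacking both parameters are excluded.
    """
    backing = []
    for code in (alt_code, bili_code):
        for p in _lab_points(lb, dm, code, uln):
            if p["study_day"] is not None and p["study_day"] > 1 and p["uln"]:
                p["uln_ratio"] = p["value"] / p["uln"]
                backing.append(p)
    payload = ChartPayload(
        "edish", {}, backing,
        meta={
            "alt_code": alt_code, "bili_code": bili_code,
            "alt_threshold": EDISH_ALT_THRESHOLD,
            "bili_threshold": EDISH_BILI_THRESHOLD,
            "log_scale": True,
        },
    )
    payload.series = payload.rebuild_series()
    _attach_links(payload, link_index)
    return payload


def spaghetti_data(
    lb: DomainTable,
    dm: DomainTable,
    parameter: str,
    groups: Mapping[str, str],
    thresholds: tuple[float | None, float | None] | None = None,
    subset_rule: str | None = None,
    aggregate: bool = True,
    link_index: Mapping[str, str] | None = None,
) -> ChartPayload:
    """Per-subject lab trajectories with optional per-arm aggregation.

    ``subset_rule="any_abnormal"`` keeps only subjects with at least
    one value outside the record-level reference range (or the supplied
    thresholds), the usual way to declutter a spaghetti plot down to
    the subjects worth reviewing. The aggregated overlay is the
    per-visit per-arm mean +/- sample SD.
    """
    refs = _subject_reference_dates(dm)
    points = []
    for rec in lb.records():
        if rec.get("LBTESTCD") != parameter:
            continue
        sid = rec[lb.subject_id_var]
        if sid not in groups:
            continue
        value = _numeric(rec.get("LBORRES"))
        if value is None:
            continue
        lo = _numeric(rec.get("LBORNRLO"))
        hi = _numeric(rec.get("LBORNRHI"))
        if thresholds is not None:
            lo = thresholds[0] if thresholds[0] is not None else lo
            hi = thresholds[1] if thresholds[1] is not None else hi
        ref = refs.get(sid)
        date = classify_partial_date(rec.get("LBDTC")).date
        points.append(
            {
                "subject_id": sid,
                "group": groups[sid],
                "parameter": parameter,
                "visit": rec.get("VISIT"),
                "visit_order": _numeric(rec.get("VISITNUM")),
                "study_day": derive_study_day(date, ref) if ref and date else None,
                "value": value,
                "low": lo,
                "high": hi,
                "abnormal": (lo is not None and value < lo)
                or (hi is not None and value > hi),
            }
        )

    if subset_rule == "any_abnormal":
        keep = {p["subject_id"] for p in points if p["abnormal"]}
        points = [p for p in points if p["subject_id"] in keep]
    elif subset_rule is not None:
        raise ValueError(f"unknown subset rule {subset_rule!r}")

    payload = ChartPayload(
        "spaghetti", {}, points,
        meta={"parameter": parameter, "aggregate": aggregate},
    )
    payload.series = payload.rebuild_series()
    _attach_links(payload, link_index)
    return payload


def shift_data(
    lb: DomainTable,
    dm: DomainTable,
    parameter: str,
    groups: Mapping[str, str],
    link_index: Mapping[str, str] | None = None,
) -> ChartPayload:
    """Baseline -> worst post-baseline shift table for one parameter.

    Baseline is the last non-missing value on or before study day 1;
    post-baseline values are classified low/normal/high against the
    record-level reference range, and the worst post-baseline category
    is the most extreme abnormal one (high outranking low when both
    occur). Subjects without a baseline land in a ``no baseline``
    margin; the series is the per-arm cross-tab of the category pairs.
    """
    refs = _subject_reference_dates(dm)
    per_subject: dict[str, list[dict]] = {}
    for rec in lb.records():
        if rec.get("LBTESTCD") != parameter:
            continue
        sid = rec[lb.subject_id_var]
        value = _numeric(rec.get("LBORRES"))
        if value is None:
            continue
        ref = refs.get(sid)
        date = classify_partial_date(rec.get("LBDTC")).date
        per_subject.setdefault(sid, []).append(
            {
                "subject_id": sid,
                "study_day": derive_study_day(date, ref) if ref and date else None,
                "value": value,
                "low": _numeric(rec.get("LBORNRLO")),
                "high": _numeric(rec.get("LBORNRHI")),
            }
        )

    def classify(point: dict) -> str:
        if point["low"] is not None and point["value"] < point["low"]:
            return "low"
        if point["high"] is not None and point["value"] > point["high"]:
            return "high"
        return "normal"

    backing = []
    for sid, pts in per_subject.items():
        if sid not in groups:
            continue
        baseline_pts = [p for p in pts if p["study_day"] is not None and p["study_day"] <= 1]
        post_pts = [p for p in pts if p["study_day"] is not None and p["study_day"] > 1]
        if baseline_pts:
            baseline_pt = max(baseline_pts, key=lambda p: p["study_day"])
            baseline = classify(baseline_pt)
        else:
            baseline = "no baseline"
        if post_pts:
            cats = {classify(p) for p in post_pts}
            worst = "high" if "high" in cats else ("low" if "low" in cats else "normal")
        else:
            worst = "no post-baseline"
        backing.append(
            {
                "subject_id": sid,
                "group": groups[sid],
                "parameter": parameter,
                "baseline": baseline,
                "worst": worst,
            }
        )
    payload = ChartPayload("shift", {}, backing, meta={"parameter": parameter})
    payload.series = payload.rebuild_series()
    _attach_links(payload, link_index)
    return payload


# ---------------------------------------------- series reconstruction


def series_from_backing(chart_kind: str, backing: list[dict], meta: dict) -> dict:
    """Derive a chart's series purely from its backing table."""
    if chart_kind == "visit_bar":
        counts: dict[tuple, set] = {}
        orders: dict[str, float] = {}
        for r in backing:
            counts.setdefault((r["visit"], r["group"]), set()).add(r["subject_id"])
            if r.get("visit_order") is not None:
                orders[r["visit"]] = r["visit_order"]
        visits = sorted({v for v, _ in counts}, key=lambda v: (orders.get(v, 0), v))
        groups = sorted({g for _, g in counts})
        return {
            "visits": visits,
            "groups": groups,
            "counts": {
                g: [len(counts.get((v, g), set())) for v in visits] for g in groups
            },
        }

    if chart_kind == "treemap":
        denom = meta.get("denominator") or 0
        tree: dict[str, dict] = {}
        for r in backing:
            soc = tree.setdefault(
                r["soc"], {"subjects": set(), "events": 0, "rank": 0, "pts": {}}
            )
            soc["subjects"].add(r["subject_id"])
            soc["events"] += 1
            soc["rank"] = max(soc["rank"], r["severity_rank"])
            pt = soc["pts"].setdefault(
                r["pt"], {"subjects": set(), "events": 0, "rank": 0}
            )
            pt["subjects"].add(r["subject_id"])
            pt["events"] += 1
            pt["rank"] = max(pt["rank"], r["severity_rank"])
        nodes = []
        for soc in sorted(tree):
            s = tree[soc]
            nodes.append(
                {
                    "level": "SOC", "label": soc, "parent": None,
                    "n_subjects": len(s["subjects"]),
                    "pct": 100.0 * len(s["subjects"]) / denom if denom else None,
                    "n_events": s["events"],
                    "worst_severity_rank": s["rank"],
                }
            )
            for pt in sorted(s["pts"]):
                p = s["pts"][pt]
                nodes.append(
                    {
                        "level": "PT", "label": pt, "parent": soc,
                        "n_subjects": len(p["subjects"]),
                        "pct": 100.0 * len(p["subjects"]) / denom if denom else None,
                        "n_events": p["events"],
                        "worst_severity_rank": p["rank"],
                    }
                )
        return {"nodes": nodes}

    if chart_kind == "edish":
        alt_code = meta.get("alt_code", "ALT")
        bili_code = meta.get("bili_code", "BILI")
        alt_thr = meta.get("alt_threshold", EDISH_ALT_THRESHOLD)
        bili_thr = meta.get("bili_threshold", EDISH_BILI_THRESHOLD)
        maxima: dict[str, dict[str, float]] = {}
        for r in backing:
            m = maxima.setdefault(r["subject_id"], {})
            m[r["parameter"]] = max(m.get(r["parameter"], 0.0), r["uln_ratio"])
        points = []
        for sid in sorted(maxima):
            m = maxima[sid]
            if alt_code not in m and bili_code not in m:
                continue
            x = m.get(alt_code)
            y = m.get(bili_code)
            if x is None or y is None:
                quadrant = "incomplete"
            elif x >= alt_thr and y >= bili_thr:
                quadrant = "potential Hy's law"
            elif x >= alt_thr:
                quadrant = "isolated transaminase elevation"
            elif y >= bili_thr:
                quadrant = "isolated hyperbilirubinemia"
            else:
                quadrant = "normal"
            points.append(
                {"subject_id": sid, "x": x, "y": y, "quadrant": quadrant}
            )
        return {
            "points": points,
            "reference_lines": {"x": alt_thr, "y": bili_thr},
        }

    if chart_kind == "spaghetti":
        lines: dict[str, list] = {}
        for r in sorted(
            backing,
            key=lambda r: (r["subject_id"], r["study_day"] if r["study_day"] is not None else 0),
        ):
            lines.setdefault(r["subject_id"], []).append(
                {"study_day": r["study_day"], "value": r["value"]}
            )
        series = {
            "lines": [
                {
                    "subject_id": sid,
                    "group": next(
                        r["group"] for r in backing if r["subject_id"] == sid
                    ),
                    "points": pts,
                }
                for sid, pts in sorted(lines.items())
            ],
            "thresholds": {
                "low": next((r["low"] for r in backing if r.get("low") is not None), None),
                "high": next((r["high"] for r in backing if r.get("high") is not None), None),
            },
        }
        if meta.get("aggregate"):
            import statistics

            agg: dict[tuple, list[float]] = {}
            orders: dict[str, float] = {}
            for r in backing:
                if r.get("visit") is None:
                    continue
                agg.setdefault((r["group"], r["visit"]), []).append(r["value"])
                if r.get("visit_order") is not None:
                    orders[r["visit"]] = r["visit_order"]
            series["aggregated"] = [
                {
                    "group": g,
                    "visit": v,
                    "n": len(vals),
                    "mean": statistics.fmean(vals),
                    "sd": statistics.stdev(vals) if len(vals) > 1 else None,
                }
                for (g, v), vals in sorted(
                    agg.items(), key=lambda kv: (kv[0][0], orders.get(kv[0][1], 0), kv[0][1])
                )
            ]
        return series

    if chart_kind == "shift":
        cats = ["low", "normal", "high", "no baseline", "no post-baseline"]
        tabs: dict[str, dict[tuple, int]] = {}
        for r in backing:
            tabs.setdefault(r["group"], {})
            key = (r["baseline"], r["worst"])
            tabs[r["group"]][key] = tabs[r["group"]].get(key, 0) + 1
        return {
            "categories": cats,
            "crosstab": {
                g: [
                    {"baseline": b, "worst": w, "n": n}
                    for (b, w), n in sorted(t.items())
                ]
                for g, t in sorted(tabs.items())
            },
        }

    raise ValueError(f"unknown chart kind {chart_kind!r}")
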