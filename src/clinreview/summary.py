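"""Descriptive and incidence summary tables with subject drill-down.

The tables mirror standard clinical-study-report summaries: demographic
frequency tables, continuous descriptive statistics, subject
disposition, and treatment-emergent adverse-event incidence at worst
severity. Each incidence cell carries the contributing subject ids so
the rendered report can link every count to the patient profiles behind
it, and any table can carry a side-by-side column recomputed on a
previous data batch.

Grouping is by treatment arm via a subject -> arm mapping; a blinded
run simply maps every subject to a single pooled column, so blinded and
unblinded outputs differ only by that mapping.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import pandas as pd

from .datamodel import DomainTable, StudyBatch
from .derivations import (
    DEFAULT_SEVERITY_ORDER,
    classify_partial_date,
    derive_study_day,
    rank_severity,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SummaryCell",
    "SummaryRow",
    "SummaryTable",
    "subject_groups",
    "summarize_categorical",
    "summarize_continuous",
    "flag_treatment_emergent",
    "summarize_ae",
    "summarize_disposition",
    "attach_previous_batch",
    "export_table",
]

#: Column label used when no treatment grouping applies (blinded runs).
ALL_GROUP = "All"

#: Row label aggregating every adverse event.
ANY_EVENT = "Any event"

#: Label for missing category levels / uncoded terms.
MISSING_LABEL = "Missing"

EXPORT_FORMATS = ("interactive_html_data", "csv", "static_doc")


@dataclass
class SummaryCell:
    """Statistics for one (row, column) of a summary table.

    Incidence tables fill ``n_subjects``/``pct``/``n_events``;
    continuous tables fill ``n``..``max``. Values are stored unrounded;
    rounding happens at export. ``subjects`` lists the distinct subject
    ids behind the cell, for profile linking.
    """

    n_subjects: int | None = None
    pct: float | None = None
    n_events: int | None = None
    n: int | None = None
    n_missing: int | None = None
    mean: float | None = None
    sd: float | None = None
    median: float | None = None
    min: float | None = None
    max: float | None = None
    subjects: list[str] = field(default_factory=list)

    def stats_equal(self, other: "SummaryCell") -> bool:
        for f in ("n_subjects", "pct", "n_events", "n", "n_missing",
                  "mean", "sd", "median", "min", "max"):
            a, b = getattr(self, f), getattr(other, f)
            if a is None or b is None:
                if a is not b:
                    return False
            elif isinstance(a, float) or isinstance(b, float):
                if not math.isclose(float(a), float(b), rel_tol=1e-12, abs_tol=1e-12):
                    return False
            elif a != b:
                return False
        return True


@dataclass
class SummaryRow:
    path: tuple[str, ...]  # nested labels, e.g. (SOC, PT, severity)
    cells: dict[str, SummaryCell]

    @property
    def label(self) -> str:
        return self.path[-1]

    @property
    def depth(self) -> int:
        return len(self.path) - 1


@dataclass
class PreviousColumn:
    """A previous batch's statistics, matched to current rows by path."""

    batch_id: str
    available: bool
    cells: dict[tuple[tuple[str, ...], str], SummaryCell] = field(default_factory=dict)
    reason: str | None = None


@dataclass
class SummaryTable:
    title: str
    columns: list[str]
    denominators: dict[str, int]
    rows: list[SummaryRow]
    previous: PreviousColumn | None = None

    def row(self, *path: str) -> SummaryRow:
        for r in self.rows:
            if r.path == tuple(path):
                return r
        raise KeyError(f"no row {path!r} in table {self.title!r}")

    def cell(self, path: tuple[str, ...] | str, column: str) -> SummaryCell:
        if isinstance(path, str):
            path = (path,)
        return self.row(*path).cells[column]


def subject_groups(
    dm: DomainTable, group_var: str | None, population: Sequence[str] | None = None
) -> dict[str, str]:
    """Subject -> treatment-arm mapping from the demographics table.

    With ``group_var=None`` (blinded run) every subject maps to the
    single pooled column.
    """
    pop = set(population) if population is not None else None
    out: dict[str, str] = {}
    for rec in dm.records():
        sid = rec[dm.subject_id_var]
        if pop is not None and sid not in pop:
            continue
        if group_var is None:
            out[sid] = ALL_GROUP
        else:
            out[sid] = rec.get(group_var) or MISSING_LABEL
    return out


def _column_order(groups: Mapping[str, str]) -> list[str]:
    seen: dict[str, None] = {}
    for g in groups.values():
        seen.setdefault(g)
    return sorted(seen)


def _denominators(
    population: Sequence[str], groups: Mapping[str, str], columns: Sequence[str]
) -> dict[str, int]:
    denom = {c: 0 for c in columns}
    for sid in dict.fromkeys(population):
        g = groups.get(sid)
        if g in denom:
            denom[g] += 1
    return denom


def summarize_categorical(
    table: DomainTable,
    var: str,
    groups: Mapping[str, str],
    population: Sequence[str],
    level_order: Sequence[str] | None = None,
    order: str = "frequency",
    title: str | None = None,
) -> SummaryTable:
    """Frequency table of a categorical variable: n (%) per arm x level.

    Counts are distinct subjects; percentages use the per-arm analysis
    population as denominator. A ``Missing`` row appears only when
    missing values exist. ``order`` is ``"given"`` (use *level_order*),
    ``"frequency"`` (descending total count) or ``"alphabetic"``.
    """
    if var not in table.variables:
        raise ValueError(f"{table.domain_code}: variable {var} not present")
    if not population:
        raise ValueError("population must be non-empty")
    pop = list(dict.fromkeys(population))
    columns = _column_order(groups)
    denom = _denominators(pop, groups, columns)

    # level -> column -> distinct subject ids
    by_level: dict[str, dict[str, set[str]]] = {}
    popset = set(pop)
    for rec in table.records():
        sid = rec[table.subject_id_var]
        if sid not in popset or sid not in groups:
            continue
        level = rec.get(var)
        label = MISSING_LABEL if level in (None, "") else str(level)
        by_level.setdefault(label, {}).setdefault(groups[sid], set()).add(sid)

    levels = [lv for lv in by_level if lv != MISSING_LABEL]
    if order == "given" and level_order is not None:
        known = [lv for lv in level_order if lv in by_level]
        levels = known + sorted(set(levels) - set(known))
    elif order == "alphabetic":
        levels = sorted(levels)
    else:  # frequency
        totals = {lv: sum(len(s) for s in by_level[lv].values()) for lv in levels}
        levels = sorted(levels, key=lambda lv: (-totals[lv], lv))
    if MISSING_LABEL in by_level:
        levels.append(MISSING_LABEL)

    rows = []
    for lv in levels:
        cells = {}
        for col in columns:
            subs = sorted(by_level.get(lv, {}).get(col, set()))
            n = len(subs)
            cells[col] = SummaryCell(
                n_subjects=n,
                pct=100.0 * n / denom[col] if denom[col] else None,
                subjects=subs,
            )
        rows.append(SummaryRow((lv,), cells))
    return SummaryTable(
        title=title or f"Summary of {table.label(var)}",
        columns=columns,
        denominators=denom,
        rows=rows,
    )


def _numeric(value) -> float | None:
    if value in (None, ""):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        return None


def summarize_continuous(
    table: DomainTable,
    var: str,
    groups: Mapping[str, str],
    population: Sequence[str],
    title: str | None = None,
) -> SummaryTable:
    """Descriptive statistics of a numeric variable per arm.

    n, mean, sample SD (n-1 denominator), median, min, max. Values that
    do not coerce to a number are excluded from the statistics and
    counted in ``n_missing``. With n=1 the SD is not defined and stays
    absent; with n=0 all statistics are absent.
    """
    if var not in table.variables:
        raise ValueError(f"{table.domain_code}: variable {var} not present")
    popset = set(population)
    columns = _column_order(groups)
    denom = _denominators(list(dict.fromkeys(population)), groups, columns)

    values: dict[str, list[float]] = {c: [] for c in columns}
    missing: dict[str, int] = {c: 0 for c in columns}
    subjects: dict[str, set[str]] = {c: set() for c in columns}
    for rec in table.records():
        sid = rec[table.subject_id_var]
        if sid not in popset or sid not in groups:
            continue
        col = groups[sid]
        x = _numeric(rec.get(var))
        if x is None:
            missing[col] += 1
        else:
            values[col].append(x)
            subjects[col].add(sid)

    rows_cells = {}
    for col in columns:
        xs = pd.Series(values[col], dtype=float)
        n = len(xs)
        rows_cells[col] = SummaryCell(
            n=n,
            n_missing=missing[col],
            mean=float(xs.mean()) if n else None,
            sd=float(xs.std(ddof=1)) if n > 1 else None,
            median=float(xs.median()) if n else None,
            min=float(xs.min()) if n else None,
            max=float(xs.max()) if n else None,
            subjects=sorted(subjects[col]),
        )
    return SummaryTable(
        title=title or f"Summary of {table.label(var)}",
        columns=columns,
        denominators=denom,
        rows=[SummaryRow((table.label(var),), rows_cells)],
    )


def exposure_windows(
    exposure: DomainTable,
    start_var: str = "EXSTDTC",
    end_var: str = "EXENDTC",
) -> dict[str, tuple]:
    """Per subject: (first dose date, last dose date or None if ongoing)."""
    windows: dict[str, list] = {}
    for rec in exposure.records():
        sid = rec[exposure.subject_id_var]
        start = classify_partial_date(rec.get(start_var)).date
        end = classify_partial_date(rec.get(end_var)).date
        first, last, open_end = windows.get(sid, (None, None, False))
        if start is not None and (first is None or start < first):
            first = start
        if end is None:
            open_end = True
        elif last is None or end > last:
            last = end
        windows[sid] = [first, last, open_end]
    return {
        sid: (first, None if open_end else last)
        for sid, (first, last, open_end) in windows.items()
    }


def flag_treatment_emergent(
    ae: DomainTable,
    exposure: DomainTable,
    lag_days: int = 30,
    start_var: str = "AESTDTC",
    ex_start_var: str = "EXSTDTC",
    ex_end_var: str = "EXENDTC",
) -> pd.Series:
    """Treatment-emergent flag per AE record.

    An AE is treatment-emergent when its (earliest-imputed) onset falls
    between the subject's first dose and last dose + ``lag_days``. AEs
    with a fully missing onset are included conservatively; subjects
    absent from the exposure table get ``False`` with a logged warning.
    An exposure record without an end date marks ongoing dosing (no
    upper bound).
    """
    windows = exposure_windows(exposure, ex_start_var, ex_end_var)
    flags = []
    warned: set[str] = set()
    for rec in ae.records():
        sid = rec[ae.subject_id_var]
        if sid not in windows:
            if sid not in warned:
                logger.warning(
                    "subject %s has adverse events but no exposure record", sid
                )
                warned.add(sid)
            flags.append(False)
            continue
        first, last = windows[sid]
        status = classify_partial_date(rec.get(start_var))
        if status.status == "missing_all":
            flags.append(True)  # unknown onset: keep, do not hide
            continue
        onset = status.date
        ok = first is not None and onset >= first
        if ok and last is not None:
            ok = (onset - last).days <= lag_days
        flags.append(bool(ok))
    return pd.Series(flags, index=ae.data.index, name="TEAE")


def summarize_ae(
    ae: DomainTable,
    population: Sequence[str],
    groups: Mapping[str, str],
    severity_order: Sequence[str] = DEFAULT_SEVERITY_ORDER,
    soc_var: str = "AEBODSYS",
    pt_var: str = "AEDECOD",
    severity_var: str = "AESEV",
    include_severity: bool = True,
    title: str = "Adverse events by system organ class and preferred term",
) -> SummaryTable:
    """Incidence of adverse events at worst severity per subject.

    Row hierarchy: an overall ``Any event`` row, then system organ
    class (SOC) -> preferred term (PT) -> severity. Within any row a
    subject counts exactly once, at the worst severity of their events
    under that row; ``n_events`` counts every event. SOC subject counts
    are therefore unions of their PTs' subject sets, not sums, while
    severity child rows partition their PT's subjects. Rows are ordered
    by descending total subject count, ties alphabetical.
    """
    popset = set(population)
    columns = _column_order(groups)
    denom = _denominators(list(dict.fromkeys(population)), groups, columns)

    events = []
    for rec in ae.records():
        sid = rec[ae.subject_id_var]
        if sid not in popset or sid not in groups:
            continue
        events.append(
            {
                "sid": sid,
                "col": groups[sid],
                "soc": rec.get(soc_var) or MISSING_LABEL,
                "pt": rec.get(pt_var) or MISSING_LABEL,
                "rank": rank_severity(rec.get(severity_var), severity_order),
            }
        )

    sev_label = list(severity_order) + [MISSING_LABEL]

    def incidence_cells(evs: list[dict]) -> dict[str, SummaryCell]:
        cells = {}
        for col in columns:
            sub = [e for e in evs if e["col"] == col]
            subs = sorted({e["sid"] for e in sub})
            cells[col] = SummaryCell(
                n_subjects=len(subs),
                pct=100.0 * len(subs) / denom[col] if denom[col] else None,
                n_events=len(sub),
                subjects=subs,
            )
        return cells

    def subject_count(evs: list[dict]) -> int:
        return len({e["sid"] for e in evs})

    rows = [SummaryRow((ANY_EVENT,), incidence_cells(events))]

    socs = sorted(
        {e["soc"] for e in events},
        key=lambda s: (-subject_count([e for e in events if e["soc"] == s]), s),
    )
    for soc in socs:
        soc_events = [e for e in events if e["soc"] == soc]
        rows.append(SummaryRow((soc,), incidence_cells(soc_events)))
        pts = sorted(
            {e["pt"] for e in soc_events},
            key=lambda p: (-subject_count([e for e in soc_events if e["pt"] == p]), p),
        )
        for pt in pts:
            pt_events = [e for e in soc_events if e["pt"] == pt]
            rows.append(SummaryRow((soc, pt), incidence_cells(pt_events)))
            if include_severity:
                # worst severity per subject within this PT
                worst: dict[str, int] = {}
                for e in pt_events:
                    worst[e["sid"]] = max(worst.get(e["sid"], 0), e["rank"])
                for rank in sorted(set(worst.values())):
                    label = (
                        sev_label[rank - 1]
                        if rank - 1 < len(sev_label)
                        else MISSING_LABEL
                    )
                    cells = {}
                    for col in columns:
                        subs = sorted(
                            s
                            for s, r in worst.items()
                            if r == rank and groups.get(s) == col
                        )
                        cells[col] = SummaryCell(
                            n_subjects=len(subs),
                            pct=(
                                100.0 * len(subs) / denom[col] if denom[col] else None
                            ),
                            subjects=subs,
                        )
                    rows.append(SummaryRow((soc, pt, label), cells))
    return SummaryTable(title=title, columns=columns, denominators=denom, rows=rows)


def summarize_disposition(
    ds: DomainTable,
    population: Sequence[str],
    groups: Mapping[str, str],
    reference_dates: Mapping[str, str] | None = None,
    status_var: str = "DSDECOD",
    completed_value: str = "COMPLETED",
    date_var: str = "DSSTDTC",
) -> tuple[SummaryTable, list[dict]]:
    """Subject disposition counts plus the discontinuation listing.

    Subjects whose disposition record equals ``completed_value`` count
    as completed; any other disposition counts as discontinued with the
    record's value as reason. Population subjects without a disposition
    record are ongoing. The companion listing has one row per
    discontinuation (subject, reason, study day) for profile linking.
    """
    popset = set(dict.fromkeys(population))
    columns = _column_order(groups)
    denom = _denominators(list(dict.fromkeys(population)), groups, columns)

    status: dict[str, tuple[str, str | None]] = {}
    for rec in ds.records():
        sid = rec[ds.subject_id_var]
        if sid not in popset:
            continue
        status[sid] = (rec.get(status_var) or MISSING_LABEL, rec.get(date_var))

    def cells_for(pred) -> dict[str, SummaryCell]:
        cells = {}
        for col in columns:
            subs = sorted(
                s for s in popset if groups.get(s) == col and pred(s)
            )
            cells[col] = SummaryCell(
                n_subjects=len(subs),
                pct=100.0 * len(subs) / denom[col] if denom[col] else None,
                subjects=subs,
            )
        return cells

    completed = lambda s: s in status and status[s][0] == completed_value
    discontinued = lambda s: s in status and status[s][0] != completed_value
    ongoing = lambda s: s not in status

    rows = [
        SummaryRow(("Completed",), cells_for(completed)),
        SummaryRow(("Discontinued",), cells_for(discontinued)),
    ]
    if any(ongoing(s) for s in popset):
        rows.append(SummaryRow(("Ongoing",), cells_for(ongoing)))

    listing = []
    for sid in sorted(s for s in popset if discontinued(s)):
        reason, date_text = status[sid]
        study_day = None
        imputed = False
        if reference_dates and reference_dates.get(sid):
            ds_status = classify_partial_date(date_text)
            if ds_status.date is not None:
                study_day = derive_study_day(
                    ds_status.date, classify_partial_date(reference_dates[sid]).date
                )
                imputed = ds_status.imputed
        listing.append(
            {
                "subject_id": sid,
                "group": groups.get(sid),
                "reason": reason,
                "study_day": study_day,
                "date_imputed": imputed,
            }
        )
    table = SummaryTable(
        title="Subject disposition",
        columns=columns,
        denominators=denom,
        rows=rows,
    )
    return table, listing


def attach_previous_batch(
    table: SummaryTable,
    previous: StudyBatch,
    compute: Callable[[StudyBatch], SummaryTable],
) -> SummaryTable:
    """Attach a side-by-side column recomputed on the previous batch.

    ``compute`` is the identical summary operation, re-run on
    *previous*. Rows that did not exist in the previous batch get empty
    previous cells; if the previous batch lacks a required domain the
    previous column is marked unavailable and the current table is
    returned intact.
    """
    try:
        prev_table = compute(previous)
    except KeyError as exc:
        table.previous = PreviousColumn(
            batch_id=previous.batch_id, available=False, reason=str(exc)
        )
        return table
    cells = {
        (row.path, col): row.cells[col]
        for row in prev_table.rows
        for col in prev_table.columns
    }
    table.previous = PreviousColumn(
        batch_id=previous.batch_id, available=True, cells=cells
    )
    return table


# ---------------------------------------------------------------- export


def format_stat(value, kind: str) -> str:
    if value is None:
        return ""
    if kind == "pct":
        return f"{value:.1f}"
    if kind in ("n_subjects", "n_events", "n", "n_missing"):
        return str(int(value))
    # continuous statistics: data precision + one extra digit
    text = f"{float(value):.4g}"
    return text


_STAT_KINDS = [
    "n_subjects", "pct", "n_events", "n", "n_missing",
    "mean", "sd", "median", "min", "max",
]


def _table_frame(table: SummaryTable) -> pd.DataFrame:
    """Long-format frame: one line per (row, column), formatted values."""
    lines = []
    for row in table.rows:
        for col in table.columns:
            cell = row.cells[col]
            line = {
                "row": ("  " * row.depth) + row.label,
                "column": col,
            }
            for kind in _STAT_KINDS:
                line[kind] = format_stat(getattr(cell, kind), kind)
            lines.append(line)
    return pd.DataFrame(lines)


def table_payload(table: SummaryTable, link_index: Mapping[str, str] | None = None) -> dict:
    """JSON-serializable payload for the interactive table widget.

    Carries the row hierarchy, unformatted-then-formatted cell values,
    per-cell subject ids and their profile link targets.
    """
    link_index = link_index or {}
    rows = []
    for row in table.rows:
        cells = {}
        for col in table.columns:
            cell = row.cells[col]
            cells[col] = {
                "stats": {
                    kind: getattr(cell, kind)
                    for kind in _STAT_KINDS
                    if getattr(cell, kind) is not None
                },
                "display": {
                    kind: format_stat(getattr(cell, kind), kind)
                    for kind in _STAT_KINDS
                    if getattr(cell, kind) is not None
                },
                "subjects": [
                    {"subject_id": s, "profile": link_index.get(s)}
                    for s in cell.subjects
                ],
            }
        rows.append({"path": list(row.path), "cells": cells})
    payload = {
        "title": table.title,
        "columns": table.columns,
        "denominators": table.denominators,
        "rows": rows,
    }
    if table.previous is not None:
        payload["previous_batch"] = {
            "batch_id": table.previous.batch_id,
            "available": table.previous.available,
            "cells": [
                {
                    "path": list(path),
                    "column": col,
                    "stats": {
                        kind: getattr(cell, kind)
                        for kind in _STAT_KINDS
                        if getattr(cell, kind) is not None
                    },
                }
                for (path, col), cell in table.previous.cells.items()
            ],
        }
    return payload


def _listing_frame(listing: Sequence[Mapping]) -> pd.DataFrame:
    return pd.DataFrame(list(listing))


def _paginate_text(frame: pd.DataFrame, title: str, rows_per_page: int = 40) -> str:
    """Plain paginated document: pages separated by form feeds."""
    if frame.empty:
        return f"{title}\n\n(no data)\n"
    text = frame.fillna("").astype(str)
    widths = {
        c: max(len(c), int(text[c].str.len().max())) for c in text.columns
    }
    header = "  ".join(c.ljust(widths[c]) for c in text.columns)
    rule = "-" * len(header)
    pages = []
    for start in range(0, len(text), rows_per_page):
        chunk = text.iloc[start : start + rows_per_page]
        body = "\n".join(
            "  ".join(str(row[c]).ljust(widths[c]) for c in text.columns)
            for _, row in chunk.iterrows()
        )
        pages.append(f"{title}\n{header}\n{rule}\n{body}\n")
    return "\f".join(pages)


def export_table(
    table,
    format: str,
    path=None,
    link_index: Mapping[str, str] | None = None,
    title: str | None = None,
):
    """Export a summary table (or a listing) for downstream consumption.

    ``format`` is one of ``interactive_html_data`` (JSON payload dict,
    optionally written to *path*), ``csv`` (flat file, hierarchy as an
    indented label column), or ``static_doc`` (plain paginated document
    text). Listings (sequences of record dicts) share the same formats.
    """
    if format not in EXPORT_FORMATS:
        raise ValueError(
            f"unknown format {format!r}: supported formats are {', '.join(EXPORT_FORMATS)}"
        )
    is_table = isinstance(table, SummaryTable)
    if format == "interactive_html_data":
        if is_table:
            payload = table_payload(table, link_index)
        else:
            link_index = link_index or {}
            payload = {
                "title": title or "Listing",
                "rows": [
                    {**dict(r), "profile": link_index.get(dict(r).get("subject_id"))}
                    for r in table
                ],
            }
        if path is not None:
            import json

            with open(path, "w", encoding="utf-8") as fh:
                json.dump(payload, fh, indent=1, sort_keys=True)
        return payload

    frame = _table_frame(table) if is_table else _listing_frame(table)
    if format == "csv":
        if path is None:
            raise ValueError("csv export requires a path")
        frame.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
        return path
    doc = _paginate_text(frame, title or (table.title if is_table else "Listing"))
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(doc)
        return path
    return doc
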