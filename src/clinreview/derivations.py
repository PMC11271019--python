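"""Light analysis-dataset derivations on SDTM-like records.

These are the standard fine-tunings applied between raw domain tables
and review displays: relative study days, partial-date flags with
earliest-date imputation, numeric severity ordering, categorization of
continuous variables, same-visit averaging of ECG/vital-sign
measurements, and the Fridericia-corrected QT interval (QTcF).

Dates are ISO-8601 text up to this point; everything here is explicit
about what happens to partial dates (``YYYY`` or ``YYYY-MM``), because
the review displays must flag imputed timings rather than hide them.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass
from statistics import fmean
from typing import Iterable, Mapping, Sequence

__all__ = [
    "DateStatus",
    "derive_study_day",
    "classify_partial_date",
    "rank_severity",
    "categorize_numeric",
    "average_visit_window",
    "derive_qtcf",
]

_ISO_RE = re.compile(r"^(\d{4})(?:-(\d{2}))?(?:-(\d{2}))?$")

#: Default clinical severity scale; any ordered list (e.g. CTCAE grades
#: ``["1", "2", "3", "4", "5"]``) may be substituted via configuration.
DEFAULT_SEVERITY_ORDER = ["MILD", "MODERATE", "SEVERE"]


@dataclass(frozen=True)
class DateStatus:
    """Completeness classification of an ISO date text.

    ``status`` is one of ``complete``, ``missing_day``,
    ``missing_month_day``, ``missing_all``. For partial (but not fully
    missing) dates, ``imputed_date`` is the earliest calendar date
    consistent with the text (missing day -> 01, missing month -> 01).
    """

    status: str
    imputed_date: dt.date | None

    @property
    def imputed(self) -> bool:
        return self.status != "complete" and self.imputed_date is not None

    @property
    def date(self) -> dt.date | None:
        """The usable date: actual when complete, else the imputation."""
        return self.imputed_date


def parse_iso_date(text: str) -> dt.date:
    """Parse a complete ISO-8601 date, rejecting partial text."""
    status = classify_partial_date(text)
    if status.status != "complete":
        raise ValueError(f"requires complete date, got {text!r}")
    assert status.imputed_date is not None
    return status.imputed_date


def classify_partial_date(text: str | None) -> DateStatus:
    """Classify an ISO date prefix (``YYYY``, ``YYYY-MM``, ``YYYY-MM-DD``).

    Empty/missing text is ``missing_all`` and carries no imputed date.
    Malformed text (impossible month or day, wrong shape) raises.
    """
    if text is None or text == "":
        return DateStatus("missing_all", None)
    # Datetime values may carry a time part; the date prefix is what counts.
    text = str(text).split("T")[0]
    m = _ISO_RE.match(text)
    if not m:
        raise ValueError(f"unparseable date: {text!r}")
    year, month, day = m.groups()
    try:
        if day is not None:
            return DateStatus("complete", dt.date(int(year), int(month), int(day)))
        if month is not None:
            return DateStatus("missing_day", dt.date(int(year), int(month), 1))
        return DateStatus("missing_month_day", dt.date(int(year), 1, 1))
    except ValueError as exc:
        raise ValueError(f"unparseable date: {text!r}") from exc


def derive_study_day(date: dt.date | str, reference_date: dt.date | str) -> int:
    """Relative study day with no day zero.

    The reference date (typically first treatment) is day 1; the day
    before it is day -1. Both dates must be complete — impute partial
    dates first so the flag can travel with the result.
    """
    if isinstance(date, str):
        date = parse_iso_date(date)
    if isinstance(reference_date, str):
        reference_date = parse_iso_date(reference_date)
    delta = (date - reference_date).days
    return delta + 1 if delta >= 0 else delta


def rank_severity(level: str | None, ordered_levels: Sequence[str]) -> int:
    """1-based rank of *level* in an ordered severity scale.

    Matching is case-insensitive; an unknown or missing level ranks one
    past the end so it sorts after every known level.
    """
    if not ordered_levels:
        raise ValueError("ordered_levels must be non-empty")
    if level is not None:
        needle = str(level).strip().upper()
        for i, known in enumerate(ordered_levels, start=1):
            if known.strip().upper() == needle:
                return i
    return len(ordered_levels) + 1


def categorize_numeric(
    value, breaks: Sequence[float], labels: Sequence[str]
) -> str | None:
    """Map a numeric value to a labelled interval.

    Intervals are left-closed/right-open, except the last which is
    closed above, so ``breaks=[65]`` splits into ``< 65`` and ``>= 65``.
    Non-numeric input yields a missing label (``None``).
    """
    if len(labels) != len(breaks) + 1:
        raise ValueError("need exactly len(breaks)+1 labels")
    if list(breaks) != sorted(breaks):
        raise ValueError("breaks must be ascending")
    try:
        x = float(value)
    except (TypeError, ValueError):
        return None
    for cut, label in zip(breaks, labels):
        if x < cut:
            return label
    return labels[-1]


def average_visit_window(
    records: Sequence[Mapping],
    nominal_day: int,
    window_days: float = 3,
    result_key: str = "result",
    day_key: str = "study_day",
    time_key: str = "timestamp",
) -> list[dict]:
    """Average same-visit measurements falling within a day window.

    All *records* belong to one subject/parameter/visit. Records whose
    study day lies within ``window_days`` of the visit's nominal day are
    collapsed to one record holding the arithmetic mean of their numeric
    results and the earliest timestamp; ``averaged_flag`` is set when
    more than one record contributed. Records outside the window pass
    through untouched. If the window holds records but none has a
    numeric result, a single record with a missing result is emitted.

    The operation is idempotent: re-averaging its output changes nothing.
    """
    in_window: list[Mapping] = []
    passthrough: list[dict] = []
    for rec in records:
        day = rec.get(day_key)
        if day is not None and abs(float(day) - nominal_day) <= window_days:
            in_window.append(rec)
        else:
            out = dict(rec)
            out.setdefault("averaged_flag", False)
            passthrough.append(out)

    out_records: list[dict] = []
    if in_window:
        values = []
        for rec in in_window:
            try:
                values.append(float(rec[result_key]))
            except (KeyError, TypeError, ValueError):
                pass
        merged = dict(in_window[0])
        timestamps = [r.get(time_key) for r in in_window if r.get(time_key)]
        if timestamps:
            merged[time_key] = min(timestamps)
        days = [float(r[day_key]) for r in in_window]
        merged[day_key] = min(days, key=lambda d: (abs(d - nominal_day), d))
        if values:
            merged[result_key] = fmean(values)
            # once averaged, always flagged — keeps the operation idempotent
            merged["averaged_flag"] = len(values) > 1 or any(
                r.get("averaged_flag") for r in in_window
            )
        else:
            merged[result_key] = None
            merged["averaged_flag"] = False
        out_records.append(merged)
    out_records.extend(passthrough)
    return out_records


def derive_qtcf(
    qt_ms: float,
    rr_s: float | None = None,
    hr_bpm: float | None = None,
) -> float | None:
    """Fridericia-corrected QT interval, in milliseconds.

    QTcF = QT / RR^(1/3) with RR in seconds. A measured RR interval is
    preferred; otherwise RR is reconstructed from heart rate as 60/HR.
    When neither constituent exists the value is simply not derived.
    """
    if qt_ms is None or float(qt_ms) <= 0:
        raise ValueError("qt_ms must be present and > 0")
    if rr_s is None:
        if hr_bpm is None or float(hr_bpm) <= 0:
            return None
        rr_s = 60.0 / float(hr_bpm)
    rr_s = float(rr_s)
    if rr_s <= 0:
        raise ValueError("rr_s must be > 0")
    return float(qt_ms) / rr_s ** (1.0 / 3.0)
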