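"""Per-subject patient profiles: stacked modules on a study-day axis.

A profile aggregates one subject's data across domains into an ordered
stack of visualization modules — *text* (label/value pairs, e.g.
demographics), *event* (point-in-time markers, e.g. disposition),
*interval* (bars with possibly ongoing ends, e.g. adverse events or
exposure), and *line* (parameter trajectories with reference bands,
e.g. labs) — sharing one horizontal axis in study days. Modules are
paginated greedily into fixed-height pages and rendered to one
paginated vector (PDF) document per subject.

Timings derived from partial dates keep their imputation flag and are
drawn with a distinct open marker, so a reviewer can tell a recorded
date from an imputed one.

Rendering is deterministic: the same batch and configuration produce
byte-identical documents, serially or across worker processes.
"""

from __future__ import annotations

import datetime as dt
import json
import re
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

from matplotlib import pyplot as plt
from matplotlib.backends.backend_pdf import PdfPages

from .datamodel import StudyBatch
from .derivations import classify_partial_date, derive_study_day
from .summary import _numeric

__all__ = [
    "ProfileModule",
    "PatientProfile",
    "build_module",
    "compose_profile",
    "render_profiles",
    "default_profile_config",
]

_MODULE_KINDS = ("text", "event", "interval", "line")


@dataclass
class ProfileModule:
    kind: str
    title: str
    domain_code: str
    empty: bool = False
    text_items: list[tuple[str, str]] = field(default_factory=list)
    events: list[dict] = field(default_factory=list)
    intervals: list[dict] = field(default_factory=list)
    lines: list[dict] = field(default_factory=list)

    @property
    def height(self) -> float:
        """Module height in abstract page units (page default is 10)."""
        if self.kind == "text":
            return 1.0 + 0.25 * len(self.text_items)
        if self.kind == "event":
            return 1.0 + 0.35 * max(len(self.events), 1)
        if self.kind == "interval":
            return 1.0 + 0.35 * max(len(self.intervals), 1)
        return 2.5 * max(len(self.lines), 1)

    def day_span(self) -> tuple[int, int] | None:
        days: list[int] = []
        for e in self.events:
            if e["study_day"] is not None:
                days.append(e["study_day"])
        for iv in self.intervals:
            if iv["start_day"] is not None:
                days.append(iv["start_day"])
            if iv["end_day"] is not None:
                days.append(iv["end_day"])
        for line in self.lines:
            days.extend(p[0] for p in line["points"] if p[0] is not None)
        if not days:
            return None
        return min(days), max(days)


@dataclass
class PatientProfile:
    subject_id: str
    modules: list[ProfileModule]
    time_range: tuple[int, int]
    pages: list[list[ProfileModule]]
    file_name: str


def subject_file_name(subject_id: str) -> str:
    """Deterministic, filesystem-safe document stem for a subject."""
    return re.sub(r"[^A-Za-z0-9_-]+", "-", subject_id) + ".pdf"


def _subject_records(batch: StudyBatch, domain: str, subject_id: str) -> list[dict]:
    table = batch.domain(domain)
    return [r for r in table.records() if r[table.subject_id_var] == subject_id]


def _reference_date(batch: StudyBatch, subject_id: str, config: Mapping) -> dt.date | None:
    domain = config.get("reference_domain", "DM")
    var = config.get("reference_var", "RFSTDTC")
    recs = _subject_records(batch, domain, subject_id)
    if not recs:
        return None
    return classify_partial_date(recs[0].get(var)).date


def _day(date_text, ref: dt.date | None) -> tuple[int | None, bool]:
    """(study day, imputed flag) for a possibly partial date text."""
    status = classify_partial_date(date_text)
    if status.date is None or ref is None:
        return None, status.status != "complete"
    return derive_study_day(status.date, ref), status.imputed


def build_module(config: Mapping, batch: StudyBatch, subject_id: str) -> ProfileModule:
    """Build one profile module for a subject from its config fragment.

    The fragment names the module ``kind``, the source ``domain`` and a
    variable mapping (see the packaged default profile config for the
    shape per kind). A module with no records for the subject is valid
    and marked empty; a configured variable missing from the domain is
    an error naming both.
    """
    kind = config["kind"]
    if kind not in _MODULE_KINDS:
        raise ValueError(f"unknown module kind {kind!r}")
    domain = config["domain"]
    table = batch.domain(domain)
    title = config.get("title", f"{domain} ({kind})")

    def need(var: str) -> str:
        if var not in table.variables:
            raise ValueError(f"profile module {title!r}: variable {var} absent from {domain}")
        return var

    records = _subject_records(batch, domain, subject_id)
    module = ProfileModule(kind=kind, title=title, domain_code=domain)
    ref = _reference_date(batch, subject_id, config)

    if kind == "text":
        variables = [need(v) for v in config["variables"]]
        if records:
            rec = records[0]
            module.text_items = [
                (table.label(v), rec.get(v) if rec.get(v) is not None else "")
                for v in variables
            ]
    elif kind == "event":
        label_var = need(config["label_var"])
        date_var = need(config["date_var"])
        marker_var = config.get("marker_var")
        if marker_var:
            need(marker_var)
        for rec in records:
            day, imputed = _day(rec.get(date_var), ref)
            module.events.append(
                {
                    "label": rec.get(label_var) or "(missing)",
                    "study_day": day,
                    "imputed": imputed,
                    "date": rec.get(date_var),
                    "marker": rec.get(marker_var) if marker_var else None,
                }
            )
    elif kind == "interval":
        label_var = need(config["label_var"])
        start_var = need(config["start_var"])
        end_var = need(config["end_var"])
        for rec in records:
            start_day, start_imputed = _day(rec.get(start_var), ref)
            end_status = classify_partial_date(rec.get(end_var))
            end_missing = end_status.date is None
            end_day, end_imputed = _day(rec.get(end_var), ref)
            if start_day is not None and end_day is not None and end_day < start_day:
                end_day = start_day
            module.intervals.append(
                {
                    "label": rec.get(label_var) or "(missing)",
                    "start_day": start_day,
                    "end_day": end_day,
                    "end_missing": end_missing,
                    "start_imputed": start_imputed,
                    "end_imputed": end_imputed,
                }
            )
    else:  # line
        param_var = need(config["parameter_var"])
        result_var = need(config["result_var"])
        date_var = need(config["date_var"])
        low_var = config.get("low_var")
        high_var = config.get("high_var")
        parameters = config.get("parameters")
        by_param: dict[str, dict] = {}
        for rec in records:
            param = rec.get(param_var)
            if param is None or (parameters and param not in parameters):
                continue
            value = _numeric(rec.get(result_var))
            if value is None:
                continue
            day, imputed = _day(rec.get(date_var), ref)
            entry = by_param.setdefault(
                param,
                {
                    "parameter": param,
                    "points": [],
                    "imputed": [],
                    "reference_low": _numeric(rec.get(low_var)) if low_var else None,
                    "reference_high": _numeric(rec.get(high_var)) if high_var else None,
                },
            )
            entry["points"].append((day, value))
            entry["imputed"].append(imputed)
        order = parameters or sorted(by_param)
        module.lines = [by_param[p] for p in order if p in by_param]

    module.empty = not (
        module.text_items or module.events or module.intervals or module.lines
    )
    return module


def compose_profile(
    modules: Sequence[ProfileModule],
    subject_id: str,
    page_height_units: float = 10.0,
) -> PatientProfile:
    """Stack modules and paginate greedily.

    Modules keep their configured order; a module that does not fit in
    the remaining page height starts a new page (no module is split).
    A module taller than a whole page gets a page of its own.
    """
    if not modules:
        raise ValueError("a profile needs at least one module")
    pages: list[list[ProfileModule]] = [[]]
    remaining = page_height_units
    for module in modules:
        if module.height > remaining and pages[-1]:
            pages.append([])
            remaining = page_height_units
        pages[-1].append(module)
        remaining -= module.height
    spans = [s for m in modules if (s := m.day_span()) is not None]
    if spans:
        time_range = (min(s[0] for s in spans), max(s[1] for s in spans))
    else:
        time_range = (1, 1)
    return PatientProfile(
        subject_id=subject_id,
        modules=list(modules),
        time_range=time_range,
        pages=pages,
        file_name=subject_file_name(subject_id),
    )


# ------------------------------------------------------------ rendering


def _render_module(ax, module: ProfileModule, time_range) -> None:
    ax.set_title(module.title, fontsize=9, loc="left")
    if module.kind == "text":
        ax.axis("off")
        lines = [f"{label}: {value}" for label, value in module.text_items] or ["(no data)"]
        ax.text(0.01, 0.95, "\n".join(lines), va="top", fontsize=8, family="monospace")
        return
    ax.set_xlim(time_range[0] - 1, time_range[1] + 1)
    ax.tick_params(labelsize=7)
    if module.kind == "event":
        labels = [e["label"] for e in module.events] or ["(no data)"]
        seen: dict[str, int] = {}
        for label in labels:
            seen.setdefault(label, len(seen))
        for e in module.events:
            if e["study_day"] is None:
                continue
            y = seen[e["label"]]
            marker = "o" if not e["imputed"] else "D"
            fill = "full" if not e["imputed"] else "none"
            ax.plot([e["study_day"]], [y], marker=marker, fillstyle=fill,
                    color="#16324f", linestyle="none", markersize=5)
        ax.set_yticks(range(len(seen)), list(seen))
        ax.set_ylim(-0.6, max(len(seen) - 0.4, 0.6))
    elif module.kind == "interval":
        seen = {}
        for iv in module.intervals:
            seen.setdefault(iv["label"], len(seen))
        for iv in module.intervals:
            if iv["start_day"] is None:
                continue
            y = seen[iv["label"]]
            end = iv["end_day"] if iv["end_day"] is not None else time_range[1] + 1
            ax.plot([iv["start_day"], end], [y, y], color="#5a7d9a", linewidth=4,
                    solid_capstyle="butt")
            start_marker = "D" if iv["start_imputed"] else "|"
            ax.plot([iv["start_day"]], [y], marker=start_marker, color="#16324f",
                    fillstyle="none", markersize=5)
            if iv["end_missing"]:
                # ongoing: open-ended arrow past the axis edge
                ax.plot([end], [y], marker=">", color="#5a7d9a", fillstyle="none",
                        markersize=6)
        ax.set_yticks(range(len(seen)), list(seen))
        ax.set_ylim(-0.6, max(len(seen) - 0.4, 0.6))
    else:  # line
        for entry in module.lines:
            pts = [(d, v) for d, v in entry["points"] if d is not None]
            pts.sort()
            if not pts:
                continue
            xs, ys = zip(*pts)
            ax.plot(xs, ys, marker="o", markersize=3, linewidth=1,
                    label=entry["parameter"])
            lo, hi = entry["reference_low"], entry["reference_high"]
            if lo is not None and hi is not None:
                ax.axhspan(lo, hi, color="#d9e6d9", alpha=0.5, zorder=0)
        if module.lines:
            ax.legend(fontsize=6, loc="upper right")
    if module.empty:
        ax.text(0.5, 0.5, "(no data)", transform=ax.transAxes,
                ha="center", fontsize=8, color="#6b7a8f")


def render_profile_pdf(profile: PatientProfile, path: Path) -> None:
    """Render one profile to a paginated PDF with deterministic bytes."""
    with PdfPages(
        path,
        metadata={
            "Creator": "clinreview", "Producer": "clinreview",
            "Title": f"Patient profile {profile.subject_id}",
            "CreationDate": None,
        },
    ) as pdf:
        for page_modules in profile.pages:
            heights = [m.height for m in page_modules]
            fig, axes = plt.subplots(
                len(page_modules), 1,
                figsize=(8.27, 11.69),  # A4 portrait
                gridspec_kw={"height_ratios": heights},
                squeeze=False,
            )
            fig.suptitle(f"Patient profile — {profile.subject_id}", fontsize=11)
            for ax, module in zip(axes[:, 0], page_modules):
                _render_module(ax, module, profile.time_range)
            axes[-1, 0].set_xlabel("Study day", fontsize=8)
            fig.subplots_adjust(hspace=0.8, top=0.93, bottom=0.06)
            pdf.savefig(fig)
            plt.close(fig)


def _render_one(args) -> tuple[str, str]:
    batch, config, subject_id, out_dir = args
    modules = [build_module(mc, batch, subject_id) for mc in config["modules"]]
    profile = compose_profile(
        modules, subject_id, config.get("page_height_units", 10.0)
    )
    out_path = Path(out_dir) / profile.file_name
    render_profile_pdf(profile, out_path)
    return subject_id, profile.file_name


def render_profiles(
    batch: StudyBatch,
    config: Mapping,
    subjects: Sequence[str] | None = None,
    out_dir: str | Path = ".",
    jobs: int = 1,
) -> dict[str, str]:
    """Render one profile document per subject; return the link index.

    ``subjects=None`` renders everyone in DM; subjects not present in
    DM are skipped with a warning. The link index (subject id ->
    relative document path) is written as a JSON sidecar and consumed
    by the table/chart link annotations. Rendering is independent per
    subject and parallelizable across worker processes (``jobs``),
    producing identical bytes either way.
    """
    import logging

    out_dir = Path(out_dir)
    profile_dir = out_dir / "profiles"
    profile_dir.mkdir(parents=True, exist_ok=True)
    dm_subjects = batch.domain(config.get("reference_domain", "DM")).subjects
    if subjects is None:
        subjects = dm_subjects
    else:
        known = set(dm_subjects)
        kept = []
        for s in subjects:
            if s in known:
                kept.append(s)
            else:
                logging.getLogger(__name__).warning(
                    "subject %s not in DM: profile skipped", s
                )
        subjects = kept

    tasks = [(batch, config, sid, str(profile_dir)) for sid in subjects]
    if jobs > 1 and len(tasks) > 1:
        with ProcessPoolExecutor(max_workers=jobs) as pool:
            results = list(pool.map(_render_one, tasks))
    else:
        results = [_render_one(t) for t in tasks]

    index = {sid: f"profiles/{name}" for sid, name in results}
    with open(out_dir / "profile_index.json", "w", encoding="utf-8") as fh:
        json.dump(index, fh, indent=1, sort_keys=True)
    return index


def default_profile_config() -> dict:
    """Module stack used when a report config does not define one.

    Demographics first, then exposure and adverse-event intervals,
    disposition events, and lab trajectories — the conventional
    top-to-bottom reading order of a patient profile.
    """
    return {
        "page_height_units": 10.0,
        "modules": [
            {"kind": "text", "domain": "DM", "title": "Demographics",
             "variables": ["AGE", "SEX", "RACE", "COUNTRY"]},
            {"kind": "interval", "domain": "EX", "title": "Treatment exposure",
             "label_var": "EXTRT", "start_var": "EXSTDTC", "end_var": "EXENDTC"},
            {"kind": "interval", "domain": "AE", "title": "Adverse events",
             "label_var": "AEDECOD", "start_var": "AESTDTC", "end_var": "AEENDTC"},
            {"kind": "event", "domain": "DS", "title": "Disposition",
             "label_var": "DSDECOD", "date_var": "DSSTDTC"},
            {"kind": "line", "domain": "LB", "title": "Laboratory",
             "parameter_var": "LBTESTCD", "result_var": "LBORRES",
             "date_var": "LBDTC", "low_var": "LBORNRLO", "high_var": "LBORNRHI"},
        ],
    }
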