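"""Report build driver: YAML config -> standalone multi-chapter HTML.

The pipeline parses a YAML report configuration (merging the packaged
blinded or unblinded defaults), validates each chapter's parameters
against the JSON schema shipped with its template, renders patient
profiles and every chapter to self-contained HTML, and assembles a
navigable index carrying a unique report identifier.

The identifier's digest component is a content hash of the
configuration and the input data, so rebuilding the same inputs yields
the same digest; the build timestamp is confined to the manifest.
Chapter renders are independent of each other: a failing chapter
produces an error page without affecting its siblings, and chapters
can render in parallel worker processes with byte-identical output.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import html as H
from .datamodel import StudyBatch, check_required_variables
from .charts import (
    ae_hierarchy_payload,
    edish,
    shift_data,
    spaghetti_data,
    visit_attendance,
)
from .diff import DEFAULT_DIFF_KEYS, diff_batches, diff_listing
from .profiles import render_profiles
from .schema import ValidationReport, validate
from .summary import (
    attach_previous_batch,
    export_table,
    flag_treatment_emergent,
    subject_groups,
    summarize_ae,
    summarize_categorical,
    summarize_continuous,
    summarize_disposition,
    table_payload,
)

__all__ = [
    "ChapterSpec",
    "ReportConfig",
    "ReportManifest",
    "load_config",
    "load_template_schema",
    "validate_chapter_params",
    "render_chapter",
    "assemble_report",
    "build_report",
    "run_blinded_vs_unblinded",
]

TEMPLATES = ("disposition", "demography", "adverse_events", "labs", "batch_comparison")

_TOP_LEVEL_KEYS = {
    "study_id", "cutoff_date", "blinded", "treatment_var", "subject_id_var",
    "population", "severity_order", "teae_lag_days", "visit_window_days",
    "required_variables", "diff_keys", "profiles", "chapters",
}


@dataclass
class ChapterSpec:
    chapter_id: str
    template: str
    title: str
    output: str
    params: dict = field(default_factory=dict)


@dataclass
class ReportConfig:
    study_id: str
    blinded: bool
    treatment_var: str | None
    subject_id_var: str
    severity_order: list[str]
    teae_lag_days: int
    required_variables: dict[str, list[str]]
    diff_keys: dict[str, list[str]]
    profiles: dict
    chapters: list[ChapterSpec]
    cutoff_date: str | None = None
    raw: dict = field(default_factory=dict)


@dataclass
class ChapterResult:
    chapter_id: str
    title: str
    output_file: str
    success: bool
    error: str | None = None


@dataclass
class ReportManifest:
    report_id: str
    digest: str
    timestamp: str
    batch_ids: list[str]
    blinded: bool
    chapters: list[ChapterResult]

    @property
    def success(self) -> bool:
        return all(c.success for c in self.chapters)


def _packaged_defaults(blinded: bool) -> dict:
    name = "report_blinded.yaml" if blinded else "report_unblinded.yaml"
    text = resources.files("clinreview.defaults").joinpath(name).read_text("utf-8")
    return yaml.safe_load(text)


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None, overrides: Mapping | None = None) -> ReportConfig:
    """Load a report configuration, merging the packaged defaults.

    The study file only needs to state what differs from the default
    (blinded or unblinded, chosen by its ``blinded`` flag). Unknown
    top-level keys are fatal, so a typo'd key is reported rather than
    silently ignored. YAML syntax errors surface with their line number.
    """
    user: dict = {}
    if path is not None:
        try:
            with open(path, "r", encoding="utf-8") as fh:
                user = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            mark = getattr(exc, "problem_mark", None)
            line = f" at line {mark.line + 1}" if mark else ""
            raise ValueError(f"invalid YAML in {path}{line}: {exc}") from exc
    if overrides:
        user = _deep_merge(user, overrides)
    unknown = set(user) - _TOP_LEVEL_KEYS
    if unknown:
        raise ValueError(
            f"unknown configuration key(s): {', '.join(sorted(unknown))} "
            f"(allowed: {', '.join(sorted(_TOP_LEVEL_KEYS))})"
        )
    merged = _deep_merge(_packaged_defaults(bool(user.get("blinded", False))), user)

    chapters = []
    seen_ids = set()
    for ch in merged.get("chapters", []):
        template = ch.get("template")
        if template not in TEMPLATES:
            raise ValueError(
                f"chapter {ch.get('id', '?')}: unknown template {template!r} "
                f"(registered: {', '.join(TEMPLATES)})"
            )
        cid = ch.get("id") or template
        if cid in seen_ids:
            raise ValueError(f"duplicate chapter id {cid!r}")
        seen_ids.add(cid)
        chapters.append(
            ChapterSpec(
                chapter_id=cid,
                template=template,
                title=ch.get("title", cid),
                output=ch.get("output", cid),
                params=dict(ch.get("params", {})),
            )
        )
    blinded = bool(merged.get("blinded", False))
    return ReportConfig(
        study_id=str(merged.get("study_id", "STUDY")),
        blinded=blinded,
        treatment_var=merged.get("treatment_var"),
        subject_id_var=merged.get("subject_id_var", "USUBJID"),
        severity_order=list(merged.get("severity_order", ["MILD", "MODERATE", "SEVERE"])),
        teae_lag_days=int(merged.get("teae_lag_days", 30)),
        required_variables={
            k: list(v) for k, v in (merged.get("required_variables") or {}).items()
        },
        diff_keys={k: list(v) for k, v in (merged.get("diff_keys") or {}).items()},
        profiles=dict(merged.get("profiles", {})),
        chapters=chapters,
        cutoff_date=merged.get("cutoff_date"),
        raw=merged,
    )


def load_template_schema(template: str) -> dict:
    if template not in TEMPLATES:
        raise KeyError(f"no schema registered for template {template!r}")
    text = (
        resources.files("clinreview.defaults.schemas")
        .joinpath(f"{template}.json")
        .read_text("utf-8")
    )
    return json.loads(text)


def validate_chapter_params(
    spec: ChapterSpec, schema: dict | None = None
) -> ValidationReport:
    """Presence-and-type check of a chapter's parameters."""
    if schema is None:
        schema = load_template_schema(spec.template)
    return validate(spec.params, schema)


# ------------------------------------------------------------- chapters


def _analysis_context(config: ReportConfig, batch: StudyBatch):
    dm = batch.domain("DM")
    population = dm.subjects
    group_var = None if (config.blinded or batch.blinded) else config.treatment_var
    if group_var is not None and group_var not in dm.variables:
        group_var = None
    groups = subject_groups(dm, group_var, population)
    reference_dates = {
        rec[dm.subject_id_var]: rec.get("RFSTDTC") for rec in dm.records()
    }
    return dm, population, groups, reference_dates


def _chapter_disposition(spec, config, batch, previous, link_index):
    p = spec.params
    dm, population, groups, refs = _analysis_context(config, batch)
    ds = batch.domain(p["dataset"])
    table, listing = summarize_disposition(
        ds, population, groups, refs,
        status_var=p.get("status_var", "DSDECOD"),
        completed_value=p.get("completed_value", "COMPLETED"),
        date_var=p.get("date_var", "DSSTDTC"),
    )
    if previous is not None:
        table = attach_previous_batch(
            table, previous,
            lambda b: summarize_disposition(
                b.domain(p["dataset"]), b.domain("DM").subjects,
                subject_groups(b.domain("DM"),
                               None if b.blinded else config.treatment_var),
                status_var=p.get("status_var", "DSDECOD"),
                completed_value=p.get("completed_value", "COMPLETED"),
            )[0],
        )
    payload = table_payload(table, link_index)
    body = [
        H.summary_table_html(payload, link_index),
        H.json_block(payload, "disposition-table"),
        H.listing_html(listing, "Discontinuations", link_index),
        H.json_block(
            export_table(listing, "interactive_html_data", link_index=link_index,
                         title="Discontinuations"),
            "disposition-listing",
        ),
    ]
    sv_code = p.get("visits_dataset")
    if sv_code and sv_code in batch.domains:
        chart = visit_attendance(batch.domain(sv_code), dm, groups, link_index)
        body.append("<h2>Subjects by visit</h2>")
        body.append(H.json_block(
            {"series": chart.series, "backing_table": chart.backing_table,
             "links": chart.links}, "visit-attendance"))
    return "\n".join(body)


def _chapter_demography(spec, config, batch, previous, link_index):
    p = spec.params
    dm_code = p["dataset"]
    dm_table = batch.domain(dm_code)
    _, population, groups, _ = _analysis_context(config, batch)
    body = []
    for var in p.get("categorical_vars", []):
        table = summarize_categorical(dm_table, var, groups, population)
        if previous is not None:
            table = attach_previous_batch(
                table, previous,
                lambda b, v=var: summarize_categorical(
                    b.domain(dm_code), v,
                    subject_groups(b.domain("DM"),
                                   None if b.blinded else config.treatment_var),
                    b.domain("DM").subjects,
                ),
            )
        payload = table_payload(table, link_index)
        body.append(H.summary_table_html(payload, link_index))
        body.append(H.json_block(payload, f"demography-{var}"))
    for var in p.get("continuous_vars", []):
        table = summarize_continuous(dm_table, var, groups, population)
        payload = table_payload(table, link_index)
        body.append(H.summary_table_html(payload, link_index))
        body.append(H.json_block(payload, f"demography-{var}"))
    return "\n".join(body)


def _chapter_adverse_events(spec, config, batch, previous, link_index):
    p = spec.params
    _, population, groups, _ = _analysis_context(config, batch)
    ae = batch.domain(p["dataset"])

    def teae_filter(b: StudyBatch):
        a = b.domain(p["dataset"])
        if p.get("treatment_emergent", True) and len(a.data):
            flags = flag_treatment_emergent(
                a, b.domain(p.get("exposure_dataset", "EX")),
                lag_days=p.get("lag_days", config.teae_lag_days),
            )
            a = type(a)(a.domain_code, a.data[flags.values].reset_index(drop=True),
                        a.variable_labels, a.subject_id_var)
        return a

    filtered = teae_filter(batch)
    table = summarize_ae(
        filtered, population, groups, config.severity_order,
        soc_var=p.get("soc_var", "AEBODSYS"),
        pt_var=p.get("pt_var", "AEDECOD"),
        severity_var=p.get("severity_var", "AESEV"),
        title="Treatment-emergent adverse events"
        if p.get("treatment_emergent", True) else "Adverse events",
    )
    if previous is not None:
        table = attach_previous_batch(
            table, previous,
            lambda b: summarize_ae(
                teae_filter(b), b.domain("DM").subjects,
                subject_groups(b.domain("DM"),
                               None if b.blinded else config.treatment_var),
                config.severity_order,
            ),
        )
    payload = table_payload(table, link_index)
    tree = ae_hierarchy_payload(
        filtered, population, config.severity_order, link_index,
        soc_var=p.get("soc_var", "AEBODSYS"), pt_var=p.get("pt_var", "AEDECOD"),
        severity_var=p.get("severity_var", "AESEV"),
    )
    return "\n".join(
        [
            H.summary_table_html(payload, link_index),
            H.json_block(payload, "ae-summary"),
            "<h2>Adverse event hierarchy (treemap / sunburst)</h2>",
            H.json_block(
                {"series": tree.series, "backing_table": tree.backing_table,
                 "links": tree.links}, "ae-treemap"),
        ]
    )


def _chapter_labs(spec, config, batch, previous, link_index):
    p = spec.params
    dm, population, groups, _ = _analysis_context(config, batch)
    lb = batch.domain(p["dataset"])
    body = []
    for param in p["parameters"]:
        rows = lb.data[lb.data["LBTESTCD"].astype(object) == param]
        sub = type(lb)(lb.domain_code, rows.reset_index(drop=True),
                       lb.variable_labels, lb.subject_id_var)
        table = summarize_continuous(
            sub, "LBORRES", groups, population, title=f"{param}: descriptive statistics"
        )
        payload = table_payload(table, link_index)
        body.append(H.summary_table_html(payload, link_index))
        body.append(H.json_block(payload, f"lab-summary-{param}"))
        if p.get("spaghetti", True):
            chart = spaghetti_data(
                lb, dm, param, groups, subset_rule=p.get("subset_rule"),
                link_index=link_index,
            )
            body.append(H.json_block(
                {"series": chart.series, "backing_table": chart.backing_table,
                 "links": chart.links}, f"lab-spaghetti-{param}"))
        if p.get("shift", True):
            chart = shift_data(lb, dm, param, groups, link_index=link_index)
            body.append(H.json_block(
                {"series": chart.series, "backing_table": chart.backing_table,
                 "links": chart.links}, f"lab-shift-{param}"))
    if p.get("edish", False):
        chart = edish(
            lb, dm, alt_code=p.get("alt_code", "ALT"),
            bili_code=p.get("bili_code", "BILI"), link_index=link_index,
        )
        body.append("<h2>Hepatotoxicity (eDish)</h2>")
        body.append(H.json_block(
            {"series": chart.series, "backing_table": chart.backing_table,
             "links": chart.links, "meta": chart.meta}, "lab-edish"))
    return "\n".join(body)


def _chapter_batch_comparison(spec, config, batch, previous, link_index):
    p = spec.params
    code = p["dataset"]
    if previous is None:
        return "<p>No previous data batch was supplied; nothing to compare.</p>"
    keys = p.get("keys") or config.diff_keys.get(code) or DEFAULT_DIFF_KEYS[code]
    diff = diff_batches(
        previous.domain(code), batch.domain(code), keys, p.get("compare_vars")
    )
    listing = diff_listing(diff, subject_id_var=config.subject_id_var)
    summary = diff.summary
    body = [
        f"<p>Comparison of batch <b>{H.escape(batch.batch_id)}</b> against "
        f"<b>{H.escape(previous.batch_id)}</b> on domain {H.escape(code)}: "
        f"{summary['addition']} additions, {summary['change']} changes, "
        f"{summary['removal']} removals.</p>",
        H.listing_html(listing, f"{code} records differing between batches", link_index),
        H.json_block(
            {"summary": summary, "keys": diff.keys,
             "schema_notes": diff.schema_notes,
             "rows": export_table(listing, "interactive_html_data",
                                  link_index=link_index)["rows"]},
            "batch-diff"),
    ]
    return "\n".join(body)


_CHAPTER_RENDERERS = {
    "disposition": _chapter_disposition,
    "demography": _chapter_demography,
    "adverse_events": _chapter_adverse_events,
    "labs": _chapter_labs,
    "batch_comparison": _chapter_batch_comparison,
}


def render_chapter(
    spec: ChapterSpec,
    config: ReportConfig,
    batch: StudyBatch,
    previous: StudyBatch | None,
    link_index: Mapping[str, str],
    out_dir: str | Path,
    report_digest: str,
) -> ChapterResult:
    """Render one chapter to a standalone HTML file.

    Parameters are schema-validated first; a validation failure or a
    rendering error is contained in this chapter — an error page is
    written and the failure recorded, leaving sibling chapters alone.
    """
    out_dir = Path(out_dir)
    out_file = f"{spec.output}.html"
    report = validate_chapter_params(spec)
    if not report.passed:
        message = f"chapter parameters invalid: {report}"
        (out_dir / out_file).write_text(
            H.error_page(spec.title, message, report_digest), "utf-8"
        )
        return ChapterResult(spec.chapter_id, spec.title, out_file, False, message)
    try:
        body = _CHAPTER_RENDERERS[spec.template](
            spec, config, batch, previous, dict(link_index)
        )
    except Exception as exc:  # contained: sibling chapters must render
        message = f"{type(exc).__name__}: {exc}"
        (out_dir / out_file).write_text(
            H.error_page(spec.title, message, report_digest), "utf-8"
        )
        return ChapterResult(spec.chapter_id, spec.title, out_file, False, message)
    (out_dir / out_file).write_text(
        H.page(spec.title, body, report_digest), "utf-8"
    )
    return ChapterResult(spec.chapter_id, spec.title, out_file, True)


def _render_chapter_worker(args) -> ChapterResult:
    return render_chapter(*args)


# ------------------------------------------------------------- assembly


def content_digest(config: ReportConfig, batch: StudyBatch,
                   previous: StudyBatch | None = None) -> str:
    """Deterministic digest of configuration plus input data content."""
    h = hashlib.sha256()
    h.update(yaml.safe_dump(config.raw, sort_keys=True).encode())
    for b in [batch] + ([previous] if previous is not None else []):
        h.update(b.batch_id.encode())
        for code in sorted(b.domains):
            table = b.domains[code]
            h.update(code.encode())
            h.update(table.data.fillna("").to_csv(index=False).encode())
    return h.hexdigest()[:12]


def assemble_report(
    config: ReportConfig,
    results: Sequence[ChapterResult],
    out_dir: str | Path,
    digest: str,
    batch: StudyBatch,
    previous: StudyBatch | None = None,
) -> ReportManifest:
    """Write the index page (table of contents) and the JSON manifest."""
    out_dir = Path(out_dir)
    timestamp = dt.datetime.now(dt.timezone.utc).isoformat(timespec="seconds")
    manifest = ReportManifest(
        report_id=f"{digest}@{timestamp}",
        digest=digest,
        timestamp=timestamp,
        batch_ids=[batch.batch_id] + ([previous.batch_id] if previous else []),
        blinded=config.blinded or batch.blinded,
        chapters=list(results),
    )
    items = []
    for r in results:
        marker = "" if r.success else ' <span class="badge removal">failed</span>'
        items.append(f'<li><a href="{H.escape(r.output_file)}">{H.escape(r.title)}</a>{marker}</li>')
    blinding = "blinded" if manifest.blinded else "unblinded"
    body = (
        f"<p>Study {H.escape(config.study_id)}, data batch "
        f"{H.escape(batch.batch_id)} ({blinding}).</p>"
        f"<h2>Chapters</h2><ol>{''.join(items)}</ol>"
    )
    (out_dir / "index.html").write_text(
        H.page(f"Clinical data review — {config.study_id}", body, digest), "utf-8"
    )
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "report_id": manifest.report_id,
                "digest": manifest.digest,
                "timestamp": manifest.timestamp,
                "batch_ids": manifest.batch_ids,
                "blinded": manifest.blinded,
                "chapters": [
                    {"id": r.chapter_id, "title": r.title, "file": r.output_file,
                     "success": r.success, "error": r.error}
                    for r in results
                ],
            },
            fh, indent=1, sort_keys=True,
        )
    return manifest


def check_batch(config: ReportConfig, batch: StudyBatch) -> dict[str, list[str]]:
    """Run required-variable existence checks; domain -> missing vars."""
    problems = {}
    for code, required in config.required_variables.items():
        if code not in batch.domains:
            continue
        report = check_required_variables(batch.domains[code], required)
        if not report.passed:
            problems[code] = report.missing_required
    return problems


def build_report(
    config: ReportConfig,
    batch: StudyBatch,
    previous: StudyBatch | None = None,
    out_dir: str | Path = "report",
    jobs: int = 1,
    subjects: Sequence[str] | None = None,
) -> ReportManifest:
    """Run the full build: profiles, chapters, index, manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if (config.blinded or batch.blinded) and config.treatment_var:
        # hard guarantee: no output may carry the treatment variable
        batch = batch.masked(config.treatment_var) if not batch.blinded else batch
        for code, table in batch.domains.items():
            assert config.treatment_var not in table.variables, (
                f"treatment variable leaked into blinded {code}"
            )
    digest = content_digest(config, batch, previous)
    profile_config = config.profiles or {}
    if not profile_config.get("modules"):
        from .profiles import default_profile_config

        profile_config = default_profile_config()
    link_index = render_profiles(
        batch, profile_config, subjects=subjects, out_dir=out_dir, jobs=jobs
    )
    tasks = [
        (spec, config, batch, previous, link_index, out_dir, digest)
        for spec in config.chapters
    ]
    if jobs > 1 and len(tasks) > 1:
        with ProcessPoolExecutor(max_workers=jobs) as pool:
            results = list(pool.map(_render_chapter_worker, tasks))
    else:
        results = [_render_chapter_worker(t) for t in tasks]
    return assemble_report(config, results, out_dir, digest, batch, previous)


def run_blinded_vs_unblinded(
    config: ReportConfig,
    batch: StudyBatch,
    out_dir: str | Path,
    previous: StudyBatch | None = None,
    jobs: int = 1,
) -> tuple[ReportManifest, ReportManifest]:
    """Build the unblinded and blinded reports from one unblinded batch.

    The two runs differ only in the treatment variable: the blinded run
    drops it everywhere and pools all subjects into a single column.
    """
    if config.treatment_var is None:
        raise ValueError("configuration names no treatment variable")
    if batch.blinded:
        raise ValueError("need an unblinded batch to run both variants")
    out_dir = Path(out_dir)

    unblinded_cfg = load_config(overrides={**config.raw, "blinded": False})
    blinded_cfg = load_config(overrides={**config.raw, "blinded": True})
    unblinded = build_report(
        unblinded_cfg, batch, previous, out_dir / "unblinded", jobs=jobs
    )
    blinded = build_report(
        blinded_cfg, batch,
        previous.masked(config.treatment_var) if previous is not None else None,
        out_dir / "blinded", jobs=jobs,
    )
    return unblinded, blinded
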