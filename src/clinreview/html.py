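"""Self-contained HTML rendering for report chapters.

Every chapter becomes one standalone HTML5 file: styles inline, chart
and table payloads embedded as ``<script type="application/json">``
blocks for the front-end widgets, plus a static HTML rendering of each
table so the page is readable as-is with no scripting. No network
resources are referenced anywhere.
"""

from __future__ import annotations

import html as _html
import json

from .summary import SummaryTable, format_stat, _STAT_KINDS

_CSS = """
body { font-family: system-ui, sans-serif; margin: 2em auto; max-width: 70em;
       color: #1a1a2e; }
h1, h2 { color: #16324f; }
table.summary { border-collapse: collapse; margin: 1em 0; }
table.summary th, table.summary td { border: 1px solid #c8d1dc; padding: 0.3em 0.7em;
       text-align: left; }
table.summary th { background: #eef3f8; }
td.indent-1 { padding-left: 2em; } td.indent-2 { padding-left: 3.5em; }
.report-id { color: #6b7a8f; font-size: 0.85em; }
.badge { padding: 0 0.4em; border-radius: 0.4em; font-size: 0.85em; }
.badge.addition { background: #d9f2d9; } .badge.removal { background: #f8d7da; }
.badge.change { background: #fff3cd; }
.error { color: #a4232f; border: 1px solid #a4232f; padding: 1em; }
a.subject-link { text-decoration: none; }
"""


def escape(text) -> str:
    return _html.escape("" if text is None else str(text))


def json_block(payload, element_id: str) -> str:
    """Embed a JSON payload for the interactive widget layer."""
    text = json.dumps(payload, indent=None, sort_keys=True, default=str)
    # "</script>" inside a JSON string must not close the block
    text = text.replace("</", "<\\/")
    return f'<script type="application/json" id="{escape(element_id)}">{text}</script>'


def _cell_text(cell: dict) -> str:
    display = cell.get("display", {})
    if "n_subjects" in display:
        text = display["n_subjects"]
        if display.get("pct"):
            text += f" ({display['pct']}%)"
        if display.get("n_events"):
            text += f" [{display['n_events']} events]"
        return text
    parts = [f"{k}={display[k]}" for k in _STAT_KINDS if k in display]
    return ", ".join(parts)


def summary_table_html(payload: dict, link_index=None) -> str:
    """Static HTML rendering of a summary-table payload."""
    link_index = link_index or {}
    columns = payload["columns"]
    head = "<tr><th></th>" + "".join(
        f"<th>{escape(c)} (N={payload['denominators'].get(c, '')})</th>"
        for c in columns
    ) + "</tr>"
    body_rows = []
    for row in payload["rows"]:
        depth = min(len(row["path"]) - 1, 2)
        cells = [f'<td class="indent-{depth}">{escape(row["path"][-1])}</td>']
        for col in columns:
            cell = row["cells"][col]
            text = escape(_cell_text(cell))
            subjects = cell.get("subjects", [])
            if subjects:
                links = ", ".join(
                    f'<a class="subject-link" href="{escape(s["profile"])}">{escape(s["subject_id"])}</a>'
                    if s.get("profile")
                    else escape(s["subject_id"])
                    for s in subjects
                )
                text += (
                    f"<details><summary>subjects</summary>{links}</details>"
                )
            cells.append(f"<td>{text}</td>")
        body_rows.append("<tr>" + "".join(cells) + "</tr>")
    return (
        f"<h2>{escape(payload.get('title', ''))}</h2>"
        f'<table class="summary">{head}{"".join(body_rows)}</table>'
    )


def listing_html(rows: list[dict], title: str, link_index=None) -> str:
    link_index = link_index or {}
    if not rows:
        return f"<h2>{escape(title)}</h2><p>No entries.</p>"
    columns = list(rows[0].keys())
    head = "<tr>" + "".join(f"<th>{escape(c)}</th>" for c in columns) + "</tr>"
    body = []
    for row in rows:
        cells = []
        for c in columns:
            v = row.get(c)
            if c == "status":
                cells.append(f'<td><span class="badge {escape(v)}">{escape(v)}</span></td>')
            elif c == "subject_id" and v in link_index:
                cells.append(
                    f'<td><a class="subject-link" href="{escape(link_index[v])}">{escape(v)}</a></td>'
                )
            else:
                cells.append(f"<td>{escape(v)}</td>")
        body.append("<tr>" + "".join(cells) + "</tr>")
    return (
        f"<h2>{escape(title)}</h2>"
        f'<table class="summary">{head}{"".join(body)}</table>'
    )


def page(title: str, body: str, report_id: str) -> str:
    """Wrap chapter body in a standalone HTML5 document."""
    return (
        "<!DOCTYPE html>\n"
        '<html lang="en"><head><meta charset="utf-8">'
        f"<title>{escape(title)}</title>"
        f"<style>{_CSS}</style></head>\n<body>\n"
        f'<p class="report-id">Report ID: {escape(report_id)}</p>\n'
        f"<h1>{escape(title)}</h1>\n{body}\n</body></html>\n"
    )


def error_page(title: str, message: str, report_id: str) -> str:
    return page(title, f'<div class="error">{escape(message)}</div>', report_id)
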