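"""Record-level comparison of two data-batch snapshots.

Review meetings revolve around "what changed since last time": the diff
classifies records of a domain as additions, removals, or changes
between two batches, keyed on configured identifier variables, and
flags exactly which variables changed. Comparison is exact on the
stored text (missing == missing counts as equal); a changed key is by
definition a removal plus an addition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .datamodel import DomainTable

__all__ = ["DiffEntry", "DiffResult", "diff_batches", "apply_diff", "diff_listing"]

#: Default per-domain diff keys; override via configuration.
DEFAULT_DIFF_KEYS: dict[str, list[str]] = {
    "AE": ["USUBJID", "AEDECOD", "AESTDTC", "AESEQ"],
    "CM": ["USUBJID", "CMTRT", "CMSTDTC"],
    "LB": ["USUBJID", "LBTESTCD", "VISITNUM"],
    "EG": ["USUBJID", "EGTESTCD", "VISITNUM"],
    "VS": ["USUBJID", "VSTESTCD", "VISITNUM"],
    "EX": ["USUBJID", "EXSTDTC"],
    "DM": ["USUBJID"],
    "DS": ["USUBJID", "DSDECOD"],
    "SV": ["USUBJID", "VISITNUM"],
    "MH": ["USUBJID", "MHTERM"],
}


@dataclass
class DiffEntry:
    key: tuple
    status: str  # addition | removal | change
    changed_vars: frozenset = frozenset()
    old_record: dict | None = None
    new_record: dict | None = None


@dataclass
class DiffResult:
    keys: list[str]
    compare_vars: list[str]
    entries: list[DiffEntry] = field(default_factory=list)
    #: variables present in only one batch (schema-level note, not
    #: per-record changes)
    schema_notes: list[str] = field(default_factory=list)

    @property
    def summary(self) -> dict[str, int]:
        counts = {"addition": 0, "removal": 0, "change": 0}
        for e in self.entries:
            counts[e.status] += 1
        return counts

    def entry(self, key: tuple) -> DiffEntry:
        for e in self.entries:
            if e.key == key:
                return e
        raise KeyError(key)


def _keyed_records(table: DomainTable, keys: Sequence[str]) -> dict[tuple, dict]:
    for k in keys:
        if k not in table.variables:
            raise ValueError(f"{table.domain_code}: key variable {k} not present")
    out: dict[tuple, dict] = {}
    for rec in table.records():
        key = tuple(rec[k] for k in keys)
        if key in out:
            raise ValueError(
                f"{table.domain_code}: duplicate key tuple {key!r} for keys {list(keys)}"
            )
        out[key] = rec
    return out


def diff_batches(
    old: DomainTable,
    new: DomainTable,
    keys: Sequence[str],
    compare_vars: Sequence[str] | None = None,
) -> DiffResult:
    """Key-based diff of one domain between two batches.

    A key present only in *new* is an addition; only in *old*, a
    removal; present in both with any compared variable differing, a
    change whose ``changed_vars`` lists exactly the differing variables.
    ``compare_vars`` defaults to all non-key variables shared by both
    tables; variables present in only one batch are reported once as a
    schema note. Duplicate key tuples within either table are an error.
    """
    keys = list(keys)
    old_recs = _keyed_records(old, keys)
    new_recs = _keyed_records(new, keys)

    old_vars, new_vars = set(old.variables), set(new.variables)
    shared = [v for v in new.variables if v in old_vars and v not in keys]
    notes = [
        f"variable {v} only in {'old' if v in old_vars else 'new'} batch"
        for v in sorted((old_vars ^ new_vars) - set(keys))
    ]
    if compare_vars is None:
        compare_vars = shared
    else:
        compare_vars = list(compare_vars)
        for v in compare_vars:
            if v not in shared:
                raise ValueError(f"compare variable {v} not shared by both batches")

    result = DiffResult(keys=keys, compare_vars=compare_vars, schema_notes=notes)
    for key, rec in new_recs.items():
        if key not in old_recs:
            result.entries.append(DiffEntry(key, "addition", new_record=rec))
            continue
        old_rec = old_recs[key]
        changed = frozenset(
            v for v in compare_vars if old_rec.get(v) != rec.get(v)
        )
        if changed:
            result.entries.append(
                DiffEntry(key, "change", changed, old_record=old_rec, new_record=rec)
            )
    for key, rec in old_recs.items():
        if key not in new_recs:
            result.entries.append(DiffEntry(key, "removal", old_record=rec))
    return result


def apply_diff(old: DomainTable, diff: DiffResult) -> DomainTable:
    """Replay a diff onto the old table (round-trip verification aid).

    The result equals the new batch on the diff's key set and compared
    variables; column scope is keys + compared variables.
    """
    columns = diff.keys + [v for v in diff.compare_vars if v not in diff.keys]
    recs = {}
    for rec in old.records():
        key = tuple(rec[k] for k in diff.keys)
        recs[key] = {c: rec.get(c) for c in columns}
    for e in diff.entries:
        if e.status == "removal":
            if e.key not in recs:
                raise ValueError(f"diff inconsistent with table: removal key {e.key!r} absent")
            del recs[e.key]
        elif e.status == "addition":
            assert e.new_record is not None
            recs[e.key] = {c: e.new_record.get(c) for c in columns}
        else:
            if e.key not in recs:
                raise ValueError(f"diff inconsistent with table: change key {e.key!r} absent")
            assert e.new_record is not None
            for v in e.changed_vars:
                recs[e.key][v] = e.new_record.get(v)
    data = pd.DataFrame(list(recs.values()), columns=columns)
    return DomainTable(
        old.domain_code,
        data,
        {k: v for k, v in old.variable_labels.items() if k in columns},
        old.subject_id_var,
    )


def diff_listing(
    diff: DiffResult,
    label_vars: Sequence[str] | None = None,
    subject_id_var: str = "USUBJID",
) -> list[dict]:
    """Annotated listing rows, one per diff entry.

    Each row carries a status badge, the key values, the display
    variables (from the new record when available, else the old), and a
    ``changed`` marker set listing flagged variables. Rows are plain
    dicts so :func:`clinreview.summary.export_table` can export them.
    """
    label_vars = list(label_vars) if label_vars is not None else diff.compare_vars
    rows = []
    for e in diff.entries:
        rec = e.new_record if e.new_record is not None else (e.old_record or {})
        row: dict = {"status": e.status}
        for k, v in zip(diff.keys, e.key):
            row[k] = v
        row["subject_id"] = rec.get(subject_id_var, row.get(subject_id_var))
        for v in label_vars:
            if v not in row:
                row[v] = rec.get(v)
        row["changed"] = sorted(e.changed_vars)
        if e.status == "change" and e.old_record is not None:
            row["previous"] = {v: e.old_record.get(v) for v in sorted(e.changed_vars)}
        rows.append(row)
    order = {"addition": 0, "change": 1, "removal": 2}
    rows.sort(key=lambda r: (order[r["status"]], tuple(str(r[k]) for k in diff.keys)))
    return rows
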