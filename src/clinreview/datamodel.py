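"""Long-format clinical domain tables and study batches.

A *domain table* holds one SDTM-like clinical domain (DM, AE, LB, ...)
in long format: one row per record, variables as columns. All values are
kept as text at this layer (``None`` marks a missing value); numeric or
date interpretation is deferred to :mod:`clinreview.derivations` so that
partial dates and decimal text survive I/O verbatim.

A *study batch* is a named, dated snapshot of the accumulating trial
database: a set of domain tables plus a blinding status. Blinded batches
never expose the treatment variable.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "DomainTable",
    "StudyBatch",
    "VariableCheckReport",
    "read_domain",
    "write_domain",
    "check_required_variables",
    "load_batch",
]

#: Internal missing-value marker. Empty strings in CSV and SAS missing
#: values in XPT both normalize to this, so comparisons can treat
#: missing == missing as equal.
MISSING = None


def _normalize(value) -> str | None:
    """Normalize a raw cell to text or the missing marker."""
    if value is None:
        return MISSING
    if isinstance(value, bytes):
        value = value.decode("utf-8", errors="replace")
    if isinstance(value, float):
        if value != value:  # NaN
            return MISSING
        if value == int(value) and abs(value) < 1e15:
            return str(int(value))
        return repr(value)
    value = str(value)
    return MISSING if value == "" else value


@dataclass
class DomainTable:
    """One clinical domain in long format.

    Parameters
    ----------
    domain_code:
        Two-letter uppercase domain code (``AE``, ``LB``, ...).
    data:
        Records as a DataFrame of text values (``None`` = missing),
        in file order. Column order is meaningful and preserved.
    variable_labels:
        Variable name -> human-readable label.
    subject_id_var:
        Name of the unique subject identifier variable.
    """

    domain_code: str
    data: pd.DataFrame
    variable_labels: dict[str, str] = field(default_factory=dict)
    subject_id_var: str = "USUBJID"

    def __post_init__(self) -> None:
        cols = list(self.data.columns)
        if len(set(cols)) != len(cols):
            dupes = sorted({c for c in cols if cols.count(c) > 1})
            raise ValueError(f"duplicate column names in {self.domain_code}: {dupes}")
        if self.subject_id_var not in cols:
            raise ValueError(
                f"{self.domain_code}: subject identifier variable "
                f"{self.subject_id_var!r} not present"
            )
        ids = self.data[self.subject_id_var]
        if ids.isna().any() or (ids.astype(object) == "").any():
            raise ValueError(
                f"{self.domain_code}: records with empty {self.subject_id_var}"
            )

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    @property
    def subjects(self) -> list[str]:
        """Distinct subject ids in record order."""
        seen: dict[str, None] = {}
        for s in self.data[self.subject_id_var]:
            seen.setdefault(s)
        return list(seen)

    def records(self) -> list[dict]:
        """Records as a list of plain dicts (missing values as None)."""
        return self.data.to_dict(orient="records")

    def label(self, var: str) -> str:
        return self.variable_labels.get(var, var)

    def drop_variable(self, var: str) -> "DomainTable":
        """Return a copy without *var* (no-op when absent)."""
        if var not in self.data.columns:
            return self
        return DomainTable(
            domain_code=self.domain_code,
            data=self.data.drop(columns=[var]).copy(),
            variable_labels={k: v for k, v in self.variable_labels.items() if k != var},
            subject_id_var=self.subject_id_var,
        )

    def copy(self) -> "DomainTable":
        return DomainTable(
            self.domain_code,
            self.data.copy(),
            dict(self.variable_labels),
            self.subject_id_var,
        )


@dataclass
class VariableCheckReport:
    """Result of an existence check on required variables."""

    domain_code: str
    missing_required: list[str]
    present: list[str]

    @property
    def passed(self) -> bool:
        return not self.missing_required


@dataclass
class StudyBatch:
    """A named, dated snapshot of the study database."""

    batch_id: str
    cutoff_date: str
    domains: dict[str, DomainTable]
    blinded: bool = False
    treatment_var: str | None = None

    def __post_init__(self) -> None:
        if self.blinded and self.treatment_var is not None:
            raise ValueError("blinded batch must not carry a treatment variable")

    def domain(self, code: str) -> DomainTable:
        try:
            return self.domains[code]
        except KeyError:
            raise KeyError(f"domain {code} not loaded in batch {self.batch_id}") from None

    def masked(self, treatment_var: str) -> "StudyBatch":
        """Blinded view: drop *treatment_var* from every domain."""
        return StudyBatch(
            batch_id=self.batch_id,
            cutoff_date=self.cutoff_date,
            domains={c: t.drop_variable(treatment_var) for c, t in self.domains.items()},
            blinded=True,
            treatment_var=None,
        )


def _read_csv_table(path: Path) -> pd.DataFrame:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        header_line = fh.readline()
        if not header_line:
            raise ValueError(f"no records in {path}")
        header = next(csv.reader(io.StringIO(header_line)))
    if len(set(header)) != len(header):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise ValueError(f"duplicate column names in {path}: {dupes}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    if df.empty:
        raise ValueError(f"no records in {path}")
    return df.map(_normalize)


def _read_label_sidecar(path: Path) -> dict[str, str]:
    sidecar = path.with_name(path.stem + "-labels" + path.suffix)
    if not sidecar.exists():
        return {}
    df = pd.read_csv(sidecar, dtype=str, keep_default_na=False)
    if not {"variable", "label"} <= set(df.columns):
        raise ValueError(f"label sidecar {sidecar} needs columns: variable,label")
    return dict(zip(df["variable"], df["label"]))


def _read_xpt_table(path: Path) -> tuple[pd.DataFrame, dict[str, str]]:
    from pandas.io.sas.sas_xport import XportReader

    with XportReader(str(path)) as reader:
        labels = {
            f["name"].decode().strip() if isinstance(f["name"], bytes) else str(f["name"]).strip():
            (f["label"].decode().strip() if isinstance(f["label"], bytes) else str(f["label"]).strip())
            for f in reader.fields
        }
        df = reader.read()
    if df.empty:
        raise ValueError(f"no records in {path}")
    df = df.map(_normalize)
    return df, {k: v for k, v in labels.items() if v}


def read_domain(
    path: str | Path,
    format: str,
    domain_code: str,
    subject_id_var: str = "USUBJID",
) -> DomainTable:
    """Read one domain file into a :class:`DomainTable`.

    ``format`` is ``"csv"`` (RFC 4180, UTF-8, header row required; an
    optional ``<stem>-labels.csv`` sidecar supplies variable labels) or
    ``"xpt"`` (SAS transport v5, labels from the transport metadata).
    Records come back in file order; empty cells / SAS missing values
    normalize to the internal missing marker.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cannot read domain {domain_code}: {path}")
    if format == "csv":
        data = _read_csv_table(path)
        labels = _read_label_sidecar(path)
    elif format == "xpt":
        data, labels = _read_xpt_table(path)
    else:
        raise ValueError(f"unknown format {format!r}: expected 'csv' or 'xpt'")
    return DomainTable(domain_code, data, labels, subject_id_var)


def write_domain(table: DomainTable, path: str | Path, labels: bool = True) -> Path:
    """Write a domain table as CSV (+ label sidecar), inverse of CSV read."""
    path = Path(path)
    out = table.data.fillna("")
    out.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
    if labels and table.variable_labels:
        sidecar = path.with_name(path.stem + "-labels" + path.suffix)
        pd.DataFrame(
            {"variable": list(table.variable_labels),
             "label": list(table.variable_labels.values())}
        ).to_csv(sidecar, index=False, encoding="utf-8", lineterminator="\n")
    return path


def check_required_variables(
    table: DomainTable, required: Iterable[str]
) -> VariableCheckReport:
    """Existence check for required variables (reports, never raises)."""
    required = list(required)
    if not required:
        raise ValueError("required variable list must be non-empty")
    have = set(table.variables)
    missing = [v for v in required if v not in have]
    present = [v for v in required if v in have]
    return VariableCheckReport(table.domain_code, missing, present)


def load_batch(directory: str | Path, manifest: Mapping) -> StudyBatch:
    """Load a batch folder per its manifest.

    The manifest names the batch id, cutoff date, blinding flag, the
    treatment variable and the domain files::

        batch_id: "2023-06"
        cutoff_date: "2023-06-30"
        blinded: false
        treatment_var: ARM
        domains: {DM: dm.csv, AE: ae.csv}

    When ``blinded`` is true the treatment variable is dropped from every
    table before the batch is returned, so no downstream consumer can see it.
    """
    directory = Path(directory)
    blinded = bool(manifest.get("blinded", False))
    treatment_var = manifest.get("treatment_var")
    subject_id_var = manifest.get("subject_id_var", "USUBJID")
    domains: dict[str, DomainTable] = {}
    for code, filename in dict(manifest["domains"]).items():
        path = directory / filename
        if not path.exists():
            raise FileNotFoundError(f"{code}: file not found: {path}")
        fmt = "xpt" if path.suffix.lower() == ".xpt" else "csv"
        table = read_domain(path, fmt, code, subject_id_var)
        if blinded and treatment_var:
            table = table.drop_variable(treatment_var)
        domains[code] = table
    return StudyBatch(
        batch_id=str(manifest.get("batch_id", directory.name)),
        cutoff_date=str(manifest.get("cutoff_date", "")),
        domains=domains,
        blinded=blinded,
        treatment_var=None if blinded else treatment_var,
    )
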