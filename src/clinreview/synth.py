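"""Synthetic SDTM-like study generator with known ground truth.

Emulates the snapshot structure a safety-review pipeline consumes: a
multi-arm study with staggered enrolment, scheduled visits with
dropout, treatment-emergent and pre-treatment adverse events with
severity/seriousness and partial onset dates, laboratory values with
reference ranges, ECG (QT + heart rate, with occasional same-visit
replicates) and vital signs per attended visit, exposure intervals and
disposition records. Every stochastic feature is recorded in a
:class:`GroundTruth` object so downstream summaries can be checked
against construction rather than re-derivation.

A second, later batch with an exactly known set of injected additions,
changes and removals is produced by :func:`generate_next_batch`, and
named safety scenarios (a Hy's-law case, a severe treatment-emergent
event, a partial onset date) by :func:`inject_case`.

The generator targets structural realism (variable naming, relational
consistency between domains), not pharmacological realism.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .datamodel import DomainTable, StudyBatch, write_domain
from .derivations import classify_partial_date
from .diff import DEFAULT_DIFF_KEYS, DiffEntry, DiffResult

__all__ = [
    "StudyRecipe",
    "BatchDelta",
    "GroundTruth",
    "CaseDescriptor",
    "generate_study",
    "generate_next_batch",
    "inject_case",
    "write_batch",
    "load_fixture_study",
]

_SOC_PT = {
    "NERVOUS SYSTEM DISORDERS": ["HEADACHE", "DIZZINESS", "SOMNOLENCE"],
    "GASTROINTESTINAL DISORDERS": ["NAUSEA", "DIARRHOEA", "VOMITING", "DYSPEPSIA"],
    "GENERAL DISORDERS": ["FATIGUE", "PYREXIA", "CHILLS"],
    "SKIN AND SUBCUTANEOUS TISSUE DISORDERS": ["RASH", "PRURITUS"],
    "INFECTIONS AND INFESTATIONS": ["NASOPHARYNGITIS", "URINARY TRACT INFECTION"],
}

#: Laboratory parameters: code -> (name, unit, lower limit, upper limit).
_LABS = {
    "ALT": ("Alanine Aminotransferase", "U/L", 7.0, 44.0),
    "BILI": ("Bilirubin", "umol/L", 3.0, 21.0),
    "CREAT": ("Creatinine", "umol/L", 49.0, 90.0),
}

_RACES = ["WHITE", "BLACK OR AFRICAN AMERICAN", "ASIAN"]
_COUNTRIES = ["BEL", "NLD", "DEU", "FRA"]
_DISC_REASONS = ["ADVERSE EVENT", "WITHDRAWAL BY SUBJECT", "LOST TO FOLLOW-UP"]


@dataclass
class StudyRecipe:
    """Study-design parameters for the generator.

    Defaults describe a small two-arm phase-II-like safety population:
    50 subjects, six visits two weeks apart, a 20% chance of a new
    adverse event at each attended visit (plus a 10% chance of one
    pre-treatment event per subject), mild-skewed severities, a 5%
    per-visit discontinuation hazard, three lab parameters with
    reference ranges, and 5% of AE onset dates recorded month-precision.
    """

    n_subjects: int = 50
    arms: Sequence[str] = ("Placebo", "Active")
    n_visits: int = 6
    visit_spacing_days: int = 14
    ae_rate: float = 0.20
    pre_treatment_ae_rate: float = 0.10
    severity_dist: Sequence[float] = (0.6, 0.3, 0.1)  # MILD, MODERATE, SEVERE
    serious_rate: float = 0.05
    ongoing_ae_rate: float = 0.2
    dropout_hazard: float = 0.05
    partial_date_rate: float = 0.05
    teae_lag_days: int = 30
    study_id: str = "CR01"
    start_date: str = "2023-01-02"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ae_rate", "pre_treatment_ae_rate", "serious_rate",
                     "ongoing_ae_rate", "dropout_hazard", "partial_date_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        if self.n_visits < 1:
            raise ValueError("need at least one visit")
        if abs(sum(self.severity_dist) - 1.0) > 1e-9:
            raise ValueError("severity_dist must sum to 1")


@dataclass
class GroundTruth:
    """Everything the generator decided, for closed-loop checks."""

    arm_by_subject: dict[str, str] = field(default_factory=dict)
    attended_visits: dict[str, list[int]] = field(default_factory=dict)
    #: subject -> discontinuation reason (absent = completed)
    discontinuations: dict[str, str] = field(default_factory=dict)
    #: (USUBJID, AESEQ) -> expected treatment-emergent flag
    teae: dict[tuple[str, str], bool] = field(default_factory=dict)
    #: (USUBJID, AESEQ) -> severity as generated
    ae_severity: dict[tuple[str, str], str] = field(default_factory=dict)
    abnormal_lab_subjects: set[str] = field(default_factory=set)
    reference_dates: dict[str, str] = field(default_factory=dict)


@dataclass
class CaseDescriptor:
    case: str
    subject_id: str
    details: dict = field(default_factory=dict)


def _iso(d: dt.date) -> str:
    return d.isoformat()


def _table(code: str, rows: list[dict], labels: dict[str, str]) -> DomainTable:
    df = pd.DataFrame(rows)
    df = df.map(lambda v: None if v is None else str(v))
    return DomainTable(code, df, labels)


def generate_study(recipe: StudyRecipe) -> tuple[StudyBatch, GroundTruth]:
    """Generate one internally consistent study batch plus ground truth.

    All randomness flows from ``recipe.seed``; two calls with the same
    recipe produce identical batches.
    """
    rng = np.random.default_rng(recipe.seed)
    start = dt.date.fromisoformat(recipe.start_date)
    truth = GroundTruth()

    subjects = [f"{recipe.study_id}-{i + 1:04d}" for i in range(recipe.n_subjects)]
    arms = list(recipe.arms)
    arm_cycle = (arms * (recipe.n_subjects // len(arms) + 1))[: recipe.n_subjects]
    rng.shuffle(arm_cycle)

    dm_rows, sv_rows, ex_rows, ds_rows = [], [], [], []
    ae_rows, lb_rows, eg_rows, vs_rows = [], [], [], []

    for sid, arm in zip(subjects, arm_cycle):
        truth.arm_by_subject[sid] = arm
        ref = start + dt.timedelta(days=int(rng.integers(0, 60)))
        truth.reference_dates[sid] = _iso(ref)
        age = int(rng.integers(22, 80))
        sex = "M" if rng.random() < 0.5 else "F"
        dm_rows.append(
            {
                "STUDYID": recipe.study_id,
                "USUBJID": sid,
                "AGE": age,
                "SEX": sex,
                "RACE": _RACES[int(rng.integers(0, len(_RACES)))],
                "COUNTRY": _COUNTRIES[int(rng.integers(0, len(_COUNTRIES)))],
                "ARM": arm,
                "RFSTDTC": _iso(ref),
            }
        )

        # visit schedule with per-visit dropout hazard
        attended: list[int] = [1]
        for v in range(2, recipe.n_visits + 1):
            if rng.random() < recipe.dropout_hazard:
                break
            attended.append(v)
        truth.attended_visits[sid] = attended
        visit_dates = {}
        for v in attended:
            jitter = 0 if v == 1 else int(rng.integers(-1, 2))
            visit_dates[v] = ref + dt.timedelta(
                days=(v - 1) * recipe.visit_spacing_days + jitter
            )
            sv_rows.append(
                {
                    "STUDYID": recipe.study_id,
                    "USUBJID": sid,
                    "VISITNUM": v,
                    "VISIT": f"VISIT {v}",
                    "SVSTDTC": _iso(visit_dates[v]),
                }
            )
        last_visit_date = visit_dates[attended[-1]]

        ex_rows.append(
            {
                "STUDYID": recipe.study_id,
                "USUBJID": sid,
                "EXTRT": "STUDY DRUG",
                "EXDOSE": 50,
                "EXDOSU": "mg",
                "EXSTDTC": _iso(ref),
                "EXENDTC": _iso(last_visit_date),
            }
        )

        completed = len(attended) == recipe.n_visits
        if completed:
            ds_rows.append(
                {
                    "STUDYID": recipe.study_id,
                    "USUBJID": sid,
                    "DSDECOD": "COMPLETED",
                    "DSSTDTC": _iso(last_visit_date),
                }
            )
        else:
            reason = _DISC_REASONS[int(rng.integers(0, len(_DISC_REASONS)))]
            truth.discontinuations[sid] = reason
            ds_rows.append(
                {
                    "STUDYID": recipe.study_id,
                    "USUBJID": sid,
                    "DSDECOD": reason,
                    "DSSTDTC": _iso(last_visit_date),
                }
            )

        # adverse events
        aeseq = 0
        sev_levels = ["MILD", "MODERATE", "SEVERE"]

        def add_ae(onset: dt.date, partial_ok: bool = True) -> None:
            nonlocal aeseq
            aeseq += 1
            soc = list(_SOC_PT)[int(rng.integers(0, len(_SOC_PT)))]
            pt = _SOC_PT[soc][int(rng.integers(0, len(_SOC_PT[soc])))]
            sev = sev_levels[
                int(rng.choice(len(sev_levels), p=list(recipe.severity_dist)))
            ]
            ongoing = rng.random() < recipe.ongoing_ae_rate
            end = None if ongoing else onset + dt.timedelta(days=int(rng.integers(1, 21)))
            start_text = _iso(onset)
            if partial_ok and rng.random() < recipe.partial_date_rate:
                start_text = start_text[:7]  # month precision
            key = (sid, str(aeseq))
            # expected flag under the earliest-imputation TEAE rule,
            # given what is actually written to the file
            written_onset = classify_partial_date(start_text).date
            teae = written_onset >= ref and (
                written_onset - last_visit_date
            ).days <= recipe.teae_lag_days
            truth.teae[key] = bool(teae)
            truth.ae_severity[key] = sev
            ae_rows.append(
                {
                    "STUDYID": recipe.study_id,
                    "USUBJID": sid,
                    "AESEQ": aeseq,
                    "AEDECOD": pt,
                    "AEBODSYS": soc,
                    "AESEV": sev,
                    "AESER": "Y" if rng.random() < recipe.serious_rate else "N",
                    "AESTDTC": start_text,
                    "AEENDTC": None if end is None else _iso(end),
                }
            )

        if rng.random() < recipe.pre_treatment_ae_rate:
            add_ae(ref - dt.timedelta(days=int(rng.integers(5, 40))), partial_ok=False)
        for v in attended:
            if rng.random() < recipe.ae_rate:
                add_ae(visit_dates[v] + dt.timedelta(days=int(rng.integers(0, 4))))

        # labs / ECG / vitals per attended visit
        for v in attended:
            date = visit_dates[v]
            for code, (name, unit, lo, hi) in _LABS.items():
                frac = float(rng.uniform(-0.25, 1.35))
                value = round(lo + frac * (hi - lo), 1)
                if value < hi * 0.02:
                    value = round(hi * 0.02, 1)
                if value < lo or value > hi:
                    truth.abnormal_lab_subjects.add(sid)
                lb_rows.append(
                    {
                        "STUDYID": recipe.study_id,
                        "USUBJID": sid,
                        "LBTESTCD": code,
                        "LBTEST": name,
                        "LBORRES": value,
                        "LBORRESU": unit,
                        "LBORNRLO": lo,
                        "LBORNRHI": hi,
                        "VISITNUM": v,
                        "VISIT": f"VISIT {v}",
                        "LBDTC": _iso(date),
                    }
                )
            n_ecg = 2 if rng.random() < 0.25 else 1  # occasional replicate
            for rep in range(1, n_ecg + 1):
                qt = round(float(rng.normal(400, 15)), 0)
                hr = round(float(rng.normal(72, 9)), 0)
                for testcd, test, val, unit in (
                    ("QT", "QT Interval", qt, "ms"),
                    ("HR", "Heart Rate", hr, "beats/min"),
                ):
                    eg_rows.append(
                        {
                            "STUDYID": recipe.study_id,
                            "USUBJID": sid,
                            "EGTESTCD": testcd,
                            "EGTEST": test,
                            "EGORRES": val,
                            "EGORRESU": unit,
                            "EGREPNUM": rep,
                            "VISITNUM": v,
                            "VISIT": f"VISIT {v}",
                            "EGDTC": _iso(date),
                        }
                    )
            for testcd, test, mean_, sd_, unit in (
                ("SYSBP", "Systolic Blood Pressure", 122, 13, "mmHg"),
                ("DIABP", "Diastolic Blood Pressure", 76, 9, "mmHg"),
            ):
                vs_rows.append(
                    {
                        "STUDYID": recipe.study_id,
                        "USUBJID": sid,
                        "VSTESTCD": testcd,
                        "VSTEST": test,
                        "VSORRES": round(float(rng.normal(mean_, sd_)), 0),
                        "VSORRESU": unit,
                        "VISITNUM": v,
                        "VISIT": f"VISIT {v}",
                        "VSDTC": _iso(date),
                    }
                )

    labels = {
        "USUBJID": "Unique Subject Identifier",
        "VISITNUM": "Visit Number",
        "VISIT": "Visit Name",
    }
    domains = {
        "DM": _table("DM", dm_rows, {**labels, "AGE": "Age", "SEX": "Sex",
                                     "ARM": "Description of Planned Arm",
                                     "RFSTDTC": "Subject Reference Start Date"}),
        "SV": _table("SV", sv_rows, labels),
        "EX": _table("EX", ex_rows, {**labels, "EXTRT": "Name of Treatment"}),
        "DS": _table("DS", ds_rows, {**labels, "DSDECOD": "Standardized Disposition Term"}),
        "LB": _table("LB", lb_rows, {**labels, "LBTESTCD": "Lab Test Short Name",
                                     "LBORRES": "Result in Original Units"}),
        "EG": _table("EG", eg_rows, {**labels, "EGTESTCD": "ECG Test Short Name"}),
        "VS": _table("VS", vs_rows, {**labels, "VSTESTCD": "Vital Signs Test Short Name"}),
    }
    ae_labels = {**labels, "AEDECOD": "Dictionary-Derived Term",
                 "AEBODSYS": "Body System or Organ Class",
                 "AESEV": "Severity/Intensity"}
    ae_columns = ["STUDYID", "USUBJID", "AESEQ", "AEDECOD", "AEBODSYS",
                  "AESEV", "AESER", "AESTDTC", "AEENDTC"]
    if ae_rows:
        domains["AE"] = _table("AE", ae_rows, ae_labels)
    else:
        domains["AE"] = DomainTable(
            "AE", pd.DataFrame(columns=ae_columns, dtype=object), ae_labels
        )

    cutoff = max(
        dt.date.fromisoformat(r["SVSTDTC"]) for r in sv_rows
    ) + dt.timedelta(days=7)
    batch = StudyBatch(
        batch_id=f"{recipe.study_id}-B1",
        cutoff_date=_iso(cutoff),
        domains=domains,
        blinded=False,
        treatment_var="ARM",
    )
    return batch, truth


@dataclass
class BatchDelta:
    """Exact differences to inject when deriving the next batch.

    ``counts`` maps domain code -> {"additions": a, "changes": c,
    "removals": r}; ``change_vars`` names the variable to perturb per
    domain (defaults ship for the standard domains).
    """

    counts: dict[str, dict[str, int]]
    change_vars: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    _DEFAULT_CHANGE_VARS = {
        "AE": "AESEV", "LB": "LBORRES", "EG": "EGORRES", "VS": "VSORRES",
        "DM": "AGE", "DS": "DSDECOD", "EX": "EXENDTC", "SV": "SVSTDTC",
    }

    def change_var(self, code: str) -> str:
        return self.change_vars.get(code, self._DEFAULT_CHANGE_VARS.get(code, "STUDYID"))


def _perturb(value: str | None) -> str:
    if value is None:
        return "UPDATED"
    try:
        return str(int(float(value)) + 1)
    except ValueError:
        pass
    rotations = {"MILD": "MODERATE", "MODERATE": "SEVERE", "SEVERE": "MILD"}
    return rotations.get(value, value + "*")


def generate_next_batch(
    batch: StudyBatch, delta: BatchDelta, keys: dict[str, list[str]] | None = None
) -> tuple[StudyBatch, dict[str, DiffResult]]:
    """Derive a consecutive batch differing by exactly the given delta.

    Returns the new batch and, per domain, the expected
    :class:`~clinreview.diff.DiffResult` ground truth (additions,
    removals, changes with their changed variable). Infeasible deltas
    (more removals/changes than records) raise.
    """
    rng = np.random.default_rng(delta.seed)
    keys = keys or DEFAULT_DIFF_KEYS
    new_domains: dict[str, DomainTable] = {c: t.copy() for c, t in batch.domains.items()}
    truth: dict[str, DiffResult] = {}

    for code, spec in delta.counts.items():
        table = batch.domains[code]
        key_vars = keys[code]
        n_add = int(spec.get("additions", 0))
        n_chg = int(spec.get("changes", 0))
        n_rem = int(spec.get("removals", 0))
        n = len(table.data)
        if n_chg + n_rem > n:
            raise ValueError(
                f"{code}: delta needs {n_chg + n_rem} distinct records, table has {n}"
            )
        df = table.data.copy().reset_index(drop=True)
        picked = rng.choice(n, size=n_chg + n_rem, replace=False) if n_chg + n_rem else []
        change_idx = sorted(int(i) for i in picked[:n_chg])
        remove_idx = sorted(int(i) for i in picked[n_chg:])
        entries: list[DiffEntry] = []
        compare_vars = [v for v in table.variables if v not in key_vars]

        var = delta.change_var(code)
        for i in change_idx:
            old_rec = {c: df.at[i, c] for c in df.columns}
            df.at[i, var] = _perturb(old_rec.get(var))
            new_rec = {c: df.at[i, c] for c in df.columns}
            entries.append(
                DiffEntry(
                    tuple(old_rec[k] for k in key_vars),
                    "change",
                    frozenset({var}),
                    old_record=old_rec,
                    new_record=new_rec,
                )
            )
        for i in remove_idx:
            rec = {c: df.at[i, c] for c in df.columns}
            entries.append(
                DiffEntry(tuple(rec[k] for k in key_vars), "removal", old_record=rec)
            )
        removed_keys = {
            tuple(df.at[i, k] for k in key_vars) for i in remove_idx
        }
        df_before_removal = df.copy()
        df = df.drop(index=remove_idx).reset_index(drop=True)

        # additions: clone a pre-existing record and bump the last key
        # variable to a fresh unique value (must not collide with a
        # removed key either, or the entry would read as a change)
        existing_keys = removed_keys | {
            tuple(rec[k] for k in key_vars) for rec in df.to_dict(orient="records")
        }
        last_key = key_vars[-1]
        counter = 0
        add_rows = []
        for _ in range(n_add):
            if len(df_before_removal) == 0:
                raise ValueError(f"{code}: cannot add records to an empty table")
            j = int(rng.integers(0, len(df_before_removal)))
            src = {c: df_before_removal.at[j, c] for c in df_before_removal.columns}
            while True:
                counter += 1
                candidate = dict(src)
                base = src.get(last_key)
                try:
                    candidate[last_key] = str(int(float(base)) + 1000 + counter)
                except (TypeError, ValueError):
                    candidate[last_key] = f"{base or 'NEW'}-N{counter}"
                key = tuple(candidate[k] for k in key_vars)
                if key not in existing_keys:
                    existing_keys.add(key)
                    break
            add_rows.append(candidate)
            entries.append(DiffEntry(key, "addition", new_record=candidate))
        if add_rows:
            df = pd.concat([df, pd.DataFrame(add_rows)], ignore_index=True)

        new_domains[code] = DomainTable(
            code, df, dict(table.variable_labels), table.subject_id_var
        )
        truth[code] = DiffResult(keys=list(key_vars), compare_vars=compare_vars,
                                 entries=entries)

    new_batch = StudyBatch(
        batch_id=batch.batch_id + "+1",
        cutoff_date=_iso(
            dt.date.fromisoformat(batch.cutoff_date) + dt.timedelta(days=28)
        )
        if batch.cutoff_date
        else batch.cutoff_date,
        domains=new_domains,
        blinded=batch.blinded,
        treatment_var=batch.treatment_var,
    )
    return new_batch, truth


def inject_case(
    batch: StudyBatch, case: str, subject_id: str | None = None
) -> tuple[StudyBatch, CaseDescriptor]:
    """Modify one subject's records to realize a named safety scenario.

    ``hys_law``: a post-baseline visit gets ALT = 4x and bilirubin = 3x
    their upper limits of normal, landing the subject alone in the
    Hy's-law quadrant (other generated values stay below 1.35x ULN).
    ``severe_teae``: two on-treatment events of one term, MILD and
    SEVERE, so worst-severity tabulation counts the subject once under
    SEVERE. ``partial_onset``: one AE onset truncated to month
    precision, so displays must flag the imputed date.
    """
    domains = {c: t.copy() for c, t in batch.domains.items()}
    out = StudyBatch(batch.batch_id, batch.cutoff_date, domains,
                     batch.blinded, batch.treatment_var)

    if case == "hys_law":
        lb = domains["LB"].data
        # need a subject with a visit beyond the baseline visit
        candidates = lb.loc[
            pd.to_numeric(lb["VISITNUM"]) > 1, "USUBJID"
        ].unique().tolist()
        sid = subject_id or candidates[0]
        for code, ratio in (("ALT", 4.0), ("BILI", 3.0)):
            mask = (
                (lb["USUBJID"] == sid)
                & (lb["LBTESTCD"] == code)
                & (pd.to_numeric(lb["VISITNUM"]) > 1)
            )
            idx = lb.index[mask]
            if len(idx) == 0:
                raise ValueError(f"subject {sid} has no post-baseline {code} result")
            uln = float(lb.at[idx[0], "LBORNRHI"])
            lb.loc[idx[0], "LBORRES"] = str(round(ratio * uln, 1))
        return out, CaseDescriptor(
            "hys_law", sid,
            {"alt_uln_ratio": 4.0, "bili_uln_ratio": 3.0,
             "expected_quadrant": "potential Hy's law"},
        )

    if case == "severe_teae":
        ae = domains["AE"].data
        ex = domains["EX"].data
        sid = subject_id or ex["USUBJID"].iloc[0]
        ref = ex.loc[ex["USUBJID"] == sid, "EXSTDTC"].iloc[0]
        onset = dt.date.fromisoformat(ref) + dt.timedelta(days=5)
        seqs = pd.to_numeric(ae.loc[ae["USUBJID"] == sid, "AESEQ"], errors="coerce")
        next_seq = int(seqs.max()) + 1 if len(seqs) and seqs.notna().any() else 1
        pt, soc = "HEPATOTOXICITY", "HEPATOBILIARY DISORDERS"
        rows = []
        for seq, sev in ((next_seq, "MILD"), (next_seq + 1, "SEVERE")):
            rows.append(
                {
                    "STUDYID": ae["STUDYID"].iloc[0] if len(ae) else "CR01",
                    "USUBJID": sid, "AESEQ": str(seq), "AEDECOD": pt,
                    "AEBODSYS": soc, "AESEV": sev, "AESER": "Y" if sev == "SEVERE" else "N",
                    "AESTDTC": _iso(onset), "AEENDTC": None,
                }
            )
        domains["AE"] = DomainTable(
            "AE",
            pd.concat([ae, pd.DataFrame(rows)], ignore_index=True)[ae.columns]
            if len(ae) else pd.DataFrame(rows),
            dict(domains["AE"].variable_labels),
        )
        return out, CaseDescriptor(
            "severe_teae", sid,
            {"preferred_term": pt, "soc": soc, "expected_worst_severity": "SEVERE",
             "n_events": 2},
        )

    if case == "partial_onset":
        ae = domains["AE"].data
        if len(ae) == 0:
            raise ValueError("no adverse events to truncate")
        sid = subject_id or ae["USUBJID"].iloc[0]
        idx = ae.index[ae["USUBJID"] == sid][0]
        full = ae.at[idx, "AESTDTC"]
        ae.loc[idx, "AESTDTC"] = str(full)[:7]
        return out, CaseDescriptor(
            "partial_onset", sid,
            {"aeseq": ae.at[idx, "AESEQ"], "original_date": full,
             "written_date": str(full)[:7]},
        )

    raise ValueError(f"unknown case {case!r}: expected hys_law, severe_teae, partial_onset")


def load_fixture_study() -> StudyBatch:
    """Load the tiny frozen six-subject study shipped with the package.

    Generated once by this module (seed 20240101) with an injected
    Hy's-law case and a severe treatment-emergent event on subject
    FIX01-0001; used for documentation examples and snapshot tests.
    """
    from importlib import resources

    from .datamodel import load_batch

    root = resources.files("clinreview") / "data" / "fixture_study"
    manifest = yaml.safe_load((root / "batch.yaml").read_text("utf-8"))
    return load_batch(Path(str(root)), manifest)


def write_batch(
    batch: StudyBatch, directory: str | Path, xpt_mirror: bool = False
) -> Path:
    """Write a batch to the folder layout ``load_batch`` consumes.

    One CSV (plus label sidecar) per domain and a ``batch.yaml``
    manifest; with ``xpt_mirror`` an XPT v5 copy of each domain is
    written alongside.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "batch_id": batch.batch_id,
        "cutoff_date": batch.cutoff_date,
        "blinded": batch.blinded,
        "treatment_var": batch.treatment_var or "ARM",
        "domains": {},
    }
    for code, table in batch.domains.items():
        filename = f"{code.lower()}.csv"
        write_domain(table, directory / filename)
        manifest["domains"][code] = filename
        if xpt_mirror:
            from .xpt import write_xpt

            write_xpt(table, directory / f"{code.lower()}.xpt")
    with open(directory / "batch.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return directory
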