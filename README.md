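# clinreview

Config-driven clinical data review reporting: an engine that turns
SDTM-like long-format clinical trial data into a modular, standalone,
multi-chapter HTML safety-monitoring report — summary tables and
listings with drill-down links to per-subject patient profiles, chart
data products, and record-level comparison between consecutive data
batches.

## Who it is for

Medical monitors, safety monitoring committees ((I)DMC/SMC) and
biostatisticians who review accumulating safety data during an ongoing
trial. Instead of static tables/listings/figures, they get one
archivable, self-contained report per data snapshot: every aggregate
count links to the subjects behind it, every figure is coupled with
the flat table of records it was computed from, and everything that
changed since the previous snapshot is flagged.

## What it computes

* **Derivations** on raw domain records: relative *study day* with the
  SDTM convention (the reference date is day 1; there is no day 0),
  partial-date classification with earliest-date imputation and an
  imputed flag that travels into every display, numeric severity
  ordering, categorization of continuous variables, same-visit
  averaging of ECG/vital-sign replicates within a ±3-day window, and
  the Fridericia-corrected QT interval
  QTcF = QT / RR^(1/3), with RR = 60/HR when only heart rate exists.
* **Summary tables**: demographic frequencies (distinct subjects,
  percentages over the per-arm analysis population), continuous
  descriptives (n, mean, sample SD, median, min, max), subject
  disposition with a discontinuation listing, and treatment-emergent
  adverse-event incidence in a SOC → PT → severity hierarchy where
  each subject counts once per row at their worst severity. Any table
  can carry a side-by-side column recomputed on the previous batch.
* **Chart data products**: subjects-by-visit bars, the AE
  treemap/sunburst hierarchy (SOC counts are subject-set unions of
  their PTs), the hepatotoxicity eDish scatter (per-subject peak
  post-baseline ALT vs total bilirubin in ULN multiples, reference
  lines at 3× and 2×; the joint-elevation quadrant is the potential
  Hy's-law region), lab spaghetti lines with per-arm mean±SD overlay,
  and baseline → worst post-baseline shift cross-tabs.
* **Batch diff**: key-based record-level comparison of two snapshots
  classifying additions, removals and changes, with the exact set of
  changed variables per record; `apply_diff` replays a diff as a
  round-trip check.
* **Patient profiles**: per-subject paginated PDF documents stacking
  text, event, interval and line modules on a shared study-day axis,
  with imputed dates drawn as open markers.
* **Report pipeline**: YAML config validated per chapter against
  packaged JSON schemas, chapters rendered to standalone HTML
  (parallelizable, deterministic), an index with a content-digest
  report identifier, and blinded/unblinded runs that differ only by
  the treatment variable.

A synthetic SDTM-like study generator (`clinreview.synth`) produces
internally consistent DM/SV/EX/DS/AE/LB/EG/VS batches with known
ground truth — including a consecutive batch with exactly known
injected differences and named safety scenarios — so every part of the
engine is testable without any real trial data.

## Worked example

```python
from clinreview import (StudyRecipe, generate_study, generate_next_batch,
                        subject_groups, summarize_ae, export_table,
                        diff_batches)
from clinreview.synth import BatchDelta

batch, truth = generate_study(StudyRecipe(n_subjects=50, seed=1))
dm = batch.domain("DM")
groups = subject_groups(dm, "ARM")
table = summarize_ae(batch.domain("AE"), dm.subjects, groups)
print(export_table(table, "static_doc"))
```

prints (first rows):

```
Adverse events by system organ class and preferred term
row                     column   n_subjects  pct   n_events ...
----------------------------------------------------------------
Any event               Active   15          60.0  28
Any event               Placebo  19          76.0  29
GENERAL DISORDERS       Active   7           28.0  7
GENERAL DISORDERS       Placebo  9           36.0  11
  PYREXIA               Active   5           20.0  5
  PYREXIA               Placebo  3           12.0  3
    MILD                Active   4           16.0
```

Read: 15 of the 25 Active-arm subjects (60.0%) had at least one
adverse event, across 28 events; 5 Active subjects had pyrexia, 4 of
whom had it at worst severity MILD. Comparing against a derived next
batch with known injected edits:

```python
new_batch, _ = generate_next_batch(
    batch, BatchDelta(counts={"AE": {"additions": 3, "changes": 2,
                                     "removals": 1}}, seed=2))
diff = diff_batches(batch.domain("AE"), new_batch.domain("AE"),
                    ["USUBJID", "AEDECOD", "AESTDTC", "AESEQ"])
print(diff.summary)   # {'addition': 3, 'removal': 1, 'change': 2}
```

A full report (profiles + chapters + index) from the shell:

```sh
clinreview simulate --out study --seed 1 --next-batch
clinreview render --data-dir study/batch2 --previous-data-dir study/batch1 \
    --output report --jobs 4
```

## Layout

```
src/clinreview/
  datamodel.py    long-format domain tables, CSV/XPT reading, batches
  derivations.py  study day, partial dates, severity rank, QTcF, averaging
  summary.py      summary tables, TEAE flags, exports, previous-batch columns
  diff.py         batch comparison, apply_diff, diff listings
  charts.py       chart payloads with coupled backing tables
  profiles.py     patient profile modules, pagination, PDF rendering
  pipeline.py     config loading, schema validation, chapter/report build
  schema.py       presence-and-type parameter validation
  synth.py        synthetic study generator with ground truth
  defaults/       packaged blinded/unblinded configs + chapter JSON schemas
  data/fixture_study/  frozen 6-subject example study (CSV)
```
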