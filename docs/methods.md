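# Methods

This note documents the conventions, parameters and design choices
behind the review engine: what each computation assumes, where a rule
had to be fixed by convention, and what the synthetic-data tests do
and do not demonstrate about real trial data.

## Data model

Domain tables are long-format: one row per record, one column per
variable, all values held as text until a computation needs a number
or a date. Keeping text at the I/O layer has two consequences we rely
on: partial dates (`2023-06`) survive verbatim until the derivation
layer classifies them, and the batch diff can compare records exactly
on their stored representation — no floating-point epsilon that could
hide a genuine edit in a snapshot (clinical snapshot values are
categorical or decimal text; an epsilon would create false negatives,
not robustness). Empty CSV cells and SAS transport missing values both
normalize to a single internal missing marker, and missing == missing
counts as equal in comparisons.

CSV is RFC 4180 with a required header and an optional
`<stem>-labels.csv` sidecar for variable labels; SAS transport (XPT
v5) is read through pandas' xport reader, which also supplies the
variable labels from the transport metadata. The package writes CSV
only; the small XPT writer in `clinreview.xpt` exists to create
transport-format fixtures for round-trip testing and writes every
variable as a character field (exact for a text-valued model).

The subject identifier defaults to `USUBJID` and is configurable; no
required-variable list is hard-coded — the per-domain defaults ship in
the packaged configuration, where a study can override them.

## Derivations

* **Study day** follows the SDTM `--DY` convention: the reference date
  is day 1, the day before it is day −1, day 0 does not exist. The
  convention was chosen for interoperability with SDTM-trained
  reviewers. Both dates must be complete; partial dates are imputed
  first so that the imputation flag can travel with the result.
* **Partial dates** are classified as complete / missing day / missing
  month+day / fully missing. Imputation is *earliest consistent*:
  missing day → 01, missing month → January. Earliest imputation makes
  the treatment-emergent flag conservative (an uncertain onset is
  pulled toward the treatment window, not out of it). Fully missing
  dates are never imputed. All downstream displays carry the imputed
  flag; patient profiles draw imputed timings with an open marker.
* **Severity ranking** is a 1-based index into a configurable ordered
  list (default MILD < MODERATE < SEVERE; CTCAE grades 1–5 work
  unchanged). Unknown or missing severities rank one past the end so
  they sort last rather than silently first.
* **Visit-window averaging** (ECG/vitals replicates): records within
  ±`window_days` (default 3) of the visit's nominal day collapse to
  their arithmetic mean; the output keeps the earliest timestamp and
  an `averaged_flag`. The width and the use of the mean (rather than
  median) are conventions; both are configurable. The flag is sticky
  so the operation is idempotent on its own output.
* **QTcF** uses Fridericia's cube-root correction,
  QTcF = QT/RR^(1/3) with RR in seconds. A measured RR interval is
  preferred; otherwise RR = 60/HR. If neither constituent exists the
  value is simply not derived. No other corrections (Bazett etc.) are
  offered.

## Summary tables

Counts are *distinct subjects*; percentages use the configured
analysis population per arm as denominator (all DM subjects by
default), not the subjects with records in the domain — so a subject
with no AE still contributes to the AE percentage denominator.
Percentages and statistics are stored unrounded and rounded only at
export (percentages to one decimal).

Treatment-emergent AEs: onset between first dose and last dose +
`lag_days` (default 30), boundaries inclusive; an exposure record
without an end date means ongoing dosing (no upper bound); fully
missing onsets are included conservatively; subjects with AEs but no
exposure record flag false with a logged warning. The lag default and
the conservative-inclusion rule are design choices — the field uses
the term without a single canonical definition.

The AE hierarchy is SOC → PT → severity. Within any row a subject
counts once, at the worst severity of their events under that row;
severity rows therefore partition their PT's subjects, while SOC
counts are subject-set unions over PTs (not sums). Rows order by
descending total subject count, ties alphabetically. Every incidence
cell retains its subject ids so the report can link each count to the
patient profiles.

The previous-batch column is computed by re-running the identical
summary operation on the earlier batch — never by caching — so the
comparison inherits any configuration change automatically. Rows new
to the current batch get empty previous cells; a missing domain marks
the previous column unavailable without touching the current table.

## Batch comparison

Diffs are keyed on configured per-domain variables (e.g. AE: subject,
preferred term, onset date, sequence number). A key only in the new
batch is an addition, only in the old a removal; both with any
compared variable differing, a change listing exactly the differing
variables. A changed key is by definition a removal plus an addition —
no fuzzy matching. Variables present in only one batch are reported
once as a schema-level note rather than per-record noise.
`apply_diff` replays a diff onto the old table and must reproduce the
new one on the compared columns; this round trip is asserted over
seeded random batch pairs.

## Chart data products

Every chart payload carries the flat backing table it was computed
from, and the series is derived from that backing table by a pure
function — so "the table behind the visualization" is a checkable
contract, not a convention. eDish uses independent per-parameter
maxima of post-baseline values in ULN multiples (record-level
reference ranges preferred, config fallback), reference lines at
3×ULN (ALT) and 2×ULN (bilirubin) on log-scaled axes; post-baseline
means study day > 1, matching the shift-plot baseline rule (last
non-missing value on or before day 1). In shift plots the worst
post-baseline category takes high over low when both occur — a
tie-break the engine had to fix; it is documented here because no
external rule decides it.

## Patient profiles

Modules stack in configured order (demographics text first, then
exposure and AE intervals, disposition events, lab lines — the
conventional reading order) on a shared study-day axis. Pagination is
greedy: a module that does not fit the remaining page height starts a
new page; modules never split. Page height is 10 abstract units
(about an A4 page at the shipped module heights). Output is one
paginated PDF per subject with a deterministic file name; PDF
metadata omits creation timestamps so identical inputs give identical
bytes, serially or across worker processes.

## Report pipeline

Chapter parameters are validated against per-template JSON schemas
(draft-07 semantics for `required` and `type`, plus enum/bounds/items)
before any rendering; failures name the parameter, the expected type
and the offending value. Configuration loading is strict: an unknown
top-level key is fatal, because the intended users are
minimally-technical and a silently ignored typo is worse than an
error. The report identifier is a 12-hex-digit SHA-256 content digest
of the configuration and the input data plus a build timestamp; only
the digest component appears on pages (so rebuilds are byte-identical)
while the timestamp is confined to the manifest. Chapters render
independently — a failure yields an error page and a nonzero exit at
the end without affecting siblings — and in parallel worker processes
when requested. Blinded runs drop the treatment variable from every
domain before any computation and assert it never reappears; the
blinded single column must equal the pooled unblinded columns exactly,
which the tests assert table-by-table on a full report pair.

## Synthetic study generator

The generator emulates the *structure* of an SDTM snapshot, not
pharmacology: staggered enrolment over 60 days, a fixed visit
schedule with ±1-day jitter and a per-visit discontinuation hazard,
exposure from reference date to last attended visit, adverse events
drawn per attended visit from a small SOC/PT catalogue with
configurable severity mix, partial onset dates at a configured rate
and pre-treatment events to exercise the TEAE boundary, labs (ALT,
bilirubin, creatinine) uniform over −0.25…1.35 of the reference
range (so abnormal values occur but never reach the eDish thresholds
unless injected), ECG QT/HR with occasional same-visit replicates for
the averaging path, and vitals. Defaults describe a small two-arm
safety population of 50 subjects, six visits two weeks apart, a 20%
per-visit AE rate, 60/30/10 mild/moderate/severe, 5% dropout hazard
and 5% month-precision onset dates. All randomness flows from one
seed through a single PCG64 stream, so batches are reproducible
across platforms.

Ground truth records every decision the generator makes (arm
assignment, attended visits, discontinuation reasons, the expected
treatment-emergent flag of each written AE record, abnormal-lab
subjects), which lets tests compare engine output against
construction rather than a re-derivation. `generate_next_batch`
injects an exactly known set of additions/changes/removals and returns
the expected diff; `inject_case` realizes named scenarios (Hy's law,
severe TEAE, partial onset) with a descriptor of the expected
downstream classification.

What passing tests show — and what they do not: the synthetic data is
relationally consistent and covers the structural edge cases (partial
dates, ongoing events, replicates, dropouts, empty domains), so the
tests demonstrate the *logic* of the engine. They do not demonstrate
robustness to the messiness of real eCRF-derived data — inconsistent
units, free-text severities, duplicate keys from data-entry errors —
beyond the specific error paths (duplicate diff keys, missing
variables, malformed dates) that raise named errors by design.

## Problem sizes and numerics

The shipped checks use 10-subject studies for the 50-pair diff loop,
200 subjects for the brute-force summary oracle, 100 randomized AE
tables for the invariants, a 30-subject pair of full reports for the
blinding identity, and the frozen 6-subject fixture for build
determinism — sizes at which every oracle is exact and the whole
suite runs in well under a minute of compute per check. Continuous
statistics use pandas with the sample (n−1) SD; equality checks on
recomputed statistics use a 1e-12 relative tolerance; count
comparisons are exact. Ties in categorical ordering break
alphabetically everywhere so output order is total and reproducible.

## Known limitations

No inferential statistics (the report is descriptive by design), no
Word-fidelity static export (the static form is a plain paginated
document), no unit conversion, no multiple imputation of dates, no
three-way batch merge, and interactivity itself (hover, click,
filter) is delegated to whatever front-end consumes the embedded JSON
payloads — the engine fixes the data and linking contracts those
widgets rely on.
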