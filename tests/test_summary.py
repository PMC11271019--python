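"""Summary engine: incidence and descriptive tables versus brute force."""

import math

import pandas as pd
import pytest

from clinreview.datamodel import DomainTable
from clinreview.summary import (
    ALL_GROUP,
    ANY_EVENT,
    attach_previous_batch,
    export_table,
    flag_treatment_emergent,
    subject_groups,
    summarize_ae,
    summarize_categorical,
    summarize_continuous,
    summarize_disposition,
)


def _table(code, rows):
    return DomainTable(code, pd.DataFrame(rows).astype(object))


class TestCategorical:
    def test_four_subjects_even_split(self):
        dm = _table("DM", [{"USUBJID": s, "SEX": v} for s, v in
                           [("S1", "M"), ("S2", "M"), ("S3", "F"), ("S4", "F")]])
        groups = {s: ALL_GROUP for s in "S1 S2 S3 S4".split()}
        table = summarize_categorical(dm, "SEX", groups, list(groups))
        for level in ("M", "F"):
            cell = table.cell(level, ALL_GROUP)
            assert cell.n_subjects == 2 and cell.pct == pytest.approx(50.0)

    def test_single_subject_is_100_pct(self):
        dm = _table("DM", [{"USUBJID": "S1", "SEX": "F"}])
        table = summarize_categorical(dm, "SEX", {"S1": ALL_GROUP}, ["S1"])
        assert table.cell("F", ALL_GROUP).pct == pytest.approx(100.0)

    def test_missing_row_only_when_missing_values_exist(self):
        dm = _table("DM", [{"USUBJID": "S1", "SEX": "M"}, {"USUBJID": "S2", "SEX": None}])
        groups = {"S1": ALL_GROUP, "S2": ALL_GROUP}
        table = summarize_categorical(dm, "SEX", groups, ["S1", "S2"])
        assert table.rows[-1].path == ("Missing",)
        dm2 = _table("DM", [{"USUBJID": "S1", "SEX": "M"}])
        table2 = summarize_categorical(dm2, "SEX", {"S1": ALL_GROUP}, ["S1"])
        assert all(r.path != ("Missing",) for r in table2.rows)

    def test_matches_groupby_distinct_count_oracle(self, large_study):
        batch, truth = large_study
        dm = batch.domain("DM")
        groups = subject_groups(dm, "ARM")
        pop = dm.subjects
        table = summarize_categorical(dm, "RACE", groups, pop)
        # independent oracle: pandas group-by distinct-count
        df = dm.data
        oracle = df.groupby(["ARM", "RACE"])["USUBJID"].nunique()
        arm_n = df.groupby("ARM")["USUBJID"].nunique()
        for (arm, race), n in oracle.items():
            cell = table.cell(race, arm)
            assert cell.n_subjects == n
            assert cell.pct == pytest.approx(100.0 * n / arm_n[arm])

    def test_percentages_sum_to_100_per_group(self, large_study):
        batch, _ = large_study
        dm = batch.domain("DM")
        groups = subject_groups(dm, "ARM")
        table = summarize_categorical(dm, "SEX", groups, dm.subjects)
        for col in table.columns:
            total = sum(r.cells[col].pct for r in table.rows)
            assert total == pytest.approx(100.0, abs=1e-9)


class TestContinuous:
    def test_basic_statistics(self):
        lb = _table("LB", [{"USUBJID": f"S{i}", "VAL": v} for i, v in enumerate([1, 2, 3])])
        groups = {f"S{i}": ALL_GROUP for i in range(3)}
        cell = summarize_continuous(lb, "VAL", groups, list(groups)).rows[0].cells[ALL_GROUP]
        assert (cell.n, cell.mean, cell.sd, cell.median, cell.min, cell.max) == (
            3, 2.0, 1.0, 2.0, 1.0, 3.0)

    def test_single_value_has_no_sd(self):
        lb = _table("LB", [{"USUBJID": "S1", "VAL": 5}])
        cell = summarize_continuous(lb, "VAL", {"S1": ALL_GROUP}, ["S1"]).rows[0].cells[ALL_GROUP]
        assert cell.n == 1 and cell.mean == 5.0 and cell.sd is None

    def test_all_missing_yields_absent_statistics(self):
        lb = _table("LB", [{"USUBJID": "S1", "VAL": "high"}])
        cell = summarize_continuous(lb, "VAL", {"S1": ALL_GROUP}, ["S1"]).rows[0].cells[ALL_GROUP]
        assert cell.n == 0 and cell.n_missing == 1 and cell.mean is None

    def test_matches_two_pass_oracle_on_synthetic_labs(self, large_study):
        batch, _ = large_study
        lb = batch.domain("LB")
        alt = DomainTable("LB", lb.data[lb.data["LBTESTCD"] == "ALT"].reset_index(drop=True))
        groups = subject_groups(batch.domain("DM"), "ARM")
        table = summarize_continuous(alt, "LBORRES", groups, batch.domain("DM").subjects)
        for col in table.columns:
            values = [
                float(r["LBORRES"]) for r in alt.records() if groups.get(r["USUBJID"]) == col
            ]
            n = len(values)
            mean = sum(values) / n
            sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
            cell = table.rows[0].cells[col]
            assert cell.n == n
            assert cell.mean == pytest.approx(mean, rel=1e-12)
            assert cell.sd == pytest.approx(sd, rel=1e-12)


class TestTreatmentEmergent:
    def _setup(self, onset):
        ae = _table("AE", [{"USUBJID": "S1", "AESTDTC": onset}])
        ex = _table("EX", [{"USUBJID": "S1", "EXSTDTC": "2023-03-01",
                            "EXENDTC": "2023-04-01"}])
        return ae, ex

    @pytest.mark.parametrize(
        "onset,expected",
        [
            ("2023-03-01", True),    # onset on first-dose day counts
            ("2023-02-28", False),   # the day before does not
            ("2023-05-01", True),    # within the 30-day lag
            ("2023-05-02", False),   # just past the lag
            ("", True),              # fully missing onset kept conservatively
        ],
    )
    def test_window_boundaries(self, onset, expected):
        ae, ex = self._setup(onset)
        assert flag_treatment_emergent(ae, ex, lag_days=30).tolist() == [expected]

    def test_subject_without_exposure_is_false_with_warning(self, caplog):
        ae = _table("AE", [{"USUBJID": "S9", "AESTDTC": "2023-03-05"}])
        ex = _table("EX", [{"USUBJID": "S1", "EXSTDTC": "2023-03-01", "EXENDTC": None}])
        with caplog.at_level("WARNING"):
            flags = flag_treatment_emergent(ae, ex)
        assert flags.tolist() == [False]
        assert any("S9" in m for m in caplog.messages)

    def test_flags_match_generator_ground_truth(self, mid_study):
        batch, truth = mid_study
        ae = batch.domain("AE")
        flags = flag_treatment_emergent(ae, batch.domain("EX"),
                                        lag_days=30)
        for rec, flag in zip(ae.records(), flags):
            key = (rec["USUBJID"], rec["AESEQ"])
            assert bool(flag) == truth.teae[key], key


class TestAeSummary:
    def test_worst_severity_counts_subject_once(self):
        ae = _table("AE", [
            {"USUBJID": "S1", "AEBODSYS": "GI", "AEDECOD": "NAUSEA", "AESEV": "MILD"},
            {"USUBJID": "S1", "AEBODSYS": "GI", "AEDECOD": "NAUSEA", "AESEV": "SEVERE"},
        ])
        table = summarize_ae(ae, ["S1"], {"S1": ALL_GROUP})
        pt = table.cell(("GI", "NAUSEA"), ALL_GROUP)
        assert pt.n_subjects == 1 and pt.n_events == 2
        assert table.cell(("GI", "NAUSEA", "SEVERE"), ALL_GROUP).n_subjects == 1
        with pytest.raises(KeyError):
            table.row("GI", "NAUSEA", "MILD")

    def test_soc_count_is_union_of_disjoint_pts(self):
        ae = _table("AE", [
            {"USUBJID": "S1", "AEBODSYS": "GI", "AEDECOD": "NAUSEA", "AESEV": "MILD"},
            {"USUBJID": "S2", "AEBODSYS": "GI", "AEDECOD": "VOMITING", "AESEV": "MILD"},
        ])
        table = summarize_ae(ae, ["S1", "S2"], {"S1": ALL_GROUP, "S2": ALL_GROUP})
        assert table.cell(("GI",), ALL_GROUP).n_subjects == 2

    def test_empty_table_yields_zero_any_event_row(self):
        ae = DomainTable("AE", pd.DataFrame(
            columns=["USUBJID", "AEBODSYS", "AEDECOD", "AESEV"], dtype=object))
        table = summarize_ae(ae, ["S1"], {"S1": ALL_GROUP})
        assert table.rows[0].path == (ANY_EVENT,)
        assert table.rows[0].cells[ALL_GROUP].n_subjects == 0

    def test_matches_per_subject_max_severity_oracle(self, mid_study):
        batch, _ = mid_study
        ae = batch.domain("AE")
        dm = batch.domain("DM")
        groups = subject_groups(dm, "ARM")
        pop = dm.subjects
        table = summarize_ae(ae, pop, groups)
        # brute-force oracle on raw records
        ranks = {"MILD": 1, "MODERATE": 2, "SEVERE": 3}
        recs = ae.records()
        socs = {r["AEBODSYS"] for r in recs}
        for soc in socs:
            soc_recs = [r for r in recs if r["AEBODSYS"] == soc]
            for col in table.columns:
                expected = {r["USUBJID"] for r in soc_recs if groups[r["USUBJID"]] == col}
                cell = table.cell((soc,), col)
                assert cell.n_subjects == len(expected)
                assert set(cell.subjects) == expected
                assert cell.n_events == sum(
                    1 for r in soc_recs if groups[r["USUBJID"]] == col)
            for pt in {r["AEDECOD"] for r in soc_recs}:
                pt_recs = [r for r in soc_recs if r["AEDECOD"] == pt]
                worst = {}
                for r in pt_recs:
                    worst[r["USUBJID"]] = max(worst.get(r["USUBJID"], 0), ranks[r["AESEV"]])
                for col in table.columns:
                    # severity children partition the PT subjects
                    total = sum(
                        table.cell((soc, pt, sev), col).n_subjects
                        for sev in ("MILD", "MODERATE", "SEVERE")
                        if any(r.path == (soc, pt, sev) for r in table.rows)
                    )
                    assert total == table.cell((soc, pt), col).n_subjects

    def test_any_event_equals_subject_union(self, mid_study):
        batch, _ = mid_study
        ae = batch.domain("AE")
        dm = batch.domain("DM")
        groups = subject_groups(dm, "ARM")
        table = summarize_ae(ae, dm.subjects, groups)
        union = {r["USUBJID"] for r in ae.records()}
        assert sum(table.cell((ANY_EVENT,), c).n_subjects for c in table.columns) == len(union)


class TestDisposition:
    def _fixture(self):
        rows = []
        for i in range(10):
            sid = f"S{i}"
            status = "COMPLETED" if i >= 2 else "ADVERSE EVENT"
            rows.append({"USUBJID": sid, "DSDECOD": status, "DSSTDTC": "2023-05-01"})
        ds = _table("DS", rows)
        groups = {f"S{i}": ALL_GROUP for i in range(10)}
        return ds, groups

    def test_counts_and_percentages(self):
        ds, groups = self._fixture()
        table, listing = summarize_disposition(ds, list(groups), groups)
        cell = table.cell("Discontinued", ALL_GROUP)
        assert cell.n_subjects == 2 and cell.pct == pytest.approx(20.0)
        assert len(listing) == 2
        assert {r["reason"] for r in listing} == {"ADVERSE EVENT"}

    def test_zero_discontinuations_gives_empty_listing(self):
        ds = _table("DS", [{"USUBJID": "S1", "DSDECOD": "COMPLETED", "DSSTDTC": "2023-05-01"}])
        table, listing = summarize_disposition(ds, ["S1"], {"S1": ALL_GROUP})
        assert table.cell("Discontinued", ALL_GROUP).n_subjects == 0
        assert table.cell("Discontinued", ALL_GROUP).pct == pytest.approx(0.0)
        assert listing == []

    def test_listing_matches_generator_reasons(self, mid_study):
        batch, truth = mid_study
        dm = batch.domain("DM")
        groups = subject_groups(dm, "ARM")
        _, listing = summarize_disposition(
            batch.domain("DS"), dm.subjects, groups, truth.reference_dates)
        assert {r["subject_id"]: r["reason"] for r in listing} == truth.discontinuations
        for row in listing:
            assert row["study_day"] is not None and row["study_day"] >= 1


class TestPreviousBatch:
    def test_identical_batch_reproduces_stats(self, small_study):
        batch, _ = small_study
        dm = batch.domain("DM")
        groups = subject_groups(dm, "ARM")
        compute = lambda b: summarize_categorical(
            b.domain("DM"), "SEX", subject_groups(b.domain("DM"), "ARM"),
            b.domain("DM").subjects)
        table = attach_previous_batch(compute(batch), batch, compute)
        assert table.previous.available
        for row in table.rows:
            for col in table.columns:
                prev = table.previous.cells[(row.path, col)]
                assert prev.stats_equal(row.cells[col])

    def test_missing_domain_marks_previous_unavailable(self, small_study):
        batch, _ = small_study
        from clinreview.datamodel import StudyBatch

        previous = StudyBatch("old", "2023-01-01", {"DM": batch.domain("DM")})
        compute = lambda b: summarize_categorical(
            b.domain("AE"), "AESEV",
            {s: ALL_GROUP for s in b.domain("DM").subjects},
            b.domain("DM").subjects)
        table = attach_previous_batch(compute(batch), previous, compute)
        assert table.previous is not None and not table.previous.available


class TestExport:
    def test_unknown_format_lists_supported(self, small_study):
        batch, _ = small_study
        table = summarize_categorical(
            batch.domain("DM"), "SEX",
            subject_groups(batch.domain("DM"), "ARM"), batch.domain("DM").subjects)
        with pytest.raises(ValueError, match="interactive_html_data.*csv.*static_doc"):
            export_table(table, "docx")

    def test_csv_round_trips_displayed_values(self, small_study, tmp_path):
        batch, _ = small_study
        dm = batch.domain("DM")
        groups = subject_groups(dm, "ARM")
        table = summarize_categorical(dm, "SEX", groups, dm.subjects)
        path = tmp_path / "sex.csv"
        export_table(table, "csv", path)
        back = pd.read_csv(path, dtype=str, keep_default_na=False)
        for row in table.rows:
            for col in table.columns:
                line = back[(back["row"].str.strip() == row.label) & (back["column"] == col)]
                assert len(line) == 1
                assert line["n_subjects"].iloc[0] == str(row.cells[col].n_subjects)
                assert line["pct"].iloc[0] == f"{row.cells[col].pct:.1f}"

    def test_interactive_payload_links_every_cell_subject(self, small_study):
        batch, _ = small_study
        dm = batch.domain("DM")
        groups = subject_groups(dm, "ARM")
        table = summarize_ae(batch.domain("AE"), dm.subjects, groups)
        link_index = {s: f"profiles/{s}.pdf" for s in dm.subjects}
        payload = export_table(table, "interactive_html_data", link_index=link_index)
        for row_payload, row in zip(payload["rows"], table.rows):
            for col in table.columns:
                subjects = row_payload["cells"][col]["subjects"]
                assert len(subjects) == len(row.cells[col].subjects)
                assert all(s["profile"] == link_index[s["subject_id"]] for s in subjects)

    def test_static_doc_paginates_with_repeated_header(self, large_study, tmp_path):
        batch, _ = large_study
        dm = batch.domain("DM")
        groups = subject_groups(dm, "ARM")
        table = summarize_ae(batch.domain("AE"), dm.subjects, groups)
        doc = export_table(table, "static_doc")
        pages = doc.split("\f")
        assert len(pages) > 1
        assert all(table.title in p for p in pages)

    def test_empty_listing_exports_without_failure(self, tmp_path):
        payload = export_table([], "interactive_html_data", title="Empty")
        assert payload["rows"] == []


class TestBlindingIdentity:
    def test_pooled_unblinded_counts_equal_blinded(self, mid_study):
        batch, _ = mid_study
        dm = batch.domain("DM")
        pop = dm.subjects
        unblinded = summarize_ae(batch.domain("AE"), pop, subject_groups(dm, "ARM"))
        blinded = summarize_ae(batch.domain("AE"), pop, subject_groups(dm, None))
        assert blinded.columns == [ALL_GROUP]
        for row in unblinded.rows:
            pooled = sum(row.cells[c].n_subjects for c in unblinded.columns)
            assert pooled == blinded.row(*row.path).cells[ALL_GROUP].n_subjects
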