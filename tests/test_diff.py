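"""Batch differencing: classification, round trip, and algebraic laws."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clinreview.datamodel import DomainTable
from clinreview.diff import apply_diff, diff_batches, diff_listing
from clinreview.synth import BatchDelta, StudyRecipe, generate_next_batch, generate_study

KEYS = ["USUBJID", "AESEQ"]


def _ae(rows):
    return DomainTable("AE", pd.DataFrame(rows).astype(object))


BASE = [
    {"USUBJID": "S1", "AESEQ": "1", "AEDECOD": "HEADACHE", "AESEV": "MILD"},
    {"USUBJID": "S1", "AESEQ": "2", "AEDECOD": "NAUSEA", "AESEV": "MODERATE"},
    {"USUBJID": "S2", "AESEQ": "1", "AEDECOD": "RASH", "AESEV": "MILD"},
]


class TestClassification:
    def test_identical_tables_produce_no_entries(self):
        diff = diff_batches(_ae(BASE), _ae(BASE), KEYS)
        assert diff.entries == []
        assert diff.summary == {"addition": 0, "removal": 0, "change": 0}

    def test_extra_record_is_single_addition(self):
        new = BASE + [{"USUBJID": "S2", "AESEQ": "2", "AEDECOD": "FATIGUE", "AESEV": "MILD"}]
        diff = diff_batches(_ae(BASE), _ae(new), KEYS)
        assert diff.summary == {"addition": 1, "removal": 0, "change": 0}
        assert diff.entries[0].key == ("S2", "2")

    def test_changed_severity_flags_exactly_that_variable(self):
        new = [dict(r) for r in BASE]
        new[0]["AESEV"] = "MODERATE"
        diff = diff_batches(_ae(BASE), _ae(new), KEYS)
        assert diff.summary["change"] == 1
        entry = diff.entries[0]
        assert entry.changed_vars == frozenset({"AESEV"})
        assert entry.old_record["AESEV"] == "MILD"

    def test_missing_equals_missing(self):
        old = [{"USUBJID": "S1", "AESEQ": "1", "AEENDTC": None}]
        diff = diff_batches(_ae(old), _ae([dict(r) for r in old]), KEYS)
        assert diff.entries == []

    def test_duplicate_key_tuple_is_error_naming_tuple(self):
        dup = BASE + [dict(BASE[0])]
        with pytest.raises(ValueError, match=r"\('S1', '1'\)"):
            diff_batches(_ae(dup), _ae(BASE), KEYS)

    def test_absent_key_variable_is_error(self):
        with pytest.raises(ValueError, match="AESPID"):
            diff_batches(_ae(BASE), _ae(BASE), ["USUBJID", "AESPID"])

    def test_variable_in_one_batch_only_is_schema_note(self):
        new = [dict(r, AESER="N") for r in BASE]
        diff = diff_batches(_ae(BASE), _ae(new), KEYS)
        assert diff.summary == {"addition": 0, "removal": 0, "change": 0}
        assert any("AESER" in n for n in diff.schema_notes)


class TestGeneratorClosedLoop:
    @pytest.mark.parametrize("seed", range(5))
    def test_injected_counts_recovered_exactly(self, seed):
        batch, _ = generate_study(StudyRecipe(n_subjects=10, seed=seed))
        delta = BatchDelta(
            counts={"AE": {"additions": 2 + seed % 3, "changes": 1 + seed % 2,
                           "removals": seed % 2},
                    "LB": {"changes": 3}},
            seed=seed + 100,
        )
        new_batch, truth = generate_next_batch(batch, delta)
        for code, expected in truth.items():
            diff = diff_batches(batch.domain(code), new_batch.domain(code), expected.keys)
            assert diff.summary == expected.summary, code
            got = {e.key: e for e in diff.entries}
            for exp in expected.entries:
                assert got[exp.key].status == exp.status
                assert got[exp.key].changed_vars == exp.changed_vars

    def test_zero_delta_is_byte_identical(self, small_study):
        batch, _ = small_study
        new_batch, truth = generate_next_batch(batch, BatchDelta(counts={"AE": {}}))
        pd.testing.assert_frame_equal(batch.domain("AE").data.reset_index(drop=True),
                                      new_batch.domain("AE").data.reset_index(drop=True))
        assert truth["AE"].entries == []


class TestRoundTrip:
    def _assert_round_trip(self, old, new, keys):
        diff = diff_batches(old, new, keys)
        replayed = apply_diff(old, diff)
        cols = replayed.variables
        left = replayed.data.sort_values(keys).reset_index(drop=True)
        right = new.data[cols].sort_values(keys).reset_index(drop=True)
        pd.testing.assert_frame_equal(left, right)

    def test_empty_diff_returns_old_unchanged(self):
        old = _ae(BASE)
        replayed = apply_diff(old, diff_batches(old, old, KEYS))
        pd.testing.assert_frame_equal(replayed.data, old.data[replayed.variables])

    def test_removal_key_absent_from_old_is_error(self):
        diff = diff_batches(_ae(BASE), _ae(BASE[:2]), KEYS)
        with pytest.raises(ValueError, match="inconsistent"):
            apply_diff(_ae(BASE[:2]), diff)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_random_batch_pairs_round_trip(self, seed):
        batch, _ = generate_study(StudyRecipe(n_subjects=8, n_visits=3, seed=seed % 50))
        delta = BatchDelta(
            counts={"AE": {"additions": seed % 4, "changes": seed % 3, "removals": seed % 2}},
            seed=seed,
        )
        new_batch, _ = generate_next_batch(batch, delta)
        self._assert_round_trip(batch.domain("AE"), new_batch.domain("AE"),
                                ["USUBJID", "AEDECOD", "AESTDTC", "AESEQ"])


class TestAlgebraicLaws:
    def _pair(self, seed):
        batch, _ = generate_study(StudyRecipe(n_subjects=10, seed=seed))
        new_batch, _ = generate_next_batch(
            batch, BatchDelta(counts={"AE": {"additions": 2, "changes": 2, "removals": 1}},
                              seed=seed + 1))
        return batch.domain("AE"), new_batch.domain("AE")

    def test_antisymmetry_swaps_additions_and_removals(self):
        old, new = self._pair(21)
        fwd = diff_batches(old, new, KEYS)
        rev = diff_batches(new, old, KEYS)
        assert fwd.summary["addition"] == rev.summary["removal"]
        assert fwd.summary["removal"] == rev.summary["addition"]
        fwd_changes = {e.key: e.changed_vars for e in fwd.entries if e.status == "change"}
        rev_changes = {e.key: e.changed_vars for e in rev.entries if e.status == "change"}
        assert fwd_changes == rev_changes

    def test_triangle_composition_over_chained_batches(self):
        a, _ = generate_study(StudyRecipe(n_subjects=10, seed=31))
        b, _ = generate_next_batch(
            a, BatchDelta(counts={"AE": {"additions": 2, "changes": 1}}, seed=32))
        c, _ = generate_next_batch(
            b, BatchDelta(counts={"AE": {"changes": 2, "removals": 1}}, seed=33))
        flagged_ab = {e.key for e in diff_batches(a.domain("AE"), b.domain("AE"), KEYS).entries}
        flagged_bc = {e.key for e in diff_batches(b.domain("AE"), c.domain("AE"), KEYS).entries}
        flagged_ac = {e.key for e in diff_batches(a.domain("AE"), c.domain("AE"), KEYS).entries}
        assert flagged_ac <= (flagged_ab | flagged_bc)

    def test_restricting_compare_vars_never_adds_changes(self):
        old, new = self._pair(41)
        full = diff_batches(old, new, KEYS)
        restricted = diff_batches(old, new, KEYS, compare_vars=["AESEV"])
        assert restricted.summary["change"] <= full.summary["change"]


class TestListing:
    def test_one_row_per_entry_with_badges(self):
        new = BASE + [{"USUBJID": "S3", "AESEQ": "1", "AEDECOD": "COUGH", "AESEV": "MILD"}]
        diff = diff_batches(_ae(BASE), _ae(new), KEYS)
        rows = diff_listing(diff)
        assert len(rows) == len(diff.entries) == 1
        assert rows[0]["status"] == "addition"
        assert rows[0]["subject_id"] == "S3"

    def test_change_rows_flag_only_changed_vars(self):
        new = [dict(r) for r in BASE]
        new[1]["AESEV"] = "SEVERE"
        rows = diff_listing(diff_batches(_ae(BASE), _ae(new), KEYS))
        assert rows[0]["changed"] == ["AESEV"]
        assert rows[0]["previous"] == {"AESEV": "MODERATE"}

    @pytest.mark.parametrize("seed", [5, 6])
    def test_row_count_equals_entry_count_for_random_diffs(self, seed):
        batch, _ = generate_study(StudyRecipe(n_subjects=10, seed=seed))
        new_batch, _ = generate_next_batch(
            batch, BatchDelta(counts={"AE": {"additions": 3, "changes": 2, "removals": 2}},
                              seed=seed))
        diff = diff_batches(batch.domain("AE"), new_batch.domain("AE"), KEYS)
        assert len(diff_listing(diff)) == len(diff.entries)
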