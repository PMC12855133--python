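import csv
from datetime import date, datetime

import pytest

from clinflow import (
    CANONICAL_ACTIVITIES,
    CleaningConfig,
    Event,
    EventLog,
    Trace,
    clean_log,
    read_csv_log,
    read_xes_log,
    validate_log,
    write_csv_log,
)
from clinflow.eventlog import ConfigurationError, EmptyInputError
from clinflow.synth import planted_defect_log

from conftest import make_trace


class TestCsvReader:
    def test_counts_preserved(self, small_csv):
        log = read_csv_log(small_csv)
        assert len(log) == 3
        assert log.n_events == 10

    def test_column_mapping_identity(self, small_csv, tmp_path):
        renamed = tmp_path / "renamed.csv"
        text = small_csv.read_text().replace("case_id,", "patient_id,", 1)
        renamed.write_text(text)
        log_canon = read_csv_log(small_csv)
        log_mapped = read_csv_log(renamed, dialect={"case_id": "patient_id"})
        assert [t.case_id for t in log_mapped] == [t.case_id for t in log_canon]
        assert list(log_mapped.events()) == list(log_canon.events())

    def test_unparseable_timestamp_collected_not_dropped(self, small_csv, tmp_path):
        bad = tmp_path / "bad.csv"
        lines = small_csv.read_text().strip().split("\n")
        lines[3] = lines[3].replace("2024-09-04T09:00:00", "n/a")
        bad.write_text("\n".join(lines) + "\n")
        log = read_csv_log(bad)
        assert log.n_events == 9
        assert len(log.unparseable) == 1
        assert log.unparseable[0]["case_id"] == "c1"

    def test_missing_mapped_column_is_config_error(self, small_csv):
        with pytest.raises(ConfigurationError):
            read_csv_log(small_csv, dialect={"case_id": "nope"})

    def test_zero_parseable_rows_is_empty_input(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("case_id,activity,resource,role,timestamp\n")
        with pytest.raises(EmptyInputError):
            read_csv_log(p)


class TestCsvWriter:
    def test_round_trip_identity(self, clean_log_3cases, tmp_path):
        out = write_csv_log(clean_log_3cases, tmp_path / "rt.csv")
        again = read_csv_log(out)
        assert list(again.events()) == list(clean_log_3cases.events())

    def test_empty_log_writes_header_only(self, tmp_path):
        out = write_csv_log(EventLog(), tmp_path / "empty.csv")
        assert out.read_text().strip() == "case_id,activity,resource,role,timestamp"

    def test_comma_in_activity_is_quoted_and_round_trips(self, tmp_path):
        tr = Trace("c1", [Event("c1", "QA, final", "s", "physicist",
                                datetime(2024, 9, 2, 9, 0))])
        out = write_csv_log(EventLog(traces=[tr]), tmp_path / "q.csv")
        # independent parser sees one row with the comma intact
        with out.open() as fh:
            rows = list(csv.DictReader(fh))
        assert len(rows) == 1 and rows[0]["activity"] == "QA, final"
        assert read_csv_log(out).traces[0].events[0].activity == "QA, final"


XES_DOC = """<?xml version="1.0" encoding="UTF-8"?>
<log xmlns="http://www.xes-standard.org/">
  <trace>
    <string key="concept:name" value="c1"/>
    <event>
      <string key="concept:name" value="CT-Sim"/>
      <string key="org:resource" value="alice"/>
      <string key="org:role" value="therapist"/>
      <date key="time:timestamp" value="2024-09-02T09:00:00"/>
    </event>
    <event>
      <string key="concept:name" value="Planning"/>
      <date key="time:timestamp" value="2024-09-03T09:00:00"/>
    </event>
  </trace>
  <trace>
    <string key="concept:name" value="c2"/>
  </trace>
</log>
"""


class TestXesReader:
    def test_cross_format_equality_with_csv(self, tmp_path):
        (tmp_path / "log.xes").write_text(XES_DOC)
        (tmp_path / "log.csv").write_text(
            "case_id,activity,resource,role,timestamp\n"
            "c1,CT-Sim,alice,therapist,2024-09-02T09:00:00\n"
            "c1,Planning,unknown,other,2024-09-03T09:00:00\n"
        )
        xes = read_xes_log(tmp_path / "log.xes")
        csv_log = read_csv_log(tmp_path / "log.csv")
        assert xes.trace("c1").events == csv_log.trace("c1").events

    def test_empty_trace_retained_and_flagged(self, tmp_path):
        (tmp_path / "log.xes").write_text(XES_DOC)
        log = read_xes_log(tmp_path / "log.xes")
        assert len(log.trace("c2")) == 0
        kinds = {v.kind for v in validate_log(log) if v.case_id == "c2"}
        assert "empty_trace" in kinds

    def test_missing_org_attributes_default(self, tmp_path):
        (tmp_path / "log.xes").write_text(XES_DOC)
        ev = read_xes_log(tmp_path / "log.xes").trace("c1").events[1]
        assert ev.resource == "unknown" and ev.role == "other"

    def test_malformed_xml_raises_parse_error(self, tmp_path):
        (tmp_path / "bad.xes").write_text("<log><trace></log>")
        with pytest.raises(ValueError, match="malformed"):
            read_xes_log(tmp_path / "bad.xes")


class TestCleaning:
    def test_planted_defect_fixture_hand_counts(self):
        log, expected = planted_defect_log()
        cleaned, report = clean_log(log, CleaningConfig(collection_end=log.collection_end))
        for key, value in expected.items():
            assert getattr(report, key) == value, key
        # conservation reconciles exactly
        assert report.n_output_events == (
            report.n_input_events
            - report.n_removed_bad_timestamp
            - report.n_duplicates_consolidated
            - report.n_events_discarded_incomplete
        )
        # synonym normalization applied ("QA" -> "QA Check")
        assert "QA" not in {ev.activity for ev in cleaned.events()}

    def test_idempotence(self):
        log, _ = planted_defect_log()
        cfg = CleaningConfig(collection_end=log.collection_end)
        once, _ = clean_log(log, cfg)
        twice, report2 = clean_log(once, cfg)
        assert list(twice.events()) == list(once.events())
        assert report2.n_removed_bad_timestamp == 0
        assert report2.n_duplicates_consolidated == 0
        assert report2.n_cases_discarded_incomplete == 0

    def test_order_stability_for_tied_timestamps(self):
        ts = datetime(2024, 9, 2, 9, 0)
        events = [
            Event("c1", "CT-Sim", "a", "therapist", ts),
            Event("c1", "Planning", "b", "dosimetrist", ts),
            Event("c1", "QA Check", "c", "physicist", ts),
            Event("c1", "Treatment", "d", "therapist", ts),
        ]
        log = EventLog(traces=[Trace("c1", events)], collection_end=date(2024, 12, 31))
        cleaned, _ = clean_log(log, CleaningConfig(collection_end=date(2024, 12, 31)))
        assert cleaned.trace("c1").activities == list(CANONICAL_ACTIVITIES)

    def test_earliest_plausible_cutoff(self):
        old = make_trace("c1", CANONICAL_ACTIVITIES, start=datetime(1999, 9, 2, 9, 0))
        log = EventLog(traces=[old], collection_end=date(2024, 12, 31))
        _, report = clean_log(log, CleaningConfig(collection_end=date(2024, 12, 31)))
        assert report.n_removed_bad_timestamp == 4

    def test_empty_required_activities_rejected(self):
        log, _ = planted_defect_log()
        with pytest.raises(ConfigurationError):
            clean_log(log, CleaningConfig(collection_end=log.collection_end,
                                          required_activities=()))


class TestValidate:
    def test_clean_log_has_no_violations(self):
        log, _ = planted_defect_log()
        cleaned, _ = clean_log(log, CleaningConfig(collection_end=log.collection_end))
        assert validate_log(cleaned) == []

    def test_stage_regression_flagged_once(self):
        tr = make_trace("c1", ["Treatment", "CT-Sim", "Planning", "QA Check"])
        log = EventLog(traces=[tr])
        out_of_seq = [v for v in validate_log(log) if v.kind == "out_of_sequence"]
        assert len(out_of_seq) == 1

    def test_duplicate_case_ids_flagged(self):
        tr1 = make_trace("c1", CANONICAL_ACTIVITIES)
        tr2 = make_trace("c1", CANONICAL_ACTIVITIES)
        dups = [v for v in validate_log(EventLog(traces=[tr1, tr2]))
                if v.kind == "duplicate_case_id"]
        assert len(dups) == 1
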