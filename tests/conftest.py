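from datetime import date, datetime

import pytest

from clinflow import CANONICAL_ACTIVITIES, Event, EventLog, Trace, sequence_model


@pytest.fixture
def pathway_net():
    return sequence_model(CANONICAL_ACTIVITIES)


def make_trace(case_id, activities, start=datetime(2024, 9, 2, 9, 0), roles=None):
    """Trace with strictly increasing timestamps one day apart."""
    events = [
        Event(case_id, act, f"staff-{i + 1}", (roles[i] if roles else "other"),
              datetime(start.year, start.month, start.day + i, start.hour, 0, 0))
        for i, act in enumerate(activities)
    ]
    return Trace(case_id, events)


@pytest.fixture
def small_csv(tmp_path):
    """10-row log over 3 cases, canonical header."""
    rows = [
        "case_id,activity,resource,role,timestamp",
        "c1,CT-Sim,alice,therapist,2024-09-02T09:00:00",
        "c1,Planning,bob,dosimetrist,2024-09-03T09:00:00",
        "c1,QA Check,carol,physicist,2024-09-04T09:00:00",
        "c1,Treatment,alice,therapist,2024-09-05T09:00:00",
        "c2,CT-Sim,alice,therapist,2024-09-02T10:00:00",
        "c2,Planning,bob,dosimetrist,2024-09-03T10:00:00",
        "c2,QA Check,carol,physicist,2024-09-04T10:00:00",
        "c2,Treatment,alice,therapist,2024-09-05T10:00:00",
        "c3,CT-Sim,alice,therapist,2024-09-02T11:00:00",
        "c3,Treatment,alice,therapist,2024-09-06T11:00:00",
    ]
    path = tmp_path / "small.csv"
    path.write_text("\n".join(rows) + "\n")
    return path


@pytest.fixture
def clean_log_3cases(small_csv):
    from clinflow import read_csv_log

    return read_csv_log(small_csv, collection_end=date(2024, 12, 31))
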