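"""Dataset IO, schema validation and cohort membership."""

import pandas as pd
import pytest

from vbmon.data_model import (
    ReferentialError,
    SchemaError,
    StudyDataset,
    cohort_membership,
    read_dataset,
    write_dataset,
)
from vbmon.simulate import CohortConfig, simulate_cohort

from conftest import make_scored


@pytest.fixture()
def small_dataset():
    return simulate_cohort(CohortConfig(seed=1, n_participants=10, study_days=30))


def _write(ds, tmp_path, sub="d"):
    return write_dataset(ds, str(tmp_path / sub))


def test_round_trip_is_identity(small_dataset, tmp_path):
    paths = _write(small_dataset, tmp_path, "a")
    ds2 = read_dataset(paths["sessions"], paths["act"], paths["participants"])
    assert not ds2.diagnostics
    assert small_dataset.sessions.equals(ds2.sessions)
    assert small_dataset.act.equals(ds2.act)
    assert small_dataset.participants.equals(ds2.participants)


def test_double_write_is_byte_identical(small_dataset, tmp_path):
    p1 = _write(small_dataset, tmp_path, "a")
    ds2 = read_dataset(p1["sessions"], p1["act"], p1["participants"])
    p2 = _write(ds2, tmp_path, "b")
    for key in p1:
        assert open(p1[key], "rb").read() == open(p2[key], "rb").read()


def test_bad_wellbeing_row_rejected_with_diagnostic(small_dataset, tmp_path):
    ds = small_dataset
    paths = _write(ds, tmp_path)
    text = open(paths["sessions"]).read().splitlines()
    # corrupt the wellbeing field of the first data row
    header, first, rest = text[0], text[1], text[2:]
    cols = header.split(",")
    fields = first.split(",")
    fields[cols.index("wellbeing")] = "MEH"
    open(paths["sessions"], "w").write("\n".join([header, ",".join(fields), *rest]) + "\n")
    ds2 = read_dataset(paths["sessions"], paths["act"], paths["participants"])
    assert len(ds2.sessions) == len(ds.sessions) - 1
    assert len(ds2.diagnostics) == 1
    assert "wellbeing" in ds2.diagnostics[0].reason


def test_missing_column_is_schema_error(small_dataset, tmp_path):
    paths = _write(small_dataset, tmp_path)
    df = pd.read_csv(paths["sessions"]).drop(columns=["wellbeing"])
    df.to_csv(paths["sessions"], index=False)
    with pytest.raises(SchemaError, match="wellbeing"):
        read_dataset(paths["sessions"], paths["act"], paths["participants"])


def test_unresolvable_participant_is_referential_error(small_dataset, tmp_path):
    paths = _write(small_dataset, tmp_path)
    df = pd.read_csv(paths["sessions"])
    df.loc[0, "participant_id"] = "GHOST"
    df.to_csv(paths["sessions"], index=False)
    with pytest.raises(ReferentialError, match="GHOST"):
        read_dataset(paths["sessions"], paths["act"], paths["participants"])


def test_empty_dataset_writes_header_only_files(small_dataset, tmp_path):
    empty = StudyDataset(
        participants=small_dataset.participants.iloc[:0],
        sessions=small_dataset.sessions.iloc[:0],
        act=small_dataset.act.iloc[:0],
    )
    paths = _write(empty, tmp_path)
    for key in paths:
        lines = open(paths[key]).read().splitlines()
        assert len(lines) == 1  # header only


def _membership_fixture():
    """84 participants: 12 with <4 sessions, 15 more with <5 NORMAL sessions."""
    parts, sess_rows, scored_rows = [], [], []
    t0 = pd.Timestamp("2022-01-01")
    for i in range(84):
        pid = f"P{i:03d}"
        parts.append({"participant_id": pid, "enrollment_date": t0})
        if i < 12:
            n_sessions, n_normal = 3, 3
        elif i < 27:
            n_sessions, n_normal = 10, 4
        else:
            n_sessions, n_normal = 10, 6
        for j in range(n_sessions):
            sess_rows.append(
                {"session_id": len(sess_rows), "participant_id": pid, "session_time": t0 + pd.Timedelta(days=j)}
            )
            state = "NORMAL" if j < n_normal else "MILD"
            scored_rows.append((pid, t0 + pd.Timedelta(days=j), 60.0, state))
    ds = StudyDataset(
        participants=pd.DataFrame(parts),
        sessions=pd.DataFrame(sess_rows),
        act=pd.DataFrame(columns=["participant_id", "act_date", "act_score"]),
    )
    return ds, make_scored(scored_rows)


def test_cohort_counts_enrollment_analysis_normalized():
    ds, scored = _membership_fixture()
    flags = cohort_membership(ds, scored)
    assert int(flags["enrollment"].sum()) == 84
    assert int(flags["analysis"].sum()) == 72
    assert int(flags["normalized"].sum()) == 57


def test_cohort_flags_are_monotone_and_boundaries_hold():
    t0 = pd.Timestamp("2022-01-01")
    parts = pd.DataFrame(
        {"participant_id": ["A", "B"], "enrollment_date": [t0, t0]}
    )
    # A: zero sessions. B: exactly 4 sessions, all NORMAL (4 < 5 -> not normalized).
    sess = pd.DataFrame(
        {
            "session_id": range(4),
            "participant_id": ["B"] * 4,
            "session_time": [t0 + pd.Timedelta(days=d) for d in range(4)],
        }
    )
    scored = make_scored([("B", t0 + pd.Timedelta(days=d), 60.0, "NORMAL") for d in range(4)])
    ds = StudyDataset(parts, sess, pd.DataFrame(columns=["participant_id", "act_date", "act_score"]))
    flags = cohort_membership(ds, scored).set_index("participant_id")
    assert flags.loc["A", "enrollment"] and not flags.loc["A", "analysis"]
    assert flags.loc["B", "analysis"] and not flags.loc["B", "normalized"]
    assert (flags["normalized"] <= flags["analysis"]).all()
    assert (flags["analysis"] <= flags["enrollment"]).all()


def test_membership_invariant_to_session_order():
    ds, scored = _membership_fixture()
    shuffled = StudyDataset(
        participants=ds.participants,
        sessions=ds.sessions.sample(frac=1.0, random_state=0),
        act=ds.act,
    )
    a = cohort_membership(ds, scored).sort_values("participant_id").reset_index(drop=True)
    b = cohort_membership(shuffled, scored).sort_values("participant_id").reset_index(drop=True)
    assert a.equals(b)
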