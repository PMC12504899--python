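"""Transition change scores, engagement and descriptive tables."""

import numpy as np
import pandas as pd
import pytest

from vbmon.data_model import StudyDataset
from vbmon.metrics import (
    descriptive_tables,
    engagement_group,
    engagement_summary,
    transition_matrix,
)

from conftest import make_scored


def test_single_pair_transition():
    t0 = pd.Timestamp("2022-01-01")
    scored = make_scored(
        [("A", t0, 60.0, "NORMAL"), ("A", t0 + pd.Timedelta(days=1), 66.0, "EXACERBATION")]
    )
    tm = transition_matrix(scored)
    cell = tm.loc[("NORMAL", "EXACERBATION")]
    assert cell["mean_change"] == 6.0
    assert cell["n_transitions"] == 1
    assert np.isnan(cell["se_change"])
    assert tm["n_transitions"].sum() == 1


def test_constant_scores_have_zero_diagonal():
    t0 = pd.Timestamp("2022-01-01")
    rows = [("A", t0 + pd.Timedelta(days=i), 60.0, "NORMAL") for i in range(5)]
    tm = transition_matrix(make_scored(rows))
    assert tm.loc[("NORMAL", "NORMAL"), "mean_change"] == 0.0
    assert tm.loc[("NORMAL", "NORMAL"), "n_transitions"] == 4


def test_pair_count_identity(analyzed):
    """Total pairs = sum over participants of (scored sessions - 1)."""
    scored = analyzed.scored
    tm = transition_matrix(scored)
    sizes = scored.groupby("participant_id").size()
    expected = int((sizes[sizes >= 2] - 1).sum())
    assert int(tm["n_transitions"].sum()) == expected


def test_time_reversal_negates_and_transposes(analyzed):
    scored = analyzed.scored
    tm = transition_matrix(scored)
    rev = scored.copy()
    tmax = rev["session_time"].max()
    rev["session_time"] = tmax - (rev["session_time"] - rev["session_time"].min())
    rev["session_id"] = -rev["session_id"]  # preserve intra-day pair order under ties
    tm_rev = transition_matrix(rev)
    for a in ("NORMAL", "MILD", "EXACERBATION"):
        for b in ("NORMAL", "MILD", "EXACERBATION"):
            n1 = tm.loc[(a, b), "n_transitions"]
            n2 = tm_rev.loc[(b, a), "n_transitions"]
            assert n1 == n2
            if n1 > 0:
                assert tm_rev.loc[(b, a), "mean_change"] == pytest.approx(
                    -tm.loc[(a, b), "mean_change"]
                )


def test_max_gap_restricts_pairs():
    t0 = pd.Timestamp("2022-01-01")
    rows = [
        ("A", t0, 60.0, "NORMAL"),
        ("A", t0 + pd.Timedelta(days=2), 62.0, "NORMAL"),
        ("A", t0 + pd.Timedelta(days=30), 64.0, "NORMAL"),
    ]
    assert transition_matrix(make_scored(rows))["n_transitions"].sum() == 2
    assert transition_matrix(make_scored(rows), max_gap_days=7)["n_transitions"].sum() == 1


@pytest.mark.parametrize(
    "total,group",
    [(65, "HIGH"), (52, "HIGH"), (51, "MEDIUM"), (26, "MEDIUM"), (25, "LOW"), (1, "LOW"), (0, None)],
)
def test_engagement_group_boundaries(total, group):
    assert engagement_group(total) == group


def _engagement_dataset():
    t0 = pd.Timestamp("2022-01-01")
    parts = pd.DataFrame(
        {"participant_id": ["A", "B"], "enrollment_date": [t0, t0 + pd.Timedelta(days=10)]}
    )
    sess_rows = []
    # A: sessions only in days 0-29 (month 1)
    for d in range(10):
        sess_rows.append({"participant_id": "A", "session_time": t0 + pd.Timedelta(days=d)})
    # B: 9 sessions in their month 3 (days 60-68 after THEIR enrollment)
    for d in range(60, 69):
        sess_rows.append(
            {"participant_id": "B", "session_time": t0 + pd.Timedelta(days=10 + d)}
        )
    sess = pd.DataFrame(sess_rows)
    sess.insert(0, "session_id", range(len(sess)))
    return StudyDataset(parts, sess, pd.DataFrame(columns=["participant_id", "act_date", "act_score"]))


def test_engagement_months_anchor_at_enrollment():
    per, groups = engagement_summary(_engagement_dataset())
    per = per.set_index("participant_id")
    assert per.loc["A", "sessions_month_1"] == 10
    assert not per.loc["A", "retained_any_m3"]
    assert per.loc["B", "sessions_month_3"] == 9
    assert per.loc["B", "retained_consistent_m3"]
    assert groups.loc["All", "n_participants"] == 2


def test_engagement_groups_partition_cohort(default_cohort):
    ds, _ = default_cohort
    per, groups = engagement_summary(ds)
    grouped = per["group"].value_counts().sum() + per["group"].isna().sum()
    assert grouped == len(ds.participants)
    assert groups.loc["All", "n_participants"] == len(ds.participants)


def test_engagement_counts_qc_failed_sessions(default_cohort, analyzed):
    """Engagement measures app use: totals count sessions QC later rejects."""
    ds, _ = default_cohort
    per, _ = engagement_summary(ds)
    assert per["total_sessions"].sum() == len(ds.sessions)
    assert per["total_sessions"].sum() > (analyzed.qc_outcomes["status"] == "SCORED").sum()


def test_descriptive_tables_symptom_free_sessions():
    t0 = pd.Timestamp("2022-01-01")
    rows = [
        ("A", t0, 60.0, "NORMAL", {"symptoms": "", "triggers": "", "severity_report": "none", "rescue_use": "none_today"})
        for _ in range(4)
    ]
    tables = descriptive_tables(make_scored(rows))
    sym = tables["symptom_by_state"]
    assert sym.loc["NORMAL", "mean_types_per_session"] == 0.0
    assert sym.loc["NORMAL", "coughing_n"] == 0


def test_descriptive_prevalence_arithmetic():
    t0 = pd.Timestamp("2022-01-01")
    extra = {"triggers": "", "severity_report": "mild", "rescue_use": "none_today"}
    rows = [("A", t0, 60.0, "NORMAL", {**extra, "symptoms": "coughing"})] * 5
    rows += [("A", t0, 60.0, "NORMAL", {**extra, "symptoms": ""})] * 15
    tables = descriptive_tables(make_scored(rows))
    assert tables["symptom_by_state"].loc["NORMAL", "coughing_pct"] == pytest.approx(25.0)


def test_symptom_prevalence_monotone_in_state(analyzed):
    """Generator injects state-graded rates; shortness of breath rises with severity."""
    sym = analyzed.descriptives["symptom_by_state"]
    sob = sym["shortness_of_breath_pct"]
    assert sob["NORMAL"] < sob["MILD"] < sob["EXACERBATION"]
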