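"""Risk-ratio engine, ACT linkage and stratified analysis."""

import numpy as np
import pandas as pd
import pytest

from vbmon.labeling import AnalysisConfig
from vbmon.risk import (
    TwoByTwo,
    ZeroCellError,
    act_linkage,
    act_risk_tables,
    risk_ratio,
    state_risk_tables,
    stratified_risk,
)

from conftest import make_scored


def test_equal_prevalences_give_unit_rr_with_log_symmetric_ci():
    res = risk_ratio(TwoByTwo(10, 90, 10, 90))
    assert res.rr == pytest.approx(1.0)
    assert res.ci_low < 1.0 < res.ci_high
    assert np.log(res.ci_high) == pytest.approx(-np.log(res.ci_low))


def test_rr_invariant_to_cell_scaling_ci_narrows():
    base = risk_ratio(TwoByTwo(12, 40, 7, 45))
    scaled = risk_ratio(TwoByTwo(120, 400, 70, 450))
    assert scaled.rr == pytest.approx(base.rr)
    assert (scaled.ci_high - scaled.ci_low) < (base.ci_high - base.ci_low)


def test_band_swap_gives_reciprocal_rr():
    res = risk_ratio(TwoByTwo(167, 704, 57, 581))
    swapped = risk_ratio(TwoByTwo(57, 581, 167, 704))
    assert swapped.rr == pytest.approx(1.0 / res.rr)
    assert swapped.ci_low == pytest.approx(1.0 / res.ci_high)
    assert swapped.ci_high == pytest.approx(1.0 / res.ci_low)


def test_zero_event_cell_errors_unless_continuity():
    with pytest.raises(ZeroCellError):
        risk_ratio(TwoByTwo(0, 50, 5, 45))
    res = risk_ratio(TwoByTwo(0, 50, 5, 45), continuity=True)
    assert res.rr > 0


def test_negative_cells_rejected():
    with pytest.raises(ValueError):
        TwoByTwo(-1, 5, 5, 5)


def test_rr_matches_brute_force_prevalence_on_small_tables():
    """Spot-grid of small tables against the direct prevalence formula."""
    for a in (1, 3, 9):
        for b in (0, 4, 15):
            for c in (1, 5, 20):
                for d in (0, 6, 18):
                    if b == 0 and d == 0:
                        continue
                    res = risk_ratio(TwoByTwo(a, b, c, d))
                    brute = (a / (a + b)) / (c / (c + d))
                    assert res.rr == pytest.approx(brute, rel=1e-12)


def _state_sessions():
    """Sessions engineered to the printed raw-score analysis-cohort cells."""
    rows = []
    t0 = pd.Timestamp("2022-06-01")
    cells = [
        ("EXACERBATION", 70.0, 167),
        ("EXACERBATION", 60.0, 57),
        ("MILD", 70.0, 390),
        ("MILD", 60.0, 194),
        ("NORMAL", 70.0, 704),
        ("NORMAL", 60.0, 581),
    ]
    for state, score, n in cells:
        rows.extend(("P", t0, score, state) for _ in range(n))
    return make_scored(rows)


def test_state_tables_reproduce_engineered_cells():
    res = state_risk_tables(_state_sessions(), AnalysisConfig())
    assert res["EXACERBATION"].rr == pytest.approx(2.15, abs=0.005)
    assert res["MILD"].rr == pytest.approx(1.42, abs=0.005)
    # the non-compared state is excluded from each table
    assert res["EXACERBATION"].table.n_high + res["EXACERBATION"].table.n_low == 167 + 57 + 704 + 581


def test_state_tables_all_normal_is_error_path():
    rows = [("P", pd.Timestamp("2022-06-01"), 70.0, "NORMAL")] * 10
    with pytest.raises(ZeroCellError):
        state_risk_tables(make_scored(rows), AnalysisConfig())


def test_normalized_analysis_requires_threshold():
    with pytest.raises(ValueError, match="normalized_threshold"):
        state_risk_tables(_state_sessions(), AnalysisConfig(), use_normalized=True)


def _acts_and_sessions():
    t0 = pd.Timestamp("2022-03-01")
    acts = pd.DataFrame(
        {
            "participant_id": ["A", "A", "B"],
            "act_date": [t0, t0 + pd.Timedelta(days=30), t0],
            "act_score": [14, 22, 17],
        }
    )
    scored = make_scored(
        [
            ("A", t0 - pd.Timedelta(days=14), 70.0, "NORMAL"),  # boundary: included
            ("A", t0 - pd.Timedelta(days=15), 10.0, "NORMAL"),  # outside window
            ("A", t0 + pd.Timedelta(days=14), 80.0, "NORMAL"),  # boundary: included
        ]
    )
    return acts, scored


def test_act_window_is_inclusive_and_averages():
    acts, scored = _acts_and_sessions()
    link = act_linkage(acts, scored, AnalysisConfig())
    first = link.iloc[0]
    assert first["n_window_scores"] == 2  # both 14-day boundary sessions, not the 15-day one
    assert first["time_averaged_score"] == pytest.approx(75.0)
    assert first["band"] == "HIGH"
    assert first["control_level"] == "POOR"


def test_act_empty_window_marked_ineligible():
    acts, scored = _acts_and_sessions()
    link = act_linkage(acts, scored, AnalysisConfig())
    # B has no sessions at all; A's second ACT is 30 days from every session
    assert not link.iloc[2]["eligible"]
    by_count = link["eligible"].sum()
    assert by_count == 1


def test_act_contrast_all_well_is_undefined():
    link = pd.DataFrame(
        {"control_level": ["WELL"] * 4, "band": ["HIGH", "LOW"] * 2, "eligible": True}
    )
    with pytest.raises(ZeroCellError):
        act_risk_tables(link)


def test_act_tables_from_engineered_assessments():
    rows = []
    for level, band, n in [
        ("POOR", "HIGH", 61),
        ("POOR", "LOW", 50),
        ("WELL", "HIGH", 18),
        ("WELL", "LOW", 26),
        ("NOT_WELL", "HIGH", 22),
        ("NOT_WELL", "LOW", 24),
    ]:
        rows.extend({"control_level": level, "band": band, "eligible": True} for _ in range(n))
    res = act_risk_tables(pd.DataFrame(rows))
    assert res["POOR"].rr == pytest.approx(1.17, abs=0.005)
    assert res["NOT_WELL"].rr == pytest.approx(1.15, abs=0.005)


def test_stratified_single_stratum_reduces_to_pooled():
    scored = _state_sessions()
    strata = pd.Series({"P": "all"})
    results, overlaps = stratified_risk(scored, AnalysisConfig(), strata)
    pooled = state_risk_tables(scored, AnalysisConfig())["EXACERBATION"]
    assert len(results) == 1 and overlaps.empty
    assert results[0].raw.rr == pytest.approx(pooled.rr)


def test_stratified_zero_event_stratum_flagged_not_raised():
    t0 = pd.Timestamp("2022-06-01")
    rows = [("A", t0, 70.0, "EXACERBATION"), ("A", t0, 60.0, "EXACERBATION")]
    rows += [("A", t0, 70.0, "NORMAL"), ("A", t0, 60.0, "NORMAL")] * 3
    rows += [("B", t0, 70.0, "NORMAL"), ("B", t0, 60.0, "NORMAL")] * 3  # no events
    scored = make_scored(rows)
    strata = pd.Series({"A": "s1", "B": "s2"})
    results, overlaps = stratified_risk(scored, AnalysisConfig(), strata)
    by_name = {r.stratum: r for r in results}
    assert by_name["s1"].raw is not None
    assert by_name["s2"].raw is None and "zero event" in by_name["s2"].undefined_reason


def test_stratified_equal_effects_usually_overlap(analyzed, default_cohort):
    ds, _ = default_cohort
    scored = analyzed.scored
    pids = sorted(scored["participant_id"].unique())
    half = len(pids) // 2
    strata = pd.Series(
        {pid: ("first" if i < half else "second") for i, pid in enumerate(pids)}
    )
    _, overlaps = stratified_risk(scored, AnalysisConfig(), strata)
    assert overlaps["overlap"].all()
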