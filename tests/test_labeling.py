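"""State classification, normalization and threshold derivation."""

import numpy as np
import pandas as pd
import pytest

from vbmon.labeling import (
    InsufficientDataError,
    classify_state,
    crosstab_zone_wellbeing,
    derive_normalized_threshold,
    normalize_scores,
    reference_scores,
    risk_band,
    state_counts_from_crosstab,
)

from conftest import make_scored

GRID = {
    ("GREEN", "GOOD"): "NORMAL",
    ("GREEN", "NOT_GOOD"): "MILD",
    ("GREEN", "BAD"): "MILD",
    ("YELLOW", "GOOD"): "MILD",
    ("YELLOW", "NOT_GOOD"): "EXACERBATION",
    ("YELLOW", "BAD"): "EXACERBATION",
    ("RED", "GOOD"): "MILD",
    ("RED", "NOT_GOOD"): "EXACERBATION",
    ("RED", "BAD"): "EXACERBATION",
}


@pytest.mark.parametrize("zone,wellbeing", list(GRID))
def test_classify_state_total_grid(zone, wellbeing):
    """Both criteria -> exacerbation, neither -> normal, one -> mild."""
    assert classify_state(zone, wellbeing) == GRID[(zone, wellbeing)]


def test_classify_state_rejects_unknown_levels():
    with pytest.raises(ValueError):
        classify_state("BLUE", "GOOD")
    with pytest.raises(ValueError):
        classify_state("GREEN", "FINE")


def _normal_scored(pid, scores):
    t0 = pd.Timestamp("2022-01-01")
    return make_scored(
        [(pid, t0 + pd.Timedelta(days=i), s, "NORMAL") for i, s in enumerate(scores)]
    )


def test_reference_is_median_of_normal_sessions():
    scored = _normal_scored("A", [60, 62, 64, 66, 68])
    norms = reference_scores(scored)
    assert norms.loc[0, "reference_score"] == 64.0
    assert norms.loc[0, "n_normal_sessions"] == 5


def test_reference_even_count_uses_midpoint():
    scored = _normal_scored("A", [60, 62, 64, 66, 68, 70])
    assert reference_scores(scored).loc[0, "reference_score"] == 65.0


def test_participant_below_cohort_floor_omitted():
    scored = _normal_scored("A", [60, 62, 64, 66])
    assert reference_scores(scored).empty


def test_mild_sessions_do_not_feed_reference():
    t0 = pd.Timestamp("2022-01-01")
    rows = [("A", t0 + pd.Timedelta(days=i), 60.0 + i, "NORMAL") for i in range(5)]
    rows += [("A", t0 + pd.Timedelta(days=9), 99.0, "MILD")]
    norms = reference_scores(make_scored(rows))
    assert norms.loc[0, "reference_score"] == 62.0


def test_normalize_scores_arithmetic():
    scored = _normal_scored("A", [60, 61, 62, 63, 64])
    scored.loc[5] = scored.loc[4]
    scored.loc[5, ["session_id", "final_score", "state"]] = [5, 68.0, "MILD"]
    norms = reference_scores(scored)
    out = normalize_scores(scored, norms)
    assert out.loc[5, "normalized_score"] == pytest.approx(68.0 - 62.0)
    # a session at the reference normalizes to zero
    assert out.loc[2, "normalized_score"] == pytest.approx(0.0)


def test_normalization_idempotent_with_zero_reference():
    scored = _normal_scored("A", [0, 1, -1, 2, -2])
    norms = reference_scores(scored)
    assert norms.loc[0, "reference_score"] == 0.0
    out = normalize_scores(scored, norms)
    assert np.allclose(out["normalized_score"], out["final_score"])


def test_threshold_degenerate_constant_scores():
    scored = pd.concat(
        [_normal_scored(pid, [60.0] * 6) for pid in ("A", "B", "C")], ignore_index=True
    )
    assert derive_normalized_threshold(reference_scores(scored)) == 0.0


def test_threshold_matches_percentile_oracle():
    scores = [50.0, 55.0, 60.0, 65.0, 70.0]
    norms = reference_scores(_normal_scored("A", scores))
    p50, p70 = np.percentile(scores, [50, 70])
    assert norms.loc[0, "p70_minus_p50"] == pytest.approx(p70 - p50)
    assert derive_normalized_threshold(norms) == pytest.approx(p70 - p50)


def test_threshold_empty_input_raises():
    with pytest.raises(InsufficientDataError):
        derive_normalized_threshold(pd.DataFrame(columns=["p70_minus_p50"]))


def test_pooled_percentile_threshold_variant():
    scored = _normal_scored("A", [60, 61, 62, 63, 64, 70])
    norms = reference_scores(scored)
    scored = normalize_scores(scored, norms)
    t = derive_normalized_threshold(norms, scored, method="pooled_p70")
    expected = np.percentile(scored["normalized_score"], 70)
    assert t == pytest.approx(expected)


@pytest.mark.parametrize(
    "score,threshold,band",
    [(65.0, 65.0, "HIGH"), (64.99, 65.0, "LOW"), (3.7, 3.7, "HIGH"), (3.69, 3.7, "LOW")],
)
def test_risk_band_threshold_is_high(score, threshold, band):
    assert risk_band(score, threshold) == band


def test_crosstab_margins_partition_sessions():
    rows = []
    t0 = pd.Timestamp("2022-01-01")
    combos = [("GREEN", "GOOD", 5), ("YELLOW", "NOT_GOOD", 3), ("RED", "BAD", 2), ("GREEN", "BAD", 1)]
    for zone, wb, n in combos:
        for i in range(n):
            rows.append(
                ("P", t0, 60.0, classify_state(zone, wb), {"zone": zone, "wellbeing": wb})
            )
    scored = make_scored(rows)
    tab = crosstab_zone_wellbeing(scored)
    assert tab.at["Total", "Total"] == 11
    assert tab.at["GREEN", "GOOD"] == 5
    assert tab.at["GREEN", "Total"] == 6
    assert tab.at["Total", "GOOD"] == 5
    # cell-wise state counts agree with the per-session labels
    counts = state_counts_from_crosstab(tab)
    assert counts == scored["state"].value_counts().to_dict()


def test_crosstab_empty_input_all_zero():
    tab = crosstab_zone_wellbeing(make_scored([]).assign(zone=None, wellbeing=None).iloc[:0])
    assert tab.at["Total", "Total"] == 0


def test_labels_never_consult_the_score(analyzed):
    """States depend only on zone and well-being, not the biomarker value."""
    scored = analyzed.scored
    recomputed = [
        classify_state(z, w) for z, w in zip(scored["zone"], scored["wellbeing"])
    ]
    assert list(scored["state"]) == recomputed


def test_reference_recovers_latent_baseline(default_cohort, analyzed):
    """Median NORMAL-session score tracks the participant's latent baseline."""
    _, truth = default_cohort
    norms = analyzed.norms.set_index("participant_id")
    well = norms[norms["n_normal_sessions"] >= 20].index
    latent = truth.participants.set_index("participant_id")["baseline_score"]
    err = (norms.loc[well, "reference_score"] - latent[well]).abs().median()
    assert err < 1.5
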