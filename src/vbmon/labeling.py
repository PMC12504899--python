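"""Respiratory-state labeling, per-participant normalization, thresholds.

A session's respiratory state combines two criteria that never consult the
biomarker itself (avoiding circularity):

* objective — relative PEF below 80% of personal best (yellow or red zone);
* subjective — well-being reported as not good or bad.

EXACERBATION requires both criteria, NORMAL neither, MILD exactly one.

Each participant with at least five NORMAL-labeled scored sessions (the
"normalized cohort") receives a reference RRVB score: the median final score
over their NORMAL sessions, spanning the whole study (no baseline period).
Normalized score = final score minus the participant's reference. The
high-risk threshold on the normalized scale is derived from the cohort as
the mean over participants of (70th - 50th percentile) of their
NORMAL-session scores; an alternative single-percentile formulation (the
70th percentile of pooled normalized NORMAL-session scores) is available via
``threshold_method``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from vbmon.data_model import STATES, WELLBEING_LEVELS, ZONES


class InsufficientDataError(ValueError):
    pass


@dataclass
class AnalysisConfig:
    """Analysis-stage knobs.

    raw_threshold : high-risk cut on raw RRVB scores (high = score >= 65,
        the screening benchmark of the upstream biomarker model).
    normalized_threshold : high-risk cut on normalized scores; ``None`` means
        derive it from the data via :func:`derive_normalized_threshold`.
    consistency_threshold : two-sample agreement tolerance in score points.
    act_window_days : half-width of the window linking sessions to an ACT
        date (14 days each side, a 4-week window centered on the ACT).
    threshold_method : ``"p70_minus_p50"`` (default) or ``"pooled_p70"``.
    """

    raw_threshold: float = 65.0
    normalized_threshold: float | None = None
    consistency_threshold: float = 10.0
    act_window_days: int = 14
    threshold_method: str = "p70_minus_p50"

    def __post_init__(self) -> None:
        if not (0.0 < self.raw_threshold < 100.0):
            raise ValueError("raw_threshold must lie in (0, 100)")
        if self.threshold_method not in ("p70_minus_p50", "pooled_p70"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")


def classify_state(zone: str, wellbeing: str) -> str:
    """Map (PEF zone, well-being) to a respiratory state.

    Total over the 3x3 grid: both criteria -> EXACERBATION, neither ->
    NORMAL, exactly one -> MILD.
    """
    if zone not in ZONES:
        raise ValueError(f"unknown zone {zone!r}")
    if wellbeing not in WELLBEING_LEVELS:
        raise ValueError(f"unknown wellbeing {wellbeing!r}")
    pef_reduced = zone in ("YELLOW", "RED")
    feels_bad = wellbeing in ("NOT_GOOD", "BAD")
    if pef_reduced and feels_bad:
        return "EXACERBATION"
    if not pef_reduced and not feels_bad:
        return "NORMAL"
    return "MILD"


def label_sessions(
    sessions: pd.DataFrame, qc_outcomes: pd.DataFrame, relative: pd.DataFrame
) -> pd.DataFrame:
    """Join QC-scored sessions with relative PEF and assign states.

    Only sessions that are SCORED and have a non-excluded relative PEF get a
    row; others carry no state label. Symptom/trigger/severity/rescue report
    columns are carried through for descriptive tables.
    """
    scored = qc_outcomes[qc_outcomes["status"] == "SCORED"][["session_id", "final_score"]]
    rel = relative.dropna(subset=["zone"])[["session_id", "relative_pct", "zone"]]
    carry = [
        c
        for c in ("wellbeing", "symptoms", "triggers", "severity_report", "rescue_use")
        if c in sessions.columns
    ]
    base = sessions[["session_id", "participant_id", "session_time", *carry]]
    df = base.merge(scored, on="session_id").merge(rel, on="session_id")
    pef_reduced = df["zone"].isin(["YELLOW", "RED"])
    feels_bad = df["wellbeing"].isin(["NOT_GOOD", "BAD"])
    df["state"] = np.select(
        [pef_reduced & feels_bad, ~pef_reduced & ~feels_bad], ["EXACERBATION", "NORMAL"], "MILD"
    )
    df["normalized_score"] = np.nan
    return df.sort_values(["participant_id", "session_time", "session_id"], kind="stable").reset_index(
        drop=True
    )


def reference_scores(scored: pd.DataFrame, min_normal_sessions: int = 5) -> pd.DataFrame:
    """Per-participant reference (median NORMAL-session score) and spread.

    Participants with fewer than ``min_normal_sessions`` NORMAL sessions are
    omitted (the normalized-cohort floor). ``p70_minus_p50`` is the 70th
    minus 50th percentile of the participant's NORMAL-session final scores
    (linear interpolation), the per-participant ingredient of the normalized
    high-risk threshold.
    """
    rows = []
    normal = scored[scored["state"] == "NORMAL"]
    for pid, sub in normal.groupby("participant_id", sort=True):
        vals = sub["final_score"].to_numpy(dtype=float)
        if vals.size < min_normal_sessions:
            continue
        p50, p70 = np.percentile(vals, [50.0, 70.0])
        rows.append(
            {
                "participant_id": pid,
                "reference_score": float(p50),
                "n_normal_sessions": int(vals.size),
                "p70_minus_p50": float(p70 - p50),
            }
        )
    return pd.DataFrame(
        rows, columns=["participant_id", "reference_score", "n_normal_sessions", "p70_minus_p50"]
    )


def normalize_scores(scored: pd.DataFrame, norms: pd.DataFrame) -> pd.DataFrame:
    """Attach ``normalized_score`` = final score minus participant reference.

    Sessions of participants outside the normalized cohort keep NaN.
    """
    out = scored.copy()
    ref = norms.set_index("participant_id")["reference_score"]
    out["normalized_score"] = out["final_score"] - out["participant_id"].map(ref)
    return out


def derive_normalized_threshold(
    norms: pd.DataFrame,
    scored: pd.DataFrame | None = None,
    method: str = "p70_minus_p50",
) -> float:
    """High-risk threshold on the normalized-score scale.

    ``p70_minus_p50`` (default): mean over normalized-cohort participants of
    the 70th-minus-50th percentile gap of their NORMAL-session scores.
    ``pooled_p70``: 70th percentile of pooled normalized NORMAL-session
    scores (requires ``scored`` with ``normalized_score``).
    """
    if method == "p70_minus_p50":
        if norms.empty:
            raise InsufficientDataError("no normalized-cohort participants")
        return float(norms["p70_minus_p50"].mean())
    if method == "pooled_p70":
        if scored is None:
            raise ValueError("pooled_p70 requires the scored-session frame")
        vals = scored.loc[scored["state"] == "NORMAL", "normalized_score"].dropna()
        if vals.empty:
            raise InsufficientDataError("no normalized NORMAL-session scores")
        return float(np.percentile(vals.to_numpy(), 70.0))
    raise ValueError(f"unknown method {method!r}")


def risk_band(score, threshold: float):
    """HIGH iff score >= threshold (the cut itself is high-risk), else LOW.

    Accepts a scalar or an array/Series; returns the same shape.
    """
    arr = np.asarray(score, dtype=float)
    out = np.where(arr >= threshold, "HIGH", "LOW")
    if np.ndim(score) == 0:
        return str(out[()])
    return out


def crosstab_zone_wellbeing(scored: pd.DataFrame) -> pd.DataFrame:
    """Zone x well-being session counts with margins and percent of total.

    Rows are zones (plus Total), columns well-being levels (plus Total);
    each cell holds the count, with companion ``pct`` columns giving percent
    of the grand total (0 when the table is empty).
    """
    counts = pd.DataFrame(0, index=list(ZONES) + ["Total"], columns=list(WELLBEING_LEVELS) + ["Total"])
    if len(scored):
        ct = pd.crosstab(scored["zone"], scored["wellbeing"])
        for z in ZONES:
            for w in WELLBEING_LEVELS:
                counts.loc[z, w] = int(ct.at[z, w]) if (z in ct.index and w in ct.columns) else 0
    counts.loc["Total"] = counts.loc[list(ZONES)].sum(axis=0)
    counts["Total"] = counts[list(WELLBEING_LEVELS)].sum(axis=1)
    grand = counts.at["Total", "Total"]
    pct = counts / grand * 100.0 if grand else counts * 0.0
    out = counts.astype(int).copy()
    for col in pct.columns:
        out[f"{col}_pct"] = pct[col].round(2)
    return out


def state_counts_from_crosstab(crosstab: pd.DataFrame) -> dict[str, int]:
    """Apply the state definition cell-wise to a zone x well-being table."""
    totals = {s: 0 for s in STATES}
    for z in ZONES:
        for w in WELLBEING_LEVELS:
            totals[classify_state(z, w)] += int(crosstab.at[z, w])
    return totals
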