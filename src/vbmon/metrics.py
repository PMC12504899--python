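"""Longitudinal metrics: change-score transitions, engagement, descriptives.

Transition analysis pairs consecutive QC-scored sessions of the same
participant (no maximum calendar gap by default; unscored sessions are
bridged over) and summarizes the score change per (earlier state, later
state) cell with mean and SE.

Engagement counts completed sessions whether or not QC passed — it measures
app use. Months are consecutive 30-day blocks anchored at each participant's
enrollment date; groups bucket total sessions as high (>=52), medium
(26-51), low (1-25). Month-3 retention is reported as minimum use (>=1
session) and consistent use (>=8 sessions).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from vbmon.data_model import RESCUE_LEVELS, SEVERITY_LEVELS, STATES, SYMPTOM_VOCAB, TRIGGER_VOCAB, StudyDataset


def transition_matrix(scored: pd.DataFrame, max_gap_days: float | None = None) -> pd.DataFrame:
    """Score-change summary per state-transition cell.

    Returns a frame indexed by (from_state, to_state) with ``mean_change``,
    ``se_change`` (sample SD / sqrt(n); NaN when n = 1) and
    ``n_transitions``. ``max_gap_days`` optionally drops pairs further apart
    in time (sensitivity analysis; default keeps every consecutive pair).
    """
    rows = []
    for _, sub in scored.groupby("participant_id", sort=True):
        sub = sub.sort_values(["session_time", "session_id"], kind="stable")
        if len(sub) < 2:
            continue
        scores = sub["final_score"].to_numpy(dtype=float)
        states = sub["state"].to_numpy()
        times = sub["session_time"].to_numpy()
        gaps = (times[1:] - times[:-1]) / np.timedelta64(1, "D")
        keep = np.ones(len(gaps), dtype=bool)
        if max_gap_days is not None:
            keep = gaps <= max_gap_days
        for i in np.flatnonzero(keep):
            rows.append((states[i], states[i + 1], scores[i + 1] - scores[i]))
    pairs = pd.DataFrame(rows, columns=["from_state", "to_state", "change"])
    index = pd.MultiIndex.from_product([STATES, STATES], names=["from_state", "to_state"])
    out = pd.DataFrame(index=index, columns=["mean_change", "se_change", "n_transitions"], dtype=float)
    grouped = pairs.groupby(["from_state", "to_state"])["change"]
    agg = grouped.agg(["mean", "std", "count"])
    for key, row in agg.iterrows():
        out.loc[key, "mean_change"] = row["mean"]
        out.loc[key, "se_change"] = row["std"] / np.sqrt(row["count"]) if row["count"] > 1 else np.nan
        out.loc[key, "n_transitions"] = row["count"]
    out["n_transitions"] = out["n_transitions"].fillna(0).astype(int)
    return out


ENGAGEMENT_GROUPS = ("HIGH", "MEDIUM", "LOW")


def engagement_group(total_sessions: int) -> str | None:
    """Bucket a participant by total completed sessions; None when zero."""
    if total_sessions >= 52:
        return "HIGH"
    if total_sessions >= 26:
        return "MEDIUM"
    if total_sessions >= 1:
        return "LOW"
    return None


def engagement_summary(
    ds: StudyDataset, n_months: int = 3, consistent_min: int = 8
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-participant engagement plus group aggregates.

    Returns ``(per_participant, by_group)``. ``by_group`` includes an "All"
    row and reports mean (SD) sessions per 30-day month and month-``n_months``
    retention fractions. Participants with zero sessions stay in
    ``per_participant`` with ``group`` None and are excluded from group rows
    but counted in "All".
    """
    enroll = ds.participants.set_index("participant_id")["enrollment_date"]
    sess = ds.sessions.copy()
    sess["day"] = (
        sess["session_time"].dt.normalize() - sess["participant_id"].map(enroll)
    ).dt.days
    sess["month"] = sess["day"] // 30 + 1

    rows = []
    for pid in ds.participants["participant_id"]:
        sub = sess[sess["participant_id"] == pid]
        monthly = [int((sub["month"] == m).sum()) for m in range(1, n_months + 1)]
        total = int(len(sub))
        last = monthly[-1]
        rows.append(
            {
                "participant_id": pid,
                "total_sessions": total,
                "group": engagement_group(total),
                **{f"sessions_month_{m}": monthly[m - 1] for m in range(1, n_months + 1)},
                "retained_any_m3": last >= 1,
                "retained_consistent_m3": last >= consistent_min,
            }
        )
    per = pd.DataFrame(rows)

    def _agg(frame: pd.DataFrame, label: str) -> dict:
        row = {"group": label, "n_participants": int(len(frame))}
        for m in range(1, n_months + 1):
            col = frame[f"sessions_month_{m}"]
            row[f"month_{m}_mean"] = float(col.mean()) if len(frame) else np.nan
            row[f"month_{m}_sd"] = float(col.std(ddof=1)) if len(frame) > 1 else np.nan
        row["total_mean"] = float(frame["total_sessions"].mean()) if len(frame) else np.nan
        row["total_sd"] = float(frame["total_sessions"].std(ddof=1)) if len(frame) > 1 else np.nan
        row["retained_any_m3_frac"] = float(frame["retained_any_m3"].mean()) if len(frame) else np.nan
        row["retained_consistent_m3_frac"] = (
            float(frame["retained_consistent_m3"].mean()) if len(frame) else np.nan
        )
        return row

    group_rows = [_agg(per, "All")]
    for g in ENGAGEMENT_GROUPS:
        group_rows.append(_agg(per[per["group"] == g], g))
    return per, pd.DataFrame(group_rows).set_index("group")


def _token_indicator(series: pd.Series, vocab: tuple[str, ...]) -> pd.DataFrame:
    tokens = series.fillna("").astype(str).str.split(";")
    return pd.DataFrame(
        {tok: tokens.map(lambda ts, t=tok: t in ts) for tok in vocab}, index=series.index
    )


def descriptive_tables(scored: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Contingency summaries of the patient-reported fields by state.

    Returns four frames:

    * ``symptom_count_by_severity`` — sessions cross-tabbed by number of
      symptom types reported and self-rated severity.
    * ``symptom_by_state`` — per-state prevalence (count and percent of
      state sessions) of each symptom type, plus mean types per session.
    * ``trigger_by_state`` — likewise for triggers.
    * ``rescue_by_state`` — rescue-inhaler use pattern by state.
    """
    sym = _token_indicator(scored["symptoms"], SYMPTOM_VOCAB)
    trg = _token_indicator(scored["triggers"], TRIGGER_VOCAB)
    n_sym = sym.sum(axis=1)

    count_by_sev = pd.crosstab(n_sym.rename("n_symptoms"), scored["severity_report"])
    count_by_sev = count_by_sev.reindex(columns=list(SEVERITY_LEVELS), fill_value=0)

    def _by_state(ind: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for state in STATES:
            mask = (scored["state"] == state).to_numpy()
            n = int(mask.sum())
            row = {"state": state, "n_sessions": n}
            for tok in ind.columns:
                c = int(ind.loc[mask, tok].sum())
                row[f"{tok}_n"] = c
                row[f"{tok}_pct"] = 100.0 * c / n if n else 0.0
            row["mean_types_per_session"] = float(ind.loc[mask].sum(axis=1).mean()) if n else 0.0
            rows.append(row)
        return pd.DataFrame(rows).set_index("state")

    rescue = pd.crosstab(scored["rescue_use"], scored["state"])
    rescue = rescue.reindex(index=list(RESCUE_LEVELS), columns=list(STATES), fill_value=0)
    rescue["total"] = rescue.sum(axis=1)
    for state in STATES:
        rescue[f"{state}_pct"] = np.where(
            rescue["total"] > 0, 100.0 * rescue[state] / rescue["total"].replace(0, 1), 0.0
        )

    return {
        "symptom_count_by_severity": count_by_sev,
        "symptom_by_state": _by_state(sym),
        "trigger_by_state": _by_state(trg),
        "rescue_by_state": rescue,
    }
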