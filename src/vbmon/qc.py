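"""Session quality control: elicitation bookkeeping and two-sample scoring.

Each app session records two voice samples. A real-time elicitation check
(acoustic criteria external to this package; only pass/fail flags are
consumed) gates each sample with up to three recording attempts. Sessions
with two elicitation-passing samples then go through two-sample scoring:
the two RRVB scores are accepted only if they agree within a consistency
threshold (default 10 points) and are averaged into one final score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

QC_STATUSES = ("SCORED", "FAIL_ELICITATION", "FAIL_CONSISTENCY")


class ScoreDomainError(ValueError):
    """A raw score lies outside the RRVB range [0, 100]."""


def apply_two_sample_scoring(s1: float, s2: float, threshold: float = 10.0) -> float | None:
    """Average two same-session scores if they agree within ``threshold``.

    Agreement is inclusive (|s1 - s2| <= threshold). Returns the mean when
    consistent, ``None`` when the pair is rejected as implausible.
    """
    for s in (s1, s2):
        if not (0.0 <= s <= 100.0):
            raise ScoreDomainError(f"score {s} outside [0, 100]")
    if abs(s1 - s2) <= threshold:
        return (s1 + s2) / 2.0
    return None


def qc_pipeline(sessions: pd.DataFrame, consistency_threshold: float = 10.0) -> pd.DataFrame:
    """Apply both quality gates, producing one outcome row per session.

    A session lacking two elicitation-passing samples (or missing either raw
    score) is FAIL_ELICITATION; a dual-pass session whose scores disagree
    beyond the threshold is FAIL_CONSISTENCY; otherwise SCORED with
    ``final_score`` = mean of the two raw scores.
    """
    s1 = sessions["raw_score_1"].to_numpy(dtype=float)
    s2 = sessions["raw_score_2"].to_numpy(dtype=float)
    p1 = sessions["elicitation_pass_1"].to_numpy(dtype=bool)
    p2 = sessions["elicitation_pass_2"].to_numpy(dtype=bool)
    present = ~np.isnan(s1) & ~np.isnan(s2)
    valid = ((s1 >= 0) & (s1 <= 100) & (s2 >= 0) & (s2 <= 100)) | ~present
    if not valid.all():
        bad = sessions.loc[~valid, "session_id"].tolist()
        raise ScoreDomainError(f"scores outside [0, 100] in session(s) {bad}")

    dual_pass = p1 & p2 & present
    consistent = np.abs(s1 - s2) <= consistency_threshold
    status = np.where(
        ~dual_pass, "FAIL_ELICITATION", np.where(consistent, "SCORED", "FAIL_CONSISTENCY")
    )
    final = np.where(dual_pass & consistent, (s1 + s2) / 2.0, np.nan)
    return pd.DataFrame(
        {
            "session_id": sessions["session_id"].to_numpy(),
            "participant_id": sessions["participant_id"].to_numpy(),
            "status": status,
            "final_score": final,
        }
    )


@dataclass
class QCStateBalance:
    """Per-state QC exclusion fractions with a chi-square homogeneity test."""

    table: pd.DataFrame  # index: state; columns: n_sessions, frac_fail_elicitation, frac_fail_consistency, frac_excluded
    chi2: float
    p_value: float
    dof: int


def qc_state_balance(outcomes: pd.DataFrame, labels: pd.Series) -> QCStateBalance:
    """Check whether QC exclusion is homogeneous across respiratory states.

    ``labels`` maps ``session_id`` to a state for every session whose PEF and
    well-being allow labeling regardless of QC outcome (the latent/pre-QC
    label). Returns per-state exclusion fractions by gate and a chi-square
    homogeneity statistic over the state x {scored, excluded} table. With a
    degenerate table (a single state, or no exclusions anywhere) the
    statistic is 0 and the p-value 1.
    """
    df = outcomes.copy()
    df["state"] = df["session_id"].map(labels)
    df = df.dropna(subset=["state"])
    rows = []
    for state in ("NORMAL", "MILD", "EXACERBATION"):
        sub = df[df["state"] == state]
        n = len(sub)
        if n == 0:
            continue
        fe = float((sub["status"] == "FAIL_ELICITATION").mean())
        fc = float((sub["status"] == "FAIL_CONSISTENCY").mean())
        rows.append(
            {
                "state": state,
                "n_sessions": n,
                "frac_fail_elicitation": fe,
                "frac_fail_consistency": fc,
                "frac_excluded": fe + fc,
            }
        )
    table = pd.DataFrame(rows).set_index("state") if rows else pd.DataFrame(
        columns=[
            "n_sessions",
            "frac_fail_elicitation",
            "frac_fail_consistency",
            "frac_excluded",
        ]
    )
    if len(table) >= 2:
        excluded = (table["frac_excluded"] * table["n_sessions"]).round().astype(int)
        kept = table["n_sessions"] - excluded
        contingency = np.column_stack([kept.to_numpy(), excluded.to_numpy()])
        if (contingency.sum(axis=0) > 0).all():
            chi2, p, dof, _ = stats.chi2_contingency(contingency)
        else:
            chi2, p, dof = 0.0, 1.0, 0
    else:
        chi2, p, dof = 0.0, 1.0, 0
    return QCStateBalance(table=table, chi2=float(chi2), p_value=float(p), dof=int(dof))


def qc_funnel_summary(sessions: pd.DataFrame, outcomes: pd.DataFrame) -> dict:
    """Attempt- and session-level QC funnel counts for reporting."""
    att1 = sessions["elicitation_attempts_1"]
    att2 = sessions["elicitation_attempts_2"]
    attempts = pd.concat([att1, att2]).dropna().astype(int)
    passes = pd.concat([sessions["elicitation_pass_1"], sessions["elicitation_pass_2"]])
    n_samples = int(attempts.size)
    counts = outcomes["status"].value_counts()
    return {
        "n_sessions": int(len(sessions)),
        "n_samples": n_samples,
        "samples_needing_retry": int((attempts > 1).sum()),
        "samples_needing_third": int((attempts > 2).sum()),
        "samples_failed_all": int((~passes.astype(bool)).sum()),
        "sessions_scored": int(counts.get("SCORED", 0)),
        "sessions_fail_elicitation": int(counts.get("FAIL_ELICITATION", 0)),
        "sessions_fail_consistency": int(counts.get("FAIL_CONSISTENCY", 0)),
        "scored_fraction": float(counts.get("SCORED", 0) / max(len(sessions), 1)),
    }
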