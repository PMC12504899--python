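"""Prevalence risk ratios with Katz log-scale confidence intervals.

The primary end point compares event prevalence between the high and low
biomarker bands. For an event state E versus the reference state NORMAL
(the third state excluded from the table entirely), with a sessions in the
high band labeled E, b labeled NORMAL, and c, d likewise in the low band:

    RR = (a / (a + b)) / (c / (c + d))

The confidence interval is the Katz log method:

    SE(ln RR) = sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d))
    CI        = exp(ln RR +/- z_{1-alpha/2} * SE)

with a two-sided p-value from the normal tail of ln(RR)/SE. The unit of
analysis is the session (for ACT contrasts, the assessment), pooled across
participants without clustering adjustment; an optional participant-level
bootstrap CI is provided as an extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from vbmon.labeling import AnalysisConfig, risk_band


class ZeroCellError(ValueError):
    """An event cell is zero; pass continuity=True to add 0.5 to all cells."""


@lru_cache(maxsize=8)
def _z_crit(alpha: float) -> float:
    return float(stats.norm.ppf(1.0 - alpha / 2.0))


@dataclass
class TwoByTwo:
    """Event/non-event counts in the high and low biomarker bands."""

    event_high: int
    nonevent_high: int
    event_low: int
    nonevent_low: int
    event_name: str = "event"
    reference_name: str = "reference"

    def __post_init__(self) -> None:
        for name in ("event_high", "nonevent_high", "event_low", "nonevent_low"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_high(self) -> int:
        return self.event_high + self.nonevent_high

    @property
    def n_low(self) -> int:
        return self.event_low + self.nonevent_low


@dataclass
class RiskRatioResult:
    rr: float
    ci_low: float
    ci_high: float
    p_value: float
    table: TwoByTwo
    alpha: float = 0.05
    se_log: float = field(default=float("nan"))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"RR {self.rr:.2f} ({self.ci_low:.2f}-{self.ci_high:.2f}), "
            f"p={self.p_value:.3g} [{self.table.event_high}/{self.table.n_high} vs "
            f"{self.table.event_low}/{self.table.n_low}]"
        )


def risk_ratio(table: TwoByTwo, alpha: float = 0.05, continuity: bool = False) -> RiskRatioResult:
    """Prevalence ratio with Katz log CI and two-sided normal p-value.

    Zero event cells are a hard error unless ``continuity`` is set, which
    adds 0.5 to all four cells (off by default: silent correction would
    change estimates computable without it).
    """
    a, b = float(table.event_high), float(table.nonevent_high)
    c, d = float(table.event_low), float(table.nonevent_low)
    if a == 0 or c == 0 or (b == 0 and d == 0):
        if not continuity:
            raise ZeroCellError(
                "zero event cell; re-run with continuity=True to add 0.5 to all cells"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    n1, n0 = a + b, c + d
    rr = (a / n1) / (c / n0)
    se = float(np.sqrt(1.0 / a - 1.0 / n1 + 1.0 / c - 1.0 / n0))
    z = _z_crit(alpha)
    log_rr = np.log(rr)
    ci_low, ci_high = float(np.exp(log_rr - z * se)), float(np.exp(log_rr + z * se))
    if se > 0:
        p = float(2.0 * stats.norm.sf(abs(log_rr) / se))
    else:
        p = 1.0 if rr == 1.0 else 0.0
    return RiskRatioResult(
        rr=float(rr), ci_low=ci_low, ci_high=ci_high, p_value=p, table=table, alpha=alpha, se_log=se
    )


def _band_state_table(
    scored: pd.DataFrame, event_state: str, score_col: str, threshold: float
) -> TwoByTwo:
    sub = scored[scored["state"].isin([event_state, "NORMAL"])].dropna(subset=[score_col])
    bands = risk_band(sub[score_col].to_numpy(), threshold)
    is_event = (sub["state"] == event_state).to_numpy()
    high = bands == "HIGH"
    return TwoByTwo(
        event_high=int((is_event & high).sum()),
        nonevent_high=int((~is_event & high).sum()),
        event_low=int((is_event & ~high).sum()),
        nonevent_low=int((~is_event & ~high).sum()),
        event_name=event_state,
        reference_name="NORMAL",
    )


def state_risk_tables(
    scored: pd.DataFrame,
    config: AnalysisConfig,
    use_normalized: bool = False,
    alpha: float = 0.05,
    continuity: bool = False,
) -> dict[str, RiskRatioResult]:
    """EXACERBATION-vs-NORMAL and MILD-vs-NORMAL risk ratios.

    Each event table excludes the non-compared state (MILD sessions never
    enter the exacerbation table's cells and vice versa). With
    ``use_normalized`` the analysis restricts to sessions carrying a
    normalized score and bands on ``normalized_threshold`` (which must be
    set on the config, e.g. via :func:`vbmon.labeling.derive_normalized_threshold`).
    """
    if use_normalized:
        score_col = "normalized_score"
        threshold = config.normalized_threshold
        if threshold is None:
            raise ValueError("config.normalized_threshold is unset; derive it first")
    else:
        score_col, threshold = "final_score", config.raw_threshold
    out = {}
    for event_state in ("EXACERBATION", "MILD"):
        table = _band_state_table(scored, event_state, score_col, threshold)
        out[event_state] = risk_ratio(table, alpha=alpha, continuity=continuity)
    return out


ACT_LEVELS = ("WELL", "NOT_WELL", "POOR")


def act_control_level(act_score) -> str:
    """ACT control categories: >=20 WELL, 16-19 NOT_WELL, <=15 POOR."""
    s = int(act_score)
    if s >= 20:
        return "WELL"
    if s >= 16:
        return "NOT_WELL"
    return "POOR"


def act_linkage(
    acts: pd.DataFrame,
    scored: pd.DataFrame,
    config: AnalysisConfig,
    use_normalized: bool = False,
) -> pd.DataFrame:
    """Link each ACT assessment to the time-averaged biomarker around it.

    Scores within ``act_window_days`` (inclusive) each side of the ACT date
    are averaged; assessments with empty windows are marked ineligible.
    Returns one row per assessment: ``participant_id, act_date, act_score,
    control_level, n_window_scores, time_averaged_score, band, eligible``.
    """
    score_col = "normalized_score" if use_normalized else "final_score"
    threshold = config.normalized_threshold if use_normalized else config.raw_threshold
    if use_normalized and threshold is None:
        raise ValueError("config.normalized_threshold is unset; derive it first")
    sess = scored.dropna(subset=[score_col])
    rows = []
    window = pd.Timedelta(days=config.act_window_days)
    by_pid = dict(tuple(sess.groupby("participant_id")))
    for _, act in acts.iterrows():
        sub = by_pid.get(act["participant_id"])
        if sub is None:
            in_win = pd.DataFrame(columns=[score_col])
        else:
            delta = (sub["session_time"].dt.normalize() - pd.Timestamp(act["act_date"]).normalize()).abs()
            in_win = sub[delta <= window]
        n = len(in_win)
        avg = float(in_win[score_col].mean()) if n else float("nan")
        rows.append(
            {
                "participant_id": act["participant_id"],
                "act_date": act["act_date"],
                "act_score": int(act["act_score"]),
                "control_level": act_control_level(act["act_score"]),
                "n_window_scores": n,
                "time_averaged_score": avg,
                "band": risk_band(avg, threshold) if n else None,
                "eligible": n > 0,
            }
        )
    return pd.DataFrame(rows)


def act_risk_tables(
    linkages: pd.DataFrame, alpha: float = 0.05, continuity: bool = False
) -> dict[str, RiskRatioResult]:
    """POOR-vs-WELL and NOT_WELL-vs-WELL prevalence ratios over assessments."""
    elig = linkages[linkages["eligible"]]
    out = {}
    for level in ("POOR", "NOT_WELL"):
        sub = elig[elig["control_level"].isin([level, "WELL"])]
        if sub.empty or (sub["control_level"] == level).sum() == 0 or (
            sub["control_level"] == "WELL"
        ).sum() == 0:
            raise ZeroCellError(f"contrast {level} vs WELL undefined: a level has no assessments")
        is_event = (sub["control_level"] == level).to_numpy()
        high = (sub["band"] == "HIGH").to_numpy()
        table = TwoByTwo(
            event_high=int((is_event & high).sum()),
            nonevent_high=int((~is_event & high).sum()),
            event_low=int((is_event & ~high).sum()),
            nonevent_low=int((~is_event & ~high).sum()),
            event_name=level,
            reference_name="WELL",
        )
        out[level] = risk_ratio(table, alpha=alpha, continuity=continuity)
    return out


@dataclass
class StratumResult:
    stratum: str
    n_sessions: int
    raw: RiskRatioResult | None
    normalized: RiskRatioResult | None
    undefined_reason: str | None = None


def stratified_risk(
    scored: pd.DataFrame,
    config: AnalysisConfig,
    strata: pd.Series,
    event_state: str = "EXACERBATION",
    alpha: float = 0.05,
) -> tuple[list[StratumResult], pd.DataFrame]:
    """Per-stratum exacerbation risk ratios (raw and normalized).

    ``strata`` maps participant_id to exactly one stratum label. Strata whose
    event counts make the CI undefined are flagged rather than raised.
    Returns the per-stratum results plus a pairwise CI-overlap frame
    (``overlap`` true when the raw-scale CIs of the two strata intersect),
    mirroring significance assessment through nonoverlapping intervals.
    """
    results: list[StratumResult] = []
    for name, pids in strata.groupby(strata):
        sub = scored[scored["participant_id"].isin(pids.index)]
        raw = norm = None
        reason = None
        try:
            raw = risk_ratio(
                _band_state_table(sub, event_state, "final_score", config.raw_threshold), alpha=alpha
            )
        except ZeroCellError as exc:
            reason = f"raw: {exc}"
        if config.normalized_threshold is not None:
            try:
                norm = risk_ratio(
                    _band_state_table(
                        sub, event_state, "normalized_score", config.normalized_threshold
                    ),
                    alpha=alpha,
                )
            except ZeroCellError as exc:
                reason = (reason + "; " if reason else "") + f"normalized: {exc}"
        results.append(
            StratumResult(
                stratum=str(name),
                n_sessions=int(len(sub)),
                raw=raw,
                normalized=norm,
                undefined_reason=reason,
            )
        )
    rows = []
    defined = [r for r in results if r.raw is not None]
    for i, r1 in enumerate(defined):
        for r2 in defined[i + 1 :]:
            overlap = (r1.raw.ci_low <= r2.raw.ci_high) and (r2.raw.ci_low <= r1.raw.ci_high)
            rows.append(
                {"stratum_a": r1.stratum, "stratum_b": r2.stratum, "overlap": bool(overlap)}
            )
    return results, pd.DataFrame(rows, columns=["stratum_a", "stratum_b", "overlap"])


def cluster_bootstrap_ci(
    scored: pd.DataFrame,
    config: AnalysisConfig,
    event_state: str = "EXACERBATION",
    use_normalized: bool = False,
    n_boot: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Participant-resampling bootstrap CI for the prevalence ratio.

    Extension to the default unclustered interval: resamples participants
    with replacement and takes percentile bounds of the RR distribution
    (replicates with undefined tables are skipped).
    """
    rng = np.random.default_rng(seed)
    score_col = "normalized_score" if use_normalized else "final_score"
    threshold = config.normalized_threshold if use_normalized else config.raw_threshold
    pids = scored["participant_id"].unique()
    groups = dict(tuple(scored.groupby("participant_id")))
    rrs = []
    for _ in range(n_boot):
        sample = rng.choice(pids, size=len(pids), replace=True)
        frame = pd.concat([groups[p] for p in sample], ignore_index=True)
        try:
            res = risk_ratio(_band_state_table(frame, event_state, score_col, threshold))
        except ZeroCellError:
            continue
        rrs.append(res.rr)
    if not rrs:
        raise ZeroCellError("all bootstrap replicates had undefined tables")
    lo, hi = np.percentile(rrs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)
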