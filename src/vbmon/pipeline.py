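"""End-to-end pipeline orchestration and report generation.

Stage order mirrors the study's analysis: session QC -> PEF personal best
and zoning -> state labeling -> cohort membership -> reference scores and
normalization -> risk tables (states, then ACT) -> longitudinal metrics.
Each stage consumes only the previous stages' tabular outputs, so the
pipeline can be re-run from any intermediate artifact with identical
downstream results. The report accompanies every estimate with its
underlying 2x2 counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import pandas as pd

from vbmon import data_model, labeling, metrics, pef, qc, risk
from vbmon.data_model import StudyDataset, read_dataset, write_dataset
from vbmon.labeling import AnalysisConfig

log = logging.getLogger("vbmon")

STAGES = ("read", "qc", "pef", "label", "normalize", "analyze", "metrics", "report")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for exit-code mapping."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    sessions_path: str | None = None
    act_path: str | None = None
    participants_path: str | None = None
    out_dir: str = "vbmon_out"
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0
    log_level: str = "INFO"

    def validate_paths(self) -> None:
        for p in (self.sessions_path, self.act_path, self.participants_path):
            if p is not None and not os.path.exists(p):
                raise FileNotFoundError(f"input path does not exist: {p}")


@dataclass
class PipelineResult:
    dataset: StudyDataset
    qc_outcomes: pd.DataFrame
    funnel: dict
    pef_profiles: pd.DataFrame
    relative_pef: pd.DataFrame
    scored: pd.DataFrame
    membership: pd.DataFrame
    norms: pd.DataFrame
    normalized_threshold: float | None
    risk_raw: dict
    risk_normalized: dict
    act_linkage_raw: pd.DataFrame
    act_tables_raw: dict
    act_linkage_normalized: pd.DataFrame | None
    act_tables_normalized: dict
    transitions: pd.DataFrame
    engagement: pd.DataFrame
    engagement_groups: pd.DataFrame
    descriptives: dict
    crosstab: pd.DataFrame
    report_text: str = ""


def _risk_or_reason(fn, *args, **kwargs):
    try:
        return {"result": fn(*args, **kwargs), "undefined": None}
    except (risk.ZeroCellError, ValueError) as exc:
        return {"result": None, "undefined": str(exc)}


def analyze_dataset(ds: StudyDataset, config: AnalysisConfig | None = None) -> PipelineResult:
    """Run every analysis stage on an in-memory dataset."""
    config = config if config is not None else AnalysisConfig()

    try:
        outcomes = qc.qc_pipeline(ds.sessions, config.consistency_threshold)
        funnel = qc.qc_funnel_summary(ds.sessions, outcomes)
    except Exception as exc:
        raise StageError("qc", exc) from exc
    log.info("qc: %d sessions -> %d scored", len(ds.sessions), funnel["sessions_scored"])

    try:
        profiles, relative = pef.pef_profiles(ds.sessions)
    except Exception as exc:
        raise StageError("pef", exc) from exc

    try:
        scored = labeling.label_sessions(ds.sessions, outcomes, relative)
        membership = data_model.cohort_membership(ds, scored)
    except Exception as exc:
        raise StageError("label", exc) from exc
    log.info("label: %d labeled sessions", len(scored))

    try:
        analysis_ids = set(membership.loc[membership["analysis"], "participant_id"])
        scored_analysis = scored[scored["participant_id"].isin(analysis_ids)].copy()
        norms = labeling.reference_scores(scored_analysis)
        scored_analysis = labeling.normalize_scores(scored_analysis, norms)
        if config.normalized_threshold is not None:
            threshold = config.normalized_threshold
        elif len(norms):
            threshold = labeling.derive_normalized_threshold(
                norms, scored_analysis, method=config.threshold_method
            )
        else:
            threshold = None
        analysis_cfg = AnalysisConfig(
            raw_threshold=config.raw_threshold,
            normalized_threshold=threshold,
            consistency_threshold=config.consistency_threshold,
            act_window_days=config.act_window_days,
            threshold_method=config.threshold_method,
        )
    except Exception as exc:
        raise StageError("normalize", exc) from exc

    try:
        risk_raw = {
            s: _risk_or_reason(
                risk.risk_ratio, risk._band_state_table(scored_analysis, s, "final_score", config.raw_threshold)
            )
            for s in ("EXACERBATION", "MILD")
        }
        if threshold is not None:
            risk_norm = {
                s: _risk_or_reason(
                    risk.risk_ratio,
                    risk._band_state_table(scored_analysis, s, "normalized_score", threshold),
                )
                for s in ("EXACERBATION", "MILD")
            }
        else:
            risk_norm = {
                s: {"result": None, "undefined": "no normalized cohort"} for s in ("EXACERBATION", "MILD")
            }

        acts_analysis = ds.act[ds.act["participant_id"].isin(analysis_ids)]
        link_raw = risk.act_linkage(acts_analysis, scored_analysis, analysis_cfg, use_normalized=False)
        act_raw = _risk_or_reason(risk.act_risk_tables, link_raw)
        if act_raw["undefined"] is None:
            act_tables_raw = {k: {"result": v, "undefined": None} for k, v in act_raw["result"].items()}
        else:
            act_tables_raw = {
                k: {"result": None, "undefined": act_raw["undefined"]} for k in ("POOR", "NOT_WELL")
            }
        if threshold is not None:
            link_norm = risk.act_linkage(acts_analysis, scored_analysis, analysis_cfg, use_normalized=True)
            act_norm = _risk_or_reason(risk.act_risk_tables, link_norm)
            if act_norm["undefined"] is None:
                act_tables_norm = {k: {"result": v, "undefined": None} for k, v in act_norm["result"].items()}
            else:
                act_tables_norm = {
                    k: {"result": None, "undefined": act_norm["undefined"]} for k in ("POOR", "NOT_WELL")
                }
        else:
            link_norm = None
            act_tables_norm = {
                k: {"result": None, "undefined": "no normalized cohort"} for k in ("POOR", "NOT_WELL")
            }
    except Exception as exc:
        raise StageError("analyze", exc) from exc

    try:
        transitions = metrics.transition_matrix(scored_analysis)
        engagement, groups = metrics.engagement_summary(ds)
        descriptives = metrics.descriptive_tables(scored_analysis)
        crosstab = labeling.crosstab_zone_wellbeing(scored_analysis)
    except Exception as exc:
        raise StageError("metrics", exc) from exc

    return PipelineResult(
        dataset=ds,
        qc_outcomes=outcomes,
        funnel=funnel,
        pef_profiles=profiles,
        relative_pef=relative,
        scored=scored_analysis,
        membership=membership,
        norms=norms,
        normalized_threshold=threshold,
        risk_raw=risk_raw,
        risk_normalized=risk_norm,
        act_linkage_raw=link_raw,
        act_tables_raw=act_tables_raw,
        act_linkage_normalized=link_norm,
        act_tables_normalized=act_tables_norm,
        transitions=transitions,
        engagement=engagement,
        engagement_groups=groups,
        descriptives=descriptives,
        crosstab=crosstab,
    )


def _fmt_rr(entry: dict) -> str:
    if entry["result"] is None:
        return f"undefined ({entry['undefined']})"
    r = entry["result"]
    t = r.table
    return (
        f"RR {r.rr:.2f} (95% CI {r.ci_low:.2f}-{r.ci_high:.2f}), p={r.p_value:.3g} "
        f"[cells {t.event_high}/{t.nonevent_high} high, {t.event_low}/{t.nonevent_low} low]"
    )


def build_report(res: PipelineResult, config_hash: str = "", seed: int | None = None) -> str:
    m = res.membership
    lines = [
        "# Monitoring pipeline report",
        "",
        f"config_hash: {config_hash}  seed: {seed}",
        "",
        "## Cohorts",
        f"- enrollment: {int(m['enrollment'].sum())} participants",
        f"- analysis (>=4 sessions): {int(m['analysis'].sum())}",
        f"- normalized (>=5 NORMAL sessions): {int(m['normalized'].sum())}",
        "",
        "## Session funnel",
        f"- completed sessions: {res.funnel['n_sessions']}",
        f"- scored after QC: {res.funnel['sessions_scored']} "
        f"({100 * res.funnel['scored_fraction']:.1f}%)",
        f"- failed elicitation: {res.funnel['sessions_fail_elicitation']}; "
        f"failed consistency: {res.funnel['sessions_fail_consistency']}",
        f"- labeled sessions (scored + valid PEF): {len(res.scored)}",
        "",
        "## Risk ratios (event vs NORMAL, high vs low band)",
        f"- raw exacerbation: {_fmt_rr(res.risk_raw['EXACERBATION'])}",
        f"- raw mild: {_fmt_rr(res.risk_raw['MILD'])}",
        f"- normalized threshold: "
        + (f"{res.normalized_threshold:.2f}" if res.normalized_threshold is not None else "n/a"),
        f"- normalized exacerbation: {_fmt_rr(res.risk_normalized['EXACERBATION'])}",
        f"- normalized mild: {_fmt_rr(res.risk_normalized['MILD'])}",
        "",
        "## ACT control contrasts (vs WELL controlled)",
        f"- raw poor: {_fmt_rr(res.act_tables_raw['POOR'])}",
        f"- raw not-well: {_fmt_rr(res.act_tables_raw['NOT_WELL'])}",
        f"- normalized poor: {_fmt_rr(res.act_tables_normalized['POOR'])}",
        f"- normalized not-well: {_fmt_rr(res.act_tables_normalized['NOT_WELL'])}",
        "",
        "## Zone x well-being cross-tab (labeled sessions)",
        res.crosstab.to_string(),
        "",
        "## State transitions (score change mean (SE), n)",
        res.transitions.to_string(float_format=lambda v: f"{v:.2f}"),
        "",
        "## Engagement",
        res.engagement_groups.to_string(float_format=lambda v: f"{v:.2f}"),
        "",
    ]
    return "\n".join(lines)


def _risk_json(tables: dict) -> dict:
    out = {}
    for key, entry in tables.items():
        if entry["result"] is None:
            out[key] = {"undefined": entry["undefined"]}
        else:
            r = entry["result"]
            out[key] = {
                "rr": r.rr,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_value": r.p_value,
                "alpha": r.alpha,
                "cells": {
                    "event_high": r.table.event_high,
                    "nonevent_high": r.table.nonevent_high,
                    "event_low": r.table.event_low,
                    "nonevent_low": r.table.nonevent_low,
                },
            }
    return out


def run_pipeline(config: PipelineConfig, ds: StudyDataset | None = None) -> PipelineResult:
    """Run the full pipeline from CSV inputs (or an in-memory dataset).

    Writes all stage outputs plus ``report.md`` and ``risk_tables.json`` to
    ``config.out_dir``. Deterministic given inputs and seed.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate_paths()
    if ds is None:
        try:
            ds = read_dataset(config.sessions_path, config.act_path, config.participants_path)
        except Exception as exc:
            raise StageError("read", exc) from exc
    res = analyze_dataset(ds, config.analysis)

    try:
        out = config.out_dir
        os.makedirs(out, exist_ok=True)
        res.qc_outcomes.to_csv(os.path.join(out, "qc_outcomes.csv"), index=False)
        res.pef_profiles.to_csv(os.path.join(out, "pef_profiles.csv"), index=False)
        res.relative_pef.to_csv(os.path.join(out, "relative_pef.csv"), index=False)
        res.scored.to_csv(os.path.join(out, "scored_sessions.csv"), index=False)
        res.norms.to_csv(os.path.join(out, "normalization.csv"), index=False)
        res.membership.to_csv(os.path.join(out, "cohorts.csv"), index=False)
        res.act_linkage_raw.to_csv(os.path.join(out, "act_linkage.csv"), index=False)
        res.transitions.to_csv(os.path.join(out, "transitions.csv"))
        res.engagement.to_csv(os.path.join(out, "engagement.csv"), index=False)
        res.engagement_groups.to_csv(os.path.join(out, "engagement_groups.csv"))
        for name, table in res.descriptives.items():
            table.to_csv(os.path.join(out, f"{name}.csv"))
        with open(os.path.join(out, "funnel.json"), "w") as fh:
            json.dump(res.funnel, fh, indent=2)
        risk_payload = {
            "normalized_threshold": res.normalized_threshold,
            "states_raw": _risk_json(res.risk_raw),
            "states_normalized": _risk_json(res.risk_normalized),
            "act_raw": _risk_json(res.act_tables_raw),
            "act_normalized": _risk_json(res.act_tables_normalized),
        }
        with open(os.path.join(out, "risk_tables.json"), "w") as fh:
            json.dump(risk_payload, fh, indent=2)
        cfg_repr = json.dumps(asdict(config.analysis), sort_keys=True)
        cfg_hash = hashlib.sha256(cfg_repr.encode()).hexdigest()[:12]
        res.report_text = build_report(res, config_hash=cfg_hash, seed=config.seed)
        with open(os.path.join(out, "report.md"), "w") as fh:
            fh.write(res.report_text)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("report", exc) from exc
    return res


def simulate_to_dir(cohort_config, out_dir: str) -> dict[str, str]:
    """Simulate a cohort and write its three CSVs plus provenance JSON."""
    from vbmon.simulate import simulate_cohort

    ds = simulate_cohort(cohort_config)
    paths = write_dataset(ds, out_dir)
    prov = {
        "seed": cohort_config.seed,
        "n_participants": cohort_config.n_participants,
        "study_days": cohort_config.study_days,
        "engagement_mix": cohort_config.engagement_mix,
        "state_marginal_target": list(cohort_config.state_marginal_target),
    }
    prov_path = os.path.join(out_dir, "provenance.json")
    with open(prov_path, "w") as fh:
        json.dump(prov, fh, indent=2)
    paths["provenance"] = prov_path
    return paths
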