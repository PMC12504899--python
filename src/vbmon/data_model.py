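"""Study data model and delimited-text IO.

The study collects three tables:

* ``sessions.csv`` — one row per completed app session: two raw RRVB scores
  in [0, 100] with per-sample elicitation-check outcomes, up to three peak
  expiratory flow (PEF) readings in L/min, a three-level asthma well-being
  response, and symptom / trigger / severity / rescue-medication reports.
* ``act.csv`` — monthly Asthma Control Test totals (5-25).
* ``participants.csv`` — enrollment demographics and clinical covariates.

All downstream modules consume the validated :class:`StudyDataset` produced
by :func:`read_dataset`. Rows that violate the documented schema are dropped
with row-level diagnostics rather than aborting the load; a missing required
column or an unresolvable participant id is a hard error.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

WELLBEING_LEVELS = ("GOOD", "NOT_GOOD", "BAD")
ZONES = ("GREEN", "YELLOW", "RED")
STATES = ("NORMAL", "MILD", "EXACERBATION")

SYMPTOM_VOCAB = (
    "shortness_of_breath",
    "chest_tightness",
    "wheezing",
    "trouble_sleeping",
    "coughing",
)
TRIGGER_VOCAB = (
    "tobacco_smoke",
    "air_pollution",
    "pets",
    "exercise",
    "disinfectant",
    "other_allergies",
    "stress",
    "other",
    "unknown",
)
SEVERITY_LEVELS = ("severe", "moderate", "mild", "none")
RESCUE_LEVELS = (
    "none_today",
    "plan_after_session",
    "earlier_for_symptoms",
    "earlier_pre_exercise",
)
ASTHMA_SEVERITIES = (
    "mild_intermittent",
    "mild_persistent",
    "moderate_persistent",
    "severe_persistent",
)

SESSION_COLUMNS = [
    "participant_id",
    "session_time",
    "raw_score_1",
    "raw_score_2",
    "elicitation_pass_1",
    "elicitation_pass_2",
    "elicitation_attempts_1",
    "elicitation_attempts_2",
    "pef_1",
    "pef_2",
    "pef_3",
    "wellbeing",
    "symptoms",
    "triggers",
    "severity_report",
    "rescue_use",
]
ACT_COLUMNS = ["participant_id", "act_date", "act_score"]
PARTICIPANT_COLUMNS = [
    "participant_id",
    "enrollment_date",
    "sex",
    "age_years",
    "ethnicity_hispanic",
    "race",
    "asthma_severity",
    "comorbidity_count",
    "mental_health_any",
]


class SchemaError(ValueError):
    """A required column is missing or a table is structurally unreadable."""


class ReferentialError(ValueError):
    """A session or ACT row references a participant_id not in participants."""


@dataclass
class RowDiagnostic:
    """One rejected row: which table, which row (0-based data row), and why."""

    table: str
    row: int
    reason: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.table}[{self.row}]: {self.reason}"


@dataclass
class StudyDataset:
    """Validated in-memory study dataset (three pandas DataFrames).

    ``sessions`` carries a stable integer ``session_id`` column (assigned in
    load/simulation order) used as the session key by every downstream stage.
    """

    participants: pd.DataFrame
    sessions: pd.DataFrame
    act: pd.DataFrame
    diagnostics: list[RowDiagnostic] = field(default_factory=list)

    def sessions_for(self, participant_id: str) -> pd.DataFrame:
        """Sessions of one participant in non-decreasing time order."""
        sub = self.sessions[self.sessions["participant_id"] == participant_id]
        return sub.sort_values(["session_time", "session_id"], kind="stable")

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def n_sessions(self) -> int:
        return len(self.sessions)


def _require_columns(df: pd.DataFrame, required: list[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing required column(s) {missing}")


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValueError(f"unparseable boolean {value!r}")


def _split_tokens(cell, vocab: tuple[str, ...], what: str) -> str:
    """Validate a semicolon-joined token cell, returning the canonical join."""
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell) == "":
        return ""
    tokens = [t for t in str(cell).split(";") if t]
    bad = [t for t in tokens if t not in vocab]
    if bad:
        raise ValueError(f"unrecognized {what} token(s) {bad}")
    return ";".join(tokens)


def read_dataset(session_path, act_path, participant_path) -> StudyDataset:
    """Read and validate the three study tables.

    Rows violating per-field type or vocabulary constraints are rejected and
    recorded in :attr:`StudyDataset.diagnostics`; structural problems
    (missing columns, unresolvable participant ids) raise.
    """
    diagnostics: list[RowDiagnostic] = []

    participants = pd.read_csv(participant_path, dtype={"participant_id": str})
    _require_columns(participants, PARTICIPANT_COLUMNS, "participants")
    keep = []
    for i, row in participants.iterrows():
        try:
            if int(row["age_years"]) < 18:
                raise ValueError("age_years below study eligibility floor (18)")
            if int(row["comorbidity_count"]) < 0:
                raise ValueError("negative comorbidity_count")
            if row["asthma_severity"] not in ASTHMA_SEVERITIES:
                raise ValueError(f"unrecognized asthma_severity {row['asthma_severity']!r}")
            _parse_bool(row["ethnicity_hispanic"])
            _parse_bool(row["mental_health_any"])
            pd.Timestamp(row["enrollment_date"])
        except (ValueError, TypeError) as exc:
            diagnostics.append(RowDiagnostic("participants", int(i), str(exc)))
            continue
        keep.append(i)
    participants = participants.loc[keep].reset_index(drop=True)
    if participants["participant_id"].duplicated().any():
        dups = participants.loc[participants["participant_id"].duplicated(), "participant_id"]
        raise SchemaError(f"participants: duplicate participant_id(s) {sorted(set(dups))}")
    participants["enrollment_date"] = pd.to_datetime(participants["enrollment_date"])
    participants["age_years"] = participants["age_years"].astype(int)
    participants["comorbidity_count"] = participants["comorbidity_count"].astype(int)
    participants["ethnicity_hispanic"] = participants["ethnicity_hispanic"].map(_parse_bool)
    participants["mental_health_any"] = participants["mental_health_any"].map(_parse_bool)
    known_ids = set(participants["participant_id"])

    sessions = pd.read_csv(
        session_path, dtype={"participant_id": str}, float_precision="round_trip"
    )
    _require_columns(sessions, SESSION_COLUMNS, "sessions")
    unresolved = sorted(set(sessions["participant_id"]) - known_ids)
    if unresolved:
        raise ReferentialError(f"sessions: unresolvable participant_id(s) {unresolved}")
    keep = []
    for i, row in sessions.iterrows():
        try:
            pd.Timestamp(row["session_time"])
            for col in ("raw_score_1", "raw_score_2"):
                v = row[col]
                if pd.notna(v) and not (0.0 <= float(v) <= 100.0):
                    raise ValueError(f"{col}={v} outside [0, 100]")
            for col in ("elicitation_attempts_1", "elicitation_attempts_2"):
                v = row[col]
                if pd.notna(v) and int(v) not in (1, 2, 3):
                    raise ValueError(f"{col}={v} not in {{1,2,3}}")
            for col in ("pef_1", "pef_2", "pef_3"):
                v = row[col]
                if pd.notna(v) and float(v) < 0:
                    raise ValueError(f"{col}={v} negative")
            if row["wellbeing"] not in WELLBEING_LEVELS:
                raise ValueError(f"unrecognized wellbeing {row['wellbeing']!r}")
            _split_tokens(row["symptoms"], SYMPTOM_VOCAB, "symptom")
            _split_tokens(row["triggers"], TRIGGER_VOCAB, "trigger")
            if row["severity_report"] not in SEVERITY_LEVELS:
                raise ValueError(f"unrecognized severity_report {row['severity_report']!r}")
            if row["rescue_use"] not in RESCUE_LEVELS:
                raise ValueError(f"unrecognized rescue_use {row['rescue_use']!r}")
            _parse_bool(row["elicitation_pass_1"])
            _parse_bool(row["elicitation_pass_2"])
        except (ValueError, TypeError) as exc:
            diagnostics.append(RowDiagnostic("sessions", int(i), str(exc)))
            continue
        keep.append(i)
    sessions = sessions.loc[keep].reset_index(drop=True)
    sessions["session_time"] = pd.to_datetime(sessions["session_time"])
    for col in ("elicitation_pass_1", "elicitation_pass_2"):
        sessions[col] = sessions[col].map(_parse_bool)
    for col in ("symptoms", "triggers"):
        sessions[col] = sessions[col].fillna("").astype(str)
    sessions = sessions.sort_values(
        ["participant_id", "session_time"], kind="stable"
    ).reset_index(drop=True)
    sessions.insert(0, "session_id", np.arange(len(sessions)))

    act = pd.read_csv(act_path, dtype={"participant_id": str})
    _require_columns(act, ACT_COLUMNS, "act")
    unresolved = sorted(set(act["participant_id"]) - known_ids)
    if unresolved:
        raise ReferentialError(f"act: unresolvable participant_id(s) {unresolved}")
    keep = []
    for i, row in act.iterrows():
        try:
            pd.Timestamp(row["act_date"])
            if not (5 <= int(row["act_score"]) <= 25):
                raise ValueError(f"act_score={row['act_score']} outside [5, 25]")
        except (ValueError, TypeError) as exc:
            diagnostics.append(RowDiagnostic("act", int(i), str(exc)))
            continue
        keep.append(i)
    act = act.loc[keep].reset_index(drop=True)
    act["act_date"] = pd.to_datetime(act["act_date"])
    act["act_score"] = act["act_score"].astype(int)

    return StudyDataset(participants=participants, sessions=sessions, act=act, diagnostics=diagnostics)


def _format_csv(df: pd.DataFrame, columns: list[str]) -> str:
    out = df.copy()
    for col in columns:
        if col not in out.columns:
            out[col] = np.nan
    out = out[columns]
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%dT%H:%M:%S")
        elif pd.api.types.is_bool_dtype(out[col]):
            out[col] = out[col].map({True: "True", False: "False"})
    buf = io.StringIO()
    out.to_csv(buf, index=False, lineterminator="\n")
    return buf.getvalue()


def write_dataset(ds: StudyDataset, out_dir) -> dict[str, str]:
    """Write the three tables to ``out_dir`` with fixed column order/format.

    Output is bit-stable given identical input; a write → read → write cycle
    yields byte-identical files. Returns the written paths keyed by table.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    specs = [
        ("sessions", ds.sessions, SESSION_COLUMNS),
        ("act", ds.act, ACT_COLUMNS),
        ("participants", ds.participants, PARTICIPANT_COLUMNS),
    ]
    for name, df, columns in specs:
        path = os.path.join(out_dir, f"{name}.csv")
        try:
            text = _format_csv(df, columns)
            with open(path, "w", encoding="utf-8", newline="") as fh:
                fh.write(text)
        except OSError as exc:
            raise OSError(f"failed writing {path}: {exc}") from exc
        paths[name] = path
    return paths


def cohort_membership(ds: StudyDataset, scored: pd.DataFrame | None) -> pd.DataFrame:
    """Per-participant cohort flags.

    * ``enrollment`` — always true (all enrolled participants).
    * ``analysis`` — at least 4 completed study sessions. Completed sessions
      (rows present) are counted, not QC-passing ones: the cohort rule is
      defined on study sessions, and QC exclusion was state-independent.
    * ``normalized`` — in the analysis cohort and at least 5 sessions labeled
      NORMAL, enabling a reference-score estimate.

    ``scored`` is a labeled session frame (from
    :func:`vbmon.labeling.label_sessions`) with ``participant_id`` and
    ``state`` columns; pass ``None`` when labels are unavailable, in which
    case ``normalized`` is false everywhere.
    """
    counts = ds.sessions.groupby("participant_id").size()
    if scored is not None and len(scored):
        normal_counts = (
            scored[scored["state"] == "NORMAL"].groupby("participant_id").size()
        )
    else:
        normal_counts = pd.Series(dtype=int)
    out = ds.participants[["participant_id"]].copy()
    out["n_sessions"] = out["participant_id"].map(counts).fillna(0).astype(int)
    out["n_normal_sessions"] = out["participant_id"].map(normal_counts).fillna(0).astype(int)
    out["enrollment"] = True
    out["analysis"] = out["n_sessions"] >= 4
    out["normalized"] = out["analysis"] & (out["n_normal_sessions"] >= 5)
    return out
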