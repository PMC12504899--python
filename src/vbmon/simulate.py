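"""Synthetic-cohort simulator for the vocal-biomarker monitoring pipeline.

Generates a :class:`~vbmon.data_model.StudyDataset` with the statistical
structure the analysis assumes, so every downstream stage can be exercised
and calibrated without external data:

* **Engagement archetypes** — each participant draws a high / medium / low
  archetype with monthly session-count trajectories matching the observed
  engagement groups (high ~22/month and stable, with a structural floor of
  8 sessions in every month; medium ~16 declining to ~8; low ~6 to ~1).
* **Latent respiratory process** — a daily 3-state Markov chain over
  NORMAL / MILD / EXACERBATION whose default transition matrix is built as
  ``a*I + (1-a)*1 pi^T`` so its stationary law equals the configured target
  marginals exactly; the chain evolves whether or not a session occurs.
* **Emissions** — per session: two raw RRVB scores (participant baseline +
  state shift + shared day noise + independent per-sample noise, clipped to
  [0, 100]); up to three PEF readings around personal best times a
  state-dependent relative level; a well-being draw; elicitation pass/fail
  per attempt; symptom / trigger / severity / rescue reports with
  state-dependent rates. MILD sessions split into a PEF-dominant and a
  symptom-dominant subtype so that typically one impairment criterion fires,
  matching the state's definition.
* **Monthly ACT** — an affine function of the trailing 30-day state burden
  plus participant offset and noise, clamped to [5, 25].

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from vbmon.data_model import (
    RESCUE_LEVELS,
    STATES,
    SYMPTOM_VOCAB,
    TRIGGER_VOCAB,
    StudyDataset,
)

_STATE_INDEX = {s: i for i, s in enumerate(STATES)}


def sticky_transition_matrix(marginal, stickiness: float = 0.6) -> np.ndarray:
    """Row-stochastic matrix ``a*I + (1-a)*1 pi^T`` with stationary law pi.

    ``stickiness`` sets the day-to-day autocorrelation of the latent state
    without disturbing the stationary marginals.
    """
    pi = np.asarray(marginal, dtype=float)
    if not np.isclose(pi.sum(), 1.0, atol=1e-9):
        raise ValueError("marginal must sum to 1")
    if not (0.0 <= stickiness < 1.0):
        raise ValueError("stickiness must lie in [0, 1)")
    return stickiness * np.eye(len(pi)) + (1.0 - stickiness) * np.tile(pi, (len(pi), 1))


# Per-state Bernoulli rates (NORMAL, MILD, EXACERBATION) chosen to be
# monotone in state severity except stress, which recedes at exacerbation.
_SYMPTOM_RATES = {
    "shortness_of_breath": (0.08, 0.30, 0.73),
    "chest_tightness": (0.05, 0.18, 0.45),
    "wheezing": (0.06, 0.20, 0.50),
    "trouble_sleeping": (0.05, 0.15, 0.35),
    "coughing": (0.24, 0.35, 0.60),
}
_TRIGGER_RATES = {
    "tobacco_smoke": (0.05, 0.06, 0.10),
    "air_pollution": (0.22, 0.25, 0.30),
    "pets": (0.08, 0.09, 0.12),
    "exercise": (0.07, 0.08, 0.10),
    "disinfectant": (0.03, 0.04, 0.06),
    "other_allergies": (0.35, 0.38, 0.53),
    "stress": (0.20, 0.20, 0.15),
    "other": (0.05, 0.08, 0.15),
    "unknown": (0.06, 0.08, 0.12),
}
_SEVERITY_PROBS = {  # given >=1 symptom: (severe, moderate, mild)
    "NORMAL": (0.03, 0.17, 0.80),
    "MILD": (0.07, 0.33, 0.60),
    "EXACERBATION": (0.20, 0.55, 0.25),
}
_RESCUE_PROBS = {  # none_today, plan_after_session, earlier_for_symptoms, earlier_pre_exercise
    "NORMAL": (0.55, 0.08, 0.33, 0.04),
    "MILD": (0.35, 0.12, 0.49, 0.04),
    "EXACERBATION": (0.15, 0.13, 0.68, 0.04),
}

_RACES = ("black", "white", "other", "asian", "american_indian")
_RACE_PROBS = (0.44, 0.15, 0.35, 0.03, 0.03)
_SEVERITY_CATS = ("mild_intermittent", "mild_persistent", "moderate_persistent", "severe_persistent")
_SEVERITY_CAT_PROBS = (0.06, 0.37, 0.33, 0.24)


@dataclass
class CohortConfig:
    """Free parameters of the cohort simulator (defaults = study conditions).

    Emission defaults are anchored to the study's reported quantities: a
    61.7-point mean normal-function score, +3 / +8 state shifts for MILD /
    EXACERBATION, per-attempt elicitation failure rates 13.3% / 35.3% /
    44.6%, per-sample noise sized so ~79% of dual-pass sessions agree within
    10 points, and latent-state marginals 61.5 / 27.8 / 10.7 percent.
    """

    n_participants: int = 84
    study_days: int = 90
    seed: int = 0

    engagement_mix: dict = field(
        default_factory=lambda: {"high": 0.33, "medium": 0.25, "low": 0.42}
    )
    monthly_session_means: dict = field(
        default_factory=lambda: {
            "high": (22.1, 22.0, 21.4),
            "medium": (16.2, 12.1, 7.7),
            "low": (6.2, 2.1, 1.3),
        }
    )
    monthly_session_sds: dict = field(
        default_factory=lambda: {
            "high": (8.4, 6.6, 6.1),
            "medium": (5.3, 3.8, 5.4),
            "low": (4.0, 2.8, 2.7),
        }
    )
    high_monthly_floor: int = 8  # HIGH archetype = consistent users, every month

    state_marginal_target: tuple = (0.615, 0.278, 0.107)
    state_stickiness: float = 0.6
    state_transition_matrix: np.ndarray | None = None  # derived when None

    baseline_score_mean: float = 61.7
    baseline_score_sd: float = 7.0
    state_score_shift: tuple = (0.0, 3.0, 8.0)  # NORMAL, MILD, EXACERBATION
    within_session_score_sd: float = 5.8  # day-level, shared by both samples
    two_sample_extra_sd: float = 5.6  # per-sample, drives 2-sample disagreement

    personal_best_mean_lpm: float = 400.0
    personal_best_sd_lpm: float = 70.0
    pef_relative_levels: dict = field(
        default_factory=lambda: {
            "NORMAL": (0.95, 0.05),
            "MILD_PEF": (0.73, 0.06),
            "MILD_SYMPTOM": (0.95, 0.05),
            "EXACERBATION": (0.70, 0.07),
        }
    )
    mild_pef_fraction: float = 0.55
    pef_reading_cv: float = 0.02
    pef_gross_error_rate: float = 0.004  # per session: one reading >1000 L/min
    pef_missing_session_rate: float = 0.005  # session with no PEF at all

    wellbeing_given_state: dict = field(
        default_factory=lambda: {
            "NORMAL": (0.96, 0.038, 0.002),
            "MILD_PEF": (0.92, 0.075, 0.005),
            "MILD_SYMPTOM": (0.08, 0.85, 0.07),
            "EXACERBATION": (0.06, 0.80, 0.14),
        }
    )

    elicitation_fail_probs: tuple = (0.133, 0.353, 0.446)

    act_intercept: float = 19.0
    act_burden_slope: float = -8.0
    act_between_sd: float = 4.0
    act_noise_sd: float = 2.0
    act_submit_probs: dict = field(
        default_factory=lambda: {"high": 0.95, "medium": 0.75, "low": 0.45}
    )

    exacerbation_missingness: float = 0.0  # P(drop a session | EXACERBATION day)
    start_date: str = "2022-01-03"
    enrollment_span_days: int = 240

    def transition_matrix(self) -> np.ndarray:
        if self.state_transition_matrix is not None:
            return np.asarray(self.state_transition_matrix, dtype=float)
        return sticky_transition_matrix(self.state_marginal_target, self.state_stickiness)

    def validate(self) -> None:
        if self.n_participants <= 0 or self.study_days <= 0:
            raise ValueError("n_participants and study_days must be positive")
        mix = np.array([self.engagement_mix[k] for k in ("high", "medium", "low")], dtype=float)
        if not np.isclose(mix.sum(), 1.0, atol=1e-9):
            raise ValueError("engagement_mix must sum to 1")
        if (mix < 0).any():
            raise ValueError("engagement_mix proportions must be non-negative")
        tm = self.transition_matrix()
        if tm.shape != (3, 3):
            raise ValueError("state_transition_matrix must be 3x3")
        if not np.allclose(tm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if (tm < 0).any() or (tm > 1).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        for p in self.elicitation_fail_probs:
            if not (0.0 <= p <= 1.0):
                raise ValueError("elicitation_fail_probs must lie in [0, 1]")
        for dist in self.wellbeing_given_state.values():
            arr = np.asarray(dist, dtype=float)
            if (arr < 0).any() or not np.isclose(arr.sum(), 1.0, atol=1e-9):
                raise ValueError("wellbeing_given_state rows must be distributions")
        if not (0.0 <= self.mild_pef_fraction <= 1.0):
            raise ValueError("mild_pef_fraction must lie in [0, 1]")
        if not (0.0 <= self.exacerbation_missingness <= 1.0):
            raise ValueError("exacerbation_missingness must lie in [0, 1]")


@dataclass
class CohortTruth:
    """Latent ground truth behind a simulated dataset (for recovery tests)."""

    participants: pd.DataFrame  # participant_id, archetype, baseline_score, personal_best_lpm, act_offset
    session_truth: pd.DataFrame  # session_id, participant_id, day, latent_state
    daily_states: pd.DataFrame  # participant_id, day, latent_state


def _sample_elicitation(rng: np.random.Generator, fail_probs, n: int):
    """Per-sample attempt counts and final pass flags (up to 3 attempts)."""
    attempts = np.ones(n, dtype=int)
    passed = rng.random(n) >= fail_probs[0]
    for k in (1, 2):
        retry = ~passed & (attempts == k)
        attempts[retry] = k + 1
        passed[retry] = rng.random(int(retry.sum())) >= fail_probs[k]
    return attempts, passed


def _multinomial_choice(rng: np.random.Generator, options, probs, n: int):
    idx = rng.choice(len(options), size=n, p=np.asarray(probs, dtype=float))
    return np.asarray(options, dtype=object)[idx]


def simulate_cohort_with_truth(config: CohortConfig) -> tuple[StudyDataset, CohortTruth]:
    """Simulate a cohort and return the dataset plus its latent truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    tm = config.transition_matrix()
    pi = np.asarray(config.state_marginal_target, dtype=float)
    n_months = int(np.ceil(config.study_days / 30))
    start = pd.Timestamp(config.start_date)

    archetypes = _multinomial_choice(
        rng,
        ["high", "medium", "low"],
        [config.engagement_mix[k] for k in ("high", "medium", "low")],
        config.n_participants,
    )

    width = max(3, len(str(config.n_participants)))
    part_rows, sess_rows, act_rows = [], [], []
    truth_part_rows, truth_sess_rows, truth_daily = [], [], []

    for p in range(config.n_participants):
        pid = f"P{p + 1:0{width}d}"
        arch = str(archetypes[p])
        enroll = start + pd.Timedelta(days=int(rng.integers(0, config.enrollment_span_days + 1)))
        baseline = rng.normal(config.baseline_score_mean, config.baseline_score_sd)
        pb = max(float(rng.normal(config.personal_best_mean_lpm, config.personal_best_sd_lpm)), 150.0)
        act_offset = rng.normal(0.0, config.act_between_sd)

        # Latent daily Markov chain, initialized from the stationary law.
        states = np.empty(config.study_days, dtype=int)
        states[0] = rng.choice(3, p=pi)
        u = rng.random(config.study_days - 1)
        cum = np.cumsum(tm, axis=1)
        for d in range(1, config.study_days):
            states[d] = np.searchsorted(cum[states[d - 1]], u[d - 1], side="right")

        # Session days from the engagement archetype, month by month.
        means = config.monthly_session_means[arch]
        sds = config.monthly_session_sds[arch]
        session_days = []
        for m in range(n_months):
            lo = m * 30
            hi = min(lo + 30, config.study_days)
            span = hi - lo
            if span <= 0:
                continue
            mean = means[min(m, len(means) - 1)]
            sd = sds[min(m, len(sds) - 1)]
            n = int(np.rint(rng.normal(mean, sd)))
            floor = config.high_monthly_floor if arch == "high" else 0
            n = int(np.clip(n, floor, span))
            if n > 0:
                session_days.extend(lo + rng.choice(span, size=n, replace=False))
        if not session_days:
            session_days = [int(rng.integers(0, min(30, config.study_days)))]
        session_days = np.sort(np.asarray(session_days, dtype=int))

        if config.exacerbation_missingness > 0:
            exac = states[session_days] == _STATE_INDEX["EXACERBATION"]
            drop = exac & (rng.random(session_days.size) < config.exacerbation_missingness)
            if drop.all():
                drop[np.argmax(~exac) if (~exac).any() else 0] = False
            session_days = session_days[~drop]

        n_s = session_days.size
        day_states = states[session_days]
        state_names = np.asarray(STATES, dtype=object)[day_states]

        # MILD subtype split and per-session emission profile keys.
        profile = state_names.copy()
        mild = state_names == "MILD"
        is_pef_type = rng.random(n_s) < config.mild_pef_fraction
        profile[mild & is_pef_type] = "MILD_PEF"
        profile[mild & ~is_pef_type] = "MILD_SYMPTOM"

        # RRVB scores: baseline + state shift + day noise + per-sample noise.
        shift = np.asarray(config.state_score_shift, dtype=float)[day_states]
        day_noise = rng.normal(0.0, config.within_session_score_sd, n_s)
        raw1 = baseline + shift + day_noise + rng.normal(0.0, config.two_sample_extra_sd, n_s)
        raw2 = baseline + shift + day_noise + rng.normal(0.0, config.two_sample_extra_sd, n_s)
        raw1, raw2 = np.clip(raw1, 0.0, 100.0), np.clip(raw2, 0.0, 100.0)

        att1, pass1 = _sample_elicitation(rng, config.elicitation_fail_probs, n_s)
        att2, pass2 = _sample_elicitation(rng, config.elicitation_fail_probs, n_s)
        raw1 = np.where(pass1, raw1, np.nan)
        raw2 = np.where(pass2, raw2, np.nan)

        # PEF: three readings around personal best x state-dependent level.
        rel_mean = np.array([config.pef_relative_levels[k][0] for k in profile])
        rel_sd = np.array([config.pef_relative_levels[k][1] for k in profile])
        rel = np.maximum(rng.normal(rel_mean, rel_sd), 0.1)
        readings = pb * rel[:, None] * (1.0 + rng.normal(0.0, config.pef_reading_cv, (n_s, 3)))
        gross = rng.random(n_s) < config.pef_gross_error_rate
        readings[gross, 0] = rng.uniform(1001.0, 1400.0, int(gross.sum()))
        all_missing = rng.random(n_s) < config.pef_missing_session_rate
        readings[all_missing] = np.nan

        wb_levels = ("GOOD", "NOT_GOOD", "BAD")
        wellbeing = np.empty(n_s, dtype=object)
        for key in ("NORMAL", "MILD_PEF", "MILD_SYMPTOM", "EXACERBATION"):
            mask = profile == key
            if mask.any():
                wellbeing[mask] = _multinomial_choice(
                    rng, wb_levels, config.wellbeing_given_state[key], int(mask.sum())
                )

        sym_ind = {
            tok: rng.random(n_s) < np.asarray(rates)[day_states]
            for tok, rates in _SYMPTOM_RATES.items()
        }
        symptoms = [
            ";".join(tok for tok in SYMPTOM_VOCAB if sym_ind[tok][i]) for i in range(n_s)
        ]
        trg_ind = {
            tok: rng.random(n_s) < np.asarray(rates)[day_states]
            for tok, rates in _TRIGGER_RATES.items()
        }
        triggers = [
            ";".join(tok for tok in TRIGGER_VOCAB if trg_ind[tok][i]) for i in range(n_s)
        ]
        any_sym = np.array([s != "" for s in symptoms])
        severity = np.full(n_s, "none", dtype=object)
        for state in STATES:
            mask = (state_names == state) & any_sym
            if mask.any():
                severity[mask] = _multinomial_choice(
                    rng, ("severe", "moderate", "mild"), _SEVERITY_PROBS[state], int(mask.sum())
                )
        rescue = np.empty(n_s, dtype=object)
        for state in STATES:
            mask = state_names == state
            if mask.any():
                rescue[mask] = _multinomial_choice(
                    rng, RESCUE_LEVELS, _RESCUE_PROBS[state], int(mask.sum())
                )

        hours = rng.integers(8, 21, n_s)
        minutes = rng.integers(0, 60, n_s)
        for i in range(n_s):
            t = enroll + pd.Timedelta(days=int(session_days[i]), hours=int(hours[i]), minutes=int(minutes[i]))
            sess_rows.append(
                {
                    "participant_id": pid,
                    "session_time": t,
                    "raw_score_1": raw1[i],
                    "raw_score_2": raw2[i],
                    "elicitation_pass_1": bool(pass1[i]),
                    "elicitation_pass_2": bool(pass2[i]),
                    "elicitation_attempts_1": int(att1[i]),
                    "elicitation_attempts_2": int(att2[i]),
                    "pef_1": readings[i, 0],
                    "pef_2": readings[i, 1],
                    "pef_3": readings[i, 2],
                    "wellbeing": wellbeing[i],
                    "symptoms": symptoms[i],
                    "triggers": triggers[i],
                    "severity_report": severity[i],
                    "rescue_use": rescue[i],
                }
            )
            truth_sess_rows.append(
                {"participant_id": pid, "day": int(session_days[i]), "latent_state": STATES[day_states[i]]}
            )

        # Monthly ACT from trailing 30-day state burden.
        weights = np.array([0.0, 1.0, 2.0])[states]
        submit_p = config.act_submit_probs[arch]
        for d in range(0, config.study_days + 1, 30):
            if rng.random() >= submit_p:
                continue
            lo = max(0, d - 30)
            hi = max(d, 1)
            burden = float(weights[lo:hi].mean())
            score = config.act_intercept + config.act_burden_slope * burden
            score += act_offset + rng.normal(0.0, config.act_noise_sd)
            act_rows.append(
                {
                    "participant_id": pid,
                    "act_date": enroll + pd.Timedelta(days=d),
                    "act_score": int(np.clip(np.rint(score), 5, 25)),
                }
            )

        part_rows.append(
            {
                "participant_id": pid,
                "enrollment_date": enroll,
                "sex": "female" if rng.random() < 0.81 else "male",
                "age_years": int(np.clip(np.rint(rng.normal(39.8, 11.6)), 18, 85)),
                "ethnicity_hispanic": bool(rng.random() < 0.58),
                "race": str(_multinomial_choice(rng, _RACES, _RACE_PROBS, 1)[0]),
                "asthma_severity": str(
                    _multinomial_choice(rng, _SEVERITY_CATS, _SEVERITY_CAT_PROBS, 1)[0]
                ),
                "comorbidity_count": int(rng.poisson(3.0)),
                "mental_health_any": bool(rng.random() < 0.46),
            }
        )
        truth_part_rows.append(
            {
                "participant_id": pid,
                "archetype": arch,
                "baseline_score": float(baseline),
                "personal_best_lpm": float(pb),
                "act_offset": float(act_offset),
            }
        )
        truth_daily.append(
            pd.DataFrame(
                {"participant_id": pid, "day": np.arange(config.study_days), "latent_state": np.asarray(STATES, dtype=object)[states]}
            )
        )

    participants = pd.DataFrame(part_rows)
    sessions = pd.DataFrame(sess_rows).sort_values(
        ["participant_id", "session_time"], kind="stable"
    ).reset_index(drop=True)
    sessions.insert(0, "session_id", np.arange(len(sessions)))
    act = pd.DataFrame(act_rows, columns=["participant_id", "act_date", "act_score"])

    truth_sessions = pd.DataFrame(truth_sess_rows)
    # session_truth rows were appended per participant in day order, matching
    # the (participant_id, session_time) sort of the sessions frame.
    truth_sessions.insert(0, "session_id", sessions["session_id"].to_numpy())
    truth = CohortTruth(
        participants=pd.DataFrame(truth_part_rows),
        session_truth=truth_sessions,
        daily_states=pd.concat(truth_daily, ignore_index=True),
    )
    ds = StudyDataset(participants=participants, sessions=sessions, act=act)
    return ds, truth


def simulate_cohort(config: CohortConfig) -> StudyDataset:
    """Simulate a cohort dataset (see :func:`simulate_cohort_with_truth`)."""
    return simulate_cohort_with_truth(config)[0]


@dataclass
class QCFunnelTally:
    """Attempt-level elicitation funnel counts from a simulated batch."""

    n_sessions: int
    n_samples: int
    first_attempt_failures: int
    second_attempts: int
    second_attempt_failures: int
    third_attempts: int
    third_attempt_failures: int
    sessions_with_0_passing: int
    sessions_with_1_passing: int
    sessions_with_2_passing: int

    @property
    def first_attempt_failure_rate(self) -> float:
        return self.first_attempt_failures / self.n_samples


def simulate_qc_funnel(config: CohortConfig, n_sessions: int, seed: int | None = None) -> QCFunnelTally:
    """Sample the elicitation funnel for ``n_sessions`` two-sample sessions.

    Each sample fails attempt k independently with the configured per-attempt
    probability; a sample passes if any of its up-to-three attempts passes.
    """
    if n_sessions <= 0:
        raise ValueError("n_sessions must be positive")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    p1, p2, p3 = config.elicitation_fail_probs
    n = 2 * n_sessions
    fail1 = rng.random(n) < p1
    fail2 = fail1 & (rng.random(n) < p2)
    fail3 = fail2 & (rng.random(n) < p3)
    passing = (~fail3).reshape(n_sessions, 2).sum(axis=1)
    return QCFunnelTally(
        n_sessions=n_sessions,
        n_samples=n,
        first_attempt_failures=int(fail1.sum()),
        second_attempts=int(fail1.sum()),
        second_attempt_failures=int(fail2.sum()),
        third_attempts=int(fail2.sum()),
        third_attempt_failures=int(fail3.sum()),
        sessions_with_0_passing=int((passing == 0).sum()),
        sessions_with_1_passing=int((passing == 1).sum()),
        sessions_with_2_passing=int((passing == 2).sum()),
    )


def null_config(base: CohortConfig | None = None, **overrides) -> CohortConfig:
    """A copy of ``base`` with zero state score shifts (null effect)."""
    base = base if base is not None else CohortConfig()
    return replace(base, state_score_shift=(0.0, 0.0, 0.0), **overrides)
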