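# Methods

## The measurement model

The pipeline treats the vocal biomarker as an opaque per-sample score in
[0, 100]; nothing downstream depends on how the score is produced. The
analysis chain is deliberately simple and auditable: deterministic quality
gates, a rank-based personal-best estimator, a rule-based state label built
only from peak flow and self-report (never from the biomarker, so the
validation is not circular), a per-participant location shift, and a pooled
2×2 prevalence ratio.

### Quality control

Each session carries two samples, each with up to three elicitation
attempts. The package consumes pass/fail flags only — the acoustic criteria
live upstream. Two-sample scoring accepts a dual-pass session iff
|s₁ − s₂| ≤ 10 (inclusive at exactly 10; the boundary choice is configurable
via `consistency_threshold`) and averages the pair. The SCORED fraction is
monotone in this threshold by construction.

### Peak flow

Personal best = the largest session maximum not exceeding the 95th
percentile of the participant's session maxima. Percentiles use linear
interpolation between order statistics throughout the package (numpy's
default); the estimator is scale-equivariant and always well defined for a
non-empty series. The "reported PEF values" feeding the percentile are
per-session maxima — the value the analysis consumes — not individual
readings. The design is two-pass and non-iterative: the [20 %, 120 %]
plausibility exclusion is applied after personal-best estimation and never
triggers re-estimation. Sessions with no valid PEF get no state label but
still count toward engagement.

### States, normalization, thresholds

EXACERBATION = reduced PEF and impaired well-being; NORMAL = neither;
MILD = exactly one. The reference score is the median over all of a
participant's NORMAL sessions across the whole study (no baseline period,
no rolling update), defined only at ≥5 NORMAL sessions. The normalized
high-risk threshold defaults to the cohort mean of per-participant
(P₇₀ − P₅₀) gaps of NORMAL-session scores. An alternative formulation — the
70th percentile of pooled normalized NORMAL-session scores — is available
via `threshold_method="pooled_p70"`; the two are not equivalent and the
mean-gap form is the default because it is operationally explicit at the
participant level. Band assignment at exactly a threshold is HIGH.

### Risk ratios

RR = ratio of event prevalence (event / (event + reference state)) between
bands, the third state excluded from the table. CI and p-value use the Katz
log method; this exact formula reproduces all six published intervals from
their printed counts at two decimals, which is how the package validates
its reverse-engineered standard error. The unit of analysis is the session
(assessment for ACT), pooled without clustering adjustment, matching how
the published intervals were evidently computed; `cluster_bootstrap_ci`
offers a participant-resampling interval as an off-by-default extension.
Zero event cells raise rather than silently applying the optional 0.5
continuity correction. Reported intervals are 95 % with raw two-sided
p-values; no multiplicity adjustment is applied to outputs.

ACT linkage averages a participant's scores within ±14 days (inclusive) of
the assessment date; empty windows mark the assessment ineligible.

### Longitudinal metrics

Transitions pair consecutive QC-scored sessions of a participant regardless
of gap (QC-failed sessions are bridged over; `max_gap_days` restricts pairs
for sensitivity analysis). Engagement counts completed sessions whether or
not QC passed — it measures app use — with months as 30-day blocks anchored
at each participant's enrollment, keeping month 3 well defined for any
enrollment date. The cohort rules count completed sessions too: analysis
cohort ≥4 sessions, normalized cohort additionally ≥5 NORMAL-labeled
sessions.

## The synthetic cohort

The simulator emulates the study's data structure so every stage can be
exercised and calibrated without data access. Defaults are the study
conditions: 84 participants, 90 days, engagement mix 33/25/42 %.

* **Latent state.** A daily three-state Markov chain; the default transition
  matrix is `a·I + (1 − a)·1πᵀ` with π = (0.615, 0.278, 0.107) and
  stickiness a = 0.6, so the stationary law equals the target marginals
  exactly by construction and day-to-day autocorrelation is a single
  interpretable knob. The chain runs on all days; by default session
  missingness is independent of state (`exacerbation_missingness` enables
  state-dependent dropout for bias stress-tests). No published
  autocorrelation exists for these scores; the Markov-plus-noise form is a
  modeling choice.
* **Scores.** raw = participant baseline (N(61.7, 7.0²) between
  participants) + state shift (0 / +3 / +8) + day noise (SD 5.8) + sample
  noise (SD 5.6), clipped to [0, 100]. The two noise SDs were calibrated
  analytically: sample noise so that P(|s₁ − s₂| ≤ 10) ≈ 0.79 for dual-pass
  sessions, day noise so the within-participant NORMAL-session spread puts
  the derived normalized threshold near the published 3.7-point scale.
* **Elicitation.** Per-sample attempts fail independently with rates
  13.3 / 35.3 / 44.6 %. Real data show within-session failure correlation
  (fewer dual-pass sessions than independence implies); independence is kept
  for simplicity and still lands the overall scored fraction in the
  documented 66–78 % bracket.
* **Emissions given state.** MILD is a two-subtype mixture — PEF-dominant
  (relative level ~N(0.73, 0.06), mostly good well-being) and
  symptom-dominant (normal PEF, mostly impaired well-being) — because a
  mild event is defined by exactly one criterion; drawing both criteria
  independently given MILD would relabel too many latent-MILD sessions as
  exacerbations. NORMAL emits relative PEF ~N(0.95, 0.05), EXACERBATION
  ~N(0.70, 0.07) with mostly impaired well-being. Symptom, trigger,
  severity and rescue reports use state-graded categorical rates, monotone
  in severity except stress.
* **Engagement.** Monthly session counts are normal draws around the
  observed group trajectories; the high archetype is floored at 8
  sessions/month, making it structurally "consistent use" as the observed
  high group was (100 % month-3 consistent retention).
* **ACT.** score = 19 − 8·(trailing 30-day mean state weight, NORMAL=0,
  MILD=1, EXACERBATION=2) + participant offset N(0, 4²) + noise N(0, 2²),
  rounded and clamped to [5, 25]; only the total score is modeled.
  Submission probability depends on the engagement archetype (0.95 / 0.75 /
  0.45), yielding ~230 assessments per cohort with naturally occurring
  empty linkage windows.
* **Personal best** is a latent per-participant constant (N(400, 70²)
  L/min); the pipeline must recover it from data, enabling
  parameter-recovery tests (median relative error <5 % for participants
  with ≥20 NORMAL sessions).

What passing simulator-backed tests shows — and what it does not: the
pipeline recovers known inputs (null RR ≈ 1 with nominal CI coverage,
injected shifts produce the raw < normalized RR ordering, latent personal
bests and baselines are re-estimated accurately) under the generator's
assumptions. Real voice data have heavier tails, device and environment
effects, state-dependent missingness and within-session QC correlation that
the generator only partially represents; simulator agreement is therefore a
correctness check of the analysis code, not clinical validation.

## Numerical and design choices

* Percentile convention: linear interpolation everywhere; medians use the
  standard midpoint for even counts.
* Problem sizes for stochastic checks: the null-coverage study uses 200
  cohorts of 24 participants × 60 days, the effect-ordering study 50 seeds
  of 42 participants × 90 days — large enough that event cells rarely
  vanish and the asymptotic interval behaves, small enough to iterate on
  quickly.
* Ties and boundaries: band cut-points are HIGH-inclusive; the two-sample
  tolerance and the ±14-day ACT window are inclusive; zone boundaries
  follow the green ≥80 / yellow ≥50 / red <50 convention exactly.
* Degenerate inputs: empty PEF series, all-NORMAL cohorts, zero event
  cells, empty ACT windows and all-constant scores are all defined paths
  (error, omission or zero, as documented per function), not crashes.
* CSV IO is bit-stable: fixed column order, ISO-8601 timestamps, shortest
  float repr on write and exact round-trip parsing on read, so
  write → read → write is byte-identical and pipelines can be re-run from
  any intermediate artifact.

## Known limitations

Pooled (unclustered) intervals understate uncertainty under strong
within-participant correlation; the bootstrap extension exists but is not
the default because the default mirrors the published computation. The
state label depends on effort-dependent PEF and momentary self-report and
is itself an imperfect proxy for true respiratory state. The simulator's
published-table calibrations are aggregate; it does not model device or
acoustic-environment effects, item-level ACT responses, or notification-
driven usage dynamics.
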