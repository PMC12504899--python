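# vbmon — vocal-biomarker asthma monitoring analysis

`vbmon` implements the analysis pipeline of a prospective smartphone-based
asthma monitoring study, in which ~84 adults with persistent asthma used an
app daily for 90 days. Each app session collected two 6-second sustained-vowel
voice samples scored 0–100 by a respiratory-responsive vocal biomarker (RRVB;
treated here as an opaque score source), up to three peak expiratory flow
(PEF) readings, a three-level asthma well-being report, and symptom / trigger
/ rescue-medication questionnaires, with monthly Asthma Control Test (ACT)
totals on the side. The package is for biostatisticians and digital-health
researchers who need to reproduce, audit, or extend this style of
longitudinal biomarker validation.

## What it computes

**Session QC.** Each sample passes a real-time elicitation check (up to three
attempts; only pass/fail flags are consumed). Dual-pass sessions are accepted
only if the two scores agree within 10 points, and are averaged:
final = (s₁ + s₂)/2 iff |s₁ − s₂| ≤ 10.

**Relative PEF and zones.** Readings > 1000 L/min are dropped as errors; the
session maximum is kept. Personal best is max{v : v ≤ P₉₅(session maxima)}
(linear-interpolation percentile). Relative PEF = 100·v/PB, excluded outside
[20 %, 120 %], else zoned green (≥80 %), yellow (50–79 %), red (<50 %).

**Respiratory state.** Per session: EXACERBATION iff reduced PEF (yellow/red)
AND well-being not good/bad; NORMAL iff neither criterion; MILD iff exactly
one. The label never consults the biomarker score.

**Normalization.** Per participant with ≥5 NORMAL sessions, reference = median
NORMAL-session score; normalized score = final − reference. The normalized
high-risk threshold is the cohort mean of (P₇₀ − P₅₀) of each participant's
NORMAL-session scores.

**Prevalence risk ratio (the primary end point).** With a/b events/non-events
in the high band and c/d in the low band (the third state excluded):

    RR = (a/(a+b)) / (c/(c+d)),
    SE(ln RR) = √(1/a − 1/(a+b) + 1/c − 1/(c+d)),
    95% CI = exp(ln RR ± 1.96·SE)   (Katz log method)

with a two-sided normal p-value, applied to exacerbation and mild events
(raw and normalized bands: score ≥65, normalized ≥ derived threshold) and to
ACT control levels via 4-week-window time-averaged scores.

**Longitudinal metrics.** Between-session score-change transition matrices,
engagement groups (high ≥52 / medium 26–51 / low 1–25 total sessions),
month-3 retention, and descriptive symptom/trigger/rescue tables.

**Synthetic cohort.** `vbmon.simulate` generates datasets with the study's
structure — engagement archetypes, a daily latent Markov state process with
stationary marginals 61.5/27.8/10.7 %, state-shifted score emissions, PEF
around a latent personal best, and burden-linked ACT — for calibration and
parameter-recovery studies.

## Worked example

```bash
python examples/01_published_risk_tables.py
```

prints, from the study's published count tables alone:

```
State risk ratios (event vs normal function, high vs low band):
         raw EXACERBATION RR 2.15 (1.62-2.85), p=1.2e-07 [167/871 vs 57/638]
         raw MILD         RR 1.42 (1.23-1.65), p=1.93e-06 [390/1094 vs 194/775]
  normalized EXACERBATION RR 3.57 (2.70-4.73), p=4.93e-19 [124/506 vs 65/948]
  normalized MILD         RR 1.31 (1.13-1.53), p=0.000506 [186/568 vs 293/1176]
```

Reading the first line: 167 of 871 high-band sessions were exacerbations
versus 57 of 638 low-band sessions, so a high-band session is 2.15× as likely
to be an exacerbation; the interval excludes 1, i.e. the biomarker stratifies
momentary respiratory state. Normalizing to each participant's own baseline
raises the exacerbation RR to 3.57 by removing between-speaker variance
unrelated to respiration. The other examples simulate a cohort end-to-end
(`02`), walk through personal-best estimation (`03`), and print engagement
and transition tables (`04`).

The same machinery runs from the shell on CSV exports:

```bash
vbmon simulate --seed 1 --out data/
vbmon run --sessions data/sessions.csv --act data/act.csv \
          --participants data/participants.csv --out results/
```

which writes every intermediate table plus `report.md` and
`risk_tables.json`, each estimate accompanied by its underlying 2×2 cells.

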