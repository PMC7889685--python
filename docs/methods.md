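# Methods

`hypobench` evaluates continuous hypotension-prediction indices on
intraoperative mean-arterial-pressure (MAP) time series. This note records
the definitions, models and numerical conventions the package implements,
and the design choices made where more than one reasonable convention
exists.

## Definitions

All series live on a nominal 20-second grid; each sample represents the
interval `[t, t + 20 s)`, so *k* consecutive samples cover 20 *k* seconds
and a span of *n* samples is *n*/3 minutes of monitoring.

- **Hypotensive event** — a maximal run of consecutive samples with
  MAP ≤ 65 mmHg lasting at least 1 minute (≥ 3 samples). A single sample
  above the threshold ends a run; runs never bridge grid gaps larger than
  1.5 nominal intervals. The threshold is inclusive (65 counts as
  hypotensive). No merging of nearby events is performed.
- **Non-event segment** — a 30-minute window whose samples all exceed
  75 mmHg and whose covered intervals stay ≥ 20 minutes away from every
  event. Segments tile each qualifying region greedily left-to-right
  without overlap, avoiding pseudo-replication of negative material.
- **Positive / negative samples** — one positive per event, read at the
  grid sample nearest to (onset − t) for horizons t ∈ {5, 10, 15} min
  (ties snap earlier); skipped when the anchor precedes the recording,
  falls inside another event, or the index is missing. One negative per
  segment at its midpoint sample (deterministic and maximally distant
  from both edges); a seeded random-within-segment placement is available
  as a sensitivity flag.
- **Burden metrics** — area under 65 mmHg is rectangle-rule
  `Σ max(0, 65 − MAP) · Δt` (Δt in minutes) at sample resolution;
  trapezoids would interpolate ambiguously across the threshold. The
  time-weighted average (TWA) divides by monitoring time, where each
  sample contributes its full interval (so a 300-sample record spans
  exactly 100 minutes and burden is additive under record splits).
  The mean MAP during hypotension averages samples strictly below
  65 mmHg and is undefined (NaN) for never-hypotensive patients.

## ROC analysis

A sample is test-positive when its index is ≥ the threshold (so threshold
0 is all-positive); thresholds run over all distinct index values. AUC is
computed as the pairwise concordance probability with ties counted ½
(rank-based, O(n log n)); a trapezoidal route over the empirical curve is
kept as an independent cross-check and agrees to numerical precision. The
reported operating point minimizes |sensitivity − specificity| with exact
float comparison; ties break toward higher sensitivity, then the lower
threshold.

Uncertainty comes from a cluster bootstrap: whole patients are resampled
with replacement (default 2000 replicates), the statistic is recomputed on
each pooled resample, and the 95% interval is the asymptotic
`point ± 1.96 · SD(replicates)`. Patient-level resampling is essential —
samples within a patient share events and overlapping windows, and a
sample-level bootstrap would understate the variance severely. Replicates
on which a statistic is undefined (e.g. a resample without positives) are
redrawn and logged; more than 50% invalid draws aborts. In per-horizon
summaries the replicate sensitivity/specificity are re-read at each
replicate's own optimal threshold, mirroring a full re-run of the analysis
per resample.

## Forward-window event rates and PPV

Index samples are binned into decades 0–9 … 90–99 plus {100}; a sample
counts as an event sample when a detected event starts within the next 15
minutes, and its warning time is the gap to that onset. Two conventions
are flagged:

- samples inside an ongoing event are excluded from denominators by
  default (a forward *search* presumes prediction, not detection); the
  inclusive convention — under which an in-event sample is an event
  sample with zero warning time — is available via
  `include_in_event_samples`;
- samples whose forward window is truncated by the end of the recording
  are excluded by default (`require_full_window`), since a clipped window
  can only under-count; the cut requires `t ≤ t_end − 15 min − 2·Δt` so
  that any run starting inside the window has its first three samples
  observed.

Quantiles of warning time use the inverted-CDF (type-1) definition, which
keeps values on the 1/3-minute grid; their CIs reuse the patient
bootstrap via per-patient weighted quantiles. Empty bins are reported
with zero counts and NaN rates, never dropped.

PPV is computed over samples with index strictly above the alarm
threshold (default 85, matching the usual alarm setting): an event start
within 15 minutes makes a true positive; otherwise a rapid MAP rise
inside the window (> 5 mmHg in 20 s, or > 8 mmHg within 2 min, from a
baseline sample below 75 mmHg; the 20-s rule takes precedence) is
consulted. A rise preceded within 5 minutes by a charted intervention
(skin incision or an ephedrine/phenylephrine/epinephrine bolus) converts
the alarm to a true positive; an unexplained rise removes the alarm from
numerator and denominator. Everything else is a false positive, so
TP + FP + excluded always equals the alarm-sample count, and mitigation
can only raise the PPV. PPV is sample-level ("all data points above the
threshold"); an episode-level variant would require an alarm-grouping
rule the sample-level definition avoids.

The exclusion rule exists because real charts under-record the
interventions behind abrupt rises. A synthetic cohort's log is complete
by construction, so when the supplied log is empty every rise is known to
be spontaneous: `evaluate_ppv` then performs no reclassification or
exclusion and reduces exactly to the naive PPV. The lower-level
`ppv_at_threshold` applies the reclassify/exclude semantics to whatever
rises it is given, regardless.

## The synthetic cohort

MAP dynamics are a discrete-state Markov chain on a 1-mmHg grid
(40–120 mmHg) rather than a continuous diffusion, so that forward event
probabilities are exact by dynamic programming and calibration is a
provable property rather than an approximation. Per 20-s step the chain
mixes three components:

1. a discretized Gaussian walk (SD 1.4 mmHg) whose mean is
   state-dependent: ordinary reversion toward the 88-mmHg baseline (rate
   0.12/step) above 82 mmHg; a steady −0.3 mmHg/step drift in the
   65–82 mmHg "decline band" (an untreated downward trend progresses at
   about 1 mmHg/min — the prodrome that makes hypotension predictable
   minutes ahead); weak residual reversion (0.015/step) below the
   threshold;
2. abrupt downward drops of (5 + Geometric(mean 4)) mmHg whose per-step
   hazard ramps logistically from 0.0014 at baseline to 0.10 near the
   threshold (knee 69 mmHg, width 1.5): instability deepens as pressure
   falls, so declines cascade; below 65 mmHg the hazard reverts to its
   base value (active management prevents further cascading);
3. upward recovery jumps of (10 + Geometric(mean 6)) mmHg at hazard
   0.07/step below the threshold — these end events after a couple of
   minutes — and 0.015/step inside the band, aborting declines.

Monitoring durations are log-normal (median 202 min, log-SD 0.38, clipped
to 60–480 min). These defaults were set against the cohort shape the
package is meant to emulate: ≈ 60% of patients with at least one event,
median event duration 2–3 minutes, ≈ 1.5–2 events per patient, and they
are verified by simulation in the test suite.

**Ground truth.** Two exact forward probabilities are computed from the
transition matrix. `exact_forward_probability` is the plain augmented-chain
quantity — the probability that ≥ 3 consecutive below-threshold steps
occur within the horizon, with the consecutive counter absorbing at 3 —
and is validated against exhaustive path enumeration. What the
event-rate analysis measures for an eligible sample, however, is subtly
different: whether a detected event *starts* strictly within the window
(the run may accumulate its third sample after the window closes), given
that the sample itself is outside any event — which conditions on the
sample's own below-threshold run (length 0–2) dying before it reaches
three samples. `exact_event_start_probability` computes this
eligibility-conditioned quantity by a joint dynamic program over (MAP
state, run length, remaining window), and it is the probability the
generator stores as ground truth and scales into the index:
`index = clip(100 · (p + ε), 0, 100)` with Gaussian ε (SD 0.05 by
default; 0 gives a perfectly calibrated index). Both programs are
validated against path enumeration and Monte-Carlo rollouts.

**Interventions.** A simulated clinician notices MAP ≤ 65 mmHg after a
recognition delay and, with arm-dependent probability, administers a
vasopressor bolus that lifts MAP by ≈ N(12, 3²) mmHg over two steps,
with a 5-minute refractory period; each case also gets one charted skin
incision early on with a smaller rise. Unblinded clinicians (who see the
continuous trace) respond after ~80 s with probability 0.85; blinded ones
(intermittent cuff readings) after ~3 min with probability 0.5 — so the
unblinded arm accrues weakly less event time, and rises that trip the
rapid-rise detector are generated both with charted support and without
(spontaneous recoveries). Interventions push the realized trajectory off
the transition kernel, so kernel-derived ground truth is exact only when
the policy is disabled; `calibration_config()` (interventions off, noise
0) is therefore the configuration for identity-line studies, while the
default trial cohort keeps them on.

## What the generator does and does not emulate

It reproduces the statistical structure the evaluation machinery needs:
grid-sampled MAP with events of realistic frequency and duration, a
known-probability index spanning the 0–100 range, slow declines that make
5–15-minute warning possible, intervention-driven rapid rises, and two
trial arms with different treatment aggressiveness. It does not model
arterial waveforms, pharmacokinetics, demographic effect modification
(demographics are decorative), inter-patient heterogeneity of baselines,
or measurement artifacts. Passing tests therefore certify the
*evaluation methodology* — detection, sampling, ROC, calibration, PPV
accounting, bootstrap — not any claim about clinical performance of a
real index on real patients.

## Numerical and statistical caveats

- **Clustered samples.** Consecutive 20-s samples share 44/45 of their
  forward windows and usually the same event, so per-bin observed rates
  are means of strongly correlated indicators. The true sampling SD of a
  bin rate is ~2–5× the naive binomial SE (patient-bootstrap design
  effects measured in the tests). Identity-line checks in the suite use
  cluster-robust (patient-bootstrap) SEs; a binomial-SE band at desk
  scale is too narrow even for a perfectly calibrated index.
- **Bootstrap coverage.** With 50-patient cohorts and 200 replicates, the
  asymptotic-normal patient bootstrap covers the generative AUC ≈ 94% of
  the time (checked over 200 replicate cohorts in the suite; scaled from
  2000 replicates for runtime).
- **Problem sizes.** Tests use 300-patient calibration cohorts, a
  2000-patient reference simulation for the generative AUC, and 200×50
  patients for coverage; the acceptance script runs the full 305-patient
  two-arm pipeline with 2000 bootstrap replicates. These sizes keep every
  check a few seconds to a few minutes at desk scale.
- **Determinism.** All randomness flows from explicit seeds through
  `numpy.random.Generator`; identical config + seed reproduce cohorts,
  reports and rendered files byte-for-byte.
- **Degenerate inputs.** Single-class sample sets raise a named error;
  an all-tied index yields the 0.5-AUC fixed point; `n_boot = 1` is
  flagged degenerate rather than reporting a sham zero-width CI; empty
  event-rate bins render as "–".
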