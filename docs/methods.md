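# Methods

This note documents the models, parameter choices and numerical conventions
behind morphmaze, in the order a session flows: scheduling → strategy
auditing → the trial engine → the virtual subject → scoring → analysis.

## Schedule generation

Candidate sequences are i.i.d. fair Bernoulli draws over {L, R}; a candidate
is accepted only if it passes all three rejection rules, otherwise the whole
sequence is discarded and redrawn. Local repair (flipping an offending
trial) would bias transition statistics; whole-sequence rejection keeps the
accepted ensemble exactly uniform over the valid set.

Rules and defaults (`SequenceConstraints`):

| rule | default | rationale |
|---|---|---|
| `max_run_length` | 3 | runs of 4+ of one side encourage a side bias |
| `alternation_band` | [0.35, 0.45] | centres the accepted set on 40% switch / 60% stay transitions, counteracting the rodent alternation instinct |
| `max_side_imbalance` | 1 | counterbalance; exact balance for even block lengths |
| `max_rejections` | 100 000 | attempt budget before declaring the constraints infeasible |

The alternation rule is vacuous for single-trial sequences (no transitions
exist). With 24 transitions (25-trial blocks) the band admits exactly 9 or
10 switches; binomial weighting of those two counts puts the ensemble mean
near 41%, which is what the Monte-Carlo audit reports.

Acceptance probabilities under the defaults, by exhaustive enumeration for
small n and batch sampling otherwise, are ≈2.3% (n=10), ≈1% (n=15),
≈1.1e-3 (n=20) and ≈4e-4 (n=25) — expected attempts per block are therefore
40–2 500, far below `max_rejections`. Monte-Carlo paths
(`monte_carlo_audit`, `audit_generator`, the acceptance script) use a
vectorised batch sampler (`sample_accepted_matrix`) with the identical
candidate distribution and acceptance rule; the test suite verifies by
exhaustive enumeration (n ≤ 16) that its reachable set equals the
validator's accepted set.

Each block schedule records its seed and constraints, so any session's
randomisation can be replayed for audit.

## Strategy auditing

Six cue-ignoring policies are simulated with reward feedback only:
always-left, always-right, random, spontaneous alternation (complement of
own last choice), win-stay (return to last rewarded side) and win-shift
(avoid it). Conventions, configurable but fixed as defaults:

- First trial of a block: history-dependent policies choose uniformly at
  random (seeded). For *compliance* scoring the state is instead seeded
  from the animal's observed first response and its outcome.
- After unrewarded trials, win-stay/win-shift act on the most recent
  *rewarded* side; before any reward they fall back to repeating /
  complementing the last choice.
- State resets at block boundaries (compliance is block-seeded).

The generator is certified when no policy's mean percent correct over
10 000 schedules exceeds 60% at any session length in {10, 15, 20, 25}.
Under the default constraints every policy sits at ≈50% (win-shift a few
points *below* chance: the 60%-stay bias of the schedules punishes
shifting). A deliberately mis-calibrated generator forced towards
alternation is caught by the audit — win-shift phase-locks onto
near-alternating schedules after its first reward and exceeds 70%. Note
that spontaneous alternation itself averages exactly 50% on *any* schedule
when its first choice is uniform, by phase symmetry: it ignores feedback,
so its whole trace is determined by the first coin flip, and the two
half-traces are complementary. Win-stay and win-shift predictions are
complementary on every trial when driven by a shared choice/reward history,
so their compliance scores on one response stream always sum to 100%.

## Trial engine

Integer-millisecond simulated clock; no wall time. Event grammar per trial:
`NOSE_POKE` (t0) → `CUE_ON` (t0; payload: tone Hz, hint flag) → either
`SENSOR_LEFT/RIGHT` at t0+latency, with `FEEDER_DISPENSE` on a correct
non-hint-assisted choice, or `TIMEOUT` at t0+timeout — then `TRIAL_END`.
On hint trials `HINT_DISPENSE` (1 pellet at the cued side) fires once the
hint delay passes without a response; a response that merely follows the
hint earns nothing further, while a correct response *before* the hint earns
the full reward. Subject latencies ≥ timeout are clock losses: the trial
times out. The log is lossless — per-trial records (cue, choice, RT,
pellets, outcome, hint flag) are reconstructed from events alone, and the
suite asserts reconstruction equals the directly returned records.

Phase defaults:

| phase | trials/block | pellets (reward = threshold) | timeout (ms) | hints | central arm (cm) |
|---|---|---|---|---|---|
| 1 | 10 | 3 | 6000 | yes | 0 |
| 2 | 15 | 2 | 6000 | yes | 0 |
| 3–4 | 15 | 2 | 6000 | no | 0 |
| 5 | 15 | 2 | 6000 | no | 20 |
| 6 | 20 | 1 | 8000 | no | 50 |
| 7 | 25 | 1 | 10000 | no | 80 |

Four blocks per session throughout (so 40 trials/day in phase 1 up to 100
in phase 7). Only the phase-1 timeout (6 s) is protocol-fixed; the
phase-6/7 values scale with arm length and are declared stand-ins,
overridable per phase via YAML. Pellet counts per correct trial equal the
scoring thresholds — the phase-1 value (3) is protocol-fixed, the rest are
implied by the thresholds. Tone mapping defaults to 7 Hz→left, 14 Hz→right
and is configurable per subject for counterbalancing. The head-turn /
body-turn criteria of phases 2–4 are observational and cannot be detected
by maze sensors; they are modelled as the subject's pre-hint response with
ordinary correct/incorrect semantics (a documented limitation).

## Virtual subject

Per trial, in order: with probability `p_timeout` (0.02) no response; with
probability `p_strategy_lapse` (0.06) the choice comes from a lapse policy
(spontaneous alternation by default) instead of the cue; otherwise the cued
side is chosen with probability `p(day) = p_start + (p_asymptote −
p_start)(1 − e^(−λ·day))`, defaults p_start = 0.55, p_asymptote = 0.90,
λ = 0.065/day.

Latencies are log-normal, parameterised by their **mode** (μ = ln(mode) +
σ²) because modes are the natural summary of these unimodal, right-skewed
densities; σ is outcome-specific, 0.25 on correct vs 0.45 on incorrect
trials, encoding that a trained animal responds consistently when right
while errors mix fast strategy-driven guesses with slow distracted
responses. Default modes per phase: 800/900/1000/1100 ms (phases 1–4) and
1200/1500/1800 ms (phases 5–7), non-decreasing over the full task as the
maze grows. Draws at or beyond the timeout are resampled (up to 100 times,
then treated as a timeout), which truncates without piling mass at the
boundary. Inter-trial intervals are a separate log-normal (mode 2.5 s) used
only for timestamps.

The default training calendar is 42 days: 10 (phase 1), 4+4+4 (phases 2–4),
6+6 (phases 5–6), 8 (phase 7). λ and the calendar were chosen analytically
so that realized accuracy (including lapses and timeouts) averages in the
low 60s% across phase 1 and the low-to-mid 80s% across phase 7 — the
qualitative learning-curve shape the package emulates, rising from
near-chance to well-trained. Hint scheduling: 90% of trials on the first
two phase-1 days, 30% for the rest of phase 1, 15% in phase 2; the
cue-to-hint delay ramps linearly 0→2000 ms across phase-1 days.

What the simulator does *not* emulate: position/locomotion, motivational
drift within a session, inter-animal variability structure beyond seed
changes, or tail-triggered sensor artefacts (early-phase sensor
unreliability is handled as a scoring-side warning instead). Passing tests
therefore certify the pipeline's logic and statistics, not any claim about
real animals.

## Scoring

- REWARD: correct iff pellets ≥ threshold (3 / 2 / 1 by phase). Hint trials
  are included: a hint-assisted trial earns one pellet, below the early-phase
  thresholds, so it scores incorrect automatically — the animal was guided,
  not correct. (A correct choice *before* the hint earns the full reward and
  scores correct.)
- SENSOR: correct iff the first reward-area sensor crossed matches the cue;
  hint trials are *included* by default, reproducing the early-phase
  inflation of raw sensor curves. Sensor scores for phases 1–4 carry an
  `unreliable` flag and a warning (tail-triggered sensors).
- MANUAL-equivalent: choice = cue with hint trials excluded (the convention
  of hand scoring).
- Timed-out trials are incorrect under every method. All methods expose an
  `exclude_hints` switch.

Learning curves use a **trailing** 3-day rolling mean with partial windows
at the start (so curves begin on day 1); trailing was chosen over centred
because it is causal — a day's smoothed score depends only on completed
days.

## Analysis

Concordance regression: per-animal-per-phase mean scores of one method
against another (one scatter point per animal per phase). Exactly two OLS
fits: the first to compute residuals, whose **absolute values**' standard
deviation (ddof = 1) defines the outlier cut at 3 SD; the second through the
survivors is the reported fit. No iteration. If fewer than 3 points survive
the cut the fit is degenerate and raises. Slope/intercept/R²/p come from
`scipy.stats.linregress` (Wald t-test on the slope).

Reaction-time analysis covers phases 5–7 only (sensor readings are not
trustworthy earlier) and always excludes timeouts, whose latencies sit at
the ceiling by construction; the sample count per summary is therefore
exactly n_trials − n_timeouts. Modes come from the peak of a 100 ms-bin
histogram over [0, max RT] (bin width configurable; the estimator is
deliberately simple and stated because modes depend on it). IQR = q75 − q25
with linear interpolation between order statistics. Correct-vs-incorrect
distributions are compared with the two-sided two-sample Kolmogorov–Smirnov
test, exact null for min(n) < 30 and asymptotic otherwise; the KS statistic
is invariant under common monotone rescalings, which the suite checks.

## Problem sizes

Default verification runs use 10 000 schedules per session length for the
certification audit and calibration statistics, 20 000–30 000 samples for
the exhaustive-coverage checks (n ≤ 16), and 1 000–2 000 draws per class
for the behavioural distribution checks — sizes at which the binomial /
coupon-collector error of each check is far smaller than the margins being
asserted.

## Known limitations

- The exact alternation-rejection rule and the phase-2–7 timeout/hint
  parameters of the original apparatus are not public; the band [0.35,
  0.45] and the timeout/hint ramps are declared, configurable stand-ins.
- Sensor-score unreliability in phases 1–4 is flagged, not modelled.
- The concordance and RT statistics of real animals depend on real
  behavioural data; the package reproduces the *procedures* and verifies
  them on synthetic subjects with known ground truth.
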