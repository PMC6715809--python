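# morphmaze

Software toolkit for automated training of rodents on a two-alternative
forced-choice (2AFC) tone-to-place task in an incrementally growing maze.
It is aimed at behavioural-neuroscience labs that run operant maze tasks and
need (a) trial schedules a rat cannot game, (b) a deterministic trial engine
with an auditable event log, and (c) automated scoring that can replace
manual scoring — plus a virtual-subject simulator so the whole pipeline can
be tested without an animal.

## What it implements

**Constrained trial scheduling.** Each block's cued-side sequence is drawn
as i.i.d. fair coin flips and rejected wholesale unless it satisfies

- max same-side run ≤ 3 (prevents side bias),
- switch fraction within [0.35, 0.45] — about 40% alternation / 60%
  same-side transitions, actively discouraging the rodent's innate
  alternation strategy,
- side counterbalance `|#L − #R| ≤ 1`.

Whole-sequence rejection keeps the accepted ensemble uniform over the valid
set, so transition statistics are unbiased.

**Strategy auditing.** Six cue-ignoring null policies — always-left,
always-right, win-stay, win-shift, spontaneous alternation, random — are
simulated on thousands of generated schedules. The generator is *certified*
only if no policy's mean reward rate exceeds 60% at any session length
(10/15/20/25 trials). The same machinery scores recorded response streams
for per-block strategy *compliance*, seeded from the animal's first
response.

**Trial engine.** A discrete-event state machine for the 7-phase protocol
(4 blocks/session; hint trials with a ramped cue-to-hint delay in early
phases; phase-graded pellet rewards and timeouts), emitting a lossless
JSONL event log: nose-poke → cue tone → sensor crossing / timeout →
dispenses, with integer-millisecond timestamps.

**Virtual subject.** A stochastic rat whose accuracy follows
`p(day) = p_start + (p_asymptote − p_start)(1 − e^(−λ·day))`, with
log-normal reaction times parameterised by mode (growing with maze length),
narrower spread on correct than incorrect trials, occasional timeouts and
strategy lapses.

**Scoring & analysis.** Manual-equivalent, reward-threshold (3/2/1 pellets
by phase) and raw-sensor scoring; trailing 3-day rolling learning curves;
score-method concordance via two-pass regression (outliers > 3 SD of
absolute residuals removed, then refit); reaction-time modes, IQRs and
two-sample Kolmogorov–Smirnov comparisons for phases 5–7, with timed-out
trials excluded from the distributions.

## Worked example

```python
>>> from morphmaze import audit_generator, generate_sequence
>>> block = generate_sequence(n_trials=25, seed=7)
>>> "".join(s.letter for s in block.sides)
'LRRRLLRLLLRRRLLLRRRLRRLLL'
>>> block.stats.alternation_frac, block.stats.max_run
(0.4166666666666667, 3)
>>> audit = audit_generator(n_sequences=2000, seed=3)
>>> round(audit.max_mean_pct_correct, 2), audit.certified
(50.63, True)
```

The generated block has 10/24 switch transitions (0.417, inside the 40%
band) and no run longer than 3. The audit shows the best any null strategy
manages across 2,000 schedules per session length is ≈50.6% reward — chance
level — so above-chance performance on these schedules requires using the
cue. More narrative walk-throughs live in `examples/` (scheduling, strategy
audit, a 42-day simulated training course, scoring concordance, reaction
times); a thin CLI (`morphmaze schedule|strategy|simulate|synth|score|analyze`)
wraps the same functions for shell use.

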