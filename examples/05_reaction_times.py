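"""Reaction-time distributions for the full task (phases 5-7).

A trial's reaction time runs from the nose-poke to the first reward-area
sensor crossing; timed-out trials are scored incorrect but never enter the
distributions.  Correct trials should form a narrower distribution than
incorrect ones (which mix fast strategy-driven guesses with slow distracted
responses), and the mode should grow with maze length.
"""

from morphmaze import rt_compare, rt_summaries, simulate_training, trials_frame

sessions = simulate_training(animal_id="rat1", seed=42)
df = trials_frame(sessions)

summaries = rt_summaries(df)
print(f"{'phase':>6} {'outcome':>10} {'n':>5} {'mode_ms':>8} {'iqr_ms':>7}")
for s in summaries:
    label = s.phase if s.phase is not None else "5-7"
    print(f"{label!s:>6} {s.outcome_class:>10} {s.n_trials:>5} "
          f"{s.mode_ms:>8.0f} {s.iqr_ms:>7.0f}")

pooled = {s.outcome_class: s for s in summaries if s.phase is None}
stat, p = rt_compare(pooled["CORRECT"].samples, pooled["INCORRECT"].samples)
print(
    f"\npooled correct vs incorrect: KS statistic={stat:.3f}, p={p:.2e}"
    f"\ncorrect IQR {pooled['CORRECT'].iqr_ms:.0f} ms < incorrect IQR "
    f"{pooled['INCORRECT'].iqr_ms:.0f} ms: the trained animal responds"
    f"\nconsistently when it is right, and the modes climb from phase 5 to 7"
    f"\nas the maze's central arm lengthens."
)
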