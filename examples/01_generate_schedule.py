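"""Generate one constrained block schedule and inspect its statistics.

A block schedule is a pseudorandom left/right sequence with three rejection
rules: no side repeated more than 3 times in a row, a switch fraction inside
[0.35, 0.45] (about 40% alternation / 60% same-side transitions, to blunt
the rodent alternation instinct), and counterbalanced sides.
"""

from morphmaze import generate_sequence, monte_carlo_audit

block = generate_sequence(n_trials=25, seed=7)
print("schedule:", "".join(s.letter for s in block.sides))
s = block.stats
print(
    f"n={s.n}  left fraction={s.frac_left:.2f}  "
    f"switch fraction={s.alternation_frac:.3f}  longest run={s.max_run}"
)
print(f"L->R transitions={s.n_LR_transitions}  R->L transitions={s.n_RL_transitions}")

# Audit the generator itself: 2,000 schedules, aggregate statistics.
audit = monte_carlo_audit(2_000, 25, seed=1)
print(
    f"\nover 2,000 schedules: mean switch fraction "
    f"{100 * audit.mean_alternation_frac:.1f}% (target ~40%), "
    f"max run {audit.max_max_run} (hard cap 3), "
    f"mean left {100 * audit.mean_frac_left:.1f}% (counterbalanced)"
)
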