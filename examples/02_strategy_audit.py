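"""Certify the schedule generator against cue-ignoring strategies.

A rat could try to earn rewards without learning the tone-place association:
always go left, always right, alternate, return to the last rewarded side
(win-stay) or avoid it (win-shift).  The generator passes only if none of
these policies averages above 60% reward on its schedules.
"""

from morphmaze import audit_generator

audit = audit_generator(n_sequences=2_000, seed=3)
print(audit.table.pivot(index="policy", columns="session_length",
                        values="mean_pct_correct").round(2))
print(
    f"\nmax policy mean = {audit.max_mean_pct_correct:.2f}% "
    f"(ceiling {audit.ceiling:.0f}%) -> "
    + ("CERTIFIED" if audit.certified else "NOT certified")
)
print("Every cell near 50% means no shortcut strategy beats chance here;")
print("the animal must use the cue to exceed the ceiling.")
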