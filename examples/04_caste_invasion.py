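"""Simulate the invasion of a novel caste under colony-level selection.

A mutant offspring type appears with per-capita productivity p_m below the
residents' p_0 and random-walks through mutation-space.  Colonies carrying few
mutants are barely penalized (the colony buffers the variant — an evolutionary
capacitor), so some lineages survive long enough for the trait to cross its
threshold and become beneficial; those fix.  Starting with a larger mutant
fraction makes early extinction more likely, so fixation probability falls
with the initial fraction.
"""

from colonyopt import EvolutionConfig, simulate_invasion

for fraction in (0.01, 0.05, 0.2, 0.5):
    cfg = EvolutionConfig(
        replicates=500, seed=5, horizon=60, ceiling=300, initial_fraction=fraction
    )
    s = simulate_invasion(cfg)
    lo, hi = s.fixation_ci
    print(
        f"initial mutant fraction {fraction:>4}: "
        f"fixation probability {s.fixation_probability:.3f} [{lo:.3f}, {hi:.3f}]  "
        f"outcomes {dict(sorted(s.outcome_counts.items()))}"
    )

print()
print("fixation probability is non-increasing in the initial mutant fraction:")
print("a deleterious trait should first be expressed in only a few ants")
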