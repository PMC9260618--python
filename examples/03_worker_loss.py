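"""Kill 20% of one task's workers and watch the colony redistribute.

After the deaths the depleted task's marginal utility rises above the others'
(its MRS against every other task exceeds 1), so re-solving the equilibrium
shifts surviving workers into it.  Redistribution buffers the loss — the
re-solved productivity beats leaving survivors in place — but cannot undo it.
"""

from colonyopt import generate_fixture, redistribute_after_loss, solve_equilibrium

scenario = generate_fixture("monomorphic-3task", seed=7)
eq = solve_equilibrium(scenario.tasks, scenario.castes, scenario.colony.n, scenario.counts)

task = "task1"
loss = 0.2 * eq.eps_star[task]  # 20% of that task's workers die
report = redistribute_after_loss(scenario.tasks, scenario.castes, eq, task, loss)

print(f"{report.n_before - report.n_after:.0f} of {report.n_before:.0f} ants died on {task}")
print("MRS of the depleted task vs the others (before re-solving):")
for tid, m in report.M_before_redistribution.items():
    print(f"  M[{task},{tid}] = {m:.4f}  (> 1: {task} is now marginally more valuable)")
print(f"eps[{task}]: {eq.eps_star[task]:.4f} -> unredistributed "
      f"{report.eps_unredistributed[task]:.4f} -> re-solved "
      f"{report.eps_redistributed[task]:.4f}")
print(f"P original        = {report.P_original:.4f}")
print(f"P redistributed   = {report.P_redistributed:.4f}")
print(f"P unredistributed = {report.P_unredistributed:.4f}")
print("ordering P_original > P_redistributed > P_unredistributed: redistribution "
      "buffers the loss")
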