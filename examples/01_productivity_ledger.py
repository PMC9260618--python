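"""Build a small two-caste colony and read its productivity ledger.

Every ant either does importance-weighted work on its task (usefulness
u = k_tau * omega) or sits idle; its competence is usefulness minus the energy
the task costs it.  Gross productivity G sums competences (equivalently, task
utilities), subsistence E sums basal metabolic costs, and net productivity
P = G - E is what colony-level selection acts on, per capita.
"""

from colonyopt import CasteSpec, ColonyState, TaskSpec, colony_ledger

tasks = [
    TaskSpec(id="forage", k_tau=0.9, R=12.0, a=0.05, c=0.05),
    TaskSpec(id="defend", k_tau=0.6, R=8.0, a=0.04, c=0.10),
]
castes = [
    CasteSpec(id="minor", E_basal=0.2, omega={"forage": 1.5, "defend": 0.5}),
    CasteSpec(id="major", E_basal=0.5, omega={"forage": 0.8, "defend": 2.0}),
]
state = ColonyState(
    n=10,
    counts={"minor": 6, "major": 4},
    eps={"forage": 0.5, "defend": 0.3},
    assignment={"minor": {"forage": 5, "defend": 1}, "major": {"defend": 2}},
)

ledger = colony_ledger(tasks, castes, state)
print(ledger.to_frame().to_string(index=False))
print()
print(f"G = {ledger.G:.4f} (sum of task utilities = sum of ant competences)")
print(f"E = {ledger.E:.4f} (subsistence), P = G - E = {ledger.P:.4f}")
print(f"per-capita p = {ledger.p:.4f}  <- the maximand of colony-level selection")
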