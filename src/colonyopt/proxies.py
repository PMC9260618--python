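"""In-silico experimental procedures: biomass proxies and knockout colonies.

Biomass proxy.  In a monomorphic colony (identical workers) at the
division-of-labor equilibrium, the per-capita utility of every active task is
the same, so a task's share of colony biomass equals its share of gross
productivity: ``U_i / G = m_i / M``.  Weighing the ants on each task then
estimates the (otherwise unmeasurable) utility shares, and total biomass
proxies gross productivity itself.  The identity is exact when per-capita and
marginal utility are proportional with the same constant on every task — i.e.
for utility families homogeneous of a common degree in the task fraction (the
``power`` family).  For other concave families the report carries the measured
proportionality error instead of asserting exactness.

Knockout experiment.  Remove every member of one caste and re-solve the
equilibrium of the reduced colony.  The model predicts *task redistribution*:
some remaining caste shifts workers into the orphaned tasks, because those
tasks' marginal utilities rose when their performers vanished.  Absence of
redistribution despite a capable remaining caste would falsify the model;
absence because no remaining caste can perform the task is a capability
limit, not a falsification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .allocation import ACTIVE_TOL, AllocationResult, solve_equilibrium
from .errors import ConfigurationError, DegenerateColonyError
from .errors import ValidationError as CValidationError
from .model import CasteSpec, TaskSpec, evaluate_utility

__all__ = ["ProxyReport", "KnockoutReport", "biomass_proxy", "knockout_experiment"]


@dataclass
class ProxyReport:
    """Biomass-based estimate of task utility shares in a monomorphic colony."""

    per_task_biomass: Dict[str, float]
    total_biomass: float
    per_capita_utility: Dict[str, float]
    proxy_utilities: Dict[str, float]
    true_utilities: Dict[str, float]
    proportionality_error: float
    per_capita_spread: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, m in self.per_task_biomass.items():
            rows.append(
                {
                    "task": t,
                    "biomass": m,
                    "biomass_share": m / self.total_biomass if self.total_biomass else np.nan,
                    "U_true": self.true_utilities[t],
                    "U_proxy": self.proxy_utilities[t],
                    "per_capita_utility": self.per_capita_utility.get(t, np.nan),
                }
            )
        df = pd.DataFrame(rows)
        df["total_biomass"] = self.total_biomass
        df["proportionality_error"] = self.proportionality_error
        return df


def biomass_proxy(
    tasks: Sequence[TaskSpec],
    castes: Sequence[CasteSpec],
    equilibrium: AllocationResult,
) -> ProxyReport:
    """Estimate utility shares from biomass shares at a solved equilibrium.

    Refuses polymorphic colonies: the proxy is derived for identical workers
    only (with several morphs, mass per ant differs across tasks and the
    shares decouple).
    """
    workers = [c for c in castes if equilibrium.counts.get(c.id, 0.0) > 0]
    if len(workers) != 1:
        raise ConfigurationError(
            "biomass proxy requires a monomorphic colony (exactly one worker "
            f"caste); got {len(workers)} castes with members"
        )
    caste = workers[0]
    n = equilibrium.n
    total_biomass = n * caste.mass_per_ant

    task_by_id = {t.id: t for t in tasks}
    per_task_biomass = {
        tid: n * eps * caste.mass_per_ant for tid, eps in equilibrium.eps_star.items()
    }
    true_U = {
        tid: evaluate_utility(task_by_id[tid], n, eps)
        for tid, eps in equilibrium.eps_star.items()
    }
    G = sum(true_U.values())
    per_capita = {
        tid: true_U[tid] / (n * eps)
        for tid, eps in equilibrium.eps_star.items()
        if eps > ACTIVE_TOL
    }
    proxy_U = {
        tid: (per_task_biomass[tid] / total_biomass) * G for tid in per_task_biomass
    }

    active = [tid for tid in equilibrium.active_set]
    err = 0.0
    for tid in active:
        u_share = true_U[tid] / G
        m_share = per_task_biomass[tid] / total_biomass
        err = max(err, abs(u_share - m_share) / abs(u_share))
    spread = 0.0
    if per_capita:
        vals = np.array(list(per_capita.values()))
        spread = float((vals.max() - vals.min()) / max(1e-300, abs(vals).max()))
    return ProxyReport(
        per_task_biomass=per_task_biomass,
        total_biomass=total_biomass,
        per_capita_utility=per_capita,
        proxy_utilities=proxy_U,
        true_utilities=true_U,
        proportionality_error=err,
        per_capita_spread=spread,
    )


@dataclass
class KnockoutReport:
    """Outcome of removing one caste and re-solving the colony's equilibrium."""

    removed_caste: str
    orphaned_tasks: List[str]
    allocation_before: Dict[str, float]
    allocation_after: Dict[str, float]
    assignment_before: Dict[str, Dict[str, float]]
    assignment_after: Dict[str, Dict[str, float]]
    redistribution_detected: bool
    falsified_flag: bool
    reason: str
    P_before: float
    P_after: float
    result_after: AllocationResult

    def to_frame(self) -> pd.DataFrame:
        tasks = sorted(set(self.allocation_before) | set(self.allocation_after))
        rows = [
            {
                "task": t,
                "eps_before": self.allocation_before.get(t, 0.0),
                "eps_after": self.allocation_after.get(t, 0.0),
                "orphaned": t in self.orphaned_tasks,
            }
            for t in tasks
        ]
        df = pd.DataFrame(rows)
        df["removed_caste"] = self.removed_caste
        df["redistribution_detected"] = self.redistribution_detected
        df["falsified"] = self.falsified_flag
        df["P_before"] = self.P_before
        df["P_after"] = self.P_after
        return df


def knockout_experiment(
    tasks: Sequence[TaskSpec],
    castes: Sequence[CasteSpec],
    equilibrium: AllocationResult,
    caste_to_remove: str,
) -> KnockoutReport:
    """Remove all members of one caste and look for task redistribution.

    A task is *orphaned* if the removed caste staffed it at the original
    equilibrium.  Redistribution is detected iff some remaining caste's
    allocation to an orphaned task it can perform strictly increased in the
    re-solved equilibrium.  If no remaining caste can perform any orphaned
    task, the absence of redistribution is reported as a capability limit
    (``falsified_flag`` stays False).
    """
    caste_ids = [c.id for c in castes]
    if caste_to_remove not in caste_ids:
        raise CValidationError(f"unknown caste {caste_to_remove!r}")
    remaining = [c for c in castes if c.id != caste_to_remove]
    rem_with_members = [c for c in remaining if equilibrium.counts.get(c.id, 0.0) > 0]
    if not rem_with_members:
        raise DegenerateColonyError(
            f"removing caste {caste_to_remove!r} would leave the colony without workers"
        )

    removed_alloc = equilibrium.assignment.get(caste_to_remove, {})
    orphaned = [t for t, x in removed_alloc.items() if x > ACTIVE_TOL]

    n_removed = equilibrium.counts.get(caste_to_remove, 0.0)
    n_after = equilibrium.n - n_removed
    counts_after = {
        c.id: equilibrium.counts.get(c.id, 0.0) for c in remaining
    }
    after = solve_equilibrium(tasks, remaining, n_after, counts_after)

    capable_exists = {
        t: any(c.can_perform(t) for c in rem_with_members) for t in orphaned
    }
    detected = False
    for c in rem_with_members:
        before_c = equilibrium.assignment.get(c.id, {})
        after_c = after.assignment.get(c.id, {})
        for t in orphaned:
            if not c.can_perform(t):
                continue
            # compare worker counts, not fractions: n changed with the knockout
            w_before = equilibrium.n * before_c.get(t, 0.0)
            w_after = n_after * after_c.get(t, 0.0)
            if w_after > w_before + 1e-9 * max(1.0, w_before):
                detected = True

    if not orphaned:
        reason = "removed caste performed no task"
        falsified = False
    elif not any(capable_exists.values()):
        reason = "no capable caste remains for the orphaned tasks"
        falsified = False
    elif detected:
        reason = "remaining castes shifted workers into the orphaned tasks"
        falsified = False
    else:
        reason = (
            "capable castes remain but none increased work on the orphaned tasks"
        )
        falsified = True

    return KnockoutReport(
        removed_caste=caste_to_remove,
        orphaned_tasks=orphaned,
        allocation_before=dict(equilibrium.eps_star),
        allocation_after=dict(after.eps_star),
        assignment_before=dict(equilibrium.assignment),
        assignment_after=dict(after.assignment),
        redistribution_detected=detected,
        falsified_flag=falsified,
        reason=reason,
        P_before=equilibrium.P_star,
        P_after=after.P_star,
        result_after=after,
    )
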