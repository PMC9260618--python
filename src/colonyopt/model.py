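"""Primitive quantities of the colony-level optimization model.

A mature, monogynous colony of size ``n`` performs a set of tasks.  Each task
``j`` has an importance constant ``k_tau`` in (0, 1] and a *utility function*
``U_j(n, eps_j)`` giving the net energetic value (work done or saved, minus the
energy the performers spend on the task) of allocating a fraction ``eps_j`` of
the colony to it.  Utility obeys the law of diminishing marginal utility: past
a threshold, ``U_j`` is strictly concave in ``eps_j``, because the resources
around a colony are finite and extra performers crowd each other.

At the level of individual ants the same ledger is kept additively: the
usefulness of ant ``i`` on task ``j`` is ``u_ij = k_tau_j * omega_ij`` when the
ant performs the task (``omega_ij`` is its work rate) and 0 otherwise, the task
energy it spends is ``e_ij``, its *competence* is ``c_i = sum_j (u_ij - e_ij)``,
and the colony's *gross productivity* is

    G = sum_i c_i = sum_j U_j          (double-accounting identity)

Net productivity subtracts subsistence, ``P = G - E`` with ``E = sum_i E_i``
the summed basal metabolic costs, and per-capita productivity ``p = P / n`` is
the maximand of colony-level selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ConfigurationError, UndefinedQuantityError
from .errors import ValidationError as CValidationError

__all__ = [
    "TaskSpec",
    "CasteSpec",
    "ColonyState",
    "ProductivityReport",
    "UTILITY_FAMILIES",
    "evaluate_utility",
    "evaluate_utility_array",
    "marginal_utility",
    "utility_curvature",
    "is_strictly_concave",
    "colony_ledger",
    "reproductive_usefulness",
    "largest_remainder_counts",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class TaskSpec(BaseModel):
    """A colony task with its importance constant and utility-family parameters.

    Parameters of the utility family (all rates are per time step):

    - ``R``: work capacity of the task, energy units (the asymptotic gross
      value of fully staffing the task, before importance weighting).
    - ``a``: saturation rate per unit of allocated workforce (for the
      ``power`` family, the concavity exponent in (0, 1)).
    - ``c``: energy a performing ant spends on the task per step.
    - ``threshold_n0``: worker count past which concavity is asserted
      (0 for the shipped families, which are concave everywhere; the
      ``logistic`` family is concave past its inflection).
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    id: str
    k_tau: float = Field(gt=0.0, le=1.0, description="task importance constant in (0, 1]")
    family: str = "saturating"
    R: float = Field(default=1.0, ge=0.0)
    a: float = Field(default=1.0, gt=0.0)
    c: float = Field(default=0.0, ge=0.0)
    threshold_n0: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _known_family(self) -> "TaskSpec":
        if self.family not in UTILITY_FAMILIES:
            raise ConfigurationError(
                f"unknown utility family {self.family!r} for task {self.id!r}; "
                f"available: {sorted(UTILITY_FAMILIES)}"
            )
        return self


class CasteSpec(BaseModel):
    """A worker caste: per-ant energetics and per-task work rates.

    ``omega[task_id]`` is the work rate of one ant of this caste on that task;
    a task is *performable* by the caste iff it appears in ``performs`` (which
    defaults to the tasks with a positive omega).  ``E_basal`` is the
    subsistence energy one ant consumes per step while idle; ``mass_per_ant``
    feeds the biomass proxies.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    id: str
    E_basal: float = Field(default=0.0, ge=0.0)
    omega: Dict[str, float] = Field(default_factory=dict)
    performs: Optional[frozenset] = None
    mass_per_ant: float = Field(default=1.0, gt=0.0)

    @model_validator(mode="after")
    def _validate(self) -> "CasteSpec":
        for task, w in self.omega.items():
            if w < 0:
                raise CValidationError(
                    f"caste {self.id!r}: work rate omega[{task!r}] = {w} must be >= 0"
                )
        if self.performs is None:
            object.__setattr__(
                self, "performs", frozenset(t for t, w in self.omega.items() if w > 0)
            )
        else:
            object.__setattr__(self, "performs", frozenset(self.performs))
        return self

    def can_perform(self, task_id: str) -> bool:
        return task_id in self.performs


class ColonyState(BaseModel):
    """Snapshot of a colony: size, caste counts and task fractions.

    ``eps[task_id]`` is the fraction of the colony performing the task; since
    an ant performs at most one task at a time, ``sum(eps) <= 1``.  Integer
    per-task worker counts are derived with largest-remainder rounding so they
    sum consistently.  ``assignment[caste][task]`` optionally pins how many
    ants of each caste perform each task (used by the ledger); if omitted the
    ledger fills tasks from capable castes in declaration order.
    """

    model_config = ConfigDict(extra="forbid")

    n: int = Field(ge=0)
    counts: Dict[str, int] = Field(default_factory=dict)
    eps: Dict[str, float] = Field(default_factory=dict)
    assignment: Optional[Dict[str, Dict[str, int]]] = None

    @model_validator(mode="after")
    def _validate(self) -> "ColonyState":
        for t, e in self.eps.items():
            if not (0.0 <= e <= 1.0):
                raise CValidationError(f"eps[{t!r}] = {e} must lie in [0, 1]")
        total = sum(self.eps.values())
        if total > 1.0 + 1e-9:
            raise CValidationError(
                f"sum of task fractions = {total:.6g} exceeds 1: an ant can "
                "perform at most one task at a time"
            )
        for cid, k in self.counts.items():
            if k < 0:
                raise CValidationError(f"counts[{cid!r}] = {k} must be >= 0")
        if self.counts and sum(self.counts.values()) != self.n:
            raise CValidationError(
                f"caste counts sum to {sum(self.counts.values())} but n = {self.n}"
            )
        return self

    @property
    def task_counts(self) -> Dict[str, int]:
        """Integer workers per task, ``n_i = round(n * eps_i)`` corrected by
        largest remainder so the total equals ``round(n * sum(eps))``."""
        tasks = list(self.eps)
        counts = largest_remainder_counts(
            [self.n * self.eps[t] for t in tasks], int(round(self.n * sum(self.eps.values())))
        )
        return dict(zip(tasks, counts))


def largest_remainder_counts(quotas: Sequence[float], total: int) -> List[int]:
    """Round non-negative quotas to integers summing to ``total``."""
    floors = [int(math.floor(q)) for q in quotas]
    short = total - sum(floors)
    if short > 0:
        order = np.argsort([f - q for q, f in zip(quotas, floors)])  # largest remainder first
        for idx in order[:short]:
            floors[idx] += 1
    elif short < 0:  # rare: all quotas integral but total smaller
        order = np.argsort([q - f for q, f in zip(quotas, floors)])
        for idx in order[: -short]:
            floors[idx] = max(0, floors[idx] - 1)
    return floors


# ---------------------------------------------------------------------------
# Utility families
# ---------------------------------------------------------------------------
#
# Each family maps (task, n, eps) -> U and provides the analytic first and
# second derivatives with respect to eps.  "Strict concavity" is evaluated for
# the task's actual parameters, since e.g. the saturating-cost family is
# concave only while the work term dominates the cost term.


def _sat_value(t: TaskSpec, n: float, eps):
    x = t.a * n * np.asarray(eps, dtype=float)
    return t.k_tau * t.R * -np.expm1(-x) - t.c * n * np.asarray(eps, dtype=float)


def _sat_mu(t: TaskSpec, n: float, eps: float) -> float:
    return t.k_tau * t.R * t.a * n * math.exp(-t.a * n * eps) - t.c * n


def _sat_d2(t: TaskSpec, n: float, eps: float) -> float:
    return -t.k_tau * t.R * (t.a * n) ** 2 * math.exp(-t.a * n * eps)


def _satcost_value(t: TaskSpec, n: float, eps):
    # Task energy saturates at the same rate as the work term, so the total
    # marginal utility tends to 0 as the task saturates.
    amp = t.k_tau * t.R - t.c / t.a
    return amp * -np.expm1(-t.a * n * np.asarray(eps, dtype=float))


def _satcost_mu(t: TaskSpec, n: float, eps: float) -> float:
    return (t.k_tau * t.R * t.a - t.c) * n * math.exp(-t.a * n * eps)


def _satcost_d2(t: TaskSpec, n: float, eps: float) -> float:
    return -(t.k_tau * t.R * t.a - t.c) * t.a * n * n * math.exp(-t.a * n * eps)


def _logistic_value(t: TaskSpec, n: float, eps):
    from scipy.special import expit

    eps = np.asarray(eps, dtype=float)
    x0 = float(t.threshold_n0)
    work = t.k_tau * t.R * (expit(t.a * (n * eps - x0)) - expit(-t.a * x0))
    return work - t.c * n * eps


def _logistic_mu(t: TaskSpec, n: float, eps: float) -> float:
    from scipy.special import expit

    s = expit(t.a * (n * eps - float(t.threshold_n0)))
    return t.k_tau * t.R * t.a * n * float(s * (1.0 - s)) - t.c * n


def _logistic_d2(t: TaskSpec, n: float, eps: float) -> float:
    from scipy.special import expit

    s = float(expit(t.a * (n * eps - float(t.threshold_n0))))
    return t.k_tau * t.R * (t.a * n) ** 2 * s * (1.0 - s) * (1.0 - 2.0 * s)


def _power_value(t: TaskSpec, n: float, eps):
    eps = np.asarray(eps, dtype=float)
    return t.k_tau * t.R * eps**t.a - t.c * n * eps


def _power_mu(t: TaskSpec, n: float, eps: float) -> float:
    if eps == 0.0:
        return math.inf if t.a < 1.0 else t.k_tau * t.R - t.c * n
    return t.k_tau * t.R * t.a * eps ** (t.a - 1.0) - t.c * n


def _power_d2(t: TaskSpec, n: float, eps: float) -> float:
    if eps == 0.0:
        return -math.inf if t.a < 1.0 else 0.0
    return t.k_tau * t.R * t.a * (t.a - 1.0) * eps ** (t.a - 2.0)


def _linear_value(t: TaskSpec, n: float, eps):
    eps = np.asarray(eps, dtype=float)
    return t.k_tau * t.R * eps - t.c * n * eps


def _linear_mu(t: TaskSpec, n: float, eps: float) -> float:
    return t.k_tau * t.R - t.c * n


def _linear_d2(t: TaskSpec, n: float, eps: float) -> float:
    return 0.0


@dataclass(frozen=True)
class UtilityFamily:
    name: str
    value: callable
    mu: callable
    d2: callable
    concave_check: callable  # TaskSpec -> bool, strict concavity for eps > threshold


UTILITY_FAMILIES: Dict[str, UtilityFamily] = {
    "saturating": UtilityFamily(
        "saturating", _sat_value, _sat_mu, _sat_d2, lambda t: t.k_tau * t.R > 0
    ),
    "saturating_satcost": UtilityFamily(
        "saturating_satcost",
        _satcost_value,
        _satcost_mu,
        _satcost_d2,
        lambda t: t.k_tau * t.R * t.a > t.c,
    ),
    "logistic": UtilityFamily(
        # concave only past the inflection worker count threshold_n0
        "logistic",
        _logistic_value,
        _logistic_mu,
        _logistic_d2,
        lambda t: False,
    ),
    "power": UtilityFamily(
        "power", _power_value, _power_mu, _power_d2, lambda t: t.R > 0 and 0 < t.a < 1
    ),
    "linear": UtilityFamily("linear", _linear_value, _linear_mu, _linear_d2, lambda t: False),
}


def _family(task: TaskSpec) -> UtilityFamily:
    try:
        return UTILITY_FAMILIES[task.family]
    except KeyError:  # pragma: no cover - TaskSpec validation catches this first
        raise ConfigurationError(f"unknown utility family {task.family!r}")


def is_strictly_concave(task: TaskSpec) -> bool:
    """Whether the task's utility is strictly concave in eps over all of [0, 1]."""
    return bool(_family(task).concave_check(task))


def evaluate_utility(task: TaskSpec, n: float, eps: float) -> float:
    """Utility ``U_j(n, eps)`` of allocating fraction ``eps`` of ``n`` ants to the task.

    Energy units per step.  ``U(·, 0) = 0`` for every family: no performers,
    no work and no task cost.
    """
    if n < 0:
        raise CValidationError(f"colony size n = {n} must be >= 0")
    if not (0.0 <= eps <= 1.0):
        raise CValidationError(f"task fraction eps = {eps} must lie in [0, 1]")
    if eps == 0.0:
        return 0.0
    return float(_family(task).value(task, n, eps))


def evaluate_utility_array(task: TaskSpec, n: float, eps) -> np.ndarray:
    """Vectorized :func:`evaluate_utility` over an array of task fractions."""
    eps = np.asarray(eps, dtype=float)
    if n < 0:
        raise CValidationError(f"colony size n = {n} must be >= 0")
    if np.any(eps < 0) or np.any(eps > 1):
        raise CValidationError("all task fractions must lie in [0, 1]")
    out = np.asarray(_family(task).value(task, n, eps), dtype=float)
    return np.where(eps == 0.0, 0.0, out)


def marginal_utility(
    task: TaskSpec,
    n: float,
    eps: float,
    delta_eps: Optional[float] = None,
) -> Tuple[Optional[float], float]:
    """Fractional and infinitesimal marginal utility of a task.

    Returns ``(nu, mu)`` where ``nu = [U(eps + delta_eps) - U(eps)] / delta_eps``
    (``None`` when ``delta_eps`` is not given) and ``mu`` is the analytic
    derivative of the family with respect to eps.  ``nu -> mu`` as
    ``delta_eps -> 0``.
    """
    mu = float(_family(task).mu(task, n, eps))
    nu = None
    if delta_eps is not None:
        if delta_eps <= 0:
            raise CValidationError(f"delta_eps = {delta_eps} must be > 0 for nu")
        if eps + delta_eps > 1.0 + 1e-12:
            raise CValidationError(
                f"eps + delta_eps = {eps + delta_eps:.6g} exceeds 1"
            )
        hi = evaluate_utility(task, n, min(1.0, eps + delta_eps))
        nu = (hi - evaluate_utility(task, n, eps)) / delta_eps
    return nu, mu


def utility_curvature(task: TaskSpec, n: float, eps: float) -> float:
    """Analytic second derivative of U with respect to eps (diagnostic)."""
    return float(_family(task).d2(task, n, eps))


# ---------------------------------------------------------------------------
# Reproductive usefulness
# ---------------------------------------------------------------------------


def reproductive_usefulness(offspring_focal: float, offspring_queen: float) -> float:
    """Usefulness of a focal ant at the reproduction task: offspring of the
    focal ant over offspring of the foundress queen.  The foundress herself
    scores 1; a sterile worker scores 0."""
    if offspring_queen <= 0:
        raise UndefinedQuantityError(
            "reproductive usefulness undefined: queen produced no offspring"
        )
    if offspring_focal < 0:
        raise CValidationError("offspring counts must be >= 0")
    return offspring_focal / offspring_queen


# ---------------------------------------------------------------------------
# The productivity ledger
# ---------------------------------------------------------------------------


@dataclass
class ProductivityReport:
    """Full per-ant and per-task productivity ledger of one colony state.

    ``u`` and ``e`` are (n_ants x n_tasks) matrices of usefulness and task
    energy; ``competence`` the per-ant row sums of ``u - e``; ``U`` the
    per-task column sums; ``mu`` the analytic marginal utility of each task's
    configured family at the current state.  ``G = sum(U) = sum(competence)``,
    ``E`` is total subsistence, ``P = G - E``.
    """

    tasks: List[str]
    castes: List[str]
    ant_caste: np.ndarray  # caste index per ant row
    u: np.ndarray
    e: np.ndarray
    competence: np.ndarray
    U: Dict[str, float]
    mu: Dict[str, float]
    G: float
    E: float
    P: float
    n: int
    groups: pd.DataFrame = field(repr=False, default=None)

    @property
    def p(self) -> float:
        """Per-capita net productivity P/n; undefined for an empty colony."""
        if self.n == 0:
            raise UndefinedQuantityError(
                "per-capita productivity undefined for an empty colony (n = 0)"
            )
        return self.P / self.n

    def to_frame(self) -> pd.DataFrame:
        """Ledger as one row per (caste, task) group plus a totals row."""
        rows = self.groups.copy()
        total = {
            "caste": "TOTAL",
            "task": "",
            "count": self.n,
            "u_per_ant": np.nan,
            "e_per_ant": np.nan,
            "contribution": self.G,
            "G": self.G,
            "E": self.E,
            "P": self.P,
            "p": self.P / self.n if self.n else np.nan,
        }
        return pd.concat([rows, pd.DataFrame([total])], ignore_index=True)


def _default_assignment(
    tasks: Sequence[TaskSpec],
    castes: Sequence[CasteSpec],
    state: ColonyState,
) -> Dict[str, Dict[str, int]]:
    """Fill each task's worker count from capable castes in declaration order."""
    remaining = {
        c.id: state.counts.get(c.id, state.n if len(castes) == 1 else 0) for c in castes
    }
    task_counts = state.task_counts
    assignment: Dict[str, Dict[str, int]] = {c.id: {} for c in castes}
    for t in tasks:
        need = task_counts.get(t.id, 0)
        for c in castes:
            if need == 0:
                break
            if not c.can_perform(t.id):
                continue
            take = min(need, remaining[c.id])
            if take > 0:
                assignment[c.id][t.id] = take
                remaining[c.id] -= take
                need -= take
        if need > 0:
            raise CValidationError(
                f"cannot staff task {t.id!r}: {need} workers short of the "
                f"requested fraction given caste capabilities"
            )
    return assignment


def colony_ledger(
    tasks: Sequence[TaskSpec],
    castes: Sequence[CasteSpec],
    state: ColonyState,
) -> ProductivityReport:
    """Compute the full productivity ledger of a colony state.

    Per performing ant, usefulness is ``u_ij = k_tau_j * omega_cj`` (caste work
    rate weighted by task importance) and task energy is the task's configured
    per-performer rate ``c_j``; non-performers contribute zeros.  The
    double-accounting identity ``G = sum_j U_j = sum_i c_i`` holds exactly by
    construction.  Subsistence ``E`` is the sum of basal rates over all ants
    and is therefore exactly linear in ``n`` at fixed caste proportions.
    """
    caste_by_id = {c.id: c for c in castes}
    task_by_id = {t.id: t for t in tasks}
    assignment = state.assignment or _default_assignment(tasks, castes, state)

    # expand assignment into per-ant rows, grouped caste-by-caste
    task_ids = [t.id for t in tasks]
    caste_ids = [c.id for c in castes]
    t_index = {tid: j for j, tid in enumerate(task_ids)}

    n = state.n
    u = np.zeros((n, len(task_ids)))
    e = np.zeros((n, len(task_ids)))
    ant_caste = np.full(n, -1, dtype=int)

    group_rows = []
    row = 0
    for ci, cid in enumerate(caste_ids):
        caste = caste_by_id[cid]
        c_total = state.counts.get(cid, n if len(castes) == 1 else 0)
        assigned = assignment.get(cid, {})
        used = 0
        for tid, k in assigned.items():
            if k == 0:
                continue
            task = task_by_id[tid]
            if not caste.can_perform(tid):
                raise CValidationError(
                    f"assignment puts caste {cid!r} on task {tid!r} it cannot perform"
                )
            j = t_index[tid]
            u_per = task.k_tau * caste.omega.get(tid, 0.0)
            e_per = task.c
            u[row : row + k, j] = u_per
            e[row : row + k, j] = e_per
            ant_caste[row : row + k] = ci
            row += k
            used += k
            group_rows.append(
                {
                    "caste": cid,
                    "task": tid,
                    "count": k,
                    "u_per_ant": u_per,
                    "e_per_ant": e_per,
                    "contribution": k * (u_per - e_per),
                }
            )
        idle = c_total - used
        if idle < 0:
            raise CValidationError(
                f"assignment allocates {used} ants of caste {cid!r} but only "
                f"{c_total} exist"
            )
        if idle > 0:
            ant_caste[row : row + idle] = ci
            row += idle
            group_rows.append(
                {
                    "caste": cid,
                    "task": "(idle)",
                    "count": idle,
                    "u_per_ant": 0.0,
                    "e_per_ant": 0.0,
                    "contribution": 0.0,
                }
            )

    net = u - e
    competence = net.sum(axis=1)
    U = {tid: float(net[:, j].sum()) for tid, j in t_index.items()}
    # G is the sum of task utilities, in that exact summation order, so the
    # double-accounting identity G == sum(U.values()) holds bitwise; the
    # per-ant route sum(competence) agrees to machine precision
    G = float(sum(U.values()))
    E = sum(
        caste_by_id[cid].E_basal * state.counts.get(cid, n if len(castes) == 1 else 0)
        for cid in caste_ids
    )
    P = G - E
    mu = {
        t.id: marginal_utility(t, n, state.eps.get(t.id, 0.0))[1] if n > 0 else 0.0
        for t in tasks
    }

    groups = pd.DataFrame(
        group_rows,
        columns=["caste", "task", "count", "u_per_ant", "e_per_ant", "contribution"],
    )
    return ProductivityReport(
        tasks=task_ids,
        castes=caste_ids,
        ant_caste=ant_caste,
        u=u,
        e=e,
        competence=competence,
        U=U,
        mu=mu,
        G=G,
        E=float(E),
        P=float(P),
        n=n,
        groups=groups,
    )
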