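"""Division-of-labor equilibrium and worker-loss redistribution.

The colony allocates fractions ``eps_j`` of its ``n`` members to tasks so as
to maximize net productivity ``P = sum_j U_j(n, eps_j) - E`` subject to
``eps_j >= 0`` and ``sum_j eps_j <= 1`` (an ant performs at most one task at a
time).  With strictly concave utilities the optimum is characterized by equal
marginal utilities on all active tasks — equivalently, a marginal rate of
substitution ``M_ij = mu_i / mu_j = 1`` for every active pair — with the
Karush-Kuhn-Tucker extension for corners: either the constraint binds and all
active ``mu_j`` equal a common multiplier ``lambda >= 0``, or there is idle
slack and all active ``mu_j = 0``; inactive tasks have ``mu_j(0) <= lambda``.

The solver maximizes ``P`` directly (SLSQP with the analytic gradient) and
then polishes the solution by inverting the marginal-utility conditions on the
active set it found, so the equal-marginal certificate holds to near machine
precision.  Colonies with several castes are handled as a transportation-type
concave program: each caste distributes its share of the colony over the tasks
it can perform, and the utility of a task depends on the total fraction
allocated to it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import ConfigurationError, UndefinedQuantityError
from .errors import ValidationError as CValidationError
from .model import (
    CasteSpec,
    ColonyState,
    TaskSpec,
    evaluate_utility,
    evaluate_utility_array,
    is_strictly_concave,
    marginal_utility,
)

__all__ = [
    "AllocationResult",
    "PerturbationReport",
    "mrs",
    "solve_equilibrium",
    "grid_oracle",
    "redistribute_after_loss",
    "subsistence",
]

ACTIVE_TOL = 1e-9  # eps below this counts as an inactive task
MRS_TOL = 1e-4  # relative tolerance for |M_ij - 1| at a certified equilibrium


def subsistence(castes: Sequence[CasteSpec], counts: Mapping[str, float]) -> float:
    """Total subsistence energy E = sum of basal rates over all ants."""
    return float(sum(c.E_basal * counts.get(c.id, 0.0) for c in castes))


def mrs(task_i: TaskSpec, task_j: TaskSpec, state: ColonyState) -> float:
    """Marginal rate of substitution ``M_ij = mu_i / mu_j`` at the given state.

    ``M_ij`` says that moving one ant onto task i is ``M_ij`` times as useful
    as moving it onto task j.  Undefined when task j is saturated (mu_j = 0).
    """
    _, mu_i = marginal_utility(task_i, state.n, state.eps.get(task_i.id, 0.0))
    _, mu_j = marginal_utility(task_j, state.n, state.eps.get(task_j.id, 0.0))
    if mu_j == 0.0:
        raise UndefinedQuantityError(
            f"MRS undefined: task {task_j.id!r} has zero marginal utility"
        )
    return mu_i / mu_j


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass
class AllocationResult:
    """Solved division-of-labor equilibrium.

    ``eps_star`` are total task fractions, ``assignment`` the per-caste split
    (fractions of the whole colony), ``lambda_common`` the common marginal
    utility on active tasks (0 with idle slack; None if castes' capability
    sets give different multipliers), ``M`` the MRS matrix over tasks with
    nonzero denominators, ``P_star`` net productivity at the optimum.
    ``oracle_gap`` is filled by callers that also run :func:`grid_oracle`.
    """

    tasks: List[str]
    eps_star: Dict[str, float]
    assignment: Dict[str, Dict[str, float]]
    lambda_common: Optional[float]
    active_set: List[str]
    M: pd.DataFrame
    P_star: float
    G_star: float
    E_total: float
    n: float
    counts: Dict[str, float]
    converged: bool
    kkt_violation: float
    oracle_gap: Optional[float] = None
    slack: float = 0.0  # 1 - sum(eps): idle fraction of the colony

    @property
    def mu_star(self) -> Dict[str, float]:
        return dict(self._mu)

    _mu: Dict[str, float] = field(default_factory=dict, repr=False)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.tasks:
            rows.append(
                {
                    "task": t,
                    "eps_star": self.eps_star[t],
                    "mu": self._mu.get(t, np.nan),
                    "active": t in self.active_set,
                }
            )
        rows.append(
            {
                "task": "TOTAL",
                "eps_star": sum(self.eps_star.values()),
                "mu": self.lambda_common if self.lambda_common is not None else np.nan,
                "active": True,
            }
        )
        df = pd.DataFrame(rows)
        df["P_star"] = self.P_star
        return df


@dataclass
class PerturbationReport:
    """Effect of losing a fraction of one task's workers (worker death).

    ``delta_eps`` is the absolute decrement of the task fraction (workers are
    gone, not idle: ``n`` shrinks by ``n * delta_eps`` and subsistence with
    it).  ``M_before_redistribution`` holds the MRS of the depleted task
    against every other active task, evaluated on the reduced colony before
    re-solving — strictly greater than 1 for strictly concave utilities, which
    is what drives redistribution.  The productivity ordering
    ``P_original >= P_redistributed >= P_unredistributed`` quantifies how much
    the re-allocation buffers the loss.
    """

    task_id: str
    delta_eps: float
    n_before: float
    n_after: float
    M_before_redistribution: Dict[str, float]
    P_original: float
    P_unredistributed: float
    P_redistributed: float
    eps_unredistributed: Dict[str, float]
    eps_redistributed: Dict[str, float]
    allocation_after: AllocationResult

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.eps_redistributed:
            rows.append(
                {
                    "task": t,
                    "eps_unredistributed": self.eps_unredistributed.get(t, 0.0),
                    "eps_redistributed": self.eps_redistributed.get(t, 0.0),
                    "M_vs_depleted": self.M_before_redistribution.get(t, np.nan),
                }
            )
        df = pd.DataFrame(rows)
        df["P_original"] = self.P_original
        df["P_unredistributed"] = self.P_unredistributed
        df["P_redistributed"] = self.P_redistributed
        df["delta_eps"] = self.delta_eps
        df["depleted_task"] = self.task_id
        return df


# ---------------------------------------------------------------------------
# Solver internals
# ---------------------------------------------------------------------------


def _mu_at(task: TaskSpec, n: float, eps: float) -> float:
    return marginal_utility(task, n, eps)[1]


def _invert_mu(task: TaskSpec, n: float, lam: float, base: float, cap: float) -> float:
    """Largest x in [0, cap] with mu(base + x) >= lam, for strictly decreasing mu."""
    if cap <= 0:
        return 0.0
    lo, hi = base, min(1.0, base + cap)
    if _mu_at(task, n, lo if lo > 0 else min(1e-14, hi)) <= lam:
        # power-family mu diverges at exactly 0; probe just inside
        if _mu_at(task, n, lo) <= lam:
            return 0.0
    if _mu_at(task, n, hi) >= lam:
        return hi - base
    x = optimize.brentq(
        lambda e: _mu_at(task, n, e) - lam, max(lo, 1e-300), hi, xtol=1e-15, rtol=8.9e-16
    )
    return max(0.0, x - base)


def _water_fill(
    tasks: Sequence[TaskSpec],
    n: float,
    budget: float,
    base: np.ndarray,
    capable: np.ndarray,
) -> np.ndarray:
    """Allocate ``budget`` across capable tasks to equalize marginal utilities.

    Solves max sum_j U_j(n, base_j + x_j) s.t. x >= 0, sum x <= budget,
    base_j + x_j <= 1, exactly (up to root-finding tolerance), exploiting that
    each mu_j is strictly decreasing.
    """
    idx = [j for j in range(len(tasks)) if capable[j]]
    if not idx or budget <= 0:
        return np.zeros(len(tasks))

    def alloc(lam: float) -> np.ndarray:
        x = np.zeros(len(tasks))
        for j in idx:
            x[j] = _invert_mu(tasks[j], n, lam, base[j], min(budget, 1.0 - base[j]))
        return x

    x0 = alloc(0.0)
    if x0.sum() <= budget + 1e-15:
        return x0
    # bracket the multiplier: h(lam) = sum(alloc) - budget is decreasing
    lam_hi = 1.0
    while alloc(lam_hi).sum() > budget:
        lam_hi *= 4.0
        if lam_hi > 1e18:  # pragma: no cover - pathological parameters
            break
    lam = optimize.brentq(
        lambda L: alloc(L).sum() - budget, 0.0, lam_hi, xtol=1e-15, rtol=8.9e-16
    )
    x = alloc(lam)
    # distribute any residual root-finding slack, keeping sum(x) == budget exactly
    resid = budget - x.sum()
    if resid > 0:
        j_best = max(idx, key=lambda j: _mu_at(tasks[j], n, base[j] + x[j]))
        x[j_best] = min(x[j_best] + resid, 1.0 - base[j_best])
    elif resid < 0:
        j_big = max(idx, key=lambda j: x[j])
        x[j_big] = max(0.0, x[j_big] + resid)
    return x


def _implicit_caste(tasks: Sequence[TaskSpec]) -> CasteSpec:
    return CasteSpec(id="worker", omega={t.id: 1.0 for t in tasks})


def solve_equilibrium(
    tasks: Sequence[TaskSpec],
    castes: Optional[Sequence[CasteSpec]] = None,
    n: float = 100,
    counts: Optional[Mapping[str, float]] = None,
    *,
    use_direct: bool = True,
    max_sweeps: int = 500,
    mrs_tol: float = MRS_TOL,
) -> AllocationResult:
    """Solve the constrained division-of-labor optimum.

    Maximizes net productivity over feasible task fractions.  For strictly
    concave families the result carries a KKT certificate: on the active set
    all marginal utilities equal a common ``lambda`` (so all pairwise MRS are
    1), and no inactive task could profitably be activated.  Refuses
    non-concave families, for which a stationary point need not be the global
    optimum.
    """
    if not tasks:
        raise CValidationError("at least one task is required")
    if n <= 0:
        raise CValidationError(f"colony size n = {n} must be > 0")
    for t in tasks:
        if not is_strictly_concave(t):
            raise ConfigurationError(
                f"task {t.id!r} uses family {t.family!r} with parameters that are "
                "not strictly concave on [0, 1]; the solver cannot certify a "
                "global optimum — use a concave family or check the "
                "configuration (threshold families are concave only past "
                "their threshold)"
            )

    if castes is None:
        castes = [_implicit_caste(tasks)]
    castes = list(castes)
    if counts is None:
        if len(castes) == 1:
            counts = {castes[0].id: float(n)}
        else:
            raise CValidationError("caste counts are required for multi-caste colonies")
    counts = {c.id: float(counts.get(c.id, 0.0)) for c in castes}
    if abs(sum(counts.values()) - n) > 1e-6 * max(1.0, n):
        raise CValidationError(
            f"caste counts sum to {sum(counts.values()):.6g} but n = {n:.6g}"
        )

    shares = np.array([counts[c.id] / n for c in castes])
    # a task no caste can perform simply stays at eps = 0
    capable = np.array(
        [[c.can_perform(t.id) for t in tasks] for c in castes], dtype=bool
    )
    n_castes, n_tasks = capable.shape
    pairs = [(ci, tj) for ci in range(n_castes) for tj in range(n_tasks) if capable[ci, tj]]

    def eps_from_x(xmat: np.ndarray) -> np.ndarray:
        return xmat.sum(axis=0)

    # --- stage 1: direct maximization (skipped when a family's mu diverges at 0,
    # where gradient-based steps are ill-posed; the polish stage is exact there)
    diverging = any(
        t.family == "power" and t.a < 1.0 for t in tasks
    )
    xmat = np.zeros((n_castes, n_tasks))
    for ci in range(n_castes):
        k = capable[ci].sum()
        if k:
            xmat[ci, capable[ci]] = shares[ci] / k * 0.999

    if use_direct and pairs and not diverging:
        x0 = np.array([xmat[ci, tj] for ci, tj in pairs])

        def negP(xv: np.ndarray) -> float:
            xm = np.zeros((n_castes, n_tasks))
            for k, (ci, tj) in enumerate(pairs):
                xm[ci, tj] = xv[k]
            eps = np.clip(eps_from_x(xm), 0.0, 1.0)
            return -sum(
                evaluate_utility(t, n, float(eps[j])) for j, t in enumerate(tasks)
            )

        def negP_grad(xv: np.ndarray) -> np.ndarray:
            xm = np.zeros((n_castes, n_tasks))
            for k, (ci, tj) in enumerate(pairs):
                xm[ci, tj] = xv[k]
            eps = np.clip(eps_from_x(xm), 0.0, 1.0)
            mu = [_mu_at(t, n, float(eps[j])) for j, t in enumerate(tasks)]
            return -np.array([mu[tj] for _, tj in pairs])

        cons = []
        for ci in range(n_castes):
            members = [k for k, (c2, _) in enumerate(pairs) if c2 == ci]
            if not members:
                continue
            jac_row = np.zeros(len(pairs))
            jac_row[members] = -1.0
            cons.append(
                {
                    "type": "ineq",
                    "fun": (lambda xv, m=members, s=shares[ci]: s - xv[m].sum()),
                    "jac": (lambda xv, row=jac_row: row),
                }
            )
        res = optimize.minimize(
            negP,
            x0,
            jac=negP_grad,
            bounds=[(0.0, 1.0)] * len(pairs),
            constraints=cons,
            method="SLSQP",
            options={"maxiter": 500, "ftol": 1e-14},
        )
        if res.success:
            for k, (ci, tj) in enumerate(pairs):
                xmat[ci, tj] = max(0.0, float(res.x[k]))

    # --- stage 2: block-coordinate equal-marginal polish (exact per caste)
    for _ in range(max_sweeps):
        delta = 0.0
        for ci in range(n_castes):
            base = eps_from_x(xmat) - xmat[ci]
            new_row = _water_fill(tasks, n, shares[ci], base, capable[ci])
            delta = max(delta, float(np.abs(new_row - xmat[ci]).max(initial=0.0)))
            xmat[ci] = new_row
        if delta < 1e-14:
            break

    eps = eps_from_x(xmat)
    overshoot = eps.sum() - 1.0
    if overshoot > 0:  # float-sum safety: the constraint holds exactly in output
        jj = int(np.argmax(eps))
        ci = int(np.argmax(xmat[:, jj]))
        xmat[ci, jj] = max(0.0, xmat[ci, jj] - overshoot)
        eps = eps_from_x(xmat)
    E_total = subsistence(castes, counts)
    G_star = float(
        sum(evaluate_utility(t, n, float(eps[j])) for j, t in enumerate(tasks))
    )
    P_star = G_star - E_total

    mu = {t.id: _mu_at(t, n, float(eps[j])) for j, t in enumerate(tasks)}
    task_ids = [t.id for t in tasks]
    eps_star = {tid: float(eps[j]) for j, tid in enumerate(task_ids)}
    active = [tid for tid in task_ids if eps_star[tid] > ACTIVE_TOL]

    slack = 1.0 - sum(eps_star.values())
    # common multiplier: with idle colony-wide slack every caste's lambda is 0
    active_mu = np.array([mu[tid] for tid in active]) if active else np.array([])
    lambda_common: Optional[float]
    if not active:
        lambda_common = 0.0
    else:
        spread = float(active_mu.max() - active_mu.min())
        scale = max(1.0, float(np.abs(active_mu).max()))
        lambda_common = float(active_mu.mean()) if spread <= mrs_tol * scale else None

    # MRS matrix over tasks (NaN where the denominator task is saturated)
    M = pd.DataFrame(index=task_ids, columns=task_ids, dtype=float)
    for ti in task_ids:
        for tj in task_ids:
            M.loc[ti, tj] = mu[ti] / mu[tj] if mu[tj] != 0.0 else np.nan

    # KKT violation: active-pair MRS deviation and profitable inactive tasks
    viol = 0.0
    if len(active) > 1:
        scale = max(1.0, float(np.abs(active_mu).max()))
        viol = float(active_mu.max() - active_mu.min()) / scale
    lam_ref = float(active_mu.mean()) if active else 0.0
    for ci in range(n_castes):
        caste_tasks = [j for j in range(n_tasks) if capable[ci, j]]
        caste_active = [j for j in caste_tasks if xmat[ci, j] > ACTIVE_TOL]
        caste_slack = shares[ci] - xmat[ci].sum()
        lam_c = (
            0.0
            if caste_slack > ACTIVE_TOL
            else (
                max(mu[task_ids[j]] for j in caste_active) if caste_active else math.inf
            )
        )
        if not math.isfinite(lam_c):
            continue
        for j in caste_tasks:
            if xmat[ci, j] <= ACTIVE_TOL:
                excess = mu[task_ids[j]] - lam_c
                viol = max(viol, excess / max(1.0, abs(lam_c)))

    converged = viol <= mrs_tol and sum(eps_star.values()) <= 1.0 + 1e-9

    assignment = {
        castes[ci].id: {
            task_ids[j]: float(xmat[ci, j]) for j in range(n_tasks) if xmat[ci, j] > 0
        }
        for ci in range(n_castes)
    }
    result = AllocationResult(
        tasks=task_ids,
        eps_star=eps_star,
        assignment=assignment,
        lambda_common=lambda_common,
        active_set=active,
        M=M,
        P_star=P_star,
        G_star=G_star,
        E_total=E_total,
        n=float(n),
        counts=counts,
        converged=converged,
        kkt_violation=viol,
        slack=slack,
    )
    result._mu = mu
    return result


# ---------------------------------------------------------------------------
# Exhaustive grid oracle (small task counts)
# ---------------------------------------------------------------------------


def grid_oracle(
    tasks: Sequence[TaskSpec],
    n: float,
    E_total: float = 0.0,
    step: float = 0.01,
    refine_steps: Sequence[float] = (0.001, 0.0001),
    ) -> Tuple[float, np.ndarray]:
    """Exhaustive lattice search for the constrained optimum (<= 3 tasks).

    Enumerates all eps vectors on a ``step`` lattice with sum <= 1, then
    refines on successively finer lattices in a one-cell window around the
    best point of the previous level.  Independent of the solver; used as its
    oracle.
    """
    eta = len(tasks)
    if eta > 3:
        raise CValidationError("grid oracle is exhaustive only up to 3 tasks")

    def evaluate(grid: np.ndarray) -> Tuple[float, np.ndarray]:
        total = np.zeros(grid.shape[0])
        for j, t in enumerate(tasks):
            total += evaluate_utility_array(t, n, grid[:, j])
        best = int(np.argmax(total))
        return float(total[best]) - E_total, grid[best]

    def lattice(lo: np.ndarray, hi: np.ndarray, h: float) -> np.ndarray:
        axes = [np.arange(lo[j], hi[j] + h / 2, h) for j in range(eta)]
        pts = np.stack([g.ravel() for g in np.meshgrid(*axes, indexing="ij")], axis=1)
        pts = np.clip(pts, 0.0, 1.0)
        return pts[pts.sum(axis=1) <= 1.0 + 1e-12]

    best_val, best_pt = evaluate(lattice(np.zeros(eta), np.ones(eta), step))
    prev = step
    for h in refine_steps:
        window = lattice(
            np.maximum(best_pt - prev, 0.0), np.minimum(best_pt + prev, 1.0), h
        )
        val, pt = evaluate(window)
        if val > best_val:
            best_val, best_pt = val, pt
        prev = h
    return best_val, best_pt


# ---------------------------------------------------------------------------
# Worker-loss redistribution
# ---------------------------------------------------------------------------


def redistribute_after_loss(
    tasks: Sequence[TaskSpec],
    castes: Optional[Sequence[CasteSpec]],
    equilibrium: AllocationResult,
    task_id: str,
    delta_eps: float,
) -> PerturbationReport:
    """Kill a fraction of one task's workers and study the colony's response.

    ``delta_eps`` is the decrement of the task fraction (in units of the
    original colony): ``n * delta_eps`` workers of the depleted task die and
    are removed from the colony.  Reports (1) the MRS of the depleted task
    against the others before re-solving (> 1 under strict concavity: the
    depleted task became marginally more valuable), (2) the re-solved
    allocation on the reduced workforce, and (3) the productivity ordering
    ``P_original >= P_redistributed >= P_unredistributed`` — redistribution
    buffers, but cannot undo, the loss.
    """
    if castes is None:
        castes = [_implicit_caste(tasks)]
    castes = list(castes)
    task_by_id = {t.id: t for t in tasks}
    if task_id not in task_by_id:
        raise CValidationError(f"unknown task {task_id!r}")
    eps0 = equilibrium.eps_star.get(task_id, 0.0)
    if not (0.0 <= delta_eps <= eps0 + 1e-12):
        raise CValidationError(
            f"delta_eps = {delta_eps} must lie in [0, eps_i0 = {eps0:.6g}]"
        )
    delta_eps = min(delta_eps, eps0)

    n0 = equilibrium.n
    dead = n0 * delta_eps
    n1 = n0 - dead

    # deaths fall on the castes staffing the depleted task, proportionally
    counts1 = dict(equilibrium.counts)
    share_i = {
        cid: alloc.get(task_id, 0.0) for cid, alloc in equilibrium.assignment.items()
    }
    tot_i = sum(share_i.values())
    for cid, s in share_i.items():
        if tot_i > 0:
            counts1[cid] = counts1[cid] - dead * (s / tot_i)
    E1 = subsistence(castes, counts1)

    # unredistributed state: survivors keep their tasks; fractions rescale to n1
    eps_unred = {}
    for tid, e in equilibrium.eps_star.items():
        workers = n0 * e - (dead if tid == task_id else 0.0)
        eps_unred[tid] = min(1.0, workers / n1) if n1 > 0 else 0.0

    P_original = equilibrium.P_star
    if n1 <= 0:
        raise CValidationError("perturbation kills the entire colony")
    P_unred = (
        sum(evaluate_utility(task_by_id[tid], n1, e) for tid, e in eps_unred.items())
        - E1
    )

    mu1 = {tid: _mu_at(task_by_id[tid], n1, e) for tid, e in eps_unred.items()}
    M_before = {
        tid: (mu1[task_id] / mu1[tid] if mu1[tid] != 0.0 else np.nan)
        for tid in eps_unred
        if tid != task_id and equilibrium.eps_star.get(tid, 0.0) > ACTIVE_TOL
    }

    realloc = solve_equilibrium(tasks, castes, n1, counts1)

    return PerturbationReport(
        task_id=task_id,
        delta_eps=delta_eps,
        n_before=n0,
        n_after=n1,
        M_before_redistribution=M_before,
        P_original=P_original,
        P_unredistributed=float(P_unred),
        P_redistributed=realloc.P_star,
        eps_unredistributed=eps_unred,
        eps_redistributed=dict(realloc.eps_star),
        allocation_after=realloc,
    )
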