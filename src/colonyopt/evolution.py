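"""Colony-level selection and the invasion of a novel caste.

A queen's genotype specifies which offspring types she produces and in what
fractions; both are heritable and subject to small mutations, so a novel type
(an "intercaste", the hypothesized precursor of a new caste) appears with some
per-capita productivity ``p_m`` that is typically below the resident workers'
``p_0``.  Because colony fitness ``w`` (daughter colonies per generation)
increases with per-capita net productivity

    P = m * p_m + (n - m) * p_0,        dP/dm = p_m - p_0,

a colony carrying ``m`` low-productivity mutants pays only a diluted price:
the rest of the colony buffers the variant from negative selection — the
colony acts as an evolutionary capacitor.  As the trait random-walks through
mutation-space it may become beneficial (``p_m >= p_0``) after a waiting time
``theta_minus``; the lineage survives if it neither goes extinct while fitness
is still declining (Case 1) nor fails to recover to ``w >= 1`` afterwards
(Case 2).  Once beneficial, the mutant count should grow — but only until
``p_m = p_0``, the predicted interior optimum ``m*``.

Time is discrete (non-overlapping colony generations: colonies reproduce, then
die).  All randomness flows from one seeded generator per replicate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Literal, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.special import expit
from scipy.stats import binomtest

from .errors import ConfigurationError
from .errors import ValidationError as CValidationError

__all__ = [
    "QueenGenotype",
    "FitnessMap",
    "SigmoidLandscape",
    "PiecewiseLinearLandscape",
    "EvolutionConfig",
    "Lineage",
    "InvasionResult",
    "InvasionSummary",
    "PhaseReport",
    "productivity_split",
    "productivity_rate",
    "fitness_from_productivity",
    "step_lineage",
    "simulate_invasion",
    "phase_analysis",
    "hill_climb_mutant_count",
]

TRAJECTORY_COLUMNS = ["step", "n_colonies", "m", "p_m", "p_0", "P", "w"]


# ---------------------------------------------------------------------------
# Productivity split (two ant types)
# ---------------------------------------------------------------------------


def productivity_split(
    m: float, n: float, p_m: float, p_0: float
) -> Tuple[float, float]:
    """Net productivity of a colony with ``m`` mutants among ``n`` ants, and
    its derivative with respect to the mutant count.

    ``P = m*p_m + (n-m)*p_0`` and ``dP/dm = p_m - p_0``: while the mutant type
    is less productive than a resident worker, every extra mutant costs the
    colony exactly the productivity gap.
    """
    if not (0 <= m <= n):
        raise CValidationError(f"mutant count m = {m} must lie in [0, n = {n}]")
    return m * p_m + (n - m) * p_0, p_m - p_0


def productivity_rate(
    m: float, dm_dt: float, p_m: float, dpm_dt: float, p_0: float
) -> float:
    """Time derivative of the split productivity:
    ``dP/dt = m * dp_m/dt + dm/dt * (p_m - p_0)``."""
    return m * dpm_dt + dm_dt * (p_m - p_0)


# ---------------------------------------------------------------------------
# Fitness maps and p_m landscapes
# ---------------------------------------------------------------------------


class FitnessMap(BaseModel):
    """Map from per-capita net productivity to colony fitness (daughter
    colonies per generation).  Strictly increasing in ``p`` wherever positive;
    clamped below at 0 (a colony cannot produce a negative number of
    daughters)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    form: Literal["linear", "exponential"] = "linear"
    w0: float = Field(default=1.0, ge=0.0, description="basal fitness at p = p_ref")
    beta: float = Field(default=1.0, description="fitness sensitivity per energy unit")
    p_ref: float = 0.0

    @model_validator(mode="after")
    def _increasing(self) -> "FitnessMap":
        if self.beta <= 0:
            raise ConfigurationError(
                f"fitness map must be strictly increasing in p: beta = {self.beta} <= 0"
            )
        return self

    def __call__(self, p):
        d = np.asarray(p, dtype=float) - self.p_ref
        if self.form == "linear":
            return np.maximum(0.0, self.w0 + self.beta * d)
        return self.w0 * np.exp(self.beta * d)


def fitness_from_productivity(p: float, fitness_map: FitnessMap) -> float:
    """Colony fitness at per-capita productivity ``p`` under the given map."""
    return float(fitness_map(p))


class SigmoidLandscape(BaseModel):
    """Mutant per-capita productivity as a sigmoid in the scalar trait: the
    trait becomes beneficial once it random-walks past a threshold."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    family: Literal["sigmoid"] = "sigmoid"
    p_lo: float
    p_hi: float
    rate: float = Field(gt=0.0)
    x0: float = 0.0

    def __call__(self, x):
        return self.p_lo + (self.p_hi - self.p_lo) * expit(
            self.rate * (np.asarray(x, dtype=float) - self.x0)
        )


class PiecewiseLinearLandscape(BaseModel):
    """Mutant per-capita productivity interpolated from (x, p_m) knots."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    family: Literal["piecewise-linear"] = "piecewise-linear"
    xs: List[float]
    ps: List[float]

    @model_validator(mode="after")
    def _check(self) -> "PiecewiseLinearLandscape":
        if len(self.xs) != len(self.ps) or len(self.xs) < 2:
            raise ConfigurationError("piecewise-linear landscape needs >= 2 (x, p) knots")
        if list(self.xs) != sorted(self.xs):
            raise ConfigurationError("landscape knots must be sorted in x")
        return self

    def __call__(self, x):
        return np.interp(np.asarray(x, dtype=float), self.xs, self.ps)


Landscape = Union[SigmoidLandscape, PiecewiseLinearLandscape]


class QueenGenotype(BaseModel):
    """Heritable reproductive strategy of a queen: which offspring types she
    produces, the fraction of each, and the mutant type's position in
    mutation-space."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    offspring_types: List[str] = Field(default_factory=lambda: ["worker", "mutant"])
    fractions: Dict[str, float] = Field(default_factory=dict)
    trait_x: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "QueenGenotype":
        for k, v in self.fractions.items():
            if v < 0:
                raise CValidationError(f"offspring fraction {k!r} = {v} must be >= 0")
        tot = sum(self.fractions.values())
        if self.fractions and abs(tot - 1.0) > 1e-9:
            raise CValidationError(f"offspring fractions sum to {tot:.6g}, not 1")
        return self

    @property
    def mutant_fraction(self) -> float:
        return self.fractions.get("mutant", 0.0)


class EvolutionConfig(BaseModel):
    """Study conditions for an invasion simulation."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    n: int = Field(default=100, gt=0, description="colony size (ants)")
    p0: float = Field(default=2.0, description="resident per-capita productivity")
    landscape: Landscape = Field(
        default_factory=lambda: SigmoidLandscape(p_lo=0.5, p_hi=3.5, rate=1.5, x0=1.0),
        discriminator="family",
    )
    initial_trait_x: float = -1.0
    initial_fraction: float = Field(default=0.05, ge=0.0, le=1.0)
    mutation_sigma: float = Field(default=0.25, ge=0.0)
    fraction_sigma: float = Field(
        default=0.01, ge=0.0, description="mutation kernel of the offspring fraction"
    )
    fitness_map: FitnessMap = Field(
        default_factory=lambda: FitnessMap(form="linear", w0=1.4, beta=0.6, p_ref=2.0)
    )
    replicates: int = Field(default=1, ge=1)
    seed: int = 0
    mode: Literal["stochastic", "deterministic"] = "stochastic"
    horizon: int = Field(default=100, ge=1)
    ceiling: int = Field(default=10_000, ge=1, description="lineage population cap")


# ---------------------------------------------------------------------------
# Lineage stepping
# ---------------------------------------------------------------------------


@dataclass
class Lineage:
    """All living colonies of one founding lineage, as parallel arrays."""

    trait_x: np.ndarray
    fraction: np.ndarray

    @property
    def size(self) -> int:
        return self.trait_x.shape[0]

    @classmethod
    def founder(cls, config: EvolutionConfig) -> "Lineage":
        return cls(
            trait_x=np.array([config.initial_trait_x], dtype=float),
            fraction=np.array([config.initial_fraction], dtype=float),
        )


def _colony_stats(lineage: Lineage, config: EvolutionConfig):
    p_m = np.asarray(config.landscape(lineage.trait_x), dtype=float)
    m = np.round(lineage.fraction * config.n)
    P = m * p_m + (config.n - m) * config.p0
    p = P / config.n
    w = np.asarray(config.fitness_map(p), dtype=float)
    return m, p_m, P, w


def step_lineage(
    lineage: Lineage, config: EvolutionConfig, rng: np.random.Generator
) -> Lineage:
    """Advance one colony generation: every colony produces daughters and dies.

    Daughter counts are Poisson(w) (``round(w)`` in deterministic mode); each
    daughter's trait takes a Gaussian step of scale ``mutation_sigma`` and her
    mutant offspring fraction a Gaussian step of scale ``fraction_sigma``
    clipped to [0, 1].  If the lineage exceeds the population ceiling it is
    uniformly thinned (seed-controlled).
    """
    if lineage.size == 0:
        raise CValidationError("cannot step an empty lineage")
    _, _, _, w = _colony_stats(lineage, config)
    if config.mode == "deterministic":
        offspring = np.round(w).astype(int)
    else:
        offspring = rng.poisson(w)
    total = int(offspring.sum())
    if total == 0:
        return Lineage(np.empty(0), np.empty(0))
    parent = np.repeat(np.arange(lineage.size), offspring)
    trait = lineage.trait_x[parent]
    frac = lineage.fraction[parent]
    if config.mutation_sigma > 0:
        trait = trait + rng.normal(0.0, config.mutation_sigma, total)
    if config.fraction_sigma > 0:
        frac = np.clip(frac + rng.normal(0.0, config.fraction_sigma, total), 0.0, 1.0)
    if total > config.ceiling:
        keep = rng.choice(total, size=config.ceiling, replace=False)
        keep.sort()
        trait, frac = trait[keep], frac[keep]
    return Lineage(trait, frac)


# ---------------------------------------------------------------------------
# Invasion simulation
# ---------------------------------------------------------------------------


@dataclass
class InvasionResult:
    """One replicate lineage: its trajectory and classified outcome."""

    replicate: int
    trajectory: pd.DataFrame
    outcome: str  # fixed | extinct_case1 | extinct_case2 | censored
    theta_minus: int
    theta_plus: int
    delta_w: float
    reached_beneficial: bool
    m_star: Optional[float] = None


@dataclass
class InvasionSummary:
    """Aggregate over replicates: outcome counts and the fixation probability
    with a 95% binomial (Wilson) confidence interval."""

    config: EvolutionConfig
    results: List[InvasionResult]
    outcome_counts: Dict[str, int]
    fixation_probability: float
    fixation_ci: Tuple[float, float]
    mean_theta_minus: float
    mean_theta_plus: float

    def to_frame(self) -> pd.DataFrame:
        row = {
            "replicates": len(self.results),
            "fixation_probability": self.fixation_probability,
            "fixation_ci_low": self.fixation_ci[0],
            "fixation_ci_high": self.fixation_ci[1],
            "mean_theta_minus": self.mean_theta_minus,
            "mean_theta_plus": self.mean_theta_plus,
        }
        for k, v in sorted(self.outcome_counts.items()):
            row[f"n_{k}"] = v
        return pd.DataFrame([row])


def _run_replicate(rep: int, config: EvolutionConfig) -> InvasionResult:
    rng = np.random.default_rng([max(0, config.seed), rep])
    lineage = Lineage.founder(config)
    rows = []
    beneficial_at: Optional[int] = None
    extinct_at: Optional[int] = None
    for step in range(config.horizon + 1):
        if lineage.size == 0:
            extinct_at = step
            break
        m, p_m, P, w = _colony_stats(lineage, config)
        rows.append(
            {
                "step": step,
                "n_colonies": lineage.size,
                "m": float(m.mean()),
                "p_m": float(p_m.mean()),
                "p_0": config.p0,
                "P": float(P.mean()),
                "w": float(w.mean()),
            }
        )
        if beneficial_at is None and p_m.mean() >= config.p0:
            beneficial_at = step
        if step < config.horizon:
            lineage = step_lineage(lineage, config, rng)
    traj = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)

    phases = phase_analysis(traj) if len(traj) else None
    if extinct_at is not None:
        outcome = "extinct_case1" if beneficial_at is None else "extinct_case2"
    else:
        last = traj.iloc[-1]
        mutant_alive = float(np.round(lineage.fraction * config.n).max(initial=0)) >= 1
        outcome = "fixed" if (mutant_alive and last["w"] >= 1.0) else "censored"
    return InvasionResult(
        replicate=rep,
        trajectory=traj,
        outcome=outcome,
        theta_minus=phases.theta_minus if phases else 0,
        theta_plus=phases.theta_plus if phases else 0,
        delta_w=phases.delta_w if phases else 0.0,
        reached_beneficial=beneficial_at is not None,
    )


def simulate_invasion(config: EvolutionConfig) -> InvasionSummary:
    """Simulate ``config.replicates`` independent founding lineages and
    classify each as fixed, extinct during the deleterious phase (Case 1),
    extinct during recovery (Case 2), or censored at the horizon.

    In deterministic mode, additionally hill-climbs the mutant count on the
    landscape expressed as a function of ``m`` (mutants filling a
    diminishing-returns niche) and records the stopping point ``m*`` where
    ``p_m(m*) = p_0``.
    """
    results = [_run_replicate(rep, config) for rep in range(config.replicates)]
    counts: Dict[str, int] = {}
    for r in results:
        counts[r.outcome] = counts.get(r.outcome, 0) + 1
    k = counts.get("fixed", 0)
    nrep = len(results)
    ci = binomtest(k, nrep).proportion_ci(confidence_level=0.95, method="wilson")
    summary = InvasionSummary(
        config=config,
        results=results,
        outcome_counts=counts,
        fixation_probability=k / nrep,
        fixation_ci=(float(ci.low), float(ci.high)),
        mean_theta_minus=float(np.mean([r.theta_minus for r in results])),
        mean_theta_plus=float(np.mean([r.theta_plus for r in results])),
    )
    if config.mode == "deterministic":
        # deterministic growth of m stops where the mutants' per-capita
        # productivity has fallen to the residents' level
        pm_of_m = _landscape_over_m(config)
        if pm_of_m is not None:
            m_star = hill_climb_mutant_count(pm_of_m, config.p0, m_max=float(config.n))
            for r in results:
                r.m_star = m_star
    return summary


def _landscape_over_m(config: EvolutionConfig) -> Optional[Callable[[float], float]]:
    """Landscape reinterpreted as diminishing returns in the mutant count.

    Only a piecewise-linear landscape with non-negative knots has a natural
    reading as ``p_m(m)`` (mutants filling a niche that crowds); the sigmoid
    trait landscape does not, and then no ``m*`` is computed."""
    ls = config.landscape
    if isinstance(ls, PiecewiseLinearLandscape) and ls.xs[0] >= 0:
        return lambda m: float(ls(m))
    return None


def hill_climb_mutant_count(
    pm_of_m: Callable[[float], float],
    p0: float,
    m0: float = 0.0,
    m_max: float = math.inf,
    step0: float = 1.0,
    min_step: float = 1e-9,
) -> float:
    """Grow the mutant count while each additional mutant is at least as
    productive per capita as a resident worker.

    With a concave, eventually decreasing ``p_m(m)`` (mutants fill a
    diminishing-returns niche), growth stops at the ``m*`` where
    ``p_m(m*) = p_0``.  Continuous ``m`` with adaptive step halving.
    """
    m = float(m0)
    if pm_of_m(m) < p0:
        return m
    step = step0
    while step >= min_step:
        trial = m + step
        if trial <= m_max and pm_of_m(trial) >= p0:
            m = trial
        else:
            step /= 2.0
    return m


# ---------------------------------------------------------------------------
# Phase analysis
# ---------------------------------------------------------------------------


@dataclass
class PhaseReport:
    theta_minus: int
    theta_plus: int
    delta_w: float
    censored: bool  # trait never became beneficial within the trajectory
    recovered: bool  # fitness returned to >= 1 after its minimum


def phase_analysis(trajectory: pd.DataFrame) -> PhaseReport:
    """Extract the waiting times and the integrated fitness change.

    ``theta_minus`` is the first step at which ``p_m >= p_0`` (the horizon,
    flagged censored, if never); ``theta_plus`` the number of steps from the
    fitness minimum back to ``w >= 1`` (0 if fitness never dips below 1).
    ``delta_w`` integrates the fitness rate ``phi = dw/dt`` over
    ``[0, theta_minus + theta_plus]``; with unit time steps the rate lives on
    the intervals between records and its integral telescopes, so ``delta_w``
    equals ``w(theta) - w(0)`` by the fundamental theorem of calculus.
    """
    required = {"p_m", "p_0", "w"}
    if trajectory is None or len(trajectory) == 0:
        raise CValidationError("phase analysis requires a nonempty trajectory")
    missing = required - set(trajectory.columns)
    if missing:
        raise CValidationError(f"trajectory lacks required fields: {sorted(missing)}")

    w = trajectory["w"].to_numpy(dtype=float)
    p_m = trajectory["p_m"].to_numpy(dtype=float)
    p_0 = trajectory["p_0"].to_numpy(dtype=float)
    horizon = len(w) - 1

    beneficial = np.nonzero(p_m >= p_0)[0]
    censored = beneficial.size == 0
    theta_minus = int(beneficial[0]) if not censored else horizon

    if np.all(w >= 1.0):
        theta_plus = 0
        recovered = True
    else:
        i_min = int(np.argmin(w))
        after = np.nonzero(w[i_min:] >= 1.0)[0]
        recovered = after.size > 0
        theta_plus = int(after[0]) if recovered else horizon - i_min

    theta = min(horizon, theta_minus + theta_plus)
    phi = np.diff(w[: theta + 1])  # per-step fitness rate on each interval
    delta_w = float(phi.sum())
    return PhaseReport(
        theta_minus=theta_minus,
        theta_plus=theta_plus,
        delta_w=delta_w,
        censored=censored,
        recovered=recovered,
    )
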