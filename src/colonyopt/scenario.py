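"""Scenario configuration: schema, YAML (de)serialization and fixture generation.

A scenario is the complete description of a study: the task list with utility
parameters, the caste list with energetics, the initial colony state, and an
optional evolution section.  Loading validates the whole document and reports
*all* problems found, not just the first.  The fixture generator draws
randomized valid scenarios from a handful of named families; everything it
produces passes the same validation and satisfies the model's shape
assumptions (strictly concave utilities, non-negative energies) by
construction, deterministically for a given seed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError as PydanticValidationError

from .errors import ConfigurationError, ScenarioError
from .evolution import EvolutionConfig
from .model import CasteSpec, ColonyState, TaskSpec

__all__ = [
    "Scenario",
    "ScenarioMeta",
    "load_scenario",
    "save_scenario",
    "scenario_from_dict",
    "generate_fixture",
    "FIXTURE_FAMILIES",
]

SCHEMA_VERSION = "1"


class ScenarioMeta(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str = "scenario"
    seed: Optional[int] = None
    schema_version: str = SCHEMA_VERSION


class ColonyConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n: int = Field(gt=0)
    counts: Dict[str, int] = Field(default_factory=dict)
    eps: Dict[str, float] = Field(default_factory=dict)

    def to_state(self) -> ColonyState:
        return ColonyState(n=self.n, counts=self.counts, eps=self.eps)


class Scenario(BaseModel):
    """A fully validated scenario document."""

    model_config = ConfigDict(extra="forbid")

    meta: ScenarioMeta = Field(default_factory=ScenarioMeta)
    tasks: List[TaskSpec]
    castes: List[CasteSpec] = Field(default_factory=list)
    colony: ColonyConfig
    evolution: Optional[EvolutionConfig] = None

    def model_post_init(self, __context) -> None:
        if not self.castes:
            object.__setattr__(
                self,
                "castes",
                [CasteSpec(id="worker", omega={t.id: 1.0 for t in self.tasks})],
            )
        if not self.colony.counts and len(self.castes) == 1:
            self.colony.counts = {self.castes[0].id: self.colony.n}

    @property
    def counts(self) -> Dict[str, float]:
        return {c.id: float(self.colony.counts.get(c.id, 0)) for c in self.castes}

    def to_dict(self) -> dict:
        d = self.model_dump(mode="json", exclude_none=True)
        # frozensets serialize unordered; fix a stable order for byte-identity
        for caste in d.get("castes", []):
            if caste.get("performs") is not None:
                caste["performs"] = sorted(caste["performs"])
        return d


def scenario_from_dict(data: dict) -> Scenario:
    """Validate a raw mapping into a Scenario, collecting all schema errors."""
    if not isinstance(data, dict):
        raise ScenarioError([f"scenario document must be a mapping, got {type(data).__name__}"])
    try:
        return Scenario.model_validate(data)
    except PydanticValidationError as exc:
        problems = []
        for err in exc.errors():
            loc = ".".join(str(part) for part in err["loc"])
            problems.append(f"{loc or '<root>'}: {err['msg']}")
        raise ScenarioError(problems) from exc
    except (ConfigurationError, ValueError) as exc:
        raise ScenarioError([str(exc)]) from exc


def load_scenario(path: Union[str, Path]) -> Scenario:
    """Load and validate a YAML scenario file."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ScenarioError([f"malformed YAML in {path}: {exc}"]) from exc
    return scenario_from_dict(raw)


def save_scenario(scenario: Scenario, path: Union[str, Path]) -> None:
    """Write a scenario as YAML; stable key order so identical scenarios
    produce byte-identical files."""
    Path(path).write_text(
        yaml.safe_dump(scenario.to_dict(), sort_keys=True, default_flow_style=False)
    )


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------
#
# Parameter ranges are the package's reference study conditions: colony size
# n = 100, task importance k in [0.4, 1], work capacity R in [10, 30] energy
# units, saturation rate a in [0.03, 0.08] per worker (so a*n spans 3-8 and
# tasks saturate within the colony's reach), per-performer task energy c in
# [0.002, 0.01], basal subsistence in [5e-4, 5e-3] energy per ant per step —
# small against marginal task value, as for real colonies where a worker's
# upkeep is far below her foraging yield.  With these ranges the allocation
# constraint binds for 2-4 tasks and equilibria are interior.

FIXTURE_FAMILIES = (
    "monomorphic-2task",
    "monomorphic-3task",
    "monomorphic-4task",
    "monomorphic-k-task",
    "monomorphic-3task-power",
    "dimorphic",
    "invasion-sigmoid",
)


def _monomorphic(rng: np.random.Generator, eta: int, seed: int, family: str = "saturating") -> Scenario:
    # the power family shares one concavity exponent across tasks: the biomass
    # proxy is exact only for a common homogeneity degree
    gamma = float(rng.uniform(0.4, 0.8)) if family == "power" else None
    tasks = []
    for j in range(eta):
        if family == "power":
            tasks.append(
                TaskSpec(
                    id=f"task{j + 1}",
                    k_tau=float(rng.uniform(0.4, 1.0)),
                    family="power",
                    R=float(rng.uniform(10.0, 30.0)),
                    a=gamma,
                    c=0.0,
                )
            )
        else:
            tasks.append(
                TaskSpec(
                    id=f"task{j + 1}",
                    k_tau=float(rng.uniform(0.4, 1.0)),
                    family="saturating",
                    R=float(rng.uniform(10.0, 30.0)),
                    a=float(rng.uniform(0.03, 0.08)),
                    c=float(rng.uniform(0.002, 0.01)),
                )
            )
    caste = CasteSpec(
        id="worker",
        E_basal=float(rng.uniform(5e-4, 5e-3)),
        omega={t.id: float(rng.uniform(0.5, 2.0)) for t in tasks},
        mass_per_ant=1.0,
    )
    n = 100
    return Scenario(
        meta=ScenarioMeta(name=f"monomorphic-{eta}task-{family}-s{seed}", seed=seed),
        tasks=tasks,
        castes=[caste],
        colony=ColonyConfig(
            n=n, counts={"worker": n}, eps={t.id: 1.0 / (eta + 1) for t in tasks}
        ),
    )


def _dimorphic(rng: np.random.Generator, seed: int) -> Scenario:
    base = _monomorphic(rng, 3, seed)
    tasks = base.tasks
    specialist = CasteSpec(
        id="minor",
        E_basal=float(rng.uniform(5e-4, 5e-3)),
        omega={tasks[0].id: float(rng.uniform(0.8, 2.0)), tasks[1].id: float(rng.uniform(0.8, 2.0))},
        mass_per_ant=0.8,
    )
    generalist = CasteSpec(
        id="major",
        E_basal=float(rng.uniform(1e-3, 8e-3)),
        omega={t.id: float(rng.uniform(0.5, 1.5)) for t in tasks},
        mass_per_ant=1.6,
    )
    n = 100
    n_minor = int(rng.integers(30, 61))
    return Scenario(
        meta=ScenarioMeta(name=f"dimorphic-s{seed}", seed=seed),
        tasks=tasks,
        castes=[specialist, generalist],
        colony=ColonyConfig(
            n=n,
            counts={"minor": n_minor, "major": n - n_minor},
            eps={t.id: 0.25 for t in tasks},
        ),
    )


def _invasion(rng: np.random.Generator, seed: int) -> Scenario:
    task = TaskSpec(id="forage", k_tau=1.0, family="saturating", R=20.0, a=0.05, c=0.005)
    caste = CasteSpec(id="worker", E_basal=1e-3, omega={"forage": 1.0})
    evo = EvolutionConfig(
        n=100,
        p0=2.0,
        initial_trait_x=-1.0,
        initial_fraction=float(rng.choice([0.01, 0.05, 0.2])),
        mutation_sigma=0.25,
        fraction_sigma=0.01,
        replicates=200,
        seed=seed,
        horizon=60,
        ceiling=300,
    )
    return Scenario(
        meta=ScenarioMeta(name=f"invasion-sigmoid-s{seed}", seed=seed),
        tasks=[task],
        castes=[caste],
        colony=ColonyConfig(n=100, counts={"worker": 100}, eps={"forage": 0.5}),
        evolution=evo,
    )


def generate_fixture(kind: str, seed: int) -> Scenario:
    """Generate a randomized valid scenario of a named family, deterministically
    for the given seed.  Families: monomorphic colonies with 2-4 saturating
    tasks (or a random k), a power-family 3-task colony (for the biomass
    proxy), a dimorphic specialist/generalist colony (for knockouts), and a
    sigmoid-landscape invasion study."""
    rng = np.random.default_rng(seed)
    if kind == "monomorphic-2task":
        return _monomorphic(rng, 2, seed)
    if kind == "monomorphic-3task":
        return _monomorphic(rng, 3, seed)
    if kind == "monomorphic-4task":
        return _monomorphic(rng, 4, seed)
    if kind == "monomorphic-k-task":
        return _monomorphic(rng, int(rng.integers(2, 5)), seed)
    if kind == "monomorphic-3task-power":
        return _monomorphic(rng, 3, seed, family="power")
    if kind == "dimorphic":
        return _dimorphic(rng, seed)
    if kind == "invasion-sigmoid":
        return _invasion(rng, seed)
    raise ConfigurationError(
        f"unknown fixture family {kind!r}; available: {FIXTURE_FAMILIES}"
    )
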