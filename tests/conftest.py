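import itertools

import numpy as np
import pytest

from colonyopt import CasteSpec, ColonyState, TaskSpec, generate_fixture, solve_equilibrium


@pytest.fixture
def default_task() -> TaskSpec:
    return TaskSpec(id="forage", k_tau=1.0, family="saturating", R=10.0, a=0.1, c=0.02)


@pytest.fixture
def hand_colony():
    """A 4-ant, 2-caste, 2-task colony small enough to sum by hand.

    Caste A (2 ants): one on task1, one on task2, work rates 2.0 / 1.0.
    Caste B (2 ants): one on task2 (rate 1.5), one idle.
    """
    tasks = [
        TaskSpec(id="task1", k_tau=0.5, R=5.0, a=0.1, c=0.1),
        TaskSpec(id="task2", k_tau=0.8, R=5.0, a=0.1, c=0.2),
    ]
    castes = [
        CasteSpec(id="A", E_basal=0.3, omega={"task1": 2.0, "task2": 1.0}),
        CasteSpec(id="B", E_basal=0.5, omega={"task2": 1.5}),
    ]
    state = ColonyState(
        n=4,
        counts={"A": 2, "B": 2},
        eps={"task1": 0.25, "task2": 0.5},
        assignment={"A": {"task1": 1, "task2": 1}, "B": {"task2": 1}},
    )
    return tasks, castes, state


@pytest.fixture(scope="session")
def solved_3task():
    """A solved random 3-task monomorphic equilibrium, shared across tests."""
    sc = generate_fixture("monomorphic-3task", 7)
    eq = solve_equilibrium(sc.tasks, sc.castes, sc.colony.n, sc.counts)
    return sc, eq


_task_ids = itertools.count()


def random_task(rng: np.random.Generator, zero_cost: bool = False) -> TaskSpec:
    return TaskSpec(
        id=f"t{next(_task_ids)}",
        k_tau=float(rng.uniform(0.4, 1.0)),
        family="saturating",
        R=float(rng.uniform(10.0, 30.0)),
        a=float(rng.uniform(0.03, 0.08)),
        c=0.0 if zero_cost else float(rng.uniform(0.002, 0.01)),
    )
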