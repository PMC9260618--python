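"""Unit and property tests for the primitive quantities and the ledger."""

import math

import numpy as np
import pytest
from pydantic import ValidationError as SchemaError

from colonyopt import (
    CasteSpec,
    ColonyState,
    ConfigurationError,
    TaskSpec,
    UndefinedQuantityError,
    UTILITY_FAMILIES,
    ValidationError,
    colony_ledger,
    evaluate_utility,
    marginal_utility,
    reproductive_usefulness,
    utility_curvature,
)
from conftest import random_task


class TestEvaluateUtility:
    def test_zero_performers_zero_utility_for_every_family(self):
        for fam in UTILITY_FAMILIES:
            t = TaskSpec(id="t", k_tau=0.7, family=fam, R=8.0, a=0.5, c=0.1)
            assert evaluate_utility(t, 100, 0.0) == 0.0

    def test_closed_form_of_default_family(self, default_task):
        # k*R*(1 - e^{-a n eps}) - c*n*eps at k=1, R=10, a=0.1, c=0.02, n=100, eps=0.5
        expected = 10.0 * (1.0 - math.exp(-5.0)) - 1.0
        assert evaluate_utility(default_task, 100, 0.5) == pytest.approx(expected, rel=1e-15)

    def test_unknown_family_rejected(self):
        with pytest.raises(SchemaError, match="unknown utility family"):
            TaskSpec(id="t", k_tau=0.5, family="quadratic", R=1.0, a=1.0)

    def test_invalid_inputs_rejected(self, default_task):
        with pytest.raises(ValidationError):
            evaluate_utility(default_task, -1, 0.5)
        with pytest.raises(ValidationError):
            evaluate_utility(default_task, 100, 1.5)

    @pytest.mark.parametrize("family", ["saturating", "saturating_satcost", "power"])
    def test_concavity_by_finite_differences(self, family):
        """Central finite-difference slopes of U in eps are strictly decreasing
        at 20 random points, for every strictly concave family."""
        rng = np.random.default_rng(42)
        h = 1e-5
        for _ in range(10):
            if family == "power":
                t = TaskSpec(
                    id="t", k_tau=float(rng.uniform(0.4, 1)), family="power",
                    R=float(rng.uniform(10, 30)), a=float(rng.uniform(0.3, 0.9)), c=0.0,
                )
            else:
                t = TaskSpec(
                    id="t", k_tau=float(rng.uniform(0.4, 1)), family=family,
                    R=float(rng.uniform(10, 30)), a=float(rng.uniform(0.03, 0.08)),
                    c=float(rng.uniform(0.0, 0.01)),
                )
            eps = np.sort(rng.uniform(0.01, 0.99, size=20))
            slopes = [
                (evaluate_utility(t, 100, e + h) - evaluate_utility(t, 100, e - h)) / (2 * h)
                for e in eps
            ]
            assert all(s1 > s2 for s1, s2 in zip(slopes, slopes[1:]))
            assert all(utility_curvature(t, 100, e) < 0 for e in eps)

    def test_work_term_marginal_vanishes_at_saturation(self):
        """Marginal utility of the work component tends to 0 as the task
        saturates; with a linear cost the total tends to -c*n."""
        t = TaskSpec(id="t", k_tau=1.0, family="saturating", R=10.0, a=2.0, c=0.05)
        _, mu = marginal_utility(t, 100, 1.0)
        assert mu == pytest.approx(-0.05 * 100, abs=1e-12)
        # with the saturating-cost variant the total marginal itself vanishes
        t2 = TaskSpec(id="t", k_tau=1.0, family="saturating_satcost", R=10.0, a=2.0, c=0.05)
        _, mu2 = marginal_utility(t2, 100, 1.0)
        assert abs(mu2) < 1e-12


class TestMarginalUtility:
    def test_linear_family_slope_identity(self):
        t = TaskSpec(id="t", k_tau=1.0, family="linear", R=3.5, a=1.0, c=0.0)
        for eps in [0.0, 0.3, 0.9]:
            nu, mu = marginal_utility(t, 50, eps, delta_eps=0.05)
            assert nu == pytest.approx(3.5, rel=1e-12)
            assert mu == pytest.approx(3.5, rel=1e-12)

    def test_fractional_tends_to_infinitesimal(self):
        """nu with a small increment matches the analytic derivative.

        Relative agreement is checked where the work term dominates (zero task
        cost): there the curvature-to-slope ratio is bounded by a*n.
        """
        rng = np.random.default_rng(7)
        for _ in range(20):
            t = random_task(rng, zero_cost=True)
            eps = float(rng.uniform(0.0, 0.9))
            nu, mu = marginal_utility(t, 100, eps, delta_eps=1e-6)
            assert abs(nu - mu) < 1e-4 * abs(mu)
        for _ in range(20):
            t = random_task(rng)
            eps = float(rng.uniform(0.0, 0.5))
            nu, mu = marginal_utility(t, 100, eps, delta_eps=1e-6)
            assert abs(nu - mu) < 1e-3

    def test_bad_increment_rejected(self, default_task):
        with pytest.raises(ValidationError):
            marginal_utility(default_task, 100, 0.5, delta_eps=0.0)
        with pytest.raises(ValidationError):
            marginal_utility(default_task, 100, 0.9, delta_eps=0.2)


class TestReproductiveUsefulness:
    @pytest.mark.parametrize(
        "focal,queen,expected", [(0, 50, 0.0), (50, 50, 1.0), (10, 40, 0.25)]
    )
    def test_ratio(self, focal, queen, expected):
        assert reproductive_usefulness(focal, queen) == expected

    def test_zero_queen_offspring_undefined(self):
        with pytest.raises(UndefinedQuantityError):
            reproductive_usefulness(10, 0)


class TestColonyLedger:
    def test_empty_colony(self, hand_colony):
        tasks, castes, _ = hand_colony
        state = ColonyState(n=0, counts={"A": 0, "B": 0}, eps={})
        rep = colony_ledger(tasks, castes, state)
        assert rep.G == 0.0 and rep.E == 0.0 and rep.P == 0.0
        with pytest.raises(UndefinedQuantityError):
            rep.p

    def test_subsistence_only_colony(self):
        tasks = [TaskSpec(id="t1", k_tau=0.5, R=5.0, a=0.1, c=0.1)]
        castes = [CasteSpec(id="w", E_basal=2.0, omega={"t1": 1.0})]
        state = ColonyState(n=1, counts={"w": 1}, eps={})
        rep = colony_ledger(tasks, castes, state)
        assert rep.G == 0.0
        assert rep.P == -2.0

    def test_hand_summation_oracle(self, hand_colony):
        """4-ant ledger matches independent hand summation exactly."""
        tasks, castes, state = hand_colony
        rep = colony_ledger(tasks, castes, state)
        # hand sums: A@t1 0.5*2-0.1=0.9; A@t2 0.8*1-0.2=0.6; B@t2 0.8*1.5-0.2=1.0
        assert rep.U == {"task1": 0.9, "task2": pytest.approx(1.6)}
        assert rep.G == pytest.approx(2.5)
        assert rep.E == pytest.approx(2 * 0.3 + 2 * 0.5)
        assert rep.P == pytest.approx(2.5 - 1.6)
        assert rep.p == pytest.approx(0.9 / 4)
        assert sorted(rep.competence, reverse=True) == pytest.approx([1.0, 0.9, 0.6, 0.0])

    def test_double_accounting_identity(self):
        """G = sum_j U_j = sum_i c_i to machine precision on random colonies."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            eta = int(rng.integers(1, 5))
            tasks = [random_task(rng) for _ in range(eta)]
            castes = [
                CasteSpec(
                    id="w",
                    E_basal=float(rng.uniform(0, 1)),
                    omega={t.id: float(rng.uniform(0.1, 3)) for t in tasks},
                )
            ]
            n = int(rng.integers(1, 200))
            eps_raw = rng.uniform(0, 1, eta)
            eps_raw *= rng.uniform(0, 1) / max(1e-12, eps_raw.sum())
            state = ColonyState(
                n=n, counts={"w": n}, eps={t.id: float(e) for t, e in zip(tasks, eps_raw)}
            )
            rep = colony_ledger(tasks, castes, state)
            assert sum(rep.U.values()) == pytest.approx(rep.G, abs=1e-12, rel=1e-14)
            assert rep.competence.sum() == pytest.approx(rep.G, abs=1e-12, rel=1e-14)
            assert rep.P == rep.G - rep.E

    def test_subsistence_linear_in_n(self, hand_colony):
        """E(2n) = 2 E(n) at fixed task fractions and caste proportions."""
        tasks, castes, state = hand_colony
        rep1 = colony_ledger(tasks, castes, state)
        state2 = ColonyState(
            n=8,
            counts={"A": 4, "B": 4},
            eps=state.eps,
            assignment={"A": {"task1": 2, "task2": 2}, "B": {"task2": 2}},
        )
        rep2 = colony_ledger(tasks, castes, state2)
        assert rep2.E == pytest.approx(2 * rep1.E, rel=1e-15)

    def test_ledger_permutation_invariant(self, hand_colony):
        """Reordering tasks and castes leaves every total unchanged."""
        tasks, castes, state = hand_colony
        rep = colony_ledger(tasks, castes, state)
        rep_perm = colony_ledger(tasks[::-1], castes[::-1], state)
        assert rep_perm.G == pytest.approx(rep.G, rel=1e-15)
        assert rep_perm.E == rep.E
        assert rep_perm.U == pytest.approx(rep.U)

    def test_assignment_beyond_capability_rejected(self, hand_colony):
        tasks, castes, _ = hand_colony
        state = ColonyState(
            n=2, counts={"A": 0, "B": 2}, eps={"task1": 0.5},
            assignment={"B": {"task1": 1}},
        )
        with pytest.raises(ValidationError, match="cannot perform"):
            colony_ledger(tasks, castes, state)


class TestColonyState:
    def test_fraction_sum_constraint(self):
        with pytest.raises(SchemaError, match="at most one task"):
            ColonyState(n=10, counts={"w": 10}, eps={"a": 0.7, "b": 0.6})

    def test_task_counts_sum_consistently(self):
        state = ColonyState(n=10, counts={"w": 10}, eps={"a": 1 / 3, "b": 1 / 3, "c": 1 / 3})
        counts = state.task_counts
        assert sum(counts.values()) == 10
        assert all(v >= 0 for v in counts.values())
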