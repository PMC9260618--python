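"""Tests of the group-selection invasion machinery."""

import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError as SchemaError

from colonyopt import (
    EvolutionConfig,
    FitnessMap,
    Lineage,
    PiecewiseLinearLandscape,
    QueenGenotype,
    SigmoidLandscape,
    ValidationError,
    fitness_from_productivity,
    hill_climb_mutant_count,
    phase_analysis,
    productivity_rate,
    productivity_split,
    simulate_invasion,
    step_lineage,
)


class TestProductivitySplit:
    def test_no_mutants(self):
        P, d = productivity_split(0, 100, p_m=0.5, p_0=2.0)
        assert P == 200.0 and d == 0.5 - 2.0

    def test_neutral_mutant(self):
        _, d = productivity_split(10, 100, p_m=2.0, p_0=2.0)
        assert d == 0.0

    def test_hand_substitution(self):
        P, d = productivity_split(10, 100, p_m=0.5, p_0=2.0)
        assert P == pytest.approx(185.0)
        assert d == pytest.approx(-1.5)

    def test_mutants_exceeding_colony_rejected(self):
        with pytest.raises(ValidationError):
            productivity_split(101, 100, 1.0, 1.0)

    def test_deleterious_phase_productivity_decreases_in_m(self):
        """While p_m < p_0, total productivity strictly decreases with every
        extra mutant; once p_m > p_0 it strictly increases."""
        for p_m, sign in [(0.5, -1), (3.0, +1)]:
            P = [productivity_split(m, 100, p_m, 2.0)[0] for m in range(0, 101, 10)]
            diffs = np.diff(P)
            assert np.all(sign * diffs > 0)

    def test_rate_decomposition(self):
        assert productivity_rate(0, 0.0, 1.0, 0.0, 2.0) == 0.0
        assert productivity_rate(5, 2.0, 1.0, 0.1, 3.0) == pytest.approx(0.5 + 2 * (-2.0))
        # deleterious phase: growing the mutant count drags productivity down
        assert productivity_rate(5, 1.0, 0.5, 0.0, 2.0) < 0


class TestFitnessMap:
    def test_reference_point(self):
        fm = FitnessMap(form="linear", w0=1.2, beta=0.5, p_ref=2.0)
        assert fitness_from_productivity(2.0, fm) == 1.2

    def test_strictly_increasing_where_unclamped(self):
        for form in ("linear", "exponential"):
            fm = FitnessMap(form=form, w0=1.0, beta=0.7, p_ref=0.0)
            ps = np.linspace(0.0, 5.0, 50)
            ws = fm(ps)
            assert np.all(np.diff(ws) > 0)

    def test_clamped_at_zero(self):
        fm = FitnessMap(form="linear", w0=1.2, beta=0.5, p_ref=0.0)
        assert fitness_from_productivity(-3.0, fm) == 0.0

    def test_decreasing_map_rejected(self):
        with pytest.raises(SchemaError, match="strictly increasing"):
            FitnessMap(form="linear", w0=1.0, beta=-0.2)


class TestQueenGenotype:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(SchemaError):
            QueenGenotype(fractions={"worker": 0.8, "mutant": 0.1})

    def test_mutant_fraction(self):
        g = QueenGenotype(fractions={"worker": 0.95, "mutant": 0.05}, trait_x=-1.0)
        assert g.mutant_fraction == 0.05


class TestStepLineage:
    def _config(self, **kw):
        defaults = dict(
            n=100,
            p0=2.0,
            landscape=SigmoidLandscape(p_lo=0.5, p_hi=3.5, rate=1.5, x0=1.0),
            initial_trait_x=-1.0,
            initial_fraction=0.05,
            mutation_sigma=0.25,
            fraction_sigma=0.01,
            seed=1,
        )
        defaults.update(kw)
        return EvolutionConfig(**defaults)

    def test_zero_fitness_means_extinction(self):
        # landscape so hostile the colony cannot reproduce at all
        cfg = self._config(
            landscape=PiecewiseLinearLandscape(xs=[-10.0, 10.0], ps=[-100.0, -100.0]),
            initial_fraction=1.0,
            fitness_map=FitnessMap(form="linear", w0=1.0, beta=0.1, p_ref=2.0),
        )
        rng = np.random.default_rng(0)
        nxt = step_lineage(Lineage.founder(cfg), cfg, rng)
        assert nxt.size == 0

    def test_faithful_inheritance_without_mutation(self):
        cfg = self._config(mutation_sigma=0.0, fraction_sigma=0.0, mode="deterministic")
        rng = np.random.default_rng(0)
        lin = Lineage.founder(cfg)
        for _ in range(3):
            lin = step_lineage(lin, cfg, rng)
            assert np.all(lin.trait_x == cfg.initial_trait_x)
            assert np.all(lin.fraction == cfg.initial_fraction)

    def test_deterministic_reproduction_bypasses_poisson(self):
        """w = 2 exactly yields exactly 2 daughter colonies."""
        cfg = self._config(
            mode="deterministic",
            mutation_sigma=0.0,
            fraction_sigma=0.0,
            initial_fraction=0.0,
            fitness_map=FitnessMap(form="linear", w0=2.0, beta=1.0, p_ref=2.0),
        )
        rng = np.random.default_rng(0)
        nxt = step_lineage(Lineage.founder(cfg), cfg, rng)
        assert nxt.size == 2

    def test_population_ceiling_thins(self):
        cfg = self._config(
            mode="deterministic",
            ceiling=5,
            initial_fraction=0.0,
            fitness_map=FitnessMap(form="linear", w0=3.0, beta=1.0, p_ref=2.0),
        )
        rng = np.random.default_rng(0)
        lin = Lineage.founder(cfg)
        for _ in range(4):
            lin = step_lineage(lin, cfg, rng)
        assert lin.size == 5


class TestSimulateInvasion:
    def test_never_deleterious_trait_fixes_immediately(self):
        cfg = EvolutionConfig(
            n=100,
            p0=2.0,
            landscape=SigmoidLandscape(p_lo=2.5, p_hi=3.5, rate=1.0, x0=0.0),
            initial_trait_x=1.0,
            initial_fraction=0.05,
            mutation_sigma=0.0,
            fraction_sigma=0.0,
            mode="deterministic",
            replicates=1,
            seed=3,
            horizon=10,
        )
        summary = simulate_invasion(cfg)
        res = summary.results[0]
        assert res.outcome == "fixed"
        assert res.theta_minus == 0

    def test_immediate_case1_extinction(self):
        cfg = EvolutionConfig(
            n=100,
            p0=2.0,
            landscape=PiecewiseLinearLandscape(xs=[-10.0, 10.0], ps=[-50.0, -50.0]),
            initial_trait_x=0.0,
            initial_fraction=0.5,
            fitness_map=FitnessMap(form="linear", w0=1.0, beta=0.1, p_ref=2.0),
            replicates=5,
            seed=4,
            horizon=10,
        )
        summary = simulate_invasion(cfg)
        assert all(r.outcome == "extinct_case1" for r in summary.results)
        assert summary.fixation_probability == 0.0

    def test_seeded_rerun_reproduces_everything(self):
        cfg = EvolutionConfig(replicates=30, seed=12, horizon=30, ceiling=200)
        s1 = simulate_invasion(cfg)
        s2 = simulate_invasion(cfg)
        assert s1.fixation_probability == s2.fixation_probability
        for r1, r2 in zip(s1.results, s2.results):
            pd.testing.assert_frame_equal(r1.trajectory, r2.trajectory)
            assert r1.outcome == r2.outcome

    def test_outcomes_cover_all_replicates(self):
        cfg = EvolutionConfig(replicates=40, seed=9, horizon=25, ceiling=200)
        summary = simulate_invasion(cfg)
        assert sum(summary.outcome_counts.values()) == 40
        assert set(summary.outcome_counts) <= {
            "fixed",
            "extinct_case1",
            "extinct_case2",
            "censored",
        }


class TestHillClimb:
    def test_growth_stops_where_productivities_equalize(self):
        """With concave diminishing returns p_m(m), the mutant count grows
        exactly until p_m(m*) = p_0."""
        p0 = 2.0
        pm = lambda m: 3.0 - 0.01 * m - 0.0002 * m**2  # concave, decreasing
        m_star = hill_climb_mutant_count(pm, p0, m_max=1000.0)
        # closed form: 0.0002 m^2 + 0.01 m - 1 = 0
        expected = (-0.01 + np.sqrt(0.01**2 + 4 * 0.0002)) / (2 * 0.0002)
        assert m_star == pytest.approx(expected, abs=1e-6)
        assert abs(pm(m_star) - p0) < 1e-3

    def test_initially_unprofitable_niche_stays_empty(self):
        assert hill_climb_mutant_count(lambda m: 1.0, p0=2.0) == 0.0

    def test_deterministic_invasion_reports_m_star(self):
        cfg = EvolutionConfig(
            n=100,
            p0=2.0,
            landscape=PiecewiseLinearLandscape(
                xs=[0.0, 10.0, 40.0, 100.0], ps=[4.0, 3.5, 2.0, 0.5]
            ),
            initial_trait_x=0.0,
            initial_fraction=0.05,
            mutation_sigma=0.0,
            fraction_sigma=0.0,
            mode="deterministic",
            replicates=1,
            seed=0,
            horizon=5,
        )
        summary = simulate_invasion(cfg)
        m_star = summary.results[0].m_star
        assert m_star is not None
        assert abs(float(cfg.landscape(m_star)) - cfg.p0) < 1e-3


class TestPhaseAnalysis:
    @staticmethod
    def _traj(w, p_m, p_0=2.0):
        w = np.asarray(w, dtype=float)
        p_m = np.asarray(p_m, dtype=float)
        return pd.DataFrame(
            {
                "step": np.arange(len(w)),
                "n_colonies": np.ones(len(w)),
                "m": np.ones(len(w)),
                "p_m": p_m,
                "p_0": p_0,
                "P": np.zeros(len(w)),
                "w": w,
            }
        )

    def test_flat_fitness(self):
        traj = self._traj(w=[1.5] * 10, p_m=np.linspace(0, 3, 10))
        rep = phase_analysis(traj)
        assert rep.delta_w == 0.0
        assert rep.theta_plus == 0

    def test_integral_matches_endpoint_difference(self):
        """Integrated fitness rate equals w(theta) - w(0): decline-and-recovery."""
        w = np.concatenate([np.linspace(1.4, 0.4, 12), np.linspace(0.4, 1.3, 15)[1:]])
        p_m = np.linspace(0.5, 3.5, len(w))
        rep = phase_analysis(self._traj(w, p_m))
        theta = rep.theta_minus + rep.theta_plus
        assert rep.delta_w == pytest.approx(w[theta] - w[0], abs=1e-8)

    def test_never_beneficial_is_flagged(self):
        traj = self._traj(w=[1.2] * 8, p_m=[0.5] * 8)
        rep = phase_analysis(traj)
        assert rep.censored
        assert rep.theta_minus == 7  # the horizon index

    def test_missing_fields_rejected(self):
        with pytest.raises(ValidationError, match="required fields"):
            phase_analysis(pd.DataFrame({"w": [1.0, 2.0]}))
        with pytest.raises(ValidationError):
            phase_analysis(pd.DataFrame())

    def test_integral_consistency_on_simulated_trajectories(self):
        cfg = EvolutionConfig(replicates=25, seed=21, horizon=40, ceiling=200)
        summary = simulate_invasion(cfg)
        for res in summary.results:
            traj = res.trajectory
            rep = phase_analysis(traj)
            theta = min(len(traj) - 1, rep.theta_minus + rep.theta_plus)
            w = traj["w"].to_numpy()
            assert rep.delta_w == pytest.approx(w[theta] - w[0], abs=1e-8)
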