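"""Cohort engine: conservation, linearity, hand oracle, microsim oracle."""
import numpy as np
import pytest

from tfacea import (PopulationPyramid, RiskParameters, ScenarioSpec,
                    assemble_transitions, build_trajectory, initialize_cohort,
                    run_cohort, step)
from tfacea.config import default_options
from tfacea.intake import IntakeTrajectory
from conftest import SMALL_SYN, flat_tables
from _microsim import replicate_microsim

OPTIONS = default_options()
NULL_RISK = RiskParameters(rr_per_2Epct=1.0, rr_ci=(1.0, 1.0))


def _pyramid(ages, counts):
    return PopulationPyramid.from_arrays(np.asarray(ages), count=np.asarray(counts, float))


def _flat_transitions(n_ages, q, p_cad, cf, horizon):
    life, morb = flat_tables(np.arange(n_ages), q=q, p_cad=p_cad, cf=cf)
    traj = IntakeTrajectory("reference", "t", np.zeros(horizon + 1))
    return assemble_transitions(life, morb, traj, NULL_RISK)


class TestInitialize:
    def test_everyone_starts_well(self):
        state = initialize_cohort(_pyramid([0, 1], [[30, 20], [25, 25]]))
        assert state.well.sum() == 100
        assert state.cad.sum() == 0 and state.history.sum() == 0 and state.dead.sum() == 0

    def test_empty_pyramid(self):
        state = initialize_cohort(_pyramid([0, 1], [[0, 0], [0, 0]]))
        assert state.total == 0


class TestStep:
    def test_identity_transitions_only_age(self):
        tr = _flat_transitions(10, q=0.0, p_cad=0.0, cf=0.0, horizon=3)
        state = initialize_cohort(_pyramid(np.arange(10), np.full((10, 2), 5.0)))
        new, flows = step(state, tr, 0)
        # all strata unchanged except the one ageing past the absorbing bound
        assert np.array_equal(new.well[:-1], state.well[:-1])
        assert np.all(new.dead[-1] == 5.0)
        assert flows["first_events"].sum() == 0

    def test_single_stratum_hand_arithmetic(self):
        tr = _flat_transitions(30, q=0.02, p_cad=0.05, cf=0.3, horizon=2)
        counts = np.zeros((30, 2))
        counts[0, 0] = 1000.0
        state = initialize_cohort(_pyramid(np.arange(30), counts))
        state.history[0, 0] = 500.0
        state.cad_first[0, 0] = 200.0
        state.cad_repeat[0, 0] = 100.0

        # independent hand arithmetic for the expected flows
        import math
        q_other = 1 - math.exp(-(-math.log(1 - 0.02) + math.log(1 - 0.05 * 0.3)))
        exp_first = 1000 * 0.05
        exp_repeat = 500 * 1.5 * 0.05
        exp_cad_deaths = 200 * 0.3 + 100 * 0.45
        exp_survivors = 300 - exp_cad_deaths
        exp_other = (1000 + 500) * q_other

        new, flows = step(state, tr, 0)
        assert flows["first_events"].sum() == pytest.approx(exp_first, rel=1e-12)
        assert flows["repeat_events"].sum() == pytest.approx(exp_repeat, rel=1e-12)
        assert flows["cad_deaths"].sum() == pytest.approx(exp_cad_deaths, rel=1e-12)
        assert flows["other_deaths"].sum() == pytest.approx(exp_other, rel=1e-12)
        assert new.well[0, 0] == pytest.approx(1000 - exp_first - 1000 * q_other, rel=1e-12)
        assert new.history[0, 0] == pytest.approx(
            500 - exp_repeat - 500 * q_other + exp_survivors, rel=1e-12)
        assert new.total == pytest.approx(1800.0, rel=1e-12)


class TestRun:
    def test_conservation_every_cycle(self, small_inputs, run_cfg):
        life, morb, pop = small_inputs
        total0 = pop.total
        traj_opt = OPTIONS["reference"]
        tr = assemble_transitions(life, morb,
                                  build_trajectory(traj_opt, run_cfg.scenario, 40),
                                  run_cfg.risk)
        state = initialize_cohort(pop)
        for t in range(40):
            state, _ = step(state, tr, t)
            assert state.total == pytest.approx(total0, rel=1e-9)

    def test_zero_incidence_matches_pure_survival(self):
        n_ages, horizon = 12, 8
        life, morb = flat_tables(np.arange(n_ages), q=0.1, p_cad=0.0, cf=0.0)
        counts = np.full((n_ages, 2), 100.0)
        pop = _pyramid(np.arange(n_ages), counts)
        ledger, final = run_cohort(OPTIONS["reference"], ScenarioSpec.preset("base"),
                                   life, morb, pop, horizon, NULL_RISK)
        assert ledger.events.sum() == 0 and ledger.cad_deaths.sum() == 0
        # independent survival bookkeeping per stratum
        q = life.as_array("q_all_cause")
        expected_dead = 0.0
        for a in range(n_ages):
            alive = 200.0  # both sexes
            for t in range(horizon):
                age = min(a + t, n_ages - 1)
                dies = alive * q[age, 0]
                alive -= dies
                expected_dead += dies
                if a + t + 1 > n_ages - 1:
                    expected_dead += alive
                    alive = 0.0
        assert ledger.other_deaths.sum() == pytest.approx(expected_dead, rel=1e-9)

    def test_population_scaling_is_linear(self, small_inputs, run_cfg):
        life, morb, pop = small_inputs
        led1, _ = run_cohort(OPTIONS["voluntary"], run_cfg.scenario, life, morb,
                             pop, 20, run_cfg.risk)
        big = PopulationPyramid.from_arrays(pop.ages, count=2.0 * pop.as_array("count"))
        led2, _ = run_cohort(OPTIONS["voluntary"], run_cfg.scenario, life, morb,
                             big, 20, run_cfg.risk)
        for k, v in led1.totals().items():
            assert led2.totals()[k] == pytest.approx(2.0 * v, rel=1e-9)

    def test_monotone_harm_in_intake(self, small_inputs, run_cfg):
        life, morb, pop = small_inputs
        cums = {}
        for oid in ("legal_limit", "voluntary", "labeling", "reference"):
            led, _ = run_cohort(OPTIONS[oid], run_cfg.scenario, life, morb, pop,
                                30, run_cfg.risk)
            cums[oid] = led.events.sum()
        assert cums["legal_limit"] <= cums["voluntary"] <= cums["labeling"] <= cums["reference"]


class TestMicrosimOracle:
    def test_cohort_matches_microsimulation(self):
        """Expected-value engine vs seeded individual-level simulation."""
        # grid covering ages 60-85; 10k persons concentrated at 3 initial ages
        ages = np.arange(60, 86)
        A = len(ages)
        q = np.clip(0.005 * np.exp(0.07 * (ages - 60)), 0, 1)[:, None] * [[1.0, 1.5]]
        q[-1, :] = 1.0
        p = np.clip(0.02 * np.exp(0.05 * (ages - 60)), 0, 1)[:, None] * [[1.0, 2.0]]
        p = np.minimum(p, 0.5)
        cf = np.full((A, 2), 0.25)
        from tfacea import LifeTable, MorbidityTable
        life = LifeTable.from_arrays(ages, q_all_cause=q)
        morb = MorbidityTable.from_arrays(ages, p_cad_first=p, case_fatality=cf)

        counts = np.zeros((A, 2))
        for a, n in ((0, 2000), (10, 2000), (20, 1000)):
            counts[a, :] = n
        pop = PopulationPyramid.from_arrays(ages, count=counts)

        horizon = 20
        scen = ScenarioSpec.preset("base")
        risk = RiskParameters()
        traj = build_trajectory(OPTIONS["reference"], scen, horizon)
        tr = assemble_transitions(life, morb, traj, risk)

        ledger, _ = run_cohort(OPTIONS["reference"], scen, life, morb, pop,
                               horizon, risk)
        cohort = ledger.totals()

        mean, sd = replicate_microsim(tr, counts, horizon, n_reps=50, seed=1234)
        for key in ("first_events", "repeat_events", "cad_deaths", "other_deaths"):
            se = sd[key] / np.sqrt(50)
            assert abs(cohort[key] - mean[key]) <= 3 * max(se, 1e-9), (
                f"{key}: cohort {cohort[key]:.1f} vs micro {mean[key]:.1f} ± {se:.2f}")
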