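"""Dose-response scaling and transition-probability assembly."""
import math

import numpy as np
import pytest

from tfacea import (InputDataError, IntakeTrajectory, RiskParameters,
                    ScenarioSpec, assemble_transitions, build_trajectory,
                    cad_probability_at, rr_for_intake_change)
from tfacea.config import default_options
from conftest import flat_tables

OPTIONS = default_options()


class TestDoseResponse:
    def test_full_dose_returns_published_rr(self):
        assert rr_for_intake_change(2.0, 1.23) == pytest.approx(1.23)

    def test_zero_change_is_null(self):
        assert rr_for_intake_change(0.0, 1.23) == 1.0

    def test_log_linear_interpolation(self):
        # independent oracle: direct exponentiation
        assert rr_for_intake_change(-0.3, 1.23) == pytest.approx(1.23 ** (-0.15), rel=1e-12)

    def test_invalid_rr_rejected(self):
        with pytest.raises(InputDataError):
            rr_for_intake_change(1.0, 0.0)


def _trajectory(values, option_id="reference"):
    return IntakeTrajectory(option_id=option_id, scenario_name="t",
                            values=np.asarray(values, dtype=float))


class TestCadProbability:
    def test_baseline_identity_at_t0(self):
        _, morb = flat_tables(np.arange(3), q=0.02, p_cad=0.01, cf=0.3)
        traj = _trajectory([0.3, 0.15, 0.0])
        risk = RiskParameters()
        assert cad_probability_at(0, 1, "F", traj, morb, risk) == 0.01

    def test_scaled_by_intake_change(self):
        _, morb = flat_tables(np.arange(3), q=0.02, p_cad=0.01, cf=0.3)
        traj = _trajectory([0.3, 0.15, 0.0])
        risk = RiskParameters()
        expected = 0.01 * 1.23 ** ((0.0 - 0.3) / 2.0)
        assert cad_probability_at(2, 0, "M", traj, morb, risk) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.009694, abs=1e-6)

    def test_null_effect_when_rr_one(self):
        _, morb = flat_tables(np.arange(3), q=0.02, p_cad=0.01, cf=0.3)
        traj = _trajectory([0.3, 0.1, 0.0])
        risk = RiskParameters(rr_per_2Epct=1.0, rr_ci=(1.0, 1.0))
        for t in range(3):
            assert cad_probability_at(t, 2, "F", traj, morb, risk) == 0.01


class TestAssembleTransitions:
    def test_zero_morbidity_decouples_cad(self):
        life, morb = flat_tables(np.arange(4), q=0.1, p_cad=0.0, cf=0.3)
        traj = _trajectory([0.3] * 3)
        tr = assemble_transitions(life, morb, traj, RiskParameters())
        assert np.all(tr.p_first_cad == 0.0)
        # Well row collapses to (1 - q, 0, q) below the terminal age
        assert np.allclose(tr.p_death_other_well[:, :-1, :], 0.1)
        assert np.allclose(tr.p_stay_well[:, :-1, :], 0.9)

    def test_zero_case_fatality_means_certain_survival(self):
        life, morb = flat_tables(np.arange(3), q=0.02, p_cad=0.05, cf=0.0)
        traj = _trajectory([0.3, 0.3])
        tr = assemble_transitions(life, morb, traj, RiskParameters())
        assert np.all(tr.p_survive_cad == 1.0)
        assert np.all(tr.p_death_cad == 0.0)

    def test_hand_computed_single_stratum(self):
        # q=0.02, p0=0.05, cf=0.3, repeat RR 1.5, no intake change (RR=1)
        life, morb = flat_tables(np.arange(2), q=0.02, p_cad=0.05, cf=0.3)
        traj = _trajectory([0.0, 0.0])
        risk = RiskParameters(rr_per_2Epct=1.0, rr_ci=(1.0, 1.0),
                              rr_repeat_event=1.5, rr_death_second_event=1.5)
        tr = assemble_transitions(life, morb, traj, risk)
        # independent hand arithmetic
        h_all = -math.log(1 - 0.02)
        h_cad_death = -math.log(1 - 0.05 * 0.3)
        q_other = 1 - math.exp(-(h_all - h_cad_death))
        t, a, s = 0, 0, 0
        assert tr.p_first_cad[t, a, s] == pytest.approx(0.05, rel=1e-12)
        assert tr.p_death_other_well[t, a, s] == pytest.approx(q_other, rel=1e-12)
        assert tr.p_stay_well[t, a, s] == pytest.approx(1 - 0.05 - q_other, rel=1e-12)
        assert tr.p_survive_cad[t, a, s] == pytest.approx(0.7, rel=1e-12)
        assert tr.p_death_cad[t, a, s] == pytest.approx(0.3, rel=1e-12)
        assert tr.p_repeat_cad[t, a, s] == pytest.approx(1.5 * 0.05, rel=1e-12)
        assert tr.p_stay_history[t, a, s] == pytest.approx(1 - 0.075 - q_other, rel=1e-12)
        assert tr.case_fatality_repeat[t, a, s] == pytest.approx(0.45, rel=1e-12)

    def test_row_stochasticity_on_default_inputs(self, small_inputs, run_cfg):
        life, morb, _ = small_inputs
        traj = build_trajectory(OPTIONS["voluntary"], run_cfg.scenario, 20)
        tr = assemble_transitions(life, morb, traj, run_cfg.risk)
        for state, sums in tr.row_sums().items():
            assert np.allclose(sums, 1.0, atol=1e-12), state

    def test_lower_intake_never_raises_event_probability(self, small_inputs, run_cfg):
        life, morb, _ = small_inputs
        lo = build_trajectory(OPTIONS["legal_limit"], run_cfg.scenario, 20)
        hi = build_trajectory(OPTIONS["reference"], run_cfg.scenario, 20)
        assert np.all(lo.values <= hi.values + 1e-15)
        tr_lo = assemble_transitions(life, morb, lo, run_cfg.risk)
        tr_hi = assemble_transitions(life, morb, hi, run_cfg.risk)
        assert np.all(tr_lo.p_first_cad <= tr_hi.p_first_cad + 1e-15)

    def test_null_rr_makes_options_identical(self, small_inputs):
        life, morb, _ = small_inputs
        risk = RiskParameters(rr_per_2Epct=1.0, rr_ci=(1.0, 1.0))
        scen = ScenarioSpec.preset("base")
        tensors = []
        for opt in OPTIONS.values():
            traj = build_trajectory(opt, scen, 15)
            tensors.append(assemble_transitions(life, morb, traj, risk))
        for tr in tensors[1:]:
            assert np.array_equal(tr.p_first_cad, tensors[0].p_first_cad)
            assert np.array_equal(tr.p_death_other_well, tensors[0].p_death_other_well)

    def test_inconsistent_inputs_raise_naming_stratum(self):
        # event + repeat probabilities cannot fit in the history row
        life, morb = flat_tables(np.arange(3), q=0.5, p_cad=0.9, cf=0.1)
        traj = _trajectory([0.0, 0.0])
        with pytest.raises(InputDataError, match=r"(well|history).*age"):
            assemble_transitions(life, morb, traj, RiskParameters())
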