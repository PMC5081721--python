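"""Discounting, cost attribution and DALY computation."""
import numpy as np
import pytest

from tfacea import (CostSet, DalyParameters, discount_factor,
                    discounted_life_expectancy)
from tfacea.config import default_options
from tfacea.engine import EventLedger
from tfacea.outcomes import compute_costs, compute_dalys
from conftest import flat_tables

OPTIONS = default_options()
DALY = DalyParameters(disability_weight_acute=0.08, disability_weight_history=0.08)


def empty_ledger(T=3, A=5, S=2):
    z = lambda *shape: np.zeros(shape)
    return EventLedger(ages=np.arange(A), first_events=z(T, A, S),
                       repeat_events=z(T, A, S), cad_deaths=z(T, A, S),
                       other_deaths=z(T, S), py_well=z(T, S), py_cad=z(T, S),
                       py_history=z(T, S))


class TestDiscounting:
    def test_year_zero_is_one(self):
        assert discount_factor(0, 0.035) == 1.0

    def test_single_year(self):
        assert discount_factor(1, 0.035) == pytest.approx(1 / 1.035, rel=1e-12)
        assert float(discount_factor(1, 0.035)) == pytest.approx(0.966184, abs=5e-7)

    def test_zero_rate_is_identity(self):
        assert np.all(discount_factor(np.arange(50), 0.0) == 1.0)


class TestCosts:
    def test_reference_with_no_events_costs_nothing(self):
        led = empty_ledger()
        bd = compute_costs(led, OPTIONS["reference"], CostSet(), 0.035)
        assert bd.total == 0.0

    def test_single_acute_event_bundle(self):
        led = empty_ledger()
        led.first_events[0, 0, 0] = 1.0
        bd = compute_costs(led, OPTIONS["reference"], CostSet(), 0.035)
        # acute bundle: in-patient + medication + emergency + outpatient
        assert bd.total == pytest.approx(3557.46 + 1605.36 + 213.78 + 854.56, rel=1e-12)
        assert bd.total == pytest.approx(6231.16, abs=1e-9)

    def test_legal_limit_zero_events_pays_food_inspection_only(self):
        led = empty_ledger(T=4)
        led.py_well[:, :] = 50.0  # 100 alive per year
        bd = compute_costs(led, OPTIONS["legal_limit"], CostSet(), 0.035)
        expected = sum(100.0 * 0.86 * (1.035 ** -t) for t in range(4))
        assert bd.total == pytest.approx(expected, rel=1e-12)
        assert bd.measures.sum() == bd.total

    def test_chronic_and_mortality_attribution(self):
        led = empty_ledger()
        led.py_history[1, 0] = 10.0
        led.cad_deaths[2, 0, 0] = 2.0
        costs = CostSet()
        bd = compute_costs(led, OPTIONS["reference"], costs, 0.0)
        assert bd.chronic.sum() == pytest.approx(
            10 * (617.34 + 6440.19 + 2158.88), rel=1e-12)
        assert bd.mortality.sum() == pytest.approx(2 * 5101.94, rel=1e-12)

    def test_linearity_in_ledger(self):
        led = empty_ledger()
        led.first_events[0, 0, 0] = 3.0
        led.py_history[1, 1] = 7.0
        led.cad_deaths[2, 1, 0] = 1.0
        bd1 = compute_costs(led, OPTIONS["voluntary"], CostSet(), 0.035)
        bd2 = compute_costs(led.scaled(2.5), OPTIONS["voluntary"], CostSet(), 0.035)
        assert bd2.total == pytest.approx(2.5 * bd1.total, rel=1e-12)

    def test_discount_monotonicity(self):
        led = empty_ledger()
        led.first_events[2, 0, 0] = 5.0
        led.py_history[1, 0] = 5.0
        totals = [compute_costs(led, OPTIONS["reference"], CostSet(), r).total
                  for r in (0.0, 0.035, 0.1)]
        assert totals[0] >= totals[1] >= totals[2]

    def test_options_with_identical_ledgers_differ_only_in_measures(self):
        led = empty_ledger()
        led.first_events[0, 0, 0] = 2.0
        led.py_well[:, :] = 100.0
        bds = {oid: compute_costs(led, opt, CostSet(), 0.035)
               for oid, opt in OPTIONS.items()}
        base = bds["reference"]
        for oid, bd in bds.items():
            assert np.allclose(bd.cad_related, base.cad_related)
            if oid != "reference":
                assert bd.measures.sum() > 0


class TestDalys:
    def test_no_events_no_dalys(self):
        life, _ = flat_tables(np.arange(5), q=0.1, p_cad=0.0, cf=0.0)
        assert compute_dalys(empty_ledger(A=5), life, DALY, 0.035) == (0.0, 0.0)

    def test_zero_weights_zero_yld(self):
        life, _ = flat_tables(np.arange(5), q=0.1, p_cad=0.0, cf=0.0)
        led = empty_ledger(A=5)
        led.first_events[0, 0, 0] = 4.0
        led.py_history[1, 0] = 9.0
        daly0 = DalyParameters(disability_weight_acute=0.0, disability_weight_history=0.0)
        _, yld = compute_dalys(led, life, daly0, 0.035)
        assert yld == 0.0

    def test_single_death_yll_equals_expectancy_oracle(self):
        # constant q = 0.2 on 30 ages; independent expectancy recursion
        life, _ = flat_tables(np.arange(30), q=0.2, p_cad=0.0, cf=0.0)
        rate = 0.035
        q = 0.2
        # oracle: e(a) = sum_{k>=1} prod_{j<k}(1-q(a+j)) ... with terminal truncation
        def expectancy(a):
            surv, total = 1.0, 0.0
            for k in range(1, 30 - a):
                surv *= (1 - q)
                total += surv / (1 + rate) ** k
            return total

        dle = discounted_life_expectancy(life, rate)
        for a in (0, 10, 28):
            assert dle[a, 0] == pytest.approx(expectancy(a), rel=1e-10)

        led = empty_ledger(T=1, A=30)
        led.cad_deaths[0, 10, 1] = 1.0
        yll, _ = compute_dalys(led, life, DALY, rate)
        assert yll == pytest.approx(expectancy(10), rel=1e-10)

    def test_yld_components(self):
        life, _ = flat_tables(np.arange(5), q=0.0, p_cad=0.0, cf=0.0)
        led = empty_ledger(A=5)
        led.first_events[0, 0, 0] = 10.0
        led.py_history[2, 1] = 100.0
        yll, yld = compute_dalys(led, life, DALY, 0.0)
        assert yll == 0.0
        assert yld == pytest.approx(10 * 0.08 * 1.0 + 100 * 0.08, rel=1e-12)

    def test_effect_discounting_switch(self):
        life, _ = flat_tables(np.arange(10), q=0.1, p_cad=0.0, cf=0.0)
        led = empty_ledger(T=5, A=10)
        led.first_events[4, 0, 0] = 10.0
        on = compute_dalys(led, life, DALY, 0.05)
        off_daly = DalyParameters(disability_weight_acute=0.08,
                                  disability_weight_history=0.08,
                                  discount_effects=False)
        off = compute_dalys(led, life, off_daly, 0.05)
        assert off[1] > on[1]
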