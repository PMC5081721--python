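"""Discounted costs and DALYs from the event ledger.

Costs fall into three groups, all in 2011 euros and discounted at the run's
annual rate:

* CAD-related costs — an acute bundle per event (in-patient, medication,
  emergency, outpatient), a chronic bundle per person-year in the
  history-of-CAD state (primary care, informal care, production loss from
  morbidity) and a per-CAD-death production loss.  The attribution of items
  to bundles is configurable on :class:`~tfacea.config.CostSet`.
* Policy-measure costs — per person alive per year, for the measures active
  under the option in that year.

DALYs = YLL + YLD.  YLL values each CAD death with the discounted remaining
period life expectancy at the age of death, computed from the run's own life
table; no age weighting.  YLD applies a disability weight to the acute event
year and to each person-year lived in the history state.  Both are
discounted to present value at the same rate as costs (switchable off via
``DalyParameters.discount_effects``).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .config import CostSet, DalyParameters, PolicyOption
from .io import LifeTable

if TYPE_CHECKING:  # pragma: no cover
    from .engine import EventLedger

__all__ = ["discount_factor", "compute_costs", "compute_dalys",
           "discounted_life_expectancy", "RunResult", "CostBreakdown"]


def discount_factor(t, rate: float):
    """Present-value multiplier (1 + rate) ** (-t); t = 0 gives 1."""
    if rate < 0:
        raise ValueError(f"discount rate must be >= 0, got {rate!r}")
    return (1.0 + rate) ** (-np.asarray(t, dtype=float))


@dataclass(frozen=True)
class CostBreakdown:
    """Per-year discounted cost series (euros) and their totals."""

    acute: np.ndarray
    chronic: np.ndarray
    mortality: np.ndarray
    measures: np.ndarray

    @property
    def cad_related(self) -> np.ndarray:
        return self.acute + self.chronic + self.mortality

    @property
    def per_year(self) -> np.ndarray:
        return self.cad_related + self.measures

    @property
    def total(self) -> float:
        return float(self.per_year.sum())

    def by_category(self) -> dict[str, float]:
        return {
            "acute": float(self.acute.sum()),
            "chronic": float(self.chronic.sum()),
            "mortality": float(self.mortality.sum()),
            "measures": float(self.measures.sum()),
        }


def compute_costs(ledger: EventLedger, option: PolicyOption, costs: CostSet,
                  discount_rate: float) -> CostBreakdown:
    """Discounted cost series per year for one option's ledger."""
    costs.validate()
    option.validate()
    T = ledger.horizon
    df = discount_factor(np.arange(T), discount_rate)

    events = ledger.events.sum(axis=(1, 2))          # all acute events per year
    history_py = ledger.py_history.sum(axis=1)
    cad_deaths = ledger.cad_deaths.sum(axis=(1, 2))
    alive = ledger.alive_start.sum(axis=1)

    acute = events * costs.acute_event_cost * df
    chronic = history_py * costs.history_year_cost * df
    mortality = cad_deaths * costs.cad_death_cost * df

    measure_rate = np.zeros(T)
    years = np.arange(T, dtype=float)
    for name, (start, end) in option.measures.items():
        active = (years >= start) & (years < (end if end is not None else np.inf))
        measure_rate += np.where(active, costs.measure_cost(name), 0.0)
    measures = alive * measure_rate * df

    return CostBreakdown(acute=acute, chronic=chronic, mortality=mortality,
                         measures=measures)


def discounted_life_expectancy(life: LifeTable, rate: float) -> np.ndarray:
    """Discounted remaining period life expectancy per (age, sex), shape (A, 2).

    e(a) = sum_k P(survive from a to a+k) / (1+rate)^k for k >= 1, from the
    life table's own annual death probabilities (curtate expectancy); zero
    at the absorbing last age.
    """
    q = life.as_array("q_all_cause")
    A = q.shape[0]
    dle = np.zeros_like(q)
    v = 1.0 / (1.0 + rate)
    for a in range(A - 2, -1, -1):
        dle[a] = (1.0 - q[a]) * v * (1.0 + dle[a + 1])
    return dle


def compute_dalys(ledger: EventLedger, life: LifeTable, daly: DalyParameters,
                  discount_rate: float) -> tuple[float, float]:
    """(YLL, YLD) for one option's ledger, discounted to present value."""
    daly.validate()
    rate = discount_rate if daly.discount_effects else 0.0
    T, A, _ = ledger.cad_deaths.shape
    df = discount_factor(np.arange(T), rate)

    dle = discounted_life_expectancy(life, rate)     # (A, S) by attained age
    yll = 0.0
    for t in range(T):
        idx = np.minimum(np.arange(A) + t, A - 1)    # age at death = initial age + t
        yll += df[t] * float((ledger.cad_deaths[t] * dle[idx, :]).sum())

    events = ledger.events.sum(axis=(1, 2))
    history_py = ledger.py_history.sum(axis=1)
    yld = float((events * daly.disability_weight_acute * daly.acute_duration * df).sum()
                + (history_py * daly.disability_weight_history * df).sum())
    return float(yll), yld


def compute_dalys_by_sex(ledger: EventLedger, life: LifeTable, daly: DalyParameters,
                         discount_rate: float) -> np.ndarray:
    """DALYs (YLL + YLD) split by sex, shape (2,), order (F, M)."""
    daly.validate()
    rate = discount_rate if daly.discount_effects else 0.0
    T, A, S = ledger.cad_deaths.shape
    df = discount_factor(np.arange(T), rate)
    dle = discounted_life_expectancy(life, rate)
    out = np.zeros(S)
    for t in range(T):
        idx = np.minimum(np.arange(A) + t, A - 1)
        out += df[t] * (ledger.cad_deaths[t] * dle[idx, :]).sum(axis=0)
    events = ledger.events.sum(axis=1)               # (T, S)
    out += (events * df[:, None]).sum(axis=0) * daly.disability_weight_acute * daly.acute_duration
    out += (ledger.py_history * df[:, None]).sum(axis=0) * daly.disability_weight_history
    return out


@dataclass(frozen=True)
class RunResult:
    """Discounted costs and DALYs plus raw counts for one option run."""

    option_id: str
    scenario_name: str
    cost_breakdown: CostBreakdown
    yll: float
    yld: float
    counts: dict[str, float] = field(default_factory=dict)

    @property
    def total_cost(self) -> float:
        return self.cost_breakdown.total

    @property
    def dalys(self) -> float:
        return self.yll + self.yld

    def summary_row(self) -> dict[str, float | str]:
        row: dict[str, float | str] = {
            "option": self.option_id,
            "scenario": self.scenario_name,
            "total_cost_eur": self.total_cost,
            "dalys": self.dalys,
            "yll": self.yll,
            "yld": self.yld,
        }
        row.update({f"cost_{k}_eur": v for k, v in self.cost_breakdown.by_category().items()})
        row.update(self.counts)
        return row


def attach_outcomes(ledger: EventLedger, option: PolicyOption, scenario_name: str,
                    life: LifeTable, costs: CostSet, daly: DalyParameters,
                    discount_rate: float) -> RunResult:
    """Bundle the ledger's discounted costs, DALYs and raw counts."""
    breakdown = compute_costs(ledger, option, costs, discount_rate)
    yll, yld = compute_dalys(ledger, life, daly, discount_rate)
    return RunResult(option_id=option.identifier, scenario_name=scenario_name,
                     cost_breakdown=breakdown, yll=yll, yld=yld,
                     counts=ledger.totals())
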