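"""Deterministic multi-age Markov cohort engine.

A closed cohort (the initial population pyramid; no births or migration)
moves in yearly cycles through Well, CAD (acute, exactly one cycle),
History-of-CAD and Dead.  The update is expected-value arithmetic: fractions
of each stratum flow along the transition probabilities; no sampling.
Stochasticity enters the analysis only through probabilistic parameter
draws, never through the cohort update.

Strata are indexed by (initial age, sex); the current age in cycle t is
initial age + t, capped at the table's last (absorbing) age, past which any
remaining occupancy is moved to Dead.  Events are counted in the cycle in
which they occur; deaths during the acute year are CAD deaths.  No
half-cycle correction is applied.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PolicyOption, RiskParameters, ScenarioSpec, SEXES
from .intake import build_trajectory
from .io import LifeTable, MorbidityTable, PopulationPyramid
from .risk import TransitionProbabilities, assemble_transitions

__all__ = ["CohortState", "EventLedger", "initialize_cohort", "step",
           "run_cohort", "run", "run_all_options", "ledger_frame"]


@dataclass
class CohortState:
    """Occupancy (persons, fractional) of the four states per (age, sex) stratum.

    The acute CAD state is split into first-event and repeat-event
    sub-compartments because their case fatalities differ; together they are
    the CAD state.  ``ages`` are initial ages (the stratum labels).
    """

    ages: np.ndarray
    well: np.ndarray
    cad_first: np.ndarray
    cad_repeat: np.ndarray
    history: np.ndarray
    dead: np.ndarray

    @property
    def cad(self) -> np.ndarray:
        return self.cad_first + self.cad_repeat

    @property
    def alive(self) -> np.ndarray:
        return self.well + self.cad + self.history

    @property
    def total(self) -> float:
        return float((self.alive + self.dead).sum())

    def copy(self) -> "CohortState":
        return CohortState(self.ages, self.well.copy(), self.cad_first.copy(),
                           self.cad_repeat.copy(), self.history.copy(), self.dead.copy())


@dataclass
class EventLedger:
    """Per-cycle flows and occupancy, by stratum where age matters.

    ``first_events``, ``repeat_events`` and ``cad_deaths`` keep the
    (cycle, initial-age, sex) resolution needed for life-expectancy-based
    outcome calculations (age at event = initial age + cycle); occupancy
    person-years and other-cause deaths are aggregated per (cycle, sex).
    """

    ages: np.ndarray
    first_events: np.ndarray   # (T, A, S)
    repeat_events: np.ndarray  # (T, A, S)
    cad_deaths: np.ndarray     # (T, A, S)
    other_deaths: np.ndarray   # (T, S)
    py_well: np.ndarray        # (T, S)
    py_cad: np.ndarray         # (T, S)
    py_history: np.ndarray     # (T, S)

    @property
    def horizon(self) -> int:
        return self.first_events.shape[0]

    @property
    def events(self) -> np.ndarray:
        """All acute CAD events per (cycle, initial age, sex)."""
        return self.first_events + self.repeat_events

    @property
    def alive_start(self) -> np.ndarray:
        """Persons alive at the start of each cycle, per (cycle, sex)."""
        return self.py_well + self.py_cad + self.py_history

    def totals(self) -> dict[str, float]:
        return {
            "first_events": float(self.first_events.sum()),
            "repeat_events": float(self.repeat_events.sum()),
            "cad_deaths": float(self.cad_deaths.sum()),
            "other_deaths": float(self.other_deaths.sum()),
        }

    def scaled(self, k: float) -> "EventLedger":
        return EventLedger(self.ages, self.first_events * k, self.repeat_events * k,
                           self.cad_deaths * k, self.other_deaths * k,
                           self.py_well * k, self.py_cad * k, self.py_history * k)


def initialize_cohort(population: PopulationPyramid) -> CohortState:
    """Everyone starts event-free: the full pyramid in Well at cycle 0."""
    counts = population.as_array("count")
    zeros = np.zeros_like(counts)
    return CohortState(ages=population.ages, well=counts.astype(float),
                       cad_first=zeros.copy(), cad_repeat=zeros.copy(),
                       history=zeros.copy(), dead=zeros.copy())


def step(state: CohortState, transitions: TransitionProbabilities, t: int,
         ) -> tuple[CohortState, dict[str, np.ndarray]]:
    """Advance the cohort one yearly cycle using year-t transition rows.

    Returns the new state plus the cycle's flows.  Flow conservation is
    exact by construction (stay-occupancies are computed as residuals of the
    stratum mass).  Negative occupancy (invalid transition rows) raises.
    """
    A = len(state.ages)
    idx = np.minimum(np.arange(A) + t, A - 1)

    p2 = transitions.p_first_cad[t][idx, :]
    p5 = transitions.p_repeat_cad[t][idx, :]
    p6 = transitions.p_death_other_well[t][idx, :]
    p7 = transitions.p_death_cad[t][idx, :]
    p8 = transitions.p_death_other_history[t][idx, :]
    cf_rep = transitions.case_fatality_repeat[t][idx, :]

    new_first = state.well * p2
    d_other_well = state.well * p6
    well = state.well - new_first - d_other_well

    d_cad = state.cad_first * p7 + state.cad_repeat * cf_rep
    survivors = state.cad_first + state.cad_repeat - d_cad

    new_repeat = state.history * p5
    d_other_hist = state.history * p8
    history = state.history - new_repeat - d_other_hist + survivors

    dead = state.dead + d_other_well + d_other_hist + d_cad

    new = CohortState(state.ages, well, new_first.copy(), new_repeat.copy(), history, dead)

    # anything alive past the absorbing age is moved to Dead (other cause)
    beyond_next = np.arange(A) + t + 1 > A - 1
    forced = np.zeros_like(well)
    if beyond_next.any():
        overflow = new.well[beyond_next] + new.cad_first[beyond_next] \
            + new.cad_repeat[beyond_next] + new.history[beyond_next]
        forced[beyond_next] = overflow
        new.dead[beyond_next] += overflow
        for arr in (new.well, new.cad_first, new.cad_repeat, new.history):
            arr[beyond_next] = 0.0

    for name, arr in (("well", new.well), ("cad", new.cad),
                      ("history", new.history), ("dead", new.dead)):
        if arr.min() < -1e-9:
            raise RuntimeError(f"negative occupancy in state {name!r} after cycle {t}: "
                               f"{arr.min():.3e} (invalid transition row)")

    flows = {
        "first_events": new_first,
        "repeat_events": new_repeat,
        "cad_deaths": d_cad,
        "other_deaths": (d_other_well + d_other_hist + forced).sum(axis=0),
    }
    return new, flows


def run_cohort(option: PolicyOption, scenario: ScenarioSpec,
               life: LifeTable, morbidity: MorbidityTable,
               population: PopulationPyramid, horizon: int,
               risk: RiskParameters, decay_shape: str = "linear",
               ) -> tuple[EventLedger, CohortState]:
    """Run one policy option's cohort over the horizon.

    Builds the option's intake trajectory and transition tensor, then
    iterates the yearly update, returning the event ledger and final state.
    """
    trajectory = build_trajectory(option, scenario, horizon, shape=decay_shape)
    transitions = assemble_transitions(life, morbidity, trajectory, risk)
    state = initialize_cohort(population)
    A, S = state.well.shape

    ledger = EventLedger(
        ages=state.ages,
        first_events=np.zeros((horizon, A, S)),
        repeat_events=np.zeros((horizon, A, S)),
        cad_deaths=np.zeros((horizon, A, S)),
        other_deaths=np.zeros((horizon, S)),
        py_well=np.zeros((horizon, S)),
        py_cad=np.zeros((horizon, S)),
        py_history=np.zeros((horizon, S)),
    )
    for t in range(horizon):
        ledger.py_well[t] = state.well.sum(axis=0)
        ledger.py_cad[t] = state.cad.sum(axis=0)
        ledger.py_history[t] = state.history.sum(axis=0)
        state, flows = step(state, transitions, t)
        ledger.first_events[t] = flows["first_events"]
        ledger.repeat_events[t] = flows["repeat_events"]
        ledger.cad_deaths[t] = flows["cad_deaths"]
        ledger.other_deaths[t] = flows["other_deaths"]
    return ledger, state


def run(option: PolicyOption, scenario: ScenarioSpec, life: LifeTable,
        morbidity: MorbidityTable, population: PopulationPyramid,
        run_config, risk: RiskParameters | None = None, costs=None):
    """Run one option end to end and attach discounted costs and DALYs.

    ``risk`` and ``costs`` default to the run configuration's parameter sets;
    the probabilistic analysis passes sampled replacements here.
    """
    from .outcomes import attach_outcomes

    risk = risk if risk is not None else run_config.risk
    costs = costs if costs is not None else run_config.costs
    ledger, _ = run_cohort(option, scenario, life, morbidity, population,
                           run_config.horizon_years, risk,
                           decay_shape=run_config.decay_shape)
    return attach_outcomes(ledger, option, scenario.name, life, costs,
                           run_config.daly, run_config.discount_rate)


def run_all_options(life: LifeTable, morbidity: MorbidityTable,
                    population: PopulationPyramid, run_config,
                    risk: RiskParameters | None = None, costs=None,
                    scenario: ScenarioSpec | None = None):
    """Run every configured option; returns {option_id: RunResult}."""
    scenario = scenario if scenario is not None else run_config.scenario
    return {
        oid: run(opt, scenario, life, morbidity, population, run_config,
                 risk=risk, costs=costs)
        for oid, opt in run_config.policy_options().items()
    }


def ledger_frame(ledger: EventLedger):
    """Per-(cycle, sex) summary of the ledger as a DataFrame for export."""
    import pandas as pd

    T, _, S = ledger.first_events.shape
    rows = []
    for s, sex in enumerate(SEXES):
        rows.append(pd.DataFrame({
            "year": np.arange(T),
            "sex": sex,
            "py_well": ledger.py_well[:, s],
            "py_cad": ledger.py_cad[:, s],
            "py_history": ledger.py_history[:, s],
            "first_events": ledger.first_events[:, :, s].sum(axis=1),
            "repeat_events": ledger.repeat_events[:, :, s].sum(axis=1),
            "cad_deaths": ledger.cad_deaths[:, :, s].sum(axis=1),
            "other_deaths": ledger.other_deaths[:, s],
        }))
    return pd.concat(rows, ignore_index=True)
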