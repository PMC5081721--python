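"""Intake-dependent CAD risk and the four-state transition probabilities.

The model links diet to disease through a single pooled relative risk:
RR = 1.23 per 2 E% of trans fat replacing carbohydrate.  Baseline CAD event
probabilities (from the morbidity table) already embed the initial intake,
so the event probability in model year t is

    p_t(a, s) = p0(a, s) * RR ** ((E_t - E_0) / 2)

clamped into [0, 1], with log-linear interpolation in the intake change —
the standard convention for pooled dose-response RRs.

From these, the eight transition probabilities of the four-state model
(Well, CAD, History-of-CAD, Dead) are assembled per (year, age, sex):

1. stay well, 2. first CAD event, 3. survive the acute event, 4. stay in the
history state, 5. repeat CAD event, 6. non-CAD death from Well, 7. death
from the acute CAD event, 8. non-CAD death from History.

Non-CAD death is the all-cause probability with the CAD-death hazard removed
by hazard subtraction, q_other = 1 - exp(-[-ln(1-q_all) + ln(1 - p_cad*cf)]),
guarded to [0, 1], which avoids double counting CAD deaths inside all-cause
mortality.  Repeat events carry RR 1.5 relative to first events, and death
from a repeat event RR 1.5 relative to the first-event case fatality, both
capped at probability 1.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import InputDataError, RiskParameters, SEXES
from .intake import IntakeTrajectory
from .io import LifeTable, MorbidityTable

__all__ = [
    "rr_for_intake_change",
    "cad_probability_at",
    "TransitionProbabilities",
    "assemble_transitions",
]

_RESIDUAL_TOL = 1e-9


def rr_for_intake_change(delta_e_pct, rr_per_2Epct: float):
    """Relative-risk multiplier for an intake change of ``delta_e_pct`` E%.

    Log-linear in the dose: RR ** (delta / 2).  delta = 0 gives 1.
    """
    if rr_per_2Epct <= 0:
        raise InputDataError(f"rr_per_2Epct must be > 0, got {rr_per_2Epct!r}")
    return rr_per_2Epct ** (np.asarray(delta_e_pct, dtype=float) / 2.0)


def cad_probability_at(t: int, age: int, sex: str, trajectory: IntakeTrajectory,
                       morbidity: MorbidityTable, risk: RiskParameters) -> float:
    """First-CAD-event probability at model year t for one stratum.

    At t = 0 this returns the baseline morbidity-table probability exactly;
    later years scale it by the RR for the intake change since year 0.
    """
    si = SEXES.index(sex)
    p0 = morbidity.as_array("p_cad_first")[age - morbidity.min_age, si]
    path = trajectory.for_sex(sex)
    delta = path[t] - path[0]
    return float(np.clip(p0 * rr_for_intake_change(delta, risk.rr_per_2Epct), 0.0, 1.0))


@dataclass(frozen=True)
class TransitionProbabilities:
    """The eight transition probabilities on a (year, age, sex) grid.

    Arrays have shape (horizon + 1, n_ages, 2); ``ages`` gives the age axis
    and sexes are ordered (F, M).  ``case_fatality_repeat`` is the fatality
    applied to repeat events (capped RR x first-event case fatality); it is
    carried alongside the eight state-row probabilities because the acute
    state mixes first and repeat events.
    """

    ages: np.ndarray
    p_stay_well: np.ndarray          # 1
    p_first_cad: np.ndarray          # 2
    p_survive_cad: np.ndarray        # 3
    p_stay_history: np.ndarray       # 4
    p_repeat_cad: np.ndarray         # 5
    p_death_other_well: np.ndarray   # 6
    p_death_cad: np.ndarray          # 7
    p_death_other_history: np.ndarray  # 8
    case_fatality_repeat: np.ndarray

    @property
    def horizon(self) -> int:
        return self.p_stay_well.shape[0] - 1

    def row_sums(self) -> dict[str, np.ndarray]:
        """Outgoing-probability sums per state (all should equal 1)."""
        return {
            "well": self.p_stay_well + self.p_first_cad + self.p_death_other_well,
            "cad": self.p_survive_cad + self.p_death_cad,
            "history": self.p_stay_history + self.p_repeat_cad + self.p_death_other_history,
        }


def assemble_transitions(life: LifeTable, morbidity: MorbidityTable,
                         trajectory: IntakeTrajectory, risk: RiskParameters,
                         ) -> TransitionProbabilities:
    """Assemble all eight transition probabilities for every (year, age, sex).

    Raises :class:`InputDataError` naming the first offending stratum if any
    residual stay-probability would be negative (inconsistent inputs, e.g.
    event plus death probabilities exceeding 1).
    """
    risk.validate()
    if not life.same_grid(morbidity):
        raise InputDataError("life and morbidity tables are on different age grids")
    ages = life.ages
    q_all = life.as_array("q_all_cause")[None, :, :]            # (1, A, S)
    p0 = morbidity.as_array("p_cad_first")[None, :, :]
    cf = morbidity.as_array("case_fatality")[None, :, :]

    intake = trajectory.as_matrix()                             # (T+1, S)
    delta = intake - intake[0:1, :]
    rr_t = rr_for_intake_change(delta, risk.rr_per_2Epct)[:, None, :]  # (T+1, 1, S)

    p_cad = np.clip(p0 * rr_t, 0.0, 1.0)
    terminal = np.broadcast_to(q_all >= 1.0, p_cad.shape)
    p_cad = np.where(terminal, 0.0, p_cad)  # the absorbing last age dies, no new events

    # hazard subtraction removes the CAD-death component from all-cause death
    with np.errstate(divide="ignore"):
        h_all = -np.log1p(-np.minimum(q_all, 1.0))
        h_cad_death = -np.log1p(-p_cad * cf)
    q_other = 1.0 - np.exp(-(np.maximum(h_all - h_cad_death, 0.0)))
    q_other = np.clip(np.broadcast_to(q_other, p_cad.shape), 0.0, 1.0)

    p_repeat = np.minimum(risk.rr_repeat_event * p_cad, 1.0)
    cf_repeat = np.broadcast_to(np.minimum(risk.rr_death_second_event * cf, 1.0), p_cad.shape)
    cf_b = np.broadcast_to(cf, p_cad.shape)

    p_stay_well = 1.0 - p_cad - q_other
    p_stay_history = 1.0 - p_repeat - q_other
    for name, resid in (("well", p_stay_well), ("history", p_stay_history)):
        if resid.min() < -_RESIDUAL_TOL:
            t, a, s = np.unravel_index(int(np.argmin(resid)), resid.shape)
            raise InputDataError(
                f"negative residual stay-probability in state {name!r} at "
                f"year {t}, age {ages[a]}, sex {SEXES[s]}: {resid[t, a, s]:.3e} "
                "(event and death probabilities exceed 1; inputs inconsistent)"
            )
    p_stay_well = np.clip(p_stay_well, 0.0, 1.0)
    p_stay_history = np.clip(p_stay_history, 0.0, 1.0)

    return TransitionProbabilities(
        ages=ages,
        p_stay_well=p_stay_well,
        p_first_cad=p_cad,
        p_survive_cad=1.0 - cf_b,
        p_stay_history=p_stay_history,
        p_repeat_cad=p_repeat,
        p_death_other_well=q_other,
        p_death_cad=cf_b + np.zeros_like(p_cad),
        p_death_other_history=q_other.copy(),
        case_fatality_repeat=cf_repeat + np.zeros_like(p_cad),
    )


def transitions_frame(trans: TransitionProbabilities):
    """Long-format audit dump (year, age, sex, p1..p8) as a DataFrame."""
    import pandas as pd

    T, A, S = trans.p_stay_well.shape
    years, ages_ix, sex_ix = np.meshgrid(
        np.arange(T), np.arange(A), np.arange(S), indexing="ij")
    return pd.DataFrame({
        "year": years.ravel(),
        "age": trans.ages[ages_ix.ravel()],
        "sex": np.array(SEXES)[sex_ix.ravel()],
        "p_stay_well": trans.p_stay_well.ravel(),
        "p_first_cad": trans.p_first_cad.ravel(),
        "p_survive_cad": trans.p_survive_cad.ravel(),
        "p_stay_history": trans.p_stay_history.ravel(),
        "p_repeat_cad": trans.p_repeat_cad.ravel(),
        "p_death_other_well": trans.p_death_other_well.ravel(),
        "p_death_cad": trans.p_death_cad.ravel(),
        "p_death_other_history": trans.p_death_other_history.ravel(),
    })
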