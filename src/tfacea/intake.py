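"""iTFA intake trajectories (E% per model year) per policy option.

Each policy option phases industrial trans fat out of the food supply on its
own schedule: the reference situation over 10 years (national efforts only),
voluntary agreements over 5, a legal limit over 2, and mandatory labeling as
a composite — two years at the reference pace until labels are in place,
after which the prepackaged half of intake declines to zero over three years
while the non-prepackaged half stays on the reference path.

The decline between anchor points is linear by default; an exponential shape
(truncated so intake still reaches exactly zero at the phase-out year) can be
selected via ``RunConfig.decay_shape``.  Intake is the population-average
iTFA intake in E%; per-stratum trajectories scale the overall path by the
scenario's sex multipliers.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .config import PolicyOption, ScenarioSpec, SEXES

logger = logging.getLogger(__name__)

__all__ = ["IntakeTrajectory", "build_trajectory", "cumulative_intake"]


def _phase_out_path(initial: float, phase_out_years: float, years: np.ndarray,
                    shape: str, exp_rate_halflives: float = 3.0) -> np.ndarray:
    """Intake path from ``initial`` at year 0 to exactly 0 at ``phase_out_years``."""
    t_end = float(phase_out_years)
    if initial == 0.0 or t_end <= 0.0:
        return np.zeros_like(years, dtype=float)
    if shape == "linear":
        path = initial * np.clip(1.0 - years / t_end, 0.0, None)
    elif shape == "exponential":
        # exponential decay shifted so the path hits exactly 0 at t_end
        k = exp_rate_halflives * np.log(2.0) / t_end
        raw = (np.exp(-k * np.clip(years, 0.0, t_end)) - np.exp(-k * t_end)) / (1.0 - np.exp(-k * t_end))
        path = initial * np.where(years >= t_end, 0.0, raw)
    else:  # pragma: no cover - guarded by RunConfig.validate
        raise ValueError(f"unknown decay shape {shape!r}")
    path[years >= t_end] = 0.0
    return path


@dataclass(frozen=True)
class IntakeTrajectory:
    """Population iTFA intake (E%) at model years 0..horizon for one option.

    ``values`` is the overall (population-average) path; per-sex paths are
    the overall path scaled by ``sex_multipliers``.
    """

    option_id: str
    scenario_name: str
    values: np.ndarray
    sex_multipliers: Mapping[str, float] = field(default_factory=lambda: {s: 1.0 for s in SEXES})

    @property
    def horizon(self) -> int:
        return len(self.values) - 1

    def initial_intake(self, sex: str | None = None) -> float:
        m = 1.0 if sex is None else float(self.sex_multipliers[sex])
        return float(self.values[0]) * m

    def for_sex(self, sex: str) -> np.ndarray:
        return self.values * float(self.sex_multipliers[sex])

    def as_matrix(self) -> np.ndarray:
        """Intake per (year, sex), shape (horizon + 1, 2), sex order (F, M)."""
        mult = np.array([float(self.sex_multipliers[s]) for s in SEXES])
        return self.values[:, None] * mult[None, :]


def build_trajectory(option: PolicyOption, scenario: ScenarioSpec, horizon: int,
                     shape: str = "linear") -> IntakeTrajectory:
    """Build the option's intake trajectory under a scenario.

    The trajectory is evaluated at integer model years t = 0..horizon, is
    non-increasing, starts at the scenario's initial intake and reaches
    exactly zero by the option's phase-out year.  A horizon shorter than the
    phase-out is valid (the path is truncated) but logged as a warning.
    """
    option.validate()
    scenario.validate()
    years = np.arange(horizon + 1, dtype=float)
    e0 = scenario.initial_intake_overall

    if option.labeling:
        ref = _phase_out_path(e0, option.reference_phase_out_years, years, shape)
        share = option.prepackaged_share
        non_pre = (1.0 - share) * ref
        pre = share * ref.copy()
        t_lead = option.labeling_lead_years
        t_done = t_lead + option.prepackaged_phase_years
        # prepackaged component: reference pace until labels are in place,
        # then linear to zero over the prepackaged phase-out window
        at_lead = share * _phase_out_path(e0, option.reference_phase_out_years,
                                          np.array([t_lead]), shape)[0]
        post = years > t_lead
        with np.errstate(invalid="ignore"):
            ramp = at_lead * np.clip(1.0 - (years - t_lead) / (t_done - t_lead), 0.0, None)
        pre[post] = ramp[post]
        pre[years >= t_done] = 0.0
        values = non_pre + pre
        phase_out = max(option.reference_phase_out_years, t_done)
    else:
        values = _phase_out_path(e0, option.phase_out_years, years, shape)
        phase_out = option.phase_out_years

    if horizon < phase_out and e0 > 0:
        msg = (f"horizon {horizon} y is shorter than the {option.identifier!r} "
               f"phase-out ({phase_out} y); trajectory truncated")
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)

    values = np.clip(values, 0.0, None)
    return IntakeTrajectory(
        option_id=option.identifier,
        scenario_name=scenario.name,
        values=values,
        sex_multipliers={s: float(scenario.sex_multipliers[s]) for s in SEXES},
    )


def cumulative_intake(trajectory: IntakeTrajectory, sex: str | None = None) -> float:
    """Cumulative intake (E% · years): the sum of yearly intakes over the path.

    The reference situation has the highest cumulative intake of the four
    options, the legal limit the lowest.
    """
    values = trajectory.values if sex is None else trajectory.for_sex(sex)
    return float(values.sum())
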