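"""EU-like synthetic demographic and epidemiologic input tables.

The real analysis is driven by European life tables, ischaemic-heart-disease
hospital-discharge statistics and the EU population pyramid.  Those extracts
are not redistributable, so this module generates inputs with the same
statistical structure, controlled by a handful of parameters
(:class:`~tfacea.config.SyntheticConfig`):

* all-cause mortality is Gompertz in the hazard — rising exponentially with
  age — with a male excess (default hazard ratio 1.5), converted to annual
  probabilities via ``q = 1 - exp(-h)``; the last age is absorbing (q = 1);
* first-CAD-event probability rises log-linearly with age and is higher in
  men (default hazard ratio 2.0); case fatality of the acute event rises
  linearly with age;
* the population pyramid (default 508 million persons) follows the survival
  curve implied by the life table, with a small seeded jitter; counts are
  non-increasing above age 65.

Rate curves are deterministic functions of the parameters; the seeded RNG
is used only for the pyramid jitter, so identical (seed, config) pairs give
identical tables.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np

from .config import SEXES, SyntheticConfig
from .io import LifeTable, MorbidityTable, PopulationPyramid

__all__ = [
    "generate_life_table",
    "generate_morbidity_table",
    "generate_population",
    "generate_inputs",
    "write_dataset",
]


def _sex_multipliers(female: float, male: float) -> np.ndarray:
    return np.array([[female, male]])  # broadcast over the age axis


def generate_life_table(config: SyntheticConfig) -> LifeTable:
    """Annual all-cause mortality q(a, s) = 1 - exp(-alpha * exp(beta*a) * k_s).

    q is non-decreasing in age everywhere (Gompertz hazard) and the terminal
    age is absorbing: q(max_age, s) = 1.
    """
    config.validate()
    ages = np.arange(config.max_age + 1)
    hazard = config.gompertz_alpha * np.exp(config.gompertz_beta * ages)[:, None]
    hazard = hazard * _sex_multipliers(1.0, config.male_mortality_ratio)
    q = 1.0 - np.exp(-hazard)
    q[-1, :] = 1.0  # absorbing last age bounds the horizon
    return LifeTable.from_arrays(ages, q_all_cause=q)


def generate_morbidity_table(config: SyntheticConfig) -> MorbidityTable:
    """First-CAD-event probability and case fatality by (age, sex).

    The event probability is p(a, s) = 1 - exp(-r0 * exp(gamma*a) * m_s)
    with the male:female hazard ratio ``male_cad_ratio``; case fatality is
    ``case_fatality_base + case_fatality_age_slope * a`` clipped to [0, 1].
    """
    config.validate()
    ages = np.arange(config.max_age + 1)
    hazard = config.cad_rate_scale * np.exp(config.cad_age_slope * ages)[:, None]
    hazard = hazard * _sex_multipliers(1.0, config.male_cad_ratio)
    p = 1.0 - np.exp(-hazard)
    cf = np.clip(config.case_fatality_base
                 + config.case_fatality_age_slope * ages, 0.0, 1.0)[:, None]
    cf = np.broadcast_to(cf, p.shape).copy()
    return MorbidityTable.from_arrays(ages, p_cad_first=p, case_fatality=cf)


def generate_population(config: SyntheticConfig,
                        life_table: LifeTable | None = None) -> PopulationPyramid:
    """A population pyramid following the life table's survival curve.

    Cell weights are the per-sex survivorship l(a) from the (generated or
    supplied) life table, perturbed by a small seeded multiplicative jitter;
    counts above age 65 are forced non-increasing, then cells are scaled to
    sum to ``population_total`` and rounded to whole persons.
    """
    config.validate()
    if life_table is None:
        life_table = generate_life_table(config)
    q = life_table.as_array("q_all_cause")
    ages = life_table.ages
    # survivorship: l(0) = 1, l(a+1) = l(a) * (1 - q(a))
    survival = np.vstack([np.ones((1, 2)), np.cumprod(1.0 - q[:-1, :], axis=0)])
    rng = np.random.default_rng(config.seed)
    j = config.pyramid_jitter
    jitter = rng.uniform(1.0 - j, 1.0 + j, size=survival.shape)
    weights = survival * jitter
    over65 = ages > 65
    if over65.any():
        start = int(np.argmax(over65))
        weights[start:, :] = np.minimum.accumulate(weights[start:, :], axis=0)
    counts = weights / weights.sum() * config.population_total
    counts = np.rint(counts)
    return PopulationPyramid.from_arrays(ages, count=counts)


def generate_inputs(config: SyntheticConfig | None = None,
                    ) -> tuple[LifeTable, MorbidityTable, PopulationPyramid]:
    """Generate the full input trio from one configuration."""
    config = config or SyntheticConfig()
    life = generate_life_table(config)
    morbidity = generate_morbidity_table(config)
    population = generate_population(config, life)
    return life, morbidity, population


def write_dataset(config: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write the three input CSVs to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    life, morbidity, population = generate_inputs(config)
    return {
        LifeTable.filename: life.write_csv(out_dir / LifeTable.filename),
        MorbidityTable.filename: morbidity.write_csv(out_dir / MorbidityTable.filename),
        PopulationPyramid.filename: population.write_csv(out_dir / PopulationPyramid.filename),
    }
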