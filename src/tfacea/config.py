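"""Parameter sets, policy-option definitions and run configuration.

Conventions used throughout the package:

* monetary values are 2011 euros;
* dietary trans-fat intake is expressed in E% (percent of total dietary
  energy contributed by industrially produced trans fatty acids, iTFA);
* all probabilities are annual; model cycles are one year;
* sexes are coded ``"F"`` and ``"M"``.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

SEXES: tuple[str, str] = ("F", "M")

#: Policy-option identifiers, in the order the incremental analysis reports them.
OPTION_IDS: tuple[str, ...] = ("reference", "voluntary", "labeling", "legal_limit")

#: Named initial-intake scenarios (population-average iTFA intake, E%).
SCENARIO_INTAKES: dict[str, float] = {
    "base": 0.3,
    "s1": 0.15,
    "s2": 0.45,
    "s3": 0.7,
}

#: Per-person-per-year policy-measure cost items (2011 euros).
MEASURE_NAMES: tuple[str, ...] = (
    "school",
    "worksite",
    "mass_media",
    "physician_counseling",
    "food_inspection",
)


class ConfigError(ValueError):
    """Invalid run configuration (bad field, unknown option, missing entry)."""


class InputDataError(ValueError):
    """Invalid input data (out-of-range probability, inconsistent grid, ...)."""


def _require(cond: bool, exc: type[Exception], msg: str) -> None:
    if not cond:
        raise exc(msg)


# ---------------------------------------------------------------------------
# Synthetic-data generator configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the EU-like synthetic demographic/epidemiologic inputs.

    Mortality is Gompertz in the hazard: h(a, s) = alpha * exp(beta * a) * k_s
    with k_F = 1 and k_M = ``male_mortality_ratio``; annual death probability
    is 1 - exp(-h).  First-CAD-event probability follows the same log-linear
    age form with a male:female hazard ratio of ``male_cad_ratio``.  Case
    fatality of the acute event rises linearly with age.
    """

    seed: int = 0
    population_total: float = 5.08e8
    max_age: int = 100
    gompertz_alpha: float = 3.0e-5
    gompertz_beta: float = 0.095
    male_mortality_ratio: float = 1.5
    cad_rate_scale: float = 2.0e-4
    cad_age_slope: float = 0.07
    male_cad_ratio: float = 2.0
    case_fatality_base: float = 0.10
    case_fatality_age_slope: float = 0.003
    pyramid_jitter: float = 0.02

    def validate(self) -> None:
        for name in (
            "population_total", "gompertz_alpha", "gompertz_beta",
            "male_mortality_ratio", "cad_rate_scale", "cad_age_slope",
            "male_cad_ratio", "case_fatality_base", "case_fatality_age_slope",
        ):
            v = getattr(self, name)
            _require(math.isfinite(v), ConfigError, f"SyntheticConfig.{name} must be finite, got {v!r}")
        _require(self.population_total > 0, ConfigError, "population_total must be > 0")
        _require(self.max_age >= 1, ConfigError, "max_age must be >= 1")
        _require(self.gompertz_alpha >= 0, ConfigError, "gompertz_alpha must be >= 0")
        _require(self.gompertz_beta >= 0, ConfigError, "gompertz_beta must be >= 0")
        _require(self.male_mortality_ratio > 0, ConfigError, "male_mortality_ratio must be > 0")
        _require(self.cad_rate_scale >= 0, ConfigError, "cad_rate_scale must be >= 0")
        _require(self.male_cad_ratio > 0, ConfigError, "male_cad_ratio must be > 0")
        _require(0.0 <= self.case_fatality_base <= 1.0, ConfigError, "case_fatality_base must lie in [0, 1]")
        _require(0.0 <= self.pyramid_jitter < 1.0, ConfigError, "pyramid_jitter must lie in [0, 1)")


# ---------------------------------------------------------------------------
# Cost parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CostSet:
    """CAD-related and policy-measure unit costs (2011 euros).

    ``*_items`` tuples control how the CAD cost items are attributed:
    ``acute_event_items`` are charged once per acute CAD event,
    ``history_year_items`` per person-year spent in the post-acute
    (history-of-CAD) state, and ``cad_death_items`` once per CAD death.
    """

    production_loss_mortality: float = 5101.94
    production_loss_morbidity: float = 2158.88
    informal_care: float = 6440.19
    primary_care: float = 617.34
    outpatient: float = 854.56
    emergency: float = 213.78
    inpatient: float = 3557.46
    medication: float = 1605.36
    # policy measures, euros per person per year
    school: float = 1.15
    worksite: float = 4.48
    mass_media: float = 1.90
    physician_counseling: float = 8.28
    food_inspection: float = 0.86

    acute_event_items: tuple[str, ...] = ("inpatient", "medication", "emergency", "outpatient")
    history_year_items: tuple[str, ...] = ("primary_care", "informal_care", "production_loss_morbidity")
    cad_death_items: tuple[str, ...] = ("production_loss_mortality",)

    CAD_ITEMS = (
        "production_loss_mortality", "production_loss_morbidity", "informal_care",
        "primary_care", "outpatient", "emergency", "inpatient", "medication",
    )

    def validate(self) -> None:
        for name in self.CAD_ITEMS + MEASURE_NAMES:
            v = getattr(self, name)
            _require(math.isfinite(v) and v >= 0, ConfigError, f"cost item {name!r} must be >= 0, got {v!r}")
        for group in (self.acute_event_items, self.history_year_items, self.cad_death_items):
            for item in group:
                _require(item in self.CAD_ITEMS, ConfigError, f"unknown cost item in attribution map: {item!r}")

    def bundle(self, items: tuple[str, ...]) -> float:
        return float(sum(getattr(self, i) for i in items))

    @property
    def acute_event_cost(self) -> float:
        return self.bundle(self.acute_event_items)

    @property
    def history_year_cost(self) -> float:
        return self.bundle(self.history_year_items)

    @property
    def cad_death_cost(self) -> float:
        return self.bundle(self.cad_death_items)

    def measure_cost(self, name: str) -> float:
        _require(name in MEASURE_NAMES, ConfigError, f"unknown policy measure {name!r}")
        return float(getattr(self, name))


# ---------------------------------------------------------------------------
# Risk and DALY parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RiskParameters:
    """Relative risks linking iTFA intake to CAD.

    ``rr_per_2Epct`` is the pooled relative risk of CAD per 2 E% of TFA
    consumed as an isocaloric replacement for carbohydrate; intermediate
    intake changes scale log-linearly (RR ** (delta_E / 2)).
    """

    rr_per_2Epct: float = 1.23
    rr_ci: tuple[float, float] = (1.11, 1.37)
    rr_repeat_event: float = 1.5
    rr_death_second_event: float = 1.5

    def validate(self) -> None:
        for name in ("rr_per_2Epct", "rr_repeat_event", "rr_death_second_event"):
            v = getattr(self, name)
            _require(math.isfinite(v) and v > 0, ConfigError, f"RiskParameters.{name} must be > 0, got {v!r}")
        lo, hi = self.rr_ci
        _require(0 < lo <= self.rr_per_2Epct <= hi, ConfigError,
                 f"rr_ci {self.rr_ci!r} must bracket rr_per_2Epct {self.rr_per_2Epct!r}")


@dataclass(frozen=True)
class DalyParameters:
    """Disability-adjusted life-year parameters.

    Disability weights carry no package defaults: they are external inputs
    (the packaged example configuration supplies values sourced from
    published GBD 2010 tables).  The acute weight applies for
    ``acute_duration`` years per CAD event; the history weight applies per
    person-year in the post-acute state.
    """

    disability_weight_acute: float
    disability_weight_history: float
    acute_duration: float = 1.0
    discount_effects: bool = True

    def validate(self) -> None:
        for name in ("disability_weight_acute", "disability_weight_history"):
            v = getattr(self, name)
            _require(0.0 <= v <= 1.0, ConfigError, f"DalyParameters.{name} must lie in [0, 1], got {v!r}")
        _require(self.acute_duration >= 0, ConfigError, "acute_duration must be >= 0")


# ---------------------------------------------------------------------------
# Scenarios and policy options
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioSpec:
    """Initial population iTFA intake (E%) with optional sex multipliers.

    The stratum-specific initial intake is ``initial_intake_overall`` times
    the sex multiplier (default 1 for both sexes, i.e. every stratum starts
    at the overall mean).
    """

    name: str
    initial_intake_overall: float
    sex_multipliers: Mapping[str, float] = field(default_factory=lambda: {"F": 1.0, "M": 1.0})

    def validate(self) -> None:
        _require(self.initial_intake_overall >= 0, ConfigError, "initial intake must be >= 0")
        for s in SEXES:
            _require(s in self.sex_multipliers, ConfigError, f"missing sex multiplier for {s!r}")
            _require(self.sex_multipliers[s] >= 0, ConfigError, f"sex multiplier for {s!r} must be >= 0")

    def initial_intake(self, sex: str) -> float:
        return self.initial_intake_overall * float(self.sex_multipliers[sex])

    @classmethod
    def preset(cls, name: str) -> "ScenarioSpec":
        _require(name in SCENARIO_INTAKES, ConfigError,
                 f"unknown scenario {name!r}; expected one of {sorted(SCENARIO_INTAKES)}")
        return cls(name=name, initial_intake_overall=SCENARIO_INTAKES[name])


@dataclass(frozen=True)
class PolicyOption:
    """One of the four EU-level policy options.

    ``phase_out_years`` is the year by which population iTFA intake reaches
    zero under the option.  ``measures`` maps policy-measure names to
    ``(start_year, end_year)`` windows (``end_year`` None = whole horizon)
    during which the per-person-per-year measure cost accrues.

    The mandatory-labeling option additionally carries the split of intake
    into a prepackaged share (phased out quickly once labels are in place)
    and a non-prepackaged share that follows the reference path.
    """

    identifier: str
    phase_out_years: float
    measures: Mapping[str, tuple[float, float | None]] = field(default_factory=dict)
    # labeling-specific structure
    labeling: bool = False
    prepackaged_share: float = 0.5
    labeling_lead_years: float = 2.0
    prepackaged_phase_years: float = 3.0
    reference_phase_out_years: float = 10.0

    def validate(self) -> None:
        _require(self.phase_out_years >= 0, ConfigError, "phase_out_years must be >= 0")
        for name, (start, end) in self.measures.items():
            _require(name in MEASURE_NAMES, ConfigError,
                     f"option {self.identifier!r}: unknown measure name {name!r}")
            _require(start >= 0, ConfigError, f"measure {name!r}: start year must be >= 0")
            if end is not None:
                _require(end >= start, ConfigError, f"measure {name!r}: end must be >= start")
        if self.labeling:
            _require(0.0 <= self.prepackaged_share <= 1.0, ConfigError,
                     "prepackaged_share must lie in [0, 1]")


def default_options(info_measure_years: float = 5.0) -> dict[str, PolicyOption]:
    """The four policy options with their phase-out and measure schedules.

    * reference — no EU action: iTFA leaves the food supply over 10 y through
      national efforts alone; no public measure costs.
    * voluntary — EU-level agreements: total removal after 5 y; food
      inspection runs over the whole horizon.
    * labeling — mandatory TFA labeling of prepackaged food: reference pace
      for 2 y until labels are in place, then the prepackaged half of intake
      drops to zero over 3 y while the rest stays on the reference path;
      food inspection plus information measures (school, worksite, mass
      media, physician counseling) for the first ``info_measure_years``.
    * legal_limit — legislative limit on iTFA content: total removal in 2 y;
      food inspection over the whole horizon.
    """
    full = (0.0, None)
    info = (0.0, float(info_measure_years))
    return {
        "reference": PolicyOption("reference", phase_out_years=10.0),
        "voluntary": PolicyOption("voluntary", phase_out_years=5.0,
                                  measures={"food_inspection": full}),
        "labeling": PolicyOption(
            "labeling", phase_out_years=10.0, labeling=True,
            measures={"food_inspection": full, "school": info, "worksite": info,
                      "mass_media": info, "physician_counseling": info}),
        "legal_limit": PolicyOption("legal_limit", phase_out_years=2.0,
                                    measures={"food_inspection": full}),
    }


# ---------------------------------------------------------------------------
# Thresholds, PSA settings, run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CEThresholds:
    """WHO cost-effectiveness thresholds anchored on GDP per capita (euros)."""

    gdp_per_capita: float = 23300.0

    def validate(self) -> None:
        _require(self.gdp_per_capita > 0, ConfigError, "gdp_per_capita must be > 0")


@dataclass(frozen=True)
class PsaSettings:
    """Probabilistic sensitivity analysis settings.

    ``se_fraction`` is the standard error assumed for parameters whose source
    prints only a point value (costs, the assumption-based relative risks);
    ``table_cv`` is the coefficient of variation of the single lognormal
    multiplier applied per draw to each probability table.
    """

    n_draws: int = 1000
    seed: int = 42
    se_fraction: float = 0.2
    table_cv: float = 0.2
    point_mass: bool = False
    max_resamples: int = 100

    def validate(self) -> None:
        _require(self.n_draws >= 0, ConfigError, "n_draws must be >= 0")
        _require(self.se_fraction >= 0, ConfigError, "se_fraction must be >= 0")
        _require(self.table_cv >= 0, ConfigError, "table_cv must be >= 0")


@dataclass(frozen=True)
class RunConfig:
    """Everything a deterministic or probabilistic run needs besides tables."""

    scenario: ScenarioSpec
    daly: DalyParameters
    horizon_years: int = 85
    discount_rate: float = 0.035
    options: tuple[str, ...] = OPTION_IDS
    decay_shape: str = "linear"
    info_measure_years: float = 5.0
    costs: CostSet = field(default_factory=CostSet)
    risk: RiskParameters = field(default_factory=RiskParameters)
    thresholds: CEThresholds = field(default_factory=CEThresholds)
    psa: PsaSettings = field(default_factory=PsaSettings)

    def validate(self) -> None:
        _require(self.horizon_years >= 1, ConfigError, "horizon_years must be >= 1")
        _require(0.0 <= self.discount_rate < 1.0, ConfigError, "discount_rate must lie in [0, 1)")
        _require(self.decay_shape in ("linear", "exponential"), ConfigError,
                 f"decay_shape must be 'linear' or 'exponential', got {self.decay_shape!r}")
        _require(len(self.options) > 0, ConfigError, "options must not be empty")
        for o in self.options:
            _require(o in OPTION_IDS, ConfigError,
                     f"unknown policy option {o!r}; expected one of {OPTION_IDS}")
        self.scenario.validate()
        self.daly.validate()
        self.costs.validate()
        self.risk.validate()
        self.thresholds.validate()
        self.psa.validate()

    def policy_options(self) -> dict[str, PolicyOption]:
        opts = default_options(self.info_measure_years)
        return {name: opts[name] for name in self.options}


# ---------------------------------------------------------------------------
# Parsing from structured text (YAML / JSON)
# ---------------------------------------------------------------------------

def _pick(d: Mapping[str, Any], cls, path: str, **extra):
    """Build a dataclass from a mapping, rejecting unknown keys."""
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - known
    _require(not unknown, ConfigError, f"{path}: unknown field(s) {sorted(unknown)}")
    kwargs = {**{k: v for k, v in d.items()}, **extra}
    try:
        return cls(**kwargs)
    except TypeError as e:  # missing required field
        raise ConfigError(f"{path}: {e}") from None


def run_config_from_dict(raw: Mapping[str, Any]) -> RunConfig:
    """Build and validate a :class:`RunConfig` from a plain mapping.

    Omitted fields take the model defaults (85-y horizon, 3.5% annual
    discount rate on costs and effects, base-case scenario, all four policy
    options).  Unknown keys raise :class:`ConfigError` naming the field.
    """
    raw = dict(raw)
    raw.pop("data", None)  # data locations are handled by the pipeline layer

    sc = raw.pop("scenario", "base")
    if isinstance(sc, str):
        scenario = ScenarioSpec.preset(sc)
    elif isinstance(sc, Mapping):
        sc = dict(sc)
        if "sex_multipliers" in sc:
            sc["sex_multipliers"] = {str(k): float(v) for k, v in sc["sex_multipliers"].items()}
        sc.setdefault("name", "custom")
        scenario = _pick(sc, ScenarioSpec, "scenario")
    else:
        raise ConfigError(f"scenario: expected preset name or mapping, got {sc!r}")

    daly_raw = raw.pop("daly", None)
    _require(daly_raw is not None, ConfigError,
             "daly: section is required (disability weights have no defaults)")
    daly = _pick(daly_raw, DalyParameters, "daly")

    costs = _pick(raw.pop("costs", {}), CostSet, "costs")
    risk_raw = dict(raw.pop("risk", {}))
    if "rr_ci" in risk_raw:
        risk_raw["rr_ci"] = tuple(float(x) for x in risk_raw["rr_ci"])
    risk = _pick(risk_raw, RiskParameters, "risk")
    thresholds = _pick(raw.pop("thresholds", {}), CEThresholds, "thresholds")
    psa = _pick(raw.pop("psa", {}), PsaSettings, "psa")
    if "options" in raw:
        raw["options"] = tuple(raw["options"])

    cfg = _pick(raw, RunConfig, "run config", scenario=scenario, daly=daly,
                costs=costs, risk=risk, thresholds=thresholds, psa=psa)
    cfg.validate()
    return cfg


def load_run_config(path: str | Path) -> RunConfig:
    """Load a run configuration from a YAML (``.yaml``/``.yml``) or JSON file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    _require(isinstance(raw, Mapping), ConfigError, f"{path}: top level must be a mapping")
    return run_config_from_dict(raw)


def example_config_path() -> Path:
    """Path to the packaged example run configuration."""
    return Path(str(resources.files("tfacea").joinpath("data/example_config.yaml")))


def default_run_config(**overrides: Any) -> RunConfig:
    """The packaged example configuration, optionally with field overrides."""
    cfg = load_run_config(example_config_path())
    if overrides:
        cfg = dataclasses.replace(cfg, **overrides)
        cfg.validate()
    return cfg
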