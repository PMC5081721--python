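# Methods

This note documents the model implemented by `tfacea`: its structure,
parameter defaults, the synthetic-data generator, numerical choices, and
known limitations.

## State-transition model

The population is a **closed cohort**: the full age pyramid at model start
ages through 85 yearly cycles with no births or migration. Each (initial
age, sex) stratum moves through four health states — *Well*, *CAD* (the
acute year of a coronary event), *History of CAD*, and *Dead* (absorbing) —
by expected-value arithmetic: fractions of each stratum flow along the
transition probabilities every cycle. Nothing is sampled inside the cohort
update; randomness enters the analysis only through probabilistic parameter
draws (see PSA below).

Per (age a, sex s, model year t) the eight transition probabilities are:

| from | to | probability |
|---|---|---|
| Well | CAD | p_cad(a,s,t) = clamp₀₁(p₀(a,s) · RR^((E_t−E₀)/2)) |
| Well | Dead (non-CAD) | q_other(a,s,t) |
| Well | Well | residual |
| CAD | Dead (CAD) | case fatality cf(a,s); for repeat events min(1, 1.5·cf) |
| CAD | History | residual |
| History | CAD (repeat) | min(1, 1.5 · p_cad) |
| History | Dead (non-CAD) | q_other(a,s,t) |
| History | History | residual |

Design points:

* **Acute state lasts exactly one cycle**, enforced structurally: CAD
  occupants either die (a CAD death) or move to History at the next
  transition. The acute state is internally split into first-event and
  repeat-event sub-compartments because their case fatalities differ.
* **Dose–response is log-linear.** The pooled RR of 1.23 applies per 2 E%
  of TFA replacing carbohydrate; intermediate intake changes scale as
  RR^(ΔE/2), the usual convention for pooled log-relative risks. Baseline
  event probabilities already embed the initial intake, so at t = 0 the
  multiplier is exactly 1.
* **Non-CAD mortality by hazard subtraction.** All-cause mortality contains
  CAD deaths, so using it directly for the "other-cause" transitions would
  double-count. We remove the CAD-death hazard:
  q_other = 1 − exp(−[−ln(1−q_all) + ln(1 − p_cad·cf)]), guarded to [0, 1].
  This is an assumption — whether the source life tables' "Well" mortality
  excludes CAD deaths is not knowable from the inputs.
* **Absorbing last age.** The life table's last age has q = 1; any occupancy
  ageing past the table is moved to Dead (counted as non-CAD death). This
  bounds the horizon and makes person conservation exact.
* **No half-cycle correction** is applied; events are counted in the cycle
  in which they occur. This is a (documented) limitation: all quantities are
  start-of-cycle.
* Inconsistent inputs — event plus death probabilities exceeding 1 in some
  stratum — raise a validation error naming the (year, age, sex) cell rather
  than being silently renormalised.

## Intake trajectories

Population iTFA intake (E% of energy) starts at the scenario value (base
0.3; alternative scenarios 0.15 / 0.45 / 0.7) and declines to exactly zero
on each option's schedule: reference 10 y, voluntary 5 y, legal limit 2 y.
The decline between anchors is **linear by default** (the source analyses
state only endpoints and durations); an exponential-to-zero shape is
available via `decay_shape: exponential`. The labeling option is a
composite: for 2 years (until labels are on all prepackaged food) intake
follows the reference path; from year 2 the prepackaged share (50 % of
intake) declines linearly to zero over 3 years while the non-prepackaged
share stays on the reference path; no spillover to non-prepackaged foods is
assumed. These shapes guarantee, for every scenario, the cumulative-intake
ordering legal ≤ voluntary ≤ labeling ≤ reference, which propagates to
events, DALYs and CAD-related costs (monotone harm).

Stratum-specific initial intakes default to the scenario's overall mean;
sex multipliers can be supplied in the scenario configuration (the original
age/sex-specific estimates are not redistributable).

## Costs

All monetary values are 2011 euros, discounted at 3.5 %/year
((1+r)^(−t), year 0 undiscounted). Three groups:

* **acute-event bundle** per CAD event: in-patient €3557.46, medication
  €1605.36, emergency €213.78, outpatient €854.56 (sum €6231.16);
* **chronic bundle** per person-year in History: primary care €617.34,
  informal care €6440.19, production loss (morbidity) €2158.88;
* **per CAD death**: production loss (mortality) €5101.94.

The attribution of items to bundles is not dictated by the source category
lists; the split above is the package default and is fully configurable via
the `acute_event_items` / `history_year_items` / `cad_death_items` fields of
the cost set.

**Policy-measure costs** are per person alive per year: food inspection
€0.86 (voluntary, labeling and legal options, whole horizon) and, for the
labeling option only, the information measures — school €1.15, worksite
€4.48, mass media €1.90, physician counseling €8.28 — over a configurable
initial window (default: first 5 years; the duration is genuinely
unspecified in the source material). The reference option carries no
measure costs.

## DALYs

DALY = YLL + YLD, discounted at the run's rate (switchable off).

* **YLL**: each CAD death at attained age a is valued with the discounted
  remaining period life expectancy at a, computed from the run's own life
  table by the backward recursion e(a) = (1−q(a))·v·(1+e(a+1)), v = 1/(1+r).
  No age weighting, consistent with GBD-2010 practice.
* **YLD**: disability_weight_acute × acute_duration (default 1 y) per acute
  event, plus disability_weight_history per person-year in History.

Disability weights are **external inputs with no package defaults**. The
packaged example configuration uses 0.080 for both: the acute value is a
time-weighted average of the GBD 2010 acute-myocardial-infarction weights
(0.422 for days 1–2, 0.056 for the following weeks) and moderate angina
(0.080) over the one-year acute state; the history value is moderate angina.

## Incremental analysis

For each option versus the reference: Δcost and ΔDALY (negative = saving /
health gain); *dominant* iff both negative, *dominated* iff both positive;
otherwise ICER = Δcost/ΔDALY reported with its natural sign (negative when
DALYs are averted at positive cost, matching the source tables) and
classified on |ICER| against WHO thresholds with GDP per capita €23,300:
|ICER| < 1×GDP highly cost-effective, < 3×GDP cost-effective, else not
cost-effective (strict-less boundaries for the better tier). All arithmetic
is at full precision; rounding happens only at presentation.

## Probabilistic sensitivity analysis

Per draw, all parameters are sampled independently:

* RR per 2 E%: log-normal with μ = ln(1.23) and σ = (ln 1.37 − ln 1.11)/(2·1.96)
  ≈ 0.0537 from the published 95 % CI (the point estimate acts as the
  median).
* Repeat-event RRs (1.5, assumption-based, no published dispersion) and all
  13 cost items: default SE = 20 % of the mean (configurable,
  `psa.se_fraction`). Costs are gamma with moment-matched shape (mean/SE)²
  and scale SE²/mean; the RRs are log-normal moment-matched so the
  arithmetic mean and SD are exact.
* Table uncertainty: one log-normal multiplier (mean 1, CV
  `psa.table_cv` = 0.2) per table per draw — all-cause mortality, CAD event
  probability, case fatality — applied cell-wise and clamped into [0, 1],
  with the absorbing last age preserved. This low-dimensional scheme moves
  whole tables coherently and keeps draw cost bounded; it is an explicit
  assumption, since the original parameterisation of table uncertainty is
  not documented.

Draws whose sampled parameters make some transition row infeasible
(event + death probabilities exceeding 1, which happens for jointly large
multiplier/repeat-RR draws at ages ≳95) are **resampled**, not truncated,
and counted in `PsaResult.n_resampled` (typically ~15 % of draws at the
default calibration). Resampling slightly trims the extreme upper tail of
the nominal distributions; this is reported rather than hidden.

Each draw reruns all four options on the same sampled parameter set, so
between-option differences within a draw isolate the policy effect.
Summaries report per option the mean Δcost and ΔDALY, the ICER of the means
(or a dominance marker), and the probabilities of saving costs, saving
DALYs, and joint dominance. With `psa.point_mass: true` every distribution
degenerates to its mean and the PSA reproduces the deterministic run
exactly — a useful equivalence check. Given identical inputs, configuration
and seed, draws and summaries are bit-reproducible.

## Synthetic inputs: what they emulate, and what they do not

The generator produces the three input tables with the statistical
structure the analysis assumes:

* **Mortality**: Gompertz hazard h = α·e^(βa)·k_s with α = 3×10⁻⁵,
  β = 0.095/y, male multiplier 1.5, converted to annual probabilities
  q = 1−e^(−h); monotone in age, absorbing at age 100.
* **CAD incidence**: first-event hazard r₀·e^(γa)·m_s with r₀ = 2×10⁻⁴,
  γ = 0.07/y, male:female hazard ratio 2.0. Case fatality 0.10 + 0.003·age,
  clipped to [0, 1].
* **Population**: 508 million persons distributed along the life table's
  survivorship curve with a small seeded jitter (±2 %), counts
  non-increasing above 65, rounded to whole persons.

The CAD parameters are calibrated so that the model's deterministic
incremental results land on the order of magnitude of the published
base-case comparison (tens of billions of euros and millions of DALYs
between options over 85 years), which is the regime the published
probabilistic conclusions live in. This burden is intentionally on the
published model's scale, which runs well above contemporary European
registry incidence — the original authors themselves note their absolute
event counts are likely overestimates. Consequently, passing tests on
synthetic data demonstrate the *machinery and the comparative conclusions*
(orderings, dominance, classification), not calibration to real European
surveillance data: the synthetic tables have smooth parametric age curves,
no cohort effects, no country heterogeneity, and no period trends in
mortality or incidence.

Rate curves are deterministic functions of the parameters; the seeded RNG
affects only the pyramid jitter. Identical (seed, config) pairs yield
byte-identical CSV outputs.

## Numerical choices

* Probabilities are the native inputs; hazard↔probability conversions use
  1−exp(−h) / −ln(1−p) throughout.
* Residual (stay) probabilities are computed by subtraction; the engine
  updates occupancies by mass balance, so person conservation holds to
  floating-point rounding (tested at 10⁻⁹ relative over 85 cycles on the
  full EU-scale cohort).
* Negative residuals beyond −10⁻⁹ are errors; tiny negative values from
  rounding are clipped to zero.
* CSVs are written with `%.17g`, and read with round-trip float parsing, so
  text round trips are bit-exact.
* Problem sizes for verification: the cohort engine is cross-validated
  against a seeded individual-level microsimulation on a 10,000-person,
  3-initial-age, 20-year instance with 50 replicates (agreement within 3
  Monte-Carlo standard errors); the probabilistic analysis is exercised at
  the full 1000 draws of the published design.

## Known limitations

* Closed cohort: no births or in-migration, so late-horizon person-years
  shrink; the original cohort definition (standing population vs closed) is
  not documented.
* No half-cycle correction.
* CAD is the only modelled outcome (as in the source analysis); other
  proposed TFA effects are excluded.
* Competing risks are handled only through the hazard subtraction above.
* The labeling option's information-measure cost window, the attribution of
  cost items to bundles, and the table-uncertainty parameterisation are
  explicit assumptions, all configurable.
* Intake trajectories are population-level; no food-category or
  reformulation economics.
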