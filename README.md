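# tfacea — cost-effectiveness of EU-level trans-fat policies

`tfacea` is a health-economic simulation package for comparing European
Union–level policy options aimed at removing industrially produced *trans*
fatty acids (iTFA) from the food supply. It implements a sex- and
age-stratified, four-state Markov cohort model of coronary artery disease
(CAD) and evaluates four policy options over a lifetime (85-year) horizon:

1. **reference** — no EU action; iTFA leaves the food supply over 10 years
   through national efforts and industry innovation alone;
2. **voluntary** — EU-level voluntary agreements; total removal after 5 years,
   plus a food-inspection programme;
3. **labeling** — mandatory TFA labeling of prepackaged foods; the
   prepackaged half of intake is removed over 3 years once labels are in
   place (after a 2-year lead), the rest follows the reference path; food
   inspection plus information measures (school, worksite, mass-media,
   physician counseling);
4. **legal_limit** — a legislative limit on iTFA content; total removal in
   2 years, plus food inspection.

It is written for health-economics and public-health modellers who want a
tested, reproducible, scriptable version of this kind of policy evaluation:
every assumption is a configuration field, and every figure in the outputs
is recomputed from the inputs at run time.

## The model

A closed cohort (the full population pyramid, default 508 million persons)
moves in yearly cycles through **Well → CAD (acute, one year) → History of
CAD → Dead**, with eight transition probabilities per (age, sex, year).
Dietary exposure enters through a single pooled relative risk,
RR = 1.23 (95% CI 1.11–1.37) per 2 E% of TFA replacing carbohydrate,
applied log-linearly to the baseline first-event probability p₀:

    p_t(a, s) = p₀(a, s) · RR^((E_t − E₀)/2)

where E_t is the policy option's population iTFA intake (E%) in model year
t. Repeat CAD events carry RR 1.5 versus first events, and death from a
repeat event RR 1.5 versus the first-event case fatality. Non-CAD mortality
is all-cause mortality with the CAD-death hazard removed by hazard
subtraction. Costs (2011 €; health-care, informal care, production losses,
and per-person policy-measure costs) and DALYs (YLL from life-table
remaining life expectancy at death, plus disability-weighted YLD) are
discounted at 3.5 %/year.

Options are compared against the reference by incremental cost-effectiveness
ratios (ICER = ΔCost/ΔDALY), dominance (saves both costs and DALYs), and the
WHO GDP-per-capita thresholds (€23,300; highly cost-effective below 1×,
cost-effective below 3×). A probabilistic sensitivity analysis (PSA)
resamples every uncertain parameter (gamma for costs, log-normal for
relative risks and table multipliers) and reruns the whole model 1000 times.

The package generates its own synthetic EU-like inputs (Gompertz mortality,
log-linear age-rising CAD incidence about twice as high in men, a
survival-shaped population pyramid), so everything is runnable and testable
without access to the original European data extracts.

## Worked example

```yaml
# run.yaml
scenario: base          # 0.3 E% initial population iTFA intake
daly:
  disability_weight_acute: 0.080     # GBD-2010-derived weights
  disability_weight_history: 0.080
data:
  synthetic: {seed: 1}  # EU-like synthetic tables, 508M persons
```

```bash
tfacea simulate --config run.yaml --out out/
```

produces `out/results_by_option.csv` and `out/incremental.csv`:

```
     option  total_cost_eur     dalys
  reference       9.471e+12 6.545e+08
  voluntary       9.458e+12 6.528e+08
   labeling       9.508e+12 6.538e+08
legal_limit       9.442e+12 6.517e+08

     option  delta_cost_eur   delta_dalys  icer_eur_per_daly       ce_class
  voluntary   -1.318506e+10 -1.677375e+06           dominant       dominant
   labeling    3.696635e+10 -6.579032e+05         -56188.134 cost_effective
legal_limit   -2.849199e+10 -2.762791e+06           dominant       dominant
```

Reading this: over 85 years the legal limit saves ≈ €28 billion and averts
≈ 2.8 million DALYs versus taking no EU action — it *dominates* (saves both
money and health), as do voluntary agreements (≈ €13 billion, 1.7 million
DALYs). Mandatory labeling averts ≈ 0.66 million DALYs but costs
≈ €37 billion more than the reference, because the information-measure and
inspection costs outweigh the savings from the relatively small extra
reduction in CAD. The negative ICER reports that cost per DALY averted.

A probabilistic analysis with the CE-plane export:

```bash
tfacea psa --config run.yaml --out out/ --n-draws 1000 --seed 42
```

writes `psa_draws.csv`, `ce_plane.csv` (DALYs avoided vs costs saved per
draw) and `summary.json` with per-option dominance probabilities.

Synthetic inputs can also be materialised for inspection:

```bash
tfacea generate-data --seed 1 --out data/
```

## Package layout

| module | role |
|---|---|
| `tfacea.synthetic` | EU-like synthetic life/morbidity/population tables |
| `tfacea.io` | CSV/YAML reading, validation, result writing |
| `tfacea.intake` | per-option iTFA intake trajectories |
| `tfacea.risk` | dose–response and the 8 transition probabilities |
| `tfacea.engine` | deterministic multi-age Markov cohort engine |
| `tfacea.outcomes` | discounted costs and DALYs (YLL + YLD) |
| `tfacea.cea` | ICERs, dominance, WHO-threshold classes |
| `tfacea.psa` | probabilistic sensitivity analysis |
| `tfacea.pipeline`, `tfacea.cli` | end-to-end runs, manifests, CLI |

See `docs/methods.md` for the full model description, parameter defaults and
known limitations.
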