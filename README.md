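# trialcea

Trial-based cost-effectiveness analysis toolkit for programme evaluations
run alongside cluster-randomized trials. It covers the full chain from a
raw cost ledger and pupil-level outcome data to cost-per-case-averted
figures and univariate sensitivity tables:

- **`trialcea.cost_engine`** — ingredients-based costing: currency
  conversion at expenditure-year rates, CPI inflation to a base year,
  capital annualization via equivalent annual cost (EAC) with resale
  value, shared-cost allocation by proportion of use, phase/category
  aggregation, and unit costs.
- **`trialcea.effect_engine`** — adjusted risk difference on a binary
  outcome from an identity-link model with a cluster-robust sandwich
  variance (schools as clusters, G/(G−1) small-sample scaling), and
  counterfactual cases-averted arithmetic with CI-derived bounds.
- **`trialcea.cea_engine`** — cost per case averted against a do-nothing
  comparator, plus a tornado driver that re-runs the whole pipeline with
  one parameter perturbed at a time.
- **`trialcea.synthetic_data`** — beta-binomial cluster-trial simulator
  and a cost-ledger simulator with exactly known totals, both fully
  seeded.
- **`trialcea.report` / `trialcea.cli`** — result bundles with per-figure
  provenance strings, deterministic CSV/text/JSON rendering, and a
  built-in worked example reproducing the headline arithmetic of an
  18-month, 21-school violence-prevention programme.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance checks: the worked
example's desk-scale arithmetic plus property-based oracles (annuity
factor vs brute-force summation, EAC full-resale identity, cluster-robust
SE vs an independent matrix computation, 200-replicate parameter
recovery, ledger conservation, tornado bracketing).

## CLI

```bash
# synthetic inputs (design.json may include a ledger_profile block)
cea simulate --design design.json --seed 1 --out pupils.csv ledger.csv

# full pipeline; writes result.json + run.log into report/
cea run --ledger ledger.csv --pupils pupils.csv \
        --config ledger.config.json --out report/

# univariate sensitivity of cost per case
cea tornado --ledger ledger.csv --pupils pupils.csv \
            --config ledger.config.json \
            --param horizon_years=1.0,2.0 --out tornado.json

# built-in worked example
cea paper-fixture --out fixture/ --format text
```

The analysis config is JSON with keys `base_year`, `base_currency`,
`discount_rate`, `horizon_years`, `exchange_rates`
(`{currency: {year: units-per-base}}`), `cpi` (`{year: index}`), and
optional `denominators`. Ledger CSVs carry
`label,phase,category,cost_basis,value,currency,year,allocation_fraction,is_capital,useful_life_years,resale_fraction`;
pupil CSVs carry `school_id,arm,outcome` plus covariate columns.

## Conventions worth knowing

- Money is normalised convert-first, inflate-second; the order is pinned
  and tested.
- All reported money rounds half-up to whole dollars and percents half-up
  to integers; internal arithmetic is full precision.
- An EAC with `resale_fraction = 1` reduces to `principal × rate`, which
  is how a fully resaleable one-off investment is charged.
- Sensitivity rows must bracket the base case; the row constructor
  enforces it.
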