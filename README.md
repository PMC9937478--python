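# saltcost

Attributable cost-of-illness modelling for excess dietary salt.

Populations eating more salt than the WHO limit of 5 g/person/day carry
avoidable cardiovascular disease (CVD) burden: salt raises systolic blood
pressure (SBP), and raised SBP raises the risk of coronary heart disease
(CHD), stroke, hypertensive disease and rheumatic heart disease (RHD).
`saltcost` estimates, for a population parameterised like Costa Rica in
2018, the share of the public health system's direct CVD costs
(hospitalisations, consultations, medications) and of premature-mortality
productivity losses that is attributable to salt intake above the
counterfactual level, with Monte Carlo uncertainty intervals.  It is aimed
at health economists and public-health modellers doing comparative risk
assessment with national parameter tables rather than individual-level data.

## The model

Salt intake is a continuous risk factor, summarised as mean ± SD g/day and
modelled as a normal distribution truncated at zero.  The intake axis is cut
into 1 g/day bins from 5 to 12 g/day with open tails; a salt difference Δs
maps linearly to an SBP difference ΔSBP = Δs × 5.8/6 mmHg, and a stratum's
per-mmHg relative risk RRₘₘ is rescaled to each bin as RRᵢ = RRₘₘ^ΔSBPᵢ.
The exposed prevalence *P* (mass above the reference bin) and the
prevalence-weighted combined relative risk *RR* then give the population
attributable risk

    PAR = 100 · P(RR − 1) / (P(RR − 1) + 1),

computed per outcome × sex × age-group stratum for the baseline and the
counterfactual intake distributions; the attributable fraction is their
difference.  Attributable direct costs apply the (population-pooled) sex
fractions to the annual national cost table by disease × service × sex,
converted at ₡600/USD.  Attributable deaths feed the human-capital side:
YLL = deaths × residual life expectancy, YPLL truncates lost years to the
working window (age 15 to pension at 60 for women / 65 for men), and
productivity losses are YPLL × monthly wage × 12 × labour-force
participation.  Uncertainty is propagated by 10,000 Monte Carlo draws of the
mean intake, every cost cell and every relative risk from log-normal
distributions; point estimates are medians of draws and 95% uncertainty
intervals are the 2.5th–97.5th percentiles.

## Worked example

```python
from saltcost import MCConfig, default_fixture, run_monte_carlo
from saltcost.model import run_deterministic

bundle = default_fixture()          # national 2018 parameter fixture
det = run_deterministic(bundle)
mc = run_monte_carlo(bundle, MCConfig(draws=10_000, seed=1))

print(det.paf.head(2))
print(det.report.grand_total, mc.interval("direct_total"))
```

Running `python examples/fixture_pipeline.py` prints:

```
outcome  sex age_group        P       RR  PAR_baseline  PAR_counterfactual  PAR_attributable
    CHD male     15-19 0.849977 1.155488     11.673357            2.980904          8.692453
    CHD male     20-24 0.849977 1.146840     11.096148            2.825864          8.270283

attributable direct costs: USD 184.8 M (95% UI 142.0-231.7 M)
  hospitalization   65%
  consultation      35%
  medication         0%

YPLL: 754 years; productivity losses: USD 4.29 M (95% UI 3.30-5.34 M)
```

`P` is the fraction of the population above 5 g/day (85% at intake
10.0 ± 5.4 g/day), `RR` the combined relative risk of that exposure, and
`PAR_attributable` the percent of each stratum's CVD burden removed by
reaching the counterfactual.  The fixture's stratified relative-risk and
cost-split tables are synthetic placeholders (the national appendices are
not public), so these totals demonstrate the machinery; supply your own
tables via `saltcost.tables.load_bundle` or the `tables_dir` config key for
substantive estimates.

The aggregation layer reproduces published results exactly when fed real
component cells — see `examples/published_table_aggregation.py`, which
recovers the USD $15.1 million headline and the 53/32/15 service split from
the printed service components.

## Command line

```bash
saltcost synth --seed 3 --out bundle/        # write a synthetic input bundle
saltcost run --config run.yaml --seed 1      # full pipeline + reports
saltcost report --results results/ --format md
```

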