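# Methods

## Scope and structure

`saltcost` is a comparative-risk-assessment cost-of-illness model: it takes
national parameter tables (intake distribution, per-mmHg relative risks,
annual costs, mortality, labour parameters) and returns the direct
healthcare costs and premature-mortality productivity losses attributable
to salt intake above a counterfactual level, with Monte Carlo uncertainty.
It does not estimate relative risks from primary data, does not model the
time lag between exposure change and disease, and does not cover
primary-care, insurance or out-of-pocket costs.

## Exposure

Intake is summarised by mean ± SD g/person/day.  Only these two moments are
ever available from national surveys, so the distribution family is an
assumption: we use a normal truncated at zero and renormalised, the minimal
choice consistent with the reported moments that puts no mass on negative
intake (untruncated, mean 10 and SD 5.4 would place about 3% below zero).
An SD of zero is a valid degenerate distribution (all mass at the mean).

The intake axis is discretised into an open bin below 5 g/day, unit bins
from 5 to 12 g/day, and an open bin above 12, configurable via
`bins: {start, stop, width, reference}`.  The sub-reference bin is the
unexposed category; each other bin is represented by its midpoint, the open
top bin by the last edge plus half the interior width (12.5 g/day by
default).  The exposed prevalence *P* is the total mass above the reference
bin.  *P* is computed from the distribution; a survey prevalence can be
substituted by passing a degenerate distribution or a custom bin scheme.

Salt maps to systolic blood pressure linearly: 6 g/day of salt ↔ 5.8 mmHg
of SBP, applied proportionally to any salt difference.  The slope is a
`DoseResponseSpec` and can be replaced.

## Risk and attributable fraction

Per-mmHg relative risks (one per outcome × sex × age group) are rescaled to
bins log-linearly, RRᵢ = RRₘₘ^ΔSBPᵢ, the standard convention for
continuous risk factors mediated by blood pressure.  The combined relative
risk over the exposure distribution is the prevalence-weighted arithmetic
mean of per-bin RRs among exposed bins.  With that definition the binary
formula PAR = 100·P(RR−1)/(P(RR−1)+1) is algebraically identical to the
multi-category attributable fraction 100·Σpᵢ(RRᵢ−1)/(Σpᵢ(RRᵢ−1)+1),
since P·(RR̄−1) = Σᵢpᵢ(RRᵢ−1); the test suite verifies the identity to
1e-12 on random three-bin instances.  Protective exposures (RR < 1) yield a
negative PAR with a warning rather than an error.

PAR is evaluated per stratum and applied per stratum; costs published only
at the sex level are attributed using the population-weighted mean of the
age-specific attributable fractions within each sex (the strata table
carries a population column for this).  A fully pooled mode is available by
collapsing the RR table before the run.

## Counterfactual handling

Attributable burden is burden(baseline) − burden(counterfactual), each
distribution evaluated against the same 5 g/day reference.  With the
default counterfactual (5.0 ± 2.65 g/day) the counterfactual's own excess
burden is small but nonzero — about half its mass lies above 5 g/day, at
bins whose relative risks are close to 1.  `counterfactual_mode:
"threshold"` instead defines the counterfactual burden as zero, attributing
everything above the reference.  When the counterfactual equals the
baseline the attributable burden is identically zero in every output.

## Direct costs

Each disease × service × sex cost cell is multiplied by the corresponding
attributable fraction; colones convert to USD at a fixed nominal ₡600/USD
(2018, no inflation adjustment).  Cells the payer could not supply
(medication costs for stroke and RHD) are *absent*, not zero: totals
exclude them and reports footnote the exclusion.  All arithmetic runs at
full floating precision; scaling to "thousand USD" and integer-percent
shares (round half away from zero, matching how published tables round)
happens only at rendering.  Published tables rounded components and totals
independently, which produces ±1 thousand discrepancies; reproducing a
printed table therefore means matching totals computed from printed
components, not re-printing the (inconsistent) printed totals.

## Productivity losses

YLL = N × L per stratum (deaths × residual life expectancy at the age of
death, band midpoint unless exact ages are supplied).  YPLL truncates each
death's lost years to the working window — age 15 to pension at 60 (women)
/ 65 (men) — and is additionally capped at L so YPLL ≤ YLL always holds.
Losses are YPLL × monthly wage × 12 × participation rate.  The USD $765
national average income is treated as a *monthly* wage (the labour-force
source reports monthly income); the annualisation factor is configurable
and this assumption matters — flagging it here deliberately.  No
discounting or age-weighting is applied by default; `discount_rate` enables
a standard annuity discount (e.g. 0.03) for sensitivity analysis.

The mortality table's death counts are interpreted as **total** CVD deaths
by stratum by default (`mortality_kind: "total"`): the stratum's
attributable fraction converts them to attributable deaths, which keeps the
null scenario exactly zero and propagates Monte Carlo uncertainty into the
productivity side.  `mortality_kind: "attributable"` accepts counts that
are already attributable (e.g. produced upstream by a macrosimulation such
as PRIME); in that mode productivity losses are deterministic inputs and
carry no Monte Carlo spread.  Only outcomes present in the mortality table
contribute (typically CHD and stroke).

## Monte Carlo uncertainty

Defaults: 10,000 draws, log-normal input distributions, 95% intervals from
the 2.5th/97.5th percentiles (order statistics with linear interpolation;
with n samples the p-th percentile sits at 0-based rank (n−1)p).  The point
estimate is the median of draws — the plain reading of "percentile
intervals for the median"; a nested bootstrap is deliberately not the
default.

Sampled inputs and their distributions:

* **mean intake** — log-normal, moment-matched to (mean, rel. SE × mean).
  Uncertainty enters as the sampling distribution of the population *mean*;
  the per-person SD stays fixed in the discretisation so that prevalence
  keeps its meaning.  The counterfactual mean is a policy constant and is
  not sampled.
* **cost cells** — log-normal, moment-matched, one independent substream
  per cell.
* **relative risks** — ln RR ~ Normal(ln RR₀, se), se = 10% of |ln RR₀|
  unless supplied.

The sources publish point values without dispersions, so the relative SEs
(default 10% for all three classes) are explicit modelling choices, exposed
in `MCConfig`; setting them to zero collapses every draw onto the
deterministic result exactly.  Each input cell derives its generator from
the one global seed plus a CRC-32 of a stable label, so adding or removing
outputs never perturbs other streams, and a fixed seed gives bit-identical
summaries and byte-identical report files.  The engine evaluates all draws
in one vectorised pass; 10,000 draws on the full national fixture take
about two seconds on one CPU.

## Synthetic inputs

`default_fixture()` carries the published national values verbatim: intake
10.0 ± 5.4 g/day at 2171 kcal (counterfactual 5.0 ± 2.65), participation
0.62, wage USD $765/month, pension ages 60/65, working age from 15, ₡600/USD,
life expectancy 82.6 (women) / 77.5 (men), and the three national service
cost totals (consultations USD $853,309,618.14, hospitalisations
USD $1,584,985,326.39, hypertension+CHD medications USD $642,090.81).

What the payer and the upstream meta-analyses never published at stratum
level is filled with deterministic, clearly synthetic defaults: the
disease/sex split of the service totals (fixed fractions), per-mmHg RR
anchors per outcome (1.012–1.035) whose log attenuates 10% per decade of
age — keeping every rescaled bin RR in a plausible 1.0–1.6 range — a
geometric age gradient of deaths from age 30 (~4,000 total, the scale of
national CVD mortality), and a smooth age pyramid (~3.7 M adults).  Age
bands are 5-year bands 15–19 … 75–79 plus 80+, the GBD convention.  These
placeholders make the pipeline runnable and testable end to end; passing
tests on them demonstrates the machinery's correctness, not agreement with
the unpublished national appendices, and fixture-level attributable totals
should not be quoted as estimates.  `generate_random_bundle(seed)` draws
jittered bundles (intake mean 8–12 g/day, log-normal cost jitter, Poisson
death counts) for stress tests; all invariants (RR ≥ 1, weakly decreasing
with age; positive costs) hold by construction and are revalidated by the
table readers.

What the generator does not emulate: real survey measurement error (24-h
urine vs FFQ), correlation between cost cells, secular trends, migration,
and any covariance between intake and risk across strata.

## Numerical choices and degenerate inputs

* Truncated-normal bin masses come from closed-form normal CDFs, clipped to
  [0, 1] before differencing to guard the extreme-tail case.
* sd = 0 anywhere is handled exactly (degenerate distribution; degenerate
  log-normal).
* P = 0 returns combined RR = 1 by convention, hence PAR = 0.
* P(RR−1) = −1 raises a singularity error rather than returning ±inf.
* Duplicate table cells (same key) are errors, never silently summed.
* Display rounding is half-away-from-zero; ties in integer shares are not
  re-normalised to force rows to 100%.

## Test problem sizes

The suite exercises the full fixture (14 age bands × 2 sexes × 4 outcomes)
for deterministic runs and a compact 2 × 2 × 2 bundle for statistical
checks; coverage of the uncertainty engine uses 100 replicates of 400 draws
against a known truth, and the timing check runs the full 10,000-draw
fixture simulation.

## Known limitations

* The combined RR rescaling assumes the per-mmHg RR is constant across the
  SBP range a bin shift spans (log-linearity).
* Sex-level cost attribution uses population-weighted pooling of
  age-specific fractions; if costs concentrate in age groups with atypical
  fractions, stratified cost tables should be supplied instead.
* The human-capital approach values lost market production only; friction
  costs and morbidity-side losses (absenteeism, presenteeism) are out of
  scope.
* Percentile intervals from 10,000 draws carry ~1% Monte Carlo noise in
  the interval endpoints themselves.
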