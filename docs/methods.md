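# Methods

This note documents the models behind `ternergy`, the choices made
where the design was genuinely open, and what the synthetic-data tests
do and do not demonstrate about real field data.

## Scope and assumptions

The package models a small colonial seabird (default parameterisation:
greater crested tern, ~0.39 kg, single-egg clutch, 68-day breeding
season) during three breeding stages — incubation, early provisioning
(chick in the nest cup) and late provisioning (mobile chick). Core
assumptions, all configurable:

- **Two-activity budget.** Time away from the colony is costed entirely
  at the flight rate. Terns neither rest on the water nor dive for more
  than seconds, so the ~1 min·d⁻¹ of plunge-diving is carved out of the
  flight block at an identical unit cost. Thermoregulation, wind fields
  and alternative flight modes are not modelled; the two flight-power
  figures entering the flight cost are inputs from an external
  aerodynamic model, not recomputed.
- **No nocturnal foraging.** Trips are bounded by nautical twilight.
  Records censored by camera coverage are completed by substituting
  morning/evening twilight, which can only lengthen a trip; trips that
  would span midnight are rejected as data errors.
- **Single-species diet.** Intake is expressed in grams of anchovy via
  one energy density; mixed diets can be emulated by adjusting Cp.
- **Random-in-time nest failure.** Survival to day *t* is exp(CMR·t)
  with CMR = ln(s)/F, so survival to fledging equals the breeding
  success s. The provisioning weight is the discrete mean of the
  survival curve over days 1…F (the closed-form geometric sum is used
  as an independent oracle in the tests, not in the implementation).

## Parameters

| parameter | default | units | note |
|---|---|---|---|
| body mass M_b | 0.39 ± 0.03 | kg | normal prior, truncated > 0 |
| BMR | 6.73 | W·kg⁻¹ | mass-specific |
| colony cost | 2 × BMR | — | resting at the colony |
| flight power | (31.8 + 39.5)/2 = 35.65 | W·kg⁻¹ | midpoint of min/max continuous-flapping power |
| prey energy Cp | 6.22 ± 0.65 | kJ·g⁻¹ wet | normal prior |
| assimilation Ea | 0.77 (fixed) | — | see below |
| stage durations | 28 / 4 / 36 | d | incubation / early / late |
| fledging period F | 40 | d | |
| asymptotic chick mass A | 370 | g | |
| allometry α, β | 539.5 kJ, 37.3 kJ·g⁻¹ | | TME = α + β·A |
| breeding success s | 0.59 | fledged·pair⁻¹ | |
| breeding pairs | 15,000 | | population scaling |

Unit costs are carried at full precision (0.8076 and 2.139
kJ·kg⁻¹·min⁻¹); a `rounded_unit_costs` preset reproduces the coarser
published rounding (0.8 / 2.0) for comparison. Published per-stage
flight-cost figures sit ~2% below minutes × full-precision cost, which
is why budget-level checks use a 5% band rather than print rounding.

**Why Ea is fixed by default.** The field literature reports the
assimilation efficiency as 0.77 ± 0.34, but that SD cannot have been
propagated in the published budgets: the reported output CVs (e.g.
adult DFI 140.9 ± 20.7, a 14.7% CV) are fully explained by expenditure
(8.9%) and prey energy density (10.45%) alone, while a 44%-CV Ea in the
denominator would roughly triple them and shift the posterior means by
tens of percent. The package therefore treats Ea as a point value by
default; supplying `assimilation_sd > 0` activates a normal prior
truncated to (0.05, 1] — an unbounded normal with that SD would produce
non-positive or >1 efficiencies.

## Inference

Stage means of trip duration, trips/day, feeding rate and prey mass are
fitted with a gamma likelihood, log link and one coefficient per stage
(the analysis reports stage means, not contrasts): y ~ Gamma(k, rate =
k/μ_s), μ_s = exp(coef_s), priors N(0, variance 10⁷) on coefficients
and U(0, 100) on the shared shape. Sampling is adaptive random-walk
Metropolis within Gibbs, all chains advanced in lock-step as rows of
one array; per-stage sufficient statistics (n, Σy, Σlog y) make each
step O(#stages) irrespective of sample size. Proposal scales adapt
toward 23.4% acceptance during burn-in only, so the post-burn-in kernel
is a valid fixed Metropolis kernel. Counts (trips/day, deliveries) are
integer-valued; the default follows the blanket gamma treatment, with a
Poisson likelihood available via `rates_likelihood="poisson"`. Zero
counts are incompatible with a gamma likelihood and are dropped with a
logged tally before fitting (~1% of early-stage feeding records);
trips/day are aggregated per nest over fully covered camera days, which
keeps them positive and matches a per-parent interpretation during
incubation and early provisioning (a nest camera cannot assign trips to
individuals). Only fully covered days enter the trips/day denominator.

The TME–mass allometry is a Bayesian linear regression with the same
flat normal priors and a U(1500, 4500) kJ prior on the residual SD,
sampled by Gibbs: the (α, β) conditional is conjugate bivariate normal
and drawn exactly; σ is drawn by inverse-CDF on a 1025-point grid. Both
steps are exact conditional draws, so chains mix essentially
immediately. One consequence worth knowing: with only ~10 species and
residual SDs of a few thousand kJ, the nominally vague N(0, 10⁷) prior
is not quite flat for the intercept — it shrinks α toward zero by
roughly 15–20% of its value (≈0.5–0.7% of TME at A = 370 g). This is a
property of the stated prior, not a sampler artefact; the slope is
unaffected.

Convergence is reported as rank-normalised split-R̂ (ranks mapped
through the normal quantile function with the (r − 3/8)/(N + ¼) offset,
then the classic split-chain potential scale reduction); the plain
split variant is available and is cross-checked against `arviz.rhat`
in the test-suite. Credible intervals are equal-tailed 2.5–97.5
percentiles throughout, not HPD. Default chain configuration is 3 ×
150,000 samples with 50,000 burn-in; tests and examples run a reduced
3 × 20,000 / 5,000 configuration, which on these small models already
yields R̂ < 1.01.

Purely deterministic transformations of independent priors (activity
costs, DEE, DFI, CPUE, provisioning arithmetic) use plain Monte-Carlo
draws rather than MCMC — equivalent for such maps and faster. One joint
draw index is used across stages so shared inputs (body mass, Cp)
remain correlated between stage budgets, and the per-draw identities
flying + colony = 1440 min and DFI·Cp·Ea = DEE hold to machine
precision. Gamma priors specified from a mean and SD are moment-matched
by default (shape = m²/sd², rate = m/sd²); the `prior_rule="literal"`
alternative (shape = mean, rate = 1) reproduces a convention sometimes
used in field workflows, at the cost of forcing variance = mean.

### Two sources for stage rates

`rates_from="data"` (default) fits the regressions to observation
tables — simulated or user-supplied. `rates_from="summary"` instead
builds stage-mean posteriors from published summaries (mean and
CI-implied SD as truncated normals). The summary path is the right tool
for reproducing a published budget table: refitting from freshly
simulated data at realistic sample sizes adds 3–8% sampling noise to
every stage mean (the late-provisioning trip rate, observed over only
~60 nest-days, carries a ±14% interval by itself), which is inherent
sampling variability, not model error.

## The synthetic-data generator

The generator's defaults are the study conditions: stage means 4.73 /
1.83 / 2.24 h trip duration, 1.52 / 4.08 / 4.57 trips·d⁻¹, feeding
rates 4.6 / 8.6 d⁻¹, mean delivered anchovy mass 4.4 / 5.2 g, and
default sample sizes matching the field effort (~1,140 and ~1,750
camera trips, 252 focal trips, 240 + 34 feeding records, 126 + 629
prey photographs). Dispersions are not published directly and were
derived from the published interval widths and sample sizes: trip
duration CV 0.83 (all three stages independently give 0.82–0.83), prey
mass CV 0.65 (early) and 0.61 (late). Counts are Poisson.

Two calibrations keep the realised means exactly on target:

- **Daylight-bounded trip durations.** A CV-0.83 gamma with mean 4.73 h
  has non-trivial mass beyond the ~13.75 h twilight span; durations are
  therefore drawn from the gamma truncated at the daylight span with
  the scale re-solved (root-finding on the truncated-mean identity) so
  the realised mean equals the stage mean.
- **Prey lengths.** Lengths are gamma; masses go through mass = a·Lᵇ
  (b = 3.2, a anchored so a 9.0 cm anchovy weighs 4.4 g — a documented
  surrogate for unpublished year-specific regressions, configurable per
  year with a pooled fallback). Because the power law is convex, the
  length-scale and shape are solved from the exact gamma moment
  formulas so the *converted masses* hit the target mean and CV.

Trips within a nest-day are placed independently (departure uniform
over the feasible daylight slot), so two simultaneous trips of one nest
can overlap in clock time; downstream analysis consumes only durations
and counts, which are unaffected. The camera window defaults to 30 min
inside each twilight, so ~8% of trips are censored at each edge and the
substitution logic is always exercised. The allometry generator can
project its noise orthogonal to the regression design
(`calibrate=True`), preserving the residual SD while making OLS — and
hence the posterior means under flat priors — recover the generating
coefficients exactly; uncalibrated noise is used for coverage tests.

What passing tests show: the estimators recover known truth at field
sample sizes, interval coverage is nominal, and the propagation
arithmetic is exact. What they do not show: robustness to features the
generator omits — individual heterogeneity and overdispersion beyond
Poisson (the real late-stage feeding rates are visibly overdispersed),
weather-driven covariance between trip length and prey size,
kleptoparasitic prey loss, camera failures mid-day, and chick growth
dynamics (asymptotic mass is a constant).

## Numerical choices and degenerate inputs

- Seeds: every public entry point is driven by one integer seed; child
  streams are derived via `SeedSequence(seed, spawn_key)` so tables,
  fits and prior draws are independent yet reproducible. Identical
  config + seed yields byte-identical output files (each carries the
  seed and a hash of the scientific config in its header).
- Draws implying ≥ 1440 min·d⁻¹ away from the colony are impossible and
  are rejected jointly across stages; more than 1% rejections aborts.
- All-identical observations push the gamma shape posterior to its
  upper prior bound and the stage mean to the common value; zero-width
  designs (all species masses equal) are rejected.
- Elasticities in the sensitivity analysis are computed in log space,
  (log f₊ − log f₋)/(log x₊ − log x₋), which is exact for power-law
  dependencies (−1 for Cp and Ea) rather than merely approximate.
- Ea truncation bounds, flight-power bounds and the σ prior interval
  are configuration, not constants.

## Known limitations

- The two-activity budget cannot separate search, transit and surface
  behaviours; CPUE is therefore food per minute *away*, not per minute
  actively foraging.
- Posterior pairing of prey mass and feeding rate draws is independent
  (they come from different datasets); any real covariance between fish
  size and delivery rate is not represented.
- The larid allometry ships as a calibrated synthetic stand-in; users
  with the real inter-species table should load it via
  `allometry_table=` and expect the intercept-shrinkage note above to
  apply.
- The sensitivity analysis is one-at-a-time around central values; it
  ranks leverage but does not explore interactions.
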