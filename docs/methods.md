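# Methods

This note documents the models, conventions and design choices behind
`chronest`, and what the synthetic-data experiments do and do not show.

## Bout detection

**Trace model.** A nest trace is a regular (default 3-minute) series of
temperatures quantised to the logger accuracy (0.0625 or 0.5 °C; any
positive step is accepted and can be inferred from the data as the
minimal positive difference between recorded values). A 30-minute
ambient series is linearly interpolated onto the trace grid. Dates run
midnight to midnight; the "night" of a date is 21:00 of the previous
evening to 05:00, and dates are reported as April days (1 April = 1).

**Incubation start.** Onsets are only meaningful once the female sits
on the nest overnight. The first analysed date is the first whose night
window holds nest − ambient ≥ 5 °C (configurable) for ≥ 75 % of night
samples; traces that never qualify yield a "not started" sentinel.

**Thresholds.** Real departures drop nest temperature by clearly more
than 0.5 °C, so the drop threshold is the larger of a 0.5 °C floor and
the 95th percentile of absolute successive differences over that
nest's night window on that date — nest- and day-specific, so noisy
nests demand larger excursions. The rise threshold is derived
symmetrically from quiet daytime samples (within 1 °C of the daytime
median, so excursion transients do not inflate it). Nights with fewer
than 10 samples fall back to all nights pooled, flagged in the result.

**State machine.** Within a day, an off-bout opens when the cumulative
decline from the running maximum of the current on-bout exceeds the
drop threshold *and* the decline is toward ambient; it closes when the
cumulative rise from the running minimum exceeds the rise threshold
(rise-rate closure; absolute-recovery closure was considered and
rejected as it conflates slow re-warming with absence). Boundaries are
backdated by one sample: the departure happened somewhere inside the
interval preceding the threshold crossing, and with coarse (0.5 °C)
quantisation the first post-departure sample can quantise to a
sub-threshold drop, so placing the boundary on the preceding sample
keeps the timing error within one sampling interval in all cases.
Dates with a gap of ≥ 2 sampling intervals are invalidated (the first
departure would be ambiguous). The daily onset is the start of the
first off-bout after the longest on-bout overlapping the night window.
Dates later than 13 days after (expected) hatch are excluded; when
hatch is unobserved it is expected 13 days after clutch completion
(hatch checks happen on incubation day 14).

## Standardisation and chronotype

Per (year, date), onsets are z-scored across females using the sample
(n−1) SD — with 3–10 females per date the unbiased denominator is the
safer default (switchable). Dates with < 3 females or zero spread are
dropped (a z-score against zero spread is undefined; assigning 0 would
fabricate agreement), then broods with < 2 retained onsets. The
chronotype is the mean z of the first brood in the female's first
measured year; "first brood" is resolved by earliest lay date, ties by
earliest incubation start, then lowest brood id. Females used in
experiments can be excluded via an explicit list. Onsets from different
breeding stages on the same date are pooled — the stage effect is
handled downstream by the breeding-day terms of the mixed model rather
than inside the standardisation.

Standardisation is affine-invariant: shifting or (positively) scaling
all onsets of a date leaves every z unchanged, which is exactly why the
method removes day-length and weather shifts. It also *constrains* the
data — every retained date has mean z = 0 — so date-level fixed effects
(April day, Year) are structurally near-null after standardisation;
calibration experiments for those fixed-effect tests therefore run on
raw onsets.

## Variance components and repeatability

The standardised onset is modelled with fixed effects Year, April day,
Year×April day, centred breeding day and its square (onsets drift later
toward hatching and recover afterwards), and crossed random intercepts
for Female, Female_Year and Nest-box. The crossed structure is fitted
by a profiled (RE)ML criterion of the standard penalised-least-squares
form: variance ratios θ_k = σ_k²/σ² are optimised by L-BFGS-B with a
zero lower bound (components can sit exactly on the boundary, as a
confounded nest-box term typically does), and all cross-products are
precomputed so each objective evaluation costs one Cholesky of a
(levels × levels) matrix. The implementation is cross-checked against
lme4 in the test suite and agrees to < 1e-3 in every component and in
the REML log-likelihood.

Repeatabilities are intraclass correlations: r_across = V_female/V_total
and r_within = (V_female + V_female_year)/V_total with V_total the sum
of all four components. The within-year decomposition necessarily
satisfies r_within ≥ r_across. Because a reported total could exclude
the (often zero) nest-box component, both denominators are computed and
written to the report. Random-effect tests are single-df likelihood-
ratio tests on REML fits (no 50:50 boundary mixture; conservative under
the null, which the calibration test confirms). Fixed-effect tests
refit by ML, since REML likelihoods are not comparable across fixed
structures.

## Selection-model suite

Eight models share the base formula C + C² + Year + C:Year + C²:Year
(+ within-year-centred lay date except in the lay-date model itself):
lay date, clutch size, hatchlings and fledglings (Gaussian), fledge
success and second brood (binomial; the second-brood model adds the
first-brood fledgling count and includes only successful first broods),
female weight (Gaussian, + time of day, time², tarsus) and nestling
biometrics (Gaussian mixed with a brood random intercept against
sibling pseudo-replication; weight adds time-of-day terms, and
within-year-centred hatch date replaces lay date). Deserting females
leave the hatchling/fledgling models; pre-hatch failures additionally
leave fledge success. Each female enters once, via her first measured
year. The suite builder returns one nestling spec (weight) by default
and expands to tarsus and P3 on request.

Hatchlings are estimated as m + (c − m − u)/2: eggs neither counted as
nestlings (m) nor recovered unhatched (u) are counted half each, which
bounds the estimate by m ≤ ĥ ≤ c − u and motivates the Gaussian rather
than Poisson/binomial error family.

**Backward reduction.** A term is droppable only while no retained
higher-order term contains it (containment compares variable powers,
so C²:Year protects C², C:Year, C, and Year). At each step the
droppable term with the largest deletion-test p is removed if
p ≥ α = 0.05 — the conventional stopping rule for stepwise reduction;
dropped terms are never re-entered. Tests are F (Gaussian,
residual-SS based), deviance χ² (binomial; the stored statistic is
signed as the deviance change from reduced to full, negative when the
term improves fit), and ML likelihood ratio (mixed). Estimates and SEs
are captured from the model in which the term was last present.
Covariates of no interest are droppable like any other term but can be
force-retained via configuration. Prediction bands draw coefficient
vectors from N(β̂, Σ̂) (2000 draws), push them through the linear
predictor and inverse link, and take 2.5/97.5 percentiles; an exactly
zero covariance yields zero-width bands, anything indefinite raises.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions the rest of the package is verified under.

* **Latent chronotype** C ~ N(0, 0.45²): the reported chronotype range
  of roughly ±1.2 z makes 0.45 a plausible SD for a Gaussian latent
  trait; only a range, not a distribution, is constrained by data.
* **Onsets** (hours): date mean (6.2 by default) + female effect +
  female-year + nest-box + residual with variances (0.15, 0.06, 0,
  0.79) — chosen so the component ratios reproduce the repeatability
  structure the pipeline is meant to detect (r_across 0.15, r_within
  0.21) and the total variance is 1. The female effect is C scaled to
  variance v_female, so measured chronotypes correlate with the latent
  truth. An optional heavy-tail contamination (occasional extremely
  early onsets) is exposed and off by default. All females of a year
  share a measurement window (optionally staggered), so every date has
  ≥ 3 females whenever the population does.
* **Life history**: lay date = 25 + year effect (defaults 0, +3, −2
  days, emulating between-season shifts) + linear·C + quad·C² +
  N(0, 5 days); clutch ≈ 9 eggs declining 0.055 eggs/day of relative
  lay date; hatch/fledge/second-brood via logit links with chronotype
  effects defaulting to zero (the null hypothesis); desertion ~3 %,
  pre-hatch failure ~1 %, total brood failure 10 %, ~8 % of hatchlings
  unobserved — rates of the order seen in monitored box populations.
* **Study entry** is staggered by default (females recruit uniformly
  across years, so first measured years differ and Year terms are
  estimable in the female-level suite); `entry_mode="all"` gives the
  balanced designs used for variance-component recovery.
* **Nest-box turnover**: females move boxes between years with
  probability 0.4; full fidelity would confound Female and Nest-box and
  make the nest-box component unidentifiable.
* **Traces**: on-bouts relax toward a 35 °C plateau (time constant
  4 min), off-bouts toward ambient (8 min) — no thermal model is
  constrained by data, and these constants make 0.5 °C-quantised traces
  still show unambiguous (> 0.5 °C within one sample) drops for real
  departures. Observation noise is N(0, 0.05 °C), i.e. of the order of
  the fine quantisation step: a quiet-logger idealisation under which
  the night-window running maximum stays within one coarse quantum of
  the plateau. Ambient is a sinusoid peaking at 15:00 (base 10 °C,
  amplitude 6 °C) binned at 30 minutes.

What the generator does **not** emulate: male visits and partner
feeding, sensor displacement ("wire/button" deployment artefacts),
weather-driven ambient excursions, gradual incubation onset, stage-
dependent onset drift, or attenuation-free chronotype measurement.
Passing recovery tests therefore show that the algorithms are correct
under the stated model, not that field traces are this clean; the
threshold machinery (nest- and day-specific quantiles) exists precisely
for messier data and is exercised separately with inflated noise.

## Numerical choices and conventions

* Seeds: one top-level seed expands into fixed named sub-streams per
  table, so each artefact is independently reproducible.
* LMM optimisation: two starts (θ = 0.5 and 0.05 per component),
  numerical gradients, ratios < 1e-8 snapped to the boundary; the
  profiled residual variance uses n − p (REML) or n (ML).
* Collinear fixed-effect columns (e.g. year terms in a single-year
  table) are dropped by a rank-building pass before fitting.
* The recovered quadratic lay-date effect in calibration experiments is
  the year-averaged coefficient when the quadratic-by-year interaction
  is retained (the raw C² coefficient is then the reference-year effect
  only).
* Binomial fits that separate perfectly are returned flagged (an
  unbounded-estimate warning), never raised.
* Problem sizes in the default test run: recovery experiments use 20
  replicates of 200 females × 3 years × 10 onsets; calibration uses 500
  null suites at n = 164 and 150 raw-onset fits for fixed-effect
  type-I error; detection round-trips use 100 nest-days per accuracy.

## Known limitations

* Measured chronotypes are noisy proxies of the latent trait, so
  selection-gradient estimates on measured chronotypes are attenuated
  (the recovery experiments regress on the latent truth to isolate the
  fitting machinery; with 10 onsets/female and the default variance
  components, the measured-vs-latent correlation is ≈ 0.7–0.8).
* Quadratic-term retention in a marginality-respecting backward path is
  a compound event: the term survives either through its own test or
  through a retained higher-order interaction, so "present in the
  final model" has a null rate near 2α while the term's own deletion
  test is calibrated at α. Both rates are reported.
* The df = 1 χ² for variance components ignores the boundary, making
  those tests conservative.
* No confidence intervals on repeatability (a parametric bootstrap
  would be a natural extension), no survival or lifetime-fitness
  models, and no sunrise-relative chronotype (the conspecific
  standardisation exists to avoid its day-length bias).
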