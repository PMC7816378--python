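# Methods

This note documents the models, conventions, and numerical choices in
`winterflux`, and what the synthetic generator does and does not emulate.

## Study system and data model

Geese carry solar GPS–accelerometer collars from two device families.
GPS fixes arrive every 30 or 60 minutes; tri-axial acceleration bursts of
3 s at 10 Hz (30 samples per axis) arrive every 6 minutes. The winter
range is partitioned into eight regions coded 1–8 (South Texas
Brushlands, MAV, Chenier Plain, Texas Mid-coast, Other, Mexico, Lower
Texas Coast, Rolling/High Plains); code 9 means "not observed". The
winter date index runs from the earliest device deployment (day 1) to
28 February (day 137), giving 19 full weekly occasions.

## Track processing

* **Distance metric.** Haversine great-circle distance with Earth radius
  6371.0088 km. The metric is symmetric and satisfies the triangle
  inequality (property-tested).
* **Day boundaries.** UTC−6 local time, so a "day" matches the
  biological day in the wintering range. Whether daily totals should use
  local or UTC days is a convention; it is configurable only by editing
  `LOCAL_UTC_OFFSET` because nothing downstream depends on the choice
  given consistent use.
* **Hourly resampling.** Within each hour the fix nearest the
  top-of-hour is kept (tolerance ±30 min, ties toward the earlier fix).
  The operation is idempotent.
* **Step lengths.** Successive great-circle distances per individual;
  steps spanning ≥ 4 h are removed — in an hourly scheme these are
  exactly the missing-fix outliers.
* **Winter delimitation.** Winter starts at the first instant at
  ≤ 40° N followed by ≥ 4 days without a further > 50-km net-southward
  daily displacement (a qualifying hop re-sets the start to the hop's
  day); "large-scale movement" is evaluated on net first-to-last daily
  displacement, not summed path. Winter ends at the first northward
  crossing of 40° N, else 28 February. Individuals never at ≤ 40° N are
  excluded with a log entry.
* **Daily-distance series.** Per-individual daily sums of retained
  steps, then the cross-individual mean; days with ≤ 3 contributing
  individuals are censored; the series is indexed 1..137.
* **Trend regression.** OLS of log mean daily distance on the day index
  with terms up to cubic; backward elimination removes the highest term
  while its p-value exceeds α (default 0.05), stopping at the linear
  term. The Shapiro–Wilk residual p-value is reported, never used as a
  gate; the log transform is always applied. The peak day is the argmax
  of the fitted curve on the integer day grid.

## Daily states and weekly capture histories

The day's fix nearest local midnight (the nearer of the day's two
midnights; ties toward the earlier fix) is point-in-polygon tested
against the eight regions; inside none → Other (5); a fix exactly on a
shared boundary resolves to the lowest region code; no usable fix → 9.

Weekly collapse reduces each 7-day block to one state. The governing
idea is that a week containing a transition must record the
transitioned-to state. The implemented rule: collapse the observed
(non-9) codes to their run sequence; with no transition, keep the state;
otherwise take the destination of the final transition, except that a
terminal return to the week's initial state is ignored (treated as an
intermediate step) unless the week ends in that state for ≥ 2 observed
days. This is the minimal rule consistent with the three contract
examples 'BBBBAAA'→A, 'AAAABBA'→B, 'AABBCCC'→C, which are frozen as unit
tests. Weeks containing 9s apply the rule to the observed subsequence
(e.g. 'AA99BBB'→B); fully unobserved weeks stay 9; partial terminal
weeks use the same rules.

## Multistate capture–recapture model

True-state space S = 9: eight regions plus an absorbing dead state.
Observation space: eight "seen in region" categories plus "not
observed"; the dead state emits "not observed" with probability 1.
Weekly event order is survive (Bernoulli φ of the current region), then
transition (categorical ψ row), then detect (Bernoulli p of the new
region) — the standard multistate ordering. Parameters are time- and
individual-constant.

* **Likelihood.** Forward algorithm over each history, conditioned on
  the first observed state; all alive/dead latent paths are
  marginalised. Verified against exhaustive path enumeration on small
  instances to 1e-12.
* **Transition parameterisation.** Per row, 7 free logits relative to
  "stay", so off-diagonal transition probabilities always sum to < 1 and
  fidelity is the complement. Priors: Normal(0, 10) on transition
  logits; Normal(0, 1) on survival and detection logits, with a switch
  (`uniform_prob_prior`) to a Uniform(0,1) prior on the probability
  scale (realised through the logistic Jacobian) because the two
  readings of "vague priors (mean 0, sd 1)" for these parameters cannot
  both hold.
* **Sampler.** Block-wise random-walk Metropolis (10 blocks: one per ψ
  row, one each for φ and p) with per-block proposal scales adapted
  every 50 burn-in iterations toward 20–40% acceptance. The forward
  likelihood is numba-compiled; a desk-scale fit (3 chains × 20,000
  iterations, burn-in 5,000, thin 5 — the default) takes about a minute
  on one CPU at 100 individuals × 19 weeks. A full-scale configuration
  (e.g. 3 × 450,000 / 9,000 / 10) is available through the same
  arguments. Initial values are drawn diagonal-dominant and re-drawn (up
  to 50 times) if the posterior is non-finite.
* **Convergence and reporting.** Classic Gelman–Rubin potential scale
  reduction per parameter across chains (constant identical chains → 1
  by convention); parameters with R̂ > 1.10 are flagged. Transitions
  never observed in the data whose posterior mean is ≤ 0.001 are flagged
  as "returned the prior" and excluded from interpretation. Survival and
  detection are reported as nuisance parameters only, because device
  failure is confounded with death. Fidelity + cumulative emigration = 1
  holds exactly per draw by construction.

## Energetics

* **Calibration.** Per-device affine maps to m/s² (bounded family:
  1 G = 1024 mV; unbounded family: G-force × 9.81).
* **Quantile mapping.** The bounded family clips at ±2048 mV, censoring
  high-amplitude behaviours. A monotone piecewise-cubic (PCHIP)
  interpolant through matched empirical quantile pairs maps the bounded
  distribution onto the unbounded one; monotonicity is guaranteed by
  construction, which a generic smoothing spline would not be. Values
  beyond the outermost pair extrapolate linearly. Because a value-wise
  monotone function cannot spread the rail's point mass,
  `QuantileMap.transform_sample` additionally offers rank-based
  matching (mid-rank plotting positions into the target quantile
  function) that restores censored mass into the target tail; a
  cumulative-density diagnostic table supports visual assessment.
* **ODBA.** Static acceleration per axis is a centred 10-sample (1-s)
  moving average, truncated at burst edges (a `discard` edge mode drops
  edge samples instead); dynamic acceleration is raw minus static;
  per-sample ODBA sums the absolute dynamic components; the burst value
  is the mean over samples (not the sum), so bursts remain comparable
  when samples are missing. ODBA is invariant to constant axis offsets
  and scales linearly.
* **Daily ODBA and the regional model.** Mean ODBA over each
  individual-day with a resolved region. The response is centred and
  standardised then inverse-hyperbolic-sine transformed (the reverse
  order is available via `transform_order`, since either reading of the
  transform chain is defensible); region is the fixed effect with MAV
  (code 2) as reference; individual and winter enter as crossed random
  intercepts via variance components, fitted by REML (falling back to an
  individual-only random intercept if the crossed fit fails). Marginal
  and conditional R² use the variance-partition definitions. All 28
  pairwise region contrasts get single-step max-|t| adjusted p-values
  computed by Monte Carlo from the joint normal of the contrast
  statistics (seeded, 100,000 draws by default).

## Behaviour

* **Features.** Per-axis static mean, dynamic SD, range; burst ODBA; and
  dynamic autocorrelations at lags 1–5 averaged over axes (the flight
  flap frequency of 4 Hz shows as strong negative lag-1/lag-2 structure
  at 10 Hz sampling). Features are deterministic.
* **Classifier.** Random forest (500 trees by default) with out-of-bag
  accuracy and an OOB confusion matrix; training requires ≥ 2 classes
  with ≥ 50 bursts each. The original training data were video-annotated
  bursts; here labels come from the generator's known classes — the
  classifier machinery, not any particular training set, is the
  contract.
* **Time budgets.** Per individual-day-region proportions of the four
  classes over that day's bursts (rows sum to 1), with regional means ±
  SE over individual-days.
* **Budget–ODBA regression.** Beta regression (logit mean link,
  constant precision — no precision submodel) of regional mean
  proportions on the region's back-transformed daily-ODBA difference
  from the reference region. The back-transformation inverts the full
  response transform chain (IHS then standardisation). The reference
  region's own point (contrast 0) is included; with ~8 points this is
  consequential and deliberate. Boundary proportions are shrunk with
  (y·(n−1)+0.5)/n, with a warning. Pseudo-R² is the squared Pearson
  correlation between logit-fitted and logit-observed values.

## Synthetic generator

The generator is first-class, tested code that defines the study
conditions:

* Latent weekly chains over the eight regions with an absorbing dead
  state; defaults: fidelity diagonal (0.89, 0.84, 0.90, 0.82, 0.73,
  0.99, 0.70, 0.93) with the off-diagonal mass spread uniformly over the
  other seven regions, weekly survival 0.95 and detection 0.90 per
  region, 100 individuals × 19 weeks. Initial states are distributed
  equally over the four device-deployment regions (South Texas
  Brushlands, Chenier Plain, Lower Texas Coast, Rolling/High Plains),
  matching the capture design that histories emulate.
* Regions are disjoint lon/lat rectangles spanning roughly 24.5–36.5° N,
  105–89° W, so great-circle distances are realistic; corner jitter is
  seed-driven and bounded below half the inter-rectangle gap, keeping
  disjointness for every seed. Real management-boundary shapefiles are
  out of scope.
* Tracks: hourly fixes at a weekly roost site during night hours and a
  forage site by day (a roost–field–roost commute), placed inside the
  current latent region; ≥ 4-h gap blocks injected at a configurable
  daily rate; staggered deployment optional.
* Bursts: class-specific signals in m/s² with gravity on the dorsal
  axis — stationary: noise only; foraging/walking: 1.2/0.7 m/s²
  oscillations at 1.5/2.5 Hz; flight: a 12 m/s², 4-Hz flapping sinusoid
  (plausible goose wingbeat) plus a smaller surge component. Amplitudes
  are package defaults chosen so that the bounded device's ±2048 mV rail
  (±2 G) actually clips flight, as in the field data. Behaviour labels
  are drawn i.i.d. per 6-min slot from the region's budget simplex
  (foraging and flight means per region follow the reported regional
  time budgets; walking is fixed at 0.15; stationary takes the
  remainder), so truth budgets are exactly recoverable; serial
  correlation of behaviour is deliberately not modelled.

What the generator does **not** emulate: GSM coverage geography, solar
charging, weather- or disturbance-driven movement, serially correlated
behaviour, inter-individual behavioural heterogeneity, and real region
geometry. Passing recovery tests therefore demonstrates estimator
correctness under the stated generating process, not performance on
field data.

## Problem sizes and known limitations

Tests and the acceptance harness use desk-scale sizes chosen as the
package's default study conditions: 100 individuals × 19 weeks and
3 × 20,000 MCMC iterations for the multistate recovery; 500 bursts per
class for the classifier; 130-day series × 200 replicates for the trend
recovery. At this scale the realised latent chain is itself noisy: the
Lower Texas Coast state (lowest fidelity, 0.70) accrues only ~100
transitions per simulated winter, so its realised fidelity has
Monte-Carlo sd ≈ 0.04 and a single replicate's posterior mean can sit
several hundredths from the generating value while still covering it
with the 95% credible interval. The vague multinomial-logit prior also
pulls fidelity slightly downward where support is thin. Survival and
detection are structurally confounded with device failure and must not
be interpreted. The weekly-collapse rule is a contract choice among
several rules consistent with its worked examples; alternatives differ
only for weeks with ≥ 2 transitions ending in a one-day return.
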