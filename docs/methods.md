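# Methods

This note documents the models, rules and numerical choices behind
`storksurv`, and what the synthetic cohorts do and do not establish.

## The analysis pipeline

The package reconstructs a juvenile-survival analysis for GPS/ACC-tagged
white storks (*Ciconia ciconia*). Tags record positions and tri-axial
body acceleration for 18 h a day (02:00–20:00 UTC); GPS fixes arrive at
1 s–20 min intervals and ACC in bursts of 1.2–4.1 s at 10.54–33.33 Hz
every 0.5–10 min. From these streams the pipeline derives, per
individual:

1. **Daily ODBA** (overall dynamic body acceleration) — per UTC day the
   per-axis mean over all samples (pooled across bursts) is subtracted
   from the raw values; a burst's ODBA is the summed absolute dynamic
   components of all three axes, divided by sampling frequency × burst
   duration (= the sample count); the daily value is the median over
   that day's bursts. **Interpretation note:** the dynamic components
   enter in absolute value. Without |·| the within-day sum is
   identically zero by construction of the mean, so the magnitude-based
   form — the standard ODBA definition — is the only meaningful
   reading. This is the most consequential interpretation in the
   package. A running-mean static component is available
   (`daily_axis_means(..., method="burst_mean")` covers the pooling
   alternative); the daily mean is the default.
2. **Daily displacement** — great-circle distance (spherical Earth,
   R = 6371.0 km) between the *first* fixes of two calendar-consecutive
   days, log-transformed with a 0.001 km floor for zero movement.
3. **Phenology** — fledging: first of two consecutive days with nest
   distance > 500 m; departure: first day whose first-fix latitude sits
   ≥ 0.38° (≈ 50 km) south of the previous day's, threshold inclusive;
   wintering region: class of the southernmost first-winter
   (1 Oct–28 Feb) latitude, with the Strait of Gibraltar fixed at
   36.0° N and the Africa split at 20° N. Latitudes below the nominal
   12° N band edge are classed Sub-Saharan with a logged warning.
4. **Fate** — dead if the accelerometer flat-lines for > 24 h (per-axis
   sample range ≤ 1 raw unit on all axes), if fixes stay within a
   100 m radius for more than three consecutive days (> 3, i.e. ≥ 4
   days; radius measured to the run's centroid, with a
   max-pairwise ≤ 200 m variant), or if the stream ends with the last
   fixes inside a buffered structure layer (a point-buffer stand-in for
   what was a manual map inspection; flagged approximate). The death
   day is the first stationary or motionless day, the earliest
   criterion winning. Streams that end early with no criterion met are
   *vanished*; streams reaching the study end are *alive*. Criteria are
   evaluated from the fledging date on — a nestling on its nest is
   stationary by the letter of the 100 m rule but not dead. An override
   table of field-confirmed deaths takes precedence where supplied.
5. **Stages** — postfledging [fledging, departure), migration
   [departure, 30 Sep], winter [1 Oct, 28 Feb next year; a leap 29 Feb
   excluded]. Each stage contributes one survival row per individual
   alive at entry: whole days to death (event) or censoring (vanished
   tag, or stage end), with first-day events given time 0.5 to avoid
   zero durations. Stage covariates are within-window medians of daily
   ODBA and log distance; covariate medians stop the day *before* a
   death, since the death day's (post-mortem) record reflects the
   outcome, not behaviour. Later stages carry the earlier stages'
   medians as carry-over covariates. Individuals without a detected
   departure stay censored in postfledging and never enter migration.

## Survival models

**Kaplan–Meier.** Product-limit estimate with Greenwood variance and a
95% interval on the log scale; median survival is the smallest event
time with S(t) ≤ 0.5. Verified against an exact rational-arithmetic
oracle in the tests.

**Cox proportional hazards.** Stratified partial likelihood (one
baseline hazard per tagging year, shared coefficients) with the Efron
tie correction (Breslow by flag), maximised by Newton–Raphson with
step-halving; convergence at ‖score‖∞ < 1e-8 or 50 iterations.
|β| > 15 is flagged as suspected monotone likelihood (separation).
Inference: likelihood-ratio test against the null within the same
strata, per-column Wald z, per-term Wald chi-square, and an
explained-variation index (1 − exp(−LR/n)) / (1 − exp(2·ll₀/n)) with
n the number of observations; the unscaled 1 − exp(−LR/n) variant is
also emitted since summaries differ on which they print.

**Restricted cubic splines.** Natural-spline truncated-power basis,
linear beyond the boundary knots; k knots give k − 1 columns. The
default four knots sit at the 0.05/0.35/0.65/0.95 quantiles, giving the
three degrees of freedom used for fledging and departure dates. (A
three-knot basis would have only 2 df, so "three degrees of freedom" is
read as four knots.) Fewer distinct values than knots degrade to linear
with a warning. Interactions are built as products of a linear term
with every spline column, both sides mean-centred at fit time; the
centring keeps the products interpretable as deviation effects and
nearly orthogonal to the main effects. The migration model's structure
(1 ODBA + 1 distance + 3 fledging-spline + 3 interaction columns) thus
books 8 df.

**Elastic net.** Penalised partial likelihood
−(1/n)·logPL + λ[α‖β‖₁ + (1−α)/2‖β‖₂²], minimised by the usual outer
quadratic approximation in the linear predictor (per-observation
gradient and diagonal curvature, Efron ties) and cyclic coordinate
descent with soft-thresholding, covariates standardised internally.
The path starts at the analytic λ_max and descends geometrically
(50 points to 0.01·λ_max). λ is chosen by k-fold (default 10)
cross-validated partial-likelihood deviance in the Verweij–Van
Houwelingen form (full-minus-training log likelihood), minimum rule;
fold assignment is seed-controlled and re-drawn if a training fold has
no events. α defaults to 0.5 and is prominently exposed — no canonical
value exists for this analysis. Selection respects term groups: any
nonzero spline column pulls the whole spline into the unpenalised
refit. The refit drops redundant predictors (any design-column pair
across two terms with |r| ≥ 0.9 drops the later term, keeping spline
groups intact).

**Diagnostics.** Proportional hazards are checked with the
Grambsch–Therneau test on scaled Schoenfeld residuals against
Kaplan–Meier-transformed time (identity and rank transforms by flag);
at tied event times each death receives the residual against the
Efron-averaged risk-set mean so residuals sum to the score. Vanished
birds are compared with alive and dead birds by Welch's
unequal-variance t (Satterthwaite df). Dependent censoring is bounded
by re-running KM and the Cox fits under vanished-as-censored /
vanished-as-dead / vanished-excluded scenarios (plus a
vanished-alive-to-window-end curve as the optimistic bound); the
bounding design stands in for a sensitivity procedure whose exact form
is not fixed by the stage definitions themselves.

## The synthetic cohort generator

`simulate_cohort` emulates the study design end to end: nestling phase
at the nest, post-fledging excursions 0.6–5 km out, a southward
migration leg (daily latitude steps lognormal with a 0.45° floor, so
the departure rule triggers on the true day) through a Gibraltar
waypoint to an individual stopping latitude drawn from the three-region
distribution (0.5526/0.2895/0.1579), then local wintering movements.
Mortality is a daily Bernoulli draw with probability
1 − exp(−λ_stage·exp(β·(x − centre))); the default stage hazards
(0.0043/0.0076/0.0019 per day) reproduce the juvenile survival profile
the three-stage analysis targets (≈ 0.87 to departure, ≈ 0.61 to 30
Sep, ≈ 0.46 to 28 Feb), and the default effects act through each
individual's activity level (ODBA, β = −0.7 per unit) and, in
migration, its realised log median daily distance (β = +0.3). Dead
birds keep transmitting for 14 days with fixes inside 30 m of the
death point and exactly constant ACC; vanished birds (daily rate
6e-4) stop without signature. Each individual runs on its own random
substream (CRC-32 of its id mixed with the global seed), so output is
byte-identical per (config, seed) and independent of generation order.

ACC raw units are arbitrary — tag calibration is not modelled — and
are scaled so one unit of computed daily ODBA equals one unit of the
hazard covariate; the per-individual activity range defaults to 2–4
ODBA units, which keeps live burst amplitudes safely above the 1-unit
flatline tolerance. Fledging dates are N(196, 8²) and departures
N(228.8, 11.1²) days of year, the departure spread matching the
tagging population's reported mean ± SD.

What the generator does **not** emulate: thermal-soaring flight
physics, weather, stopovers, habitat, social behaviour, GPS error
structure beyond uniform jitter, solar-driven duty-cycle variation, or
tag-calibration drift. Passing tests therefore demonstrate that the
pipeline's rules and estimators recover a truth *of the kind the rules
assume*; they do not validate the 500 m / 0.38° / 100 m thresholds
against real stork behaviour.

One known non-ideality is retained deliberately: stage covariates are
medians over the observed window, so a bird dying mid-travel has its
migration distance summarised from travel days only, while a survivor's
median includes post-arrival days. This endogenous truncation mirrors
the stage-median design itself; the parameter-recovery study therefore
targets the activity effect, whose daily values are stationary within
stages and unaffected by truncation.

## Problem sizes and tolerances

The test suite and `scripts/acceptance.py` use: 200 random datasets
(n ≤ 12) for the exact KM oracle; 100 micro-datasets (n ≤ 8, ties) for
the brute-maximised Efron oracle at 1e-3; 200 replicate cohorts of 500
birds for parameter recovery (mean within ±0.1 of β = −0.7, Wald
coverage in [0.90, 0.98]); 200 proportional-hazards simulations
(n = 100) for test calibration (rejection in [0.02, 0.08] at the 5%
level); and one 300-bird stream-level cohort for fate detection
(≥ 95% status recovery, death day within ±1 day for ≥ 90% of deaths).
Stream-level fixtures thin the GPS/ACC sampling density relative to
the tag defaults — detection rules depend on signatures spanning hours
to days, not on within-minute density — while hazards, effect sizes
and noise levels stay at the defaults throughout.

## Limitations

* The structure-proximity criterion is a point-buffer approximation of
  a manual map-inspection step and is flagged as such in its output.
* Competing risks, time-varying covariates, frailty and multi-state
  models are out of scope; vanished birds are handled by censoring
  plus the bounding sensitivity analysis, not by a formal dependent-
  censoring model.
* The explained-variation index for a Cox model is not unique; both
  emitted variants are LR-based and neither equals a true R².
* With daily-resolution event times the Efron correction handles the
  resulting ties, but very heavy tie structure (many deaths per
  stratum-day) pushes all partial-likelihood methods away from the
  continuous-time ideal.
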