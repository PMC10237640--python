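# Methods

This note documents the models, conventions and numerical choices behind
`nearshore-overlap`, and what the synthetic validation does and does not
establish about real survey data.

## Coordinate frame and geometry

All analysis runs in a per-beach tangent-plane metric frame: x alongshore
(metres from the beach start), y increasing seaward, the shoreline near
y = 0.  Geographic input is converted by equirectangular scaling about the
beach centroid; over a single beach (≤ a few km) the projection error is
millimetres, far below the survey's distance resolution.  Files record this
convention in their headers.

The wave break — where waves break, or the seaward edge of the whitewash —
is the zero reference for cross-shore position.  A break line is built from
points traced on sequential first-leg frames: points are kept in
along-track order, deduplicated within 1 m, and Douglas–Peucker simplified
at 2 m (≈ 85 px at the 60 m-altitude ground scale, below any reported
distance resolution).  Signed distance to the break is the Euclidean
nearest distance to the polyline, negative shoreward.  Because the polyline
is open, the side test needs an orientation: the line stores which side the
beach is on, and a query point's side is evaluated against the local
tangent at its nearest point (at a vertex, the interpolated chord — the
angle-bisector tie-break).  Surveyed area is the strip between the
shoreline and its seaward offset curve.

## Photogrammetry

The camera is modelled as exactly nadir-pointing with no lens distortion
(survey video is recorded orthogonally; at 60–120 m over water, terrain
and refraction corrections are not meaningful for ±1 m work).  Two
footprint conventions are implemented because they genuinely differ:

- `video_fov` (default): the vertical field of view spans the full sensor
  height, `ground_height = altitude · sensor_height / focal_length`, and
  width follows from the 16:9 video aspect.  With the default camera this
  gives 107 m × 60 m = 6,420 m² at 60 m (the area is the product of the
  dimensions rounded to whole metres, the convention used when survey
  areas are reported).
- `gsd_width`: both dimensions equal pixel counts times the width-basis
  ground sample distance `sensor_width · altitude / (focal_length ·
  image_width)`, the calibration used by cm/px calculators.  At 60 m this
  gives 90 m × 50.6 m.

The ~15% disagreement reflects video cropping of the sensor; both are
exposed rather than hiding one inside the other.

## The synthetic survey generator

The generator is the package's ground truth and emulates the statistical
structure the analysis assumes:

- **Coast**: straight shoreline with the break a strictly positive,
  sinusoidally meandering offset seaward (default mean 50 m, amplitude
  10 m, random per-beach phase); the two polylines cannot cross by
  construction.
- **Coast-wide clumping**: shark daily means are scaled by 0.02 away from
  the configured aggregation beaches (default 2 of 12), so sharks are
  effectively confined to aggregation sites, as observed at persistent
  nearshore aggregations.
- **Cross-shore placement** (signed metres relative to the break; only the
  ordering of groups and the shark law are empirically constrained, so all
  families are configurable): waders Uniform(−40, 0); bodyboarders
  Normal(−10, 15) truncated at 0; swimmers Normal(10, 25); surfers
  Normal(25, 30); SUP Normal(120, 60) truncated ≥ 0; sharks Lognormal with
  median 101 m and log-sd σ = 1.1, whose central 99.9% spans ≈ 2–700 m.
- **Alongshore placement**: humans are a Gaussian mixture centred on
  beach-access points (default two per beach, sd 80 m — most water users
  keep within ~200 m of public access); sharks cluster on one hotspot per
  aggregation beach (sd 150 m).  Setting the cluster scale to `None` gives
  uniform placement (verified by Kolmogorov–Smirnov).
- **Daily abundance**: per-group counts are Poisson with log-link mean
  `base_mean · exp(Σ f_k(covariate_k))`.  Default base means per beach-day
  — wader 6, surfer 5, bodyboarder 1.2, swimmer 0.8, SUP 0.3 — echo the
  observed dominance of waders and surfers and the rarity of SUP.  The
  shark default is 15 present per aggregation-beach day: persistent
  aggregations produce daily sighting counts from a handful in winter to
  many tens in summer, and the default sits in that regime.  Default
  covariate effects: warmer water raises human abundance, wind suppresses
  it, board-sport abundance peaks at ~1 m wave height; shark abundance
  peaks at low wave height and falls with negative SST anomalies.
- **Environment**: one row per beach-day with the 13 covariates plus tidal
  range and temporal terms — an annual SST cycle with daily anomalies,
  lognormal wave heights, a spring–neap tidal cycle, a synodic lunar
  cycle, wind capped at 8 m/s (drone operating limit), cloud-base height
  above the 620 m flight floor.
- **Flight**: first leg parallels the shoreline for 1 km at 90 m altitude
  (one frame then holds both shoreline and break), then a lawnmower
  pattern at 60 m steps seaward in 50 m legs to 500 m offshore; frame
  poses are spaced speed × interval (default 5.75 m/s × 5 s).  Footprints
  cover ≥ 99% of the strip.
- **Detection**: a subject is detected in every frame whose footprint
  contains it; sharks are additionally gated by surface availability,
  drawn independently per (shark, pass) with probability 0.7 — the
  simplest model consistent with sharks being surface-associated for up to
  ~70% of the day.  No autocorrelated dive model is attempted.  Humans
  carry a unique appearance key (size, clothing colour and the like make
  people recognisable within a survey); marked sharks carry their mark,
  unmarked sharks a per-pass track key, since an observer can follow an
  animal within a pass but not across passes.

All randomness derives from one root seed via named, crc32-keyed child
streams, so any beach-day regenerates identically in isolation.

What the generator does *not* emulate — and hence what passing tests do
not establish about field data: multi-day shark movement (site fidelity is
imposed, not emergent), within-day tides or a moving break line, imagery
and the computer-vision step (detection is geometric), observer error in
tracing or identification, and spatial autocorrelation of counts beyond
the beach factor.

## Conservative individual counting

A shark is only added to the daily individual count when the evidence
cannot be a repeat sighting: distinct marks prove distinct individuals, and
unmarked sharks co-visible in one frame are necessarily distinct.  The
count is `(# distinct marks) + max over frames (# unmarked sharks in the
frame)`; an unmarked shark seen repeatedly but never co-visible collapses
to one.  Both summands are bounded by the respective true subpopulations,
so the estimate never exceeds the truth (verified over randomized days);
it is also monotone when marks are added.  The mean estimate runs at about
half the true number under realistic availability — the price of never
over-counting.  No mark–recapture abundance model is attempted.

## Overlap statistics

Survey day × beach is the unit of co-occurrence: a day co-occurs when both
groups have positive counts.  Which days enter the denominator is an
explicit eligibility argument rather than a hidden rule.  Reported
percentages round half-up to the printed precision.  Relative abundance
sums counts over surveys, divides by surveys flown (empty-beach surveys
stay in the denominator), and normalises to shares.  Maximum density is
the largest daily individual count divided by the surveyed area in
hectares.

Cross-shore distributions are compared with rank tests (the distributions
are heavily skewed): tie-corrected Kruskal–Wallis with a χ² reference,
Dunn's pairwise z with tie-corrected pooled variance and Bonferroni
m = k(k−1)/2, and the two-sample Wilcoxon rank-sum with continuity-corrected
normal approximation.  For tiny samples (≤ 10 per group) the p-value is
computed by exhaustive enumeration of group assignments instead.  Group
letters come from an insert-and-absorb compact letter display at α = 0.05.

Space use is summarised by an axis-aligned product-Gaussian KDE on a
128 × 128 grid spanning the data bounding box padded by 3 bandwidths, with
per-axis normal-reference bandwidth `1.06 · min(sd, IQR/1.34) · n^(−1/5)`.
Highest-density-region levels are found by sorting grid cells by density
and accumulating mass; the 95% regions of two groups give the symmetric
overlap `area(A∩B)/area(A∪B)` and the shark-conditional overlap
`area(A∩B)/area(A)`.  On a standard bivariate normal the 95% HDR area is
within ~3% of the closed form `2π·ln 20` at n = 10⁴ (the KDE smooths
N(0,1) to N(0, 1+h²), inflating the area by ≈ (1+h²)).

## Environmental abundance models

Daily counts are modelled as `log E[count] = α + Σ f_j(x_j) + beach`, with
f_j penalized cubic B-splines (basis dimension 6, second-order difference
penalty, sum-to-zero constraint absorbed by null-space reparameterisation)
and beach an unpenalized factor standing in for the between-beach random
structure — the pragmatic fixed-effect reading of a "mixed" model when the
random effect is a dozen beaches.  Fitting is penalized IRLS to deviance
tolerance 10⁻⁸.  The family is Poisson; when the Poisson fit's Pearson
dispersion exceeds 2 the model refits as NB2 with a moment-estimated
dispersion.  Model complexity is EDF = tr(hat matrix), and model
comparison uses AIC = deviance + 2·EDF.

Selection follows the survey procedure: a combined forward/backward greedy
search (every single-term addition and deletion scored each iteration,
best move accepted if it improves AIC by > 2, deterministic given data
order; the family and NB dispersion are frozen from the full candidate
model so AIC stays comparable across moves).  Selected terms are ranked by
drop-one deviance importance; covariate pairs with |r| > 0.7 and
correlation-test p < 0.05 lose their lower-importance member, except that
month / SST / air temperature are never pruned against each other (they
are correlated through season but ecologically distinct) and the SST
anomaly is never dropped (local thermal anomalies carry signal beyond
season — anomalous cooling is associated with sharks leaving aggregation
sites).

Smoothing weights for reported fits are chosen per term by univariate grid
search over {0.1 … 10⁵} scored by BIC (deviance + log n · EDF); the
stepwise search itself uses a fixed weight of 1 for speed and determinism.
BIC rather than AIC because reported curves feed a shape classifier:
AIC-level undersmoothing leaves boundary wiggle that flips genuinely
monotone effects to "non-monotone" labels.  A smooth whose EDF falls to
≤ 1.2 is reported as linear.

Fitted partial effects are annotated with the field's shape labels:
"+"/"−" for monotone (largest drawdown/run-up of the curve ≤ 2% of its
range — a cumulative criterion, since per-step slopes of a genuine slow
trend can fall below any per-step tolerance), "p" for a single interior
peak whose limbs are monotone under the same tolerance, "q" otherwise, and
"0" for a curve flat relative to the response scale.  The labels are
invariant to affine rescaling of the covariate axis.  Mean-anchored curves
show the predicted mean count as one covariate varies with all others at
their means (factors at their mode).

## Validation studies and problem sizes

Three replicated studies close the loop against generator truth (the same
code backs `scripts/acceptance.py`):

- **Coast-wide recovery** — default campaign (12 beaches, 2 aggregations,
  60 days), survey-level observation path at the aggregation beaches with
  distances measured against the break polyline.  Per replicate the shark
  distance median must fall within 10% of the configured 101 m (the
  per-replicate median pools ~1,100 observations, SE ≈ 4–5 m) and the
  observed co-occurrence rate inside the exact-binomial 99% interval of
  the generating probability `mean_days[(1−exp(−0.7·λ_shark)) ·
  (1−exp(−λ_humans))]`; 100 replicates in the test suite, 50 in the
  acceptance script.
- **Selection recovery** — 3 active covariates (monotone SST, parabolic
  wave height peaking at 1 m, monotone-negative wind) among 10 candidates
  with independent covariate draws, n = 500 beach-days, 50 replicates:
  sensitivity, per-candidate false-inclusion rate (falsely selected inert
  terms over all inert candidacies), and shape-label accuracy on the
  active-term fits.
- **Conservative counting** — 200 randomized single-beach days (random
  mark fraction 0–0.8, availability 0.3–1, 1–12 sharks present) through
  the full per-frame rendering path; the individual count must never
  exceed the truth.

These sizes keep the whole suite under two minutes while leaving the
statistical margins wide (measured pass rates sit at or near 100%, not at
the thresholds).

## Known limitations

- The sign convention, break tracing and distance measurement assume one
  break line per survey; a break that moves within a survey is not
  modelled.
- Appearance keys are assumed unique within a survey for humans; two
  look-alike subjects seen only in disjoint frames would merge, which is
  conservative in the same direction as the shark rule.
- The beach factor is a fixed effect; with many beaches a true random
  effect would shrink estimates and change AIC bookkeeping.
- Importance ranking and pruning act on the final selected set only; terms
  discarded by the stepwise search are never revisited.
- Shapefile input is not supported; polylines are exchanged as GeoJSON.
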