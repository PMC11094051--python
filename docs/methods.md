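# Methods

## Detection process and offsets

The package decomposes imperfect detection at a point count into
*availability* and *perceptibility*.

**Availability.** A bird present at the survey gives detectable cues as a
Poisson process with rate `φ` (per minute), so the probability of being
available within a count of duration `T` minutes is `p = 1 − e^{−φT}`.
Removal data — the first one-minute interval of detection of each detected
individual during a 5-min count — identify `φ` through the conditional
multinomial with cell probabilities
`π_j = (e^{−φ t_{j−1}} − e^{−φ t_j}) / (1 − e^{−φ T})`.
`log φ` is linear in centred Julian day and minutes-since-dawn (optionally
with quadratics); the nine-model candidate set (all combinations of the two
variables with optional quadratic per included linear term, plus the null)
is ranked by AICc with `n` = number of individuals.

**Perceptibility.** An available bird at distance `r` is perceived with
half-normal probability `g(r) = e^{−r²/τ²}` (`τ` in metres). Distances are
recorded in 50-m bins up to 200 m with an unlimited last bin; conditional on
detection, the bin probabilities are
`π_k = e^{−r_{k−1}²/τ²} − e^{−r_k²/τ²}` (equivalently, the integral of
`2πr·g(r)` over the bin divided by `πτ²`). The half-normal is the only key
function implemented: it is the standard default for songbird point counts
and makes the effective detection radius closed-form. `log τ` is linear in
survey covariates, selected in two AICc stages: noise sources first
(distance to river and to highway, each linear, linear+quadratic, or
log-transformed, singly and in cross-combinations — 16 candidates; the
printed description of that candidate set is ambiguous about
cross-combining forms, and this enumeration is our interpretation, kept
configurable), then land cover added to the perpetuated winner (canopy,
high+medium-density urban, total urban, and canopy×urban combinations, all
as 75-m focal means).

**Effective detection radius and the offset.** With unlimited distances the
sampled area is unbounded, so density is referenced to the EDR `ρ`: the
radius at which birds missed inside equal birds detected outside,
`∫₀^ρ (1−g) 2πr dr = ∫_ρ^∞ g 2πr dr`. For half-normal `g`, `ρ = τ` exactly;
`edr_from_balance` solves the defining integral numerically as an
independent check. The per-survey correction is `C = A·p·q` with
`A = πρ²` converted to hectares and `q = 1` within the EDR by definition.
`log C` enters count models as an offset, inverting the identity
`E[Y] = D·A·p·q`.

Numerical choices: likelihoods are maximized by BFGS (gradient tolerance
1e-8) from a scale-aware start — zero coefficients, except the distance
intercept which starts at `log` of half the largest finite bin edge, since a
1-m start leaves the surface numerically flat — with three seeded jittered
restarts on failure. A weak ridge penalty (0.5 × Σ slope², intercept
excluded) stabilizes fits against quasi-separation when only a handful of
individuals inform a candidate (routine at calibration size 10); it is
negligible whenever slopes are genuinely estimable, and reported
log-likelihoods and AICc are unpenalized. Linear predictors are clipped at
±15 on the log scale. Candidates with `n ≤ k+1` are skipped (AICc
undefined).

## Zero-inflated density models

Stage 1 fits a probability-of-occurrence learner to detection/non-detection
labels over all landscape covariates at all five focal radii, evaluates AUC
on the independent test set, and thresholds predictions at the
training-sample prevalence (ties count as suitable) to produce a binary
suitability mask; suitable area = suitable cells × cell area. Stage 2 fits
a Poisson count learner with exposure `C` to counts from suitable cells
only, and predicts density over suitable cells; mean density is the mean
over suitable cells (the study area alternative is not used), and
population is the exact sum of density × cell area. Survey covariates are
taken from the containing cell. The count stage uses the 75-m focal means
only — a deliberately reduced variable set standing in for the pre-selected
influential variables a real multi-species study would carry over from
prior work, which has no desk-scale equivalent.

Two learner families honour the same exposure contract
(`E[count] = C × density`, so doubling all offsets halves fitted density):

* **fallback** (default, used throughout the tests): L2-penalized logistic
  regression on standardized features for occurrence; Poisson GLM with
  explicit `log C` offset for counts. Deterministic and fast; all-zero
  count data short-circuit to a zero surface rather than a divergent IRLS
  path.
* **boosted**: gradient-boosted trees with interaction depth 3, bag
  fraction 0.75, and a learning rate halved (up to 6 times, with a warning
  if unattainable) until the selected tree count falls in [1000, 5000] —
  selected by 10-fold cross-validated log-loss for the classifier, and by
  validation-based early stopping for the Poisson stage, which realizes the
  exposure contract through the rate-with-weights equivalence (fit `y/C`
  with Poisson deviance and sample weights `C`).

Tree-count ranges, folds and depths are configurable (`LearnerConfig`), so
the boosted path can be exercised quickly with small ranges.

## Frameworks

All frameworks share the pipeline; they differ in the offsets. The
benchmark uses structured data end to end (`T = 5` min). The fixed
framework applies `C = π·200²` m² (≈ 12.57 ha) with `p = q = 1` — on a
homogeneous fixture its population estimate should land near the analytic
ratio `(τ² p)/200²` of truth, the quantified version of its perfect-
detection bias. The independent framework fits detection models on the full
structured dataset; the calibration framework on a sample drawn by shuffling
the benchmark and accumulating surveys until `n_occ ∈ {10, 30, 100, 250}`
of them contain a detection (negatives drawn en route are kept; an
infeasible request reports the available count). Detection models are
always fitted after the iteration's suitability mask exists, restricted to
surveys in predicted-suitable habitat; an empty calibration intersection
falls back to the unrestricted calibration sample with a warning (the
degenerate case is otherwise undefined), and the independent framework
refits per iteration for symmetry. Community surveys never enter detection
models (they carry no removal/distance records); offsets are only *applied*
to them, at their own durations and covariates. With pooling, calibration
surveys join the occurrence and count training data with their own offsets.

A master seed spawns per-iteration child seeds (`numpy.random.SeedSequence`),
and within an iteration fixed-order substreams for the occurrence,
detection, count and calibration-sampling stages — so unpooled calibration
and independent runs share identical occurrence stages at a fixed seed.
Endpoint medians use the standard even-count midpoint rule; percent of
benchmark is `100 × estimate / benchmark median`, with a warning and NaN
when the benchmark median is zero.

## Synthetic data

The simulator generates what the estimators assume, plus the community-data
pathologies the filtering rules target:

* **Landscape**: a square grid (default 80×80 cells of 50 m) of Gaussian
  random fields (white noise smoothed at 300 m, standardized), with
  edge-truncated focal means at 75/165/315/615/1215 m. Two fields are
  transformed to positive river/highway distances (lognormal); coordinates
  are planar metres with half-open cells anchored at the origin — also the
  grid convention used for 200-m geographic sampling, whose true origin and
  boundary convention in the field are not standardized (our choice, not a
  claim).
* **Species truth**: logistic suitability in a 165-m covariate thresholded
  to a target suitable fraction; log-linear density within suitable habitat
  and zero outside; `φ` constant by default (log-linear machinery in day
  and time is exercised by dedicated simulations); `τ` weakly log-linear in
  75-m canopy.
* **Surveys**: birds are an inhomogeneous Poisson process (per-cell Poisson
  counts, uniform positions). Each count draws a first-availability time
  `Exponential(φ)` per bird and a single perceptibility Bernoulli with
  `g(r)` — the simplest mechanism consistent with a half-normal distance
  function, and the one the estimators are specified for. Structured counts
  emit removal intervals and distance bins; community checklists emit only
  a count, with Uniform(3, 30) min durations, protocol/location labels,
  hotspot clustering, incomplete checklists, pre-dawn start times, and
  observer profiles: a detection-scale multiplier `κ` on `τ`, binomial
  count thinning, and presence-only "X" substitution. `κ = 1`, thinning 1,
  X-probability 0 reproduces a structured observer exactly. The
  thinning/X/κ mechanism is a stand-in for observer heterogeneity, not a
  claim about how real community observers truncate or round counts.
  Dates are Julian day 120–190 and start times within seven hours of dawn.
* **Scenarios**: `common` (suitable fraction 0.5, ~1.1 birds/ha,
  prevalence ≈ 0.4), `uncommon` (0.35, 0.45/ha), `rare` (0.10, 0.5/ha,
  < 60 positive structured surveys, so large calibration sizes are
  infeasible), and `aurally_cryptic` (`common` with community `κ = 0.65`,
  i.e. counts biased low by ≈ κ² = 0.42 — the song-dominated-detection
  discrepancy). A separate homogeneous fixture (constant density, τ = 80 m,
  5-min availability 0.8, 5-min community checklists) isolates the
  fixed-radius bias ratio. Default sizes — 500 structured surveys and 1400
  raw community checklists on a 1600-ha landscape, 10 seeds or iterations
  per summary — were chosen so a full multi-framework experiment runs in
  minutes while keeping Monte-Carlo error well inside the tolerances the
  tests assert; survey points keep a 250-m margin from the landscape edge
  so detection neighbourhoods are not clipped.

What passing tests do *not* show about real data: the simulator draws
surveys independently of bird activity (no preferential survey initiation),
uses a single species with correctly specified half-normal/exponential
detection, and has no false positives, double counting, location error or
temporal population change. Recovery here validates the estimation
machinery, not the field realism of any particular dataset.

## Known limitations

* Half-normal perceptibility only; no hazard-rate or mixture availability.
* Detection neighbourhoods that straddle suitable-habitat boundaries
  violate the locally-homogeneous-density assumption slightly, biasing
  density a few percent low near patch edges (visible as benchmark recovery
  medians a little under 100%).
* Calibration at `n_occ = 10` is usable but long-tailed: single fits can be
  far off even though the median is accurate; precision improves sharply by
  `n_occ = 30`, and pooling is the default recommendation whenever a
  detection discrepancy is plausible.
* The occurrence stage uses plain (seeded, survey-level) cross-validation
  in the boosted path; no spatial blocking.
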