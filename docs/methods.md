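# Methods

This note documents the models behind `wearaq`, the parameter choices
that matter, what the synthetic campaign generator does and does not
emulate, and the numerical conventions the package pins down.  It states
no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Data model

All series are per-minute, timezone-aware UTC; missing values are NaN,
never sentinels.  Clock-local logic (the overnight home rule, simulated
night structure) converts through a per-participant timezone, default
Europe/Paris.  Raw samples are floored to the containing minute and
averaged within it; exact duplicate timestamps keep the last occurrence
(logged).  The fused table holds the eight classifier inputs
(temperature, humidity, PM₁, PM₂.₅, PM₁₀, NO₂, BC, GPS-derived speed)
plus position and an optional environment label; a row exists only when
at least one of the seven *measured* channels has a value — a GPS-only
minute makes no row, because position alone is not a measurement.

## Curation chain

Stages run in a frozen order per channel: NO₂ warm-up trim → range
filter → BC floor → peak rule → PM nesting → GPS speed filter →
per-minute speed → fusion.

* **Peak rule.** `s_i` is an artifact when
  `s_i > f · mean{s_j : |j−i| ≤ k, j ≠ i}` over the non-missing in-window
  neighbours; defaults k=2, f=2 (five-minute window, spikes more than
  twice the neighbourhood mean).  The rule is one-sided: negative
  excursions are the range filter's and BC floor's business.  A position
  needs at least max(k, 2) valid neighbours to be flaggable, so series
  boundaries and gappy windows cannot fire.  Flagged values are removed
  (set missing), never interpolated.
* **Order rationale.** The range filter and the BC floor run *before*
  the peak rule: a −2000 ng·m⁻³ BC excursion or a +3000 µg·m⁻³ glitch
  inside a window drags the neighbour mean toward zero or infinity and
  corrupts the ratio test.  Measured on the default synthetic campaign,
  floor-after-peak made the peak rule discard roughly a tenth of clean
  BC minutes; floor-first reduces that to about one in two thousand.
  The stage order is pinned and the removal report's per-rule counts must
  sum to the total (a property test enforces this).
* **Warm-up.** Electrochemical NO₂ cells read high after power-on; the
  first 3 minutes after every boundary (series start, or a gap longer
  than 10 minutes) are removed.  Inside `curate` the trimmed minutes stay
  in the index as missing placeholders, which makes the whole chain
  idempotent: a second pass sees the same boundaries and removes nothing.
* **BC floor.** −1500 ng·m⁻³, three times the instrument noise SD at
  background (its detection limit).  Small negative values are genuine
  measurement variability and are kept; the boundary is inclusive.
* **GPS.** A single forward pass drops any point implying more than
  130 km·h⁻¹ (haversine distance) from the last retained point — urban
  campaigns do not move faster; a zero-time-delta displaced point is
  dropped and logged.  Speed is the mean of segment speeds whose midpoint
  falls in the minute.
* **Default range limits** (config-exposed): NO₂ [0, 1000] µg·m⁻³, PM
  [0, 2000] µg·m⁻³, temperature [−30, 60] °C, humidity [0, 100] %RH.
  BC has no range limit; the floor handles it.

## Class balancing

Training windows are balanced to the median class count: majority classes
are uniformly undersampled, minority classes get SMOTE rows
x + λ(x_nn − x), λ ~ U(0, 1), x_nn among the k = 5 nearest minority
neighbours.  Balancing operates on window-feature rows (the learner's
input space), not raw minutes.  Feature rows may carry missing blocks
(a sensor view absent for a whole window): neighbours are searched on a
median-imputed copy while interpolation uses raw values, so missingness
propagates to synthetic rows instead of being invented.  Original rows
are never modified; provenance is tracked per row.  The augmenter is a
pluggable callable — SMOTE is the reference implementation; a generative
augmenter can be substituted without touching the pipeline contract.

## Environment classifier

Multi-view stacking.  Each channel is a view; for every minute, its
trailing W = 15-minute window yields eight features (mean, SD, min, max,
median, IQR, OLS slope, fraction missing).  One first-level learner per
view (random forest by default, gradient boosting selectable; 80 trees),
trained on the rows where that view is present.  The meta-learner
receives 8 × (predicted class index, probability of that class) = 16
numbers; absent views contribute a sentinel class index and a uniform
probability.  Meta-training uses out-of-fold first-level predictions
(stratified K = 5) to avoid resubstitution leakage; the paper-facing
evaluation splits by participant (grouped), never by random minutes, to
avoid temporal leakage.  Minutes where no view has data receive no label.

Chance-level control: with shuffled training labels, plain minute
accuracy of a truth-independent predictor equals Σ qₖpₖ (its marginals
times the truth marginals), which is not 1/K under heavy imbalance.  The
statistic whose expectation is exactly 1/K regardless of the predictor's
marginals is balanced accuracy (macro recall, E = Σ qₖ / K); the test
suite asserts it sits at 20 % ± 5 pp for five classes.

## Post-processing

Three rules correct minute-level classifier noise:

1. **Stop segmentation.** Positions are binned on a local equirectangular
   grid (100 m cells — adequate at mid-latitude city scale, projection
   error ≪ cell size).  Minutes in cells at or above the 0.9 density
   quantile with speed ≤ 5 km·h⁻¹ are stop candidates; runs of ≥ 5
   minutes become stop segments tiling the span with move segments.  The
   modal model label propagates within each stop.
2. **Home rule.** The cell(s) with maximal position counts between 2 and
   5 a.m. local over the participant's record define the home site; stop
   segments there are relabelled home.  Site matching tolerates one-cell
   adjacency (a dwelling jittering across a cell edge is one place).
   Known failure mode: a week spent in a hotel names the hotel "home" —
   the rule is density-based, not semantic.  The rule engine accepts
   plug-in rules; only the home rule ships.
3. **Smoothing.** Label runs shorter than 3 minutes are absorbed into the
   adjoining longer run, shortest run first, earlier run on ties;
   iterated to a fixed point (idempotent by construction).

## Exposure statistics

Percentiles use linear interpolation between order statistics throughout.
A participant-day enters daily statistics only when strictly more than
20 % of its 1440 minutes carry data.  Hour-level statistics are
two-stage: hourly means first (any hour with ≥ 1 observation), then
mean/SD/median over those hourly means.  Campaign-level summaries pool
participant-days and per-participant hourly means.  WHO 24-h guideline
levels: NO₂ 25, PM₂.₅ 15, PM₁₀ 45 µg·m⁻³; PM₁ and BC carry no 24-h
guideline and are reported as skipped, not compared.  A self-consistency
identity is enforced by test: the overall mean equals the
occupancy-weighted mean of per-environment means on the same labelled
minutes.

## Sensor qualification

Both series are block-averaged to a common step (1/5/15-minute reference
cadences supported) and paired where both are present; presence is
recorded-over-expected bins on the overlap.  Correlations of a constant
series are reported missing, not zero.  Match score and low-frequency
energy have several operational definitions in the evaluation literature;
this package pins: match score = fraction of pairs agreeing on exceeding
the reference p90 (config-exposed threshold), LFE = 1 − the error
periodogram's power fraction below 1/60 min⁻¹ (DC excluded — constant
bias is RMSE's business; zero error power scores 1).  For the IPI, RMSE
maps to 1/(1 + RMSE/IQR_ref), correlations to (r+1)/2, the bounded
metrics enter natively; the index is the equal-weight mean over defined
metrics (weights config-exposed).  Undefined metrics are excluded rather
than imputed.

## Synthetic campaign generator

The generator is first-class, tested code: it defines the study
conditions everything downstream is verified under.

* **Schedule.** Semi-Markov over the five environments; bout durations
  Gamma(shape 2) around per-environment means (home 300, office 240,
  indoor 45, outdoor 30, transport 25 min); the next environment is the
  one with the largest remaining time deficit, so realized occupancy
  converges to the request (default home 68 %, office 24 %, indoor 3 %,
  outdoor 1 %, transport 4 %).  The 00:00–06:00 local window is forced to
  home, giving the 2–5 a.m. home rule a truthful signal; occupancy
  recovery is exact only when the requested home fraction is at least the
  night-span fraction (0.25).
* **Emissions.** Concentrations are log-normal with AR(1) persistence
  (ρ = 0.85) around environment-conditional means anchored to the
  qualitative structure such campaigns report: NO₂ highest in transport
  (45 µg·m⁻³) and lowest at home (18), office 28; PM highest in other
  indoor spaces (cooking venues); BC lowest at home/office
  (≈800 ng·m⁻³).  Temperature and humidity are Gaussian per environment.
  Decaying pollution peaks (e-folding 8 min) are genuine exposure and
  stay out of the artifact ledger; PM peaks attach to PM₁ *before* the
  nested construction pm25 = pm1(1+u₁), pm10 = pm25(1+u₂), u ≥ 0, so
  clean data satisfy the nesting identically and only injected faults can
  break it.
* **GPS.** Stationary bouts jitter (SD 10 m) around fixed per-participant
  sites; transport follows a Brownian-bridge path between the adjacent
  stationary sites whose per-minute step length matches the target speed
  (22 km·h⁻¹; outdoor walks at 4); teleport outliers exercise the speed
  filter.
* **Faults** (all ledger-recorded, rates per minute unless noted):
  ×8 single-minute spikes (1/h per pollutant channel), out-of-range
  glitches (0.04), PM-order violations (0.10), below-floor BC dips
  (0.05), BC instrument noise (SD 150 ng·m⁻³), block dropouts (3/day,
  mean 25 min) and a +80 µg·m⁻³ NO₂ warm-up bias for 3 minutes after
  each power-on.  These defaults put the curation chain's removal
  fraction in the high single digits — the regime wearable campaigns
  report — and are not tuned per test.
* **Not emulated:** meteorology-driven dispersion, street-network
  routing, inter-unit sensor variability, humidity effects on optical PM
  (real campaigns leave them uncorrected too), underground PM density
  bias, sub-minute GPS cadence.  Passing tests therefore demonstrate the
  pipeline's correctness and its behaviour under these structured
  conditions, not field performance on any real cohort.

## Problem sizes and determinism

The end-to-end checks run on 10 participant-weeks (grouped 7-train /
3-test) for classifier skill, 6 × 3 days for the chance-level control,
3 × 7 days for artifact recall, and 5 × 7 days for byte-identical
reproducibility — sizes at which every statistic of interest is stable.
All randomness flows from one explicit seed through
`numpy.random.SeedSequence` spawning; learners run single-threaded with
fixed `random_state`, so identical seeds give bitwise-identical reports.

## Known limitations

* The classifier's accuracy on synthetic campaigns is an upper bound on
  real-cohort performance: the generator's environments are more
  separable than life.
* The home rule mislabels participants who sleep away; only one
  "a priori" rule ships, though the engine accepts more.
* Match score and LFE follow this package's operational definitions;
  swap in a toolbox's exact formulas via the config points if
  comparability with a specific evaluation suite is required.
* Balancing targets the median class count; extremely rare classes
  (under k+1 = 6 windows) cannot be SMOTE-expanded and raise or warn.
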