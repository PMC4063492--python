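# Methods

`bearfall` re-implements, as a tested pipeline driven entirely by a synthetic
data generator, the analysis of grizzly bear fall habitat selection and
movement under whitebark pine (WBP) decline: adaptive local convex hull
(a-LoCoH) fall home ranges, fix-success-weighted Manly–Chesson (MC)
selectivity for WBP and secure habitat, NDVI-impact-adjusted availability,
day-of-use timing, movement indices, and AICc-based trend-model selection.
This note documents the models, the generator, the numerical choices, and
what the tests do and do not establish.

## The selectivity model

For a two-habitat system the Manly–Chesson standardized index is

    MC = (U/A) / (U/A + (1−U)/(1−A)),

with `U` the proportion of an animal's locations in the habitat and `A` the
proportion of its seasonal range covered by it. The index lives in [0, 1];
0.5 means use proportional to availability. An equivalent form used
throughout the package is `MC = sigmoid(logit U − logit A)`, which makes two
properties immediate: strict monotonicity in `U`, and the relabeling symmetry
`MC(U, A) + MC(1−U, 1−A) = 1`. The index is undefined when `A` is 0 or 1
(zero availability of one habitat) and erratic when `U` and `A` are both
extreme, which motivates the sample filters below.

Impact-adjusted selectivity discounts availability for canopy decline:
`A′ = A × (1 − ΔNDVI)`, where ΔNDVI is the mean proportional NDVI decline
(relative to the first study year) over scored 250-m cells inside the range.
Since `A′ ≤ A`, the adjusted index is never below the raw one when any use
occurred.

## Fall home ranges (a-LoCoH)

Each location's local set is the point plus nearest neighbors added in order
of increasing distance while the cumulative sum of neighbor distances stays
within the adaptive parameter `a`; the 100% isopleth is the union of the
local convex hulls and covers every input point. The default
`a = 2 × max pairwise distance`; when the union contains interior rings
("orphaned holes") the multiplier is searched outward from 2.0 in 0.1 steps
within [1.0, 2.4] (2.0, 1.9, 2.1, 1.8, …) and the nearest succeeding value is
used. Ties in neighbor distance break by point index; duplicate coordinates
are collapsed before hull building; degenerate local sets (< 3 distinct
points) contribute a 1-m buffer of their segment. Area comparisons use a
relative tolerance of 1e-9.

Two practical findings from synthetic tracks are worth recording. First,
orphaned holes are not rare: a looping track whose local hulls are small
relative to the loop encloses holes at *every* multiplier in [1.0, 2.4]. The
library API treats this as an error (`select_a` reports all failed
multipliers); the pipeline falls back to the default-multiplier union with
holes retained and flagged in the diagnostics, keeping the bear in the sample
rather than discarding it. Second, hole frequency rises with fix density,
because dense revisited clusters shrink the cumulative-distance budget per
hull.

## Habitat layers

Secure habitat is the complement of a 500-m road buffer within the study
extent, with patches under 4.05 ha removed — the interagency definition used
for this population. All road classes are treated alike (the analysis only
needs the binary layer). Point-in-polygon uses `covers` semantics (boundary
points are inside, so fixes on digitized edges are never silently lost), and
all geometry is in a projected CRS in meters; geographic-looking coordinates
are rejected at ingest. The impact surface scores only 250-m cells of WBP
with ≥ 50% canopy; cell membership for polygon means uses cell centers,
matching the MODIS grid convention and keeping the brute-force oracle exact.

## Fix-success weighting

GPS fix failure is habitat-dependent (canopy attenuation), so discarding
failures biases `U` downward in closed-canopy WBP. Every scheduled attempt is
therefore kept: a failure bracketed by successes no more than `max_gap`
(default 24 h) apart receives a time-interpolated coordinate, habitat flags
at that coordinate, and weight = concordance × decay, where concordance is 1
when both bracketing fixes share the imputed point's habitat class on every
layer and 0.5 otherwise, and decay = 1 − gap/max_gap. Unbracketed failures
get weight 0. A bear's overall weight (mean attempt weight) enters the
selectivity regressions as a case weight. The 0.5 discordance factor makes a
fully ambiguous assignment count half; all three constants are exposed in the
run configuration.

Validation on synthetic tracks with ~20% habitat-dependent dropout at 32
fixes/day: certainty-weighted assignment accuracy is ≈ 0.92 (raw accuracy
≈ 0.90 — errors concentrate in the half-weighted discordant assignments,
which is exactly what the weights are for), and the weighted use proportion
is roughly three times less biased than the discard-failures estimate.
Weighted accuracy is the estimator-relevant measure because assignments enter
every downstream statistic multiplied by their certainty weight.

## Sample filters

Bears are retained when monitored (≥ 1 successful fix) on at least 95% of the
47-day season (15 Aug – 30 Sep, inclusive). The WBP analyses exclude bears
with `A_WBP < 0.05`; the secure analysis excludes bears with
`A_secure > 0.95` or whose range lies entirely inside national parks.
Boundary values are eligible. A day counts as a WBP-use day when the weighted
proportion of its positive-weight attempts in WBP is at least 0.14 (1 of 7
locations for the sparsest schedule); daily proportions use certainty
weights, consistent with the use proportions.

## Trend models

Each response gets the same three-model candidate set — Base
(CONES + SEX + CONES×SEX), Base + YEAR, Base + YEAR + YEAR×CONES — ranked by
AICc with Akaike weights `exp(−Δ/2)/Σ exp(−Δ/2)`:

* **MC indices** (per-bear): weighted least squares with the overall
  fix-success weights; K = coefficients + residual variance.
* **Day-of-year of WBP use** (per-bear-day): quantile regression at
  τ ∈ {0.1, 0.5, 0.9}. The AICc likelihood uses the asymmetric-Laplace
  construction with its scale at the MLE (`σ̂ = Σρ_τ/n`); K = coefficients +
  scale. Standard errors come from a seeded xy-pair bootstrap (default 500
  resamples; the pipeline uses 100). A constant response returns the
  degenerate intercept-only solution (the constant minimizes the check loss
  at every τ).
* **Log movement indices** (per-bear-day): linear mixed model with a random
  intercept per bear-year, fit by maximum likelihood (not REML) so AICc is
  comparable across fixed-effect sets; K includes the random-intercept and
  residual variances. Zero net displacements are floored at 0.001 km before
  the log. The need for the random intercept can be tested with a boundary
  likelihood-ratio test against the 50:50 χ²₀/χ²₁ mixture null.

Cone years are rated good/poor against the overall median of the annual
median cone counts, taken as the *lower* median (the ⌈n/2⌉-th order
statistic) with counts equal to the median rating good; this convention is
forced by the published annual ratings, which rate the at-median years good
(an interpolated median of the printed series would be 10.25 and would
misclassify them).

Contrasts are `cᵀβ` with Wald 95% intervals (`± 1.96 · se`); sexes are
averaged by setting the male dummy to 0.5. Designs made rank-deficient by
degenerate inputs (e.g., two study years making YEAR collinear with CONES)
are rejected with the aliased columns named; the pipeline skips such a
candidate set and logs it. No multiple-testing correction is applied — the
framework is model selection, not null-hypothesis testing.

## The synthetic generator

The generator defines the study conditions; its defaults are fixed and the
tests are run against them.

**Landscape.** Round WBP patches (radius ≈ 4% of the extent scale) accumulate
until the target area fraction (default 0.25–0.3) is reached within ±0.05;
roads are jittered transects; one rectangular park occupies the northwest
corner. **Impact.** Each scored cell accumulates `severity × (year −
baseline)` of NDVI decline (default 0.01/yr, giving range means within the
0–0.11 band typical of the study period) with a fixed per-cell
susceptibility in U(0.4, 1.0). **Cones.** A two-state masting chain (switch
probability 0.8) draws 8–22 cones/tree in good regimes, 0–2 in poor ones.

**Movement.** A Metropolis random walk on the 250-m grid inside a square
window (default half-width 8 km) around a random home center, 48 substeps per
day with proposals within ±1 cell (≤ 0.25 km per half-hour move). Habitat
preference is a log-odds term in the acceptance ratio, so the stationary
distribution over the window is ∝ exp(s·wbp); the initial cell is drawn from
the stationary distribution, so occupancy is exactly stationary from the
first step. Because `MC = sigmoid(logit U − logit A)` and the stationary use
is `U* = sigmoid(logit A + s)`, the walk's target MC index is `sigmoid(s)`
regardless of local availability — cohorts are programmed by inverting this
(default: a linear MC decline from 0.69 to 0.48 across twelve study years,
optionally modulated by cone counts for males). The step scale was calibrated
to the reported movement regime: it yields median daily net displacements of
≈ 1.2 km (reported median 1.4 km) inside the reported 0–25.9 km envelope;
larger steps produce teleporting tracks for which interpolation-based
imputation is meaningless. Fix schedules mix 7–48 attempts/day; fix success
improves with year (base 0.90 + 0.007/yr, capped at 0.98) with an 8% penalty
in WBP by default.

The generator exposes two levels of ground truth: per-attempt true
coordinates and polygon-classified habitat (for validating imputation), and
raster-level use/availability proportions over the window (for validating
the selectivity machinery, since the walk's stationary guarantee lives on the
grid).

**What the generator does not emulate:** topography and elevation,
behavioral states (denning, predation), attraction to point resources
(squirrel middens), serial correlation in fix failure, and map error in the
habitat layers. Passing tests therefore show that the estimators recover
what this data-generating process encodes, not that the original field
estimates are correct.

## Problem sizes used in the test suite

The parameter-recovery study uses 100 replicates of a 60-bear × 12-year
cohort (5 bears/year, mixed fix schedules) on a fixed 20-km landscape,
computing per-bear MC from the simulator's raster truth and ranking the
candidate WLS models per replicate (the full geometry route — a-LoCoH →
availability → MC — runs end-to-end in the pipeline test instead of inside
the replicate loop). The fix-weighting validation uses 50 bears at 32
fixes/day. The whole suite runs in under two minutes on one CPU.

## Known limitations

* The fix-weighting scheme is this package's concrete re-specification of a
  method whose original supplement is not reproduced here; equivalence with
  the original cannot be asserted, only the emulated intent (interpolate,
  check concordance, decay with gap length).
* The asymmetric-Laplace likelihood for quantile-model AICc is one defensible
  choice among several; only within-set comparisons are meaningful.
* Whether secure habitat should also buffer developments (not just roads) is
  unresolved; only road polylines are buffered.
* The GLS/AR1 temporal-lag robustness check and real-data ingestion are out
  of scope.
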