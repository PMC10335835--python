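# Methods

## The assay and its statistical model

A behavioral arena is a filter-paper corral (default radius 3.0 mm) on agar
with a small bacterial lawn (default radius 1.5 mm) at its center. Prey
animals (*C. elegans*) lay eggs over the course of the assay; each egg is
recorded as pixel coordinates, converted to a distance from the lawn center
(mm) and a signed distance from the lawn edge, and classified off-lawn iff
it lies strictly outside the closed lawn disk (the boundary itself counts
as on-lawn — the event has measure zero for real coordinates, so the
convention is inconsequential but fixed).

Egg counts per arena are treated as binomial: the number of eggs off the
lawn out of the arena total, with off-lawn probability P(off) modeled on
the logit scale

    logit P(off) = log[ P(off) / (1 − P(off)) ] = x'β,

where x encodes experimental factors with treatment (reference-cell)
coding — the reference level is declared in the model spec (the control:
mock condition, wild-type genotype), never inferred alphabetically — plus
continuous covariates such as assay time in hours, and interaction columns
as elementwise products up to the declared order. Eggs within an arena are
treated as independent Bernoulli trials pooled into the binomial count; no
overdispersion adjustment is applied. This models the assay as designed —
a per-arena random effect would be the natural extension but is out of
scope.

### Fitting

Maximum likelihood by IRLS: weighted least squares on the working response,
iterated to relative deviance change < 1e-8 (max 100 iterations), with
step-halving whenever a step increases the deviance. The start is the
empirical logit of (y + 0.5)/(n + 1). The coefficient covariance is the
inverse expected information at the optimum. Complete or quasi-separation
is reported (never silently truncated) whenever a coefficient passes ±15 on
the logit scale; such a fit is flagged non-converged. The gaussian path
(egg counts, log₂ fluorescence) solves least squares directly, with
dispersion = RSS/df.

### Analysis of deviance

Term tests are likelihood-ratio χ² (binomial) or F (gaussian), Type II:
the test of term T compares the model containing every term that does not
contain T, with and without T, respecting marginality. Degrees of freedom
equal the coefficients removed. This matches the default behavior of the
standard analysis-of-deviance tooling this workflow descends from; Type III
tests are deliberately not offered.

### Predictions

Expected P(off) = logistic(x'β̂) with 95% CI computed on the logit scale as
η ± 1.959964·SE(η), SE from x'Σ̂x, then back-transformed — hence CIs are
asymmetric about the point estimate and always inside (0, 1).

## Simultaneous inference and the predator response

Post hoc comparisons are linear combinations Kβ̂: pairwise condition
differences on the logit scale, and differences of differences (e.g. the
predator response of a mutant minus that of wild type, which in a 2×2
factorial is exactly the interaction coefficient). The predator response
itself is

    log(odds off-lawn | predator) − log(odds off-lawn | mock)

at fixed settings of the other factors, divided by ln 2 for reporting
(one log₂ unit = twofold odds change). All inference happens on natural-log
odds; the log₂ rescaling happens only at presentation, so p-values and
coverage are unaffected.

Family-wise correction is the single-step max-|Z| method: with R the
correlation matrix of the contrast statistics (from KΣ̂K'), the adjusted p
for contrast i is 1 − P(max_j |Z_j| ≤ |z_i|) under the central multivariate
normal with correlation R; simultaneous CIs use the critical value c
solving P(max_j |Z_j| ≤ c) = 1 − α, found by bisection to 1e-4 between the
univariate and Bonferroni quantiles (so c ≥ z_{1−α/2}, with equality at
k = 1, and never exceeds the Bonferroni value). Binomial models use the
normal (Z) reference; gaussian models use the multivariate t with residual
df. Rectangle probabilities are evaluated by scipy's quasi-Monte Carlo
multivariate normal/t integration with absolute tolerance 1e-5 and a seeded
generator, so results are reproducible and stable well inside the 1e-4
tolerance quoted for adjusted p-values. A degenerate contrast covariance
(duplicated or linearly dependent rows) is collapsed onto a maximal
non-degenerate subset of rows for the max distribution — the max over
perfectly correlated statistics equals the max over the representatives —
with a warning.

Contrast families are user-declared: whatever comparisons are passed
together are corrected jointly, and a contrast tested alone reduces exactly
to the unadjusted two-sided test.

## Bootstrap trajectory bands

Tracking data are per-arena mean distances from the arena center, 15
frames/hour for 20 h (300 time points). The resampling unit is the whole
arena trace — the biological replicate — never individual frames or worms,
which would fabricate independence within an arena. Each bootstrap
iteration draws N arenas with replacement and records the pointwise mean
(ignoring missing frames); the band is the pointwise empirical 2.5% and
97.5% quantile over iterations (default 10⁵; tests use 10⁴). Two
conditions are declared different (p < 0.05) at time points where the
closed bands fail to overlap; touching envelopes count as overlapping.
The disjoint fraction is reported both over time points where both bands
are defined and over the full grid. Fold-change bands resample both
conditions independently and take pointwise ratios, suppressing time
points whose denominator mean is numerically zero.

Pointwise percentile bands of this kind undercover somewhat at small
replicate counts (empirically ≈91% at 12 arenas, ≈95% by 100 arenas, white
noise); this is a known property of the percentile bootstrap, inherited by
design rather than corrected, since the non-overlap criterion is defined on
exactly these bands.

## The synthetic-data generator

`simdata` emulates the statistical structure the inference consumes, not
the biology generating it (no encounter or biting mechanics, no worm
identity):

- egg count per arena ~ Poisson(rate), default rate 90 (arenas average
  ~90 eggs);
- each egg is off-lawn with the condition's ground-truth probability;
  defaults are a two-condition design, mock P(off) = 0.10 vs predator 0.70,
  12 arenas per condition — the canonical strong-predator configuration —
  with the option of a logit-linear time course P(off)(t) =
  logistic(a + b·t) mirroring the continuous-time models;
- on-lawn eggs are uniform on the lawn disk and off-lawn eggs uniform on
  the lawn–corral annulus (radius density ∝ r). Real off-lawn eggs cluster
  along bacterial streaks; that spatial texture is not modeled, so passing
  tests validate counts, distances and on/off structure, not fine-grained
  spatial pattern;
- trajectories: control arenas hold a baseline mean distance (default
  0.5 mm, inside the lawn); predator-exposed arenas ramp logistically from
  baseline to a shifted distance just outside the lawn edge (default
  1.75 mm vs the 1.5 mm lawn radius). The ramp begins at the changepoint
  (default 5.5 h): it is centered half a ramp width later and its 10–90%
  rise spans one ramp width (default 1 h). I.i.d. gaussian noise (default
  SD 0.2 mm) is added per frame; negative distances are truncated at zero
  and counted. Worm counts per arena are drawn uniformly from 2–6 for
  schema fidelity; they do not affect the trace generation.

Everything is reproducible from the config seed, and `truth.json` in a
fixture bundle records the generating parameters next to the emitted data.

Under these defaults the mock and predator bands separate shortly after the
changepoint and stay separated, so the disjoint region covers ≈71–73% of
the 300 time points — the band pipeline's expected output for a sustained
post-onset shift of this size.

## Numerical and design choices

- 95% CIs use the normal quantile 1.959964 throughout.
- Distances are computed on continuous (sub-pixel) coordinates; no
  rounding. Distance computation commutes with unit conversion to 1e-9
  relative tolerance.
- Zero-egg arenas are dropped with a logged reason (a 0-trial binomial row
  is uninformative); arenas with ≥2 escaped worms, or a predator observed
  in a control arena, are discarded by the QC rules with a per-arena log.
- File I/O is plain CSV (UTF-8, header row) with a configurable
  canonical-name → file-name column mapping; distance columns present in a
  file are verified against the coordinates to 1e-6 mm and recomputed on
  disagreement, with a warning naming the rows.
- The spread test is the Brown–Forsythe variant of Levene's test (absolute
  deviations from group medians), the robust default.
- Fisher's exact p uses the probability-ordering two-sided rule; the test
  suite checks it against full hypergeometric enumeration.
- Coefficient of variation uses the sample (n−1) standard deviation.
- Dispersion and off-lawn summaries are exposed both per arena and pooled
  per time point, since either grouping can be of interest for filled
  arenas.

## Problem sizes used by the validation suite

The packaged checks run on synthetic data sized for tight sampling error
while staying quick: 400 arenas/condition for pooled-probability
reproduction (binomial SE ≈ 0.002), 1000 simulated assays at the default
12 arenas × ~90 eggs for recovery bias and CI coverage, 10⁵ bootstrap
iterations for the tracking-band comparison at the study's 12+12 arenas,
and 50 random small designs for the IRLS-vs-direct-maximization check.

## Known limitations

- No mixed-effects (random arena) models, no overdispersion correction, no
  Bayesian fitting, no model selection.
- Single-step correction only; no step-down/step-up procedures.
- The simulator's spatial placement is uniform; streak-clustered off-lawn
  placement would be a natural extension.
- Percentile bootstrap bands undercover at small arena counts (see above).
- Lawn centers are taken from the recorded circle annotations; lawn
  boundaries are not re-fit from images (image segmentation is out of
  scope; inputs are coordinate tables).
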