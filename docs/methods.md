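# Methods

`lifesignal` implements a longitudinal biomarker-of-aging analysis: given
per-animal expression trajectories of fluorescent reporters in an isogenic
cohort followed from hatch to death, it quantifies how much of the
inter-individual variation in lifespan is statistically explained by each
reporter's expression level and trend during a time window, and how
redundant that information is between reporters. A synthetic cohort
generator with analytically known ground truth validates every stage.

## The regression model

For a closed window `[t0, t1]` (hours post-hatch, both endpoints
inclusive), each animal *i* alive beyond `t1` contributes two features of
its expression series `x_i(t)`:

- `m_i` — the arithmetic mean of the in-window observations;
- `b_i` — the ordinary-least-squares slope of `x_i` on age over those
  observations (units: expression per hour).

Lifespan `T_i` is regressed on each feature singly and on both jointly by
OLS; the coefficient of determination `R² = 1 − SSR/SST` is the headline
statistic. The joint `R²` is the fraction of lifespan variance linearly
explained by (level, trend) of that reporter over that window.

**Censoring.** Animals dying *at or before* `t1` are removed from that
window's regression ("died before or within the window"). This avoids
truncation artifacts — short-lived animals necessarily contribute fewer
observations — at the cost of conditioning the analyzed population on
survival, which itself removes part of the lifespan variance. The
censored count is carried on every result. Surviving animals with fewer
than `min_obs` (default 3) in-window observations are censored too; a
surviving animal with *zero* in-window observations indicates a window
outside the sampled age range and is an error, not a censoring event.

**Window search.** Because reporters differ in temporal dynamics, the
informative window is found by exhaustive search: both endpoints move on a
12-hour lattice anchored at 72 h (3 days post-hatch), bounded above by the
cohort's 90%-survival timepoint, minimum width 12 h. The window
maximizing the joint `R²` is reported; exact ties resolve to the earliest
start, then the smallest width, making the search deterministic.
Maximizing over ~40–100 windows inflates `R²` under the null relative to
a single pre-specified window; the package documents and tests this
(pure-noise search maxima are compared against a lifespan-permutation
max-null distribution), and the fixed-window analysis is provided as the
unoptimized companion.

**Survival quantile convention.** `S(t)` is the fraction of included
animals with lifespan strictly greater than `t`; the q-survival timepoint
is the age of the death event that first brings `S` to `q` or below. All
deaths are observed in this culture design, so no Kaplan–Meier censoring
machinery is needed.

## Normalization

Replicates differ in absolute fluorescence and somewhat in lifespan.
Before pooling, the selected reporter/statistic values are z-scored within
each biological replicate — pooling all (animal × timepoint) values of the
replicate, population (1/n) SD convention — and every age is multiplied by
`pooled median lifespan / replicate median lifespan`, so replicate medians
align. Both transforms record parameters sufficient for exact inversion.
A per-timepoint z-transform variant is available behind a switch
(`per_timepoint=True`); the pooled form is the default reading of
standardizing "relative to each biological replicate". Note that the
per-timepoint variant does not round-trip through `invert()` after time
rescaling (parameters are keyed by original ages); the default pooled form
inverts exactly.

## Bootstrap inference

Confidence intervals for `R²` (and for semipartial increments) are
percentile bootstrap intervals: the analysis population is resampled with
replacement at the level of whole animals, the statistic recomputed per
resample, and the 2.5th/97.5th percentiles of the 1000 (default) resampled
values taken as the 95% interval — order statistics, no smoothing or bias
correction. The animal is the exchangeable unit because the statistic is
cross-sectional over animals; resampling timepoints would destroy the
longitudinal structure. On simulated cohorts with known population `R²`
(cohort size 400, 500 resamples, 1000 replicate studies) the measured
coverage of the nominal 95% interval is ≈94%, with estimator bias below
0.01 — percentile intervals for `R²` undercover slightly because the
estimator is positively biased and right-skewed.

## Power

The design question "how many animals detect a biomarker with true
`R² = 0.15`?" is answered under the convention of a single correlation of
magnitude `r = √R²` tested two-sided at level α via the Fisher
z-transform: `power = Φ(√(n−3)·atanh(r) − z_{1−α/2}) + Φ(−…)`. At
`n = 80`, `R² = 0.15`, `α = 0.05` this gives 94.8% — the source of the
"95% power at n = 80" design rule. The noncentral-F convention for the
two-predictor joint test is implemented as an alternative (≈92% at the
same point, slightly conservative), as is a direct Monte-Carlo rejection
rate; the Fisher-z reading is the default because it reproduces the
design point.

## Redundancy and informational hierarchy

When two reporters are measured in the same animals, each contributes a
2-predictor block (windowed mean, slope) over a common window with joint
censoring. The semipartial (part) `R²` of reporter A given B is the
increment from adding A's block to a model already containing B's block —
the lifespan variance uniquely attributable to A. It is computed two ways
(hierarchical increment and residualized-block regression) that agree to
1e-10 by OLS algebra; the identity is asserted in tests. The additivity
gap `R²_A + R²_B − R²_AB` is ≈0 for independent information channels,
≈`min(R²_A, R²_B)` under full redundancy, and can be negative under
suppression.

Because an in-sample `R²` increment is never negative, raw semipartials
cannot be tested against zero by their own bootstrap percentiles. For
hierarchy inference the increments are therefore computed on the
Ezekiel-adjusted scale, `R²_adj = 1 − (1−R²)(n−1)/(n−k−1)`, whose
increment is centered near zero when the added block is uninformative.
The edge "A ≥ B" (A carries strictly more lifespan information) is
asserted when the bootstrap interval of B's adjusted increment given A
reaches zero while A's given B stays strictly positive. Edges generate a
partial order (closed under transitivity); cyclic evidence is reported as
inconsistent rather than resolved.

## The synthetic cohort generator

The generator emulates the structure of single-animal culture data:
samples every 4 h from hatch to death, several biological replicates with
additive expression offsets and ±5%-scale lifespan factors, lifespan CV
defaulting to 0.21 (isogenic *C. elegans* cohorts are reported at
0.19–0.23), median lifespan 240 h.

Each animal carries latent standard-normal state variables, one per
lifespan-determining process. Lifespan is a baseline law — log-normal
(default) or Gompertz, parameterized by (median, CV) — times
`exp(Σ_p c_p z_p)`; the baseline CV is shrunk so the total CV matches the
configured value. Expression is a deterministic age template (declining,
peaked, increasing, or constant) plus a latent-coupled level-and-trend
deviation that ramps in linearly over 24 h starting at 120 h (≈5 days
post-hatch) — reproducing the observation that expression variability
exists early but predicts lifespan only from mid-adulthood — plus i.i.d.
Gaussian measurement noise. Optional terms: a coupling *offset* age (for
planting a bounded informative window) and a moribundity signal rising in
the final 48 h of life (for cohorts whose predictivity is pure
imminent-death anticipation, which exclusion buffers should abolish).

The joint distribution of lifespan and expression level/slope across
individuals is not characterized by longitudinal culture data itself; the
linear-Gaussian latent formulation is an explicit modeling assumption, and
recovery results should be read as validating the estimator under that
assumption, not as a statement about real cohorts. Real data features the
generator does not emulate: autofluorescence spectral bleed-through,
nonstationary measurement noise, device-position effects beyond a scalar
batch offset, and non-Gaussian lifespan outliers (e.g. matricide).

**Closed-form ground truth.** Under this model the windowed features are
linear-Gaussian in the latent state and lifespan is log-linear in it, so
the population `R²` of any feature set has a closed form. Crucially the
form is computed *conditional on surviving the window*: with
`S = log(T/median) ~ N(0, v)`, conditioning on `S > s0` keeps `(z, S)`
jointly tractable (`z = (c/v)S + u`, `u ⊥ S`), and all required moments of
the truncated log-normal are expressible via the normal pdf/sf. This
matters: for the default scenario the uncensored population `R²` of 0.35
drops to 0.24 conditional on surviving a 144–204 h window. The
censoring-aware value is what the regression engine estimates, verified
against an independent Monte-Carlo of the latent model. `calibrate_coupling`
inverts the closed form to plant an exact target `R²`. (Censoring-aware
form: log-normal family, single replicate, window inside the saturated
coupling regime.)

The planted-hierarchy scenario gives three reporters nested process sets
(A reads X, Y, Z; B reads X, Y; C reads X) with lifespan loading equally
on all three processes, so B's extra information beyond A is exactly zero
at the population level whenever A's features read its processes with
little noise. Coupling strength 0.085 per process puts the trio's
single-reporter `R²` near 0.36/0.22/0.10, within the range observed for
strongly predictive reporters.

## Numerical and design choices

- OLS `R²` is computed by centered least squares (`numpy.linalg.lstsq`),
  the standard formula; cross-checked against `statsmodels` OLS in tests.
- Percentiles (image statistics and bootstrap endpoints) use linear
  interpolation between order statistics.
- `mean_over_p99` averages pixels *strictly above* the region's 99th
  percentile, falling back to the maximum when no pixel exceeds it.
- Circle regions include pixel centers at Euclidean distance ≤ radius,
  clipped at image borders.
- Lifespan quantile bins are rank-based with stable animal-id tie-breaks;
  sizes differ by at most one.
- LOWESS (visualization only): tricube weights, fraction 0.3, one
  robustness iteration, evaluated on a regular age grid.
- Whole-trajectory peak statistics carry a survivorship artifact (more
  observations → stochastically higher, later maxima); an optional common
  age bound removes it.
- Degenerate inputs (zero lifespan or predictor variance, empty regions,
  zero-variance replicates) raise typed errors; windows that cannot seat a
  regression are skipped in searches and omitted (logged) in timecourses.

## Problem sizes used in validation

Simulation-backed checks run at the scale the analysis is designed for:
recovery/coverage at cohort size 400 with 400 replicate studies and 500
bootstrap resamples per study; hierarchy recovery at cohort size 400 over
100 replicate studies with 300 resamples; search/brute-force equivalence
on 50 random cohorts of 60–200 animals; power Monte-Carlo at 50 000
simulated samples. The acceptance script (`scripts/acceptance.py`) re-runs
the same studies at 200 replicate studies for the recovery block.

## Known limitations

- No regularized or nonlinear regression, no multiple-testing correction
  across reporters, and no cross-validated window selection; the search
  maximum is reported raw with its bootstrap CI, as is conventional for
  this analysis, with the overfitting behaviour documented and tested.
- The censoring-aware closed form covers the log-normal lifespan family;
  Gompertz cohorts are validated only where censoring is negligible.
- Batch effects confound the closed form; analytic ground truth is used
  with single-replicate cohorts (the normalization module is exercised on
  multi-replicate cohorts separately).
- The informational hierarchy is an observational partial order; it cannot
  distinguish a signaling chain from integration of multiple processes.
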