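# Methods

This note records the statistical conventions, numerical choices and
design decisions behind `hedgelife`, and what the synthetic-data tests do
and do not establish.

## Cohort life tables

The input is a frequency table of integer ages-at-death within a stratum.
Treating those deaths as a synthetic cohort assumes the age distribution
is stationary over the collection period — an assumption inherited from
the sampling design, not checked by the package.

Construction, for ages `x = 0 … max_age` plus a terminal row at
`max_age + 1`:

- `lx` is the reverse cumulative sum of deaths (`l0` = cohort size;
  terminal `lx = 0`); ages with zero deaths still get rows, since
  survivors pass through them.
- `nqx = ndx/lx`, `npx = 1 − nqx`, `nLx = lx − nax·ndx`,
  `Tx(x) = Tx(x+1) + nLx(x)` with terminal `Tx = 0`, `ex = Tx/lx`,
  `nmx = ndx/nLx`.
- `nax = 0.5` in **every** interval, including the last: deaths are
  assumed uniform within the year.  A consequence worth knowing: an
  interval in which all `l` entrants die has `nLx = 0.5·l` and therefore
  `nmx = 2.0` deaths per person-year — that value is a convention, not a
  biological rate.
- Ratio columns of the terminal row (`nqx`, `npx`, `nLx`, `ex`, `nmx`) are
  NaN internally and rendered as `-`.

All identities (`Σndx = l0`, `Tx` telescoping,
`nmx = nqx/(1 − 0.5·nqx)`, monotone `lx`) are enforced by property tests
on random count tables.  Internal values are full precision; the
conventional rounding (3 d.p. for probabilities/rates/`ex`, 1 d.p. for
person-years) is applied only when rendering.  Half-way decimal cases are
rounded against the true binary value (Python's built-in `round`), which
matches how the reference tables were printed.

Interval length is fixed at one year; abridged tables, smoothing and
parametric (e.g. Gompertz) hazard fits are out of scope.

## Survivorship-type classification

Field practice classifies survivorship curves (Type I/II/III) by eye.  To
make the call reproducible the package tests the *trend of the hazard with
age*: interval deaths are modelled as Poisson with log person-years as an
offset and age as the covariate, so the slope is the log-linear trend in
`nmx`.  Slope significantly positive at the two-sided 5% level → Type I;
significantly negative → Type III; otherwise Type II.  Wald inference uses
the normal reference (plain Poisson, dispersion fixed at 1), appropriate
for count aggregates of this size.

Terminal intervals in which every entrant dies are excluded: their rate is
pinned at 2.0 by the `nax` convention and carries no trend information.
At least three usable intervals are required.

A weighted least-squares regression of raw `nmx` on age (weights `nLx`)
was considered and rejected: on the packaged female table it has no power
(p ≈ 0.14 from 6 points) and fails to detect the clearly rising female
hazard, whereas the Poisson trend test (p ≈ 0.005) agrees with the visual
classification for both sexes.  The full diagnostic (slope, SE, z, p,
interval count) is always attached to the call.

## Mean-age confidence intervals

`mean ± z_{(1+level)/2} · sd/√n` with the sample (n−1) standard deviation
and the normal quantile (z = 1.959964 at 95%).  At the packaged sample
sizes (388, 177, 109) z- and t-based intervals agree to two decimals; the
simpler convention is used and is what reproduces the published intervals.
With one observation the CI is undefined and flagged rather than invented.
Coverage (~95% over simulated replicates) is verified in the tests.

## Quasi-Poisson GLM

- Log link; IRLS with working response `z = η − offset + (y − μ)/μ` and
  weights `μ`, solved by QR least squares on `√μ`-scaled rows.
- Initialisation `μ⁰ = y + 0.5` (guards zeros under the log link);
  convergence when the relative deviance change is below 1e−10;
  non-convergence is flagged on the result, never silent.
- Dispersion `φ = Σ(y−μ̂)²/μ̂ / (n−p)` (Pearson).  Coefficients equal
  Poisson maximum likelihood and are invariant to `φ`; only standard
  errors scale by `√φ`.
- Wald p-values use Student's t with `n − p` degrees of freedom, matching
  the reporting convention (t statistics with residual d.f.) of the R GLM
  ecosystem this analysis style comes from.
- Rank deficiency is detected via QR and reported with the names of the
  collinear columns.
- In the heterozygosity designs, cause of death is dichotomised to
  traffic vs non-traffic (in-care and wild merge into non-traffic);
  records of unknown cause are dropped from dichotomised designs, and
  records missing heterozygosity are dropped with a logged count.
  Age-0 records are retained — zero is a valid count outcome.
  Unknown-sex records are retained by default (`drop_unknown_sex` flag to
  exclude them), since the reference analysis pooled them.

An established GLM implementation is used in the test-suite as an
independent oracle (coefficients, standard errors and dispersion agree to
1e−8 on random datasets); it is never the engine.

## Habitat classification

Neighborhood membership is center-to-center: a cell belongs to a site's
neighborhood when its center lies within the radius of the center of the
cell containing the site.  At 500 m / 100 m this gives exactly 81 cells —
the count that pins down the geometry; alternatives (cell-overlap,
site-point distance) give other counts.  The majority rule compares urban
vs rural cell counts only (`other` excluded); equal counts yield
`unclassified` rather than an arbitrary break.  Edge-clipped neighborhoods
are classified on the available cells and flagged as truncated.

Grids are ESRI ASCII rasters; the packaged code→category default maps the
CORINE artificial-surface block (codes 1–11) to urban and the
agricultural/forest/semi-natural/wetland/water blocks (12–44) to rural.
It approximates the published reclassification (whose exact table is in a
supplement not reproduced here) and is user-overridable.  Coordinates are
assumed already metric; projecting longitude/latitude is the caller's
concern via the `transform` hook.

## Synthetic cohorts

The generator states a simple world matching the packaged study's
structure:

| parameter | default | basis |
|---|---|---|
| sex mix (M/F/unknown) | 0.456 / 0.281 / 0.263 | observed sample |
| cause mix (traffic/in-care/wild/unknown) | 0.557 / 0.222 / 0.216 / 0.005 | observed sample |
| male hazard | constant q = 0.32 / yr | flat male hazard; puts e0 ≈ 2.6 y |
| female hazard | q(x) = min(1, 0.25·e^{0.25x}) | rising female hazard; e0 ≈ 2.2 y |
| max age cap | 20 y | above the oldest observation (16) |
| iH_O | TruncNormal(0.240, 0.074) on [0,1] | observed mean and SD |
| iH_O age slope | 0 | no inbreeding–longevity association |
| month peaks | M: July; F: September (non-traffic), July (traffic) | observed modal months |
| road-kill habitat | 37.5% urban / 62.5% rural | observed split |

The female Gompertz parameters and the exact monthly shapes are
illustrative — the study constrains only the direction of the female trend
and the modal months — and are documented as such.  Unsexed animals draw
their hazard (and month distribution) from a 50/50 latent male/female
mixture.  Cause and month are independent of age given sex, a
simplification; no spatial mechanics, detection bias or carcass-removal
bias is simulated.  A green test on simulated data therefore establishes
estimator correctness under the stated world, not realism of that world.

A non-zero heterozygosity slope thins the annual death odds by
`exp(−slope·(iH_O − mean))`.  For a constant hazard this scales the
expected age-at-death exactly by `exp(slope·(iH_O − mean))`, so the
log-link regression slope is recovered without bias (verified by
simulation); for age-varying hazards it is a proportional-odds
approximation.

All draws come from one integer-seeded generator in a fixed order, so a
(config, seed) pair is reproducible byte-for-byte across runs.

## Degenerate inputs and tie-breaks

- Empty age counts, empty record lists, all-missing covariates and filters
  that remove everything raise errors rather than returning empty results.
- Peak-month ties are returned as sets; habitat ties as `unclassified`.
- Unrecognised sex/cause codes in input files degrade to the explicit
  `unknown` category with a logged warning; invalid ages are hard errors
  with the row number.

## Known limitations

- The cohort interpretation of a single collection season's ages-at-death
  assumes stationary age structure and equal detectability across ages,
  sexes and causes; none of these are testable from the data the package
  consumes.
- The survivorship classifier tests only a log-linear hazard trend;
  U-shaped (juvenile + senescent) mortality would be called Type II.
- The packaged reclassification table is an approximation at land-cover
  block level, not the published supplement's exact mapping.
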