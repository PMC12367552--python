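# Methods

This note documents the models, the numerical choices, and what the
synthetic world does and does not represent.

## Grid model

All mapping computation happens on `GridLayer`: a 2-D real field on a
regular lat/lon grid (default 0.1° cells) with an explicit boolean validity
mask.  Row 0 is the northern edge; cell identity is (row, col) from the
upper-left origin.  Masked cells are excluded from every reduction — maxima,
percentiles and weighted sums all run over valid cells only.  A derived
cell is masked only when *all* of its inputs are masked (aggregation) or
when *any* input is masked (the environmental composite, where a missing
term leaves the formula undefined).

Resampling supports only integer cell-size ratios, as block means over
valid children; block-mean downsampling preserves the valid-cell-weighted
global mean exactly.  Arbitrary reprojection is out of scope: synthetic
data is generated directly on the target grid, and real-data use assumes
pre-aligned inputs.  On-disk formats are ESRI ASCII grid (plain text,
bit-exact round trips via shortest-repr floats) and TIFF through
`tifffile`, with cell size, origin and the nodata value carried in a JSON
`ImageDescription` tag.

## Infrastructure layers

Counts per infrastructure type are scaled by the type's maximum valid cell
(cross-type comparability; count distributions differ by orders of
magnitude between, say, power poles and waste sites), then combined by
equal-weight cell means within each category.  The default catalog maps
telecom/energy/transport → economic, health/education → social,
water/waste → environmental; the sensitivity reclassification moves water
into the economic and waste into the social category, leaving the
environmental composite to rest on green space, air and heat alone.

The environmental composite is

    Env = 0.5 · CI_env + 0.5 · e^Green / ln(e^Air · e^Heat)

whose denominator simplifies algebraically to `Air + Heat`.  Because the
normalized Air and Heat layers can both be exactly zero, the denominator
is floored at ε = 1e−6 (configurable).  The composite output is *not*
rescaled to [0, 1]; scale is absorbed downstream by the 95th-percentile
access normalization.

Calibration against night-time lights fits `ln(NTL) = a·ln(I′) + b` by OLS
over cells where both sides are strictly positive (log-undefined cells are
excluded from the fit but retained as zero in application), optionally
restricted to a caller-supplied boolean footprint such as an
urban-plus-buffer mask.  The fitted law is applied as `I = e^b·I′^a`, with
`I(0) = 0` by continuity convention; for a > 0 the transform is strictly
increasing, so within-layer rankings are unchanged.  One shared (a, b)
pair calibrates both socio-economic layers by default; a per-category
switch exists in the config.

## Access and inequality

Access per unit is the population-weighted mean `IE = Σ Pᵢ Iᵢ / Σ Pᵢ` over
the unit's cells.  By default a cell contributes only when both population
and infrastructure are valid; `treat_missing_as_zero` instead counts the
population with zero infrastructure.  Units with zero total population are
excluded with a logged warning.  Per administrative level and category, IE
is divided by the 95th percentile across units (linear interpolation
between order statistics — the mainstream numerical convention, which the
underlying method leaves unspecified) and capped at 1.  The normalization
pool is global per (level, category); county-level percentiles are
recomputed at the county level rather than reusing country-level ones.

Within-unit inequality is a population-weighted Gini: cells sorted by
access, ties grouped, Lorenz curve of cumulative population share against
cumulative `pop·access` share, trapezoid integration.  This is
algebraically identical to the pairwise-difference form
`ΣΣ pᵢpⱼ|yᵢ−yⱼ| / (2(Σp)²ȳ)`, which the tests use as an independent
oracle (agreement to 1e−12).  All-zero access is defined as perfect
equality (Gini 0) with a logged note; single-cell units get Gini 0 and a
`degenerate` flag.  The auxiliary inequality index is half the
population-weighted relative mean absolute deviation, clipped to [0, 1] —
a documented stand-in with the same endpoints and orientation as the
Gini, pluggable through `unit_inequality(inq_fn=...)` for any alternative
formula.  Nothing downstream depends on it.

## Classification

Per dimension, units below the 25th percentile are L, above the 75th H,
else M.  Values exactly on a threshold class as M — strictness keeps H and
L as genuine quartile exceedances; the boundary closure is a deliberate
package convention, configurable quantiles included.  The three-letter
label (economic-social-environmental order) has 27 possible values; the
general classes are I (no L), II (at least one H and one L), III (no H),
which partition the 27 exactly into 8/12/7.  Classification is invariant
under any strictly monotone transform of the access values.

## Health models

Models I–III share the controls LnPop and LnGDP and differ in the
infrastructure terms (I: access only; II: inequality only; III: both),
fitted by REML linear mixed-effects regression with a random intercept on
the North/South group.  A random intercept over only two groups is
statistically fragile — the variance component is estimated from two
draws — so the fit warns, uses BFGS with a Powell fallback (the default
L-BFGS optimizer can diverge on the nearly flat two-group variance
profile), treats a boundary variance estimate (τ² ≈ 0) as exact
degeneration to OLS, and offers a `group_as_fixed` fallback that replaces
the random intercept with a fixed group effect.

Diagnostics: Kolmogorov–Smirnov normality of the response (against a
normal with estimated mean/sd) decides the log transform — applied only
when KS rejects at p < 0.05, or forced either way; Levene's test on
conditional residuals by group checks homoscedasticity, and when it
rejects at p < 0.05 the fixed-effect covariance is replaced by an HC1
sandwich estimate (the small-sample-corrected heteroscedasticity-
consistent variant), from which z, p and Wald CIs are rebuilt.  R² is
reported as the squared correlation between fitted and observed response —
for a mixed model no single canonical R² exists, and this definition is
recorded in the output metadata.  All p-values are two-sided and
unadjusted.  DALY models reuse Models I–III verbatim with the response
swapped.

Pearson correlations use Fisher-z 95% CIs.  Random-forest importance fits
`n_runs` independent 500-tree forests, reporting per covariate both the
increase in mean squared error under column permutation and the total
impurity decrease (node purity); a fixed master seed makes the whole table
bit-reproducible.  Group comparisons use the pooled-variance t-test with
Cohen's d for two groups and one-way ANOVA with Cohen's f
(√(η²/(1−η²))) for more.

## Synthetic world

The generator emulates the *structure* of the real inputs, not their
geography: countries are rectangular tiles (split into rectangular
counties), population is a sum of Gaussian clusters with log-normal
amplitudes and multiplicative noise, and per-type infrastructure counts
are gamma-Poisson draws around an intensity proportional to
`relpop^(loading·c)` — `relpop` the cell's population relative to the
country mean, `c` the country's *concentration* parameter.  Intensities
are budget-normalized within each country, so concentration redistributes
infrastructure towards population rather than adding to it: at c = 0 the
intensity is flat and noise terms vanish (within-country Gini near zero),
and the median Gini rises monotonically with c.  Social facility types
carry a higher concentration multiplier (scarce, town-bound services) and
water/waste a lower one, which reproduces the empirical ordering of
inequality across categories.  "North" countries receive an abundance
boost and draw lower concentrations, so the generated world shows the
expected contrast: higher access and lower inequality in the North.

Night-time lights follow `NTL = e^b·I′^a·e^noise` of the normalized
economic layer with (a, b) = (1.58, 5.03) by default — the published
calibration coefficients — so a noise-free world lets `fit_calibration`
recover both to machine precision.  Country health outcomes are drawn from
the Model III linear predictor using covariates computed from the
generated grids by the package's own access and inequality routines, with
the published Model III coefficients as the default generating law, fixed
group intercepts γ_North = +2, γ_South = −2 years, and homoscedastic
N(0, 3²) residuals (a heteroscedastic switch doubles the South sd to
exercise the Levene/sandwich path).  GDP is log-linear in population and
economic access with noise.  All randomness flows from one seed through
`SeedSequence.spawn` children per layer, so adding a layer never perturbs
the others.

What the generator does *not* emulate: real coastlines or country shapes,
volunteered-data completeness bias, spatially correlated infrastructure
noise across types, travel-time accessibility, or population mobility.
Passing tests therefore demonstrate the correctness of the computations
and the recoverability of known parameters under realistic structure —
not agreement with the real global estimates, which depend on the actual
rasters.

## Problem sizes and determinism

Default study conditions: a 96×192 grid of 0.1° cells hosting 166
countries (matching the global study's country count) with 4 counties
each; repeated-fit analyses use country panels of n = 160 (51 North / 109
South, the health-model sample) with 500 replicates for coverage checks
and 100 forest runs of 500 trees.  Tests and the acceptance script use
smaller worlds (24 or 12 countries on 48×96 / 32×64 grids) where only the
mechanics, not the statistics, are at stake.  Pipeline CSVs are written
with fixed float formatting, and two runs with identical config and seed
are byte-identical; the run manifest records per-stage config hashes so
current stages are skipped on rerun.

## Known limitations

* The two-group random intercept is at the edge of what mixed models
  identify; interval estimates for the intercept are wide and the group
  variance is unstable (surfaced via warning and the fixed-effect
  fallback).
* The auxiliary inequality index is a documented placeholder, not a
  reproduction of any specific published index.
* Only integer-ratio grid alignment is supported; real-data reprojection
  must happen upstream.
* Percentile normalization pools are global per level; regional pooling
  exists behind a config switch but is not the default.
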