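# Methods

This note documents the statistical choices behind `mortset`: the model
pool, the evaluation and trimming machinery, the synthetic-data
generator the tests rely on, and the numerical decisions taken where
the design was genuinely open.

## Data model

A `MortalitySurface` holds central death rates `m[x, t]` (optionally
death counts and exposures) on a grid of consecutive single-year ages by
consecutive calendar years. The last age group may be open-ended
("100+"); it is treated as the integer point 100 in every model's age
arithmetic, so a 60–100+ surface has k = 41 age points and `x̄`, `x − x̄`
and related terms are computed on 60…100. Cells with zero observed
deaths keep rate 0 in storage; log-domain consumers replace a zero by
half the smallest positive rate in the same year's column before taking
logs, which avoids −∞ while preserving the within-year ordering.

## Model pool (registry labels 1–17)

**1–8, Poisson GAPC family.** Deaths are Poisson with mean
`e[x, t]·exp(η[x, t])` and

    η[x, t] = α_x + Σ_i f_i(x) κ_t^{(i)} + g(x) γ_{t−x},

covering LC-Poisson, Renshaw-Haberman (estimated cohort loading
`β_x^{(0)}`), APC, CBD (`f_1 = 1, f_2 = x − x̄`), M6, M7 (adds
`(x − x̄)² − σ̂²`), M8 (`g(x) = x_c − x` with `x_c` profiled over integer
candidates just above the age range, ties to the smallest), and Plat
(`f_2 = x̄ − x`, `f_3 = (x̄ − x)⁺`). Estimation is by alternating
one-dimensional Newton updates of each parameter block — the standard
Poisson log-bilinear scheme — with one refinement: if a full sweep fails
to decrease the deviance, the sweep is retried with step factors
0.5, 0.25, 0.1, 0.01, so the deviance trace is non-increasing by
construction. Convergence is declared when the relative deviance change
falls below 1e-6 (cap 500 iterations; the Renshaw-Haberman model often
hits the cap, which is reported through `converged_` rather than as a
failure, and is started from an APC pre-fit; M6/M7/M8 start from
CBD/M6 pre-fits, which also guarantees the nested-deviance ordering).

Cohorts observed fewer than 3 times are excluded: their cells get
weight 0 in the likelihood and their `γ` is reported as 0. Exclusion
(rather than keeping the cells with `γ` pinned) is what makes the
identifiability transformations exact: the constraint step re-expresses
the fitted model — scaling estimated loadings to sum 1, transferring a
degree-0/1/2 polynomial in cohort out of `γ` with compensating changes
to `α` and the `κ`'s, and centring `κ`'s into `α` — leaving the linear
predictor unchanged (≤ 1e-10) at every cell that enters the likelihood.

**9–12, Gaussian Lee-Carter.** `α` is the per-age mean of log rates,
`(β, κ)` the leading singular pair of the centred matrix, scaled to
`Σβ = 1, Σκ = 0`, with the sign chosen so the fitted drift of `κ` is
non-positive (declining mortality) — this makes runs reproducible where
the SVD sign is arbitrary. The variants re-solve each `κ_t`: against
total deaths (bracketed root find, label 9), against the age
distribution of deaths via the Poisson deviance (bounded scalar
minimization, label 10 — no fitting-period reselection is performed),
or against the observed period life expectancy at the youngest age of
the window (label 11; with a 60+ window "life expectancy at birth" is
not computable, so expectancy at 60 anchors the adjustment). Adjusted
`κ` is not re-centred — its level carries information. The lifetable
uses `a_x = 0.5` within single-year groups and `1/m_last` person-years
in the open group. Label 12 is the raw SVD fit; it coincides exactly
with the K = 1 unsmoothed functional model.

**13–17, functional time series.** Log-mortality curves are smoothed
over age by a discrete penalized regression spline (second-difference
penalty λ, default 10; λ = 0 reproduces the input, λ → ∞ approaches the
least-squares line) with a monotonicity projection
(pool-adjacent-violators) from age 65 up, since old-age mortality rises
with age. Weighted FPCA of the smoothed curves gives a mean function,
orthonormal components (eigenvectors of the weighted sample covariance)
and projection scores; default K = 6 components for single-population
variants, K_common = K_specific = 3 for the multilevel model (K is
configurable; nothing in the method pins it). The product-ratio model
fits independent FPCAs to `ln √(m_M m_F)` and `ln √(m_M / m_F)` (the
ratio part gets at most 3 components — it is a small, slowly varying
signal) and recombines; the multivariate model stacks populations into
one long vector per year; the multilevel model decomposes each
population into its mean curve, a common trend `R_t(x)` (FPCA of the
across-population average of centred curves) and a specific trend
`U_t^j(x)` (FPCA of the deviation from that average — defined against
the observed average, not its FPCA truncation, so identical populations
have exactly zero specific trend).

### Robust outlier rule (label 14)

The robust variant must flag whole years whose curves do not belong to
the common structure. Two facts shape the design. First, a candidate
outlier can mask itself: with K ≥ 2 a principal component will bend
toward a single aberrant year, so its in-sample integrated squared
error (ISE) ends up *smaller* than that of clean years. Scoring each
year against the basis fitted *without* it (leave-one-year-out) removes
the masking channel. Second, level shifts — the empirically important
outlier type for mortality (wars, epidemics shift whole curves) — are
nearly collinear with the smooth leading component, so the detection
runs on unsmoothed log rates against a rank-1 leave-one-out basis,
where the age-wise roughness of the loading keeps the shift visible,
and squared residuals are standardized by a per-age robust scale
(median of squared residuals over years, chi-squared-median
consistent) before being summed over ages. The resulting per-year
statistic is heavy-tailed but approximately lognormal on clean data, so
a year is flagged when the robust z-score of its log statistic (median
and MAD calibrated) exceeds the normal critical value at the
Bonferroni-adjusted tail `1 − (1 − level)/n` (familywise `level`
defaults to 0.999; n years are tested). Flagged years then get weight 0
and the K-component model is refitted once. A plain chi-squared rule on
in-sample ISE with df = k − K was evaluated and rejected: masking makes
the outlier invisible at K ≥ 2, and residual correlation across ages
makes the clean ISE distribution far heavier-tailed than χ²(k−K),
producing frequent false flags.

## Forecasting

Principal-component scores and `κ` indexes follow a random walk with
drift: drift = mean first difference, innovation variance = MLE from
the n − 1 differences, and forecast variance
`u_{n+h|n} = σ̂² h (1 + h/(n−1))`, which includes the drift-estimation
term. Families with several period indexes simulate a joint RWD with
the sample covariance of the differences; cohort indexes follow an
ARIMA(p, d, q) with p, q ∈ {0, 1, 2}, d ∈ {0, 1} selected by AIC
(fallback to RWD with a warning if every fit fails). Gaussian/functional
models build symmetric intervals from
`var ≈ Σ_k φ_k(x)² u_k + v_x` with normal quantiles; GAPC models push
1000 (default) simulated index paths through the predictor and take
empirical quantiles, with future cohort effects simulated from the
ARIMA and recent, data-sparse cohorts treated as unobserved. Parameter
uncertainty is not simulated — intervals carry forecast (index) and
residual uncertainty only. Everything is seeded; repeated invocation is
bit-identical.

## Evaluation, trimming, combination

The expanding-window design refits every model on data up to each
origin year and forecasts h = 1 steps ahead; with the 1975/1995/2005/
2015 split this yields 10 validation and 10 test forecasts per model.
Losses are computed on the log-rate scale — the scale every model in
the pool is built for — as per-curve RMSFE and per-curve mean interval
score at α = 0.2. Model failures at an origin are logged and excluded,
never zero-filled.

The MCS procedure studentizes mean loss differentials with
moving-block-bootstrap variances (B = 5000 by default, reduced in
tests; block length = the maximum count of significant AR coefficients
across all pairwise differential series, AIC order selection up to
`floor(N^{1/3}) + 1`, floored at 1). The null distribution of
`T_R = max |t_ρξ|` or `T_max = max t_ρ·` is the same bootstrap with
differentials recentred by their sample means. Elimination uses the
standardized form of the relative loss for both rules — `e_max` divides
by the standard deviation, not the variance, matching the definition of
`t_ρ·`. Bootstrap replicates are redrawn each elimination round with a
seed advanced deterministically from the base seed, so the elimination
trace never depends on the test level and superior sets are nested
across confidence levels by construction. A zero bootstrap variance
with a nonzero mean differential yields p-value 0 with a warning.

Equal weights over the superior set and inverse-validation-error
weights over all models combine the stored test-period forecasts;
interval bounds are combined by the same convex average as the points
(averaging predictive distributions instead would widen mixtures and is
out of scope). The combined forecast therefore lies elementwise in the
convex hull of its members.

## Synthetic-data generator

The generator is the test bed: it emulates a retirement-age mortality
panel with the same log-bilinear structure the pool is built around.
Defaults: ages 60…100+ (41 groups), years 1975…2015 (41 years), age
profile `α_x = −9 + 0.09 (x − 60)` (a Gompertz line), loading `β` drawn
uniform on (0.5, 1.5) and normalized to sum 1, period index a random
walk with drift −0.5 and innovation SD 0.3 centred to sum 0, exposure
1e5 person-years per cell, Poisson death counts, and an optional
additive log-rate gap between two populations (default 0.35 in the
pipeline fixture, a male/female-sized gap). Multi-population panels mix
a common innovation stream with idiosyncratic ones so that increment
correlation equals `cross_corr` (default 0.8). A deterministic mode
replaces Poisson sampling by the expected rates for exact-recovery
tests, and `inject_outlier_years` shifts chosen years' log rates.

What the generator does *not* emulate: cohort effects are off by
default (so GAPC cohort terms are tested for null recovery, not power),
the age loading is rough rather than demographically smooth, there are
no structural breaks or heteroscedastic exposure patterns, and the two
populations share one `β`. Passing tests therefore demonstrate
correctness of the machinery under the model's own assumptions, not
forecast accuracy on real national data.

A consequence worth knowing: at exposure 1e5 the youngest ages carry
log-rate noise with SD ≈ 0.3, and any unweighted projection (SVD
Lee-Carter, FPCA scores) inherits it — the score-path correlation with
the generating index plateaus around 0.985, while the
likelihood-weighted Poisson fit reaches 0.995+. Age smoothing cannot
recover the gap because smoothers preserve the near-constant direction
the projection measures.

## Numerical choices and problem sizes

* Poisson deviance convergence 1e-6 relative, 500-iteration cap,
  damped sweeps; constraint transformations exact to ~1e-10.
* κ-adjustment root finds bracketed at κ ± 50; deaths-distribution
  adjustment by bounded Brent minimization on the same interval.
* M8 candidate grid: integer ages from the top of the age range to
  +20 above it.
* FPCA eigenvector signs fixed by making each component's largest
  absolute entry positive.
* Default experiment sizes keep everything desk-scale: B = 500
  bootstrap replicates and 400 GAPC simulation paths in the pipeline
  fixture, B = 1000 in the calibration studies, 200 replications for
  coverage and MCS size/power, 20 for the outlier rule. The full test
  suite runs in under two minutes on one CPU.

## Known limitations

* The Renshaw-Haberman fit is slow to converge (a known property of
  the model); its `converged_` flag should be checked.
* GAPC intervals omit parameter uncertainty, so they are somewhat
  narrow; the observed one-step coverage of nominal 80% intervals on
  synthetic data is ~72–75%.
* Inverse-variance weighting of FPCA scores would improve index
  recovery at low exposures but would depart from the plain-projection
  definition used here.
* The block-length rule returns 1 for a single weakly-dependent pair
  series; it develops resolution only when many pair series are
  scanned (the max over pairs).
* No graduation, Lexis triangles, abridged age groups, or
  coverage-probability-deviance evaluation.
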