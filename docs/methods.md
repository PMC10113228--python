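# Methods

## Data model and preprocessing

One *event* is a single animal crossing the light barrier of a
hibernaculum entrance: timestamp (second resolution), site, species,
direction (in/out). Events are aggregated to hourly in/out counts per
site and species, with explicit zero rows over each site's covered
recording span. Both count series are smoothed by a centred 3-hour
moving average; at the edges of each contiguous block of recorded hours
the window shrinks (2-term mean) rather than discarding the hour, and
smoothing never crosses a recording gap. The response is
`y = min(s_in, s_out)`: the minimum of the two smoothed series, which
suppresses one-way bulk movements during the final departure. `y` is
therefore a non-negative *real* number.

Weather covariates are joined by site-hour. The air-pressure trend is
the centred difference `APT_t = AP_{t+1} - AP_{t-1}` (hPa per 2 h); the
first and last hour of each contiguous weather block have no APT and are
dropped. *Sun time* ST maps each timestamp onto the diel cycle anchored
at the sun: sunset = 0, the night interpolates linearly to +1 at the
next sunrise, the day from −1 at sunrise to 0 at sunset; ST is
continuous and periodic with period 2 across the sunrise seam. Day of
year uses January 1 = day 0; rows beyond day 136 (mid-May, the end of
the spring activity period) are dropped, as is any row with a missing
covariate. Every dropped row is counted by reason and the accounting is
logged and attached to the frame (`frame.attrs["drops"]`).

Sunrise/sunset come from the standard NOAA low-precision solar-position
equations (zenith 90.833°), accurate to one or two minutes at temperate
latitudes — negligible against hourly aggregation. Polar day/night is
outside the supported domain and raises an error. All timestamps live on
one clock (UTC in the synthetic world); only consistency between event,
weather and solar timestamps matters.

## The penalized Poisson GAM

Hourly counts are modelled as
`y ~ Poisson(mu)`, `log mu = alpha + site + x'beta + f1(ST) + f2(DOY) + f3(ST, DOY)`,
with seven linear weather terms, a site factor (treatment coding,
configurable reference, default Mayen-Mauerstollen), and cyclic smooths.
Because `y` is a minimum of moving averages it is not integer; the
Poisson deviance `D = 2 Σ [y log(y/μ) − (y − μ)]` (with `y log y := 0`
at `y = 0`) is well defined for real `y ≥ 0` and is used as a
quasi-likelihood with dispersion fixed at 1. No offsets, weights or
overdispersion scale are estimated.

### Cyclic cubic regression splines

A cyclic cubic regression spline on knots `x_0 < … < x_k` (with `x_k`
identified with `x_0 + period`) is parameterized by its values at the
`k` distinct knots. Second-derivative continuity of the piecewise-cubic
interpolant yields the cyclic tridiagonal system `B γ = D f` linking
values `f` and second derivatives `γ`; the wiggliness penalty is exact:
`∫ f''² = f' D' B⁻¹ D f`. Value, first and second derivatives match at
the period endpoints by construction, and the constant function is
representable with zero penalty. Defaults: 10 basis functions for
`f1(ST)` over [−1, 1], 20 for `f2(DOY)` over [0, 366] (the annual cycle
wraps at the year boundary even though data cover only days 0–136), 5×5
margins for `f3`; all config-exposed. Knots sit at sample quantiles
(first knot at the period start; the upper period endpoint is the wrap
knot so the wrap interval keeps a regular width); degenerate quantiles
fall back to uniform spacing.

Each smooth is centred by a single sum-to-zero constraint over the
training sample (removing the confound with the intercept); the
interaction `f3` is built from sum-to-zero-constrained margins whose
pairwise products exclude both main effects, so `f1 + f2 + f3` is
identifiable — the tensor space is orthogonal to pure functions of
either margin on a crossed design, and nearly so on observational
designs.

### Fitting, smoothing selection, inference

Penalized IRLS maximizes the penalized quasi-log-likelihood: working
weights `W = μ`, working response `z = η + (y − μ)/μ`, Cholesky solve of
`(X'WX + Σ λ_i S_i) β = X'Wz`, step-halving on the penalized objective,
convergence at relative change < 1e−8 (max 100 iterations, error with
iteration trace beyond). The linear predictor is clipped at ±30 so an
all-zero response converges to the boundary (intercept ≈ −30) instead of
diverging. Linear covariates are centred internally for conditioning and
the fit is transformed back to the raw scale. A pivoted-QR diagnostic
names collinear columns on rank deficiency. Refits of identical input
are bit-identical.

Smoothing parameters minimize the GCV score `n·D / (n − edf)²` by
coordinate descent (two sweeps by default) over a log-spaced grid of
relative λ per penalty; each penalty's unit λ is pre-scaled so its
Frobenius norm is comparable to its block's information matrix,
making one grid serve smooths of very different units. Boundary
solutions are logged. A fixed-λ mode bypasses the search. Replicated
simulation studies use a coarser grid (6 points, 1 sweep) — the model is
unchanged, only the search resolution.

Inference uses the Bayesian covariance `(X'WX + S_λ)⁻¹`: Wald z-tests
with two-sided normal p-values and conventional stars for the
parametric terms, and for each smooth the quadratic form of its
coefficient block against its covariance block referred to χ² with the
block's effective degrees of freedom (`edf = tr[(X'WX+S)⁻¹X'WX]` summed
over the block). The edf is floored at 1: under heavy shrinkage the
block edf collapses toward zero and a χ² reference with near-zero df
would declare any nonzero statistic significant. This plain Wald-χ² is a
documented simplification of refined randomized-df smooth tests; in our
calibration study it is near-nominal to mildly conservative (5–7
rejections per 100 null replicates at α = 0.05). Deviance explained is
`1 − D/D_null` with the null fit being intercept-only (`μ = ȳ`, the
closed-form Poisson MLE).

Prediction is component-selective (intercept, site, linear, f1, f2, f3)
on the link or response scale; components add on the link scale, and
full response-scale training predictions sum to Σy (canonical-link score
equation). Extrapolation beyond fitted covariate ranges is warned, not
refused.

## Residual activity and functional groups

The residual-activity curve is `f2` evaluated on the day grid 0–136 on
the link scale (sum-to-zero centred, so 0 means "fully explained by
weather, site and diel cycle"). "DOY alone" deliberately excludes the
ST×DOY interaction (it is not a function of DOY alone); an option adds
the ST-marginalized interaction. Species are ranked by the median of
|curve| over the grid. Grouping: Kruskal–Wallis omnibus over the
per-day absolute values, all pairwise two-sided Mann–Whitney tests,
Bonferroni adjustment (p × number of pairs, capped at 1), and a compact
letter display built as a greedy clique cover of the non-significant
graph — every non-significant pair shares a letter, no significant pair
does, every species gets at least one. HRA/MRA/LRA labels attach to the
letter groups by rank thirds. The per-day curve values serve as the
test sample; they are serially correlated along the grid, which the
rank tests ignore — a known caveat of testing smooth curves pointwise,
accepted here because the grouping is descriptive.

## Emergence timing and synchronization

Daily activity is the full-model response-scale prediction summed over
hours and sites per day of year (model-predicted, not observed, so
weather gaps do not distort the distribution; an option uses observed
daily totals). Weighted quantiles interpolate linearly on the midpoint
cumulative weights (mass of day d centred at `F(d−) + w_d/2`), so a
symmetric distribution returns its centre and a point mass returns its
day with IQR 0. The summary reports the weighted median, quartiles,
IQR (= synchronization: days holding the central 50 % of activity),
weighted mean day, and both the signed mean and the mean absolute
residual-activity value (the signed mean is the default regressor, the
absolute version is also emitted). Cross-species OLS regressions
(median DOY ~ mean residual; IQR ~ median DOY) report slope, intercept,
R² and the slope's two-sided p; with six species these are illustrative,
not confirmatory.

## Synthetic data: what it emulates, and what not

The weather generator reproduces the structure the analysis relies on,
not real climatology: seasonal + diel air-temperature cycles with AR(1)
noise; soil temperature as a 100-day low-pass of air temperature plus an
independent slow component (soil thermal inertia decouples the two at
short lags); air pressure as an AR(1) around 1013 hPa with a ~4-day
synoptic decorrelation time; softplus-positive wind; two-state-Markov
wet spells with exponential hourly rain; integer cloud cover correlated
with wet hours. Defaults keep every pairwise covariate correlation
below 0.5 (observed max ≈ 0.4, between the two temperatures) — the
low-collinearity regime in which the separation of weather effects is
well posed. Parameter-recovery results therefore say: *given* this
regime and a correctly specified model, the machinery recovers the
truth. They do not certify behaviour under strong collinearity,
misspecified smooths, overdispersion or autocorrelated residuals, all of
which real entrance data may exhibit.

Activity simulation draws hourly totals `N ~ Poisson(exp(g))` from the
model equation, splits entries/exits as `Binomial(N, 0.5)` (no in/out
asymmetry is modelled) and scatters event timestamps uniformly within
the hour — sub-hour placement is irrelevant after hourly aggregation.
Species presets carry the published linear coefficients and site
offsets; seasonal truths are mean-zero periodic Gaussian bumps whose
peak day, width and amplitude reflect each species' reported phenology
(early/diffuse for *Plecotus*, late/sharp for *M. bechsteinii*). A
per-species intercept calibration aligns simulated event volumes with
the published photo totals over five seasons — the published intercept
is net of unpublished smooth-term contributions and alone understates
absolute rates by orders of magnitude. Recovery and calibration studies
generate the model frame directly (`y ~ Poisson(exp(g))`, the model's
own equation); the event-level path with the min-of-smoothed response is
used for end-to-end pipeline runs, where that response construction
introduces a deliberate downward robustification bias that clean
CI-coverage checks should not inherit.

Study sizes: fits use n = 20,000 site-hours (five sites over two
simulated seasons); 50 replicates for CI coverage, 100 for null
calibration, 25 (six species each) for ordering recovery. The relative
bias of a coefficient whose true value is far below its standard error
(cloud cover at −0.005) is noise-dominated at any feasible replicate
count, so bias is assessed on the well-identified coefficients (air
temperature, wind speed).

## Numerical choices and degenerate inputs

* η clipped at ±30; tiny ridge (1e−10 × diagonal scale) on the normal
  equations for boundary cases; all-zero response converges to the
  boundary rather than erroring.
* GCV edf denominator floored at 1e−3; smooth-test df floored at 1.
* Weighted quantiles demand positive total weight; zero-weight input is
  a data error.
* Empty gap specs are identities; overlapping gap windows merge with a
  warning; events removed and weather values blanked are counted.
* Species with fewer than 100 frame rows (configurable) are skipped with
  a logged reason rather than fitted.
* All randomness flows through `numpy.random.default_rng` seeded from
  configuration; pipeline reruns produce byte-identical CSV artifacts.

## Known limitations

* Smooth-term p-values are the plain Wald-χ² described above, not the
  refined mgcv-style tests; they are adequate for the descriptive use
  here and calibrated in simulation, but not exchangeable with mgcv's
  printed values.
* GCV (not REML) selects smoothing; at very low counts GCV can
  undersmooth, and where a species' observed activity is essentially
  zero over long stretches the log-scale DOY effect is weakly bounded
  below, so residual curves can show large negative plateaus.
* The serial correlation of residual-curve values (grouping tests) and
  of hourly counts (model fitting) is not modelled; no GEE/autocorrelation
  correction, no random effects, no other response families.
* One clock and one weather station per site; no timezone arithmetic,
  no station-to-site transfer error.
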