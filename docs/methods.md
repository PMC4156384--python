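# Methods

## Model

The population state is a vector of 50 one-day age classes of females.
One projection step is `n(t+1) = M(T_t) · n(t)`, where `M(T)` is a Leslie
matrix rebuilt from the mean air temperature of day `t`: the matrix of a
calendar day governs the transition out of that day. Fecundities
`f_x(T)` occupy the first row, daily survival probabilities `p_x(T)` the
subdiagonal, and no survival entry leaves the last class — age 50 is
absorbing death. All life stages experience ambient air temperature; the
model is linear (no density dependence, Allee effects, migration, host
limitation or thermal-history carryover), so trajectories are
deterministic given the weather and scale linearly in the initial vector.
Absolute abundances are therefore *relative* indices; the informative
outputs are growth patterns, timing and stage composition.

Stage classification is fixed by age: 1–3 d eggs, 4–7 d larvae, 8–9 d
pupae, 10–50 d adults. The daily total population estimate is log10 of
the vector sum; zero-total days are flagged `extinct` and carry NaN
rather than −∞.

## Thermal performance curves

Demographic rates are hump-shaped functions of temperature, zero outside
a lower/upper critical limit. Three families are implemented:

| family      | form                                   | default domain        |
|-------------|----------------------------------------|-----------------------|
| quadratic   | max(0, a + bT + cT²), c < 0            | its real roots        |
| gaussian    | rmax · exp(−(T−Topt)²/2σ²)             | Topt ± 3σ             |
| briere1     | a·T·(T−TL)·√(TU−T)                     | (TL, TU)              |

The Gaussian is truncated at ±3σ so that, like the other families, it
has finite critical limits; the tails carry < 1.2 % of the peak rate.
Survival evaluations are additionally clamped to [0, 1]. Fitting is
bounded nonlinear least squares (`scipy.optimize.curve_fit`) with
data-derived starting values; fits require at least as many distinct
temperatures as parameters and at least one positive rate, and accept
per-point precision weights (zero-weight points are dropped).

## Demographic schedule and its defaults

Survival is grouped into age blocks (default: one curve per life stage),
because 50 independent per-age fits are unidentifiable from realistic
cohort data. Fecundity is separable: `f_x(T) = w(x)·F(T)/d`, where
`w(x)` is an adult age profile (zero before age 10) and `d` the sex-ratio
divisor (default 2.0, i.e. a 1:1 sex ratio; the matrix tracks females).
A full (age × temperature) table can be supplied instead by building a
schedule with per-age blocks.

The built-in default schedule is synthetic but parameterized to the range
laboratory life tables report for *D. suzukii*:

* fecundity: Gaussian, peak 12 total eggs/female/day at 22 °C, σ = 5 °C;
* immature daily survival (ages 1–9): Gaussian, 0.98 at 20 °C, σ = 8 °C;
* adult daily survival (10–50): Gaussian, 0.96 at 20 °C, σ = 9 °C;
* age profile `w(x) = u·e^(1−u)`, `u = (x−9)/10`: laying ramps over the
  first adult week, peaks at age 19 and decays slowly. With the 12/day
  peak this gives a lifetime fecundity near 300 eggs at the optimum,
  consistent with published cohort studies of this species.

Under these defaults the dominant eigenvalue crosses 1 near 14.8 °C and
falls below 1 again above ≈ 25.7 °C, with λ ≈ 1.25 at the optimum. These
two crossings are what generate the qualitative regional contrast: a
climate whose midsummer mean overshoots ~26 °C produces a bimodal season
(growth, midsummer collapse, autumn rebound), while a mild climate that
never overshoots produces a single late-season peak.

## Biofix

The biofix rule makes "the temperature first allows growth" explicit and
testable: the first date `d` such that λ(M(T̄)) > 1 on `persistence`
(default 3) consecutive days, where T̄ is the trailing `window`-day
(default 7) mean temperature ending on each day. Smoothing lives only in
the biofix; projection always uses the raw daily mean. A fixed calendar
date can be supplied instead, matching historical usage (e.g. fixed
early-February or early-April starts by region). The initial vector is
100 flies spread uniformly (10 per class) over ages 41–50 — old,
post-diapause females; the per-class split is a design choice since only
the total and the age range are prescribed.

## Degree-days

The single-sine method models the diurnal trace as one sine through
(tmin, tmax) and integrates the excess above the lower threshold
(default 4 °C) in closed form: with α = (tmax−tmin)/2 and
θ = arcsin((TL−tmean)/α),

* tmin ≥ TL → dd = tmean − TL
* tmax ≤ TL → dd = 0
* otherwise → dd = [(tmean−TL)(π/2−θ) + α·cosθ]/π.

An optional upper threshold uses the horizontal cutoff (time above TU
accrues at TU−TL), implemented as the difference of two single-sine
integrals. Weather series carrying only a daily mean cannot support the
sine and fall back to max(0, tmean−TL) with a logged warning, rather than
fabricating a diurnal range. Accumulation defaults to the series start
(1 January for annual series) and is configurable.

## Synthetic data

The weather generator produces a sinusoidal annual cycle
(`annual_mean + annual_amplitude·sin(2π(doy−105)/365)`) with i.i.d.
Gaussian daily noise and a fixed symmetric diurnal range; phase 105 puts
the warmest day in mid-July. Two presets bracket the climates of
interest: `hot-summer` (mean 17.5 °C, amplitude 10, midsummer mean
≈ 27.5 °C, above the fecundity optimum) and `temperate` (mean 11.5 °C,
amplitude 7, midsummer mean ≈ 18.5 °C). The generator does not emulate
synoptic autocorrelation, heat waves, humidity or microclimate; passing
tests on it demonstrates correctness of the machinery under the stated
thermal regimes, not calibration to any real station.

The life-table generator simulates constant-temperature cohorts from a
known schedule: survivors follow a binomial chain with daily `p_x(T)`,
and eggs are Poisson with mean equal to the schedule's total (both-sex)
daily egg load per surviving female. Replicate cohorts are pooled. It
reproduces the key pathology of real cohort data — at hostile
temperatures few or no females survive to adulthood, so fecundity there
is censored, not observed.

## Estimating fecundity from life tables

A naive per-temperature average of egg rates confounds survival with
fecundity: at hostile temperatures only young, low-laying adults are ever
observed, which biases the apparent thermal breadth downward. The
estimator used here is the one the separable model implies: a weighted
rank-1 factorization `rate(x,T) ≈ w(x)·F(T)` by alternating least
squares, each observation weighted by the number of surviving females
behind it, with `w` normalized to peak 1. The temperature curve is then
fitted to `F(T)` weighted by adult female-days per temperature, so
temperatures with no surviving adults contribute no information instead
of spurious zeros. Under the reference recovery conditions (9
temperatures × 5 cohorts of 100) this recovers the generating optimum to
within ≈ 0.2 °C and the ±3σ critical limits to well under 1 °C across
seeds. Daily survival over an age window is estimated by the exposure
MLE: total day-to-day survivals divided by total days at risk.

## Numerical choices

* Dominant eigenvalue/vector via dense `numpy.linalg.eig` (order-50
  matrices); the Perron root of a nonnegative matrix is its spectral
  radius, returned with its nonnegative eigenvector normalized to sum 1.
  Reproduction-free (nilpotent) matrices return λ = 0 with no
  distribution. The test suite cross-checks against power iteration and
  against Euler–Lotka roots found by Brent's method.
* Curve optimum by bounded scalar minimization on the curve's domain
  (tolerance 1e−8 °C).
* Trap regression by `statsmodels` OLS on calendar months present in
  both series (no interpolation); df = (1, n−2); at least 3 shared months
  and a non-constant predictor are required. P-values are per-site,
  uncorrected.
* Seasonal peak counting: 21-day centred moving average of the log10
  totals, `scipy.signal.find_peaks` with prominence 0.3 log10 units
  (≈ two-fold dip), plus an endpoint maximum if the curve is still rising
  at the series end.
* All simulations take an integer seed through
  `numpy.random.default_rng`; sub-streams in the acceptance script are
  spawned from a single `SeedSequence`.

## Problem sizes

The reference checks use 201-day constant-temperature runs (growth-rate
and age-structure convergence, measured over days 150–200), 365-day
synthetic years for seasonal behaviour, 10,000 random days for the
degree-day oracle, 9 × 5 × 100 life-table simulations for recovery, and
1,000 null simulations for regression calibration.

## Limitations

* Rates respond to the current day's mean temperature only; no thermal
  history, acclimation, humidity or resource effects.
* Linearity means absolute abundances are relative indices, not counts.
* The default schedule is a documented synthetic stand-in with the same
  structure and plausible magnitudes as published laboratory regressions
  for this species, not a refit of any published dataset; users with
  their own life tables should fit and supply their own schedule.
* Fecundity separability (no age × temperature interaction) is the
  minimal structure; supply per-age blocks if your data show interaction.
* The comparison against published station-year degree-day totals
  requires the user to obtain the station archives; the repository ships
  no station data.
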