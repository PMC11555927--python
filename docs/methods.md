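# Methods

This note documents the statistical procedures implemented in `atckit`,
the conventions chosen where a definition was genuinely open, and what
the synthetic-data tests do and do not establish.

## Changes and alignment

All estimators operate on paired change series
$(t, x^{\Delta}_t, y^{\Delta}_t)$ at a fixed horizon $l$ on an integer
time grid. Calendar time is mapped to that grid in I/O (step = gcd of
observed spacings; off-grid timestamps are an error, not interpolated).
Missing observations are *absent entries*, never sentinel values: one
missing raw value at time $t$ removes the two differences at $t$ and
$t+l$, and a pair is dropped as soon as either side is undefined — even
if the other side is available. No imputation is performed.

The nowcast definition branches on whether the truth at $t-l$ was known
at issue time $t$. That depends on the application's reporting process,
so the branch takes a caller-supplied predicate `truth_known(s, t)`; the
default is a configurable fixed reporting delay (0 by default: the truth
is used whenever present). The forecast mode reuses the same mechanism
for the case where the truth at $t-l$ is unreported at $t-l$, falling
back to the nowcast-style value $x_{t-l|t-l}$.

## Ratio estimators

The ATC ratio is the concordant fraction
$\mu = \sum_t 1\{x^{\Delta}_t y^{\Delta}_t > 0\} / |\mathcal{T}|$ where
$\mathcal{T}$ is the set of considered pairs. Two conventions are fixed
deliberately:

- **Zero products.** The sign condition is strict, so a pair with
  $x^{\Delta}_t y^{\Delta}_t = 0$ counts in the denominator but never the
  numerator. Real data contain exact zeros ("no change" predictions);
  `zero_change_count` exposes how many, so users can assess sensitivity.
- **Inclusive exclusion boundaries.** A point exactly on an exclusion
  area boundary is excluded ($\leq$ in the set definitions).

Rolling estimates use a backward-looking window over the sequence of
*defined pairs*, not raw calendar time; calendar gaps therefore compress.
The signed ratios $\mu^{\pm}$ restrict the denominator to
$x^{\Delta}_t > 0$ (resp. $< 0$); they satisfy
$n^{+}\mu^{+} + n^{-}\mu^{-} = n\mu$ when no predicted change is exactly
zero, which the tests verify against brute-force recounts.

## Bootstrap confidence intervals

Pairs are resampled i.i.d. with replacement; serial correlation is
ignored (differencing removes most of it; a block bootstrap is left as
an extension). Percentile, basic, and BCa intervals are built from the
same bootstrap distribution; the basic interval is clipped to $[0,1]$
and flagged if clipping breaks the ordering around the point estimate.

BCa details: the bias constant $z_0$ uses the fraction of bootstrap
values strictly below the point estimate with ties counted half (and is
clipped away from 0/1 by half a resample weight); the acceleration comes
from the leave-one-out jackknife skewness. If the jackknife variance is
zero the interval falls back to percentile quantiles and is flagged
degenerate; a fully degenerate bootstrap distribution yields the point
interval. Resamples on which the statistic is undefined (empty
denominator under an exclusion area) are discarded and counted. The
exclusion area is *not* re-estimated inside resamples — the statistic
closure carries the thresholds fixed from the original sample, keeping
the estimand constant.

The estimators are ratios of indicator sums, so resampling is vectorized
over index matrices; arbitrary statistic callables are supported through
a per-resample loop on identical indices. scipy's independent BCa
implementation is used as a cross-check in the tests, never as the
implementation.

## Conditional ATC curve

$P(X^{\Delta}Y^{\Delta}>0 \mid X^{\Delta}=\chi)$ is estimated from a
product-Gaussian-kernel KDE of the pairs. For this kernel the half-plane
integrals are exact mixture sums — each kernel centred at $(x_i, y_i)$
contributes weight $\varphi((\chi-x_i)/b_x)$ and tail mass
$\Phi(\pm y_i/b_y)$ — so no quadrature tolerance exists, and the curve is
a weighted mean of values in $[0,1]$ by construction. Grid points where
the marginal density falls below $10^{-12}$ are emitted as NaN. The
default grid is 201 points between the 1st and 99th percentile of
$x^{\Delta}$, skipping $\chi = 0$ (where the quantity is undefined) and
any requested exclusion band.

Bandwidths come from statsmodels' `KDEMultivariate`: the likelihood
cross-validation selector (`cv_ml`) is the default and recommendation;
the covariance-based normal-reference rule (`rule_of_thumb`) is fast and
adequate for near-Gaussian samples but tends to oversmooth;
least-squares cross-validation (`cv_ls`) is available but slow and prone
to collapsing bandwidths, so it is never a default and a nonpositive
bandwidth raises. `cv_ml` is $O(n^2)$ per objective evaluation; for
samples beyond a few thousand pairs the reference rule (or fitting on a
subsample) is the practical choice.

For the correlated bivariate normal with covariance $[[4,3],[3,4]]$ the
exact curve is $\Phi(3|\chi|/(2\sqrt{7}))$: conditional on
$X^{\Delta}=\chi$, $Y^{\Delta}$ is normal with mean $3\chi/4$ and
variance $7/4$, and concordance flips sign with $\chi$, hence the
absolute value. (For $\chi > 0$ alone the formula is $\Phi(3\chi/(2\sqrt7))$
without the modulus; the symmetrized form is the correct concordance
probability for both signs and is what the package returns.)

## Probabilistic evaluation

The probability of increase is $p_t = 1 - F(y_{t-l})$ with $F$ the
predictive CDF ($F_{t|t}$ for nowcasts, $F_{t|t-l}$ for forecasts).
Quantile predictions are interpolated by the piecewise-linear CDF through
$(q_p, p)$ — uniform mass within each quantile interval — extended below
the lowest and above the highest quantile by spreading the remaining tail
mass uniformly over an interval the width of the nearest inner interval.
This construction reduces exactly to the even-spacing interpolation
formulas when levels are even-spaced and handles uneven level grids (the
common forecast-hub format) unchanged. Degenerate cases: if the nearest
interval has zero width (an atom at the extreme), the nearest *positive*
width is used; all-equal quantiles are treated as a point mass; a
reference value on an atom takes the upper level (right-continuous CDF)
with a warning. The resulting $p_t$ is continuous and nonincreasing in
$y_{t-l}$.

When the reference value itself is only known as a distribution, the
probability of increase is computed by Monte-Carlo: sample both
predictive distributions (assumed independent; a joint sampler hook
covers dependence) and count strictly positive differences.

Scoring: $z_t = 1\{y^{\Delta}_t > 0\}$ (exact zeros are non-increases),
Brier score $= \operatorname{mean}((p_t - z_t)^2)$ over the non-missing
scored times. Reliability tables default to quantile binning of the
predicted probabilities with ties kept in one bin; bins merge (with a
warning) when there are few distinct values, and with equal-width binning
empty bins are reported with count 0 and undefined frequency and are
skipped in plots.

## Synthetic generators

Scheme 1 draws $x^{\Delta}_t \sim N(0,1) + U(-10,10)$ and sets
$y^{\Delta}_t = x^{\Delta}_t n_t b_t$ with $n_t$ normal(1, 0.5) truncated
to $(0,\infty)$ (rejection sampling, so $y^{\Delta}=0$ never occurs) and
$b_t = +1$ with probability $k$ — read as $P(b{=}{+}1) = k$, the only
reading under which the construction has concordance probability $k$.
$t$ starts at 1. Variants: constant $k$; seasonal
$k_t = 0.75 + \sin(t/365.25\cdot 2\pi)/4$; asymmetric
$k(x) = 0.5 + \mathrm{clamp}((x{+}5)/10, 0, 1)/2$ with exact overall ATC
0.75. The bivariate normal scheme has ATC
$1/2 + \arcsin(\rho)/\pi \approx 0.7700$ at $\rho = 3/4$.

These generators produce serially independent pairs with known
concordance: they exercise the estimators, the bootstrap, and the KDE
under exactly the assumptions those methods make. They do *not* emulate
serial dependence, reporting artefacts, heavy-tailed noise, or systematic
missingness of real surveillance or monitoring data, so passing tests
validate correctness of the implementations, not robustness to those
features.

## Study scales and numerical choices

The bootstrap coverage study defaults to 1,000 replicate datasets with
2,000 resamples per interval at the 90% level over
$T \in \{30, 52, 168, 365, 720, 1024\}$ (500 replicates at $T = 1024$ in
the acceptance script); full scale (10,000/10,000) is a parameter away.
Every result carries its binomial Monte-Carlo standard error so reduced
runs remain comparable. Ground-truth concordance probabilities are
verified by streaming $10^8$-draw Monte-Carlo (chunked; standard error
$\approx 4\times10^{-5}$) against the closed forms. Bootstrap quantiles
use linear interpolation (`numpy.quantile` default). All randomness
flows from `numpy.random.Generator` seeds; fixed seeds give bit-identical
datasets, intervals, and coverage tables. Wall-clock comparisons between
bootstrap methods are reported in the coverage table (`seconds` column)
but never asserted — they are hardware-dependent.

## Known limitations

- No chance-corrected or class-imbalance-aware concordance measures
  (relevant when observed rises vastly outnumber falls, or vice versa).
- No time-series (block) bootstrap; intervals assume exchangeable pairs.
- No confidence bands on the conditional ATC curve.
- No Brier-score decomposition or CRPS.
- The conditional curve inherits KDE boundary/smoothing bias; with the
  reference-rule bandwidth expect a bias of a few hundredths at moderate
  $|\chi|$ for $n \sim 10^4$.
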