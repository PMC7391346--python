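# Methods

`moveseg` re-implements, as a tested pipeline, a behavioral-segmentation
analysis of satellite-tracked juvenile loggerhead turtles (*Caretta
caretta*) in the southern Tyrrhenian Sea: error-prone Argos locations are
regularized with a continuous-time movement model, 6-hr intervals are
classified into three behavioral states with a hidden Markov model over
movement and dive streams, and the decoded states feed post hoc analyses
of water temperature, distance to coast, bathymetry and space use. A
synthetic-data generator with known ground truth makes every stage
verifiable without the original tag data.

## Coordinate frame

All linear algebra (Kalman filtering, kernel densities, dead reckoning)
runs in a planar km frame obtained by a spherical azimuthal equidistant
projection centred on the capture area (38.5°N, 14.7°E). The study area is
about 10³ km across; the projection's distortion over that span is far
below Argos location error, and distances from the centre are exact by
construction. Longitudes/latitudes are recovered by the exact inverse
projection; the frame does not handle antimeridian crossings (the
supported seas never reach it). Great-circle step lengths use the
haversine formula with an atan2-form (Vincenty-type) spherical formula as
an independent cross-check in tests.

## Track regularization (CTCRW)

Each coordinate of the position process is the integral of an
Ornstein–Uhlenbeck velocity:

    dv = −β v dt + σ dW,   x(t) = x(0) + ∫ v ds

* `beta` — velocity autocorrelation rate, 1/h. Large β ⇒ velocity decorrelates
  quickly (nearly Brownian position); small β ⇒ persistent, smooth motion.
* `sigma` — velocity diffusion scale, km·h^−3/2; the stationary speed SD per
  coordinate is σ/√(2β).

The exact discrete transition over any gap Δt is linear-Gaussian, so the
irregular fixes form a standard state-space model with the fix's error
ellipse as measurement covariance. The ellipse (semi-major a, semi-minor
b, orientation θ from east) maps to Σ = R(θ)·diag(a², b²)·R(θ)ᵀ with the
axes treated as 1-σ extents by default; the scale factor is configurable
because the Argos literature uses several conventions, and the pipeline
report states the convention used. (θ measured clockwise from north is
available as an option.)

(β, σ) are estimated per animal by maximizing the Kalman prediction-error
likelihood on the log scale with quasi-Newton iterations from five spread
starts (tolerance 1e-10 on the objective). The initial state is a diffuse
prior: position centred on the first fix with variance 10⁴ km² per
coordinate, velocity at the stationary variance. Smoothed positions on
the exact 6-hr grid (anchored at the first fix, spanning first to last
fix) come from a Rauch–Tung–Striebel pass over the union of fix and grid
times; gaps are predicted across, and grid points more than 48 h from any
fix are flagged rather than dropped. Joint draws of the position process
("multiple imputation" of the track, 100 draws by default) use the
mean-correction simulation smoother: simulate an unconditional state and
observation path, smooth both the real and simulated observations, and
form `smoothed(real) + (simulated − smoothed(simulated))`, which has
exactly the conditional distribution.

## Interval summaries

Regular-grid positions give step lengths (great-circle km between
successive positions) and turning angles (signed change of successive
bearings, wrapped to (−π, π]; undefined for each track's first step).
Dives are assigned to the 6-hr interval containing their start; per
interval the pipeline records the dive count, maximum depth, summed dive
time, and proportionally split haul-out seconds. Temperature is
summarized in two stages: (mean, median, SD) over each dive's 17 profile
cut points, then the median of per-dive medians per interval. Intervals
without a temperature-carrying dive keep missing temperature — a missing
covariate is distinct from a zero dive count. The first 24 h after
release are excluded (post-release stress can bias behavior); on a 6-hr
grid that is exactly four intervals per animal.

## The 3-state hidden Markov model

Observations per interval: step length ~ Gamma, turning angle ~ von
Mises, dive count ~ Poisson, each with state-dependent parameters; a
first-order Markov chain with row-stochastic transition matrix Γ and a
free initial distribution δ shared across animals (each animal's track
restarts at δ; a stationary-δ option exists). The three states map onto
transit (long steps, straight, few dives), low-intensity diving, and
high-intensity diving (short tortuous steps, many dives). Optional extra
streams (normal or gamma families) allow the structural comparison of
models with and without covariates such as temperature via AIC; the
default model is the 3-stream one.

Fitting is direct numerical maximization of the forward log-likelihood —
not EM — over unconstrained working parameters: logs for positive
parameters, multinomial logits (diagonal-referenced rows) for Γ and δ,
and the pair (κ·cos μ, κ·sin μ) for each von Mises component. Multi-start
(25 by default): start 1 uses an N-quantile split of each stream's
observed values for initial moments, later starts perturb log-normally
(scale 0.4); each start runs a capped quasi-Newton exploration and the
best incumbent is polished to convergence. The forward recursion uses
per-step scaling with a per-interval max-shift of log-densities, compiled
with numba. Missing stream values contribute likelihood 1 for that
stream; undefined first turning angles are missing, as are angles across
multi-interval gaps. Zero step lengths (possible after smoothing) are
replaced by half the smallest positive step, with a warning, because the
Gamma density has no mass at zero.

Label switching is resolved canonically: states are reordered by
ascending Poisson dive rate, so state 1 is always "transit" and state 3
"high-intensity diving". AIC = −2·loglik + 2k with k the number of free
working parameters (23 for the default model).

Decoding: exact Viterbi (ties toward the lower state index) and
forward–backward posteriors; the posterior masses of states 2 and 3 are
merged into a single "diving probability". Model checking uses one-step-
ahead forecast pseudo-residuals (probit-transformed forecast CDFs; mid-P
for the discrete dive stream), with lag-1..10 autocorrelations and a
Jarque–Bera statistic; constant streams are flagged degenerate rather
than producing NaN.

Multiple-imputation fits are pooled by Rubin's rules on the working
scale: pooled estimate = mean of per-imputation working parameters;
total variance = within + (1 + 1/M)·between. Per-fit covariance matrices
are not propagated, so the within term is zero here and the reported
spread is the between-imputation component — the location-uncertainty
contribution that multiple imputation exists to capture. Fits are checked
for consistent canonical state ordering before pooling.

## Post hoc analyses

**Temperature.** A multinomial logistic (softmax) regression of the
Viterbi state on the interval's median water temperature, baseline =
transit, fitted by Newton–Raphson on the multinomial log-likelihood
(gradient ∞-norm < 1e-8), with Wald standard errors from the observed
information. Complete separation raises an error suggesting a small ridge
(1e-6) fallback. Intervals without dives (no temperature) are excluded. A
posterior-weighted (soft-label) variant can be built by resampling states
from the forward–backward posteriors; the default is hard labels.

**Distance to coast and bathymetry.** The coastline is the set of raster
cells adjacent to an elevation sign change; distance is the great-circle
distance to the nearest coastline cell centre (nearest neighbour found in
the planar frame with a k-d tree). Points over land are flagged. Activity
budgets are within-bin state proportions over closed-left bins [a, a+w),
default widths 10 km (coast distance) and 400 m (seafloor depth), with an
animal-exclusion filter to examine individual influence.

**Space use.** A Gaussian product-kernel density on the planar grid
(margin 3 bandwidths, cell ≤ bandwidth/3, ≥ 200×200 cells), with Scott's
reference bandwidth computed at the effective sample size
n_eff = n(1−ρ)/(1+ρ), ρ the mean lag-1 coordinate autocorrelation. This
is a deliberate, documented approximation to full autocorrelated KDE
(AKDE): tracks are not independent draws from the utilization
distribution, and the inflation widens the bandwidth accordingly, but no
variogram model is fitted and no area debiasing is applied, so areas are
not numerically comparable to AKDE software output. Home ranges are
smallest-area isopleths (75% by default: highest-density cells until the
level is enclosed); overlap is the Bhattacharyya coefficient
Σ√(f_A·f_B)·cellarea, computed on a common lattice (bilinear resampling
when grids differ).

## Synthetic data: what it emulates and what it does not

The generator's defaults are the study conditions: nine animals, 6-hr
intervals, the fitted transition matrix diag (0.86, 0.80, 0.86), step
means/SDs 8.152±3.27 / 6.2±2.0 / 5.3±1.5 km, turning-angle means 0.01 /
0.08 / −0.11 rad, Poisson dive rates 1.6 / 6.54 / 14.12 per 6 h. The
printed angle dispersions (1.4 / 1.85 / 1.91 rad) are interpreted as
circular SDs and converted to von Mises concentrations via the
wrapped-normal relation R = exp(−sd²/2), κ = A₁⁻¹(R); read as
concentrations instead they would order transit as the least directional
state, contradicting its description, so the circular-SD reading is used.
Argos ellipse axes are lognormal with (μ, σ_log) matched to the reported
mean and median of each axis — for the semi-major axis (mean 14,198 m,
median 4,637 m) this single choice also reproduces the reported SD
(~41,400 m), which supports the family choice; orientation is normal
(87.64° ± 30.41°) wrapped to [0, 180). Fix times are Poisson (mean 3 per
interval) at uniform positions within intervals, interpolated linearly
between true interval endpoints. Dives are placed uniformly within their
interval at whole-second unique start times; depths are lognormal
(median 25 m, ≥ 4 m — the tag's dive threshold), durations exponential
(mean 15 min). Temperature profiles follow base 19 °C + 3 °C seasonal
sine − 0.02 °C/m depth lapse + 0.3 °C noise, clipped to the sensor range
[−5, 35] °C; 17 cut points from the surface to the dive's maximum depth.
Haul-outs (≥ 5 min) occur only in transit intervals — a fixture
assumption for testability, not an inference. The island bathymetry is a
radially symmetric cone (peak 900 m, slope 30 m/km, floor −3,600 m), so
the coastline radius and distances have closed forms.

Not emulated: ocean currents, satellite orbital pass geometry, tag
saltwater-switch electronics, behavior-dependent fix availability,
spatial prey fields. Passing recovery tests therefore demonstrates the
estimators are correct under the stated model, not that the model is
adequate for any particular real dataset.

## Problem sizes and numerical choices

The main recovery experiment refits the HMM to 9 × 600 intervals (the
scale at which the transition-matrix diagonal is recoverable to ±0.03)
with 25 starts. The multiple-imputation recovery experiment uses 4
animals × 200 intervals with 100 imputations, warm-starting each
imputation's fit from the previous one (the first fit uses 10 starts) —
the standard practice for imputation refits, which also keeps the
experiment affordable. CTCRW parameter recovery uses 2,000 fixes.
Exhaustive-enumeration oracles are restricted to instances with
N^T ≤ 10⁵ paths. KDE closed-form checks use 5·10⁴ i.i.d. points so the
reference-bandwidth convolution bias (h²/σ² ≈ 2.7%) stays inside the 5%
tolerance.

Degenerate inputs: absorbing transition rows are legal (identity Γ gives
constant state paths); all-identical positions are rejected by the KDE;
no-data raster cells are NaN and propagate through interpolation;
duplicate Argos timestamps keep the first record (a deterministic rule
where no convention is established).

## Known limitations

* Bathymetry I/O reads ESRI ASCII grids only; regional rasters in other
  formats must be converted first.
* The KDE approximation is not AKDE: isopleth areas are comparable across
  animals within a run, not with AKDE outputs.
* The CTCRW has no land-avoidance or haul-out-informed stopping; tracks
  can be smoothed across land.
* Real AIC values depend on the real data; only structural model
  comparisons (2 vs 3 states, with/without temperature streams) are
  reproducible synthetically.
* δ is a free parameter shared across animals; per-animal δ is not
  implemented.
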