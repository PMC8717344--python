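# Methods

`gapcal` reimplements, at desk scale, a calibration workflow that connects
tree-ring basal-area reconstructions to an individual-based forest gap
model: a toy gap simulator with a synthetic-data generator, ring-width
processing, the fading-record observation proxy, a one-at-a-time (OAT)
sensitivity analysis, optimal-coring-year selection, and modularized
Kennedy–O'Hagan (KOH) Gaussian-process calibration with bias correction.
This note records the models, the defaults and why they were chosen, the
numerical choices, and what the synthetic experiments do and do not show.

## The gap simulator

Each tree is an individual with a diameter (DBH) trajectory. Annual
diameter increment uses the classic gap-model logistic kernel

    ΔD = g · m · D · (1 − D/Dmax) · f_site,   gated by GDD ≥ DDmin

where `g` is the species maximum growth scalar (yr⁻¹), `Dmax` the maximum
attainable diameter (cm), `f_site ∈ (0,1]` a single resource factor
standing in for light/water/nutrient limitation, and GDD the annual
growing degree-day sum Σ max(0, T_month − 5 °C) · days, computed from
monthly temperatures drawn from climate normals. `m` is a per-tree
lognormal growth multiplier (median 1, log-SD `growth_sd`, default 0.5)
representing individual vigor — microsite and genetic variation. It is
load-bearing: without it, an entire cohort crosses the stress threshold
(below) in the same year and the stress parameter acts as an
all-or-nothing cliff on the population instead of the graded response a
calibration needs.

Mortality has two components applied every year:

* background: probability `4.605/max_age`, the standard gap-model
  convention under which about 1% of a cohort reaches its species' life
  expectancy (`e^−4.605 ≈ 0.01`);
* stress: a tree whose increment falls below `dbh_min` (cm/yr) increments
  a stress counter (reset on a good year); once the counter reaches 2 the
  tree additionally dies with probability `p_stress` per year, constrained
  to the empirical range [0.21, 0.33] (default 0.27, the midpoint).

Stands start at bare ground; recruitment is Poisson (`recruit_rate`/yr)
at 1 cm DBH. Simulation years are 1-based; a tree recruited in year t has
its first DBH recorded at t. All randomness is seeded. Per-tree draws
(mortality uniforms, vigor) come from streams keyed by (seed, species,
tree index), so a tree's fate does not depend on how many neighbours are
alive: runs at different parameter values under one seed are coupled by
common random numbers (CRN), and the simulator behaves as a deterministic
function of the calibration parameters — the setting the surrogate
methodology assumes. Within-run BA bookkeeping satisfies
`BA_s(t) = Σ π(D/2)²` over alive trees exactly (tested to 1e−9).

### Default study conditions

Two boreal-spruce-like species on one site (resource factor 0.9,
interior-boreal climate normals):

| parameter | PIGL (fast) | PIMA (slow) | units |
|---|---|---|---|
| g | 0.065 | 0.045 | yr⁻¹ |
| dbh_min | 0.03 | 0.07 | cm/yr |
| max_age | 250 | 200 | yr |
| dd_min | 280 | 250 | degree-days |
| dmax | 60 | 45 | cm |
| p_stress | 0.27 | 0.27 | – |
| recruit_rate | 6 | 6 | yr⁻¹ |
| growth_sd | 0.5 | 0.5 | log units |

Growth scalars give diameter increments of a few mm/yr: a tree reaches
coreable size (10 cm) in roughly 40–60 years and approaches `dmax` only on
multi-century timescales, so a ~120-year record still responds to `g`.
The default synthetic coring year is 120, matching ~100-year field
records. `recruit_rate` = 6/yr yields ~15–30 coreable trees per species at
coring — more than the ~2–3 cores of a real plot; the surplus is a
deliberate identifiability choice, because single-tree granularity makes
the observable BA response a staircase. The calibrated parameters and
their uniform priors are `g` of the fast species (0.04–0.09) and
`dbh_min` of the slow species (0.04–0.10). The `dbh_min` prior is centred
on the window where sapling-stress mortality acts gradually on the vigor
distribution; below ~0.04 cm/yr the parameter is invisible in the
alive-tree subset because the weak trees it would kill die of background
mortality long before coring anyway.

## Ring processing

Basal-area increment uses the outside-in approach: the outermost ring year
is assigned the effective radius — the larger of the ring-width sum and
the measured radius `diam/2 − bark` — and earlier radii follow by
subtracting ring widths, so `BAI_t = π(r_t² − r_{t−1}²)` and the series
telescopes exactly to the disc area. Cores missing their outer ring
cannot be anchored and are excluded. Species totals are cumulative BAI
sums by year (the trajectory is growing stand basal area); trees
contribute from their innermost ring year, with no pith-offset
correction. Widths are stored in mm, areas in cm². Readers accept a tidy
CSV and Tucson-style decadal text (stop marker 999 → 0.01 mm units,
−9999 → 0.001 mm); malformed decadal lines fail with line numbers.

## Fading-record proxy

The alive-tree subset at candidate coring year c contains exactly the
trees alive in year c with DBH strictly greater than 10 cm, each
contributing its full own history back to its birth year. This mirrors
what coring can observe: trees that died before sampling left no record.
Subset BA is bounded by full-stand BA at every year, and the early-history
gap between them shrinks toward the coring year.

## Sensitivity analysis

For each species parameter, 8 equally spaced levels span a uniform prior
`[default − w, default + w]`; each run varies one parameter. Every
trajectory is reduced to its first-principal-component score (columns
centred, projection on the leading eigenvector, sign fixed so the
largest-magnitude loading is positive), and parameters are ranked by the
variance of their scores — PC1 summarises the dominant mode of trajectory
shape, so the parameter that moves trajectories along it most is the one
worth calibrating. Equally spaced levels (not random draws) make the
design reproducible and space-filling. Exact ties rank lexicographically
and are flagged.

## Optimal coring year

The field record is anchored in calendar time but not successional time.
Every candidate simulation year c is scored by comparing the field record
against the alive-tree subset at c, aligned at the coring date. Scoring
choices that matter, each adopted after measuring recovery on synthetic
truth:

* **Common span.** Every candidate is scored on the same observations —
  the field record's ring-bearing years (leading sub-noise-floor years
  trimmed). A candidate younger than the record has its subset
  left-padded with zeros (no stand existed before bare ground). AIC
  values are then comparable across candidates; comparing fits with
  different sample sizes trivially favours short overlaps.
* **Candidates ≥ chronology age.** A stand is at least as old as its
  oldest surviving ring record, so younger candidates are not scanned.
* **Log scale with noise-floor censoring.** Both series are censored at
  `max(1 cm², 3σ_ε)` and log-transformed. The log scale gives the young,
  small-BA end of the record — where candidate ages differ most — equal
  weight with the mature end; censoring stops clipped noise from
  masquerading as old-stand early basal area.
* **Offset, not regression.** The subset enters with slope fixed at one:
  field and subset are the same physical quantity in the same units. A
  free slope or intercept absorbs the level information that
  distinguishes stand ages.
* **Ridge-penalized smooth.** The residual log-ratio is smoothed by a
  B-spline basis (df 10) under a ridge penalty (α = 10) on *all*
  coefficients. A conventional curvature penalty leaves linear trends
  unpenalized, and a free trend absorbs exactly the successional signal;
  the ridge does not. AIC = 2·edf − 2·llf with edf the trace of the
  smoother matrix and a Gaussian log-likelihood whose scale is floored at
  1e−12 so exact fits stay finite.

Species AICs are summed per candidate; the per-simulation argmin years
(ties → earliest, flagged; AIC ranges under ~2 points flagged unstable)
are combined across an ensemble of stands by their median — the optimal
coring time, which doubles as a stand-age estimate. With noiseless
records, median recovery errors on synthetic truth are ≤ 8 years; at
noise ≥ 0.5% of peak BA the estimator acquires a +10–15-year bias (the
candidate space is one-sided and the early-record signal drowns), a
known limitation. The default synthetic noise for this experiment is
0.1% of peak — generous relative to actual ring-measurement error
(0.001-mm width precision), since the dominant observational error, the
fading record, is modeled explicitly by the proxy.

The stand-age experiment cores stands of known ages (60–180 yr) and
compares chronology age (longest ring record) with the estimated stand
age: the estimate tracks the truth while the chronology age increasingly
underestimates it, reproducing the fading-record stand-age bias pattern.

## Kennedy–O'Hagan calibration

The field record is modeled as the simulator at the best input plus a
smooth discrepancy and white noise: `Y_F(t) = y_M(t, u*) + b(t) + ε`,
`ε ~ N(0, σ_ε²)`.

**Design.** 36 parameter points from a Latin hypercube (exactly one point
per equal-width stratum per margin). Each design run shares the
simulation seed (CRN); its alive-tree subset at the coring year is
sampled on an 8-year stride, giving ~540 training points over
(year, u₁, u₂).

**Surrogate.** A zero-mean (output-centred) GP with inputs standardized
to [0,1] by the design bounds. Kernels: Matérn-5/2 (default) or squared
exponential, both with per-dimension ranges θ (units of squared length;
the squared-exponential correlation is `exp(−Σ Δx²/θ_k)`) and a relative
nugget ν with a strictly positive floor of 1e−8 (the deterministic-
simulator jitter convention). Hyperparameters maximize the concentrated
marginal likelihood (signal variance profiled analytically) by L-BFGS-B
on log parameters. Heteroskedastic mode, the default for noisy targets,
smooths log squared leave-one-out residuals over the time input
(Nadaraya–Watson, bandwidth 0.1) into relative noise multipliers that
scale the nugget before a final refit — capturing the growing spread of
gap-model trajectories over succession. Cholesky factorizations escalate
diagonal jitter (1e−8 ×100 steps) if needed.

**Likelihood surface.** For each cell of the 20×20 grid (400 candidate
parameter pairs; the 36-run design covers 9% of them), the frozen
surrogates predict each species' trajectory at the field years, and a
zero-mean GP over time is fitted to the residuals `Y_F − ŷ`: Matérn-5/2,
GLS-profiled intercept (a constant offset in the residuals is absorbed
exactly, so the score depends on trajectory shape), signal variance
concentrated, and (range, nugget) maximized over a fixed log-spaced grid
(ranges {0.01, 0.04, 0.16, 0.64, 2.56} on the squared standardized
record — 0.04 is the (1/5-record-length)² smoothness prior — and nuggets
{1e−8…1}). The gridded fit makes the 400-cell scan deterministic and
cheap: each range's eigendecomposition is computed once and reused for
every cell and nugget. The cell NLL is the residuals' negative log
marginal likelihood; per-species surfaces are summed (the toy simulator
has no interspecific competition, so each species' surface is flat along
the other's axis and only the joint sum localizes both parameters). The
arg-min cell is û (ties → first in row-major order, logged). Field and
surrogate are compared on the surrogate's training-year grid; between
those years the surrogate only interpolates in time, so scoring them
would measure interpolation error, not parameters.

**Bias correction.** At û the residual GP supplies the bias mean b̂(t),
its pointwise variance, σ̂_ε² (signal variance × nugget), and the bias
square error (mean b̂²). The corrected prediction is `ŷ(t|û) + b̂(t)` with
95% intervals `±1.96·√(surrogate var + bias var + σ̂_ε²)`.

**Closed-loop validation.** A truth cell is drawn uniformly on the grid,
the simulator generates the field record there through the proxy, and
the pipeline must return it. Noise-free: the generating run is appended
to the design and the nugget pinned at the floor, so the surrogate
interpolates it and exact recovery checks the self-consistency of the
whole likelihood pipeline (under CRN the subset response is piecewise
constant in `dbh_min` — adjacent grid cells can be literally identical —
so exactness is only meaningful when the truth trajectory is pinned).
Noisy (σ_ε = 5% of each species' peak BA): the pure 36-run Latin
hypercube with ML-fitted heteroskedastic nugget, compared on every
observed year, with the bias GP run in known-noise mode (σ_ε is known by
construction in the synthetic study, so candidates cannot explain misfit
as extra noise).

Measured resolution of the noisy closed loop: the growth axis (`g`)
recovers within one grid cell in essentially every seed; the stress axis
(`dbh_min`) typically lands within two to three cells, so the joint
within-one-cell-per-axis rate is only ~50–70% of seeds. Two mechanisms
cap it, both diagnosed directly: (i) information — near plateaus of the
subset response, adjacent `dbh_min` cells differ by less than the noise
(trajectory RMS differences of ~30 cm² against a 400–650 cm² noise SD),
so no estimator could separate them; (ii) surrogate resolution — with 36
design points on a response built from single-tree steps, the GP's
interpolation error near the prior edges (~1300 cm² RMS in the worst
diagnosed case) can exceed the cell-to-cell signal. More design points
or replicated design runs would lift (ii); (i) is intrinsic to
calibrating a ~15–30-tree stochastic stand at this noise level.

## Problem sizes and determinism

Default experiment sizes — 120–200-year stands, ~700–1300 trees, 36-run
designs, 20×20 grids, ensembles of 8–20 stands, 5–20 replicate seeds —
were chosen so the full synthetic validation runs in minutes on one core.
Every stochastic stage draws from `numpy` SeedSequence streams spawned
from one master seed, so results are bit-reproducible and enlarging one
stage never perturbs another's draws.

## What the synthetic experiments do not show

The generator emulates multi-tree ring series, fading-record observation,
additive noise and smooth bias, but not: interspecific competition (the
two species are resource-independent; in a real gap model u₂ would leak
into species 1's trajectory), permafrost or nitrogen dynamics, climate
trends (normals are stationary), cross-dating error, or real sites' small
core counts (~2–3 trees). Passing recovery tests therefore demonstrates
that the statistical machinery is correct and internally consistent, not
that a 23-parameter forest model calibrated against 2-core records would
be identifiable. The multi-modal likelihood surfaces and partially
overlapping subsets reported for the real system are expected to be
harder than this toy setting; the coring-year noise sensitivity noted
above is one concrete instance.
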