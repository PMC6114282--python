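# Methods

This note documents the models and procedures implemented in `premolt`, the
assumptions behind them, the parameters that matter, and what the synthetic
test bed does and does not establish about real tracking data.

## Geodesy and coordinate conventions

All coordinates are WGS84 decimal degrees, longitude in (−180, 180], all
times UTC.  Distances are spherical great-circle distances (law of cosines)
on a sphere of radius 6 378 137 m, the default of the `distCosine`-style
functions conventionally used in Argos track processing; no ellipsoidal
correction is applied, so distances are reproducible in convention rather
than maximally accurate (~0.3 % spherical error).  Local planar work —
kernel estimation, track simulation, coastline distances — uses a spherical
azimuthal-equidistant projection centred on the colony, which renders
distances from the centre exactly and keeps distortion negligible over the
~2 500 km region of interest.

## SDA filtering

The speed-distance-angle filter removes implausible Argos fixes in three
stages, iterated to a fixpoint so the retained set satisfies every
criterion on re-scan and the filter is idempotent:

1. class-Z fixes are dropped (configurable);
2. *speed stage* (McConnell): the non-endpoint fix with the largest
   root-mean-square of segment speeds to its two preceding and two
   succeeding retained neighbours is removed while that RMS exceeds
   `vmax` (default 2.0 m/s, a mean penguin swimming speed).  Ties go to
   the later fix; near track ends the RMS uses the neighbours available.
3. *spike stage*: a non-endpoint fix is removed when its internal turning
   angle (angle at the fix between great-circle bearings to the adjacent
   retained fixes; 180° = straight, 0° = full reversal) is below 15°/25°
   while both adjacent steps exceed 2.5/5 km.

Track endpoints are never removed; fixes are removed, never relocated.
Coincident points are treated as straight continuation (angle 180°), so
duplicate positions can never register as spikes.

A caution established by the synthetic experiments: with realistic class
A/B location errors (5–10 km) and several fixes per day, apparent
between-fix speeds from location error alone routinely approach 2 m/s, so
the filter removes an appreciable share (~10–25 %) of legitimate A/B fixes
along with essentially all gross outliers.  This mirrors the behaviour of
the filter on real Argos data, where retention rates around 80 % are
typical, and is a property of the method, not an implementation artefact
(with location noise disabled the filter removes nothing but injected
outliers).

## Daily aggregation

One record per bird per UTC calendar day: the arithmetic mean of the day's
fix times in epoch seconds, and the geographic mean position computed by
averaging unit 3-vectors and renormalizing (antimeridian-safe; degenerate
antipodal sets raise).  Daily steps carry the great-circle distance, the
elapsed time between mean times, and a gap-safe `km/day` rate defined as
step distance divided by the whole-day date difference — this keeps
"daily travel distance" well defined across days without fixes, which the
source material leaves implicit.  No interpolation or regularization is
performed.

## Trip segmentation

- **Final departure**: the first day of the last maximal run of days
  further than 20 km from the colony that spans at least 3 days.  Shorter
  earlier runs are pre-departure foraging sorties and are excluded from
  trip statistics; a return to within the 5 km coastal buffer after the
  qualifying run is the landfall that ends the trip.
- **Trip reversal**: the day of maximum great-circle distance from the
  deployment site, earliest day on ties.  If the maximum falls in the last
  three records and the mean distance of those records exceeds the mean of
  the three before them, the track is still receding and no reversal is
  declared.
- **Landfall**: the first post-reversal day within 5 km of the coastline,
  evaluated in the colony-centred projected plane.
- **Destination**: STF if the maximum-range position lies north of a
  configurable front boundary latitude (default −52°), else SAF.  A fixed
  boundary rather than clustering keeps the rule auditable; the default
  separates the two published destination groups exactly.
- **Durations** are whole-day calendar differences; this is the only
  convention consistent with all five published complete-trip durations.
  `outward_days` is reversal − departure and `inbound_days` is
  landfall − reversal; published per-bird inbound day counts follow an
  unstated convention and do not all equal landfall − reversal, so they
  are not used as targets.

Cohort statistics are medians (even n: mean of the central pair), minima
and maxima over the subset of birds for which each quantity is defined;
date medians are computed on day offsets and converted back.  Undefined
subsets yield no statistic rather than zero.

## Kernel densities

Phase point sets: outward = daily positions from departure to reversal of
birds with an observed reversal; inward = positions after reversal up to
landfall for birds that reached the coast.  Densities are bivariate
Gaussian KDEs on projected kilometres with Silverman's reference bandwidth
(a fixed isotropic bandwidth is available for sensitivity checks; the
bandwidth used by the original GIS tooling is unknowable, so isopleth
*areas* are treated as qualitative).  The q % isopleth is the smallest
region containing q % of the density mass: cell masses on a 25 km
evaluation grid are sorted descending and accumulated to the threshold,
and the isopleth polygon is the union of the selected cells.  This makes
mass accounting exact by construction, guarantees nesting, and is verified
to be stable (< 5 %) under halving the cell size.

## Trip-parameter models

Each trip parameter (departure date, maximum range, median daily travel
distance, duration, trip length) is modelled as
`parameter ~ destination + sex + (1 | bird)` with reference levels SAF and
female.  Every bird contributes exactly one observation, so the
random-intercept variance cannot be separated from the residual; the fixed
effects then coincide with ordinary least squares, which the implementation
solves directly and the tests confirm against an independent
normal-equations fit (statsmodels OLS) at 1e-6 relative tolerance.  The
variance decomposition is flagged non-identifiable rather than reported.
Standard errors, t and p use the small-sample t convention with residual
degrees of freedom n − 3 (6 for the nine-bird models, 2 for the
five-bird models).  Date responses are converted to day offsets from an
arbitrary origin (which cancels in all non-intercept effects) and the
intercept is converted back to the nearest day.

Duration and trip length are restricted to complete trips.  Refitting the
models to the packaged per-bird table reproduces the published estimates
to the printed decimal for all blocks except the trip-length STF
coefficient, where the published value is inconsistent with the exact
least-squares solution of the published per-bird trip lengths (−1 829.1
computed vs −1 823.1 printed, with the other two coefficients of that
block matching); it is therefore excluded from the reproduction targets.

## Travel-rate smooth

Daily travel rate (km/day) over relative trip time t ∈ [0, 1] (days since
departure divided by trip duration) is smoothed with a penalized cubic
B-spline (12 uniform interior knots, second-difference penalty) plus
per-bird intercepts shrunk by a ridge penalty — the ridge-penalized bird
offsets are the random intercepts of the mixed formulation.  The smoothing
parameter is selected by generalized cross-validation over a log-spaced
grid; bird offsets are recentred to weighted mean zero with the mean
absorbed into the spline (a B-spline basis sums to one, so a constant
shift is exact).  On synthetic data from a known U-shaped mean curve with
bird offsets (5 birds × 60 days), the fitted curve recovers the truth
within 10 % RMSE of the curve range.

## Environmental stack and K-select

Layers are composited over the destination time window by cell-wise means
that ignore masked cells (32-day windows; 5-day sea-level-anomaly products
averaged to match; climatological mixed-layer depth exempt from
compositing).  Slope is the Horn 3×3 gradient magnitude of the depth field
in m/km; current speed is the cell-wise norm of the u/v components.  All
layers are resampled to one equal-area analysis grid (57.4 km cells, the
coarsest native resolution among the source products) by bilinear or
nearest-neighbour interpolation with mask propagation.

K-select measures per-animal habitat selection at the trip destination,
using daily positions within ±10 days of the reversal date:

1. variables are standardized to weighted zero mean and unit variance over
   the pooled availability (each animal's availability weighted by that
   animal's weight);
2. each animal's marginality vector is its mean used conditions minus mean
   available conditions in that space (used cells counted once per daily
   position, so usage intensity multiplies; availability is every
   non-masked cell within 300 km of the animal's destination-window
   centroid — the source material does not define availability, and a
   destination-local disc matches its verbal description);
3. animal weights are proportional to relocation counts;
4. the weighted cross-product of marginality vectors is
   eigen-decomposed (non-centred weighted PCA).  Eigenvector signs are
   fixed deterministically (largest-magnitude loading positive).

The eigenvalue sum equals the weighted mean squared marginality norm
(trace identity, asserted at 1e-9), axes are orthonormal, and depth keeps
its negative-down sign so a preference for shallow water appears as a
positive depth-direction marginality.  An optional permutation test of
per-animal marginality strength (resampling used points from availability)
is provided but off by default, as no test statistics are part of the
reproduction surface.  Two retained axes are a default, not a result: the
published share of marginality on axes 1–2 (81 %) depends on the real
tracks and rasters and is not reproducible from synthetic inputs.

## Synthetic data: what it does and does not emulate

Tracks are three-phase correlated random walks in the colony-centred
plane: outbound in a corridor around a south-westerly heading (default
230°, daily distance drawn per bird from 40–80 km/day), a 10–20 day loiter
at the destination drifting slightly outward (so the true maximum range
falls inside the loiter window), and an inbound leg back to the colony,
with two short pre-departure coastal sorties (25–40 km, a free parameter)
separated from the final departure by colony days.  Within a day the bird
holds its anchor for the first half and relocates over the second half,
keeping true speeds below the filter threshold.  Two destination regimes
(~1 500 and ~2 200 km) and the observed censoring mix (5 complete : 4
inbound-incomplete : 8 outward-incomplete of 17) are assigned per bird.
Fix counts are uniform on 1–8 per day with a class mix giving ≈49 % A/B
fixes; location error is isotropic bivariate normal with class-dependent
scale (150 m to 10 km per axis) and heavy tails (5 % of draws at 5×
scale); a configurable fraction of fixes is displaced 50–500 km as gross
outliers.  One RNG stream per bird is derived from (seed, bird index), so
cohorts are bit-reproducible and stable under parallel generation.

The environment generator produces co-registered layers with controllable
structure (SST gradient with two front steps, patchy chlorophyll
optionally elevated along one front, Gaussian-eddy SLA whose gradient
drives current speed, a ridge/seamount chain, smooth MLD).  It makes no
attempt at mechanistic realism: no tides, wind, advection of the
chlorophyll field, or behavioural foraging responses.  Consequently the
synthetic tests establish *algorithmic* correctness and recovery of known
ground truth under stated noise — not ecological validity of any
particular parameter estimate on real data.

## Numerical choices and degenerate inputs

- Antipodal great-circle pairs return πR exactly; NaN coordinates raise.
- Geographic means of sets with (numerically) zero resultant raise rather
  than returning an arbitrary point.
- Median of an even number of values is the mean of the central pair.
- KDE requires ≥ 10 distinct points; degenerate (all-identical) point sets
  raise.
- Zero-variance environmental variables over availability raise naming the
  variable (with a scale-aware tolerance).
- Filter ties in the speed stage remove the later fix; tracks with fewer
  than three fixes pass through unchanged.

## Problem sizes

The packaged test bed uses a 20-bird cohort (~100 days × 1–8 fixes/day,
~9 000 fixes) for filter and segmentation recovery, 300-point densities
for kernel checks, 8 animals × 150 availability cells for K-select
properties, and 5 birds × 60 days for travel-rate recovery — sizes chosen
to match the scale of the study cohort while keeping the full suite fast.

## Known limitations

- No state-space smoothing (Kalman/CRAWL): filtering only removes fixes.
- No behavioural state inference; segmentation is purely geometric.
- Ellipsoidal geodesy, bandwidth cross-validation, autocorrelated-error
  smooths, and model selection machinery are out of scope.
- The availability definition (300 km destination disc) is one defensible
  choice among several; loadings can shift under a different availability
  design.
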