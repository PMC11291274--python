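# Methods

This note documents the models, numerical choices and limitations of the
`gdemapper` pipeline: what each stage computes, what the synthetic
landscapes do and do not emulate, and where the design was genuinely
open.

## Grid model and geodesy

All gridded quantities are north-up lon/lat (WGS84 datum) rasters with
square cells, a north-west-corner origin and a nodata sentinel
(−9999.0, matched by exact equality). Pixel coordinates are 0-based,
row-major, and refer to pixel centers. Projected grids are out of scope.

Cell areas use the spherical-quadrangle formula
`A = R² · Δλ · (sin φ_top − sin φ_bot)` on the authalic sphere
(R = 6371.0072 km), with edge latitudes clamped to ±90°. Summed over a
global grid this reproduces 4πR² to machine precision, which is what
makes the area-weighted statistics downstream exactly conservative.

Focal means use a Euclidean-radius footprint of pixel centers; radius
1.5 px is the 8-connected 3×3 neighbourhood plus center. Border windows
shrink to the in-grid cells. In `fill_only` mode valid pixels pass
through unchanged, which makes DTG gap-filling idempotent.

Block aggregation to area density divides the geodesic area of 1-pixels
by total block area (nodata included; a `valid_denominator` switch uses
valid area only, and the layer name records which was used). Trailing
partial blocks are computed over their actual extent, so
`Σ fraction × block area = Σ 1-pixel area` holds to 1e-9 relative.
The density layer reported by the drivers is *GDE-classified area /
total cell area*; analysed-area density can be produced the same way
from the extent mask.

Rasters are stored as single-band ESRI ASCII grids written with `%.17g`,
so write→read round-trips are lossless; points are CSV
(`lon,lat,label,source,region`, labels restricted to GDE/NONGDE) and
polygons GeoJSON (rings must be explicitly closed).

## Analysis extent

The extent is the pixelwise conjunction of three binary masks:

* **climate** — classes B, Csa, Csb, Csc of a declared vocabulary are
  dryland; mapping real Köppen–Geiger codes onto it is the caller's
  responsibility;
* **land cover** — cropland, built-up and open water are excluded. One
  collapsed land-cover layer stands in for the separate agricultural/
  urban and ocean products a global run would use;
* **depth to groundwater** — pixels deeper than 30 m are excluded, with
  the boundary *inclusive* (exactly 30 m is in).

DTG gap-filling runs in three steps: open-water pixels → 0; remaining
gaps → 1.5-px focal mean of valid neighbours; anything still missing →
0. The zero-fill is applied to *all* remaining gaps by default (the rule
is stated unconditionally in its source), with a stricter
water-adjacent-only variant behind a flag. Valid input values are never
altered. The order of the three masks is irrelevant to the conjunction.

## Predictor variables

**Spectral indices.** NDVI = (NIR−R)/(NIR+R), NDMI = (NIR−SWIR1)/
(NIR+SWIR1), NDWI = (G−NIR)/(G+NIR), MSAVI = (2·NIR+1−√((2·NIR+1)²−
8(NIR−R)))/2. Zero denominators and negative radicands map to nodata.

**Observation screening.** Scenes with cloud fraction strictly above 20%
are dropped whole; in retained scenes, cloud/shadow/snow pixels become
nodata in the reflectance bands, and LST pixels with uncertainty
strictly above 5 °C are dropped. Both rules use strict ">" so the stated
boundary values (20%, 5 °C) are retained.

**Dry-season statistics.** The dry season is 1 July–30 September in the
northern hemisphere and 1 January–31 March in the southern, chosen per
pixel by latitude sign (the equator row counts as northern). Per pixel:
annual value = mean of valid dry-season observations that year; the
multi-year mean averages the annual values; the CV divides their sample
standard deviation (n−1; a `ddof=0` switch gives the population form) by
their mean, reported as a magnitude. Pixels whose mean is below 1e-6 in
magnitude, or with fewer than two years of data, get CV nodata. Years
with no valid observation at a pixel are simply absent from that pixel's
average rather than invalidating it.

**ETaP** is the mean over years of annual transpiration sum / annual
precipitation sum — the mean of annual ratios, not the ratio of pooled
sums (the two differ under interannual variability). Each year used must
be calendar-complete in both series; zero-precipitation years drop from
a pixel's mean.

**CTI** = ln((upstream_count + 1) · A_cell / tan β). Slope comes from
Horn's 3×3 operator with metric, latitude-aware spacing (edges use
replicated padding); flow accumulation is single-direction D8 steepest
descent with drops scaled by pixel distance (diagonals √2), ties broken
to the lowest neighbour index in a fixed enumeration, and cells with no
lower neighbour acting as sinks. Processing cells in decreasing
elevation order is a valid topological order because flow requires a
strictly positive drop. tan β is floored at 0.001 so flats stay finite.
The algorithm is validated through ordinal properties (valley > ridge,
contour invariance) rather than against a reference dataset, since no
specific CTI algorithm is prescribed by the source data it emulates.

**LST spatial anomaly.** Per observation, a pixel's anomaly is the mean
over three scales of (LST − windowed mean LST), with square windows of
side 270, 2,700 and 5,400 m. The stated window sizes carry an "m²" unit
in their source, which cannot be meant literally (270 m² is sub-pixel at
30 m); they are read as side lengths, giving 9/91/181-pixel windows at
the nominal 30 m pixel, with even pixel spans rounded up to odd so a
center exists. Open-water pixels are excluded from every window mean and
are nodata in the output. Window means use clipped integral-image box
sums (valid pixels only), then the per-observation anomalies go through
the same dry-season annual-mean/multi-year-average machinery as the
indices. The temporal window for the anomaly is assumed identical to the
index dry-season window.

## Classifier

Training points carry predictor vectors sampled at their containing
pixel; points with any nodata predictor are dropped and counted, never
imputed. The 80/20 split is stratified by class and deterministic per
seed.

The ensemble is scikit-learn's random forest behind the module surface,
with the published configuration as default: 40 trees, 5 candidate
variables per split, minimum leaf population 2, bag fraction 0.7
(bootstrap with replacement), and a 3,010-node cap per tree. The node
cap maps to `max_leaf_nodes = ⌈3010/2⌉ = 1505` because a binary tree
with L leaves has 2L−1 nodes; the split criterion is Gini (not
prescribed by the source platform; documented here). Out-of-bag error is
1 − OOB accuracy.

Per-pixel probability is the **fraction of trees voting GDE**, computed
tree by tree (each tree votes its majority class at the reached leaf) —
not scikit-learn's `predict_proba`, which averages leaf class
proportions and differs from vote counting whenever leaves are impure.

The binary map codes GDE = 1, non-GDE = 2, nodata outside the extent.
Probability exactly at the threshold maps to GDE (≥, chosen so the
stated 50% threshold includes its own value). The dynamic threshold
sweeps {0.00, 0.01, …, 1.00}, maximises validation accuracy, and breaks
ties to the smallest threshold. Validation reports a 2×2 confusion table
with accuracy, precision and recall (GDE positive); zero-denominator
ratios are NaN, not 0.

Species-level label consensus: a species is GDE when ≥ 2 regions flag it
as a phreatophyte, non-GDE when ≥ 3 flag it as not one, otherwise
unlabelled and excluded. If both rules fire simultaneously the GDE rule
wins — rule precedence is not prescribed and this choice is flagged to
users. Externally supplied validation point sets (e.g. literature-derived
points generated inside polygons) are supported as validate-only inputs
and never enter training.

Regional cross-validation retrains with one region's points held out
entirely and validates inside it. The distribution overlap index is the
summed per-bin minimum of two relative frequency histograms on shared
bins (Freedman–Diaconis bin count on the pooled sample, shared range);
it is symmetric, 0 for disjoint samples and exactly 1 for a sample
against itself. Note the estimator has a finite-sample floor: even two
IID samples from the same distribution score ≈ 0.95 at n ≈ 10⁴ because
per-bin counts fluctuate. Hyperparameter search is exhaustive over a
user-supplied grid, scored by held-out accuracy on an internal
stratified split, ties to fewer trees then fewer variables per split.

## Storage trends and area summaries

Groundwater storage anomalies are recovered by subtraction:
GWS = TWS − SM − SWE − canopy (cm equivalent water thickness, aligned
monthly series). Trends are least-squares slopes of the anomaly on
decimal time over April 2002–April 2022, with annual and semiannual
harmonics co-estimated. The harmonics matter: with discrete monthly
sampling, a pure seasonal sinusoid is *not* exactly orthogonal to time —
a raw slope-on-time fit aliases ~0.01–0.02 cm yr⁻¹ of a 2–3 cm seasonal
cycle into the trend even over whole years — whereas the harmonic fit
recovers planted trends to machine precision on noiseless series
(`seasonal=False` gives the raw fit). Decimal time is month-resolution
(year + (month−1)/12), exactly uniform for monthly series. Missing
months are simply absent from the fit; fewer than 24 in-window months is
an error. "Declining" is sign-of-slope only; the slope standard error is
returned for users who want significance filtering.

Area summaries weight by GDE density × geodesic cell area. The
declining-storage fraction excludes cells without trend data from both
numerator and denominator ("among areas with available data") and is
invariant to uniform density rescaling. The covariate-overlap statistic
uses strict exceedance of the cutoff. Protection categories
(unprotected / protected-area only / policy only / both) partition GDE
area exactly; only polygon protected areas are supported (point records
are excluded, as in the source inventory). Zone membership is
cell-center containment under the geometry library's even-odd rule.
Density must be supplied at the trend grid's resolution — the functions
refuse silent resampling; an explicit `aggregate_fraction` call is
required, which keeps area accounting exact.

## Synthetic landscapes

`generate_scene` builds a 200×200-pixel (1 arcsec ≈ 30 m), 6-year scene
by default, with three dry-season and three wet-season observations per
year. Components draw from independent generator streams spawned from
the master seed, so adding a component never perturbs the others; a
fixed seed reproduces a scene bit for bit.

GDE truth is placed as a mix of random-walk riparian corridors dilated
to 1–3 px, 1–2 px spring discs, and smoothed-noise blob patches —
fragmented-versus-contiguous geometries without any claim of realism.
Patches accumulate until the requested areal fraction is met; the last
patch is trimmed so the realised count tracks the target within a few
percent. Truth avoids masked land-cover blocks and the humid corner, and
always sits over water tables shallower than 30 m.

A single `contrast` knob scales every GDE-vs-matrix difference:

* dry-season NIR raised and SWIR1 depressed by `contrast × noise_sd`
  (default noise_sd 0.05 reflectance);
* LST lowered by 2 °C per unit contrast;
* the annual transpiration/precipitation factor is 0.65 on the matrix
  and 0.65 + 0.30 × contrast on GDE pixels (1.25 at the default
  contrast 2 — above the ETaP = 1 groundwater line, while the matrix
  stays below);
* the DEM is carved down along GDE features in proportion to contrast,
  so the topographic-wetness signal points at them.

At contrast 0 every predictor is statistically identical between truth
and matrix, which provides the chance-level control. Wet-season
observations are emitted with no GDE advantage, so dry-season
compositing must actually select. Interannual wobble is shared across
pixels, which leaves GDE pixels with a lower CV simply because their
means are higher.

Two noise structures are deliberate: smooth spatial fields (soil
brightness, thermal terrain, climate gradients) give the landscape
realistic autocorrelation, and *persistent* per-pixel band offsets
(soil/canopy texture, 0.8 × noise_sd per band, 0.5 °C for LST) are
identical in every observation, so temporal compositing cannot average
them away. The persistent term is what keeps the spectral indices
honest, moderately noisy separators while ETaP and the thermal anomaly —
the distinctive groundwater signatures — carry most of the ensemble's
feature importance, as they should.

What the simulator does **not** emulate: radiative transfer, orbital
geometry and revisit patterns, sensor point-spread functions, mixed
pixels, cross-sensor harmonisation, real geography or real effect
sizes — the contrast scalings are testability choices, not estimates of
real GDE separability. Passing tests therefore demonstrate that the
pipeline recovers structure *of the kind assumed*, at separations that
are generous compared to real scenes; they say nothing about accuracy on
real imagery. The default contrast 2 regime is easy by construction
(held-out accuracy ≈ 1), which is intended: the acceptance checks are
about the machinery being correct, and the contrast 0 control confirms
the machinery finds nothing when nothing is planted.

Storage series plant a groundwater trend plus annual sinusoid plus white
noise; soil moisture, snow and canopy are independent zero-trend
seasonal series and TWS is their exact sum, so decomposition recovery is
exact by construction. The default 241 months span April 2002–April
2022, matching the trend-reporting window.

Labelled points sample uniformly within strata (truth pixels → GDE;
in-extent non-truth, non-barren pixels → non-GDE; barren pixels →
non-GDE absences, mirroring barren-area absence sampling) at pixel
centers, tagged with a quadrant region label for regional
cross-validation. Requesting more points than a stratum holds is an
error naming the stratum.

## Problem sizes

The shipped analyses and tests run at 200×200 pixels (unit tests 80×80),
6 years × 6 observations, 10³ points per class, 10-seed Monte Carlo for
end-to-end checks and 200 seeds for scalar trend recovery. These sizes
were chosen so the full suite exercises every stage, including the
slowest (the 181-px-window LST anomaly over 36 observations), in tens of
seconds on one CPU; all statistics of interest are already stable at
these sizes.

## Known limitations

* Vote-fraction probabilities are quantised to 1/n_trees (1/40 by
  default), so dynamic thresholds are only meaningful to that
  resolution.
* OOB error with 40 trees occasionally leaves a few training points
  without any out-of-bag vote; scikit-learn scores them by majority
  fallback, a negligible effect at the shipped sizes.
* The overlap index inherits the histogram floor described above;
  comparisons near 1.0 should be read as "indistinguishable at this
  sample size", not as exact identity.
* CTI uses single-direction D8 flow; dispersive algorithms (D∞, MFD)
  would shift absolute values, though the ordinal valley/ridge contrast
  that the classifier consumes is robust to the choice.
* Polygon zone membership is by cell center, so zones much smaller than
  a cell can report no coverage.
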