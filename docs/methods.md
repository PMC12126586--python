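# Methods

## Rasters, grids, and georeferencing

All rasters are north-up with 0-based row/col indices, origin at the
top-left corner, and half-open cell intervals. Area arithmetic (cell count ×
cell area) is only meaningful in an equal-area CRS; the continental default
is an Africa Albers equal-area definition (`ESRI:102022`, configurable) and
synthetic fixtures use an abstract Cartesian CRS whose unit is a metre and
which is equal-area by construction. `area_table_from_map` refuses any other
CRS unless explicitly overridden.

GeoTIFFs are written through `tifffile` with the standard georeferencing
tags (ModelPixelScale, ModelTiepoint, a minimal GeoKeyDirectory carrying the
CRS as a citation string, GDAL_NODATA) plus a JSON ImageDescription holding
the CRS name and band names. Rotated geotransforms are out of scope: inputs
are assumed co-registered, matching the pipeline's contract. Integer rasters
round-trip bit-for-bit; float rasters are stored at their native precision
(float32 or float64) and also round-trip exactly.

The coarse analysis grid (10 km in the continental setting, 2 km in the
synthetic default) is anchored at the template raster's origin and requires
the coarse cell size to be an exact multiple of the fine cell size, so every
fine cell belongs to exactly one coarse cell and the assignment is a
partition. Anchoring at the origin is a deterministic choice made for
reproducibility; grid placement is otherwise arbitrary.

Nodata cells are excluded from every statistic (composites, memberships,
counts), with one deliberate exception: population aggregation treats nodata
as 0 persons (with a warning), because an absent population estimate over
open water or desert is best read as "nobody counted there", not as missing
at random.

## Composites and predictor variables

Seasonal composites take the per-cell median (default), mean, or maximum of
co-registered same-season scenes, per band, over non-nodata inputs. The
zone policy defaults to the maximum for arid and semi-arid zones — where
the wetland signal is the seasonal extreme, not the typical state — and the
median elsewhere; both the policy and the statistic are configuration, and
the mean is supported anywhere.

Optical indices are the usual normalized differences; a zero denominator
yields nodata rather than ±inf. The MNDWI SWIR band defaults to B11 and can
be switched to B12. Tasseled-cap wetness is a configurable linear form
whose default coefficients are the published Sentinel-2 wetness set
(Nedkov 2017); they are configuration, not a claim about ground truth. SAR
ratio indices are computed in linear power — dB inputs are converted first,
since ratios of logarithms are not physically meaningful; the scene object
declares its scale.

## Classification

One random forest per climate zone, 500 trees by default (the error-rate
plateau in a 100–600 sweep), `mtry = floor(sqrt(p))` as is standard when no
value is specified, and an explicit seed for every stochastic operation
(per-stage seeds are derived from one master seed by hashing the stage
name). The legend carries the five wetland types plus an explicit
non-wetland background class trained from background control points — a
continental map must separate wetland from everything else, and making the
background an ordinary class keeps the confusion matrix honest about it.

Variable screening refits the forest five times (configurable) and averages
the per-run MDI scores, each run normalised to sum to one; ties in the
aggregate ranking break by declared feature order. Control points are split
50/50 into training and testing halves, stratified per class within zone,
with the train share `round(fraction·n)` per class.

Accuracy assessment: overall accuracy = trace/total of the confusion
matrix; kappa = (p₀ − pₑ)/(1 − pₑ) with pₑ from the row/column margins
(cross-checked in the tests against an independent implementation);
producer's and user's accuracy per class, reported as NaN — not 0 — for a
class absent from the reference or the predictions.

## Fragmentation

A fragment is a maximal connected region of cells sharing one wetland
class; 4-connectivity is the default (matching common raster-to-polygon
behaviour), 8 is available for sensitivity analysis, and a merged-mask mode
treats all wetland classes as one. Per-coarse-cell counting uses presence
semantics: a fragment contributes 1 to every coarse cell it touches, so the
column sum over cells is ≥ the number of distinct fragments with equality
exactly when no fragment crosses a cell boundary. Production labeling runs
on `scipy.ndimage.label` per class; the test oracle is a separate
hand-written iterative flood fill that shares no code with it.

## WFPI

Population is aggregated to the coarse grid by summation by default (a
count of persons per cell); the mean is available, and under automatic
membership bounds the two give identical WFPI because the linear membership
is invariant to positive affine rescaling. Membership bounds default to the
layer's own min/max over the analysis extent ("auto"); explicit bounds are
supported for cross-run comparability and clamp to [0, 1]. A constant layer
has no defined linear membership and is rejected by name. The overlay is
the fuzzy AND (cellwise minimum); fuzzy OR is provided for contrast
experiments only. Threat intervals follow the quoted phrasing exactly:
heavy is strictly WFPI > 0.5, moderate is the closed interval [0.3, 0.5].

## Carbon accounting

All totals are linear in area and factors. Areas convert km² → ha at ×100;
CO₂ equivalents are carbon mass × 44/12 exactly, with no CH₄/N₂O GWP
weighting. Factors carry their own sign (positive = release, negative =
uptake), so pristine-condition uptake and wet-regime (WTL 1) uptake fall
out of the same summation. The six water-table codes partition depth by
half-open intervals with each printed boundary attached to the drier class
(−70 cm is code −3, −50 cm is −2, …, +40 cm is 1); `classify_wtl` is total
and monotone. Factor values are user-supplied tables; the shipped
`example_factors_synthetic.csv` contains round placeholder numbers for
demonstration and testing only and must be replaced for real accounting.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the pipeline assumes:
class-conditional Gaussian band signatures (independent per band, truncated
at 0) with a wet/dry contrast on water-sensitive bands for flood-driven
classes; patchy truth maps from thresholded smoothed noise fields (or
exactly placed rectangles when a test needs a constructed inventory);
population as Gaussian city kernels over a background; and control points
sampled uniformly within class, with optional label noise.

Default conditions, chosen once as a realistic-but-separable regime: five
wetland classes plus background, class-mean separation 8 within-class
standard deviations, prevalence 0.09 per class, 200 control points per
class, a 200×200 truth raster at 50 m with population at 1 km and a 2 km
analysis grid (the continental setting's 10 m / 1 km / 10 km stack scaled
to desk size with the fine-to-coarse ratios' roles preserved), three scenes
per season composited per the zone policy. Under these conditions held-out
OA and kappa reach 1.0; that validates the machinery (feature extraction,
training, prediction, bookkeeping), not real-world attainable accuracy —
real composites have correlated noise, mixed pixels, class overlap (swamp
vs peatland especially) and imperfect control points, none of which the
default generator emulates. A smoothed-noise option and a label-noise knob
exist to make the problem harder; identical class signatures demonstrably
drive pairwise accuracy to chance.

The generator's fragment inventory is computed by its own flood fill,
independent of the production labeler, so end-to-end fragment counts are
checked against an oracle rather than against the code under test.

## Numerical and degenerate-input choices

Zero denominators in normalized differences → nodata. All-nodata composite
cells stay nodata. Constant layers are rejected by the membership transform
with the offending layer named. Empty feature sets, duplicate feature
names, permuted feature order at prediction time, single-class training
sets, out-of-range water-table codes and missing factors are all hard
errors, not warnings. Forest training, the split, and every generator draw
are seeded; pipeline artifacts are hashed (SHA-256) into the run manifest
and reruns are bit-identical.

## Known limitations

No reprojection or resampling beyond nearest-neighbour-aligned inputs; no
atmospheric correction, terrain flattening or speckle filtering; no
landscape metrics beyond fragment counts and areas; no uncertainty
propagation in carbon accounting beyond what the linear forms make obvious;
the continental accuracy and carbon figures of a real survey are not
reproducible here because they require the real imagery archive, curated
control points, gridded population data and literature factor values.
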