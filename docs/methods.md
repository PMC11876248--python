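# Methods

## Scope and model structure

`pollscape` models one growing season's pollination service on categorical
raster landscapes, treating pollinators as central-place foragers whose
visitation probability decays with distance from their habitat cell. The
chain is deliberately short: land-use class → mortality hazard → foraging
exposure → remaining capacity ("health") → health-weighted visitation
("service"). There is no population dynamics, no behavioral preference for
floral quality, no pesticide drift onto non-target cells, and no
crop-specific dose–response toxicology; hazard is an abstract mortality
percentage per land-use class, standing in for the side-effect classes
published for registered products.

## Foraging kernel

Visitation weight at centre-to-centre distance *d* is `exp(−d/δ)`,
truncated at the foraging radius *r* and normalized to a unit sum over the
square stencil of side `2⌊r/h⌋+1` cells. Exponential distance decay is the
convention of the Lonsdorf lineage of pollination models; the e-folding
distance defaults to δ = r/2 so that the truncation removes only ~13 % of
the untruncated kernel mass, and both δ and the focal-cell weight are
configurable (`include_focal_cell=False` removes the d = 0 term). Defaults
for the gradient experiment: r = 500 m, h = 10 m, landscape 2000 × 2000 m
— chosen so a large clustering gradient fits inside the landscape at
moderate cost. The scenario uses r ∈ {400, 1000} m for short- and
long-range forager guilds, with δ scaling as r/2.

Two boundary treatments exist. `renormalize` (default) rescales weights to
sum to one over the in-bounds stencil, so edge cells average over their
available neighbourhood rather than seeing phantom hazard-free space.
`torus` wraps periodically and exists mainly because it makes analytic
expectations exact (translation equivariance, stencil identities), which
the test suite exploits.

## Exposure, health, service

Exposure is a kernel-weighted **average** of hazard — it reflects the
composition of the foraging disc and is bounded by the maximum hazard
present. Service is a kernel-weighted **sum** of health over habitat cells
(with the same normalization denominator) — it scales with how much of the
disc is healthy habitat, reaching 100 only for a disc entirely made of
full-health habitat. This asymmetry is what produces the study's central
interaction: scattering habitat raises service per unit habitat at low
hazard (habitat near every field) but maximizes exposure at high hazard
(every habitat cell sits in an agricultural neighbourhood), whereas
compact habitat shelters its interior at the price of serving fewer
fields. Health is clamped at zero; capacity cannot be negative.

Convolutions run through real FFTs (`scipy.signal.fftconvolve`; an
explicit circular convolution for the torus). Magnitudes below 1e-9 are
snapped to zero after each smoothing stage: the truncated kernel's support
is exact in the direct sum, and the snap removes the O(1e-15) FFT residue
without approaching the 1e-9 tolerance at which the FFT path is required
to match the direct-sum oracle. The renormalization denominator (a
convolution of ones) is cached per grid shape and kernel, since the
factorial experiment reuses it thousands of times.

## Neutral landscape generator

Each binary landscape is built in four steps: (1) independent Uniform(0,1)
noise on a coarse grid of cell size *c* (an integer multiple of *h*);
(2) nearest-neighbour resampling to *h*; (3) Gaussian smoothing with
standard deviation equal to the autocorrelation length *a* (wrap-around
boundary, so the field is stationary); (4) thresholding at the empirical
quantile so that exactly `round(p·N)` cells become habitat. Ties (constant
blocks when *a* = 0) are broken by flat cell index via a stable sort —
equivalent to an infinitesimal index-keyed jitter — so composition control
is exact, which the gradient design requires. Both *c* and *a* increase
clustering; the default candidate ladder spans (c, a) from (10 m, 0) —
white noise, log-LSI ≈ 2.35 at p = 0.05 — to (200 m, 250 m) — essentially
one compact blob, log-LSI ≈ 0.3.

Clustering is measured by the landscape-level shape index
`LSI = 0.25·E*/√A` with E* including the outer boundary (McGarigal's
landscape-level form, minimum exactly 1 for a single-class square), logged
with the natural logarithm; only the ordering matters for gradient
construction. Gradient levels are chosen by estimating each candidate's
mean log-LSI over seeds and selecting the subset closest (total absolute
deviation, monotone-assignment DP, provably optimal for sorted sequences)
to an equally spaced sequence between the candidate extremes. A candidate
set with identical realized log-LSI raises a configuration error rather
than silently collapsing the factorial design.

## Experiment design

Defaults: habitat steps {3, 5, 10, 15, 30, 50} % (denser at the low end,
where hedgerow-type habitat shares of European agricultural landscapes
actually sit), hazard levels {0, 25, 50, 75, 100} %, 5 clustering levels,
50 replicates. Seeds derive from the base seed through NumPy's splittable
`SeedSequence` keyed by (fraction, level, replicate), so any subset of the
design is reproducible in isolation. Landscapes are shared across hazard
levels within a replicate (paired design): the paper-level smoothness of
the hazard curves comes from differencing out landscape sampling noise.
Zero-habitat or zero-demand landscapes yield NaN summaries, never silent
zeros. Execution is serial; a full default run is a few thousand FFT
convolutions on 200 × 200 grids and completes in minutes, so the
`--workers` flag is accepted for interface stability but not parallelized.

## Scenario fixture

The multi-crop scenario is a synthetic, stylized layout (rectangular
parcels, packaged as code and configurable via YAML) emulating the
topology of a Dutch river-area fruit district, not its geography: a
1200 × 1800 m cluster of fruit parcels carrying 75 % hazard and demanding
pollination, pesticide-free arable fields elsewhere, thin inert strips for
roads, and four 100 × 100 m habitat patches — two embedded inside the
fruit cluster (their short-range foragers encounter almost exclusively
treated fruit) and two among the clean fields ~900 m east of the cluster
(beyond a 400 m foraging radius, partly within a 1000 m one). OTHER cells
contribute zero hazard and count in the service denominator but are
neither sources nor demand. Patches are identified by 4-connected
labelling, consistent with the LSI edge definition; patch classification
uses the Euclidean distance transform to the nearest fruit cell.

With these distances, the 400 m run shows service hotspots only within
reach of a patch, zero service on remote fruit, and a large health gap
between embedded and distant patches; the 1000 m run evens out service
over fruit (smaller coefficient of variation) and narrows the patch-health
spread, because embedded-patch foragers reach clean fields and
distant-patch foragers reach fruit.

## What the generator does and does not emulate

Synthetic landscapes have exactly two classes, homogeneous hazard on
agriculture, homogeneous habitat quality (initial capacity 100 %
everywhere), and stationary random geometry. Passing tests therefore
demonstrate the *configuration* mechanisms — composition control, the
clustering gradient, the exposure/service trade-off, foraging-range
effects — not predictive skill on real landscapes, where hazard varies by
crop and date, habitat quality varies with floral resources, and parcel
geometry is far from stationary.

## Numerical and design choices

- All lengths in metres, all model quantities in percent; enforced at I/O
  boundaries (categorical rasters: integer codes, nodata −1; field maps:
  floats, nodata −9999; ESRI ASCII format, byte-deterministic writes).
- Distances are centre-to-centre Euclidean; the grid origin is the
  lower-left corner, rows stored top-down.
- Exposure and service are clipped to [0, 100] after smoothing; the clip
  is inactive in exact arithmetic and guards FFT round-off only.
- The interpolated hazard crossover between clustered and dispersed
  configurations is computed by linear interpolation of the paired
  mean-service difference between adjacent hazard grid levels.
- Strict YAML schemas: unknown keys are errors, and every run echoes its
  effective configuration and seed to the output directory.

## Known limitations

Exposure aggregates hazard linearly and instantaneously; there is no
dose accumulation over repeated visits, no within-season recovery, and no
distinction between contact and oral routes. Service is visitation-based
and unweighted by crop-specific pollinator dependence. The clustering
gradient is defined operationally by the generator's two knobs; other
neutral-landscape algorithms (midpoint displacement, patch growing) would
trace somewhat different log-LSI ↔ pattern relationships.
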