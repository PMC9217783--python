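# Methods

## Scope and data model

The toolkit analyses planar annotation exports from serially sectioned
cortex: per-section layer polygons (I, II, III, IV–VI, WM), typed
marker points (neuropil threads, neuritic thread clusters, neurons),
vessel profiles (centre + diameter), sulcus landmarks (fundus and two
mouth points), and per-section affine alignment transforms.  All
coordinates and lengths are micrometres; no pixel data enters the
pipeline anywhere.  Geometry is convention-free — no axis orientation
is assumed — and polygons are stored as explicit closed rings (holes
allowed), winding-normalised on load.  Section order is declared in the
bundle config, never inferred from identifiers.

Manual alignment of serial sections is modelled as one invertible
affine per section.  This is a generalisation: alignment software
rarely documents its parameterisation, and an affine covers
translation, rotation and modest shear/scale while keeping
point-in-polygon relations invariant (a property the test suite
checks directly).  Vessel diameters rescale by `sqrt(|det|)` of the
linear part, the only isotropic choice consistent with an anisotropic
affine.

## Stereological estimators

**Optical fractionator.**  `N̂ = ΣQ⁻ / (ssf · asf · tsf)` with
`ssf = cut_thickness / section_period`, `asf = grid_fraction`, and
`tsf = dissector_height / mounted_thickness`.  The default design is a
serial exhaustive one: 50 µm sections every 500 µm (`ssf = 0.1`), a
700 × 700 µm counting frame tiling 100 % of the region (`asf = 1`), an
11 µm dissector with 2 µm guard zones.  The two-forbidden-edges frame
rule (half-open frame membership) is implemented and used whenever
`grid_fraction < 1`; with an exhaustive grid it is vacuous.

*Mounted thickness caveat.*  `tsf` divides by the post-shrinkage
mounted thickness, which published designs frequently omit.  The
default, 15 µm, is the minimum admissible value (dissector plus both
guards).  It rescales every estimate by a constant, so absolute
densities are comparable across studies only when this constant is
known; ratios (between layers, partitions or subjects) are unaffected.

**Gundersen–Jensen CE.**  Smoothness class m = 1 is the default (the
conventional choice for biological section series; m = 0 is
selectable).  The systematic-sampling variance term is clamped at zero
— a perfectly even series carries only the Poisson nugget, giving
`CE = sqrt(ΣQ)/ΣQ`.  The CE is *undefined* (None, flagged downstream as
"insufficient counts") for series shorter than three sections or with a
zero total; it is never silently reported as 0.  The report layer flags
every estimate with CE ≥ 0.15, mirroring the conventional
acceptability bound, which in practice trips only for rare structures
such as tau-bearing neurons.

**Cavalieri volume.**  `V = Σ area_i × period` over the contoured
per-section layer areas.  With serial exhaustive sections this is the
only volume rule consistent with the sampling design; no 3D
reconstruction or shrinkage modelling is attempted.

## Spatial analyses

**Layer assignment** is boundary-inclusive point-in-polygon containment
restricted to the marker's own section, with ties on shared boundaries
resolved to the superficial-most layer in the fixed order I → WM, so
assignment is deterministic.  Markers outside every polygon are
labelled `unassigned` and surface in a logged warning, never silently
dropped counts.

**Sulcal/gyral partition.**  Sulcal depth is the mean Euclidean
distance from the annotated fundus to the two mouths; a marker is
sulcal iff it lies in the cortical ribbon within `depth_fraction`
(default 1/3) × depth of the fundus.  Straight-line distance to the
fundus was chosen over geodesic depth along the ribbon midline: the
bottom-third convention in the field has no published computable
definition, and the Euclidean rule is reproducible from the landmarks
alone.  Partition areas (ribbon ∩ fundus-centred disc, and the
remainder) convert partition counts into densities via the same
fractionator + Cavalieri chain as the layers.

**Perivascular association.**  Eligibility is diameter strictly
greater than 30 µm; association is edge distance
`max(0, ‖marker − centre‖ − d/2)` at most 100 µm, inclusive.  The mean
distance is averaged over *associated* vessels only, each contributing
its nearest marker — published summary tables (all mean distances
below the threshold) are consistent with this reading and inconsistent
with averaging over all vessels.  All marker types are pooled by
default; a structure filter is exposed.  These boundary conventions
are stated because printed tables cannot disambiguate them.

**Heatmaps** bin the raw pooled markers (no fractionator correction —
they show the total distribution, not the estimated population) on a
250 µm grid by default, with optional Gaussian smoothing (default
bandwidth one cell) kept in a separate matrix so the count-conservation
invariant always holds on the raw bins.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes,
not tissue biophysics.  Per section, the cortical ribbon is a Gaussian
valley (one sulcus) with layer bands as vertical offsets of the pial
curve — band areas are exactly thickness × length, and the bands tile
the ribbon, which makes area bookkeeping testable to polygonisation
tolerance.  Markers follow an inhomogeneous Poisson process

    λ(layer, x) = λ0 · α^(layer) · (1 + β · 1[sulcal disc])

with `wm_factor · λ0` in white matter, realised as superposition of a
base process and an independent extra process at rate βλ restricted to
the sulcal disc (identical in law to thinning a (1+β)λ process).  A
`perivascular_fraction` p of markers is relocated to Gaussian offsets
(sd 30 µm) around a vessel chosen uniformly per marker; this preserves
total intensity exactly and yields an association percentage that
rises monotonically in p.  Vessels are homogeneous Poisson in the
cortex with log-normal diameters (μ = 3.5, σ = 0.45 in log-µm, median
≈ 33 µm), deliberately placing a sizeable share below the 30 µm cut so
the eligibility filter is exercised.

Defaults are λ0 = 200 markers/mm², α = 0.6, β = 2, p = 0.2, 10
sections, an 8 mm ribbon with layer thicknesses (150, 200, 350,
700) µm over 600 µm of white matter — rates that give ~10⁴ markers per
bundle, enough for percent-level recovery tests at negligible runtime.
Randomness uses a single master seed with deterministic substreams
(geometry, vessels, markers); a fixed seed reproduces bundles
byte-for-byte.

*Geometry choice.*  The default sulcus is deep and narrow
(amplitude 2400 µm, width 500 µm) relative to the 1400 µm cortical
stack.  This was chosen by analysing the model: the sulcal-depth disc
then crosses the full layer stack on the sulcal walls and samples the
layers in close to their global area proportions (layer-mix factor
≈ 1.007 by numerical integration), so the realised sulcal/gyral density
ratio is (1 + β) to within ~1 % and the per-layer decay stays within
~5 % of α even with enrichment on.  A shallow, wide sulcus would
confound the two axes: its disc oversamples superficial layers, and
whole-layer densities would then deviate from pure geometric decay —
a property of the generative model worth knowing before interpreting
recovery tests.

The stored ground truth contains the realised per-layer and partition
counts (assigned by the generator's analytic band test, independent of
the polygon path used by the analysis), analytic expected intensities
including the enrichment and relocation components, and the realised
vessel-association rate computed by an all-pairs scan.

**What the generator does not emulate:** measurement noise in manual
contouring, section-to-section misalignment (transforms are identity
unless set), anisotropic tissue shrinkage, marker-type-specific spatial
patterns, vessels crossing section boundaries, and any disease
progression dynamics.  Passing recovery tests therefore demonstrates
correctness of the estimators under the stated sampling model, not
robustness to annotation error in real material.

## Numerical choices

* Layer-overlap validation tolerates interior intersections below 1e-6
  of the smaller polygon area (vertex-snapping noise).
* Sulcal discs are shapely buffers at 128 quadrant segments; the area
  error is far below the 1 % oracle tolerance used in tests.
* The vessel mean distance uses `fsum` over sorted distances, making
  the summary exactly permutation-invariant.
* Transform singularity is |det| ≤ 1e-9; degenerate sulci (zero depth)
  and zero partition areas are errors, not silent zeros.
* Monte-Carlo test sizes (150–500 replicates, 10³ populations, 10⁴
  oracle points) were sized so that 3-standard-error bands sit well
  inside the asserted tolerances while the whole suite runs in
  seconds.

## Known limitations

* Densities are 2D-count-per-3D-volume estimates under the stated
  design; no correction for lost caps, over-projection or z-axis
  inhomogeneity is applied.
* Sulcal depth is landmark-based; heavily curved sulci where the
  Euclidean fundus distance cuts across a gyral crown would need the
  (unimplemented) geodesic alternative.
* One sulcus per section is assumed in the generator and the partition
  driver; real material with multiple sulci requires per-sulcus
  annotation sets.
* The pipeline is purely descriptive — no inferential statistics are
  computed across subjects, mirroring the small-n survey designs it
  targets.
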