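# Methods

## Contour model

A structure is an ordered stack of closed planar polygons, one per axial
slice, in patient coordinates (mm). Polygons are stored *open* (no repeated
closing vertex), matching the DICOM CLOSED_PLANAR convention and avoiding
double-counting a vertex in the HSC denominator. Orientation is normalized
to counter-clockwise on ingest (the original orientation is recorded and
restored on RT-STRUCT write), so area and centroid signs are predictable.
Multi-ring (donut/island) slices and non-planar contours are out of scope.

Area and centroid are the standard polygon formulas (via shapely).
`resample(c, n)` places `n` points at equal arc-length spacing starting at
the original first vertex. Note that resampling an arbitrary polygon cannot
preserve perimeter exactly — samples that miss an original vertex cut the
corner — so perimeter is exactly preserved only when the original vertices
are among the samples (e.g. equally spaced vertices upsampled by an integer
factor); on smooth phantom slices the shrinkage is below 0.5 % at 4×
upsampling. Contour-editing software does not publish its boundary
parameterization, so equal-arc-length spacing is this package's convention.

## HSC

`HSC = N_U / N_T`: `N_T` is the total boundary-point count of the final
contour, `N_U` the number of final points with a matching initial point.
Matching decisions:

- **Tolerance.** Default `match_tol = 1e-6` mm operationalizes "unchanged
  coordinates": exact float equality is unreliable after I/O round-trips
  (DICOM decimal strings), and 1e-6 mm is far below any clinical
  displacement. The adapted variant raises the tolerance to a clinical
  indistinguishability limit, default 0.5 mm.
- **Slice pairing.** Points match only within paired slices (z within half
  the smaller slice thickness); contour editing is per-slice, so cross-slice
  matches are forbidden.
- **Discipline.** One-to-one by default: candidate pairs within tolerance
  are processed in ascending distance (ties broken on point indices for
  determinism) and each initial point certifies at most one final point.
  This is conservative — a single stationary vertex cannot certify a whole
  neighborhood — and is exposed as a knob (`many_to_one` for the permissive
  reading). Greedy ascending-distance matching is not guaranteed to be a
  maximum-cardinality matching, but for tolerances far below the inter-point
  spacing (the intended regime) candidates are unique and the distinction is
  moot; the implementation (kd-tree candidate generation) is verified against
  an exhaustive O(n²) matcher in tests.

HSC is asymmetric by construction: an oversized initial contour may contain
many points absent from the final contour; only those also on the final
contour count, and the denominator never changes.

## DSC and comparators

DSC is the volumetric Dice `2|A∩B| / (|A|+|B|)` on rasterized masks. The
rasterizer uses pixel-center inclusion with boundary counting as inside —
deterministic and bit-reproducible — on a default 1 mm isotropic in-plane
grid (the CT pixel size the phantom emulates), 2 mm margin. Whether the
reference implementation in contouring software is 3D volumetric or
slice-averaged is not documented; this package computes the 3D volumetric
form and exposes `pixel_size`.

`surface_dsc` and `apl` are deliberately *simplified, slice-wise 2D*
comparators (dense equal-arc boundary sampling, distance to the paired
slice's boundary ring): the 3D surface versions are not specified precisely
enough in the literature this package follows to warrant inventing fidelity.
They are provided for qualitative comparison only.

## Synthetic phantom

The phantom stands in for a filled bladder on pelvic CT: defaults are 28
slices at 3 mm (≈84 mm extent), 40 mm maximal radius, 64 points per slice
(≈4 mm in-plane vertex spacing after 1 mm-scale editing granularity),
superellipse exponent 2.2 (mildly squarish cross-sections), and 1 mm of
seeded low-frequency radial noise (harmonics k = 2, 3) so slices are smooth
and star-shaped but not perfectly elliptical. All randomness flows from one
integer seed; generation is bit-reproducible.

The axial radius profile is an inferior hemispherical dome over the bottom
30 % of the stack and a flat-radius body above it. A deliberately asymmetric
profile (rather than a pole-to-pole taper) is required by the constrained
construction below: the untouched band is anchored at the inferior pole, and
anchoring it in the tapered end keeps the band's *volume* fraction below its
*point* fraction, which is what makes the low-Dice members of the fixed-HSC
schedule reachable. `cylinder` and `sphere` profiles are available for
analytic cross-checks (cylinder: constant radius; sphere: r(z) = √(R²−z²)
with empty slices dropped).

What the phantom does **not** emulate: real bladder anatomy (slice-to-slice
shape correlation, wall irregularity, neighboring-organ interfaces),
observer-drawn vertex distributions, and multi-ring topology. Tests passing
on the phantom therefore validate the *metrics and construction machinery*,
not anatomical generality.

## Constrained contour sets

Both simulated sets use one primitive: keep a contiguous band of slices
untouched (copied verbatim from ground truth) and shrink every other slice
radially about its centroid by a single global factor `f ∈ (0, 1]`. Any
`f < 1` displaces every point of a shrunk slice, so the measured HSC equals
the untouched band's point fraction exactly — the HSC is set by band
selection, quantized in steps of one slice's point mass (1/28 ≈ 0.036 at
defaults; with the default band of 13 slices, 13/28 = 0.4643 vs the 0.464
target). The band grows from the inferior (lowest-z) slice; the closest
achievable point fraction wins, ties to the smaller band.

Dice against ground truth is continuous and monotone non-decreasing in `f`
(shrunk slices stay inside their originals), so the original trial-and-error
adjustment is replaced by bisection on `f ∈ [10⁻³, 1]` (≤60 iterations,
stopping when the measured Dice is within half the requested tolerance of
the target; default achieved-vs-target tolerance 0.005). The reachable floor
is the Dice at `f → 0⁺` — `2·V_u/(V_u+V_gt)` with `V_u` the untouched band's
volume — and targets below it raise an infeasibility error reporting the
floor. On the noise-free cylinder the solver is validated against the closed
form `DSC(f) = 2f²/(1+f²)`.

- **Fixed-DSC set** (five cases): HSC targets 0, 0.111, 0.295, 0.507, 0.704
  with common Dice 0.850.
- **Fixed-HSC set** (seven cases): one band (HSC 0.464) with Dice targets
  0.640, 0.730, 0.765, 0.805, 0.849, 0.899, 0.953.

All achieved values reported in manifests are re-measured with the metrics
module, never assumed from the construction.

## Timing-study analysis

Timing fixtures store absolute seconds and each observer's from-scratch
contouring time; normalized times (seconds / same-observer scratch seconds)
are recomputed, never read from the printed column, then cross-checked
against it. Per-case means are taken over observers on unrounded values and
rounded half-up to 3 decimals (the printed tables' convention; two per-case
HSC means of the rounded observer values land exactly on the .0005 boundary
and may differ from print by one last-digit unit). Regressions are
unweighted ordinary least squares (scipy), with `R² = 1 − SS_res/SS_tot`;
the fitting method behind the published coefficients is not stated, and OLS
reproduces them. A fit is rejected when the predictor is constant and
flagged when its span is below 0.02 or its R² is below 0.5 (both thresholds
are package choices for surfacing degenerate/weak fits, e.g. regressing on
DSC within the fixed-DSC set).

## Numerical choices and limitations

- Rasterization ties (pixel center exactly on an edge) count as inside.
- Slice pairing tolerance is half the smaller slice thickness.
- RT-STRUCT coordinates are written with 6 decimals (DICOM DS 16-byte
  limit); round-trips are lossless to 5×10⁻⁷ mm. Structure sets carry no
  slice-thickness element, so it is inferred as the median z-gap on read.
- HSC quantization: achieved-vs-target HSC error is bounded by one slice's
  point mass; increase `points_per_slice`/`n_slices` to refine.
- The HSC presumes smooth initial contours; for boundaries oscillating at
  high spatial frequency (alternate points on/off the final contour) the
  untouched fraction no longer tracks editing effort.
- The metric ranks editing effort; it does not estimate absolute seconds
  for a specific person, which depend on software familiarity, organ
  contrast, and habit.
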