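# Methods

This note documents the models, conventions and numerical choices behind
`oviscan`, and what the phantom-based validation does and does not show.

## Data model

Image stacks are `(z, y, x)` arrays with an `(x, y, z)` spacing triple in
micrometres; a single slice is a stack of depth 1. Pixel coordinates are
0-based, boxes half-open. Binary masks share the spacing of their source
stack; no operation resamples, so spacing survives every module boundary.
Meshes live in millimetres. TIFF (multi-page, uint8/uint16) is the
interchange format for stacks and 0/255 uint8 TIFF for masks; meshes
export to STL/PLY/OBJ via trimesh.

## Segmentation chain

The 2D chain mirrors an interactive tomography workflow: rectangular ROI
crop in all three views; point-wise contrast enhancement mapping a value
band linearly onto the full dtype domain (integer outputs rounded
half-up); mask creation by a closed value band (both endpoints included —
boundary pixels differ between open/closed conventions, so this is
explicit); and structure splitting. `split_structures` takes the largest
connected tissue component under 8-connectivity (26 in 3D), fills its
cavities under the complementary 4-connectivity (6 in 3D) to obtain the
whole-organ solid ("external"), and defines the lumen ("internal") as
solid minus tissue. The complementary-connectivity duality avoids
topological leaks through diagonal pixel contacts. Value bands are
deliberately user inputs: the original segmentations were interactive and
no numeric thresholds are recoverable; an Otsu-based `suggest_band` is
provided as a labeled convenience only.

## Fold caliper

Folds are protrusions of the wall into the lumen. They are isolated as
connected components of `tissue − opening(tissue, disc(r))`: the opening
reconstructs the wall without anything a disc of radius `r` cannot enter.
The base scale `r` must lie strictly between the half-width of the widest
fold and the wall half-thickness; the default is 0.85 × a robust wall
half-thickness estimate (99th percentile of the tissue Euclidean distance
transform). This presumes the wall is thicker than the folds are wide —
true of the phantoms and of the emulated anatomy, and the parameter is
exposed for cases where it is not.

Measurement conventions (all validated against constructed phantom truth
before being frozen):

- the **medial path** is routed from the base midpoint to the apex (the
  component pixel farthest from the attachment chord) by a geodesic whose
  cost is weighted toward the distance-transform ridge — uniform-cost
  shortest paths on a raster are non-unique and can hug the boundary;
- the path is smoothed (moving average, window 7, endpoints re-anchored)
  because an 8-connected pixel chain overstates Euclidean arc length by
  up to ~8% depending on orientation;
- the path is trimmed where the remaining arc length no longer exceeds
  the local half-width (the tip cap), and **length** = base offset +
  shaft arc + cap radius + 1 px. The base offset (the path start's height
  above the attachment chord) restores the clipped base of wide folds,
  where the opening disc penetrates the junction; the final +1 px is the
  raster-extent correction (pixel-centre distances understate physical
  extent by half a pixel at each end);
- **width** = 2 × mean distance-transform value along the middle 50% of
  the trimmed shaft, avoiding base flare and tip taper. Whether a manual
  protocol would read base, mid or maximum width is unknowable; mid-shaft
  mean thickness is this package's convention.

On 200 default phantoms the detector recovers the constructed fold count
in every slice and the caliper's mean absolute error is ≈0.6 px (length)
and ≈0.25 px (width); both are asserted at ≤2 px in the test suite.
Folds touching the image border are flagged truncated and excluded from
summaries by default.

## Box-counting dimension and lacunarity

The analysis window is the foreground bounding box, so background padding
does not dilute box masses. Scales default to powers of two from 2 px up
to ⌊0.45·min(window)⌋ (FracLac-like); windows thinner than 8 px in one
dimension fall back to the larger dimension so a 1-px line still gets a
series. Grid origins: the first is always (0, 0); the rest are seeded
uniform shifts in [0, ε)², applied **toroidally** within the window
(equivalently, the window content is rolled). A plainly shifted grid
introduces partial edge cells that inflate N(ε) at coarse scales and
would bias even a filled square away from dimension 2; the toroidal
convention keeps every grid position at exactly ⌈H/ε⌉·⌈W/ε⌉ cells and
reduces to the plain grid at offset (0, 0).

The dimension is the least-squares slope of log N*(ε) vs log(1/ε) with
N*(ε) the **minimal** count over the grid origins examined — the most
efficient cover, which is what the box-dimension definition asks for.
Averaging counts over origins instead systematically over-counts sets
aligned with one grid (a grid-aligned Sierpinski triangle drifts from
1.585 to ≈1.52). Offset-mean counts remain available on the curve for
reporting. With defaults the estimator returns 2.000 (filled 256²
square, exact), 1.000 (line, exact), 1.58496 (Sierpinski order 7, exact)
and ≈1.26 (Koch order 6).

Recursive phantom rasters are generated at their natural pixel depth
(Sierpinski side 2^order px, Koch base 3^order px, centred on the
canvas); block-upscaled rasters have a fine-scale crossover to dimension
2 that no fixed scale series avoids, and finite-order curves additionally
merge strands below their unit-segment scale — both are properties of the
raster, not the estimator.

Lacunarity is the bare λ(ε) = (σ/μ)² of the cell-mass distribution
(population variance; empty cells inside the window count toward masses,
never toward N), averaged over grid origins per scale, and aggregated as
the unweighted mean Λ over scales. The bare convention (rather than
(σ/μ)²+1) is used because published aggregate values below 1 exist for
strongly fold-filled sections, which the +1 variant cannot produce; the
+1 variant is available behind a flag and recorded in result provenance
so incompatible results cannot be compared silently.

## Surfaces, volumes, shape factor

Volume is foreground voxel count × voxel volume. Surfaces are closed
marching-cubes isosurfaces at the 0.5 level of the (1-voxel padded) mask,
in millimetres, including the cut ends of a segment so V and S are
self-consistent. Raw marching-cubes surfaces of binary data carry a
staircase artifact that overstates area by roughly 5–8% on smooth test
solids; the default smoothing is Taubin (λ = 0.5, ν = 0.526, 10
iterations — the pass-band condition 0 < 1/λ − 1/ν < 0.1), which removes
most of that bias while preserving enclosed volume to ≈0.1% even at 20
iterations. Plain Laplacian smoothing is available for comparison and
strictly shrinks the solid (≈−3% volume at 20 iterations on a sphere) —
the reason an "appropriate number of iterations" matters and the
volume-preserving filter is the default. Each mesh carries a report of
area and enclosed volume before and after smoothing.

The shape factor is F = S·h/V with F/h in 1/mm. The segment height h is
a pipeline input (slice count × z-spacing, or the reference 4.46 mm when
reproducing published values), never inferred from the mesh. Values are
kept at full precision internally and rounded half-up to two decimals
only at report time. Of the 32 published (V, S, h) triples in the
reference table, 27 reproduce the printed shape index exactly at two
decimals and 30 of 32 reproduce the printed per-mm index; the remaining
cells disagree by 0.01–0.10 (printed rounding residue in the source
table, whose upstream unrounded values were evidently not the printed
ones). The package reproduces from printed inputs and bounds the
residuals rather than guessing the unrounded data.

## Phantoms: what they emulate, and what they do not

The fold phantom is an annular wall (default lumen radius 180 px, wall
64 px at 7.4 µm/px — the acquisition pixel size of the emulated protocol)
carrying radially oriented rounded-tip rectangular folds at jittered
equal angles, with sizes drawn per fold from configurable ranges
(defaults ≈150–800 µm length, ≈60–270 µm width, mid-range of the
published regional envelopes). Blind crypts are modeled as narrow radial
slots in the wall opening into the lumen. Specs whose folds would merge
are rejected rather than silently rasterized. Tube phantoms provide a
solid cylinder (analytic V, S, h), a helical tube (checked against
numeric centre-line arc length × section area), and an extruded annular
tube with optional longitudinal folds.

Phantoms are noiseless, perfectly segmented, and geometrically ideal:
folds are straight, walls are circular, there is no beam hardening,
reconstruction artifact, partial-volume blur or contrast variation.
Passing phantom tests therefore demonstrates correctness of the
*measurement operators* under known geometry — not robustness of
segmentation on real tomography, which remains the user's
responsibility via explicit value bands and ROIs.

## Regional pipeline

`run_region_analysis` chains phantom (or mask input) → structure split →
fold caliper → fractal statistics per slice, pools fractal results as
min–max ranges plus medians (ranges are how regional results are
conventionally reported; the median adds stability), attaches shape
factors from either a tube phantom or precomputed (V, S) inputs, and
records full provenance (config hash, seeds) so reports regenerate
byte-identically. The default fractal target is the mucosal relief
(tissue minus its opening): on phantoms, whole-wall masks trend opposite
to the published regional direction because a sparse-fold region's
compact annulus fills its window more evenly, whereas the fold-occupancy
logic of the published contrast applies to the relief itself. With this
convention, 20-seed UTJ-like vs AIJ-like suite comparisons (4 slices per
region) reproduce the published directional pattern — AIJ folds larger,
FD higher, lacunarity lower — in ≥18/20 runs for every metric.

Slice counts per region and phantom geometry are configuration, not
reproductions: the source study does not report how many slices fed its
per-region ranges.

## Problem sizes

Default validation sizes are chosen for exactness at desk scale:
576–672 px cross-sections, 256–2187 px fractal rasters, 50 µm voxels for
3D oracles (≈180k voxels per tube), 200-phantom recovery sweeps and
20-seed directional suites. Voxel budgets above a configurable cap
(2×10⁸) are rejected by the tube generator.

## Known limitations

- Fold detection requires the wall to be thicker than the widest fold;
  very wide folds on thin walls need an explicit `base_scale_px`.
- Box counting here is 2D; volumetric fractal analysis is out of scope.
- The caliper measures each 2D section independently; folds are not
  tracked across slices.
- DICOM input is not supported; convert to TIFF stacks first.
- No statistical inference between phases or regions is provided — the
  pipeline reports descriptive contrasts only.
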