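# oviscan

Quantitative morphometry of tubular organs from microCT-style image
stacks, developed around the swine oviduct. The oviduct's inner (mucosal)
wall carries sheet-like folds that differ sharply between regions — the
utero-tubal junction (UTJ) has few small folds, the ampullary-isthmic
junction (AIJ) many large ones — and those architectural differences
matter for designing biomimetic devices such as an oviduct-on-a-chip.
`oviscan` turns binary masks of such cross-sections and volumes into the
standard descriptors of that architecture:

- **fold calipers** — per-fold length (base → apex along the medial
  path) and width (transverse thickness), in µm;
- **box-counting fractal dimension** — the slope of log N(ε) vs
  log(1/ε), where N(ε) is the minimal number of ε-boxes covering the
  structure over the grid origins examined;
- **gliding-grid lacunarity** — λ(ε) = (σ/μ)² of the per-box mass
  distribution; high values mean a gappy, heterogeneous texture;
- **shape factor** — F = S·h/V for a segment of surface S (mm²), volume
  V (mm³) and height h (mm), with its height-normalized companion F/h
  (1/mm). F is dimensionless and scale-invariant; a closed cylinder
  gives F = 2h/r + 2, and convoluted lumina score far higher.

Because no raw imaging data ships with the published study, the package
includes a first-class **phantom generator**: fold-bearing cross-sections,
fractal rasters of known dimension, and voxel tubes with analytic volume
and surface. Every pipeline stage is validated against those ground
truths.

## Worked example

`examples/fractal_calibration.py` measures rasters of known dimension
with the estimator's defaults:

```
raster                      fd  analytic      r2  lacunarity
filled_square            2.000     2.000  1.0000       0.000
line                     1.000     1.000  1.0000       0.000
sierpinski_triangle      1.585     1.585  1.0000       1.819
koch_curve               1.263     1.262  0.9971       8.726
```

The fitted dimension matches the similarity dimension of each set, and
lacunarity rises from the homogeneous square (0) to the gappy Koch curve.

`examples/cylinder_shape_factor.py` closes the loop on the 3D side
(voxelized cylinder, r = 1 mm, h = 4.46 mm, 50 µm voxels):

```
volume  : measured   14.062 mm^3   analytic   14.012 mm^3
surface : measured   34.818 mm^2   analytic   34.306 mm^2
shape factor F = S*h/V : measured 11.04, analytic 10.92 (= 2h/r + 2 = 10.92)
```

The other examples measure folds on a phantom cross-section
(`fold_phantom_morphometry.py`), recompute the published oviduct shape
indices from their printed volume/surface/height triples
(`reference_shape_indices.py`), and run the full regional pipeline on
UTJ-like vs AIJ-like phantom suites (`regional_contrast_report.py`),
reproducing the published directional pattern: AIJ folds larger, AIJ
fractal dimension higher, AIJ lacunarity lower.

A thin CLI mirrors the library:
`oviscan phantom|segment|folds|fractal|shape|report` (see `--help`).

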