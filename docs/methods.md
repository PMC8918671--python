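# Methods

## Model

`spottype` treats a single-molecule SRT experiment as a spatial point pattern
marked by gene identity. The modeling assumption is that within a
neighborhood of bandwidth σ, the mixture of gene labels among nearby
molecules reflects the expression profile of the cell occupying that
location. The pipeline therefore (i) smooths each gene's point pattern into a
pixel image by Gaussian KDE, (ii) ranks reference cell-type signatures by
Pearson correlation against each pixel's cross-gene expression vector, and
(iii) masks out pixels whose total signal is too low to plausibly come from a
cell. No cell boundaries are estimated at any point; the output is a label
per pixel, not per cell.

### Fast KDE

The estimator makes two deliberate approximations to the exact Gaussian KDE:

1. **Pixel snapping.** Each molecule is rounded to its nearest output pixel,
   so all molecules share one pre-computed kernel image. Snapping displaces a
   molecule by at most half a pixel per axis.
2. **Two-bandwidth truncation.** The kernel patch is cut at radius
   ⌈2σ_px⌉. A 2-D Gaussian holds erf(2/√2)² ≈ 91.1% of its mass within ±2σ,
   so at most 8.9% of each molecule's mass is affected by the cut.

The truncated patch is renormalized to sum to exactly 1. This is a design
choice the gridded estimator leaves open (raw exp values would also work):
renormalization makes each molecule contribute exactly one unit of signal, so
per-gene plane sums equal molecule counts (testable mass conservation) and
the expression threshold has natural units of *effective molecules per
pixel*. The combined approximation error per molecule is bounded by ≈12% of
the per-molecule peak value 1/(2πσ_px²): up to ≈7% of peak from a half-pixel
snap (gradient of the Gaussian at r = σ times a √2/2-pixel shift, σ = 3 px)
plus ≈9.8% from renormalizing away the truncated tail. The test suite and
acceptance script verify the fast estimator against an exact, untruncated,
continuous-center KDE under this per-pixel bound, scaled by the number of
molecules within patch reach of each pixel.

Accumulation cost is exactly one patch addition (P² = (2⌈2σ_px⌉+1)² pixel
operations) per molecule — linear in molecule count, which an operation
counter on the density stack asserts directly.

## Parameters

| parameter | units | default | notes |
|---|---|---|---|
| `bandwidth` | μm | none (required) | kernel σ; 2–25 μm is a sensible range — larger for sparse data (~3–5 molecules/cell), smaller for dense (~20–30/cell). Dataset-specific, so no default. |
| `width_px` | px | none (required) | output map width; controls memory and spatial resolution. Height follows from the data's aspect ratio. |
| `threshold` | effective molecules/px | 0 | foreground cutoff on the gene-summed density; higher extracellular noise demands a higher value. Dataset-specific. |
| `measure` | — | `pearson` | `pearson` or `cosine`. Pearson is the parent method's choice and is scale- and offset-invariant in the pixel vector. |
| preview `size` | μm | 100 | edge length of the parameter-optimization window. |

## Numerical choices

- **Grid.** `scale = width_px / x-range` (px/μm), identical on both axes;
  `height_px = ceil(scale · y-range)`, floored at 1, so every molecule lands
  inside the grid. Pixel (r, c) covers the μm square
  [y_min + r/scale, y_min + (r+1)/scale) × [x_min + c/scale, x_min + (c+1)/scale);
  row 0 is the smallest y. Zero x-range is a validation error.
- **Snapping** rounds half away from zero and clamps to the grid, so extent
  extrema stay inside.
- **Border handling.** Patches are cropped at grid edges (no reflection or
  wrap-around); mass conservation consequently holds only for molecules whose
  patch fits inside the grid, and tests place molecules accordingly.
- **Determinism.** Molecules are reduced to a canonical (gene, row, column)
  order before accumulation, so the density stack — and everything downstream
  — is bit-identical under any permutation of the input table. The only
  randomness in the package is the seeded generator in `synth`.
- **Ties and degenerate pixels.** Equal correlations resolve to the lowest
  signature row index. Pixels with a constant expression vector have no
  defined correlation and fall to background even above threshold. A
  zero-variance *signature* row is rejected up front with the cell type named.
- **Threshold semantics.** Foreground is `total >= threshold`; the mask is
  independent of the correlation step, so raising the threshold can only grow
  the background and never relabels surviving foreground.
- **Preview windows** are converted to whole-pixel bounds of the full-run
  grid and the local grid is anchored on those pixel boundaries with the full
  run's scale; molecules are cropped by snapped pixel. With the 2σ-truncated
  kernel this makes preview pixels at least ⌈2σ_px⌉ from the window border
  bit-identical to the full run, which the tests assert.
- **Abundance** fractions are normalized over classified pixels only; the
  background row carries a count but fraction 0.

## Synthetic data

`synth.make_tissue` / `simulate_spots` emulate the regimes the method is
meant for: circular cells of known type on a jittered lattice (guaranteed
disjoint), per-cell molecule counts ~ Poisson(depth), genes drawn from the
cell type's signature row, positions scattered isotropically
(σ = radius/2) around the center, plus a uniform extracellular noise
fraction with uniformly random gene labels. Defaults — 1,000 cells of 5
types with 4 exclusive binary markers each, 10 μm radius over 1 mm², depth
20, 10% noise — represent a dense assay with clean markers. The ground truth
rasterizes cell disks onto any grid, and typing accuracy is evaluated on
pixels that are foreground in the prediction and inside a cell in the truth.

What the generator does **not** emulate: optical blur and decoding errors,
z-structure, irregular or overlapping cell shapes, correlated (structured)
background, and realistic signature cross-talk between types. Passing the
recovery tests therefore demonstrates the pipeline's correctness and its
behavior under idealized noise, not expected accuracy on real tissue, where
signatures overlap and noise is spatially structured.

`scale_dataset` reproduces the benchmark constructions for throughput
studies: 0.5× by seeded sampling without replacement of ⌊N/2⌋ rows; 2× by
appending a copy shifted (+1, +1) μm; 3× by appending a (−1, −1) μm copy to
the 2× table; 5× as the original plus four copies shifted (+1..+4, +1..+4) μm.
The 5× wording admits other readings (e.g., repeated doubling); the
original-plus-four-shifted-copies interpretation is adopted because it yields
exactly 5N molecules.

## Problem sizes

The test suite and acceptance script run on deliberately small instances —
64–80 px oracle grids with 200–400 molecules (the exact KDE oracle is
quadratic in grid size × molecules), and a 400 px, ~25k-molecule tissue for
recovery — chosen so the whole suite completes in seconds while every
property (mass conservation, oracle agreement, linear cost, preview
consistency, recovery ≥ 90%) is exercised at meaningful scale. The fast KDE
itself handles millions of molecules, since its cost is one small patch
addition per molecule.

## Limitations

- Correlation against signatures is *guided* typing only: unknown cell types
  cannot be discovered, and pixels mixing two cell types get whichever
  signature correlates best.
- A single isotropic bandwidth is used everywhere; no adaptive or anisotropic
  smoothing, and only the Gaussian kernel is provided.
- 2-D only; z-coordinates in input files are ignored.
- The pixel grid is fit to the data extent, so a handful of stray molecules
  far from the tissue will stretch the grid and coarsen the effective
  resolution.
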