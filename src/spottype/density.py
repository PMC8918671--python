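"""Gridded Gaussian kernel density estimation of per-gene signal strength.

The spatial model is a stack of pixel matrices, one per gene, holding the
local density of decoded molecules. Molecule coordinates (μm) are rescaled
linearly so the data's x-range spans a user-chosen pixel width; the Gaussian
bandwidth is rescaled with the same factor. The fast estimator snaps every
molecule to its nearest pixel and accumulates a pre-computed Gaussian mass
patch truncated at two bandwidths, so the cost is exactly one patch addition
per molecule — linear in the number of molecules. A naive, untruncated,
continuous-center KDE is provided as a verification oracle for small inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .spots_io import SpotTable

#: suggested bandwidth range (μm) for typical single-molecule datasets —
#: larger for sparse data (a few molecules per cell), smaller for dense.
BANDWIDTH_GUIDELINE_UM = (2.0, 25.0)


# ---------------------------------------------------------------------------
# parameter and grid types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KDEParams:
    """The three analysis parameters: bandwidth (μm), output pixel width,
    and the total-expression threshold separating foreground from background.
    """

    bandwidth: float  # Gaussian sigma, μm
    width_px: int  # output map width, pixels
    threshold: float = 0.0  # total signal cutoff, effective molecules/pixel

    def __post_init__(self) -> None:
        if not (self.bandwidth > 0 and math.isfinite(self.bandwidth)):
            raise ValidationError(f"bandwidth must be > 0, got {self.bandwidth}")
        if int(self.width_px) != self.width_px or self.width_px < 2:
            raise ValidationError(f"width_px must be an integer >= 2, got {self.width_px}")
        if not (self.threshold >= 0):
            raise ValidationError(f"threshold must be >= 0, got {self.threshold}")
        object.__setattr__(self, "width_px", int(self.width_px))


@dataclass(frozen=True)
class GridSpec:
    """Linear μm→pixel mapping.

    Pixel column c covers μm interval [x_min + c/scale, x_min + (c+1)/scale);
    row 0 holds the smallest y. The same scale applies to both axes, so the
    aspect ratio of the data is preserved.
    """

    x_min: float  # μm
    y_min: float  # μm
    scale: float  # pixels per μm
    width_px: int
    height_px: int
    bandwidth_px: float  # sigma in pixel units

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """μm coordinates of pixel centers: (x of columns, y of rows)."""
        xs = self.x_min + (np.arange(self.width_px) + 0.5) / self.scale
        ys = self.y_min + (np.arange(self.height_px) + 0.5) / self.scale
        return xs, ys


@dataclass(frozen=True)
class GaussianPatch:
    """Pre-computed Gaussian mass on integer offsets, truncated at 2σ.

    The (2r+1)×(2r+1) patch with r = ceil(2σ) holds
    exp(-(di²+dj²)/(2σ²)) renormalized to total mass 1, so one patch
    accumulation deposits exactly one unit of signal.
    """

    mass: np.ndarray  # (P, P), sums to 1
    radius_px: int
    sigma_px: float


@dataclass(frozen=True)
class DensityStack:
    """Per-gene local signal strength: values[g, row, col] >= 0."""

    values: np.ndarray  # (G, H, W) float64
    genes: list[str]
    grid: GridSpec
    ops: int = field(default=0, compare=False)  # patch-accumulation op count

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3 or values.shape[0] != len(self.genes):
            raise ValidationError("density stack must be (G, H, W) with G gene labels")
        object.__setattr__(self, "values", values)

    @property
    def total(self) -> np.ndarray:
        """Gene-summed signal strength (H, W) — the KDE heatmap quantity."""
        return self.values.sum(axis=0)


# ---------------------------------------------------------------------------
# grid construction and pixel snapping
# ---------------------------------------------------------------------------


def make_grid(spots: SpotTable, params: KDEParams) -> GridSpec:
    """Fit the pixel grid to the data extent.

    scale = width_px / x-range; height_px = ceil(scale * y-range), at least 1,
    so the grid covers the full vertical spread; bandwidth_px = bandwidth * scale.
    """
    if len(spots) == 0:
        raise ValidationError("cannot build a grid from an empty spot table")
    x_min, x_max = float(spots.x.min()), float(spots.x.max())
    y_min, y_max = float(spots.y.min()), float(spots.y.max())
    if x_max <= x_min:
        raise ValidationError("zero x-range: all molecules share one x coordinate")
    scale = params.width_px / (x_max - x_min)
    height_px = max(1, math.ceil(scale * (y_max - y_min)))
    return GridSpec(
        x_min=x_min,
        y_min=y_min,
        scale=scale,
        width_px=params.width_px,
        height_px=height_px,
        bandwidth_px=params.bandwidth * scale,
    )


def _round_half_away(v: np.ndarray) -> np.ndarray:
    # np.round ties to even; the snapping convention is half-away-from-zero
    return np.trunc(v + np.copysign(0.5, v))


def snap_to_pixels(spots: SpotTable, grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Map each molecule to its nearest pixel (col, row), clamped to the grid."""
    cols = _round_half_away(grid.scale * (spots.x - grid.x_min)).astype(np.int64)
    rows = _round_half_away(grid.scale * (spots.y - grid.y_min)).astype(np.int64)
    np.clip(cols, 0, grid.width_px - 1, out=cols)
    np.clip(rows, 0, grid.height_px - 1, out=rows)
    return cols, rows


# ---------------------------------------------------------------------------
# Gaussian patch and fast KDE
# ---------------------------------------------------------------------------


def make_patch(sigma_px: float) -> GaussianPatch:
    """Build the truncated, normalized Gaussian mass patch for one molecule."""
    if not (sigma_px > 0 and math.isfinite(sigma_px)):
        raise ValidationError(f"sigma_px must be > 0, got {sigma_px}")
    radius = math.ceil(2.0 * sigma_px)
    d = np.arange(-radius, radius + 1, dtype=np.float64)
    sq = d[:, None] ** 2 + d[None, :] ** 2
    mass = np.exp(-sq / (2.0 * sigma_px**2))
    mass /= mass.sum()
    return GaussianPatch(mass=mass, radius_px=radius, sigma_px=float(sigma_px))


def _gene_index(spots: SpotTable, genes: list[str]) -> np.ndarray:
    lookup = {g: i for i, g in enumerate(genes)}
    try:
        return np.fromiter((lookup[g] for g in spots.gene), dtype=np.int64, count=len(spots))
    except KeyError as exc:
        raise ValidationError(
            f"spot gene {exc.args[0]!r} not in the provided gene list; align genes first"
        ) from None


def run_kde(
    spots: SpotTable,
    genes: list[str],
    params: KDEParams,
    grid: GridSpec | None = None,
) -> DensityStack:
    """Fast gridded KDE: one truncated-Gaussian patch addition per molecule.

    Molecules are snapped to their nearest pixel and the shared patch is
    accumulated into the plane of their gene, cropped at grid borders.
    The result is independent of the input row order (molecules are reduced
    to a canonical order before summation) and the operation count is
    exactly ``len(spots) * P**2`` for patch side P.
    """
    if grid is None:
        grid = make_grid(spots, params)
    gidx = _gene_index(spots, genes)
    patch = make_patch(grid.bandwidth_px)
    r, P = patch.radius_px, 2 * patch.radius_px + 1
    H, W = grid.height_px, grid.width_px
    values = np.zeros((len(genes), H, W), dtype=np.float64)

    cols, rows = snap_to_pixels(spots, grid)
    # canonical order: summation becomes permutation-invariant bit-for-bit
    order = np.lexsort((cols, rows, gidx))
    for g, rr, cc in zip(gidx[order], rows[order], cols[order]):
        y0, y1 = max(rr - r, 0), min(rr + r + 1, H)
        x0, x1 = max(cc - r, 0), min(cc + r + 1, W)
        values[g, y0:y1, x0:x1] += patch.mass[
            y0 - (rr - r) : P - ((rr + r + 1) - y1),
            x0 - (cc - r) : P - ((cc + r + 1) - x1),
        ]
    return DensityStack(values=values, genes=list(genes), grid=grid, ops=len(spots) * P * P)


def naive_kde(
    spots: SpotTable,
    genes: list[str],
    params: KDEParams,
    grid: GridSpec | None = None,
) -> DensityStack:
    """Exact continuous-center, untruncated Gaussian KDE (verification oracle).

    Every pixel receives ``sum_m exp(-d²(pixel, molecule_m)/(2σ²)) / (2πσ²)``
    with distances measured in pixel units to the molecule's unsnapped scaled
    position, so each molecule carries total mass 1 on an infinite grid.
    Quadratic cost — intended for small inputs only.
    """
    if grid is None:
        grid = make_grid(spots, params)
    gidx = _gene_index(spots, genes)
    sigma = grid.bandwidth_px
    if not sigma > 0:
        raise ValidationError("bandwidth_px must be > 0")
    H, W = grid.height_px, grid.width_px
    px = grid.scale * (spots.x - grid.x_min)  # continuous pixel coords
    py = grid.scale * (spots.y - grid.y_min)
    cols = np.arange(W, dtype=np.float64)
    rows = np.arange(H, dtype=np.float64)
    norm = 1.0 / (2.0 * math.pi * sigma**2)
    values = np.zeros((len(genes), H, W), dtype=np.float64)
    for g, mx, my in zip(gidx, px, py):
        gx = np.exp(-((cols - mx) ** 2) / (2.0 * sigma**2))
        gy = np.exp(-((rows - my) ** 2) / (2.0 * sigma**2))
        values[g] += norm * gy[:, None] * gx[None, :]
    return DensityStack(values=values, genes=list(genes), grid=grid, ops=len(spots) * H * W)
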