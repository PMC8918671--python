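"""Per-pixel cell typing of a density stack by signature correlation.

Each pixel's gene-expression vector (one value per gene, taken across the
density stack) is compared to every cell-type signature and the pixel is
assigned the best-correlating type. Pixels whose summed signal falls below
the expression threshold are background (label -1) and receive no type, as
are pixels whose expression vector has zero variance (no correlation is
defined there). Abundance is quantified over rectangular views, counting
classified pixels only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .density import DensityStack, GridSpec, KDEParams, make_grid, run_kde, snap_to_pixels
from .errors import ValidationError
from .spots_io import CellTypeMap, SignatureMatrix, SpotTable

MEASURES = ("pearson", "cosine")

#: default edge length (μm) of the parameter-optimization preview window
DEFAULT_PREVIEW_SIZE_UM = 100.0


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------


def correlate_pixel(expr: np.ndarray, sig_row: np.ndarray) -> float:
    """Pearson correlation between one pixel's expression vector and one
    signature row; NaN if the pixel vector has zero variance (undefined,
    treated as -inf when ranking cell types)."""
    expr = np.asarray(expr, dtype=np.float64)
    sig_row = np.asarray(sig_row, dtype=np.float64)
    if expr.shape != sig_row.shape or expr.ndim != 1:
        raise ValidationError("expression and signature vectors must have equal length")
    if expr.size < 2:
        raise ValidationError("correlation needs at least 2 genes")
    if np.ptp(sig_row) == 0:
        raise ValidationError("signature row has zero variance")
    ec = expr - expr.mean()
    denom = math.sqrt((ec**2).sum())
    if denom == 0.0:
        return float("nan")
    sc = sig_row - sig_row.mean()
    return float((ec @ sc) / (denom * math.sqrt((sc**2).sum())))


def _standardize_rows(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and L2-normalize rows; returns (standardized, zero-variance mask)."""
    c = m - m.mean(axis=1, keepdims=True)
    norm = np.sqrt((c**2).sum(axis=1))
    zero = norm == 0
    c[~zero] /= norm[~zero, None]
    return c, zero


def assign_celltypes(
    stack: DensityStack,
    sig: SignatureMatrix,
    threshold: float,
    measure: str = "pearson",
) -> CellTypeMap:
    """Assign every pixel the cell type whose signature correlates best.

    Pixels with summed signal below ``threshold`` are background (-1), as are
    pixels whose expression vector is constant across genes. Correlation ties
    break toward the lowest signature row index, so the result is
    deterministic. ``measure`` selects Pearson correlation (default) or
    cosine similarity.
    """
    if measure not in MEASURES:
        raise ValidationError(f"unknown correlation measure {measure!r}; use one of {MEASURES}")
    if stack.genes != sig.genes:
        raise ValidationError(
            "density stack gene order does not match signature columns; align genes first"
        )
    if sig.n_celltypes < 1:
        raise ValidationError("need at least one cell-type signature")
    G, H, W = stack.values.shape
    if G < 2:
        raise ValidationError("cell typing needs at least 2 genes")

    sig_m = sig.values
    if measure == "pearson":
        zs, zero_sig = _standardize_rows(sig_m.copy())
    else:  # cosine: normalize without centering
        norms = np.sqrt((sig_m**2).sum(axis=1))
        zero_sig = norms == 0
        zs = np.where(zero_sig[:, None], 0.0, sig_m / np.where(zero_sig, 1.0, norms)[:, None])
    if zero_sig.any():
        bad = sig.celltypes[int(np.flatnonzero(zero_sig)[0])]
        raise ValidationError(f"signature for cell type '{bad}' has zero variance")

    flat = stack.values.reshape(G, H * W)
    total = flat.sum(axis=0)
    foreground = total >= threshold

    labels = np.full(H * W, -1, dtype=np.int64)
    if foreground.any():
        expr = flat[:, foreground].T.copy()  # (n_fg, G)
        if measure == "pearson":
            ze, zero_expr = _standardize_rows(expr)
        else:
            norms = np.sqrt((expr**2).sum(axis=1))
            zero_expr = norms == 0
            ze = np.where(zero_expr[:, None], 0.0, expr / np.where(zero_expr, 1.0, norms)[:, None])
        corr = ze @ zs.T  # (n_fg, K)
        best = corr.argmax(axis=1)  # argmax takes the first max: lowest index wins ties
        best[zero_expr] = -1  # undefined correlation -> background
        labels[foreground] = best
    return CellTypeMap(labels=labels.reshape(H, W), legend=list(sig.celltypes), grid=stack.grid)


# ---------------------------------------------------------------------------
# abundance over rectangular views
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ViewRect:
    """Half-open pixel rectangle [row_start, row_stop) × [col_start, col_stop)."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    def __post_init__(self) -> None:
        if self.row_stop <= self.row_start or self.col_stop <= self.col_start:
            raise ValidationError("view rectangle is empty")

    @classmethod
    def full(cls, grid_or_labels) -> "ViewRect":
        shape = getattr(grid_or_labels, "shape", None)
        if shape is None:
            shape = (grid_or_labels.height_px, grid_or_labels.width_px)
        return cls(0, shape[0], 0, shape[1])

    @classmethod
    def from_um(
        cls, grid: GridSpec, x_lo: float, x_hi: float, y_lo: float, y_hi: float
    ) -> "ViewRect":
        """Convert a μm rectangle to pixel bounds, clipped to the grid."""
        c0 = max(0, int(np.floor(grid.scale * (x_lo - grid.x_min) + 0.5)))
        c1 = min(grid.width_px, int(np.floor(grid.scale * (x_hi - grid.x_min) + 0.5)) + 1)
        r0 = max(0, int(np.floor(grid.scale * (y_lo - grid.y_min) + 0.5)))
        r1 = min(grid.height_px, int(np.floor(grid.scale * (y_hi - grid.y_min) + 0.5)) + 1)
        if c1 <= c0 or r1 <= r0:
            raise ValidationError("view rectangle does not intersect the grid")
        return cls(r0, r1, c0, c1)


def quantify_abundance(ctmap: CellTypeMap, view: ViewRect | None = None) -> pd.DataFrame:
    """Relative cell-type abundance over classified pixels in a view.

    Fractions are normalized over classified (non-background) pixels; the
    background row reports its pixel count with fraction 0. Counts over all
    rows sum to the view's pixel count.
    """
    if view is None:
        view = ViewRect.full(ctmap.labels)
    H, W = ctmap.labels.shape
    if not (0 <= view.row_start < view.row_stop <= H and 0 <= view.col_start < view.col_stop <= W):
        raise ValidationError("view rectangle out of grid bounds")
    window = ctmap.labels[view.row_start : view.row_stop, view.col_start : view.col_stop]
    K = len(ctmap.legend)
    counts = np.bincount(window.ravel() + 1, minlength=K + 1)  # slot 0 = background
    n_classified = int(counts[1:].sum())
    fractions = counts[1:] / n_classified if n_classified else np.zeros(K)
    return pd.DataFrame(
        {
            "celltype": list(ctmap.legend) + ["background"],
            "count": list(counts[1:].astype(int)) + [int(counts[0])],
            "fraction": list(fractions) + [0.0],
        }
    )


# ---------------------------------------------------------------------------
# subsection preview
# ---------------------------------------------------------------------------


def preview_subsection(
    spots: SpotTable,
    sig: SignatureMatrix,
    center: tuple[float, float],
    size: tuple[float, float] | float,
    params: KDEParams,
    measure: str = "pearson",
) -> tuple[DensityStack, CellTypeMap]:
    """Run the pipeline on a small μm window for parameter optimization.

    The window of the given size (μm) centered at ``center`` is clipped to
    the data extent and analyzed on a local grid that keeps the full run's
    μm-per-pixel resolution and pixel alignment, so bandwidth_px matches the
    full-image run and interior pixels (further than the 2σ patch radius from
    the window border) reproduce the full run exactly.
    """
    if isinstance(size, (int, float)):
        size = (float(size), float(size))
    full_grid = make_grid(spots, params)
    cx, cy = center
    half_w, half_h = size[0] / 2.0, size[1] / 2.0

    cols, rows = snap_to_pixels(spots, full_grid)
    # window in full-grid pixel indices, clipped
    c0 = max(0, int(np.floor(full_grid.scale * (cx - half_w - full_grid.x_min) + 0.5)))
    c1 = min(full_grid.width_px,
             int(np.floor(full_grid.scale * (cx + half_w - full_grid.x_min) + 0.5)) + 1)
    r0 = max(0, int(np.floor(full_grid.scale * (cy - half_h - full_grid.y_min) + 0.5)))
    r1 = min(full_grid.height_px,
             int(np.floor(full_grid.scale * (cy + half_h - full_grid.y_min) + 0.5)) + 1)
    if c1 <= c0 or r1 <= r0:
        raise ValidationError("preview window does not intersect the data extent")

    inside = (cols >= c0) & (cols < c1) & (rows >= r0) & (rows < r1)
    if not inside.any():
        raise ValidationError("preview window contains no molecules")
    crop = spots.select(inside)

    local_grid = GridSpec(
        x_min=full_grid.x_min + c0 / full_grid.scale,
        y_min=full_grid.y_min + r0 / full_grid.scale,
        scale=full_grid.scale,
        width_px=c1 - c0,
        height_px=r1 - r0,
        bandwidth_px=full_grid.bandwidth_px,
    )
    stack = run_kde(crop, sig.genes, params, grid=local_grid)
    ctmap = assign_celltypes(stack, sig, params.threshold, measure=measure)
    return stack, ctmap
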