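"""Synthetic spot tables with known ground truth, and dataset re-scaling.

The tissue model is deliberately simple: circular cells of known type are
scattered over a rectangular extent; each cell emits a Poisson number of
molecules whose genes follow the cell type's signature row and whose
positions scatter isotropically around the cell center (σ = radius/2);
uniformly placed noise molecules with uniformly random genes emulate
extracellular, diffused mRNA. Everything is driven by one integer seed,
so fixtures are byte-reproducible.

``scale_dataset`` implements the benchmark constructions used to stress-test
throughput: random 50% downsampling, and 2×/3×/5× datasets built by
appending copies of the coordinate table shifted by whole μm along both axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .density import GridSpec
from .errors import ValidationError
from .spots_io import SignatureMatrix, SpotTable


# ---------------------------------------------------------------------------
# signatures and tissue model
# ---------------------------------------------------------------------------


def binary_signatures(n_types: int, genes_per_type: int = 4) -> SignatureMatrix:
    """Disjoint binary marker signatures: type k expresses only its own block
    of ``genes_per_type`` genes."""
    G = n_types * genes_per_type
    values = np.zeros((n_types, G))
    for k in range(n_types):
        values[k, k * genes_per_type : (k + 1) * genes_per_type] = 1.0
    return SignatureMatrix(
        celltypes=[f"type{k}" for k in range(n_types)],
        genes=[f"g{j:02d}" for j in range(G)],
        values=values,
    )


@dataclass(frozen=True)
class TissueModel:
    """Ground-truth description of a synthetic tissue.

    ``cells`` holds one (x μm, y μm, radius μm, celltype index) tuple per
    cell; ``depth`` is the expected molecule count per cell; a
    ``noise_fraction`` share of all molecules is uniform extracellular noise.
    """

    cells: list[tuple[float, float, float, int]]
    signatures: SignatureMatrix
    depth: float  # expected molecules per cell
    noise_fraction: float  # in [0, 1)
    extent: tuple[float, float]  # (width μm, height μm), origin at (0, 0)
    seed: int

    def __post_init__(self) -> None:
        if not self.depth > 0:
            raise ValidationError("depth must be > 0")
        if not (0 <= self.noise_fraction < 1):
            raise ValidationError("noise_fraction must lie in [0, 1)")
        w, h = self.extent
        for cx, cy, rad, k in self.cells:
            if not (0 <= cx <= w and 0 <= cy <= h):
                raise ValidationError("cell center outside extent")
            if not (0 <= k < self.signatures.n_celltypes):
                raise ValidationError("cell type index out of range")


@dataclass(frozen=True)
class GroundTruth:
    """Rasterizable ground truth: cell disks carry their type, else background."""

    cells: list[tuple[float, float, float, int]]
    n_celltypes: int
    _tree: cKDTree = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        centers = np.array([(cx, cy) for cx, cy, _, _ in self.cells])
        object.__setattr__(self, "_tree", cKDTree(centers))

    def label_map(self, grid: GridSpec) -> np.ndarray:
        """(H, W) int labels for any grid: nearest cell's type within its
        radius, -1 outside every cell."""
        xs, ys = grid.pixel_centers()
        px = np.repeat(ys, grid.width_px), np.tile(xs, grid.height_px)
        pts = np.column_stack([px[1], px[0]])  # (x, y) order
        dist, idx = self._tree.query(pts)
        radii = np.array([rad for _, _, rad, _ in self.cells])
        types = np.array([k for _, _, _, k in self.cells])
        labels = np.where(dist <= radii[idx], types[idx], -1)
        return labels.reshape(grid.height_px, grid.width_px).astype(np.int64)


def make_tissue(
    n_cells: int,
    signatures: SignatureMatrix,
    extent: tuple[float, float] = (1000.0, 1000.0),
    cell_radius: float = 10.0,
    depth: float = 20.0,
    noise_fraction: float = 0.1,
    seed: int = 0,
) -> TissueModel:
    """Place ``n_cells`` non-overlapping cells on a jittered lattice.

    Lattice spacing is chosen so the requested count fits the extent; each
    center is jittered uniformly by up to (spacing/2 − radius) per axis, which
    keeps cells disjoint ("well separated") as long as spacing > 2·radius.
    Cell types cycle through the signature rows, then are shuffled.
    """
    rng = np.random.default_rng(seed)
    w, h = extent
    nx = int(np.ceil(np.sqrt(n_cells * w / h)))
    ny = int(np.ceil(n_cells / nx))
    sx, sy = w / nx, h / ny
    if min(sx, sy) <= 2 * cell_radius:
        raise ValidationError(
            f"{n_cells} cells of radius {cell_radius} μm do not fit {w}x{h} μm without overlap"
        )
    jitter_x = sx / 2 - cell_radius
    jitter_y = sy / 2 - cell_radius
    sites = [(i, j) for j in range(ny) for i in range(nx)][:n_cells]
    types = np.arange(n_cells) % signatures.n_celltypes
    rng.shuffle(types)
    cells = []
    for (i, j), k in zip(sites, types):
        cx = (i + 0.5) * sx + rng.uniform(-jitter_x, jitter_x)
        cy = (j + 0.5) * sy + rng.uniform(-jitter_y, jitter_y)
        cells.append((float(cx), float(cy), float(cell_radius), int(k)))
    return TissueModel(
        cells=cells,
        signatures=signatures,
        depth=depth,
        noise_fraction=noise_fraction,
        extent=extent,
        seed=seed,
    )


def simulate_spots(model: TissueModel) -> tuple[SpotTable, GroundTruth]:
    """Draw a decoded-spot table from the tissue model.

    Per cell: molecule count ~ Poisson(depth); genes ~ categorical with
    probabilities proportional to the cell type's signature row; positions =
    center + isotropic Gaussian displacement (σ = radius/2), clipped to the
    extent. Noise molecules (uniform position, uniform gene over the panel)
    are added so their expected share equals ``noise_fraction``. Deterministic
    given ``model.seed``.
    """
    rng = np.random.default_rng(model.seed)
    sig = model.signatures
    row_sums = sig.values.sum(axis=1)
    if (row_sums == 0).any():
        bad = sig.celltypes[int(np.flatnonzero(row_sums == 0)[0])]
        raise ValidationError(f"signature row '{bad}' is all zero")
    probs = sig.values / row_sums[:, None]
    gene_arr = np.asarray(sig.genes, dtype=object)
    w, h = model.extent

    genes, xs, ys = [], [], []
    for cx, cy, rad, k in model.cells:
        n = rng.poisson(model.depth)
        if n == 0:
            continue
        genes.append(gene_arr[rng.choice(sig.n_genes, size=n, p=probs[k])])
        xs.append(np.clip(cx + rng.normal(0.0, rad / 2.0, size=n), 0.0, w))
        ys.append(np.clip(cy + rng.normal(0.0, rad / 2.0, size=n), 0.0, h))

    n_cell_mol = sum(len(g) for g in genes)
    if model.noise_fraction > 0:
        expected_noise = n_cell_mol * model.noise_fraction / (1.0 - model.noise_fraction)
        n_noise = rng.poisson(expected_noise)
        if n_noise:
            genes.append(gene_arr[rng.integers(0, sig.n_genes, size=n_noise)])
            xs.append(rng.uniform(0.0, w, size=n_noise))
            ys.append(rng.uniform(0.0, h, size=n_noise))

    if genes:
        spots = SpotTable(np.concatenate(genes), np.concatenate(xs), np.concatenate(ys))
    else:
        spots = SpotTable(np.array([], dtype=object), np.array([]), np.array([]))
    return spots, GroundTruth(cells=list(model.cells), n_celltypes=sig.n_celltypes)


# ---------------------------------------------------------------------------
# dataset scaling (benchmark constructions)
# ---------------------------------------------------------------------------

SCALE_FACTORS = (0.5, 2, 3, 5)


def _shifted(spots: SpotTable, dx: float, dy: float) -> SpotTable:
    return SpotTable(spots.gene.copy(), spots.x + dx, spots.y + dy)


def _concat(parts: list[SpotTable]) -> SpotTable:
    return SpotTable(
        np.concatenate([p.gene for p in parts]),
        np.concatenate([p.x for p in parts]),
        np.concatenate([p.y for p in parts]),
    )


def scale_dataset(spots: SpotTable, factor: float, seed: int = 0) -> SpotTable:
    """Down-/up-scale a spot table for throughput benchmarking.

    * 0.5× — seeded uniform sample of floor(N/2) rows without replacement;
    * 2×  — original plus a copy shifted by (+1, +1) μm;
    * 3×  — the 2× table plus the original shifted by (−1, −1) μm;
    * 5×  — original plus four copies shifted by (+1..+4, +1..+4) μm.

    Gene labels are preserved, so the gene marginal distribution is invariant
    under the upscaling constructions.
    """
    if len(spots) == 0:
        raise ValidationError("cannot scale an empty spot table")
    if factor == 0.5:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(spots), size=len(spots) // 2, replace=False)
        return spots.select(np.sort(keep))
    if factor == 2:
        return _concat([spots, _shifted(spots, 1.0, 1.0)])
    if factor == 3:
        return _concat([spots, _shifted(spots, 1.0, 1.0), _shifted(spots, -1.0, -1.0)])
    if factor == 5:
        return _concat([spots] + [_shifted(spots, float(d), float(d)) for d in (1, 2, 3, 4)])
    raise ValidationError(f"unsupported scale factor {factor}; choose one of {SCALE_FACTORS}")
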