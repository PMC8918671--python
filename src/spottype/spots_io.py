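"""Input/output for decoded-spot tables, signature matrices and cell-type maps.

Two plain-text CSV inputs drive the pipeline:

* a **coordinate table** with one row per decoded mRNA molecule (gene label
  plus x/y position in micrometers), following the DecodedSpot convention of
  the Starfish ecosystem;
* a **signature matrix** with cell types as rows and gene names as columns,
  holding binary or normalized reference expression profiles.

Outputs are a tab-separated integer label matrix, a legend CSV mapping label
indices to cell-type names and colors, a rendered PNG of the cell-type map,
and an abundance CSV.
"""

from __future__ import annotations

import colorsys
import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .errors import FormatError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .density import GridSpec

logger = logging.getLogger(__name__)

DEFAULT_COLUMNS = {"gene": "gene", "x": "x", "y": "y"}

#: RGB used for background (label -1) pixels in rendered maps.
BACKGROUND_COLOR = (210, 210, 210)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpotTable:
    """One record per decoded mRNA molecule: gene label, x/y in μm."""

    gene: np.ndarray  # dtype=object, non-empty strings
    x: np.ndarray  # float64, μm
    y: np.ndarray  # float64, μm

    def __post_init__(self) -> None:
        gene = np.asarray(self.gene, dtype=object)
        x = np.asarray(self.x, dtype=np.float64)
        y = np.asarray(self.y, dtype=np.float64)
        if not (len(gene) == len(x) == len(y)):
            raise ValidationError("gene/x/y arrays must have equal length")
        if len(x) and not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValidationError("spot coordinates must be finite")
        object.__setattr__(self, "gene", gene)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return len(self.x)

    @property
    def genes(self) -> list[str]:
        """Distinct gene labels in order of first appearance."""
        return list(pd.unique(self.gene))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.gene, "x": self.x, "y": self.y})

    def select(self, mask: np.ndarray) -> "SpotTable":
        return SpotTable(self.gene[mask], self.x[mask], self.y[mask])


@dataclass(frozen=True)
class SignatureMatrix:
    """Reference expression profiles: cell types as rows, genes as columns."""

    celltypes: list[str]
    genes: list[str]
    values: np.ndarray  # (K, G) float64, finite, >= 0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.shape != (len(self.celltypes), len(self.genes)):
            raise ValidationError("signature values shape does not match labels")
        if len(set(self.celltypes)) != len(self.celltypes):
            raise FormatError("duplicate cell-type labels in signature matrix")
        if len(set(self.genes)) != len(self.genes):
            raise FormatError("duplicate gene labels in signature matrix")
        if values.size and (not np.isfinite(values).all() or (values < 0).any()):
            raise ValidationError("signature values must be finite and >= 0")
        object.__setattr__(self, "values", values)

    @property
    def n_celltypes(self) -> int:
        return len(self.celltypes)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.celltypes, columns=self.genes)


@dataclass(frozen=True)
class CellTypeMap:
    """Per-pixel cell-type labels; -1 marks background."""

    labels: np.ndarray  # (H, W) int, entries in {-1, 0, .., K-1}
    legend: list[str]  # cell-type names, index k <-> label k
    grid: "GridSpec | None" = field(default=None, compare=False)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64)
        if labels.ndim != 2:
            raise ValidationError("label matrix must be 2-D")
        if labels.size and (labels.min() < -1 or labels.max() >= len(self.legend)):
            raise ValidationError("labels must lie in {-1, 0, .., K-1}")
        if self.grid is not None and labels.shape != (self.grid.height_px, self.grid.width_px):
            raise ValidationError("label matrix shape does not match grid")
        object.__setattr__(self, "labels", labels)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_spots(path: str | Path, columns: Mapping[str, str] | None = None) -> SpotTable:
    """Read a decoded-spot coordinate CSV into a :class:`SpotTable`.

    Parameters
    ----------
    path
        CSV file with a header row. Default column names are ``gene``, ``x``,
        ``y``; ``columns`` may remap any of them, e.g. ``{"gene": "target"}``.
        Extra (unmapped) columns such as ``z`` are tolerated and ignored.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"coordinate file not found: {path}")
    mapping = dict(DEFAULT_COLUMNS)
    if columns:
        mapping.update(columns)
    df = pd.read_csv(path)
    for role, name in mapping.items():
        if name not in df.columns:
            raise FormatError(f"coordinate file is missing column '{name}' (for '{role}')")
    gene = df[mapping["gene"]].astype(str).to_numpy(dtype=object)
    coords = {}
    for role in ("x", "y"):
        raw = df[mapping[role]]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() & raw.notna() | raw.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"non-numeric {role}-coordinate at data row {row + 1} "
                f"(value {raw.iloc[row]!r})"
            )
        coords[role] = num.to_numpy(dtype=np.float64)
    table = SpotTable(gene, coords["x"], coords["y"])
    logger.info("read %d molecules, %d distinct genes from %s", len(table), len(table.genes), path)
    return table


def write_spots(spots: SpotTable, path: str | Path) -> None:
    """Write a SpotTable in the same CSV format :func:`read_spots` reads."""
    spots.to_frame().to_csv(path, index=False, float_format="%.10g")


def read_signatures(path: str | Path) -> SignatureMatrix:
    """Read a signature CSV (first column = cell type, header = gene names)."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"signature file not found: {path}")
    # pandas mangles duplicate header names, so check the raw header first
    with open(path, newline="") as fh:
        header = next(csv.reader(fh), [])
    genes_raw = header[1:]
    if len(set(genes_raw)) != len(genes_raw):
        dup = next(g for i, g in enumerate(genes_raw) if g in genes_raw[:i])
        raise FormatError(f"duplicate gene column '{dup}' in signature file")
    df = pd.read_csv(path, index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate cell-type row '{dup}' in signature file")
    values = np.empty(df.shape, dtype=np.float64)
    for j, col in enumerate(df.columns):
        num = pd.to_numeric(df[col], errors="coerce")
        bad = num.isna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"non-numeric signature value at row '{df.index[i]}', column '{col}'"
            )
        values[:, j] = num.to_numpy()
    sig = SignatureMatrix(
        celltypes=[str(c) for c in df.index],
        genes=[str(g) for g in df.columns],
        values=values,
    )
    logger.info("read %d cell types x %d genes from %s", sig.n_celltypes, sig.n_genes, path)
    return sig


def write_signatures(sig: SignatureMatrix, path: str | Path) -> None:
    sig.to_frame().to_csv(path, float_format="%.10g")


# ---------------------------------------------------------------------------
# gene alignment
# ---------------------------------------------------------------------------


def align_genes(
    spots: SpotTable, sig: SignatureMatrix
) -> tuple[SpotTable, SignatureMatrix, dict[str, list[str]]]:
    """Restrict both inputs to their shared gene panel.

    Gene matching is case-sensitive exact string match. The signature column
    order is preserved; spot rows for genes absent from the signature panel
    are dropped with a logged warning. Returns ``(spots, sig, report)`` where
    ``report`` lists the genes dropped from each side.
    """
    spot_genes = set(spots.genes)
    sig_genes = set(sig.genes)
    shared = spot_genes & sig_genes
    if not shared:
        raise ValidationError("no genes shared between spot table and signature matrix")
    dropped_spots = sorted(spot_genes - shared)
    dropped_sig = sorted(sig_genes - shared)
    report = {"dropped_from_spots": dropped_spots, "dropped_from_signatures": dropped_sig}

    if dropped_spots:
        logger.warning(
            "dropping %d gene(s) absent from signatures: %s",
            len(dropped_spots), ", ".join(dropped_spots),
        )
        keep = np.fromiter((g in shared for g in spots.gene), dtype=bool, count=len(spots))
        spots = spots.select(keep)
    if dropped_sig:
        cols = [j for j, g in enumerate(sig.genes) if g in shared]
        sig = SignatureMatrix(
            celltypes=list(sig.celltypes),
            genes=[sig.genes[j] for j in cols],
            values=sig.values[:, cols],
        )
    return spots, sig, report


# ---------------------------------------------------------------------------
# cell-type map output
# ---------------------------------------------------------------------------


def default_palette(n: int) -> list[str]:
    """n visually distinct hex colors (evenly spaced hues, alternating value)."""
    colors = []
    for k in range(n):
        h = (k * 0.61803398875) % 1.0  # golden-ratio hue stride
        s = 0.65 if k % 2 else 0.85
        v = 0.95 if k % 3 else 0.70
        r, g, b = colorsys.hsv_to_rgb(h, s, v)
        colors.append("#{:02x}{:02x}{:02x}".format(int(r * 255), int(g * 255), int(b * 255)))
    return colors


def _hex_to_rgb(color: str) -> tuple[int, int, int]:
    c = color.lstrip("#")
    return tuple(int(c[i : i + 2], 16) for i in (0, 2, 4))  # type: ignore[return-value]


def write_map(
    ctmap: CellTypeMap,
    out_prefix: str | Path,
    palette: Sequence[str] | None = None,
) -> dict[str, Path]:
    """Write a cell-type map as label TSV + legend CSV + rendered PNG.

    Round-tripping the TSV and legend through :func:`read_map` reproduces the
    label matrix bit-exactly. Background pixels render in a fixed neutral
    gray.
    """
    if palette is None:
        palette = default_palette(len(ctmap.legend))
    if len(palette) < len(ctmap.legend):
        raise ValidationError(
            f"palette has {len(palette)} colors but legend has {len(ctmap.legend)} cell types"
        )
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    labels_path = prefix.with_name(prefix.name + "_labels.tsv")
    legend_path = prefix.with_name(prefix.name + "_legend.csv")
    png_path = prefix.with_name(prefix.name + "_map.png")

    np.savetxt(labels_path, ctmap.labels, fmt="%d", delimiter="\t")
    pd.DataFrame(
        {"label": range(len(ctmap.legend)), "celltype": ctmap.legend,
         "color": list(palette)[: len(ctmap.legend)]}
    ).to_csv(legend_path, index=False)

    lut = np.array(
        [BACKGROUND_COLOR] + [_hex_to_rgb(c) for c in list(palette)[: len(ctmap.legend)]],
        dtype=np.uint8,
    )
    rgb = lut[ctmap.labels + 1]  # shift so background (-1) indexes row 0
    Image.fromarray(rgb, mode="RGB").save(png_path)
    return {"labels": labels_path, "legend": legend_path, "png": png_path}


def read_map(out_prefix: str | Path) -> CellTypeMap:
    """Read back the label TSV + legend CSV written by :func:`write_map`."""
    prefix = Path(out_prefix)
    labels = np.loadtxt(
        prefix.with_name(prefix.name + "_labels.tsv"), dtype=np.int64, delimiter="\t", ndmin=2
    )
    legend = pd.read_csv(prefix.with_name(prefix.name + "_legend.csv"))
    return CellTypeMap(labels=labels, legend=[str(c) for c in legend["celltype"]])


def write_abundance(table: pd.DataFrame, path: str | Path) -> None:
    """Write an abundance table (celltype,count,fraction rows + background)."""
    table.to_csv(path, index=False, float_format="%.10g")


def write_density_sum(density_sum: np.ndarray, path: str | Path) -> None:
    """Export the gene-summed density matrix as TSV (the KDE heatmap quantity)."""
    np.savetxt(path, density_sum, fmt="%.10g", delimiter="\t")
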