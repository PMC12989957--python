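"""Tile-grid construction from low-magnification tissue/pen segmentation masks.

Whole-slide images are tessellated into non-overlapping tiles at the target
magnification (nominally 20x) guided by a binary tissue mask produced at a
much lower magnification (nominally 1.25x, i.e. a scale ratio of 16). A tile
of ``tile_size_20x`` pixels therefore has a footprint of
``tile_size_20x / scale`` mask pixels. Tiles that are mostly slide
background (tissue coverage below 5%) or that touch a pen marking are
excluded from the feature bags.

Conventions: the grid is anchored at the mask origin, 0-based, half-open,
row-major; partial tiles at the right/bottom edges are discarded so every
emitted tile has the same area. Coverage exactly at the threshold is kept
("less than 5%" is excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from PIL import Image

__all__ = ["TissueMask", "TileGrid", "tessellate", "filter_tiles", "read_mask_png", "write_mask_png"]


@dataclass(frozen=True)
class TissueMask:
    tissue: np.ndarray  # 2-D {0,1}
    pen: np.ndarray  # 2-D {0,1}, same shape
    mask_magnification: float = 1.25
    target_magnification: float = 20.0

    def __post_init__(self) -> None:
        t = np.asarray(self.tissue)
        p = np.asarray(self.pen)
        if t.shape != p.shape:
            raise ValueError("tissue and pen masks must share a shape")
        if t.ndim != 2:
            raise ValueError("masks must be 2-D")
        for name, m in (("tissue", t), ("pen", p)):
            if not np.isin(m, (0, 1)).all():
                raise ValueError(f"{name} mask must be binary")


@dataclass(frozen=True)
class TileGrid:
    """Per-tile bookkeeping for one mask.

    ``tiles`` is a DataFrame with columns col, row, x_px_20x, y_px_20x,
    tissue_fraction, pen_overlap, kept.
    """

    tiles: pd.DataFrame
    tile_size_20x: int
    scale: int

    @property
    def n_kept(self) -> int:
        return int(self.tiles["kept"].sum())

    @property
    def n_excluded(self) -> int:
        return int(len(self.tiles) - self.n_kept)


def tessellate(mask: TissueMask, tile_size_20x: int = 224, scale: int = 16) -> TileGrid:
    """Lay a non-overlapping tile grid over the mask and measure coverage.

    Only tiles whose footprint lies entirely within the mask are emitted.
    All emitted tiles start as kept; apply :func:`filter_tiles` to enforce
    the coverage and pen rules.
    """
    if tile_size_20x % scale != 0:
        raise ValueError(
            f"tile_size_20x={tile_size_20x} not divisible by scale={scale}"
        )
    f = tile_size_20x // scale  # footprint in mask pixels
    h, w = mask.tissue.shape
    n_rows, n_cols = h // f, w // f
    if n_rows == 0 or n_cols == 0:
        tiles = pd.DataFrame(
            columns=[
                "col", "row", "x_px_20x", "y_px_20x",
                "tissue_fraction", "pen_overlap", "kept",
            ]
        )
        return TileGrid(tiles=tiles, tile_size_20x=tile_size_20x, scale=scale)

    tissue = np.asarray(mask.tissue, dtype=np.float64)[: n_rows * f, : n_cols * f]
    pen = np.asarray(mask.pen, dtype=bool)[: n_rows * f, : n_cols * f]
    # Block-sum via reshape: (rows, f, cols, f).
    frac = tissue.reshape(n_rows, f, n_cols, f).sum(axis=(1, 3)) / (f * f)
    pen_any = pen.reshape(n_rows, f, n_cols, f).any(axis=(1, 3))

    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    tiles = pd.DataFrame(
        {
            "col": cols.ravel(),
            "row": rows.ravel(),
            "x_px_20x": cols.ravel() * tile_size_20x,
            "y_px_20x": rows.ravel() * tile_size_20x,
            "tissue_fraction": frac.ravel(),
            "pen_overlap": pen_any.ravel(),
            "kept": True,
        }
    )
    return TileGrid(tiles=tiles, tile_size_20x=tile_size_20x, scale=scale)


def filter_tiles(grid: TileGrid, min_tissue: float = 0.05) -> TileGrid:
    """Apply the exclusion rules: keep tiles with coverage >= ``min_tissue``
    and no pen overlap."""
    if not (0.0 <= min_tissue <= 1.0):
        raise ValueError("min_tissue must lie in [0, 1]")
    tiles = grid.tiles.copy()
    tiles["kept"] = (tiles["tissue_fraction"] >= min_tissue) & ~tiles["pen_overlap"]
    return replace(grid, tiles=tiles)


def write_mask_png(mask: TissueMask, tissue_path, pen_path) -> None:
    """Write the two binary channels as 8-bit PNGs (0/255)."""
    Image.fromarray((np.asarray(mask.tissue, dtype=np.uint8) * 255)).save(tissue_path)
    Image.fromarray((np.asarray(mask.pen, dtype=np.uint8) * 255)).save(pen_path)


def read_mask_png(tissue_path, pen_path, **kwargs) -> TissueMask:
    """Read binary masks from 8-bit PNGs (any nonzero pixel counts as set)."""
    tissue = (np.asarray(Image.open(tissue_path).convert("L")) > 0).astype(np.uint8)
    pen = (np.asarray(Image.open(pen_path).convert("L")) > 0).astype(np.uint8)
    return TissueMask(tissue=tissue, pen=pen, **kwargs)
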