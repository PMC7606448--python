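"""Non-overlapping tiling of slide images and background-tile removal.

A slide image is split into disjoint, axis-aligned ``tile_size x tile_size``
tiles (512 px by default, assuming inputs at x20 magnification); partial
remainders at the right/bottom edges are discarded rather than padded.
Tiles with more than 50% background — pixels whose three channels all reach
the whiteness threshold (220/255 by default) — are removed from further
analysis.  A tile at exactly the threshold fraction is kept ("more than"
is strict).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "TileGrid",
    "tile_slide",
    "background_fraction",
    "filter_tiles",
    "load_image",
]

DEFAULT_TILE_SIZE = 512
DEFAULT_WHITENESS = 220
DEFAULT_BG_THRESHOLD = 0.5


@dataclass
class TileGrid:
    """Positions and retained/background status of a slide's tiles.

    Tile ``(r, c)`` covers pixel rows ``[r*tile_size, (r+1)*tile_size)`` and
    columns likewise, row-major, 0-based, top-left origin.
    """

    slide_id: str
    tile_size: int
    rows: int
    cols: int
    retained: np.ndarray = field(default=None)  # bool (rows, cols)

    def __post_init__(self) -> None:
        if self.retained is None:
            self.retained = np.ones((self.rows, self.cols), dtype=bool)
        self.retained = np.asarray(self.retained, dtype=bool)
        if self.retained.shape != (self.rows, self.cols):
            raise ValueError(
                f"retained shape {self.retained.shape} != ({self.rows}, {self.cols})"
            )

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    def retained_positions(self) -> list[tuple[int, int]]:
        """Row-major list of (row, col) for retained tiles."""
        rr, cc = np.nonzero(self.retained)
        return list(zip(rr.tolist(), cc.tolist()))

    def to_manifest(self, fractions: np.ndarray | None = None):
        """Grid manifest as a DataFrame: slide_id, row, col, retained[, background_fraction]."""
        import pandas as pd

        rows = []
        for r in range(self.rows):
            for c in range(self.cols):
                rec = {
                    "slide_id": self.slide_id,
                    "row": r,
                    "col": c,
                    "retained": bool(self.retained[r, c]),
                }
                if fractions is not None:
                    rec["background_fraction"] = float(fractions[r, c])
                rows.append(rec)
        return pd.DataFrame(rows)


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image as an RGB uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def tile_slide(
    image: np.ndarray,
    tile_size: int = DEFAULT_TILE_SIZE,
    slide_id: str = "slide",
) -> tuple[TileGrid, dict[tuple[int, int], np.ndarray]]:
    """Split an image into its non-overlapping tile grid.

    Parameters
    ----------
    image : array (H, W, 3)
        RGB slide image, already at the target magnification.
    tile_size : int
        Side length in pixels of the square tiles.

    Returns
    -------
    (grid, tiles) where ``tiles[(r, c)]`` is the tile's pixel array (a view
    into ``image``).  ``floor(H/tile_size) * floor(W/tile_size)`` tiles are
    produced; edge remainders smaller than a full tile are dropped.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected RGB image (H, W, 3), got shape {image.shape}")
    h, w = image.shape[:2]
    if h < tile_size or w < tile_size:
        raise ValueError(
            f"image {h}x{w} smaller than one {tile_size}x{tile_size} tile"
        )
    rows, cols = h // tile_size, w // tile_size
    tiles = {
        (r, c): image[
            r * tile_size : (r + 1) * tile_size,
            c * tile_size : (c + 1) * tile_size,
        ]
        for r in range(rows)
        for c in range(cols)
    }
    grid = TileGrid(slide_id=slide_id, tile_size=tile_size, rows=rows, cols=cols)
    return grid, tiles


def background_fraction(
    tile_image: np.ndarray, whiteness: int = DEFAULT_WHITENESS
) -> float:
    """Fraction of pixels whose three channels all reach ``whiteness``."""
    tile = np.asarray(tile_image)
    if tile.ndim != 3 or tile.shape[2] != 3:
        raise ValueError(f"expected RGB tile (h, w, 3), got shape {tile.shape}")
    white = (tile >= whiteness).all(axis=2)
    return float(white.mean())


def filter_tiles(
    grid: TileGrid,
    fractions: np.ndarray,
    threshold: float = DEFAULT_BG_THRESHOLD,
) -> TileGrid:
    """Remove tiles with more than ``threshold`` background.

    ``retained(r, c) = fraction(r, c) <= threshold`` — strict "more than"
    semantics, so a tile at exactly the threshold is kept.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape != (grid.rows, grid.cols):
        raise ValueError(
            f"fractions shape {fractions.shape} != grid ({grid.rows}, {grid.cols})"
        )
    return TileGrid(
        slide_id=grid.slide_id,
        tile_size=grid.tile_size,
        rows=grid.rows,
        cols=grid.cols,
        retained=grid.retained & (fractions <= threshold),
    )
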