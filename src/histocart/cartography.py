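"""Molecular cartographies, tensor stacks and combination-colored maps.

A molecular cartography arranges a slide's binary tile predictions for one
trait in a matrix whose positions mirror the tile grid.  Stacking the
per-trait cartographies of a slide gives its tensor molecular cartography.
Collapsing the tensor tile-wise — encoding the exact subset of positive
traits at each tile as an integer — yields a combination map, the input to
the heterogeneity index and to the rendered heterogeneity maps.

Combination indices use binary encoding over the declared trait order: bit
``t`` is set iff trait ``t`` is positive, so index 0 is the all-negative
tile and, for two traits (A, B), indices 1, 2, 3 are A-only, B-only, Both.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from histocart.tiling import TileGrid
from histocart.scoring import TilePredictionSet

__all__ = [
    "MolecularCartography",
    "TensorCartography",
    "CombinationMap",
    "build_cartography",
    "stack_cartographies",
    "combination_map",
    "default_palette",
    "render_heterogeneity_map",
]


@dataclass
class MolecularCartography:
    """One trait's binary predictions in slide coordinates.

    ``matrix`` is float with values 0, 1 or NaN (missing = background /
    unretained tile).
    """

    slide_id: str
    trait: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        vals = self.matrix[~np.isnan(self.matrix)]
        if not np.isin(vals, [0.0, 1.0]).all():
            raise ValueError("cartography values must be 0, 1 or NaN")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.matrix)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.matrix).to_csv(
            path, sep="\t", index=False, header=False, na_rep="NA"
        )

    @classmethod
    def from_tsv(
        cls, path: str | Path, slide_id: str = "", trait: str = ""
    ) -> "MolecularCartography":
        mat = pd.read_csv(
            path, sep="\t", header=None, na_values=["NA"]
        ).to_numpy(dtype=float)
        return cls(slide_id=slide_id, trait=trait, matrix=mat)


@dataclass
class TensorCartography:
    """Stack of per-trait cartographies for one slide, aligned on one grid."""

    slide_id: str
    traits: list[str]
    data: np.ndarray  # (T, rows, cols), float with shared NaN mask

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] != len(self.traits):
            raise ValueError("tensor shape must be (T, rows, cols)")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.data[0])

    def layer(self, trait: str) -> np.ndarray:
        return self.data[self.traits.index(trait)]


@dataclass
class CombinationMap:
    """Matrix of positive-trait-subset indices, plus the index legend."""

    slide_id: str
    traits: list[str]
    matrix: np.ndarray  # float, values in 0..C or NaN

    @property
    def C(self) -> int:
        return 2 ** len(self.traits) - 1

    def legend(self) -> dict[int, tuple[str, ...]]:
        """index -> tuple of positive trait names (index 0 -> empty tuple)."""
        return {
            i: tuple(t for b, t in enumerate(self.traits) if i >> b & 1)
            for i in range(self.C + 1)
        }

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.matrix).to_csv(
            path, sep="\t", index=False, header=False, na_rep="NA"
        )


def build_cartography(
    predictions: TilePredictionSet | pd.DataFrame,
    grid: TileGrid,
    trait: str,
    model: str | None = None,
) -> MolecularCartography:
    """Place a slide's tile predictions at their grid positions.

    Predictions must cover all retained tiles of ``grid``; a prediction at
    a non-retained position is a consistency error.
    """
    if isinstance(predictions, TilePredictionSet):
        f = predictions.select(slide_id=grid.slide_id, trait=trait, model=model)
    else:
        f = predictions
    mat = np.full((grid.rows, grid.cols), np.nan)
    for row in f.itertuples(index=False):
        r, c = int(row.row), int(row.col)
        if not (0 <= r < grid.rows and 0 <= c < grid.cols):
            raise ValueError(f"prediction at ({r}, {c}) outside grid")
        if not grid.retained[r, c]:
            raise ValueError(f"prediction at non-retained position ({r}, {c})")
        mat[r, c] = float(row.prediction)
    uncovered = grid.retained & np.isnan(mat)
    if uncovered.any():
        miss = np.argwhere(uncovered)[0]
        raise ValueError(
            f"retained tile ({miss[0]}, {miss[1]}) has no prediction"
        )
    return MolecularCartography(slide_id=grid.slide_id, trait=trait, matrix=mat)


def stack_cartographies(
    cartographies: list[MolecularCartography],
    trait_order: list[str] | None = None,
) -> TensorCartography:
    """Stack aligned per-trait cartographies into a tensor.

    All layers must share one slide, one shape and one missing-mask.
    """
    if not cartographies:
        raise ValueError("need at least one cartography")
    by_trait = {c.trait: c for c in cartographies}
    if trait_order is None:
        trait_order = [c.trait for c in cartographies]
    layers = [by_trait[t] for t in trait_order]
    first = layers[0]
    for lay in layers[1:]:
        if lay.slide_id != first.slide_id:
            raise ValueError("layers belong to different slides")
        if lay.matrix.shape != first.matrix.shape:
            raise ValueError("layer shapes differ")
        if not np.array_equal(lay.missing_mask, first.missing_mask):
            raise ValueError("layer missing-masks differ")
    data = np.stack([lay.matrix for lay in layers])
    return TensorCartography(
        slide_id=first.slide_id, traits=list(trait_order), data=data
    )


def combination_map(tensor: TensorCartography) -> CombinationMap:
    """Encode each tile's positive-trait subset as a binary index.

    ``index(r, c) = sum_t 2**t * layer_t(r, c)`` over non-missing tiles;
    missing tiles stay NaN.
    """
    weights = 2 ** np.arange(len(tensor.traits), dtype=float)
    mat = np.tensordot(weights, tensor.data, axes=(0, 0))
    return CombinationMap(
        slide_id=tensor.slide_id, traits=list(tensor.traits), matrix=mat
    )


def default_palette(trait_count: int) -> dict[int | str, tuple[int, int, int]]:
    """Colors for combination indices 0..C plus the missing key.

    For two traits the scheme follows the field's convention for
    heterogeneity maps: one color per single trait, a blend color when both
    traits manifest, light gray for all-negative tiles, white for missing.
    Larger trait counts get evenly spaced hues.
    """
    C = 2 ** trait_count - 1
    palette: dict[int | str, tuple[int, int, int]] = {
        0: (211, 211, 211),
        "missing": (255, 255, 255),
    }
    if trait_count == 1:
        palette[1] = (199, 21, 133)
    elif trait_count == 2:
        palette[1] = (219, 112, 147)  # trait 1 only (pink)
        palette[2] = (60, 179, 113)   # trait 2 only (green)
        palette[3] = (139, 69, 19)    # both (brown)
    else:
        import colorsys

        for i in range(1, C + 1):
            r, g, b = colorsys.hsv_to_rgb((i - 1) / C, 0.75, 0.82)
            palette[i] = (int(r * 255), int(g * 255), int(b * 255))
    return palette


def render_heterogeneity_map(
    combo: CombinationMap,
    palette: dict | None = None,
    tile_px: int = 16,
    out_path: str | Path | None = None,
    legend_path: str | Path | None = None,
) -> np.ndarray:
    """Render a combination map as a block image, one color per combination.

    Each tile becomes a ``tile_px``-square block of its combination's
    palette color; missing tiles use the palette's ``missing`` color.
    Deterministic: identical inputs yield byte-identical images.
    """
    if palette is None:
        palette = default_palette(len(combo.traits))
    needed = set(range(combo.C + 1)) | {"missing"}
    if not needed <= set(palette):
        raise ValueError("palette does not cover all combination indices")
    rows, cols = combo.matrix.shape
    rgb = np.zeros((rows, cols, 3), dtype=np.uint8)
    for r in range(rows):
        for c in range(cols):
            v = combo.matrix[r, c]
            key = "missing" if np.isnan(v) else int(v)
            rgb[r, c] = palette[key]
    img = np.kron(rgb, np.ones((tile_px, tile_px, 1), dtype=np.uint8))
    if out_path is not None:
        Image.fromarray(img).save(out_path)
    if legend_path is not None:
        legend = {
            str(i): {"traits": list(subset), "color": list(palette[i])}
            for i, subset in combo.legend().items()
        }
        legend["missing"] = {"traits": None, "color": list(palette["missing"])}
        Path(legend_path).write_text(json.dumps(legend, indent=2))
    return img
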