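"""Slide-to-tile geometry, foreground filtering and the feature contract.

A whole-slide image is divided into fixed-size square tiles (default 224 px,
~112 µm at the working magnification).  A binary tissue mask — produced
upstream by any segmenter — decides which tiles contain enough matter: a tile
is kept when at least ``min_matter`` (default 50%) of its pixels are
foreground.  Conventions, used everywhere: 0-based coordinates, half-open
pixel boxes [x0, x0+tile_px) × [y0, y0+tile_px), row-major tile order.
Border strips that do not fit a complete tile are discarded.

Feature extraction is a pluggable contract: any stateless callable mapping a
tile to a fixed-dimension vector (the production choice would be a frozen
pretrained CNN; synthetic extractors are provided for testing).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, List, Sequence, Tuple, Union

import numpy as np

from .exceptions import ContractViolationError, ShapeMismatchError

TILE_PX_DEFAULT = 224
TILE_UM_DEFAULT = 112.0
MIN_MATTER_DEFAULT = 0.5


@dataclass
class TileGrid:
    """Tile geometry of one slide after foreground filtering.

    ``tiles`` rows are (row, col, x0, y0, matter_fraction) in row-major
    order; x is the column-pixel axis, y the row-pixel axis.
    """

    slide_id: str
    tile_px: int = TILE_PX_DEFAULT
    tile_um: float = TILE_UM_DEFAULT
    tiles: List[Tuple[int, int, int, int, float]] = None

    def __post_init__(self):
        if self.tiles is None:
            self.tiles = []

    def __len__(self) -> int:
        return len(self.tiles)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.tiles,
                            columns=["row", "col", "x0", "y0", "matter_fraction"])


@dataclass
class FeatureMatrix:
    """Per-tile feature vectors of one slide, paired with a TileGrid."""

    slide_id: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeMismatchError("feature matrix must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ContractViolationError(
                f"slide {self.slide_id}: non-finite feature values")

    @property
    def n_tiles(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


def load_mask(source: Union[str, Path, np.ndarray]) -> np.ndarray:
    """Binary mask from an array or an 8-bit single-channel raster file.

    Any value strictly above half the dtype range (or above 0 for boolean /
    0-1 arrays) counts as foreground.
    """
    if isinstance(source, (str, Path)):
        import matplotlib.image as mpimg
        arr = mpimg.imread(str(source))
        if arr.ndim == 3:           # collapse a grayscale-encoded RGB(A)
            arr = arr[..., 0]
        return arr > (0.5 * arr.max() if arr.max() > 1 else 0.5)
    arr = np.asarray(source)
    if arr.dtype == bool:
        return arr
    return arr > (127 if arr.max() > 1 else 0.5)


def tile_slide(mask: Union[np.ndarray, str, Path], tile_px: int = TILE_PX_DEFAULT,
               min_matter: float = MIN_MATTER_DEFAULT,
               slide_id: str = "slide", tile_um: float = TILE_UM_DEFAULT,
               ) -> TileGrid:
    """Tile a binary tissue mask into complete tiles passing the matter filter.

    Parameters
    ----------
    mask : 2-D binary array (True/nonzero = foreground) or raster path.
    tile_px : tile side in pixels.
    min_matter : minimum foreground fraction for a tile to be kept.

    Returns an empty grid (not an error) when the mask is smaller than one
    tile in either dimension.
    """
    mask = load_mask(mask)
    if mask.size == 0:
        raise ValueError("empty mask")
    if tile_px < 1:
        raise ValueError("tile_px must be >= 1")
    h, w = mask.shape
    n_rows, n_cols = h // tile_px, w // tile_px
    tiles = []
    m = mask.astype(float)
    for r in range(n_rows):
        for c in range(n_cols):
            y0, x0 = r * tile_px, c * tile_px
            frac = float(m[y0:y0 + tile_px, x0:x0 + tile_px].mean())
            if frac >= min_matter:
                tiles.append((r, c, x0, y0, frac))
    return TileGrid(slide_id=slide_id, tile_px=tile_px, tile_um=tile_um,
                    tiles=tiles)


def extract_features(grid: TileGrid, source: Sequence,
                     extractor: Callable, d: int) -> FeatureMatrix:
    """Apply a pluggable tile->vector extractor over a grid.

    ``source`` supplies one item per grid tile (pixels, latent labels —
    whatever the extractor consumes).  The extractor must be stateless per
    tile and return a finite vector of the declared dimension ``d``; row i of
    the output corresponds to tile i of the grid.
    """
    if len(source) != len(grid):
        raise ShapeMismatchError(
            f"slide {grid.slide_id}: {len(source)} source items for "
            f"{len(grid)} grid tiles")
    rows = np.empty((len(grid), d))
    for i, item in enumerate(source):
        v = np.asarray(extractor(item), dtype=float).ravel()
        if v.shape != (d,):
            raise ContractViolationError(
                f"slide {grid.slide_id}, tile {i}: extractor returned "
                f"shape {v.shape}, expected ({d},)")
        if not np.all(np.isfinite(v)):
            raise ContractViolationError(
                f"slide {grid.slide_id}, tile {i}: non-finite extractor output")
        rows[i] = v
    return FeatureMatrix(slide_id=grid.slide_id, values=rows)


class GaussianExtractor:
    """Synthetic extractor: a seeded Gaussian vector per tile.

    Deterministic: the vector depends only on (seed, tile item hash), so the
    same grid yields the same matrix on every call.
    """

    def __init__(self, d: int, seed: int = 0):
        self.d = d
        self.seed = seed

    def __call__(self, item) -> np.ndarray:
        h = hash((self.seed, repr(item))) % (2 ** 31)
        return np.random.default_rng(h).normal(size=self.d)
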