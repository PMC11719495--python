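"""Tile 35 per-channel scalogram images into one 500x700 composite.

Channel i's tile sits at grid column ``i % 7`` and grid row ``i // 7``
(row-major filling: x fast, y slow), so 35 tiles of 100x100 px form a
7-column x 5-row composite of 700 px width and 500 px height. Pixel (0, 0)
is the top-left corner; row indices increase downward. Tiles are placed by
exact block copy — no resampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TileLayout", "tile_position", "compose", "extract_tile"]


@dataclass(frozen=True)
class TileLayout:
    n_cols: int = 7
    n_rows: int = 5
    tile_size: tuple[int, int] = (100, 100)  # (height, width) px

    def __post_init__(self) -> None:
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid dimensions must be positive")
        if min(self.tile_size) < 1:
            raise ValueError("tile size must be positive")

    @property
    def n_tiles(self) -> int:
        return self.n_cols * self.n_rows

    @property
    def composite_shape(self) -> tuple[int, int, int]:
        """(height, width, channels) of the composite image."""
        return (
            self.n_rows * self.tile_size[0],
            self.n_cols * self.tile_size[1],
            3,
        )


def tile_position(i: int, layout: TileLayout = TileLayout()) -> tuple[int, int]:
    """Grid (col, row) of channel index ``i``: col = i % 7, row = i // 7."""
    if not (0 <= i < layout.n_tiles):
        raise ValueError(f"tile index {i} outside 0..{layout.n_tiles - 1}")
    return i % layout.n_cols, i // layout.n_cols


def _check_tile(tile: np.ndarray, layout: TileLayout) -> np.ndarray:
    tile = np.asarray(tile)
    expected = (*layout.tile_size, 3)
    if tile.shape != expected:
        raise ValueError(f"tile shape {tile.shape} != expected {expected}")
    return tile


def compose(tiles, layout: TileLayout = TileLayout()) -> np.ndarray:
    """Concatenate the per-channel tiles into one composite image.

    ``tiles`` must hold exactly ``layout.n_tiles`` images of shape
    (tile_h, tile_w, 3); tile i occupies pixel rows
    [row*tile_h, (row+1)*tile_h) and columns [col*tile_w, (col+1)*tile_w).
    """
    tiles = list(tiles)
    if len(tiles) != layout.n_tiles:
        raise ValueError(f"expected {layout.n_tiles} tiles, got {len(tiles)}")
    th, tw = layout.tile_size
    out = np.zeros(layout.composite_shape, dtype=np.asarray(tiles[0]).dtype)
    for i, tile in enumerate(tiles):
        tile = _check_tile(tile, layout)
        col, row = tile_position(i, layout)
        out[row * th : (row + 1) * th, col * tw : (col + 1) * tw] = tile
    return out


def extract_tile(
    composite: np.ndarray, i: int, layout: TileLayout = TileLayout()
) -> np.ndarray:
    """Exact pixel-block slice of tile ``i``; inverse of :func:`compose`."""
    composite = np.asarray(composite)
    if composite.shape != layout.composite_shape:
        raise ValueError(
            f"composite shape {composite.shape} != expected {layout.composite_shape}"
        )
    col, row = tile_position(i, layout)
    th, tw = layout.tile_size
    return composite[row * th : (row + 1) * th, col * tw : (col + 1) * tw].copy()
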