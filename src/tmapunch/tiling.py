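"""Punching-grid tiling and annotated reassembly.

A normalised slide is cut into a rows x cols punching grid (default 8 x 9,
the grid used to sample one core per cell).  Base cell size is the floor
division of the image size; the last row / column absorbs the remainder, so
the cells partition the image exactly.  After classification the tiles are
reassembled into one overview image with a coloured border per tile:
red = affected, green = unaffected, gray = non-informative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .errors import GridMismatchError

__all__ = [
    "AFFECTED",
    "UNAFFECTED",
    "NON_INFORMATIVE",
    "TILE_LABELS",
    "BORDER_COLORS",
    "GridSpec",
    "make_grid",
    "cut_tiles",
    "annotate_and_reassemble",
]

AFFECTED = "affected"
UNAFFECTED = "unaffected"
NON_INFORMATIVE = "non_informative"
TILE_LABELS = (AFFECTED, UNAFFECTED, NON_INFORMATIVE)

BORDER_COLORS = {
    AFFECTED: (255, 0, 0),
    UNAFFECTED: (0, 200, 0),
    NON_INFORMATIVE: (128, 128, 128),
}


@dataclass(frozen=True)
class GridSpec:
    """Rectangular grid of half-open pixel cells partitioning an image."""

    width: int
    height: int
    rows: int
    cols: int

    @property
    def n_tiles(self) -> int:
        return self.rows * self.cols

    def bounds(self, row: int, col: int) -> Tuple[int, int, int, int]:
        """(y0, y1, x0, x1) of the 0-based cell, half-open."""
        ch = self.height // self.rows
        cw = self.width // self.cols
        y0 = row * ch
        x0 = col * cw
        y1 = self.height if row == self.rows - 1 else y0 + ch
        x1 = self.width if col == self.cols - 1 else x0 + cw
        return y0, y1, x0, x1

    def cells(self) -> List[Tuple[int, int, int, int]]:
        """All cell bounds in row-major order."""
        return [
            self.bounds(r, c) for r in range(self.rows) for c in range(self.cols)
        ]


def make_grid(width: int, height: int, rows: int = 8, cols: int = 9) -> GridSpec:
    """Build the punching grid for an image of the given pixel size."""
    if rows <= 0 or cols <= 0:
        raise ValueError("rows and cols must be positive")
    if rows > height or cols > width:
        raise ValueError(
            f"grid {rows}x{cols} exceeds image size {width}x{height}"
        )
    return GridSpec(width=int(width), height=int(height), rows=rows, cols=cols)


def cut_tiles(image: np.ndarray, grid: GridSpec) -> List[np.ndarray]:
    """Cut the image into row-major tiles; a lossless partition."""
    img = np.asarray(image)
    h, w = img.shape[:2]
    if (w, h) != (grid.width, grid.height):
        raise GridMismatchError(
            f"grid built for {grid.width}x{grid.height}, image is {w}x{h}"
        )
    return [img[y0:y1, x0:x1].copy() for y0, y1, x0, x1 in grid.cells()]


def annotate_and_reassemble(
    tiles: Sequence[np.ndarray],
    labels: Sequence[str],
    grid: GridSpec,
    border_px: int = 5,
) -> np.ndarray:
    """Reassemble tiles into one image, framing each with its label colour."""
    if len(tiles) != grid.n_tiles or len(labels) != grid.n_tiles:
        raise ValueError(
            f"expected {grid.n_tiles} tiles and labels, "
            f"got {len(tiles)} / {len(labels)}"
        )
    out = np.zeros((grid.height, grid.width, 3), dtype=np.uint8)
    for (y0, y1, x0, x1), tile, label in zip(grid.cells(), tiles, labels):
        if label not in BORDER_COLORS:
            raise ValueError(f"unknown tile label {label!r}")
        th, tw = y1 - y0, x1 - x0
        if tile.shape[:2] != (th, tw):
            raise GridMismatchError("tile size does not match its grid cell")
        cell = tile if tile.ndim == 3 else np.stack([tile] * 3, axis=-1)
        view = out[y0:y1, x0:x1]
        view[:] = cell
        b = min(border_px, th // 2, tw // 2)
        if b > 0:
            color = BORDER_COLORS[label]
            view[:b, :] = color
            view[-b:, :] = color
            view[:, :b] = color
            view[:, -b:] = color
    return out
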