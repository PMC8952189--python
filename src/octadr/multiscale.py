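"""Multi-scale decomposition of a composite frame.

One full frame is analyzed at four levels: the frame itself, four
non-overlapping quarters, sixteen non-overlapping tiles, and a single
centered crop around the fovea.  For a 1024-pixel frame the quarters
are 512 px, the tiles 256 px and the fovea crop 512 px, each level
feeding its own classifier.

Conventions: 0-based (row, col) origins, half-open windows, row-major
tile order.  Tiles inherit the parent's subject id and label (tiles
carry the whole-image label as a weak label).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .channels import CompositeImage

__all__ = ["TileGrid", "split_tiles", "stitch_tiles", "crop_fovea", "LEVELS", "decompose"]

LEVELS = ("full", "quarters", "sixteenths", "fovea")


@dataclass
class TileGrid:
    """Ordered patches with their (row, col) origins and the source geometry."""

    tiles: list[CompositeImage]
    origins: list[tuple[int, int]]
    level: str
    source_side: int
    tile_px: int


def split_tiles(src: CompositeImage, tile_px: int, level: str | None = None) -> TileGrid:
    """Split a square composite into non-overlapping row-major tiles.

    The source side must be divisible by ``tile_px``; each tile keeps
    its origin so the grid can be stitched back bit-identically.
    """
    side = src.channels.shape[0]
    if src.channels.shape[1] != side:
        raise ValueError(f"source must be square, got {src.channels.shape[:2]}")
    if tile_px < 1 or side % tile_px != 0:
        raise ValueError(f"source side {side} is not divisible by tile_px {tile_px}")
    n = side // tile_px
    if level is None:
        level = {1: "full", 2: "quarters", 4: "sixteenths"}.get(n, f"grid{n}x{n}")
    tiles, origins = [], []
    for r in range(n):
        for c in range(n):
            r0, c0 = r * tile_px, c * tile_px
            patch = src.channels[r0 : r0 + tile_px, c0 : c0 + tile_px]
            tiles.append(
                CompositeImage(channels=patch.copy(), subject_id=src.subject_id, label=src.label)
            )
            origins.append((r0, c0))
    return TileGrid(tiles=tiles, origins=origins, level=level, source_side=side, tile_px=tile_px)


def stitch_tiles(grid: TileGrid) -> CompositeImage:
    """Reassemble a full frame from a tile grid (origins, not order, place tiles)."""
    side, t = grid.source_side, grid.tile_px
    expected = {(r * t, c * t) for r in range(side // t) for c in range(side // t)}
    present = set(grid.origins)
    missing = sorted(expected - present)
    if missing:
        raise ValueError(f"missing tiles at origins {missing}")
    out = np.empty((side, side, grid.tiles[0].channels.shape[2]), dtype=grid.tiles[0].channels.dtype)
    for tile, (r0, c0) in zip(grid.tiles, grid.origins):
        out[r0 : r0 + t, c0 : c0 + t] = tile.channels
    first = grid.tiles[0]
    return CompositeImage(channels=out, subject_id=first.subject_id, label=first.label)


def crop_fovea(src: CompositeImage, crop_px: int, offset: tuple[int, int] | None = None) -> CompositeImage:
    """Centered crop around the fovea (the frame centre for en-face scans).

    For a 1024 source and crop_px=512 the window is rows/cols
    [256, 768).  Odd remainders floor the top-left offset.  A manual
    ``offset`` overrides the centring.
    """
    h, w = src.channels.shape[:2]
    if crop_px > min(h, w):
        raise ValueError(f"crop_px {crop_px} exceeds source side {min(h, w)}")
    if offset is None:
        r0, c0 = (h - crop_px) // 2, (w - crop_px) // 2
    else:
        r0, c0 = offset
        if not (0 <= r0 <= h - crop_px and 0 <= c0 <= w - crop_px):
            raise ValueError(f"offset {offset} places the crop outside the frame")
    patch = src.channels[r0 : r0 + crop_px, c0 : c0 + crop_px].copy()
    return CompositeImage(channels=patch, subject_id=src.subject_id, label=src.label)


def decompose(src: CompositeImage, levels: tuple[str, ...] = LEVELS) -> dict[str, list[CompositeImage]]:
    """All requested analysis levels of one frame, keyed by level name.

    Quarters are side/2 tiles, sixteenths side/4 tiles, and the fovea
    crop is side/2 centered — the scale ratios used for 1024-pixel
    frames, applied to any divisible side.
    """
    side = src.channels.shape[0]
    out: dict[str, list[CompositeImage]] = {}
    for level in levels:
        if level == "full":
            out[level] = [src]
        elif level == "quarters":
            out[level] = split_tiles(src, side // 2, level).tiles
        elif level == "sixteenths":
            out[level] = split_tiles(src, side // 4, level).tiles
        elif level == "fovea":
            out[level] = [crop_fovea(src, side // 2)]
        else:
            raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")
    return out
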