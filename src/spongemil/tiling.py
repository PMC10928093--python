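"""On-the-fly tiling of preprocessed slides into MIL bags.

Slides are split into non-overlapping 224 px tiles (about 200 um at 10x),
optionally from a random grid offset so successive epochs see different
tilings.  Background tiles (whitened to plain white upstream) are excluded
by a mean-intensity threshold, and training bags keep the K darkest tiles —
dense cellular regions are inherently darker.
"""

from __future__ import annotations

import numpy as np

from .types import SlideImage, TileBag, TileGrid

TILE_SIZE = 224
#: tiles with mean RGB intensity above this fraction of 255 are background
BACKGROUND_INTENSITY_FRACTION = 0.90


def _pixels(image) -> np.ndarray:
    return image.pixels if isinstance(image, SlideImage) else np.asarray(image)


def grid_tiles(image, tile_size: int = TILE_SIZE, random_offset: bool = False,
               rng: np.random.Generator | None = None) -> TileGrid:
    """Non-overlapping grid of fully-contained tiles.

    With ``random_offset`` the origin is drawn uniformly in
    ``[0, tile_size)^2``; partial tiles at the borders are dropped, giving
    ``floor((H - dy) / t) * floor((W - dx) / t)`` tiles.
    """
    pixels = _pixels(image)
    h, w = pixels.shape[:2]
    if h < tile_size or w < tile_size:
        raise ValueError(f"image {h}x{w} smaller than one {tile_size} px tile")
    if random_offset:
        if rng is None:
            raise ValueError("random_offset=True requires an rng")
        # bound the offset so at least one full tile always fits
        dx = int(rng.integers(0, min(tile_size, w - tile_size + 1)))
        dy = int(rng.integers(0, min(tile_size, h - tile_size + 1)))
    else:
        dx = dy = 0
    ny = (h - dy) // tile_size
    nx = (w - dx) // tile_size
    ys = dy + tile_size * np.arange(ny)
    xs = dx + tile_size * np.arange(nx)
    gx, gy = np.meshgrid(xs, ys)
    coords = np.stack([gx.ravel(), gy.ravel()], axis=1)
    return TileGrid(origin_offset=(dx, dy), tile_size=tile_size, coords=coords)


def tile_mean_intensities(image, grid: TileGrid) -> np.ndarray:
    """Mean RGB intensity of each grid tile (raster order of ``grid.coords``)."""
    pixels = _pixels(image).astype(float)
    t = grid.tile_size
    return np.array([
        pixels[y:y + t, x:x + t].mean() for x, y in grid.coords
    ])


def filter_background(image, grid: TileGrid,
                      threshold: float = BACKGROUND_INTENSITY_FRACTION) -> TileGrid:
    """Drop tiles whose mean intensity exceeds ``threshold * 255``."""
    means = tile_mean_intensities(image, grid)
    keep = means <= threshold * 255.0
    if not keep.any():
        raise ValueError("no foreground tiles after background filtering")
    return TileGrid(origin_offset=grid.origin_offset, tile_size=grid.tile_size,
                    coords=grid.coords[keep])


def select_bag(image, grid: TileGrid, k: int,
               slide_id: str = "") -> TileBag:
    """Bag of the K lowest mean-intensity tiles (all tiles if fewer than K).

    Ties are broken deterministically in raster (y, x) order.
    """
    if k <= 0:
        raise ValueError("bag size K must be positive")
    if len(grid) == 0:
        raise ValueError("empty tile grid")
    means = tile_mean_intensities(image, grid)
    # lexsort: primary key last -> sort by intensity, then y, then x
    order = np.lexsort((grid.coords[:, 0], grid.coords[:, 1], means))
    chosen = order[:k]
    chosen.sort()  # keep raster order inside the bag
    return TileBag(
        slide_id=slide_id,
        coords=grid.coords[chosen],
        intensity_scores=means[chosen],
        selection_mode="min_intensity" if k < len(grid) else "all",
        tile_size=grid.tile_size,
    )


def whole_slide_bag(image, tile_size: int = TILE_SIZE,
                    threshold: float = BACKGROUND_INTENSITY_FRACTION,
                    slide_id: str = "") -> TileBag:
    """All foreground tiles at zero offset — the whole-slide inference bag."""
    grid = filter_background(image, grid_tiles(image, tile_size), threshold)
    means = tile_mean_intensities(image, grid)
    return TileBag(slide_id=slide_id, coords=grid.coords,
                   intensity_scores=means, selection_mode="all",
                   tile_size=tile_size)


def extract_tile(image, coord, tile_size: int = TILE_SIZE) -> np.ndarray:
    x, y = int(coord[0]), int(coord[1])
    pixels = _pixels(image)
    tile = pixels[y:y + tile_size, x:x + tile_size]
    if tile.shape[:2] != (tile_size, tile_size):
        raise ValueError(f"tile at ({x},{y}) not fully inside the image")
    return tile


def extract_bag_tiles(image, bag: TileBag) -> np.ndarray:
    """Stack of bag tiles, shape (K, tile, tile, 3)."""
    return np.stack([extract_tile(image, c, bag.tile_size) for c in bag.coords])


def dihedral_transform(tile: np.ndarray, element: int) -> np.ndarray:
    """Apply element ``0..7`` of the dihedral group D4 to a square tile.

    Elements 0-3 are counter-clockwise rotations by 90 deg * k; elements 4-7
    additionally flip horizontally first.
    """
    if not 0 <= element < 8:
        raise ValueError("dihedral element must be in 0..7")
    out = tile[:, ::-1] if element >= 4 else tile
    return np.rot90(out, k=element % 4)


def augment(tile: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniformly random 90-degree rotation / flip of a square tile."""
    if tile.shape[0] != tile.shape[1]:
        raise ValueError("augmentation requires a square tile")
    return dihedral_transform(tile, int(rng.integers(0, 8)))
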