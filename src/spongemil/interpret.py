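"""Interpretability outputs: attention heatmaps, top/bottom-k tiles,
normalized attention entropy and Grad-CAM tile saliency."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage as ndi

from . import nn
from .mil_model import TransMIL
from .tiling import extract_tile
from .types import SlidePrediction


@dataclass
class AttentionHeatmap:
    """Per-tile attention values stitched onto the slide raster.

    ``array`` holds each tile footprint filled with its attention weight
    (NaN outside tiles); rendering uses a reversed spectral colormap (red =
    high attention, blue = low).
    """

    array: np.ndarray
    tile_size: int
    mean_attention: float


def stitch_heatmap(prediction: SlidePrediction, slide_shape: tuple[int, int],
                   tile_size: int = 224) -> AttentionHeatmap:
    """Fill each tile footprint with its attention value."""
    h, w = slide_shape[:2]
    array = np.full((h, w), np.nan)
    for (x, y), a in zip(prediction.coords, prediction.attention):
        if not (0 <= x and x + tile_size <= w and 0 <= y and y + tile_size <= h):
            raise ValueError(f"tile at ({x},{y}) outside the slide")
        array[y:y + tile_size, x:x + tile_size] = a
    return AttentionHeatmap(array=array, tile_size=tile_size,
                            mean_attention=float(prediction.attention.mean()))


def render_heatmap(heatmap: AttentionHeatmap, image=None, path=None,
                   alpha: float = 0.5):
    """Optional PNG overlay with the reversed-spectral colormap; returns the
    matplotlib figure.  The numeric heatmap array is the tested surface."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    if image is not None:
        pixels = image.pixels if hasattr(image, "pixels") else image
        ax.imshow(pixels)
        im = ax.imshow(heatmap.array, cmap="Spectral_r", alpha=alpha)
    else:
        im = ax.imshow(heatmap.array, cmap="Spectral_r")
    cbar = fig.colorbar(im, ax=ax)
    cbar.ax.axhline(heatmap.mean_attention, color="k")
    cbar.set_label(f"attention (mean {heatmap.mean_attention:.4f})")
    ax.set_axis_off()
    if path is not None:
        fig.savefig(path, dpi=100, bbox_inches="tight")
        plt.close(fig)
    return fig


def extract_attention(heatmap: AttentionHeatmap, coords) -> np.ndarray:
    """Read back per-tile attention values from a stitched heatmap."""
    return np.array([heatmap.array[y, x] for x, y in np.asarray(coords)])


def topk_tiles(prediction: SlidePrediction, image, k: int,
               direction: str = "high", tile_size: int = 224):
    """The k tiles with highest (or lowest) attention, with their crops.

    Ties are broken by raster (y, x) order.  Returns a list of
    ``(coord, attention, crop)`` sorted by attention in the requested
    direction.
    """
    if direction not in ("high", "low"):
        raise ValueError("direction must be 'high' or 'low'")
    n = len(prediction.attention)
    if k > n:
        raise ValueError(f"k={k} exceeds bag size {n}")
    key = -prediction.attention if direction == "high" else prediction.attention
    order = np.lexsort((prediction.coords[:, 0], prediction.coords[:, 1], key))
    out = []
    for idx in order[:k]:
        coord = tuple(prediction.coords[idx])
        out.append((coord, float(prediction.attention[idx]),
                    extract_tile(image, coord, tile_size)))
    return out


def normalized_entropy(attention) -> float:
    """Shannon entropy of the attention weights divided by its maximum.

    H = -sum(a_k ln a_k) / ln(N) with 0 ln 0 := 0; base-independent after
    normalization.  Defined as 0 for a single-tile bag.
    """
    a = np.asarray(attention, dtype=float).ravel()
    if np.any(a < -1e-12):
        raise ValueError("attention weights must be non-negative")
    if abs(a.sum() - 1.0) > 1e-6:
        raise ValueError("attention weights must sum to 1")
    n = len(a)
    if n == 1:
        return 0.0
    pos = a[a > 0]
    h = -(pos * np.log(pos)).sum()
    return float(h / np.log(n))


@dataclass
class SaliencyMap:
    """Non-negative, max-normalized Grad-CAM raster upsampled to tile size."""

    tile_index: int
    map: np.ndarray
    target_layer: str


def gradcam_tile(model: TransMIL, tiles: np.ndarray, tile_index: int,
                 target_layer: str = "conv3") -> SaliencyMap:
    """Grad-CAM saliency of the slide logit for one tile of a bag.

    Channel weights are the spatial mean of the logit gradient at the target
    convolutional activation; the map is ReLU(sum_c alpha_c A^c), bilinearly
    upsampled to the tile size and max-normalized to [0, 1].
    """
    available = model.encoder.layer_names()
    if target_layer not in available:
        raise ValueError(
            f"unknown layer {target_layer!r}; available layers: {available}")
    tiles = np.asarray(tiles)
    if tiles.ndim == 3:
        tiles = tiles[None]
    if not 0 <= tile_index < len(tiles):
        raise IndexError("tile_index outside the bag")
    was_training = model.training
    model.eval()
    model.encoder.cache_activations = True
    try:
        logit, _ = model.forward(tiles)
        activation = model.encoder.activations[target_layer]
        logit.backward()
    finally:
        model.encoder.cache_activations = False
        model.encoder.activations = {}
        model.train(was_training)
        model.zero_grad()
    act = activation.data[tile_index]          # (C, h, w)
    grad = activation.grad[tile_index]
    alpha = grad.mean(axis=(1, 2))             # channel weights
    cam = np.maximum((alpha[:, None, None] * act).sum(axis=0), 0.0)
    tile_size = tiles.shape[1]
    cam = ndi.zoom(cam, tile_size / cam.shape[0], order=1)
    cam = np.maximum(cam, 0.0)
    if cam.max() > 0:
        cam = cam / cam.max()
    return SaliencyMap(tile_index=tile_index, map=cam,
                       target_layer=target_layer)
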