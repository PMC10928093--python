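"""Shared containers flowing through the screening pipeline.

A slide is an RGB raster plus physical pixel-size metadata (microns per
pixel, ``mpp``); everything downstream — masking, tiling, the MIL model,
stain quantification — is expressed against these containers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

#: physical pixel size (um/px) of the scanners' highest magnification (40x)
MPP_40X = 0.23
#: export scale used for model training/inference (10x objective)
MPP_10X = 0.92
#: coarse scale at which foreground morphology is performed (1.25x objective)
MPP_1_25X = 7.36

HE = "HE"
TFF3 = "TFF3"


@dataclass
class SlideImage:
    """RGB 8-bit slide raster with physical metadata.

    ``mpp`` is microns per pixel at the raster's own scale.  ``magnification``
    is the nominal objective (e.g. 10 for 10x) and, when present, must be
    consistent with ``mpp`` assuming 0.23 um/px at 40x (within 5%).
    """

    pixels: np.ndarray
    mpp: float
    stain: str = HE
    slide_id: str = ""
    label: Optional[int] = None
    magnification: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("SlideImage.pixels must be an HxWx3 raster")
        if not self.mpp > 0:
            raise ValueError("mpp must be positive")
        if self.stain not in (HE, TFF3):
            raise ValueError(f"stain must be one of {HE!r}, {TFF3!r}")
        if self.magnification is not None:
            implied = MPP_40X * 40.0 / self.magnification
            if abs(self.mpp - implied) > 0.05 * implied:
                raise ValueError(
                    f"mpp {self.mpp} inconsistent with magnification "
                    f"{self.magnification} (implied {implied:.3f} um/px)"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class ForegroundMask:
    """Binary tissue mask aligned to a slide raster."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def foreground_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass(frozen=True)
class SectionBox:
    """Half-open pixel box [x0, x1) x [y0, y1), 0-based."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError("SectionBox must have positive extent")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1


@dataclass
class StainMatrix:
    """Unit stain vectors (rows) in optical-density RGB space."""

    rows: np.ndarray
    names: Sequence[str]

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.ndim != 2 or self.rows.shape[1] != 3:
            raise ValueError("StainMatrix.rows must be (n_stains, 3)")
        norms = np.linalg.norm(self.rows, axis=1)
        if np.any(norms <= 0):
            raise ValueError("stain vectors must be nonzero")
        self.rows = self.rows / norms[:, None]
        if len(self.names) != self.rows.shape[0]:
            raise ValueError("names must match number of rows")


@dataclass
class GroundTruthMask:
    """Planted tile-level truth for a synthetic slide.

    ``tile_positive[i, j]`` is True iff grid tile (row i, col j) of the
    zero-offset tiling intersects at least one planted goblet-cell disk.
    """

    slide_id: str
    tile_positive: np.ndarray
    blob_centers: np.ndarray  # (n, 2) as (x, y) in H&E frame
    blob_radii: np.ndarray
    tile_size: int = 224


@dataclass
class TileGrid:
    """Non-overlapping tile coordinates fully inside an image."""

    origin_offset: tuple[int, int]  # (dx, dy)
    tile_size: int
    coords: np.ndarray  # (n, 2) of (x, y) top-left corners

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class TileBag:
    """The subset of grid tiles fed to the MIL model for one slide."""

    slide_id: str
    coords: np.ndarray
    intensity_scores: np.ndarray
    selection_mode: str = "min_intensity"  # or "all"
    tile_size: int = 224

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int).reshape(-1, 2)
        self.intensity_scores = np.asarray(self.intensity_scores, dtype=float)
        if len(self.coords) < 1:
            raise ValueError("a bag must contain at least one tile")
        if len(self.intensity_scores) != len(self.coords):
            raise ValueError("intensity scores must align with coords")

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class SlidePrediction:
    """Slide probability plus the per-tile attention distribution."""

    slide_id: str
    probability: float
    attention: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.attention = np.asarray(self.attention, dtype=float).ravel()
        self.coords = np.asarray(self.coords, dtype=int).reshape(-1, 2)
        if len(self.attention) != len(self.coords):
            raise ValueError("attention must align with coords")
        if np.any(self.attention < -1e-12):
            raise ValueError("attention weights must be non-negative")
        if abs(self.attention.sum() - 1.0) > 1e-5:
            raise ValueError("attention weights must sum to 1")

    def predicted_label(self, threshold: float) -> int:
        return int(self.probability >= threshold)


@dataclass
class StainRatioMap:
    """Per-tile DAB-positive fraction on the registered TFF3 section."""

    slide_id: str
    coords: np.ndarray
    ratio: np.ndarray
    flagged: np.ndarray  # True where the tile had no foreground

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int).reshape(-1, 2)
        self.ratio = np.asarray(self.ratio, dtype=float).ravel()
        self.flagged = np.asarray(self.flagged, dtype=bool).ravel()
        if not (len(self.coords) == len(self.ratio) == len(self.flagged)):
            raise ValueError("coords, ratio and flagged must align")
        if np.any((self.ratio < 0) | (self.ratio > 1)):
            raise ValueError("stain ratios must lie in [0, 1]")
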