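"""Synthetic paired H&E / TFF3 slides with planted goblet-cell blobs.

Real capsule-sponge cohorts cannot be redistributed, so every downstream
stage is exercised on synthetic pairs that emulate the geometry and stain
chemistry the pipeline relies on: two elliptical tissue sections side by
side on a plain white background; pink H&E tissue texture with scattered
hematoxylin-dark nuclei; in positive slides, translucent bluish goblet-cell
blobs on the H&E image whose locations carry dark-brown DAB stain on the
paired TFF3 image, optionally displaced by a small global deformation
between the adjacent sections.  Tile-level ground truth (which zero-offset
grid tiles intersect a planted disk) is recorded for every slide.

The module also generates synthetic per-sample decision tables (H&E model,
TFF3 model, pathologist calls) for the workflow simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .preprocess import HED_MATRIX, od_to_rgb, write_slide
from .types import HE, TFF3, GroundTruthMask, SlideImage

# ---------------------------------------------------------------------------
# appearance constants
# ---------------------------------------------------------------------------

# H&E: pink eosin-dominated tissue, dark purple nuclei, and goblet-cell
# groups drawn as a pale low-saturation blue-gray disk (translucent mucin)
# bounded by a darker basophilic rim — the nuclei of goblet cells are
# displaced to the cell periphery, giving the group a crisp outline
HE_TISSUE_RGB = np.array([231.0, 161.0, 190.0])
HE_NUCLEUS_RGB = np.array([96.0, 61.0, 150.0])
HE_GOBLET_RGB = np.array([170.0, 190.0, 220.0])
HE_GOBLET_RIM_RGB = np.array([110.0, 90.0, 160.0])
HE_GOBLET_ALPHA = 0.8
HE_GOBLET_RIM_WIDTH = 4.0

# TFF3: pale hematoxylin counterstained tissue, darker nuclei, and goblet
# blobs drawn as pure DAB at a fixed concentration so that stain
# deconvolution recovers a high DAB signal
TFF3_TISSUE_RGB = np.array([208.0, 202.0, 222.0])
TFF3_NUCLEUS_RGB = np.array([98.0, 88.0, 158.0])
DAB_CONCENTRATION = 1.2
DAB_BROWN_RGB = np.clip(
    od_to_rgb(DAB_CONCENTRATION * HED_MATRIX.rows[2]), 0, 255
)

NUCLEUS_RADIUS = 3
#: one nucleus per this many tissue pixels
NUCLEUS_DENSITY = 1 / 450.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters for a synthetic cohort.

    Defaults emulate the exported 10x slides the pipeline consumes: a
    1024x2048 px crop (two ~2 mm sections side by side at 0.92 um/px),
    4-9 goblet blobs of 18-36 px radius in positive slides, and a small
    global displacement between the adjacent H&E and TFF3 sections.
    """

    n_slides: int = 40
    prevalence: float = 0.5
    slide_size: tuple[int, int] = (1024, 2048)  # (H, W)
    mpp: float = 0.92
    goblet_count_range: tuple[int, int] = (4, 9)
    goblet_radius_px: tuple[int, int] = (18, 36)
    deformation_px: float = 6.0
    noise_sd: float = 3.0
    tile_size: int = 224
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        if self.slide_size[0] <= 0 or self.slide_size[1] <= 0:
            raise ValueError("slide_size must be positive")
        if self.goblet_count_range[0] > self.goblet_count_range[1]:
            raise ValueError("invalid goblet_count_range")
        if self.goblet_radius_px[0] > self.goblet_radius_px[1]:
            raise ValueError("invalid goblet_radius_px")
        if self.deformation_px < 0 or self.noise_sd < 0:
            raise ValueError("deformation_px and noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# rasterization helpers
# ---------------------------------------------------------------------------

def rasterize_disk(shape: tuple[int, int], center: tuple[float, float],
                   radius: float) -> np.ndarray:
    """Boolean raster of a disk; a pixel (x, y) is inside iff
    (x - cx)^2 + (y - cy)^2 <= r^2."""
    h, w = shape
    cx, cy = center
    x0 = max(0, int(np.floor(cx - radius)))
    x1 = min(w, int(np.ceil(cx + radius)) + 1)
    y0 = max(0, int(np.floor(cy - radius)))
    y1 = min(h, int(np.ceil(cy + radius)) + 1)
    mask = np.zeros(shape, dtype=bool)
    if x0 >= x1 or y0 >= y1:
        return mask
    ys, xs = np.mgrid[y0:y1, x0:x1]
    mask[y0:y1, x0:x1] = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius ** 2
    return mask


def disk_intersects_tile(center: tuple[float, float], radius: float,
                         tile_xy: tuple[int, int], tile_size: int) -> bool:
    """Disk / axis-aligned-square intersection via closest-point distance."""
    cx, cy = center
    x0, y0 = tile_xy
    nearest_x = min(max(cx, x0), x0 + tile_size - 1)
    nearest_y = min(max(cy, y0), y0 + tile_size - 1)
    return (cx - nearest_x) ** 2 + (cy - nearest_y) ** 2 <= radius ** 2


def tile_ground_truth(shape: tuple[int, int], centers: np.ndarray,
                      radii: np.ndarray, tile_size: int) -> np.ndarray:
    """Boolean (rows, cols) grid: tile positive iff it intersects any disk."""
    h, w = shape
    rows, cols = h // tile_size, w // tile_size
    out = np.zeros((rows, cols), dtype=bool)
    for (cx, cy), r in zip(np.atleast_2d(centers), np.atleast_1d(radii)):
        for i in range(rows):
            for j in range(cols):
                if not out[i, j] and disk_intersects_tile(
                        (cx, cy), r, (j * tile_size, i * tile_size), tile_size):
                    out[i, j] = True
    return out


def _blend_disk(canvas: np.ndarray, center, radius, rgb, alpha: float) -> None:
    # local-window blend; equivalent to masking with rasterize_disk
    h, w = canvas.shape[:2]
    cx, cy = center
    x0 = max(0, int(np.floor(cx - radius)))
    x1 = min(w, int(np.ceil(cx + radius)) + 1)
    y0 = max(0, int(np.floor(cy - radius)))
    y1 = min(h, int(np.ceil(cy + radius)) + 1)
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    inside = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius ** 2
    window = canvas[y0:y1, x0:x1]
    window[inside] = (1.0 - alpha) * window[inside] + alpha * np.asarray(rgb)


def _section_params(spec: SyntheticSpec, rng: np.random.Generator):
    """Centers and radii of the two side-by-side elliptical sections."""
    h, w = spec.slide_size
    params = []
    for cx_frac in (0.25, 0.75):
        cx = cx_frac * w + rng.uniform(-0.02, 0.02) * w
        cy = 0.5 * h + rng.uniform(-0.04, 0.04) * h
        rx = rng.uniform(0.30, 0.42) * (w / 2)
        ry = rng.uniform(0.30, 0.40) * h
        params.append((cx, cy, rx, ry))
    return params


def _ellipse_mask(shape, cx, cy, rx, ry) -> np.ndarray:
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    return ((xs - cx) / rx) ** 2 + ((ys - cy) / ry) ** 2 <= 1.0


def _paint_tissue(shape, sections, shift, tissue_rgb, nucleus_rgb,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """White canvas with textured elliptical sections and nuclei dots."""
    h, w = shape
    canvas = np.full((h, w, 3), 255.0)
    tissue = np.zeros((h, w), dtype=bool)
    for cx, cy, rx, ry in sections:
        mask = _ellipse_mask(shape, cx + shift[0], cy + shift[1], rx, ry)
        tissue |= mask
        texture = rng.normal(0.0, 6.0, size=(int(mask.sum()), 3))
        canvas[mask] = np.clip(tissue_rgb + texture, 0, 255)
        n_nuclei = int(mask.sum() * NUCLEUS_DENSITY)
        # sample nucleus centers inside the ellipse by rejection-free mapping
        t = rng.uniform(0, 2 * np.pi, n_nuclei)
        u = np.sqrt(rng.uniform(0, 1, n_nuclei))
        nx = cx + shift[0] + u * rx * np.cos(t)
        ny = cy + shift[1] + u * ry * np.sin(t)
        for px, py in zip(nx, ny):
            _blend_disk(canvas, (px, py), NUCLEUS_RADIUS, nucleus_rgb, 0.85)
    return canvas, tissue


def _place_blobs(spec: SyntheticSpec, sections, rng: np.random.Generator):
    """Goblet blob centers and radii, fully inside a section ellipse."""
    n = int(rng.integers(spec.goblet_count_range[0],
                         spec.goblet_count_range[1] + 1))
    centers, radii = [], []
    for _ in range(n):
        r = float(rng.integers(spec.goblet_radius_px[0],
                               spec.goblet_radius_px[1] + 1))
        cx, cy, rx, ry = sections[int(rng.integers(len(sections)))]
        t = rng.uniform(0, 2 * np.pi)
        u = np.sqrt(rng.uniform(0, 1))
        # keep the disk well inside the section (goblet-cell groups sit in
        # tissue, not at ragged section edges)
        px = cx + 0.85 * u * (rx - r) * np.cos(t)
        py = cy + 0.85 * u * (ry - r) * np.sin(t)
        centers.append((px, py))
        radii.append(r)
    return np.array(centers), np.array(radii)


def make_pair(spec: SyntheticSpec, label: int, rng: np.random.Generator,
              slide_id: str = "synthetic", with_tff3: bool = True):
    """One paired (H&E, TFF3) synthetic slide with tile-level ground truth.

    Positive slides carry translucent bluish goblet blobs on H&E and
    dark-brown DAB disks at the same locations on the TFF3 image, displaced
    globally by at most ``deformation_px`` between the adjacent sections.

    All TFF3-specific random draws happen after the H&E image is complete,
    so ``with_tff3=False`` (skip rendering the TFF3 image, returned as
    None) leaves the H&E image and ground truth bit-identical.
    """
    shape = spec.slide_size
    sections = _section_params(spec, rng)
    if spec.deformation_px > 0:
        shift = tuple(rng.uniform(-spec.deformation_px, spec.deformation_px,
                                  size=2))
    else:
        shift = (0.0, 0.0)

    if label:
        centers, radii = _place_blobs(spec, sections, rng)
    else:
        centers = np.zeros((0, 2))
        radii = np.zeros((0,))

    he_canvas, _ = _paint_tissue(shape, sections, (0.0, 0.0),
                                 HE_TISSUE_RGB, HE_NUCLEUS_RGB, rng)
    for (cx, cy), r in zip(centers, radii):
        _blend_disk(he_canvas, (cx, cy), r, HE_GOBLET_RIM_RGB,
                    HE_GOBLET_ALPHA)
        _blend_disk(he_canvas, (cx, cy), max(1.0, r - HE_GOBLET_RIM_WIDTH),
                    HE_GOBLET_RGB, 1.0)
    if spec.noise_sd > 0:
        he_canvas = he_canvas + rng.normal(0, spec.noise_sd, he_canvas.shape)
    he = SlideImage(np.clip(np.round(he_canvas), 0, 255).astype(np.uint8),
                    mpp=spec.mpp, stain=HE, slide_id=slide_id, label=label)

    tff3 = None
    if with_tff3:
        tff3_canvas, _ = _paint_tissue(shape, sections, shift,
                                       TFF3_TISSUE_RGB, TFF3_NUCLEUS_RGB, rng)
        for (cx, cy), r in zip(centers, radii):
            _blend_disk(tff3_canvas, (cx + shift[0], cy + shift[1]), r,
                        DAB_BROWN_RGB, 1.0)
        if spec.noise_sd > 0:
            tff3_canvas = tff3_canvas + rng.normal(0, spec.noise_sd,
                                                   tff3_canvas.shape)
        tff3 = SlideImage(
            np.clip(np.round(tff3_canvas), 0, 255).astype(np.uint8),
            mpp=spec.mpp, stain=TFF3, slide_id=slide_id, label=label)

    truth = GroundTruthMask(
        slide_id=slide_id,
        tile_positive=tile_ground_truth(shape, centers, radii, spec.tile_size),
        blob_centers=centers,
        blob_radii=radii,
        tile_size=spec.tile_size,
    )
    return he, tff3, truth


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def cohort_labels(spec: SyntheticSpec):
    """Deterministic labels, pathways and per-slide seeds for a cohort.

    Exactly ``round(n_slides * prevalence)`` slides are positive.
    """
    master = np.random.SeedSequence(spec.seed)
    streams = master.spawn(spec.n_slides + 1)
    assign_rng = np.random.default_rng(streams[0])
    n_pos = int(round(spec.n_slides * spec.prevalence))
    labels = np.array([1] * n_pos + [0] * (spec.n_slides - n_pos))
    assign_rng.shuffle(labels)
    pathways = np.where(assign_rng.random(spec.n_slides) < 0.5,
                        "surveillance", "screening")
    return labels, pathways, streams[1:]


def generate_pair(spec: SyntheticSpec, index: int, with_tff3: bool = True):
    """Regenerate a single cohort slide pair by index (bit-reproducible)."""
    labels, _, streams = cohort_labels(spec)
    if not 0 <= index < spec.n_slides:
        raise IndexError(index)
    rng = np.random.default_rng(streams[index])
    return make_pair(spec, int(labels[index]), rng,
                     slide_id=f"slide_{index:04d}", with_tff3=with_tff3)


def generate_cohort(spec: SyntheticSpec, with_tff3: bool = True):
    """In-memory cohort: yields (he, tff3 | None, truth, pathway) tuples."""
    labels, pathways, streams = cohort_labels(spec)
    for i in range(spec.n_slides):
        rng = np.random.default_rng(streams[i])
        he, tff3, truth = make_pair(spec, int(labels[i]), rng,
                                    slide_id=f"slide_{i:04d}",
                                    with_tff3=with_tff3)
        yield he, tff3, truth, pathways[i]


def make_dataset(spec: SyntheticSpec, out_dir) -> pd.DataFrame:
    """Write TIFF pairs plus a labels table to ``out_dir``.

    The labels CSV has one row per written file with columns
    (slide_id, stain, label, pathway, path); a companion ground_truth.csv
    records the planted blob disks.  Fully reproducible from ``spec.seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows, gt_rows = [], []
    seen = set()
    for he, tff3, truth, pathway in generate_cohort(spec):
        if truth.slide_id in seen:
            raise ValueError(f"duplicate slide_id {truth.slide_id}")
        seen.add(truth.slide_id)
        for img, tag in ((he, "HE"), (tff3, "TFF3")):
            path = out / f"{truth.slide_id}_{tag}.tiff"
            write_slide(img, path)
            rows.append({"slide_id": truth.slide_id, "stain": tag,
                         "label": int(img.label), "pathway": pathway,
                         "path": path.name})
        for (cx, cy), r in zip(truth.blob_centers, truth.blob_radii):
            gt_rows.append({"slide_id": truth.slide_id, "cx": float(cx),
                            "cy": float(cy), "radius": float(r)})
    labels = pd.DataFrame(rows, columns=["slide_id", "stain", "label",
                                         "pathway", "path"])
    labels.to_csv(out / "labels.csv", index=False)
    pd.DataFrame(gt_rows, columns=["slide_id", "cx", "cy", "radius"]).to_csv(
        out / "ground_truth.csv", index=False)
    return labels


# ---------------------------------------------------------------------------
# synthetic decision tables for the workflow simulator
# ---------------------------------------------------------------------------

def make_decisions(n: int, prevalence: float,
                   sens_he: float, spec_he: float,
                   sens_tff3: float, spec_tff3: float,
                   agreement: float = 0.0,
                   seed: int = 0) -> pd.DataFrame:
    """Per-sample binary calls for the two models and the pathologist.

    The pathologist call equals the ground-truth label (diagnostic labels
    are the pathologists' reading).  Model calls are Bernoulli with the
    requested class-conditional rates; ``agreement`` in [0, 1] correlates
    the two models' errors through a shared Gaussian factor.
    """
    for name, v in [("prevalence", prevalence), ("sens_he", sens_he),
                    ("spec_he", spec_he), ("sens_tff3", sens_tff3),
                    ("spec_tff3", spec_tff3), ("agreement", agreement)]:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    label = (rng.random(n) < prevalence).astype(int)
    z_common = rng.standard_normal(n)
    calls = {}
    for key, (sens, spec) in {"he": (sens_he, spec_he),
                              "tff3": (sens_tff3, spec_tff3)}.items():
        z = (np.sqrt(agreement) * z_common
             + np.sqrt(1.0 - agreement) * rng.standard_normal(n))
        u = norm.cdf(z)
        p_pos_call = np.where(label == 1, sens, 1.0 - spec)
        calls[key] = (u < p_pos_call).astype(int)
    return pd.DataFrame({
        "sample_id": [f"s{i:06d}" for i in range(n)],
        "label": label,
        "he_pred": calls["he"],
        "tff3_pred": calls["tff3"],
        "path_pred": label,
    })


def scaled_spec(spec: SyntheticSpec, **overrides) -> SyntheticSpec:
    """Convenience: a copy of ``spec`` with fields replaced."""
    return replace(spec, **overrides)
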