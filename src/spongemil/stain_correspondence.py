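"""TFF3/DAB expression quantification and stain-attention correspondence.

The TFF3 section adjacent to an H&E section carries brown DAB stain at
goblet cells.  This module separates hematoxylin and DAB channels by stain
deconvolution, builds Otsu masks of foreground and stain, registers the
TFF3 section onto the H&E frame (affine then coarse cubic B-spline, mutual
information, via SimpleITK), computes a per-tile DAB-positive fraction on
the H&E tiling grid, and correlates it with the model's attention weights.

Transforms are fitted at a coarse scale but parameterized in physical
(micron) coordinates, so the same fitted transform applies at any
resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import SimpleITK as sitk
from scipy import stats
from skimage import morphology, transform as sktransform
from skimage.filters import threshold_otsu

from .interpret import normalized_entropy
from .preprocess import (
    HED_MATRIX,
    deconvolve,
    macenko_stain_matrix,
    optical_density,
)
from .types import SlideImage, SlidePrediction, StainRatioMap, TileGrid

#: minimum DAB optical density for a pixel to count as stained; guards the
#: Otsu threshold against splitting pure noise on stain-free slides
MIN_DAB_OD = 0.15
#: hole-removal area threshold for the stain mask at 10x (px^2)
MIN_HOLE_AREA = 64


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def dab_mask(image: SlideImage, min_hole_area: int = MIN_HOLE_AREA
             ) -> tuple[np.ndarray, np.ndarray]:
    """(foreground mask, DAB stain mask) for a TFF3 slide.

    Hematoxylin and DAB concentrations are thresholded independently with
    Otsu's method; small holes are filled in the stain mask.  Foreground is
    hematoxylin-positive or DAB-positive (strongly stained goblet cells can
    displace the counterstain).  A constant channel yields an empty mask
    with a warning.
    """
    conc = deconvolve(optical_density(image), HED_MATRIX)
    hema, dab = conc[..., 0], conc[..., 2]
    masks = []
    for channel, floor in ((hema, 0.0), (dab, MIN_DAB_OD)):
        if np.ptp(channel) < 1e-9:
            warnings.warn("constant stain channel: empty mask", stacklevel=2)
            masks.append(np.zeros(channel.shape, dtype=bool))
            continue
        thr = max(threshold_otsu(channel), floor)
        masks.append(channel > thr)
    fg, stain = masks
    if stain.any():
        stain = morphology.remove_small_holes(stain, max_size=min_hole_area)
    fg = fg | stain
    return fg, stain


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap of two binary masks."""
    a, b = np.asarray(mask_a, bool), np.asarray(mask_b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * (a & b).sum() / denom


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

@dataclass
class RegistrationTransform:
    """Fitted fixed->moving mapping in physical (micron) coordinates."""

    transform: sitk.Transform
    affine_only: bool
    fit_mpp: float

    def displacement_px(self, points_xy: np.ndarray, mpp: float) -> np.ndarray:
        """Displacement T(p) - p in pixels at scale ``mpp`` for (x, y) points."""
        pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
        out = []
        for x, y in pts:
            tx, ty = self.transform.TransformPoint((x * mpp, y * mpp))
            out.append((tx / mpp - x, ty / mpp - y))
        return np.asarray(out)


def _hema_image(image: SlideImage) -> np.ndarray:
    if image.stain == "HE":
        matrix = macenko_stain_matrix(image)
    else:
        matrix = HED_MATRIX
    return deconvolve(optical_density(image), matrix)[..., 0]


def _to_sitk(array: np.ndarray, mpp: float) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(array, dtype=np.float64))
    img.SetSpacing((mpp, mpp))
    return img


def _downsample(array: np.ndarray, mpp: float, target_mpp: float):
    factor = mpp / target_mpp
    if factor >= 1.0:
        return array, mpp
    shape = (max(8, int(round(array.shape[0] * factor))),
             max(8, int(round(array.shape[1] * factor))))
    out = sktransform.resize(array, shape, order=1, anti_aliasing=True)
    return out, mpp * array.shape[0] / shape[0]


def register(fixed_he: SlideImage, moving_tff3: SlideImage,
             affine_mpp: float = 7.36, bspline_mpp: float = 3.68,
             bspline: bool = True) -> RegistrationTransform:
    """Fit an affine then coarse cubic B-spline (5x5 control grid) mapping of
    the TFF3 hematoxylin image onto the H&E hematoxylin image.

    Both stages optimize Mattes mutual information.  The two stages run at
    progressively finer coarse scales; the returned transform lives in
    physical coordinates and is applicable at any mpp.  If the B-spline
    stage fails the affine-only transform is returned with a warning.
    """
    fixed_full = _hema_image(fixed_he)
    moving_full = _hema_image(moving_tff3)

    fixed_a, mpp_fa = _downsample(fixed_full, fixed_he.mpp, affine_mpp)
    moving_a, mpp_ma = _downsample(moving_full, moving_tff3.mpp, affine_mpp)
    f_img = _to_sitk(fixed_a, mpp_fa)
    m_img = _to_sitk(moving_a, mpp_ma)

    initial = sitk.CenteredTransformInitializer(
        f_img, m_img, sitk.AffineTransform(2),
        sitk.CenteredTransformInitializerFilter.GEOMETRY)
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=50)
    reg.SetMetricSamplingStrategy(reg.NONE)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-4, numberOfIterations=200,
        relaxationFactor=0.6)
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetInitialTransform(initial, inPlace=True)
    affine = reg.Execute(f_img, m_img)

    if not bspline:
        return RegistrationTransform(affine, affine_only=True, fit_mpp=mpp_fa)

    try:
        fixed_b, mpp_fb = _downsample(fixed_full, fixed_he.mpp, bspline_mpp)
        moving_b, mpp_mb = _downsample(moving_full, moving_tff3.mpp, bspline_mpp)
        f_img2 = _to_sitk(fixed_b, mpp_fb)
        m_img2 = _to_sitk(moving_b, mpp_mb)
        # 5x5 control points for a cubic B-spline -> 2x2 mesh cells
        bspline_t = sitk.BSplineTransformInitializer(
            f_img2, transformDomainMeshSize=[2, 2], order=3)
        reg2 = sitk.ImageRegistrationMethod()
        reg2.SetMetricAsMattesMutualInformation(numberOfHistogramBins=50)
        reg2.SetMetricSamplingStrategy(reg2.NONE)
        reg2.SetInterpolator(sitk.sitkLinear)
        reg2.SetOptimizerAsLBFGSB(gradientConvergenceTolerance=1e-7,
                                  numberOfIterations=50)
        reg2.SetMovingInitialTransform(affine)
        reg2.SetInitialTransform(bspline_t, inPlace=True)
        reg2.Execute(f_img2, m_img2)
        composite = sitk.CompositeTransform(2)
        composite.AddTransform(affine)
        composite.AddTransform(bspline_t)
        return RegistrationTransform(composite, affine_only=False,
                                     fit_mpp=mpp_fb)
    except RuntimeError as err:  # optimization divergence
        warnings.warn(f"B-spline stage failed ({err}); returning affine-only",
                      stacklevel=2)
        return RegistrationTransform(affine, affine_only=True, fit_mpp=mpp_fa)


def apply_transform(reg: RegistrationTransform, moving: np.ndarray,
                    fixed_shape: tuple[int, int], mpp: float,
                    is_mask: bool = False) -> np.ndarray:
    """Resample ``moving`` onto the fixed frame at scale ``mpp``."""
    was_bool = moving.dtype == bool
    m_img = _to_sitk(moving.astype(np.float64), mpp)
    reference = sitk.Image(int(fixed_shape[1]), int(fixed_shape[0]),
                           sitk.sitkFloat64)
    reference.SetSpacing((mpp, mpp))
    interp = sitk.sitkNearestNeighbor if is_mask else sitk.sitkLinear
    out = sitk.Resample(m_img, reference, reg.transform, interp, 0.0)
    arr = sitk.GetArrayFromImage(out)
    return arr > 0.5 if (is_mask or was_bool) else arr


# ---------------------------------------------------------------------------
# per-tile stain ratio and correspondence
# ---------------------------------------------------------------------------

def tile_stain_ratio(stain_mask: np.ndarray, fg_mask: np.ndarray,
                     grid: TileGrid, slide_id: str = "") -> StainRatioMap:
    """Per-tile DAB ratio: stained pixels / foreground pixels in the tile.

    Tiles with empty foreground carry ratio 0 and are flagged.
    """
    stain_mask = np.asarray(stain_mask, bool)
    fg_mask = np.asarray(fg_mask, bool)
    if stain_mask.shape != fg_mask.shape:
        raise ValueError("stain and foreground masks must share a frame")
    h, w = fg_mask.shape
    t = grid.tile_size
    ratios, flagged = [], []
    for x, y in grid.coords:
        if x < 0 or y < 0 or x + t > w or y + t > h:
            raise ValueError(f"tile at ({x},{y}) outside the mask frame")
        fg_count = int(fg_mask[y:y + t, x:x + t].sum())
        stain_count = int((stain_mask & fg_mask)[y:y + t, x:x + t].sum())
        if fg_count == 0:
            ratios.append(0.0)
            flagged.append(True)
        else:
            ratios.append(stain_count / fg_count)
            flagged.append(False)
    return StainRatioMap(slide_id=slide_id, coords=grid.coords,
                         ratio=np.array(ratios), flagged=np.array(flagged))


def _minmax(v: np.ndarray) -> np.ndarray:
    rng = v.max() - v.min()
    if rng == 0:
        return np.zeros_like(v)
    return (v - v.min()) / rng


@dataclass
class CorrespondenceResult:
    pearson_r: float
    n_tiles: int
    attention_entropy: float
    registration_quality: Optional[float] = None  # foreground Dice
    flagged_constant: bool = False


def stain_attention_correlation(ratio_map: StainRatioMap,
                                prediction: SlidePrediction,
                                registration_quality: Optional[float] = None
                                ) -> CorrespondenceResult:
    """Pearson correlation between per-tile stain ratio and attention.

    Both vectors are min-max normalized per slide (Pearson r is invariant to
    this affine rescaling); the result is flagged undefined when either
    vector is constant.
    """
    if len(ratio_map.coords) != len(prediction.coords) or not np.array_equal(
            np.sort(ratio_map.coords.view("i8,i8").ravel()),
            np.sort(prediction.coords.view("i8,i8").ravel())):
        raise ValueError("ratio map and prediction must cover the same tiles")
    if len(ratio_map.coords) < 3:
        raise ValueError("need at least 3 tiles for a correlation")
    # align by coordinate
    order_r = np.lexsort((ratio_map.coords[:, 0], ratio_map.coords[:, 1]))
    order_p = np.lexsort((prediction.coords[:, 0], prediction.coords[:, 1]))
    ratio = _minmax(ratio_map.ratio[order_r])
    attn = _minmax(prediction.attention[order_p])
    entropy = normalized_entropy(prediction.attention)
    if ratio.std() == 0 or attn.std() == 0:
        return CorrespondenceResult(pearson_r=np.nan, n_tiles=len(ratio),
                                    attention_entropy=entropy,
                                    registration_quality=registration_quality,
                                    flagged_constant=True)
    r, _ = stats.pearsonr(ratio, attn)
    return CorrespondenceResult(pearson_r=float(r), n_tiles=len(ratio),
                                attention_entropy=entropy,
                                registration_quality=registration_quality)
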