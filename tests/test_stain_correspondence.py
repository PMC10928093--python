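"""DAB quantification, section registration, stain-attention correlation."""

import numpy as np
import pytest

from spongemil import preprocess as pp
from spongemil import stain_correspondence as sc
from spongemil import synthdata as sd
from spongemil import tiling
from spongemil.pipeline import correspondence_for_slide
from spongemil.types import TFF3, SlideImage, SlidePrediction, TileGrid


def _grid(coords, tile=224):
    return TileGrid(origin_offset=(0, 0), tile_size=tile,
                    coords=np.asarray(coords))


class TestDabMask:
    def test_stain_mask_matches_planted_disks(self):
        spec = sd.SyntheticSpec(seed=8, deformation_px=0.0,
                                slide_size=(512, 1024))
        _, tff3, truth = sd.make_pair(spec, 1, np.random.default_rng(9))
        _, stain = sc.dab_mask(tff3)
        blob = np.zeros(spec.slide_size, dtype=bool)
        for (cx, cy), r in zip(truth.blob_centers, truth.blob_radii):
            blob |= sd.rasterize_disk(spec.slide_size, (cx, cy), r)
        iou = (stain & blob).sum() / (stain | blob).sum()
        assert iou >= 0.8

    def test_no_brown_pixels_gives_empty_stain_mask(self):
        spec = sd.SyntheticSpec(seed=8, slide_size=(512, 1024))
        _, tff3, _ = sd.make_pair(spec, 0, np.random.default_rng(10))
        fg, stain = sc.dab_mask(tff3)
        assert stain.sum() == 0
        assert fg.any()  # tissue still detected

    def test_constant_image_warns_and_is_empty(self):
        img = SlideImage(np.full((64, 64, 3), 255, np.uint8), mpp=0.92,
                         stain=TFF3)
        with pytest.warns(UserWarning):
            fg, stain = sc.dab_mask(img)
        assert not fg.any() and not stain.any()


@pytest.fixture(scope="module")
def tff3_slide():
    spec = sd.SyntheticSpec(seed=5, deformation_px=0.0,
                            slide_size=(512, 1024))
    _, tff3, _ = sd.make_pair(spec, 1, np.random.default_rng(3))
    return tff3


class TestRegistration:

    def test_known_shift_recovered_within_one_pixel(self, tff3_slide):
        arr = tff3_slide.pixels
        dx, dy = 12, -7
        shifted = np.full_like(arr, 255)
        shifted[:dy, dx:] = arr[-dy:, :-dx]
        moving = SlideImage(shifted, mpp=tff3_slide.mpp, stain=TFF3)
        reg = sc.register(tff3_slide, moving, bspline=False)
        pts = np.array([[300, 200], [512, 256], [700, 300]])
        disp = reg.displacement_px(pts, tff3_slide.mpp)
        assert np.abs(disp - [dx, dy]).max() < 1.0

    def test_identity_pair_is_near_identity(self, tff3_slide):
        moving = SlideImage(tff3_slide.pixels.copy(), mpp=tff3_slide.mpp,
                            stain=TFF3)
        reg = sc.register(tff3_slide, moving)
        pts = np.array([[200, 150], [512, 256], [800, 350]])
        disp = reg.displacement_px(pts, tff3_slide.mpp)
        assert np.abs(disp).mean() < 0.5

    def test_deformed_pair_dice_not_decreased(self):
        spec = sd.SyntheticSpec(seed=8, deformation_px=6.0)
        he, tff3, _ = sd.make_pair(spec, 1, np.random.default_rng(9))
        he_t = pp.he_foreground_mask(he).mask
        tff3_t = pp.he_foreground_mask(tff3).mask
        pre = sc.dice(he_t, tff3_t)
        reg = sc.register(he, tff3)
        moved = sc.apply_transform(reg, tff3_t, he_t.shape, he.mpp,
                                   is_mask=True)
        post = sc.dice(he_t, moved)
        assert post >= pre - 0.005

    def test_large_shift_strictly_improves_dice(self, tff3_slide):
        arr = tff3_slide.pixels
        shifted = np.full_like(arr, 255)
        shifted[:, 30:] = arr[:, :-30]
        moving = SlideImage(shifted, mpp=tff3_slide.mpp, stain=TFF3)
        fixed_t = pp.he_foreground_mask(tff3_slide).mask
        moving_t = pp.he_foreground_mask(moving).mask
        pre = sc.dice(fixed_t, moving_t)
        reg = sc.register(tff3_slide, moving, bspline=False)
        moved = sc.apply_transform(reg, moving_t, fixed_t.shape,
                                   tff3_slide.mpp, is_mask=True)
        assert sc.dice(fixed_t, moved) > pre + 0.01


class TestTileStainRatio:
    def test_pixel_count_oracle(self):
        fg = np.zeros((224, 448), dtype=bool)
        stain = np.zeros_like(fg)
        fg[:10, :10] = True                 # tile 0: 100 fg px
        stain[:5, :5] = True                # 25 stained inside fg
        fg[:, 224:] = True                  # tile 1: fully foreground
        stain[:, 224:] = True               # fully stained
        rmap = sc.tile_stain_ratio(stain, fg, _grid([[0, 0], [224, 0]]))
        assert rmap.ratio[0] == pytest.approx(0.25)
        assert rmap.ratio[1] == pytest.approx(1.0)
        assert not rmap.flagged.any()

    def test_empty_foreground_tile_flagged_zero(self):
        fg = np.zeros((224, 448), dtype=bool)
        fg[:, 224:] = True
        stain = np.zeros_like(fg)
        rmap = sc.tile_stain_ratio(stain, fg, _grid([[0, 0], [224, 0]]))
        assert rmap.ratio[0] == 0.0
        assert rmap.flagged[0]
        assert not rmap.flagged[1]

    def test_out_of_frame_grid_rejected(self):
        fg = np.ones((224, 224), dtype=bool)
        with pytest.raises(ValueError):
            sc.tile_stain_ratio(fg, fg, _grid([[100, 0]]))

    def test_no_double_counting_across_tiles(self):
        rng = np.random.default_rng(11)
        fg = rng.random((224, 448)) < 0.7
        stain = fg & (rng.random((224, 448)) < 0.3)
        grid = _grid([[0, 0], [224, 0]])
        rmap = sc.tile_stain_ratio(stain, fg, grid)
        total_stained = sum(
            rmap.ratio[i] * (fg[y:y + 224, x:x + 224]).sum()
            for i, (x, y) in enumerate(grid.coords))
        assert total_stained == pytest.approx((stain & fg).sum())


class TestCorrelation:
    @staticmethod
    def _pred(attention):
        attention = np.asarray(attention, float)
        coords = np.array([[224 * i, 0] for i in range(len(attention))])
        return SlidePrediction("s", 0.5, attention / attention.sum(), coords)

    @staticmethod
    def _ratio(values):
        values = np.asarray(values, float)
        coords = np.array([[224 * i, 0] for i in range(len(values))])
        from spongemil.types import StainRatioMap

        return StainRatioMap("s", coords, values,
                             np.zeros(len(values), dtype=bool))

    def test_proportional_vectors_give_r_one(self):
        a = np.array([0.1, 0.2, 0.3, 0.4])
        res = sc.stain_attention_correlation(self._ratio(a / 2), self._pred(a))
        assert res.pearson_r == pytest.approx(1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(12)
        n = 10_000
        a = rng.random(n)
        b = rng.random(n)
        res = sc.stain_attention_correlation(self._ratio(b), self._pred(a))
        assert abs(res.pearson_r) < 0.05

    def test_r_invariant_to_minmax_normalization(self):
        from scipy.stats import pearsonr

        rng = np.random.default_rng(13)
        a = rng.random(50)
        b = 0.2 + 0.5 * rng.random(50)
        res = sc.stain_attention_correlation(self._ratio(b), self._pred(a))
        raw_r, _ = pearsonr(b, a / a.sum())
        assert res.pearson_r == pytest.approx(raw_r, abs=1e-12)

    def test_constant_vector_flagged(self):
        res = sc.stain_attention_correlation(
            self._ratio([0.5, 0.5, 0.5]), self._pred([0.1, 0.5, 0.4]))
        assert res.flagged_constant
        assert np.isnan(res.pearson_r)

    def test_fewer_than_three_tiles_rejected(self):
        with pytest.raises(ValueError):
            sc.stain_attention_correlation(self._ratio([0.1, 0.9]),
                                           self._pred([0.4, 0.6]))


class TestTrainedCorrespondence:
    def test_positive_slides_have_positive_correlation(self, desk_run):
        """True-positive slides correlate stain ratio with attention."""
        checked = 0
        for idx in desk_run.positive_test_indices()[:3]:
            res = correspondence_for_slide(desk_run, idx)
            assert res.pearson_r > 0.0
            assert res.registration_quality > 0.8
            checked += 1
        assert checked == 3
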