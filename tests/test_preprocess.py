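"""Stain deconvolution, foreground masking, section finding and export."""

import numpy as np
import pytest

from spongemil import preprocess as pp
from spongemil import synthdata as sd
from spongemil.types import HE, TFF3, ForegroundMask, SectionBox, SlideImage, StainMatrix


def _slide(pixels, mpp=0.92, stain=HE):
    return SlideImage(np.asarray(pixels, dtype=np.uint8), mpp=mpp, stain=stain)


class TestOpticalDensity:
    def test_white_has_no_absorbance(self):
        img = _slide(np.full((4, 4, 3), 255))
        assert np.allclose(pp.optical_density(img), 0.0, atol=5e-3)

    def test_closed_form_tenth_transmission(self):
        # I = 25.5 -> transmission 0.1 -> OD = 1 per channel (eps -> 0)
        img = np.full((2, 2, 3), 25.5)
        od = pp.optical_density(img, eps=0.0)
        assert np.allclose(od, 1.0)

    def test_round_trip_recovers_intensity(self):
        rng = np.random.default_rng(0)
        pixels = rng.integers(0, 256, size=(16, 16, 3)).astype(float)
        od = pp.optical_density(pixels)
        assert np.allclose(pp.od_to_rgb(od), pixels, atol=1e-6)


class TestDeconvolve:
    def test_basis_vector_recovers_unit_concentration(self):
        h_vec = pp.HED_MATRIX.rows[0]
        od = np.tile(h_vec, (3, 3, 1))
        conc = pp.deconvolve(od, pp.HED_MATRIX)
        assert np.allclose(conc[..., 0], 1.0, atol=1e-9)
        assert np.allclose(conc[..., 1:], 0.0, atol=1e-9)

    def test_zero_od_gives_zero_concentration(self):
        conc = pp.deconvolve(np.zeros((2, 2, 3)), pp.HED_MATRIX)
        assert np.allclose(conc, 0.0)

    def test_synthetic_mixture_recovered(self):
        od = 0.7 * pp.HED_MATRIX.rows[0] + 0.3 * pp.HED_MATRIX.rows[2]
        conc = pp.deconvolve(od[None, None], pp.HED_MATRIX)[0, 0]
        assert np.allclose(conc, [0.7, 0.0, 0.3], atol=1e-6)

    def test_singular_matrix_rejected(self):
        rows = np.array([[1.0, 0, 0], [1.0, 0, 0]])
        m = StainMatrix(rows + 1e-18, names=("a", "b"))
        m.rows = np.array([[1.0, 0, 0], [1.0, 0, 0]])  # force singular
        with pytest.raises(ValueError, match="singular"):
            pp.deconvolve(np.zeros((1, 1, 3)), m)


class TestMacenko:
    def test_recovers_generating_vectors(self):
        # mixtures plus pure-stain pixels, as in real H&E where nuclei and
        # stroma carry nearly single-stain absorbance
        rng = np.random.default_rng(1)
        truth = pp.DEFAULT_HE_MATRIX.rows
        conc = rng.uniform(0.05, 1.0, size=(4000, 2))
        pure = rng.integers(0, 2, size=1200)
        conc[:1200, 0] *= pure
        conc[:1200, 1] *= 1 - pure
        od = conc @ truth + rng.normal(0, 0.005, size=(4000, 3))
        pixels = np.clip(pp.od_to_rgb(np.maximum(od, 0)), 0, 255)
        img = _slide(pixels.reshape(50, 80, 3))
        est = pp.macenko_stain_matrix(img)
        for est_row, true_row in zip(est.rows, truth):
            angle = np.arccos(np.clip(abs(est_row @ true_row), -1, 1))
            assert angle < 0.05

    def test_all_white_falls_back_with_warning(self):
        img = _slide(np.full((32, 32, 3), 255))
        with pytest.warns(UserWarning, match="falling back"):
            est = pp.macenko_stain_matrix(img)
        assert np.allclose(est.rows, pp.DEFAULT_HE_MATRIX.rows)

    def test_rows_unit_norm(self):
        rng = np.random.default_rng(2)
        img = _slide(rng.integers(0, 255, size=(40, 40, 3)))
        est = pp.macenko_stain_matrix(img)
        assert np.allclose(np.linalg.norm(est.rows, axis=1), 1.0)


class TestDiskRadius:
    @pytest.mark.parametrize("mpp,expected", [(7.36, 8), (1.84, 33), (0.92, 65)])
    def test_physical_radius_is_60um(self, mpp, expected):
        # 8 px at 1.25x objective; scales with processing resolution
        assert pp.disk_radius_px(mpp) == expected


@pytest.fixture(scope="module")
def synthetic_pair():
    spec = sd.SyntheticSpec(seed=42, deformation_px=0.0)
    he, tff3, truth = sd.make_pair(spec, 1, np.random.default_rng(5))
    return spec, he, tff3, truth


def _section_area_mask(spec, he):
    # independent tissue definition: any clearly non-white pixel
    return he.pixels.astype(int).sum(axis=2) < 3 * 240


class TestForegroundMasks:
    def test_tff3_mask_covers_sections_not_background(self, synthetic_pair):
        spec, he, tff3, truth = synthetic_pair
        mask = pp.tff3_foreground_mask(tff3)
        tissue = _section_area_mask(spec, tff3)
        # nuclei thresholding + 60 um closing recovers the section area
        assert mask.mask[tissue].mean() >= 0.95
        assert mask.mask[~tissue].mean() < 0.01

    def test_he_mask_recall_and_false_positives(self, synthetic_pair):
        spec, he, tff3, truth = synthetic_pair
        mask = pp.he_foreground_mask(he)
        tissue = _section_area_mask(spec, he)
        recall = mask.mask[tissue].mean()
        background_fp = mask.mask[~tissue].mean()
        assert recall >= 0.95
        assert background_fp <= 0.01

    def test_he_mask_rotation_equivariance(self, synthetic_pair):
        _, he, _, _ = synthetic_pair
        small = SlideImage(he.pixels[::4, ::4], mpp=he.mpp * 4, stain=HE)
        mask = pp.he_foreground_mask(small).mask
        rotated = SlideImage(np.rot90(small.pixels).copy(), mpp=small.mpp,
                             stain=HE)
        mask_rot = pp.he_foreground_mask(rotated).mask
        # coarse-scale morphology resampling allows boundary wiggle
        assert (np.rot90(mask) == mask_rot).mean() > 0.99

    def test_all_white_yields_empty_mask(self):
        img = _slide(np.full((64, 64, 3), 255), stain=TFF3)
        with pytest.warns(UserWarning):
            mask = pp.tff3_foreground_mask(img)
        assert mask.foreground_fraction == 0.0

    def test_mask_invariant_to_background_whitening(self, synthetic_pair):
        _, he, _, _ = synthetic_pair
        mask = pp.he_foreground_mask(he)
        whitened = pp.whiten_background(he, mask)
        mask2 = pp.he_foreground_mask(whitened)
        agreement = (mask.mask == mask2.mask).mean()
        assert agreement > 0.99


class TestFindSections:
    def test_two_sections_found_with_blob_containment(self, synthetic_pair):
        spec, he, tff3, truth = synthetic_pair
        mask = pp.he_foreground_mask(he)
        boxes = pp.find_sections(mask, expected=2, mpp=he.mpp)
        assert len(boxes) == 2
        assert boxes[0].x0 < boxes[1].x0
        for cx, cy in truth.blob_centers:
            assert any(b.contains(cx, cy) for b in boxes)

    def test_boxes_exclude_other_component(self, synthetic_pair):
        spec, he, _, _ = synthetic_pair
        mask = pp.he_foreground_mask(he)
        boxes = pp.find_sections(mask, expected=2, mpp=he.mpp)
        # brute force: no masked pixel belongs to both boxes
        ys, xs = np.nonzero(mask.mask)
        in0 = (xs >= boxes[0].x0) & (xs < boxes[0].x1) & \
              (ys >= boxes[0].y0) & (ys < boxes[0].y1)
        in1 = (xs >= boxes[1].x0) & (xs < boxes[1].x1) & \
              (ys >= boxes[1].y0) & (ys < boxes[1].y1)
        assert not np.any(in0 & in1)

    def test_single_component_warns(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[40:60, 40:60] = True
        with pytest.warns(UserWarning, match="expected 2"):
            boxes = pp.find_sections(ForegroundMask(mask), expected=2, mpp=7.36)
        assert len(boxes) == 1


class TestWhitenBackground:
    def test_all_ones_mask_is_identity(self):
        rng = np.random.default_rng(3)
        img = _slide(rng.integers(0, 255, size=(8, 8, 3)))
        out = pp.whiten_background(img, ForegroundMask(np.ones((8, 8), bool)))
        assert np.array_equal(out.pixels, img.pixels)

    def test_all_zeros_mask_is_white(self):
        img = _slide(np.zeros((8, 8, 3)))
        out = pp.whiten_background(img, ForegroundMask(np.zeros((8, 8), bool)))
        assert np.all(out.pixels == 255)

    def test_checkerboard_mask_whitens_half(self):
        img = _slide(np.zeros((8, 8, 3)))
        mask = np.indices((8, 8)).sum(axis=0) % 2 == 0
        out = pp.whiten_background(img, ForegroundMask(mask))
        white = np.all(out.pixels == 255, axis=2)
        assert white.sum() == 32

    def test_shape_mismatch_rejected(self):
        img = _slide(np.zeros((8, 8, 3)))
        with pytest.raises(ValueError):
            pp.whiten_background(img, ForegroundMask(np.ones((4, 4), bool)))


class TestCropExport:
    def test_40x_to_10x_downscale_factor_four(self, tmp_path):
        img = _slide(np.full((128, 128, 3), 128), mpp=0.23)
        box = SectionBox(0, 0, 128, 128)
        out = pp.crop_export(img, box, tmp_path / "a.tiff", target_mpp=0.92)
        assert out.pixels.shape[:2] == (32, 32)

    def test_same_mpp_is_pixel_identical(self, tmp_path):
        rng = np.random.default_rng(4)
        img = _slide(rng.integers(0, 255, size=(64, 64, 3)))
        out = pp.crop_export(img, SectionBox(8, 8, 40, 40),
                             tmp_path / "b.tiff", target_mpp=img.mpp)
        assert np.array_equal(out.pixels, img.pixels[8:40, 8:40])

    def test_written_file_round_trips_mpp(self, tmp_path):
        img = _slide(np.full((32, 32, 3), 100), mpp=0.46)
        pp.crop_export(img, SectionBox(0, 0, 32, 32), tmp_path / "c.tiff",
                       target_mpp=0.92)
        back = pp.read_slide(tmp_path / "c.tiff")
        assert abs(back.mpp - 0.92) < 1e-3
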