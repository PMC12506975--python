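import numpy as np
import pytest
from scipy import ndimage

from duotomo.errors import SurfaceNotFoundError, UndefinedCNRError
from duotomo.geometry import build_grid
from duotomo.pact_recon import ReconImage
from duotomo.phantom_forward import make_fluence
from duotomo.vessel_postproc import (
    Volume,
    assemble_volume,
    compute_cnr,
    depth_compensate,
    depth_encoded_projection,
    detect_skin_surface,
    frangi_enhance,
    skeletonize_vessels,
)


@pytest.fixture
def grid100():
    return build_grid(50.0, 50.0, 0.5, (0.0, 0.0))


def _img(pixels, grid, variant="unipolar"):
    return ReconImage(pixels=np.asarray(pixels, float), grid=grid, variant=variant)


class TestSkinDetection:
    def test_flat_surface_found_everywhere(self, grid100):
        px = np.zeros((grid100.n_y, grid100.n_x))
        px[30, :] = 1.0
        depth = detect_skin_surface(_img(px, grid100))
        rows = depth / grid100.pitch_mm - 0.5
        assert np.all(np.abs(rows - 30) <= 1)

    def test_tilted_surface_tracked(self, grid100):
        px = np.zeros((grid100.n_y, grid100.n_x))
        rows = np.linspace(20, 40, grid100.n_x).astype(int)
        px[rows, np.arange(grid100.n_x)] = 1.0
        depth = detect_skin_surface(_img(px, grid100))
        detected = depth / grid100.pitch_mm - 0.5
        assert np.abs(detected - rows).max() <= 2

    def test_all_zero_image_raises(self, grid100):
        with pytest.raises(SurfaceNotFoundError):
            detect_skin_surface(_img(np.zeros((grid100.n_y, grid100.n_x)),
                                     grid100))

    def test_gap_columns_interpolated(self, grid100):
        px = np.zeros((grid100.n_y, grid100.n_x))
        px[30, :] = 1.0
        px[:, 40:50] = 0.0  # no crossing in these columns
        depth = detect_skin_surface(_img(px, grid100))
        rows = depth / grid100.pitch_mm - 0.5
        assert np.all(np.abs(rows[40:50] - 30) <= 1)


class TestDepthCompensation:
    def test_depth_uniform_image_is_identity(self, grid100):
        px = np.full((grid100.n_y, grid100.n_x), 0.3)
        skin = np.full(grid100.n_x, 2.0)
        out = depth_compensate(_img(px, grid100), skin)
        assert np.allclose(out.pixels, px)

    def test_gain_cap_one_is_identity(self, grid100):
        rng = np.random.default_rng(0)
        px = rng.random((grid100.n_y, grid100.n_x))
        skin = np.full(grid100.n_x, 2.0)
        out = depth_compensate(_img(px, grid100), skin, gain_cap=1.0)
        assert np.allclose(out.pixels, px)

    def test_never_reduces_and_respects_cap(self, grid100):
        rng = np.random.default_rng(1)
        px = rng.random((grid100.n_y, grid100.n_x)) * np.exp(
            -0.1 * grid100.depth_of_row_mm
        )[:, None]
        skin = np.full(grid100.n_x, 2.0)
        out = depth_compensate(_img(px, grid100), skin, gain_cap=8.0)
        ratio = np.where(px > 0, out.pixels / np.where(px > 0, px, 1.0), 1.0)
        assert ratio.min() >= 1.0 - 1e-12
        assert ratio.max() <= 8.0 + 1e-9

    def test_two_absorbers_under_fluence_restored(self, grid100):
        """Identical absorbers at 10 and 40 mm depth under the 62-fold
        dark-field profile end up within 25% of each other."""
        fl = make_fluence("dark_field", 62.0, 50.0)
        skin = np.full(grid100.n_x, 1.0)
        depth = grid100.depth_of_row_mm[:, None] - skin[None, :]
        px = 0.05 * fl(depth) * np.ones((grid100.n_y, grid100.n_x))
        r10 = int((10.0 + 1.0) / 0.5)
        r40 = int((40.0 + 1.0) / 0.5)
        for r in (r10, r40):
            px[r - 1: r + 2, 48:53] += float(fl(grid100.depth_of_row_mm[r] - 1.0))
        out = depth_compensate(_img(px, grid100), skin, gain_cap=40.0)
        a10 = out.pixels[r10 - 1: r10 + 2, 48:53].max()
        a40 = out.pixels[r40 - 1: r40 + 2, 48:53].max()
        assert 0.8 <= a40 / a10 <= 1.25


class TestFrangiEnhance:
    def test_constant_image_unchanged_after_normalisation(self, grid100):
        px = np.full((grid100.n_y, grid100.n_x), 0.5)
        out = frangi_enhance(_img(px, grid100))
        assert np.allclose(out.pixels, 1.0)

    def test_tube_contrast_increases(self, grid100):
        rng = np.random.default_rng(2)
        px = 0.05 * rng.random((grid100.n_y, grid100.n_x))
        px[50:54, 20:80] = 1.0  # 4-px tube
        img = _img(px, grid100)
        out = frangi_enhance(img)
        tube = np.zeros_like(px, bool)
        tube[50:54, 20:80] = True
        bg = ~ndimage.binary_dilation(tube, iterations=5)

        def cnr(im):
            return (im[tube].mean() - im[bg].mean()) / im[bg].std()

        assert cnr(out.pixels) > cnr(px / px.max())

    def test_default_blend_weight(self):
        import inspect

        sig = inspect.signature(frangi_enhance)
        assert sig.parameters["blend_weight"].default == 0.1
        assert sig.parameters["diameter_px_range"].default == (2.0, 7.0)


class TestSkeletonization:
    def test_blank_image_no_segments(self, grid100):
        sk = skeletonize_vessels(_img(np.zeros((grid100.n_y, grid100.n_x)),
                                      grid100))
        assert sk.segments == []
        assert not sk.skeleton_mask.any()

    def test_straight_tube_single_segment_with_correct_length(self, grid100):
        px = np.zeros((grid100.n_y, grid100.n_x))
        px[50:53, 15:85] = 1.0
        sk = skeletonize_vessels(_img(px, grid100))
        assert len(sk.segments) == 1
        seg = sk.segments[0].astype(float)
        steps = np.diff(seg, axis=0)
        length = np.hypot(steps[:, 0], steps[:, 1]).sum()
        assert abs(length - 69.0) / 69.0 <= 0.05

    def test_y_junction_splits_into_three_segments(self, grid100):
        px = np.zeros((grid100.n_y, grid100.n_x))
        px[20:52, 49:52] = 0.0
        # stem
        px[50:80, 49:52] = 1.0
        # two arms
        for k in range(28):
            px[50 - k, 49 - k: 52 - k] = 1.0
            px[50 - k, 49 + k: 52 + k] = 1.0
        sk = skeletonize_vessels(_img(px, grid100))
        assert len(sk.segments) == 3
        nbr = ndimage.convolve(sk.skeleton_mask.astype(int),
                               np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]]),
                               mode="constant")
        assert (nbr[sk.skeleton_mask] <= 2).all()

    def test_no_component_below_five_pixels(self, grid100):
        rng = np.random.default_rng(5)
        px = rng.random((grid100.n_y, grid100.n_x)) ** 4
        sk = skeletonize_vessels(_img(px, grid100))
        if sk.skeleton_mask.any():
            labels, n = ndimage.label(sk.skeleton_mask,
                                      structure=np.ones((3, 3), int))
            sizes = ndimage.sum_labels(sk.skeleton_mask, labels,
                                       index=np.arange(1, n + 1))
            assert sizes.min() >= 5

    def test_cleanup_idempotent_segment_count(self, grid100):
        px = np.zeros((grid100.n_y, grid100.n_x))
        px[50:53, 15:85] = 1.0
        px[20:70, 30:33] = 1.0
        sk = skeletonize_vessels(_img(px, grid100))
        rendered = ndimage.binary_dilation(sk.skeleton_mask,
                                           iterations=1).astype(float)
        sk2 = skeletonize_vessels(_img(rendered, grid100))
        assert len(sk2.segments) == len(sk.segments)


class TestVolumeAssembly:
    def _slice(self, shift=(0.0, 0.0)):
        rng = np.random.default_rng(7)
        base = ndimage.gaussian_filter(rng.random((60, 80)), 3.0)
        return ndimage.shift(base, shift, order=1, mode="nearest")

    def test_identical_slices_recover_zero_shift(self):
        grid = build_grid(40.0, 30.0, 0.5, (0.0, 0.0))
        imgs = [_img(self._slice(), grid) for _ in range(4)]
        vol = assemble_volume(imgs, step_mm=0.5)
        assert np.allclose(vol.slice_shifts_px, 0.0, atol=1e-9)

    def test_known_shifts_recovered_subpixel(self):
        grid = build_grid(40.0, 30.0, 0.5, (0.0, 0.0))
        true = [(0.0, 0.0), (1.5, -2.0), (3.0, 1.0), (-2.0, 2.5)]
        imgs = [_img(self._slice(s), grid) for s in true]
        vol = assemble_volume(imgs, step_mm=0.5)
        # registration recovers the negative of the injected displacement
        rec = -vol.slice_shifts_px
        err = rec - np.array(true)
        err -= err[0]
        assert np.sqrt((err ** 2).mean()) <= 0.25

    def test_z_interpolation_plane_count(self):
        grid = build_grid(10.0, 10.0, 0.1, (0.0, 0.0))
        base = np.zeros((grid.n_y, grid.n_x))
        imgs = [_img(base, grid) for _ in range(86)]
        vol = assemble_volume(imgs, step_mm=1.0)
        assert vol.data.shape[0] == 851
        assert vol.voxel_mm == (0.1, 0.1, 0.1)

    def test_single_slice_passthrough(self):
        grid = build_grid(10.0, 10.0, 0.5, (0.0, 0.0))
        img = _img(np.ones((grid.n_y, grid.n_x)), grid)
        vol = assemble_volume([img], step_mm=0.71)
        assert vol.data.shape[0] == 1


class TestDepthEncodedProjection:
    def _volume(self, grid, n_z=20):
        data = np.zeros((n_z, grid.n_y, grid.n_x))
        return data

    def test_uniform_depth_vessel_maps_to_constant_distance(self):
        grid = build_grid(20.0, 20.0, 1.0, (0.0, 0.0))
        data = self._volume(grid)
        skin = np.zeros_like(data, bool)
        skin[:, 0, :] = True
        data[:, 10, :] = 1.0  # vessel plane 10 voxels below the skin
        vol = Volume(data, (1.0, 1.0, 1.0), grid)
        out = depth_encoded_projection(vol, skin, (1, 20))
        assert np.allclose(out.depth_mm, 10.0)
        assert np.allclose(out.amplitude, 1.0)

    def test_projection_takes_per_column_max(self):
        grid = build_grid(30.0, 30.0, 1.0, (0.0, 0.0))
        data = self._volume(grid, n_z=5)
        skin = np.zeros_like(data, bool)
        skin[:, 0, :] = True
        data[:, 5, :] = 0.6
        data[:, 25, :] = 1.0
        vol = Volume(data, (1.0, 1.0, 1.0), grid)
        out = depth_encoded_projection(vol, skin, (0, 30))
        assert np.allclose(out.amplitude, 1.0)
        assert np.allclose(out.depth_mm, 25.0)

    def test_hemispherical_skin_constant_offset(self):
        grid = build_grid(40.0, 40.0, 0.5, (0.0, 0.0))
        n = 80
        vox = 0.5
        data = np.zeros((n, n, n))
        z, y, x = np.mgrid[:n, :n, :n].astype(float) * vox
        r = np.sqrt((z - 20) ** 2 + (y - 20) ** 2 + (x - 20) ** 2)
        skin = np.abs(r - 18.0) < 0.5 * vox
        vessel = np.abs(r - 10.0) < 0.5 * vox  # constant 8-mm skin offset
        data[vessel] = 1.0
        vol = Volume(data, (vox, vox, vox), grid)
        out = depth_encoded_projection(vol, skin, (0, n))
        sel = out.amplitude > 0.5
        assert np.abs(out.depth_mm[sel] - 8.0).max() <= 0.5

    def test_empty_slab_rejected(self):
        grid = build_grid(10.0, 10.0, 1.0, (0.0, 0.0))
        vol = Volume(np.zeros((3, grid.n_y, grid.n_x)), (1, 1, 1), grid)
        with pytest.raises(ValueError):
            depth_encoded_projection(vol, np.ones_like(vol.data, bool), (5, 5))


class TestCNR:
    def test_matching_stats_give_zero(self, grid100):
        rng = np.random.default_rng(11)
        px = rng.normal(0.5, 0.1, (grid100.n_y, grid100.n_x))
        vessel = np.zeros_like(px, bool)
        vessel[10:20, 10:20] = True
        bg = np.zeros_like(px, bool)
        bg[60:90, 60:90] = True
        img = _img(px, grid100)
        cnr = compute_cnr(img, vessel, bg)
        assert abs(cnr) < 0.5  # same distribution, CNR near zero

    def test_known_arithmetic(self, grid100):
        px = np.full((grid100.n_y, grid100.n_x), 0.2)
        rng = np.random.default_rng(12)
        bg = np.zeros_like(px, bool)
        bg[60:90, :] = True
        px[bg] = rng.normal(0.2, 0.1, bg.sum())
        # rescale the realised background to exactly mean 0.2, std 0.1
        vals = px[bg]
        px[bg] = (vals - vals.mean()) / vals.std() * 0.1 + 0.2
        vessel = np.zeros_like(bg)
        vessel[10:20, :] = True
        px[vessel] = 1.0
        assert compute_cnr(_img(px, grid100), vessel, bg) == pytest.approx(8.0)

    def test_zero_background_variance_rejected(self, grid100):
        px = np.full((grid100.n_y, grid100.n_x), 0.2)
        vessel = np.zeros_like(px, bool)
        vessel[5, 5] = True
        bg = np.zeros_like(px, bool)
        bg[20:30, 20:30] = True
        with pytest.raises(UndefinedCNRError):
            compute_cnr(_img(px, grid100), vessel, bg)

    def test_overlapping_masks_rejected(self, grid100):
        px = np.zeros((grid100.n_y, grid100.n_x))
        m = np.ones_like(px, bool)
        with pytest.raises(ValueError):
            compute_cnr(_img(px, grid100), m, m)
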