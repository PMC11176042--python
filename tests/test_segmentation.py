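"""Background subtraction, thresholding, hole filling, gland separation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from glandmorph import segmentation as seg
from glandmorph import synthetic as syn
from glandmorph.synthetic import _paint_capsule

SEC = (1.5, 1.52, 1.52)


class TestSubtractBackground:
    def test_flat_volume_becomes_zero(self):
        out = seg.subtract_background(np.full((16, 40, 40), 55.0), 30.0, SEC)
        assert np.allclose(out, 0.0)

    def test_single_bright_voxel_preserved(self):
        img = np.zeros((16, 40, 40))
        img[8, 20, 20] = 123.0
        out = seg.subtract_background(img, 30.0, SEC)
        assert out[8, 20, 20] == pytest.approx(123.0)

    def test_output_nonnegative(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 100, size=(12, 30, 30))
        out = seg.subtract_background(img, 20.0, SEC)
        assert (out >= 0).all()

    def test_gradient_background_removed_around_tube(self):
        # tube on a strong smooth gradient: after subtraction + Otsu, the
        # recovered mask should essentially equal the clean tube mask
        shape = (24, 60, 120)
        img = np.zeros(shape)
        _paint_capsule(img, 120.0, np.array([18.0, 45.0, 20.0]),
                       np.array([18.0, 45.0, 160.0]), 6.0, SEC)
        tube = img > 0
        zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        background = 40.0 + 0.4 * xx + 0.3 * yy
        out = seg.subtract_background(img + background, 30.0, SEC)
        mask = seg.binarize(out, "otsu")
        inter = (mask & tube).sum()
        union = (mask | tube).sum()
        assert inter / union >= 0.95

    def test_subvoxel_sphere_rejected(self):
        with pytest.raises(ValueError, match="smaller than one voxel"):
            seg.subtract_background(np.zeros((5, 5, 5)), 0.5, (7, 1.52, 1.52))


class TestBinarize:
    def test_fixed_threshold_identity_on_binary(self):
        vol = (np.random.default_rng(1).random((6, 6, 6)) > 0.5).astype(float)
        mask = seg.binarize(vol, "fixed:0.5")
        assert np.array_equal(mask, vol.astype(bool))

    def test_otsu_lands_between_bimodal_modes(self):
        rng = np.random.default_rng(2)
        vol = np.concatenate(
            [rng.normal(30, 12, size=4000), rng.normal(90, 12, size=4000)]
        ).reshape(20, 20, 20)
        from glandmorph.segmentation import binarize_with_threshold

        # brute-force sweep minimizing intra-class variance
        flat = vol.ravel()
        ts = np.linspace(flat.min(), flat.max(), 512)[1:-1]
        intra = [
            flat[flat <= t].var() * (flat <= t).mean()
            + flat[flat > t].var() * (flat > t).mean()
            for t in ts
        ]
        t_ref = ts[int(np.argmin(intra))]
        _, t = binarize_with_threshold(vol, "otsu")
        assert 30.0 < t < 90.0
        assert abs(t - 60.0) / 60.0 < 0.05
        assert abs(t - t_ref) < 3.0

    def test_constant_volume_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            seg.binarize(np.zeros((4, 4, 4)), "otsu")


class TestFillHoles:
    def test_hollow_sphere_becomes_solid(self):
        img = np.zeros((30, 30, 30))
        _paint_capsule(img, 1.0, np.array([15.0] * 3), np.array([15.0] * 3), 10.0, (1, 1, 1))
        solid = img > 0
        hollow = solid.copy()
        inner = np.zeros_like(img)
        _paint_capsule(inner, 1.0, np.array([15.0] * 3), np.array([15.0] * 3), 6.0, (1, 1, 1))
        hollow &= ~(inner > 0)
        assert np.array_equal(seg.fill_holes_3d(hollow), solid)

    def test_solid_tube_unchanged(self):
        img = np.zeros((12, 12, 30))
        _paint_capsule(img, 1.0, np.array([6.0, 6.0, 3.0]), np.array([6.0, 6.0, 27.0]), 4.0, (1, 1, 1))
        tube = img > 0
        assert np.array_equal(seg.fill_holes_3d(tube), tube)

    @settings(max_examples=25, deadline=None)
    @given(hnp.arrays(bool, (6, 7, 8), elements=st.booleans()))
    def test_idempotent(self, mask):
        once = seg.fill_holes_3d(mask)
        assert np.array_equal(seg.fill_holes_3d(once), once)


class TestSeparateGlands:
    def test_scene_glands_recovered_one_each(self, noiseless_segmentation):
        scene, truth, mask, glands = noiseless_segmentation
        assert len(glands) == len(scene.gland_trees)

    def test_empty_lumen_rejected(self):
        with pytest.raises(ValueError, match="lumen"):
            seg.separate_glands(
                np.ones((4, 4, 4), bool), np.zeros((4, 4, 4), bool), (1, 1, 1)
            )

    def test_no_glands_gives_empty_list(self):
        lumen = np.zeros((6, 6, 6), bool)
        lumen[2:4, 2:4, 2:4] = True
        assert seg.separate_glands(lumen.copy(), lumen, (1, 1, 1)) == []

    def test_border_touching_gland_flagged(self):
        mask = np.zeros((10, 10, 30), bool)
        lumen = np.zeros_like(mask)
        lumen[4:7, 4:7, 25:] = True
        mask[4:7, 4:7, :20] = True  # gland slab reaching the x=0 border
        mask |= lumen
        glands = seg.separate_glands(mask, lumen, (1, 1, 1), min_volume_voxels=10)
        assert len(glands) == 1
        assert glands[0].touches_border

    def test_min_volume_filters_specks(self):
        mask = np.zeros((10, 10, 20), bool)
        lumen = np.zeros_like(mask)
        lumen[4:6, 4:6, 16:] = True
        mask[4:6, 4:6, 10:14] = True  # 32-voxel blob
        mask[0, 0, 0] = True  # 1-voxel speck
        mask |= lumen
        glands = seg.separate_glands(mask, lumen, (1, 1, 1), min_volume_voxels=10)
        assert len(glands) == 1
        assert glands[0].n_voxels == 16

    def test_attachment_is_nearest_lumen_point(self, noiseless_segmentation):
        scene, truth, mask, glands = noiseless_segmentation
        from glandmorph.evaluate import match_glands

        matched = match_glands(glands, truth.labels)
        spacing = np.array(scene.spec.voxel_size_um)
        for lab, (g, _) in matched.items():
            tree = scene.gland_trees[lab - 2]
            err = np.linalg.norm(g.attachment_point_um - tree.attachment_point_um)
            assert err <= 2.5 * np.linalg.norm(spacing)

    def test_volume_conservation(self, noiseless_segmentation):
        scene, truth, mask, glands = noiseless_segmentation
        voxvol = float(np.prod(scene.spec.voxel_size_um))
        total_fg = (mask | (truth.labels == 1)).sum() * voxvol
        lumen_vol = (truth.labels == 1).sum() * voxvol
        assert sum(g.volume_um3 for g in glands) + lumen_vol <= total_fg + voxvol

    def test_noiseless_identity_after_dilation(self, noiseless_segmentation):
        # segmentation of a noiseless render reproduces the rasterized
        # ground-truth gland voxels exactly, up to the same lumen dilation
        scene, truth, mask, glands = noiseless_segmentation
        from scipy import ndimage

        lumen_dil = ndimage.binary_dilation(truth.labels == 1, seg.STRUCT_26)
        expected = (truth.labels >= 2) & ~lumen_dil
        got = np.zeros_like(expected)
        for g in glands:
            got[g.voxels[:, 0], g.voxels[:, 1], g.voxels[:, 2]] = True
        assert np.array_equal(got, expected)
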