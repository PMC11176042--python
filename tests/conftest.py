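import numpy as np
import pytest

from glandmorph import synthetic as syn


@pytest.fixture(scope="session")
def small_gland_scene():
    """One whole-mount scene with glands spanning branch counts 0-8."""
    spec = syn.SceneSpec(
        volume_shape_voxels=(28, 768, 288),
        voxel_size_um=syn.WHOLE_MOUNT_SPACING,
        n_glands=9,
        branch_counts=[0, 1, 2, 3, 4, 5, 6, 7, 8],
        gland_length_range_um=(90, 160),
        seed=3,
    )
    return syn.make_gland_scene(spec)


@pytest.fixture(scope="session")
def noiseless_segmentation(small_gland_scene):
    """Segmented glands from the noiseless render of the shared scene."""
    from glandmorph import segmentation as seg

    scene = small_gland_scene
    truth = syn.rasterize_labels(scene)
    vol = syn.render_volume(scene, syn.ImagingParams.noiseless(), ["gland_marker"])
    mask = seg.fill_holes_3d(seg.binarize(vol.data.astype(float), "fixed:60"))
    glands = seg.separate_glands(mask, truth.labels == 1, scene.spec.voxel_size_um)
    return scene, truth, mask, glands


def capsule_mask(shape, segments, radius, spacing=(1.0, 1.0, 1.0)):
    """Rasterize a union of capsules; helper for small topology fixtures."""
    from glandmorph.synthetic import _paint_capsule

    img = np.zeros(shape)
    for a, b in segments:
        _paint_capsule(img, 1.0, np.asarray(a, float), np.asarray(b, float), radius, spacing)
    return img > 0
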