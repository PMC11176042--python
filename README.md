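# glandmorph

3D morphometry of branched uterine glands and implantation geometry from
confocal z-stacks, with a synthetic ground-truth generator that makes every
stage of the pipeline verifiable.

Mouse uterine glands are tubular epithelial invaginations that bud off the
uterine lumen and branch in adulthood; their secretions (notably the
cytokine LIF) are required for embryo implantation. Quantifying how gland
*structure* relates to gland *function* requires measuring, from 3D
fluorescence volumes: how many branch points each gland has, how long it
is, how the implanting blastocyst is oriented relative to the uterine
mesometrial–antimesometrial (M-AM) axis, and how much transcript signal a
gland compartment contains. `glandmorph` implements that measurement chain
as a reproducible pipeline:

1. **synthetic scenes** — phantom volumes containing a luminal tube, gland
   trees with *known* branch counts and lengths, blastocysts with known
   axis angles, and punctate transcript signal of known volume fraction,
   rendered through a PSF → Poisson → Gaussian imaging model;
2. **segmentation** — top-hat background subtraction with a 30 µm
   spherical structuring element (anisotropy-corrected), thresholding,
   3D hole filling, and separation of glands from the lumen by subtracting
   a dilated lumen mask and taking 26-connected components;
3. **skeleton morphometry** — topology-preserving 3D thinning, condensation
   of the skeleton into a spatial graph (junction clusters merge into
   single branch points), spur/loop pruning, branch-point counting
   (nodes of degree ≥ 3), branch categories {0, 1–3, >3}, and gland length
   as the straight-line (chord) distance from the lumen attachment point
   to the furthest skeleton tip;
4. **implantation geometry** — the embryo-axis alignment angle: the
   ICM→abembryonic axis is projected onto the plane spanned by the M-AM
   axis and the axis's in-plane component, and the unsigned angle is
   folded into [0°, 90°];
5. **signal quantification** — thresholded signal volume per compartment
   volume (e.g. *Lif* per gland volume, in normalized units) and
   marker-positive cell fractions from labeled nuclei;
6. **statistics** — two-sided Mann–Whitney (exact enumeration for small
   tie-free samples), Kruskal–Wallis with Dunn's pairwise post-hoc tests,
   the pooled two-proportion Z-test, and implantation/rescue table
   arithmetic.

## Worked example

```python
import numpy as np

from glandmorph import (
    ImagingParams, SceneSpec, make_gland_scene, render_volume,
    subtract_background, binarize, fill_holes_3d, separate_glands,
    measure_gland, branch_category_table, mann_whitney,
)
from glandmorph.synthetic import WHOLE_MOUNT_SPACING, rasterize_labels

# a whole-mount z-stack phantom: 9 glands with 0..8 true branch points
spec = SceneSpec(
    volume_shape_voxels=(28, 768, 288),
    voxel_size_um=WHOLE_MOUNT_SPACING,   # (7, 1.52, 1.52) µm
    n_glands=9,
    branch_counts=[0, 1, 2, 3, 4, 5, 6, 7, 8],
    gland_length_range_um=(90, 160),
    seed=42,
)
scene = make_gland_scene(spec)
volume = render_volume(scene, ImagingParams(), ["gland_marker"])

# segment: top-hat background subtraction, Otsu, hole filling, then cut
# glands away from the lumen mask
img = subtract_background(volume.channel("gland_marker").astype(np.float32),
                          sphere_diameter_um=30.0,
                          voxel_size_um=spec.voxel_size_um)
mask = fill_holes_3d(binarize(img, "otsu"))
lumen = rasterize_labels(scene).labels == 1
glands = separate_glands(mask, lumen, spec.voxel_size_um)

records = [measure_gland(g, mask.shape, spec.voxel_size_um) for g in glands]
print(f"{len(glands)} glands segmented")
print("branch points:", sorted(r.n_branch_points for r in records),
      "(truth:", sorted(scene.true_branch_counts), ")")
print(branch_category_table(records)[["branch_category", "n_glands", "percent"]]
      .to_string(index=False))

res = mann_whitney([7, 9, 8, 10, 9], [3, 4, 2, 5])
print(f"Mann-Whitney U={res.statistic:.0f}, p={res.p_value:.4f}")
```

Output:

```
9 glands segmented
branch points: [0, 1, 2, 3, 4, 5, 6, 7, 8] (truth: [0, 1, 2, 3, 4, 5, 6, 7, 8] )
branch_category  n_glands   percent
              0         1 11.111111
            1-3         3 33.333333
             >3         5 55.555556
Mann-Whitney U=20, p=0.0195
```

Every branch count is recovered exactly from the noisy render, and the
category table gives the per-group percentages of glands with 0, 1–3, and
>3 branches that group comparisons (two-proportion Z-tests) operate on.

## Command line

`glandmorph` exposes subcommands mirroring the pipeline stages:

```bash
glandmorph simulate --config configs/example_glands.yaml --out out/ --seed 1
glandmorph segment --volume out/volume.ome.tif --lumen-mask out/truth_labels.ome.tif \
    --sphere-diameter 30 --threshold otsu --out out/
glandmorph skeletonize --labels out/gland_labels.ome.tif --glands-csv out/glands.csv --out out/
glandmorph quantify-axis --volume out/volume.ome.tif --mam-axis x+ --out out/
glandmorph quantify-signal --volume out/volume.ome.tif --signal-channel lif \
    --region-mask out/gland_labels.ome.tif --region gland --out out/
glandmorph stats --table groups.csv --test kw --group-col genotype --value-col angle_deg --out out/
glandmorph pipeline --config configs/example_glands.yaml --out out/ --seed 1
```

All CSV outputs are byte-stable for a fixed config and seed, and each
report carries a JSON provenance sidecar (config hash, seed, version).

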