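# Methods

This note documents the models, conventions, and numerical choices behind
`glandmorph`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Coordinate and measurement conventions

Voxel indices are 0-based `(z, y, x)`; physical coordinates are
`index × voxel_size_um` at voxel centers, in micrometres. Two spacing
presets mirror common confocal acquisition: whole-mount tile scans at
`(7, 1.52, 1.52)` µm and section stacks at `(1.5, 1.52, 1.52)` µm.
Anisotropy is handled by physical-distance weighting of every path and
structuring element, never by resampling, which would interpolate across
7 µm z-steps.

The mesometrial direction is `+x`; the optical section plane ("XY") is a
constant-z plane.

## Synthetic scenes

A scene contains a straight luminal tube along `y`, gland trees budding
from the anti-mesometrial lumen surface, optional blastocysts, clustered
transcript signal, and labeled epithelial cell nuclei. Ground truth —
per-gland branch-point count and chord length, per-embryo axis angle,
exact signal-voxel sets, positive-cell identities — is recorded at
generation time, so each pipeline stage has a recovery test.

**Gland trees.** Each gland is a jittered trunk polyline growing away from
the lumen with `k` terminal side branches hung off distinct trunk nodes
(each adds exactly one degree-3 node). Geometry is chosen so the
measurement problem is realistic but well-posed:

* tube radius 6 µm (gland tubes a dozen µm across);
* side branches 30–40 µm long, directed mostly perpendicular to the trunk
  (components −0.55 x̂ ± 0.80 ŷ ± ≤0.2 ẑ, alternating in y). Near-parallel
  branches would merge with the trunk tube for most of their length and
  make the branch count ill-defined at this resolution;
* junctions spaced ≥ 24 µm along the trunk so their skeleton clusters stay
  distinct;
* trunks are steered back when they drift more than 14 µm from their lane
  center, which guarantees neighboring glands never touch;
* branch-count categories sample as `0 → 0`, `1–3 → uniform{1,2,3}`,
  `>3 → uniform{4..8}`.

Gland length ground truth is the chord: the maximum Euclidean distance
from the lumen attachment point to any tree node.

**Embryos.** A blastocyst is a sphere (radius 32 µm by default, reduced to
fit the lumen when embedded in a gland scene) rendered in the nuclei
channel, with the inner cell mass (ICM) as a smaller, brighter sub-sphere
placed against the wall. The embryonic axis (ICM centroid minus
abembryonic pole) is laid in the optical plane so that it makes exactly
the requested angle with the M-AM axis under the projection convention
below.

**Transcript signal.** Signal voxels are chosen inside the gland raster as
clustered blobs (default radius 7 µm) stamped until exactly
`round(fraction × gland voxels)` voxels are marked; the last blob is
trimmed, so the noiseless volume fraction is exact by construction. The
blob scale models the coherent clusters that strong glandular expression
forms rather than single-molecule dots; diffraction-limited single puncta
at these voxel sizes are not separable volumetrically and are out of
scope.

**Cells.** Epithelial nuclei (radius 2.6 µm) sit in rings of six around
the tube axis, ~5 µm apart along it; exactly
`round(fraction × n)` cells are marked positive.

**Imaging model.** Each channel is the binary rasterization × amplitude,
blurred with a Gaussian PSF, offset by a constant background, Poisson
resampled (gain = photons per intensity unit; 0 disables), and perturbed
with Gaussian read noise, then clipped to the bit depth. Defaults:
PSF σ = (2, 1, 1) µm, background 8, gain 1, read noise σ = 3,
amplitude 120, 16-bit — shot-noise-limited SNR ≈ 10, enough to stress
thresholding without making segmentation the bottleneck. The generator
does **not** model depth-dependent attenuation, clearing or mounting
artifacts, tile-stitching seams, autofluorescence texture, or
non-epithelial structures; passing recovery tests therefore demonstrates
the correctness of the measurement chain, not robustness to every
real-tissue nuisance.

## Segmentation

* **Background subtraction** is a grayscale top-hat with a spherical
  element of physical diameter 30 µm, converted to an anisotropy-corrected
  ellipsoid in voxel units. For large elements the opening is evaluated at
  a pooled scale: block min-pooling (an exact box erosion sampled at the
  block stride), a small-ellipsoid erosion/dilation at that scale, and
  nearest-neighbor upsampling of the resulting background. The background
  by definition varies on scales larger than the sphere, so pooling
  changes the result negligibly while making whole-horn volumes tractable.
  The 30 µm value follows the convention of treating the "largest sphere
  diameter" of surface-detail background subtraction as a physical
  diameter; it is configurable.
* **Thresholding** is Otsu by default (recorded in provenance) or a fixed
  value; constant images raise instead of returning an empty mask.
* **Hole filling** is standard 3D binary fill of cavities not connected to
  the volume border; it is idempotent.
* **Gland separation** subtracts a one-voxel-dilated lumen mask (the
  programmatic replacement for manually cutting glands off the lumen
  surface) and labels 26-connected components of at least 50 voxels
  (26-connectivity so thin diagonal tubes do not fragment; the minimum
  volume suppresses noise specks and is reported in provenance). The
  lumen mask is an explicit input: synthetic runs take it from ground
  truth and real data can supply a curated one. Each gland's attachment
  point is its voxel closest (physical distance) to the lumen surface,
  ties broken by lowest `(z, y, x)`.

## Skeleton morphometry

Glands are thinned with topology-preserving 3D thinning (Lee-type, via
scikit-image). Two systematic artifacts of voxel thinning are corrected
explicitly:

* **Missed tips.** For tubes nearly aligned with a grid axis at certain
  sub-voxel offsets, no voxel at the tube end satisfies the thinning
  endpoint condition and the skeleton retracts along the tube (tens of
  voxels in the worst case). The skeleton is therefore verified against
  the mask: the geodesic (in-mask) distance from the skeleton to every
  mask voxel must not exceed the gland's maximum tube radius plus two
  voxel diagonals. Any voxel beyond that is reconnected by a shortest
  path routed along the medial ridge (path costs divided down where the
  distance transform is large), restoring the missing tip without
  disturbing topology elsewhere.
* **Junction loops.** Thick junctions can thin into small cycles of two
  nearby degree-3 nodes. Since every genuine edge of a tree skeleton is a
  bridge, short non-bridge edges (< 2× the spur threshold) are removed;
  this provably never disconnects the skeleton and never touches real
  branches.

The skeleton condenses into a spatial graph: junction voxels (≥ 3 skeleton
neighbors, 26-connectivity) merge per connected cluster into one node at
the cluster centroid — a junction *cluster* counts as one branch point —
endpoints are degree-1 nodes, and edges carry their voxel polyline and
anisotropy-weighted length. Terminal spurs shorter than the pruning
threshold are removed iteratively (shortest first), and junctions left
with degree 2 are dissolved. The default spur threshold is 2× the gland's
mean tube radius (mean of the distance transform along the skeleton),
which removes surface-bump artifacts (≲ one radius) while preserving true
branches; it is configurable and recorded.

**Branch points** are graph nodes of degree ≥ 3; categories are
`0`, `1–3` = {1,2,3}, `>3` = {4,…}. **Gland length** is the chord — the
straight-line distance from the attachment point to the furthest skeleton
tip — matching the verbal definition of the bounding-box length
measurement; the geodesic (along-skeleton) distance to the furthest tip
is exported as a secondary column.

## Embryo-axis geometry

The alignment angle of the embryonic axis `v = ICM − abembryonic pole`
against the M-AM axis reproduces a three-point measurement placed on the
M-AM plane: `v` is projected onto the plane spanned by the M-AM axis and
the in-plane (constant-z) component of `v`, and the unsigned angle between
the projection and the M-AM axis is folded into [0°, 90°]. Folding is the
natural reading of reported alignment medians, which never exceed 90°.
Because the optical plane is part of the construction, the angle is
invariant under rotations about the optical axis (and to swapping
`v → −v`), but not under arbitrary 3D rotations — the same is true of the
manual measurement it reproduces. The M-AM axis is always an explicit
input; inferring it from tissue geometry is out of scope.

From volumes, embryos are bright nuclei-channel clusters of at least 200
voxels; the ICM is the brighter sub-cluster (second Otsu split within the
embryo, intensity-weighted centroid), and the abembryonic pole is found by
marching from the cluster centroid away from the ICM to the mask boundary.

## Signal quantification

`Lif`-style signal is quantified volumetrically: signal voxels are the
thresholded channel restricted to the compartment mask, the ratio is
signal volume / compartment volume (unitless "normalized units", raw
volumes retained). The threshold is computed from intensities *inside*
the region (the masked-channel construction). With Otsu, a no-signal
guard rejects splits whose class separation is under 4× the background
class spread — Otsu always splits something, and without the guard a
blank region would report ≈ half its volume as signal. Raising the
threshold can never raise the ratio, and the ratio is exactly
volume-additive over disjoint sub-regions at a fixed threshold.

Cell positivity: a cell is positive iff the mean marker intensity over its
nucleus label is at least the threshold (Otsu over the distribution of
within-region cell means by default, or a fixed config value).

## Statistics

* **Mann–Whitney** (two-sided): exact by full enumeration over rank
  assignments when `n₁+n₂ ≤ 12` and tie-free (midranks make the exact
  test well-defined under ties when forced with `mode="exact"`); the
  two-sided p is the null probability of a U at least as far from
  `n₁n₂/2` as observed. Otherwise the tie-corrected normal approximation
  with continuity correction. The mode used is recorded.
* **Kruskal–Wallis** with tie-corrected H; with two groups the call
  delegates to Mann–Whitney; all-identical data reports H = 0, p = 1.
  **Dunn's** pairwise z uses the pooled-rank variance
  `(N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/nᵢ + 1/nⱼ)`; the family adjustment
  is Bonferroni by default (Holm and none available) — the post-hoc
  procedure is named ambiguously in common usage, so the adjustment is
  explicit configuration.
* **Two-proportion Z**: pooled variance, two-sided normal p; a pooled
  proportion of exactly 0 or 1 is flagged degenerate (z = 0, p = 1).
* Implantation-table operations (embryos per embryo-bearing mouse,
  mouse- and embryo-level rescue percentages) are pure rational
  arithmetic; percentages are display-rounded to integers with full
  precision retained.

## Problem sizes

The recovery suites use 208 glands per condition (four whole-mount scenes
of 32 glands and five section scenes of 16, branch counts cycling 0–8),
seven axis angles spanning 0–90°, signal fractions {0, 0.1, 0.3, 0.5},
and 600 cells for positivity calling — sizes chosen so the binomial/CI
assertions are meaningful while a full run stays at desk scale on one
CPU.

## Known limitations

* The generator's glands are herringbone-like (all bifurcations on one
  trunk); deeply nested or coiled topologies are not exercised, and no
  tortuosity/coiling index is computed.
* Segmentation is classical (threshold-based); densely packed real glands
  whose tubes touch would need a curated lumen mask and possibly manual
  splitting, as in the interactive workflow this pipeline replaces.
* The embryo-axis measurement assumes one bright cluster per embryo and a
  denser ICM; degenerate or fragmented embryos are skipped with a log
  entry.
* Signal-volume ratios depend on the threshold convention; values are
  comparable within a pipeline run (fixed convention) but not across
  different thresholding schemes.
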