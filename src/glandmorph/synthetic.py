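"""Ground-truth 3D scene generator for uterine-gland morphometry.

A scene holds a luminal tube running along the y axis with gland trees
budding from its anti-mesometrial (low-x) surface, optional blastocysts
with a known embryonic-axis orientation, punctate transcript signal of a
known volume fraction inside the glands, and marker-positive cell labels.
Every quantity the downstream pipeline measures (branch points, chord
length, axis angle, signal fraction, positive-cell fraction) is recorded
exactly at generation time, so each stage has a recovery test against
known truth.

Coordinates are physical micrometres in ``(z, y, x)`` order; the
mesometrial direction is ``+x``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import CHANNEL_ROLES, LabelMask, VolumeImage

__all__ = [
    "SceneSpec",
    "ImagingParams",
    "GlandTree",
    "Embryo",
    "GroundTruthScene",
    "GeometryError",
    "make_gland_scene",
    "make_embryo_scene",
    "render_volume",
    "render_cell_marker",
    "rasterize_labels",
    "WHOLE_MOUNT_SPACING",
    "SECTION_SPACING",
]

#: Confocal voxel-spacing presets (z, y, x) in µm: whole-horn tile scans
#: with 7 µm z-steps, and section stacks with 1.5 µm z-steps.
WHOLE_MOUNT_SPACING = (7.0, 1.52, 1.52)
SECTION_SPACING = (1.5, 1.52, 1.52)

BRANCH_CATEGORIES = ("0", "1-3", ">3")

MESOMETRIAL_AXIS = np.array([0.0, 0.0, 1.0])  # +x in (z, y, x)

_ZHAT = np.array([1.0, 0.0, 0.0])
_YHAT = np.array([0.0, 1.0, 0.0])
_XHAT = np.array([0.0, 0.0, 1.0])


class GeometryError(ValueError):
    """Requested scene geometry does not fit inside the volume."""


def normalize_category(cat: str) -> str:
    c = str(cat).replace("–", "-").strip()
    if c not in BRANCH_CATEGORIES:
        raise ValueError(f"unknown branch category {cat!r}")
    return c


def branch_category(n_branch_points: int) -> str:
    """Map a branch-point count to its reporting category."""
    if n_branch_points < 0:
        raise ValueError("branch count must be nonnegative")
    if n_branch_points == 0:
        return "0"
    if n_branch_points <= 3:
        return "1-3"
    return ">3"


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene.

    ``branch_counts`` gives explicit per-gland branch-point counts;
    alternatively ``branch_count_distribution`` maps the reporting
    categories ``{"0", "1-3", ">3"}`` to sampling probabilities.
    """

    volume_shape_voxels: tuple[int, int, int] = (28, 512, 288)
    voxel_size_um: tuple[float, float, float] = WHOLE_MOUNT_SPACING
    lumen_radius_um: float = 22.0
    n_glands: int = 0
    branch_counts: list[int] | None = None
    branch_count_distribution: dict[str, float] | None = None
    gland_length_range_um: tuple[float, float] = (90.0, 200.0)
    tortuosity: float = 0.15
    gland_radius_um: float = 6.0
    embryo_axis_angle_deg: float | None = None
    embryo_radius_um: float = 32.0
    lif_volume_fraction: float = 0.0
    lif_punctum_radius_um: float = 7.0
    esr1_positive_fraction: float = 0.0
    n_cells: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.volume_shape_voxels = tuple(int(s) for s in self.volume_shape_voxels)
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if any(s <= 0 for s in self.volume_shape_voxels):
            raise ValueError("volume shape must be positive")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be strictly positive")
        if self.lumen_radius_um <= 0 or self.gland_radius_um <= 0:
            raise ValueError("radii must be positive")
        if self.n_glands < 0:
            raise ValueError("n_glands must be nonnegative")
        lo, hi = self.gland_length_range_um
        if not (0 < lo <= hi):
            raise ValueError("gland_length_range_um must be a positive interval")
        if self.tortuosity < 0:
            raise ValueError("tortuosity must be nonnegative")
        if not (0.0 <= self.lif_volume_fraction <= 1.0):
            raise ValueError("lif_volume_fraction must lie in [0, 1]")
        if not (0.0 <= self.esr1_positive_fraction <= 1.0):
            raise ValueError("esr1_positive_fraction must lie in [0, 1]")
        if self.embryo_axis_angle_deg is not None and not (
            0.0 <= self.embryo_axis_angle_deg <= 90.0
        ):
            raise ValueError("embryo_axis_angle_deg must lie in [0, 90]")
        if self.branch_counts is not None:
            self.branch_counts = [int(k) for k in self.branch_counts]
            if any(k < 0 for k in self.branch_counts):
                raise ValueError("branch counts must be nonnegative")
            if len(self.branch_counts) != self.n_glands:
                raise ValueError("branch_counts length must equal n_glands")
        if self.branch_count_distribution is not None:
            dist = {
                normalize_category(c): float(p)
                for c, p in self.branch_count_distribution.items()
            }
            if any(p < 0 for p in dist.values()):
                raise ValueError("category probabilities must be nonnegative")
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError("category probabilities must sum to 1")
            self.branch_count_distribution = dist

    @property
    def extent_um(self) -> np.ndarray:
        return (np.array(self.volume_shape_voxels) - 1) * np.array(self.voxel_size_um)


@dataclass
class ImagingParams:
    """Forward imaging model: PSF blur, then Poisson, then Gaussian noise.

    ``poisson_gain`` is the photon count per intensity unit; 0 disables
    shot noise.  Intensities are clipped to the stated bit depth.
    """

    psf_sigma_um: tuple[float, float, float] = (2.0, 1.0, 1.0)
    background_level: float = 8.0
    poisson_gain: float = 1.0
    gaussian_sd: float = 3.0
    bit_depth: int = 16
    amplitude: float = 120.0

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if any(s < 0 for s in self.psf_sigma_um):
            raise ValueError("PSF sigmas must be nonnegative")
        if self.background_level < 0 or self.gaussian_sd < 0:
            raise ValueError("noise levels must be nonnegative")
        if self.poisson_gain < 0:
            raise ValueError("poisson_gain must be nonnegative")
        max_signal = self.amplitude + self.background_level
        if max_signal > 2**self.bit_depth - 1:
            raise ValueError("rendered intensities exceed the bit depth")

    @classmethod
    def noiseless(cls, amplitude: float = 120.0, bit_depth: int = 16) -> "ImagingParams":
        return cls(
            psf_sigma_um=(0.0, 0.0, 0.0),
            background_level=0.0,
            poisson_gain=0.0,
            gaussian_sd=0.0,
            bit_depth=bit_depth,
            amplitude=amplitude,
        )


@dataclass
class GlandTree:
    """One ground-truth gland: a spatial tree rooted at the lumen surface."""

    attachment_point_um: np.ndarray
    nodes: dict[int, np.ndarray]
    edges: list[tuple[int, int]]

    @property
    def degrees(self) -> dict[int, int]:
        deg: dict[int, int] = {n: 0 for n in self.nodes}
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    @property
    def true_branch_points(self) -> int:
        return sum(1 for d in self.degrees.values() if d >= 3)

    @property
    def true_length_um(self) -> float:
        """Chord length: max Euclidean distance from attachment to any node."""
        pts = np.array(list(self.nodes.values()))
        return float(
            np.max(np.linalg.norm(pts - self.attachment_point_um, axis=1))
        )

    @property
    def category(self) -> str:
        return branch_category(self.true_branch_points)

    def polylines(self) -> list[np.ndarray]:
        """Edges as 2-point polylines (µm), ready for tube rasterization."""
        return [
            np.stack([self.nodes[a], self.nodes[b]]) for a, b in self.edges
        ]


@dataclass
class Embryo:
    """A blastocyst with a recorded embryonic-axis orientation."""

    center_um: np.ndarray
    radius_um: float
    icm_point_um: np.ndarray
    abembryonic_point_um: np.ndarray
    icm_radius_um: float
    mam_axis: np.ndarray
    true_angle_deg: float


@dataclass
class GroundTruthScene:
    spec: SceneSpec
    lumen_centerline_um: np.ndarray
    lumen_radius_um: float
    gland_trees: list[GlandTree]
    embryos: list[Embryo] = field(default_factory=list)
    lif_voxels: np.ndarray | None = None  # (M, 3) voxel indices inside glands
    cells: list[dict] = field(default_factory=list)
    positive_cell_ids: frozenset[int] = frozenset()
    mam_axis: np.ndarray = field(default_factory=lambda: MESOMETRIAL_AXIS.copy())

    @property
    def true_branch_counts(self) -> list[int]:
        return [t.true_branch_points for t in self.gland_trees]

    @property
    def true_lengths_um(self) -> list[float]:
        return [t.true_length_um for t in self.gland_trees]


# ---------------------------------------------------------------------------
# rasterization helpers


def _voxel_grid_axes(shape, spacing):
    return [np.arange(n) * s for n, s in zip(shape, spacing)]


def _paint_capsule(out: np.ndarray, value, a, b, radius, spacing) -> None:
    """Set voxels within ``radius`` µm of segment a–b (physical coords)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    spacing = np.asarray(spacing, float)
    lo_um = np.minimum(a, b) - radius
    hi_um = np.maximum(a, b) + radius
    lo = np.maximum(np.floor(lo_um / spacing).astype(int), 0)
    hi = np.minimum(np.ceil(hi_um / spacing).astype(int) + 1, out.shape)
    if np.any(lo >= hi):
        return
    axes = [
        (np.arange(l, h) * s).astype(float)
        for l, h, s in zip(lo, hi, spacing)
    ]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        d2 = np.sum((pts - a) ** 2, axis=-1)
    else:
        t = np.clip(((pts - a) @ ab) / denom, 0.0, 1.0)
        proj = a + t[..., None] * ab
        d2 = np.sum((pts - proj) ** 2, axis=-1)
    sel = d2 <= radius * radius
    view = out[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    view[sel] = value


def _paint_ball(out: np.ndarray, value, center, radius, spacing) -> None:
    _paint_capsule(out, value, center, center, radius, spacing)


def rasterize_labels(scene: GroundTruthScene) -> LabelMask:
    """Rasterize the scene into an integer label volume.

    Label 1 is the lumen, labels 2..(1+n_glands) are the glands in tree
    order, and labels beyond that are embryos.  Gland voxels that would
    fall inside the lumen stay lumen, so gland labels partition cleanly.
    """
    spec = scene.spec
    shape = spec.volume_shape_voxels
    spacing = spec.voxel_size_um
    labels = np.zeros(shape, dtype=np.int32)
    # glands first, lumen painted over them so the shared wall is lumen
    for gi, tree in enumerate(scene.gland_trees):
        for seg in tree.polylines():
            _paint_capsule(labels, 2 + gi, seg[0], seg[1], spec.gland_radius_um, spacing)
    cl = scene.lumen_centerline_um
    if len(cl):
        for a, b in zip(cl[:-1], cl[1:]):
            _paint_capsule(labels, 1, a, b, scene.lumen_radius_um, spacing)
    next_label = 2 + len(scene.gland_trees)
    table = {1: "lumen"}
    table.update({2 + gi: "gland" for gi in range(len(scene.gland_trees))})
    for ei, emb in enumerate(scene.embryos):
        _paint_ball(labels, next_label + ei, emb.center_um, emb.radius_um, spacing)
        table[next_label + ei] = "embryo"
    return LabelMask(labels=labels, voxel_size_um=spacing, label_table=table)


# ---------------------------------------------------------------------------
# gland tree construction


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector")
    return v / n


def _sample_branch_count(rng: np.random.Generator, dist: dict[str, float]) -> int:
    cats = BRANCH_CATEGORIES
    probs = [dist.get(c, 0.0) for c in cats]
    cat = cats[rng.choice(len(cats), p=probs)]
    if cat == "0":
        return 0
    if cat == "1-3":
        return int(rng.integers(1, 4))
    return int(rng.integers(4, 9))


#: side-branch length range (µm): long enough to survive default spur pruning
BRANCH_LEN_RANGE = (30.0, 40.0)
#: side-branch direction components: mostly perpendicular to the trunk so
#: the branch tube separates from the trunk tube close to the junction
BRANCH_Y_COMPONENT = 0.80
BRANCH_X_COMPONENT = 0.55
BRANCH_Z_COMPONENT = 0.20
#: trunk centerlines are steered to stay within this lateral drift (µm)
TRUNK_DRIFT_LIMIT = 14.0
#: minimal junction spacing along the trunk (µm)
MIN_JUNCTION_GAP = 24.0
_LEAD_IN = 30.0  # straight run from the lumen before the first junction
_TAIL = 18.0


def _lane_half_width(gland_radius_um: float) -> float:
    return (
        TRUNK_DRIFT_LIMIT
        + BRANCH_Y_COMPONENT * BRANCH_LEN_RANGE[1]
        + gland_radius_um
        + 6.0
    )


def _trunk_length(target_length: float, n_branches: int) -> float:
    return max(target_length, _LEAD_IN + n_branches * MIN_JUNCTION_GAP + _TAIL)


def _grow_tree(
    rng: np.random.Generator,
    attachment: np.ndarray,
    n_branches: int,
    target_length: float,
    tortuosity: float,
) -> GlandTree:
    """Grow one gland tree away from the lumen (the -x direction).

    The trunk is a jittered polyline steered to stay inside its y/z lane;
    each of the ``n_branches`` bifurcations hangs a terminal side branch
    off a trunk node, with the side direction alternating in y (plus a
    small z tilt) so sibling branches never collide.  Side branches are
    long enough to survive default spur pruning, and junctions are spaced
    so their skeleton clusters stay distinct.
    """
    trunk_len = _trunk_length(target_length, n_branches)
    step = 11.0
    n_steps = max(3, int(round(trunk_len / step)))
    step = trunk_len / n_steps

    base_dir = _unit(
        -_XHAT
        + rng.uniform(-0.06, 0.06) * _YHAT
        + rng.uniform(-0.04, 0.04) * _ZHAT
    )
    nodes: dict[int, np.ndarray] = {0: attachment.copy()}
    edges: list[tuple[int, int]] = []
    pos = attachment.copy()
    direction = base_dir.copy()
    trunk_ids = [0]
    for i in range(1, n_steps + 1):
        jitter = tortuosity * rng.normal(0.0, 0.22, size=3)
        direction = _unit(0.65 * direction + 0.35 * base_dir + jitter)
        # steer back toward the lane center when drifting too far
        for ax in (0, 1):  # z then y
            drift = (pos[ax] + step * direction[ax]) - attachment[ax]
            if abs(drift) > TRUNK_DRIFT_LIMIT:
                direction[ax] = -0.3 * np.sign(drift)
                direction = _unit(direction)
        pos = pos + step * direction
        nodes[i] = pos.copy()
        edges.append((trunk_ids[-1], i))
        trunk_ids.append(i)

    if n_branches:
        arc = np.array([np.linalg.norm(nodes[i] - attachment) for i in trunk_ids])
        lo, hi = _LEAD_IN, max(np.max(arc) - _TAIL, _LEAD_IN + 1.0)
        wanted = np.linspace(lo, hi, n_branches + 2)[1:-1] if n_branches > 1 else [
            0.5 * (lo + hi)
        ]
        next_id = n_steps + 1
        for j, s in enumerate(wanted):
            jid = trunk_ids[int(np.argmin(np.abs(arc - s)))]
            ysign = 1.0 if j % 2 == 0 else -1.0
            ztilt = rng.uniform(-BRANCH_Z_COMPONENT, BRANCH_Z_COMPONENT)
            side = _unit(
                -BRANCH_X_COMPONENT * _XHAT
                + ysign * BRANCH_Y_COMPONENT * _YHAT
                + ztilt * _ZHAT
            )
            blen = rng.uniform(*BRANCH_LEN_RANGE)
            mid = nodes[jid] + 0.5 * blen * side
            tip = nodes[jid] + blen * _unit(
                side + tortuosity * rng.normal(0.0, 0.12, size=3)
            )
            nodes[next_id] = mid
            nodes[next_id + 1] = tip
            edges.append((jid, next_id))
            edges.append((next_id, next_id + 1))
            next_id += 2

    tree = GlandTree(attachment_point_um=attachment.copy(), nodes=nodes, edges=edges)
    assert tree.true_branch_points == n_branches
    return tree


def _place_embryo(
    rng: np.random.Generator,
    center: np.ndarray,
    radius: float,
    angle_deg: float,
    mam_axis: np.ndarray,
) -> Embryo:
    theta = math.radians(angle_deg)
    # axis lies in the optical XY plane so the projection convention is exact
    axis = math.cos(theta) * mam_axis + math.sin(theta) * _YHAT
    axis = _unit(axis)
    icm_radius = 0.38 * radius
    icm_center = center + (radius - icm_radius) * axis
    ab_point = center - radius * axis
    return Embryo(
        center_um=center.astype(float),
        radius_um=float(radius),
        icm_point_um=icm_center,
        abembryonic_point_um=ab_point,
        icm_radius_um=icm_radius,
        mam_axis=mam_axis.copy(),
        true_angle_deg=float(angle_deg),
    )


def make_gland_scene(spec: SceneSpec) -> GroundTruthScene:
    """Build a ground-truth scene from a spec; identical seed, identical scene.

    Raises :class:`GeometryError` when the requested gland lengths cannot
    fit between the lumen and the volume wall.
    """
    rng = np.random.default_rng(spec.seed)
    extent = spec.extent_um
    spacing = np.array(spec.voxel_size_um)
    margin = spec.gland_radius_um + 2 * float(np.max(spacing))

    lumen_x = 0.80 * extent[2]
    n_cl = max(2, int(extent[1] // 40) + 1)
    ys = np.linspace(0.0, extent[1], n_cl)
    centerline = np.stack(
        [np.full(n_cl, extent[0] / 2.0), ys, np.full(n_cl, lumen_x)], axis=1
    )

    if spec.branch_counts is not None:
        counts = list(spec.branch_counts)
    elif spec.branch_count_distribution is not None:
        counts = [
            _sample_branch_count(rng, spec.branch_count_distribution)
            for _ in range(spec.n_glands)
        ]
    else:
        counts = [0] * spec.n_glands

    # room available for gland growth toward low x
    max_reach = lumen_x - spec.lumen_radius_um - margin
    lo, hi = spec.gland_length_range_um
    max_count = max(counts, default=0)
    needed = _trunk_length(hi, max_count) + BRANCH_LEN_RANGE[1] + TRUNK_DRIFT_LIMIT
    if spec.n_glands and needed > max_reach:
        raise GeometryError(
            f"glands reaching {needed:.0f} µm do not fit: only "
            f"{max_reach:.0f} µm between lumen and volume wall"
        )

    trees: list[GlandTree] = []
    if spec.n_glands:
        # lay glands out in y lanes, on up to two z layers for thick stacks
        half_width = _lane_half_width(spec.gland_radius_um)
        pitch = 2 * half_width
        z_layer_extent = 2 * (
            spec.gland_radius_um
            + BRANCH_Z_COMPONENT * BRANCH_LEN_RANGE[1]
            + TRUNK_DRIFT_LIMIT
        ) + 2 * spacing[0]
        n_layers = 2 if extent[0] >= 2 * z_layer_extent + 20.0 else 1
        per_layer = int((extent[1] - pitch) // pitch) + 1
        if spec.n_glands > per_layer * n_layers:
            raise GeometryError(
                f"{spec.n_glands} glands do not fit: capacity is "
                f"{per_layer * n_layers} for this volume"
            )
        if n_layers == 1:
            z_centers = [extent[0] / 2.0]
        else:
            z_centers = [0.30 * extent[0], 0.70 * extent[0]]
        slots = [
            (z_centers[layer], half_width + lane * pitch)
            for layer in range(n_layers)
            for lane in range(per_layer)
        ]
        for gi in range(spec.n_glands):
            zc, yc = slots[gi]
            attachment = np.array(
                [zc, yc + rng.uniform(-4.0, 4.0), lumen_x - spec.lumen_radius_um]
            )
            length = rng.uniform(lo, hi)
            trees.append(
                _grow_tree(rng, attachment, counts[gi], length, spec.tortuosity)
            )

    embryos: list[Embryo] = []
    if spec.embryo_axis_angle_deg is not None:
        center = np.array([extent[0] / 2.0, extent[1] / 2.0, lumen_x])
        radius = min(spec.embryo_radius_um, 0.9 * spec.lumen_radius_um)
        embryos.append(
            _place_embryo(rng, center, radius, spec.embryo_axis_angle_deg, MESOMETRIAL_AXIS)
        )

    scene = GroundTruthScene(
        spec=spec,
        lumen_centerline_um=centerline,
        lumen_radius_um=spec.lumen_radius_um,
        gland_trees=trees,
        embryos=embryos,
    )
    _attach_signal_truth(scene, rng)
    return scene


def make_embryo_scene(
    angle_deg: float | list[float],
    spec: SceneSpec,
) -> GroundTruthScene:
    """Scene containing one or more blastocysts at exact axis angles.

    The embryonic axis (ICM centroid minus abembryonic pole) makes exactly
    ``angle_deg`` with the stored mesometrial–antimesometrial unit vector
    under the in-plane projection convention of the geometry module.
    """
    angles = [angle_deg] if np.isscalar(angle_deg) else list(angle_deg)
    for a in angles:
        if not (0.0 <= float(a) <= 90.0):
            raise ValueError(f"axis angle {a} outside [0, 90]")
    rng = np.random.default_rng(spec.seed)
    extent = spec.extent_um
    radius = spec.embryo_radius_um
    if 2 * radius + 10 > min(extent):
        raise GeometryError("embryo does not fit inside the volume")
    n = len(angles)
    ys = np.linspace(0, extent[1], n + 2)[1:-1]
    embryos = [
        _place_embryo(
            rng,
            np.array([extent[0] / 2.0, y, extent[2] / 2.0]),
            radius,
            float(a),
            MESOMETRIAL_AXIS,
        )
        for a, y in zip(angles, ys)
    ]
    scene = GroundTruthScene(
        spec=spec,
        lumen_centerline_um=np.zeros((0, 3)),
        lumen_radius_um=spec.lumen_radius_um,
        gland_trees=[],
        embryos=embryos,
    )
    _attach_signal_truth(scene, rng)
    return scene


# ---------------------------------------------------------------------------
# signal truth (transcript puncta and marker-positive cells)


def _attach_signal_truth(scene: GroundTruthScene, rng: np.random.Generator) -> None:
    spec = scene.spec
    need_lif = spec.lif_volume_fraction > 0 and scene.gland_trees
    need_cells = scene.gland_trees and (
        spec.n_cells or spec.esr1_positive_fraction > 0
    )
    if not (need_lif or need_cells):
        scene.lif_voxels = np.zeros((0, 3), dtype=np.int64)
        return

    labels = rasterize_labels(scene).labels
    gland_mask = labels >= 2

    if need_lif:
        scene.lif_voxels = _pick_puncta_voxels(
            rng,
            gland_mask,
            spec.lif_volume_fraction,
            spec.voxel_size_um,
            punctum_radius_um=spec.lif_punctum_radius_um,
        )
    else:
        scene.lif_voxels = np.zeros((0, 3), dtype=np.int64)

    if need_cells:
        _place_cells(scene, rng)


def _pick_puncta_voxels(
    rng: np.random.Generator,
    gland_mask: np.ndarray,
    fraction: float,
    spacing,
    punctum_radius_um: float = 7.0,
) -> np.ndarray:
    """Choose gland voxels as clustered signal blobs with an exact count.

    Blobs are stamped as balls (clipped to the gland mask) until
    ``round(fraction * |gland|)`` voxels are marked; the last blob is
    trimmed deterministically so the voxel count is exact.  The default
    blob size models the coherent clusters that strong glandular
    transcript expression forms, rather than single-molecule dots.
    """
    coords = np.argwhere(gland_mask)
    n_total = len(coords)
    target = int(round(fraction * n_total))
    if target == 0:
        return np.zeros((0, 3), dtype=np.int64)
    spacing = np.asarray(spacing, float)
    chosen = np.zeros_like(gland_mask)
    n_chosen = 0
    # precompute punctum offsets in voxel units
    r_vox = np.maximum(punctum_radius_um / spacing, 0.0)
    ranges = [np.arange(-int(np.floor(r)), int(np.floor(r)) + 1) for r in r_vox]
    zz, yy, xx = np.meshgrid(*ranges, indexing="ij")
    inside = (
        (zz * spacing[0]) ** 2 + (yy * spacing[1]) ** 2 + (xx * spacing[2]) ** 2
    ) <= punctum_radius_um**2
    offsets = np.stack([zz[inside], yy[inside], xx[inside]], axis=1)
    shape = np.array(gland_mask.shape)
    order = rng.permutation(n_total)
    for idx in order:
        if n_chosen >= target:
            break
        seed_vox = coords[idx]
        pts = seed_vox + offsets
        ok = np.all((pts >= 0) & (pts < shape), axis=1)
        pts = pts[ok]
        sel = gland_mask[pts[:, 0], pts[:, 1], pts[:, 2]] & ~chosen[
            pts[:, 0], pts[:, 1], pts[:, 2]
        ]
        pts = pts[sel]
        if not len(pts):
            continue
        room = target - n_chosen
        if len(pts) > room:
            pts = pts[:room]
        chosen[pts[:, 0], pts[:, 1], pts[:, 2]] = True
        n_chosen += len(pts)
    return np.argwhere(chosen).astype(np.int64)


def _place_cells(scene: GroundTruthScene, rng: np.random.Generator) -> None:
    """Seed gland epithelial cell nuclei along the tree polylines.

    Cells sit in rings around the tube axis (epithelium lines the gland
    wall), several per cross-section, spaced so nuclei barely touch.
    """
    spec = scene.spec
    ring_radius = max(spec.gland_radius_um - 2.8, 0.0)
    n_ring = 6
    stations: list[np.ndarray] = []
    for tree in scene.gland_trees:
        for seg in tree.polylines():
            a, b = seg
            length = np.linalg.norm(b - a)
            n = max(1, int(length // 5.0))
            axis = _unit(b - a)
            ref = _ZHAT if abs(axis @ _ZHAT) < 0.9 else _YHAT
            u = _unit(np.cross(axis, ref))
            w = np.cross(axis, u)
            for t in np.linspace(0.1, 0.9, n):
                center = a + t * (b - a)
                phase = rng.uniform(0, 2 * math.pi)
                for j in range(n_ring):
                    ang = phase + 2 * math.pi * j / n_ring
                    stations.append(
                        center + ring_radius * (math.cos(ang) * u + math.sin(ang) * w)
                    )
    if spec.n_cells is not None:
        if spec.n_cells > len(stations):
            raise GeometryError(
                f"cannot place {spec.n_cells} cells on {len(stations)} stations;"
                " use more or longer glands"
            )
        keep = rng.choice(len(stations), size=spec.n_cells, replace=False)
        stations = [stations[i] for i in sorted(keep)]
    n = len(stations)
    n_pos = int(round(spec.esr1_positive_fraction * n))
    pos_ids = set(rng.choice(n, size=n_pos, replace=False).tolist()) if n_pos else set()
    scene.cells = [
        {
            "cell_id": i,
            "center_um": stations[i],
            "radius_um": 2.6,
            "positive": i in pos_ids,
        }
        for i in range(n)
    ]
    scene.positive_cell_ids = frozenset(int(i) for i in pos_ids)


def rasterize_cell_labels(scene: GroundTruthScene) -> LabelMask:
    """Nuclei instance labels: cell_id + 1 per nucleus ball."""
    spec = scene.spec
    labels = np.zeros(spec.volume_shape_voxels, dtype=np.int32)
    for cell in scene.cells:
        _paint_ball(
            labels, cell["cell_id"] + 1, cell["center_um"], cell["radius_um"], spec.voxel_size_um
        )
    table = {c["cell_id"] + 1: "other" for c in scene.cells}
    return LabelMask(labels=labels, voxel_size_um=spec.voxel_size_um, label_table=table)


# ---------------------------------------------------------------------------
# rendering


def _noiseless_channel(scene: GroundTruthScene, role: str) -> np.ndarray:
    spec = scene.spec
    shape = spec.volume_shape_voxels
    spacing = spec.voxel_size_um
    img = np.zeros(shape, dtype=float)
    if role == "gland_marker":
        for tree in scene.gland_trees:
            for seg in tree.polylines():
                _paint_capsule(img, 1.0, seg[0], seg[1], spec.gland_radius_um, spacing)
    elif role == "epithelium":
        for tree in scene.gland_trees:
            for seg in tree.polylines():
                _paint_capsule(img, 1.0, seg[0], seg[1], spec.gland_radius_um, spacing)
        cl = scene.lumen_centerline_um
        for a, b in zip(cl[:-1], cl[1:]):
            _paint_capsule(img, 1.0, a, b, scene.lumen_radius_um, spacing)
    elif role == "nuclei":
        for cell in scene.cells:
            _paint_ball(img, 0.8, cell["center_um"], cell["radius_um"], spacing)
        for emb in scene.embryos:
            _paint_ball(img, 0.45, emb.center_um, emb.radius_um, spacing)
            icm_center = emb.icm_point_um
            _paint_ball(img, 1.0, icm_center, emb.icm_radius_um, spacing)
    elif role == "lif":
        if scene.lif_voxels is not None and len(scene.lif_voxels):
            v = scene.lif_voxels
            img[v[:, 0], v[:, 1], v[:, 2]] = 1.0
    elif role == "vasculature":
        pass  # no vessels in the phantom; channel renders as background
    else:
        raise ValueError(
            f"unknown channel role {role!r}; expected one of {CHANNEL_ROLES}"
        )
    return img


def render_volume(
    scene: GroundTruthScene,
    imaging: ImagingParams,
    channels: list[str],
    noise_seed: int | None = None,
) -> VolumeImage:
    """Render the scene into a noisy multi-channel volume.

    Each channel is the binary rasterization scaled by ``amplitude``, then
    PSF-blurred, offset by the background, Poisson-resampled, and finally
    perturbed with Gaussian read noise.  The ground truth is untouched.
    """
    for role in channels:
        if role not in CHANNEL_ROLES:
            raise ValueError(
                f"unknown channel role {role!r}; expected one of {CHANNEL_ROLES}"
            )
    spec = scene.spec
    spacing = np.array(spec.voxel_size_um)
    seed = spec.seed + 7919 if noise_seed is None else noise_seed
    rng = np.random.default_rng(seed)
    sigma_vox = np.array(imaging.psf_sigma_um) / spacing
    out = []
    for role in channels:
        img = _noiseless_channel(scene, role) * imaging.amplitude
        if np.any(sigma_vox > 0):
            img = ndimage.gaussian_filter(img, sigma=sigma_vox)
        img = img + imaging.background_level
        if imaging.poisson_gain > 0:
            img = rng.poisson(img * imaging.poisson_gain) / imaging.poisson_gain
        if imaging.gaussian_sd > 0:
            img = img + rng.normal(0.0, imaging.gaussian_sd, size=img.shape)
        hi = 2**imaging.bit_depth - 1
        img = np.clip(np.rint(img), 0, hi)
        out.append(img.astype(np.uint8 if imaging.bit_depth == 8 else np.uint16))
    data = np.stack(out) if len(out) > 1 else out[0]
    names = list(channels)
    return VolumeImage(data=data, voxel_size_um=tuple(spacing), channel_names=names)


def render_cell_marker(
    scene: GroundTruthScene,
    imaging: ImagingParams,
    positive_level: float = 1.0,
    negative_level: float = 0.15,
    noise_seed: int | None = None,
) -> np.ndarray:
    """Render a nuclear marker channel whose intensity encodes positivity.

    Used to emulate receptor immunostaining: marker-positive cells render
    at ``positive_level`` × amplitude, negative cells at ``negative_level``.
    """
    spec = scene.spec
    spacing = np.array(spec.voxel_size_um)
    img = np.zeros(spec.volume_shape_voxels, dtype=float)
    for cell in scene.cells:
        level = positive_level if cell["positive"] else negative_level
        _paint_ball(img, level, cell["center_um"], cell["radius_um"], spacing)
    img = img * imaging.amplitude
    sigma_vox = np.array(imaging.psf_sigma_um) / spacing
    if np.any(sigma_vox > 0):
        img = ndimage.gaussian_filter(img, sigma=sigma_vox)
    img = img + imaging.background_level
    seed = spec.seed + 104729 if noise_seed is None else noise_seed
    rng = np.random.default_rng(seed)
    if imaging.poisson_gain > 0:
        img = rng.poisson(img * imaging.poisson_gain) / imaging.poisson_gain
    if imaging.gaussian_sd > 0:
        img = img + rng.normal(0.0, imaging.gaussian_sd, size=img.shape)
    return np.clip(img, 0, 2**imaging.bit_depth - 1)
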