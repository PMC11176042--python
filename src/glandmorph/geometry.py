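"""Embryo–uterine axis alignment geometry.

The embryonic axis runs from the abembryonic (mural trophectoderm) pole to
the inner cell mass (ICM); proper implantation orients the ICM toward the
mesometrial pole.  The alignment angle is measured against the
mesometrial–antimesometrial (M-AM) axis after projecting the embryonic
axis onto the plane spanned by the M-AM axis and the axis's in-plane (XY,
i.e. constant-z optical section) component — mirroring a three-point
measurement placed on the M-AM plane — and folding the unsigned angle into
[0, 90] degrees.  The M-AM axis is an explicit input.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import VolumeImage
from .segmentation import STRUCT_26
from .synthetic import GroundTruthScene

__all__ = ["AxisMeasurement", "compute_axis_angle", "measure_embryos"]

log = logging.getLogger(__name__)

_ZHAT = np.array([1.0, 0.0, 0.0])


@dataclass
class AxisMeasurement:
    """One embryo's ICM point, abembryonic point, and alignment angle."""

    embryo_id: int
    icm_point_um: np.ndarray
    abembryonic_point_um: np.ndarray
    mam_axis: np.ndarray
    angle_deg: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.angle_deg <= 90.0):
            raise ValueError("angle must lie in [0, 90] degrees")

    def as_row(self) -> dict:
        iz, iy, ix = (float(v) for v in self.icm_point_um)
        az, ay, ax = (float(v) for v in self.abembryonic_point_um)
        return {
            "embryo_id": self.embryo_id,
            "icm_z_um": iz,
            "icm_y_um": iy,
            "icm_x_um": ix,
            "abembryonic_z_um": az,
            "abembryonic_y_um": ay,
            "abembryonic_x_um": ax,
            "angle_deg": self.angle_deg,
        }


def compute_axis_angle(
    icm_point: np.ndarray,
    abembryonic_point: np.ndarray,
    mam_axis: np.ndarray,
) -> float:
    """Alignment angle (degrees, folded into [0, 90]) of the embryonic axis.

    The embryonic axis ``v = icm - abembryonic`` is projected onto the
    plane spanned by the M-AM axis and v's in-plane (constant-z) component;
    the unsigned angle between the projection and the M-AM axis is
    returned.  0° means the ICM faces exactly mesometrially; 90° means the
    axis is perpendicular to the M-AM axis.
    """
    icm = np.asarray(icm_point, float)
    ab = np.asarray(abembryonic_point, float)
    m = np.asarray(mam_axis, float)
    if np.allclose(icm, ab):
        raise ValueError("ICM and abembryonic points coincide")
    if np.allclose(m, 0):
        raise ValueError("M-AM axis must be nonzero")
    v = icm - ab
    e1 = m / np.linalg.norm(m)
    v_inplane = v - (v @ _ZHAT) * _ZHAT
    e2 = v_inplane - (v_inplane @ e1) * e1
    n2 = np.linalg.norm(e2)
    if n2 < 1e-12:
        # the axis's in-plane component is parallel to the M-AM axis (or
        # absent): the projected axis is either along M-AM (angle 0) or the
        # axis points out of plane entirely (perpendicular to M-AM)
        c1 = v @ e1
        if abs(c1) < 1e-12:
            return 90.0
        vp = np.array([c1, 0.0])
    else:
        e2 = e2 / n2
        vp = np.array([v @ e1, v @ e2])
    norm = np.linalg.norm(vp)
    if norm == 0:
        return 90.0
    cosang = min(1.0, abs(vp[0]) / norm)
    return math.degrees(math.acos(cosang))


def _measure_from_scene(scene: GroundTruthScene) -> list[AxisMeasurement]:
    out = []
    for i, emb in enumerate(scene.embryos):
        out.append(
            AxisMeasurement(
                embryo_id=i,
                icm_point_um=np.asarray(emb.icm_point_um, float),
                abembryonic_point_um=np.asarray(emb.abembryonic_point_um, float),
                mam_axis=np.asarray(emb.mam_axis, float),
                angle_deg=compute_axis_angle(
                    emb.icm_point_um, emb.abembryonic_point_um, emb.mam_axis
                ),
            )
        )
    return out


def measure_embryos(
    source: VolumeImage | GroundTruthScene,
    mam_axis: np.ndarray | None = None,
    nuclei_channel: str = "nuclei",
    min_embryo_voxels: int = 200,
) -> list[AxisMeasurement]:
    """Locate embryos and measure their axis alignment.

    For a ground-truth scene the stored points are used directly.  For a
    volume, each embryo is a large bright cluster in the nuclei channel;
    the ICM is the intensity-dense sub-cluster (intensity-weighted centroid
    of the brightest voxels), and the abembryonic pole is the cluster
    boundary point antipodal to the ICM through the cluster centroid.
    Returns an empty list (with a log entry) when no embryo is found.
    """
    if isinstance(source, GroundTruthScene):
        return _measure_from_scene(source)

    if mam_axis is None:
        raise ValueError("mam_axis is required when measuring from a volume")
    m = np.asarray(mam_axis, float)
    img = source.channel(nuclei_channel).astype(float)
    spacing = np.asarray(source.voxel_size_um, float)
    if np.ptp(img) == 0:
        log.info("nuclei channel is constant; no embryos found")
        return []
    from skimage.filters import threshold_otsu

    t = threshold_otsu(img)
    fg = img > t
    labels, n = ndimage.label(fg, structure=STRUCT_26)
    measurements: list[AxisMeasurement] = []
    eid = 0
    for lab in range(1, n + 1):
        mask = labels == lab
        if int(mask.sum()) < min_embryo_voxels:
            continue
        vox = np.argwhere(mask)
        pts = vox * spacing
        centroid = pts.mean(axis=0)
        # ICM: the bright sub-cluster, split off by a second Otsu within the
        # embryo; its intensity-weighted centroid marks the embryonic pole
        vals = img[mask]
        hi = threshold_otsu(vals)
        icm_sel = vals > hi
        if not icm_sel.any():
            log.warning("embryo %d has no distinct ICM; skipped", lab)
            continue
        w = vals[icm_sel]
        icm = (pts[icm_sel] * w[:, None]).sum(axis=0) / w.sum()
        u = centroid - icm
        nu = np.linalg.norm(u)
        if nu < 1e-9:
            log.warning("embryo %d has no distinct ICM; skipped", lab)
            continue
        u = u / nu
        # march from the centroid along u to the far boundary of the mask
        step = float(np.min(spacing)) / 2.0
        p = centroid.copy()
        last_inside = centroid.copy()
        for _ in range(10000):
            p = p + step * u
            idx = np.rint(p / spacing).astype(int)
            if np.any(idx < 0) or np.any(idx >= mask.shape) or not mask[tuple(idx)]:
                break
            last_inside = p.copy()
        ab_point = last_inside
        measurements.append(
            AxisMeasurement(
                embryo_id=eid,
                icm_point_um=icm,
                abembryonic_point_um=ab_point,
                mam_axis=m,
                angle_deg=compute_axis_angle(icm, ab_point, m),
            )
        )
        eid += 1
    if not measurements:
        log.info("no embryo-sized clusters in the nuclei channel")
    return measurements
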