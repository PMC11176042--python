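"""Matching of segmented glands against generator ground truth.

Used by recovery tests and the acceptance script: segmented gland objects
are matched one-to-one to ground-truth gland labels by intersection over
union, and branch counts / chord lengths are compared per matched gland.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import segmentation as _seg
from . import skeleton as _skel
from . import synthetic as _syn
from .segmentation import GlandObject
from .skeleton import MorphometryRecord
from .synthetic import GroundTruthScene, rasterize_labels

__all__ = ["match_glands", "recovery_table", "run_recovery_experiment"]


def match_glands(
    glands: list[GlandObject],
    truth_labels: np.ndarray,
    iou_threshold: float = 0.5,
) -> dict[int, tuple[GlandObject, float]]:
    """One-to-one matching of segmented glands to truth labels by IoU.

    ``truth_labels`` holds gland labels >= 2 (label 1 is the lumen).
    Candidate pairs with IoU >= ``iou_threshold`` are assigned greedily in
    decreasing IoU; returns ``{truth_label: (gland, iou)}``.
    """
    truth_labels = np.asarray(truth_labels)
    truth_sizes = {
        int(lab): int((truth_labels == lab).sum())
        for lab in np.unique(truth_labels)
        if lab >= 2
    }
    candidates = []
    for g in glands:
        at_voxels = truth_labels[g.voxels[:, 0], g.voxels[:, 1], g.voxels[:, 2]]
        labs, counts = np.unique(at_voxels[at_voxels >= 2], return_counts=True)
        for lab, inter in zip(labs, counts):
            union = g.n_voxels + truth_sizes[int(lab)] - int(inter)
            iou = inter / union
            if iou >= iou_threshold:
                candidates.append((float(iou), int(lab), g))
    candidates.sort(key=lambda c: -c[0])
    matched: dict[int, tuple[GlandObject, float]] = {}
    used_glands: set[int] = set()
    for iou, lab, g in candidates:
        if lab in matched or id(g) in used_glands:
            continue
        matched[lab] = (g, iou)
        used_glands.add(id(g))
    return matched


def recovery_table(
    scene: GroundTruthScene,
    glands: list[GlandObject],
    records: list[MorphometryRecord],
    iou_threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-truth-gland comparison of measured vs true branch count and length.

    Unmatched truth glands appear with NaN measurements so recovery rates
    can be computed over the full ground truth.
    """
    truth = rasterize_labels(scene).labels
    matched = match_glands(glands, truth, iou_threshold)
    rec_by_label = {r.gland_label: r for r in records}
    rows = []
    for gi, tree in enumerate(scene.gland_trees):
        lab = 2 + gi
        row = {
            "truth_label": lab,
            "true_branch_points": tree.true_branch_points,
            "true_length_um": tree.true_length_um,
            "matched": lab in matched,
            "iou": np.nan,
            "measured_branch_points": np.nan,
            "measured_length_um": np.nan,
        }
        if lab in matched:
            g, iou = matched[lab]
            row["iou"] = iou
            rec = rec_by_label.get(g.label)
            if rec is not None:
                row["measured_branch_points"] = rec.n_branch_points
                row["measured_length_um"] = rec.length_um
        rows.append(row)
    return pd.DataFrame(rows)


def run_recovery_experiment(
    spec: _syn.SceneSpec,
    imaging: _syn.ImagingParams | None = None,
    threshold: str = "otsu",
    sphere_diameter_um: float | None = 30.0,
    min_spur_length_um: float | None = None,
) -> pd.DataFrame:
    """Generate a scene, run the full segmentation + morphometry pipeline on
    its rendered gland-marker channel, and return the per-gland recovery
    table (true vs measured branch counts and lengths).
    """
    imaging = imaging or _syn.ImagingParams()
    scene = _syn.make_gland_scene(spec)
    truth = rasterize_labels(scene)
    vol = _syn.render_volume(scene, imaging, ["gland_marker"])
    img = vol.data.astype(np.float32)
    if sphere_diameter_um:
        img = _seg.subtract_background(img, sphere_diameter_um, spec.voxel_size_um)
    mask = _seg.fill_holes_3d(_seg.binarize(img, threshold))
    glands = _seg.separate_glands(mask, truth.labels == 1, spec.voxel_size_um)
    records = [
        _skel.measure_gland(
            g, mask.shape, spec.voxel_size_um, min_spur_length_um=min_spur_length_um
        )
        for g in glands
    ]
    return recovery_table(scene, glands, records)
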