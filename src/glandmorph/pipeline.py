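"""End-to-end pipeline: simulate, segment, skeletonize, quantify, report.

Drives the library modules from a single configuration mapping so a fixed
config + seed always produces byte-identical CSV outputs.  This is the
engine behind the ``pipeline`` CLI subcommand.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry, segmentation, signal, skeleton, synthetic
from .io import LabelMask, VolumeImage, write_mask, write_report, write_volume

__all__ = ["scene_from_config", "imaging_from_config", "simulate", "run_pipeline"]

_PRESETS = {
    "whole_mount": synthetic.WHOLE_MOUNT_SPACING,
    "section": synthetic.SECTION_SPACING,
}


def scene_from_config(cfg: dict, seed: int | None = None) -> synthetic.GroundTruthScene:
    sc = dict(cfg.get("scene", {}))
    kind = sc.pop("kind", "glands")
    preset = sc.pop("voxel_preset", None)
    if preset:
        sc["voxel_size_um"] = _PRESETS[preset]
    angles = sc.pop("embryo_angles_deg", None)
    if seed is not None:
        sc["seed"] = int(seed)
    spec = synthetic.SceneSpec(**sc)
    if kind == "embryos":
        if angles is None:
            angles = [spec.embryo_axis_angle_deg or 0.0]
        return synthetic.make_embryo_scene(angles, spec)
    if kind != "glands":
        raise ValueError(f"unknown scene kind {kind!r}")
    return synthetic.make_gland_scene(spec)


def imaging_from_config(cfg: dict) -> synthetic.ImagingParams:
    im = dict(cfg.get("imaging", {}))
    if im.pop("noiseless", False):
        return synthetic.ImagingParams.noiseless(
            **{k: v for k, v in im.items() if k in ("amplitude", "bit_depth")}
        )
    return synthetic.ImagingParams(**im)


def _truth_tables(scene: synthetic.GroundTruthScene) -> tuple[pd.DataFrame, pd.DataFrame]:
    gland_rows, edge_rows = [], []
    for gi, tree in enumerate(scene.gland_trees):
        az, ay, ax = (float(v) for v in tree.attachment_point_um)
        gland_rows.append(
            {
                "truth_label": 2 + gi,
                "true_branch_points": tree.true_branch_points,
                "true_length_um": tree.true_length_um,
                "branch_category": tree.category,
                "attachment_z_um": az,
                "attachment_y_um": ay,
                "attachment_x_um": ax,
            }
        )
        for a, b in tree.edges:
            pa, pb = tree.nodes[a], tree.nodes[b]
            edge_rows.append(
                {
                    "truth_label": 2 + gi,
                    "node_a": a,
                    "node_b": b,
                    "az_um": float(pa[0]),
                    "ay_um": float(pa[1]),
                    "ax_um": float(pa[2]),
                    "bz_um": float(pb[0]),
                    "by_um": float(pb[1]),
                    "bx_um": float(pb[2]),
                    "length_um": float(np.linalg.norm(pb - pa)),
                }
            )
    return pd.DataFrame(gland_rows), pd.DataFrame(edge_rows)


def simulate(cfg: dict, out_dir: str | Path, seed: int | None = None) -> dict:
    """Generate a scene, render it, and write volume + ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scene = scene_from_config(cfg, seed)
    imaging = imaging_from_config(cfg)
    channels = list(cfg.get("channels", ["gland_marker", "nuclei"]))
    vol = synthetic.render_volume(scene, imaging, channels)
    write_volume(vol, out / "volume.ome.tif")
    truth = synthetic.rasterize_labels(scene)
    write_mask(truth, out / "truth_labels.ome.tif")
    glands_df, edges_df = _truth_tables(scene)
    if len(glands_df):
        write_report(glands_df, out / "truth_glands.csv", config=cfg, seed=scene.spec.seed)
        write_report(edges_df, out / "truth_edges.csv", config=cfg, seed=scene.spec.seed)
    if scene.embryos:
        emb_df = pd.DataFrame(
            [
                {
                    "embryo_id": i,
                    "true_angle_deg": e.true_angle_deg,
                    "icm_z_um": float(e.icm_point_um[0]),
                    "icm_y_um": float(e.icm_point_um[1]),
                    "icm_x_um": float(e.icm_point_um[2]),
                    "ab_z_um": float(e.abembryonic_point_um[0]),
                    "ab_y_um": float(e.abembryonic_point_um[1]),
                    "ab_x_um": float(e.abembryonic_point_um[2]),
                }
                for i, e in enumerate(scene.embryos)
            ]
        )
        write_report(emb_df, out / "truth_embryos.csv", config=cfg, seed=scene.spec.seed)
    return {"scene": scene, "volume": vol, "truth": truth, "out": out}


def run_pipeline(cfg: dict, out_dir: str | Path, seed: int | None = None) -> dict:
    """Simulate, then run every analysis stage; returns key results.

    Writes ``morphometry.csv``, ``branch_categories.csv``, and (when the
    scene contains them) ``axis_measurements.csv`` and ``signal_quant.csv``
    under ``out_dir``.
    """
    out = Path(out_dir)
    sim = simulate(cfg, out, seed)
    scene: synthetic.GroundTruthScene = sim["scene"]
    vol: VolumeImage = sim["volume"]
    truth: LabelMask = sim["truth"]
    spacing = vol.voxel_size_um
    seg_cfg = dict(cfg.get("segmentation", {}))
    sk_cfg = dict(cfg.get("skeleton", {}))
    sample_id = str(cfg.get("sample_id", "sample"))
    results: dict = {"out": out}

    if scene.gland_trees:
        marker = vol.channel("gland_marker").astype(np.float32)
        sphere = seg_cfg.get("sphere_diameter_um", 30.0)
        if sphere:
            marker = segmentation.subtract_background(marker, sphere, spacing)
        mask = segmentation.binarize(marker, seg_cfg.get("threshold", "otsu"))
        mask = segmentation.fill_holes_3d(mask)
        lumen = truth.labels == 1
        glands = segmentation.separate_glands(
            mask,
            lumen,
            spacing,
            min_volume_voxels=int(seg_cfg.get("min_volume_voxels", 50)),
        )
        results["glands"] = glands
        seg_mask = segmentation.glands_to_label_mask(glands, mask.shape, spacing)
        write_mask(seg_mask, out / "gland_labels.ome.tif")
        records = [
            skeleton.measure_gland(
                g,
                mask.shape,
                spacing,
                sample_id=sample_id,
                min_spur_length_um=sk_cfg.get("min_spur_length_um"),
            )
            for g in glands
        ]
        results["records"] = records
        if records:
            write_report(records, out / "morphometry.csv", config=cfg, seed=seed)
            cats = skeleton.branch_category_table(records)
            write_report(cats, out / "branch_categories.csv", config=cfg, seed=seed)
            results["categories"] = cats

        if scene.spec.lif_volume_fraction > 0 and glands:
            region = np.zeros(mask.shape, dtype=bool)
            for g in glands:
                region[g.voxels[:, 0], g.voxels[:, 1], g.voxels[:, 2]] = True
            quant = signal.quantify_signal_in_region(
                vol.channel("lif").astype(float),
                region,
                spacing,
                threshold_method=cfg.get("signal", {}).get("threshold", "otsu"),
                region_label="gland",
                sample_id=sample_id,
            )
            results["signal"] = quant
            write_report([quant], out / "signal_quant.csv", config=cfg, seed=seed)

    if scene.embryos:
        mam = scene.mam_axis
        measurements = geometry.measure_embryos(vol, mam_axis=mam)
        results["axis"] = measurements
        if measurements:
            write_report(measurements, out / "axis_measurements.csv", config=cfg, seed=seed)

    return results
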