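"""Volume, mask, and table I/O with run provenance.

Conventions used throughout the package:

* voxel indices are 0-based in ``(z, y, x)`` order;
* physical coordinates are ``index * voxel_size_um`` at voxel centers,
  also ``(z, y, x)`` and in micrometres;
* multi-channel volumes carry the channel axis first, ``(C, Z, Y, X)``;
* channel roles are resolved by name, never by position.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "VolumeImage",
    "LabelMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "write_report",
    "load_config",
    "config_hash",
]

CHANNEL_ROLES = ("nuclei", "gland_marker", "epithelium", "lif", "vasculature")


@dataclass
class VolumeImage:
    """A 3D (or multi-channel 4D) intensity grid with anisotropic voxel spacing.

    ``data`` is ``(Z, Y, X)`` or ``(C, Z, Y, X)``; ``voxel_size_um`` is the
    physical spacing ``(z, y, x)`` in micrometres.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float]
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError(
                f"volume must be 3D (ZYX) or 4D (CZYX), got {self.data.ndim}D"
            )
        vs = tuple(float(v) for v in self.voxel_size_um)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size_um must be 3 positive reals, got {vs}")
        self.voxel_size_um = vs
        if self.data.ndim == 4:
            if not self.channel_names:
                self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]
            if len(self.channel_names) != self.data.shape[0]:
                raise ValueError(
                    f"{len(self.channel_names)} channel names for "
                    f"{self.data.shape[0]} channels"
                )
        elif self.channel_names and len(self.channel_names) != 1:
            raise ValueError("3D volume admits at most one channel name")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("volume intensities must be finite")

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[-3:])

    @property
    def voxel_volume_um3(self) -> float:
        z, y, x = self.voxel_size_um
        return z * y * x

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as a 3D array, selected by name."""
        if self.data.ndim == 3:
            if not self.channel_names or self.channel_names[0] == name:
                return self.data
            raise KeyError(f"channel {name!r} not present")
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.data[idx]


@dataclass
class LabelMask:
    """Integer label grid aligned with a volume; 0 is background.

    ``label_table`` maps each nonzero label to a compartment tag from
    ``{lumen, gland, embryo, other}``.
    """

    labels: np.ndarray
    voxel_size_um: tuple[float, float, float]
    label_table: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label mask must be 3D (ZYX)")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)

    def compartment_mask(self, compartment: str) -> np.ndarray:
        labels = [l for l, c in self.label_table.items() if c == compartment]
        return np.isin(self.labels, labels)


def _ome_voxel_size(path: Path) -> tuple[float, float, float] | None:
    with tifffile.TiffFile(path) as tf:
        if tf.ome_metadata:
            import xml.etree.ElementTree as ET

            root = ET.fromstring(tf.ome_metadata)
            ns = {"ome": root.tag.split("}")[0].strip("{")}
            px = root.find(".//ome:Pixels", ns)
            if px is not None:
                z = px.get("PhysicalSizeZ")
                y = px.get("PhysicalSizeY")
                x = px.get("PhysicalSizeX")
                if z and y and x:
                    return (float(z), float(y), float(x))
    return None


def read_volume(
    path: str | Path,
    voxel_size_um: tuple[float, float, float] | None = None,
    channel_names: list[str] | None = None,
) -> VolumeImage:
    """Read a TIFF/OME-TIFF volume, normalising axes to (C)ZYX.

    Voxel spacing is taken from OME metadata when present, else from the
    ``voxel_size_um`` override; if both are missing an error is raised.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        raise ValueError(f"{path} is 2D; a z-stack is required")
    if data.ndim not in (3, 4):
        raise ValueError(f"{path}: unsupported dimensionality {data.ndim}")
    meta_vs = _ome_voxel_size(path)
    vs = meta_vs or voxel_size_um
    if vs is None:
        raise ValueError(
            f"{path}: no voxel spacing in metadata and no override given"
        )
    names = channel_names
    if names is None and data.ndim == 4:
        with tifffile.TiffFile(path) as tf:
            if tf.ome_metadata:
                import xml.etree.ElementTree as ET

                root = ET.fromstring(tf.ome_metadata)
                ns = {"ome": root.tag.split("}")[0].strip("{")}
                found = [
                    ch.get("Name")
                    for ch in root.findall(".//ome:Channel", ns)
                    if ch.get("Name")
                ]
                if len(found) == data.shape[0]:
                    names = found
    return VolumeImage(data=data, voxel_size_um=tuple(vs), channel_names=names or [])


def write_volume(vol: VolumeImage, path: str | Path) -> Path:
    """Write a volume as OME-TIFF (ZCYX on disk) with voxel size metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    z, y, x = vol.voxel_size_um
    metadata = {
        "axes": "CZYX" if vol.data.ndim == 4 else "ZYX",
        "PhysicalSizeZ": z,
        "PhysicalSizeY": y,
        "PhysicalSizeX": x,
        "PhysicalSizeZUnit": "µm",
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeXUnit": "µm",
    }
    if vol.channel_names:
        metadata["Channel"] = {"Name": list(vol.channel_names)}
    tifffile.imwrite(path, vol.data, ome=True, photometric="minisblack", metadata=metadata)
    return path


def write_mask(mask: LabelMask, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    z, y, x = mask.voxel_size_um
    tifffile.imwrite(
        path,
        mask.labels.astype(np.uint16 if mask.labels.max() < 2**16 else np.uint32),
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "ZYX",
            "PhysicalSizeZ": z,
            "PhysicalSizeY": y,
            "PhysicalSizeX": x,
        },
    )
    sidecar = path.with_suffix(".labels.json")
    sidecar.write_text(
        json.dumps({str(k): v for k, v in sorted(mask.label_table.items())}, indent=1)
    )
    return path


def read_mask(path: str | Path) -> LabelMask:
    path = Path(path)
    labels = tifffile.imread(path)
    vs = _ome_voxel_size(path)
    if vs is None:
        raise ValueError(f"{path}: mask is missing voxel spacing metadata")
    table: dict[int, str] = {}
    sidecar = path.with_suffix(".labels.json")
    if sidecar.exists():
        table = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    return LabelMask(labels=np.asarray(labels).astype(np.int64), voxel_size_um=vs, label_table=table)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping, for provenance."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def write_report(
    records,
    path: str | Path,
    config: dict | None = None,
    seed: int | None = None,
) -> Path:
    """Write records to CSV with a JSON provenance sidecar.

    The CSV column order is stable and floats are formatted explicitly so
    that identical records always produce byte-identical files.  The sidecar
    carries the config hash, the seed, and the package version.
    """
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        records = list(records)
        if not records:
            raise ValueError("refusing to write an empty report")
        rows = []
        for r in records:
            if hasattr(r, "as_row"):
                rows.append(r.as_row())
            elif isinstance(r, dict):
                rows.append(r)
            else:
                rows.append(vars(r))
        df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("refusing to write an empty report")
    df.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    prov = {
        "software": "glandmorph",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
        "n_records": int(len(df)),
    }
    sidecar.write_text(json.dumps(prov, indent=1, sort_keys=True) + "\n")
    return path
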