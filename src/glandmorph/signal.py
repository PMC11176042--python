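"""Transcript-signal and marker-positivity quantification.

Punctate transcript signal (e.g. in-situ hybridization dots) is treated
volumetrically: the thresholded signal volume inside a compartment mask is
divided by the compartment volume, giving a unitless "signal per region
volume" ratio with the raw volumes retained.  Marker positivity (e.g.
receptor immunostaining) is called per nucleus from the mean marker
intensity inside each labeled cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .io import LabelMask, VolumeImage

__all__ = ["SignalQuant", "CellFraction", "quantify_signal_in_region", "positive_cell_fraction"]


@dataclass
class SignalQuant:
    """Thresholded signal volume inside one region, and their ratio."""

    region_label: str
    region_volume_um3: float
    signal_volume_um3: float
    ratio: float
    threshold: float
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        if self.region_volume_um3 <= 0:
            raise ValueError("region volume must be positive")
        if not (0.0 <= self.signal_volume_um3 <= self.region_volume_um3 + 1e-9):
            raise ValueError("signal volume must lie within the region volume")

    def as_row(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "region_label": self.region_label,
            "region_volume_um3": self.region_volume_um3,
            "signal_volume_um3": self.signal_volume_um3,
            "ratio": self.ratio,
            "threshold": self.threshold,
        }


@dataclass
class CellFraction:
    """Marker-positive cell counts within a compartment."""

    n_positive: int
    n_total: int
    compartment: str = "gland"

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if not (0 <= self.n_positive <= self.n_total):
            raise ValueError("0 <= n_positive <= n_total required")

    @property
    def fraction(self) -> float:
        return self.n_positive / self.n_total

    def as_row(self) -> dict:
        return {
            "compartment": self.compartment,
            "n_positive": self.n_positive,
            "n_total": self.n_total,
            "fraction": self.fraction,
        }


def _resolve_threshold(values: np.ndarray, threshold_method) -> float:
    if isinstance(threshold_method, (int, float)):
        return float(threshold_method)
    if threshold_method == "otsu":
        if np.ptp(values) == 0:
            # constant signal in the region: anything at/above the value is
            # all-or-nothing; put the threshold at the value itself
            return float(values.flat[0])
        return float(threshold_otsu(values))
    if isinstance(threshold_method, str) and threshold_method.startswith("fixed:"):
        return float(threshold_method.split(":", 1)[1])
    raise ValueError(f"unknown threshold method {threshold_method!r}")


def quantify_signal_in_region(
    signal_channel: np.ndarray | VolumeImage,
    region_mask: np.ndarray,
    voxel_size_um: tuple[float, float, float] | None = None,
    threshold_method="otsu",
    region_label: str = "region",
    sample_id: str = "sample",
) -> SignalQuant:
    """Signal volume per region volume for one compartment.

    The threshold (Otsu by default) is computed over the intensities
    *inside* the region, mirroring masking the signal channel under the
    region surface before building the signal volume.  Raising the
    threshold can never increase the ratio.
    """
    if isinstance(signal_channel, VolumeImage):
        if voxel_size_um is None:
            voxel_size_um = signal_channel.voxel_size_um
        signal = np.asarray(signal_channel.data)
    else:
        signal = np.asarray(signal_channel)
    if voxel_size_um is None:
        raise ValueError("voxel_size_um required when passing a bare array")
    region_mask = np.asarray(region_mask, bool)
    if signal.shape != region_mask.shape:
        raise ValueError("signal channel and region mask must be aligned")
    n_region = int(region_mask.sum())
    if n_region == 0:
        raise ValueError("region mask is empty")
    inside = signal[region_mask]
    t = _resolve_threshold(inside, threshold_method)
    if threshold_method == "otsu" and np.ptp(inside) == 0:
        # uniform region: all signal if nonzero, none if blank
        n_signal = n_region if inside.flat[0] > 0 else 0
    elif threshold_method == "otsu":
        # guard against splitting pure noise: the two classes must be
        # separated by more than the background spread to count as signal
        below = inside[inside <= t]
        above = inside[inside > t]
        sd0 = float(below.std())
        if len(above) == 0 or (
            sd0 > 0 and (above.mean() - below.mean()) < 4.0 * sd0
        ):
            n_signal = 0
            t = float("inf")
        else:
            n_signal = int((inside > t).sum())
    else:
        n_signal = int((inside >= t).sum())
    voxvol = float(np.prod(voxel_size_um))
    return SignalQuant(
        region_label=region_label,
        region_volume_um3=n_region * voxvol,
        signal_volume_um3=n_signal * voxvol,
        ratio=n_signal / n_region,
        threshold=t,
        sample_id=sample_id,
    )


def positive_cell_fraction(
    nuclei_mask: LabelMask,
    marker_channel: np.ndarray,
    region_mask: np.ndarray | None = None,
    positivity_threshold="otsu",
    compartment: str = "gland",
) -> CellFraction:
    """Fraction of labeled cells whose mean marker intensity calls positive.

    A cell is positive iff its mean marker intensity is at least the
    positivity threshold; ``"otsu"`` derives the threshold from the
    distribution of within-region cell means (cells are restricted to
    ``region_mask`` by their centroid when a region is given).
    """
    labels = nuclei_mask.labels
    marker = np.asarray(marker_channel, float)
    if labels.shape != marker.shape:
        raise ValueError("nuclei labels and marker channel must be aligned")
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if region_mask is not None:
        region_mask = np.asarray(region_mask, bool)
        centroids = ndimage.center_of_mass(
            np.ones_like(labels), labels=labels, index=ids
        )
        keep = []
        for cid, c in zip(ids, centroids):
            idx = tuple(np.clip(np.rint(c).astype(int), 0, np.array(labels.shape) - 1))
            if region_mask[idx]:
                keep.append(cid)
        ids = np.asarray(keep)
    if len(ids) == 0:
        raise ValueError("no cells in the region")
    means = np.asarray(ndimage.mean(marker, labels=labels, index=ids))
    if isinstance(positivity_threshold, str) and positivity_threshold == "otsu":
        if np.ptp(means) == 0:
            t = float(means[0])
        else:
            t = float(threshold_otsu(means))
    else:
        t = float(positivity_threshold)
    n_pos = int((means >= t).sum())
    return CellFraction(n_positive=n_pos, n_total=len(ids), compartment=compartment)
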