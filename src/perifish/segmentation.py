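"""Automatic 3D nucleus segmentation.

The pipeline is: 3D median filter (noise suppression) → global Otsu
threshold → morphological dilation with a box structuring element (to grow
masks outward so they also cover the lamin shell) → 26-connected component
labelling with a minimum-size filter.

Kernel and structuring-element sizes are given in ``(x, y, z)`` order —
fine in-plane, coarse axially — matching the anisotropic voxels of a
typical z-stack; volumes themselves are indexed ``(z, y, x)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator
from scipy import ndimage
from skimage.filters import threshold_otsu

from .stack import ImageStack

logger = logging.getLogger(__name__)


class DegenerateVolumeError(ValueError):
    """A volume with fewer than two distinct values cannot be thresholded."""


class SegmentationParams(BaseModel):
    model_config = ConfigDict(extra="forbid")

    median_size_xyz: tuple[int, int, int] = (13, 13, 5)
    dilation_se_xyz: tuple[int, int, int] = (5, 5, 3)
    min_nucleus_voxels: int = 500
    segmentation_channel: str = "dna"

    @field_validator("median_size_xyz", "dilation_se_xyz")
    @classmethod
    def _odd_positive(cls, v):
        if any(s < 1 or s % 2 == 0 for s in v):
            raise ValueError(f"sizes must be odd and >= 1 per axis, got {v}")
        return v

    @field_validator("min_nucleus_voxels")
    @classmethod
    def _nonneg(cls, v):
        if v < 0:
            raise ValueError("min_nucleus_voxels must be >= 0")
        return v


@dataclass
class LabeledNuclei:
    """Per-voxel nucleus instance labels (0 = background) with provenance.

    ``label_volume`` carries the dilated masks (grown to cover the lamin
    staining, as the 3D distance path needs); ``core_mask`` is the binary
    mask *before* dilation, whose boundary tracks the actual nucleus
    surface — the 2D radial readout normalizes against that contour.
    """

    label_volume: np.ndarray
    threshold: float
    table: pd.DataFrame  # one row per label: n_voxels, bbox, centroid
    core_mask: np.ndarray | None = None

    @property
    def n_nuclei(self) -> int:
        return len(self.table)

    @property
    def labels(self) -> np.ndarray:
        return self.table["label"].to_numpy()


def _size_xyz_to_zyx(size_xyz) -> tuple[int, int, int]:
    x, y, z = size_xyz
    return (z, y, x)


def median_filter_3d(volume: np.ndarray, size_xyz: tuple[int, int, int]) -> np.ndarray:
    """Median filter with an ``x × y × z`` box window and reflect borders.

    Each output voxel is the median over the window centred on it; reflect
    padding avoids the edge darkening a zero-padded median would introduce,
    which would otherwise bias the downstream Otsu threshold.
    """
    volume = np.asarray(volume)
    if volume.size == 0:
        raise ValueError("empty volume")
    if len(size_xyz) != 3 or any(s < 1 or s % 2 == 0 for s in size_xyz):
        raise ValueError(f"kernel size must be odd and >= 1 per axis, got {size_xyz}")
    return ndimage.median_filter(volume, size=_size_xyz_to_zyx(size_xyz), mode="reflect")


def otsu_threshold(volume: np.ndarray) -> float:
    """Otsu's threshold: maximizes between-class variance of the histogram.

    The binarization rule throughout the package is ``voxel > threshold``.
    For integer volumes the histogram is exact (one bin per distinct value),
    so the returned threshold equals an exhaustive scan over candidate
    values; ties resolve to the lowest qualifying threshold. Raises
    :class:`DegenerateVolumeError` for a constant volume.
    """
    volume = np.asarray(volume)
    values = volume.ravel()
    uniq = np.unique(values)
    if uniq.size < 2:
        raise DegenerateVolumeError(
            "volume is constant; Otsu's method needs at least two distinct values"
        )
    if np.issubdtype(volume.dtype, np.integer):
        counts = np.bincount((values - uniq[0]).astype(np.int64))
        centers = np.arange(uniq[0], uniq[0] + counts.size)
        keep = counts > 0
        return float(threshold_otsu(hist=(counts[keep], centers[keep].astype(float))))
    return float(threshold_otsu(values, nbins=256))


def dilate_binary(mask: np.ndarray, se_xyz: tuple[int, int, int]) -> np.ndarray:
    """Binary dilation by an ``x × y × z`` box structuring element.

    The output is the union of SE-translates over foreground voxels,
    clipped at the volume borders; dilation is extensive (output ⊇ input).
    """
    mask = np.asarray(mask).astype(bool)
    if len(se_xyz) != 3 or any(s < 1 or s % 2 == 0 for s in se_xyz):
        raise ValueError(f"structuring element must be odd and >= 1 per axis, got {se_xyz}")
    se = np.ones(_size_xyz_to_zyx(se_xyz), dtype=bool)
    return ndimage.binary_dilation(mask, structure=se)


def segment_nuclei(stack: ImageStack, params: SegmentationParams) -> LabeledNuclei:
    """Segment nuclei: median filter → Otsu → dilation → instance labelling.

    Components are 26-connected; touching nuclei therefore merge into one
    label (no watershed splitting). Components smaller than
    ``min_nucleus_voxels`` are discarded and the survivors relabelled
    1..N. A volume in which no component survives yields an empty result
    with a warning, not an error; a constant volume raises
    :class:`DegenerateVolumeError`.
    """
    volume = stack.channel(params.segmentation_channel)
    filtered = median_filter_3d(volume, params.median_size_xyz)
    threshold = otsu_threshold(filtered)
    core = filtered > threshold
    mask = dilate_binary(core, params.dilation_se_xyz)

    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    raw_labels, n_raw = ndimage.label(mask, structure=structure)
    if n_raw == 0:
        warnings.warn("no nuclei found above the Otsu threshold", stacklevel=2)
        return LabeledNuclei(
            label_volume=raw_labels,
            threshold=threshold,
            table=_empty_table(),
            core_mask=core,
        )

    sizes = np.bincount(raw_labels.ravel())[1:]
    keep = np.flatnonzero(sizes >= params.min_nucleus_voxels) + 1
    if keep.size == 0:
        warnings.warn(
            f"all {n_raw} components smaller than min_nucleus_voxels="
            f"{params.min_nucleus_voxels}",
            stacklevel=2,
        )
        return LabeledNuclei(np.zeros_like(raw_labels), threshold, _empty_table(), core)

    remap = np.zeros(n_raw + 1, dtype=raw_labels.dtype)
    remap[keep] = np.arange(1, keep.size + 1)
    labels = remap[raw_labels]

    rows = []
    objects = ndimage.find_objects(labels)
    centroids = ndimage.center_of_mass(labels > 0, labels, np.arange(1, keep.size + 1))
    for lab, (sl, com) in enumerate(zip(objects, centroids), start=1):
        rows.append(
            {
                "label": lab,
                "n_voxels": int((labels[sl] == lab).sum()),
                "z0": sl[0].start, "z1": sl[0].stop,
                "y0": sl[1].start, "y1": sl[1].stop,
                "x0": sl[2].start, "x1": sl[2].stop,
                "centroid_z": com[0], "centroid_y": com[1], "centroid_x": com[2],
            }
        )
    logger.info("segmented %d nuclei (threshold=%.1f)", keep.size, threshold)
    return LabeledNuclei(
        label_volume=labels, threshold=threshold, table=pd.DataFrame(rows), core_mask=core
    )


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "label", "n_voxels", "z0", "z1", "y0", "y1", "x0", "x1",
            "centroid_z", "centroid_y", "centroid_x",
        ]
    )
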