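"""Distance readouts: 3D shortest distance to the lamina and the 2D
normalized radial position.

Two readouts quantify how close a FISH locus sits to the nuclear
periphery:

* **3D shortest distance** — the Euclidean minimum, in micrometres, from
  the spot to any point of its nucleus's lamin point cloud, with pixel
  coordinates rescaled per axis by the voxel size beforehand.
* **2D normalized radial position** — on a per-nucleus 2D mask (from a
  manually traced closed cubic spline, or a projected segmentation mask),
  the Euclidean distance transform with respect to the mask contour,
  divided by its per-nucleus maximum: 0 at the periphery, 1 at the deepest
  interior point (the nucleus centre).

Distributions are summarised as probability-density histograms whose bar
heights are counts over total, summing to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath
from scipy import ndimage
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree
from shapely.geometry import LineString

from .stack import ImageStack

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


# ----------------------------------------------------------------- records


@dataclass
class DistanceRecord:
    """One locus measurement; at least one of the two readouts is present."""

    nucleus_id: int
    spot_id: int
    distance_3d_um: float | None = None
    normalized_position: float | None = None
    condition: str = ""

    def __post_init__(self) -> None:
        if self.distance_3d_um is None and self.normalized_position is None:
            raise ValueError("a DistanceRecord needs at least one readout")
        if self.distance_3d_um is not None and self.distance_3d_um < 0:
            raise ValueError("distance_3d_um must be >= 0")
        if self.normalized_position is not None and not (
            0.0 <= self.normalized_position <= 1.0
        ):
            raise ValueError("normalized_position must be in [0, 1]")


def records_to_frame(records: list[DistanceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "nucleus_id": [r.nucleus_id for r in records],
            "spot_id": [r.spot_id for r in records],
            "distance_3d_um": [r.distance_3d_um for r in records],
            "normalized_position": [r.normalized_position for r in records],
            "condition": [r.condition for r in records],
        }
    )


# ------------------------------------------------------------- 3D distance


def min_distance_3d(spot_um: np.ndarray, cloud_um: np.ndarray) -> float:
    """Shortest Euclidean distance from a spot to a lamin point cloud (µm).

    All coordinates must already be in micrometres (rescaled per axis).
    The k-d tree query is exact, i.e. identical to the exhaustive
    all-pairs minimum.
    """
    cloud_um = np.asarray(cloud_um, dtype=float).reshape(-1, 3)
    if cloud_um.shape[0] == 0:
        raise ValueError("empty lamin point cloud")
    d, _ = cKDTree(cloud_um).query(np.asarray(spot_um, dtype=float))
    return float(d)


# ------------------------------------------------------------- projection


def max_project(stack: ImageStack) -> np.ndarray:
    """Per-channel maximum projection over z, shape ``(C, Y, X)``."""
    return stack.data.max(axis=1)


def max_project_composite(stack: ImageStack) -> np.ndarray:
    """RGB composite of the per-channel maximum projections.

    Channels are mapped to distinct display colours (probe → green,
    lamin → red, dna → blue), each normalized to its own maximum.
    """
    proj = max_project(stack).astype(float)
    colors = {"probe": (0.0, 1.0, 0.0), "lamin": (1.0, 0.0, 0.0), "dna": (0.0, 0.0, 1.0)}
    fallback = [(1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 0)]
    rgb = np.zeros(proj.shape[1:] + (3,), dtype=float)
    for i, role in enumerate(stack.channel_roles):
        chan = proj[i]
        if chan.max() > 0:
            chan = chan / chan.max()
        color = colors.get(role, fallback[i % len(fallback)])
        rgb += chan[..., None] * np.asarray(color)
    return np.clip(rgb, 0.0, 1.0)


# ------------------------------------------------------------ 2D spline ROI


@dataclass
class SplineROI:
    """A manually traced nucleus outline: a closed periodic cubic spline
    through five or more control points, given as ``(y, x)`` pixels."""

    nucleus_id: int
    control_points: np.ndarray  # (N, 2) as (y, x)

    def __post_init__(self) -> None:
        self.control_points = np.asarray(self.control_points, dtype=float).reshape(-1, 2)
        if self.control_points.shape[0] < 5:
            raise ValueError(
                f"a spline ROI needs >= 5 control points, got {self.control_points.shape[0]}"
            )

    def sample(self, n: int) -> np.ndarray:
        """Sample ``n`` points along the closed spline (uniform parameter)."""
        pts = np.vstack([self.control_points, self.control_points[:1]])
        t = np.arange(len(pts), dtype=float)
        spline = CubicSpline(t, pts, bc_type="periodic")
        u = np.linspace(0.0, t[-1], n, endpoint=False)
        return spline(u)


def rasterize_spline(roi: SplineROI, image_shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a closed spline ROI to a 2D binary mask.

    The spline is densified at >= 8 samples per pixel of arc length before
    polygon filling; a pixel is foreground when its centre lies inside the
    closed curve. Self-intersecting splines are rejected.
    """
    # arc length estimate from a moderate sampling, then densify
    coarse = roi.sample(max(64, 8 * len(roi.control_points)))
    arc = np.sum(np.linalg.norm(np.diff(np.vstack([coarse, coarse[:1]]), axis=0), axis=1))
    n = max(128, int(np.ceil(8 * arc)))
    curve = roi.sample(n)  # (n, 2) as (y, x)
    ring = LineString(np.vstack([curve, curve[:1]]))
    if not ring.is_simple:
        raise ValueError(f"spline ROI for nucleus {roi.nucleus_id} is self-intersecting")
    h, w = image_shape
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xx.ravel(), yy.ravel()])  # Path wants (x, y)
    path = MplPath(curve[:, ::-1], closed=True)
    mask = path.contains_points(pts).reshape(h, w)
    return mask


# --------------------------------------------------- normalized distance map


@dataclass
class NormalizedDistanceMap:
    """Contour distance transform divided by its per-nucleus maximum."""

    nucleus_id: int
    map: np.ndarray  # 2D float, in [0, 1], 0 outside the mask
    max_location: tuple[int, int]
    max_raw_distance: float  # px, before normalization


def normalized_distance_map(mask: np.ndarray, nucleus_id: int = 0) -> NormalizedDistanceMap:
    """Distance map with respect to the mask contour, normalized to [0, 1].

    The Euclidean distance transform gives each foreground pixel its
    distance to the nearest background pixel (the contour); dividing by
    the per-nucleus maximum puts the deepest interior point — the nucleus
    centre for convex masks — at exactly 1 and the periphery near 0.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    dist = ndimage.distance_transform_edt(mask)
    max_raw = float(dist.max())
    argmax = np.unravel_index(int(np.argmax(dist)), dist.shape)
    return NormalizedDistanceMap(
        nucleus_id=nucleus_id,
        map=dist / max_raw,
        max_location=(int(argmax[0]), int(argmax[1])),
        max_raw_distance=max_raw,
    )


def normalized_position(spot_yx: tuple[float, float], ndmap: NormalizedDistanceMap) -> float:
    """Look up a spot's normalized radial position by bilinear interpolation.

    The spot's nearest pixel must lie inside the ROI mask; near the contour
    the interpolation tapers toward 0 as background pixels carry value 0.
    """
    y, x = float(spot_yx[0]), float(spot_yx[1])
    h, w = ndmap.map.shape
    iy, ix = int(round(y)), int(round(x))
    if not (0 <= iy < h and 0 <= ix < w) or ndmap.map[iy, ix] <= 0:
        raise ValueError(
            f"spot at (y={y:.2f}, x={x:.2f}) lies outside the mask of nucleus "
            f"{ndmap.nucleus_id}"
        )
    val = ndimage.map_coordinates(ndmap.map, [[y], [x]], order=1, mode="nearest")[0]
    return float(np.clip(val, 0.0, 1.0))


# ---------------------------------------------------------------- histogram


@dataclass
class PDFHistogram:
    """A histogram whose bar heights are counts over total (sum = 1)."""

    bin_edges: np.ndarray
    heights: np.ndarray
    n: int
    condition: str = ""


def pdf_histogram(values, bin_edges, condition: str = "") -> PDFHistogram:
    """Bin values into a probability histogram: bar height = count / total."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("empty input")
    bin_edges = np.asarray(bin_edges, dtype=float)
    if values.min() < bin_edges[0] or values.max() > bin_edges[-1]:
        raise ValueError(
            f"bins [{bin_edges[0]}, {bin_edges[-1]}] do not cover the data range "
            f"[{values.min()}, {values.max()}]"
        )
    counts, edges = np.histogram(values, bins=bin_edges)
    return PDFHistogram(
        bin_edges=edges, heights=counts / values.size, n=int(values.size), condition=condition
    )


def default_bins(values, readout: str) -> np.ndarray:
    """Default binning: 20 uniform bins on [0, 1] for normalized positions,
    Freedman–Diaconis for micrometre distances."""
    if readout == "normalized_position":
        return np.linspace(0.0, 1.0, 21)
    values = np.asarray(values, dtype=float)
    edges = np.histogram_bin_edges(values, bins="fd")
    if len(edges) < 3:  # fd degenerates on tiny/constant samples
        edges = np.histogram_bin_edges(values, bins=10)
    return edges


def plot_pdf(
    histograms: list[PDFHistogram],
    out_path: str | Path,
    xlabel: str = "normalized distance to periphery",
) -> None:
    """Plot one or more probability histograms side by side, annotated with n."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for i, h in enumerate(histograms):
        centers = 0.5 * (h.bin_edges[:-1] + h.bin_edges[1:])
        width = np.diff(h.bin_edges) * (0.8 / len(histograms))
        offset = (i - (len(histograms) - 1) / 2) * width
        label = f"{h.condition or f'condition {i}'} (n={h.n})"
        ax.bar(centers + offset, h.heights, width=width, label=label, alpha=0.8)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("probability")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


# ------------------------------------------------------------- comparison


@dataclass
class ConditionComparison:
    readout: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    mean_a: float
    mean_b: float
    median_difference: float  # median_a - median_b
    histogram_a: PDFHistogram = field(repr=False, default=None)
    histogram_b: PDFHistogram = field(repr=False, default=None)


def compare_conditions(
    records_a: list[DistanceRecord],
    records_b: list[DistanceRecord],
    readout: str = "normalized_position",
    bin_edges: np.ndarray | None = None,
    plot_path: str | Path | None = None,
) -> ConditionComparison:
    """Summarise two conditions on a shared readout: per-condition n,
    median, mean, and the difference of medians (A minus B), with the two
    probability histograms on shared bins. No hypothesis test is attached;
    the comparison is descriptive.
    """
    if readout not in ("normalized_position", "distance_3d_um"):
        raise ValueError(f"unknown readout {readout!r}")

    def extract(records, name):
        if not records:
            raise ValueError(f"condition {name} has no records")
        vals = [getattr(r, readout) for r in records]
        if any(v is None for v in vals):
            raise ValueError(f"condition {name} has records without the {readout} readout")
        return np.asarray(vals, dtype=float)

    a, b = extract(records_a, "A"), extract(records_b, "B")
    if bin_edges is None:
        bin_edges = default_bins(np.concatenate([a, b]), readout)
    hist_a = pdf_histogram(a, bin_edges, condition=records_a[0].condition or "A")
    hist_b = pdf_histogram(b, bin_edges, condition=records_b[0].condition or "B")
    if plot_path is not None:
        xlabel = (
            "normalized distance to periphery"
            if readout == "normalized_position"
            else "distance to lamina (µm)"
        )
        plot_pdf([hist_a, hist_b], plot_path, xlabel=xlabel)
    return ConditionComparison(
        readout=readout,
        n_a=len(a), n_b=len(b),
        median_a=float(np.median(a)), median_b=float(np.median(b)),
        mean_a=float(np.mean(a)), mean_b=float(np.mean(b)),
        median_difference=float(np.median(a) - np.median(b)),
        histogram_a=hist_a, histogram_b=hist_b,
    )
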