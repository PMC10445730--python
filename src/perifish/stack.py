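"""Multi-channel 3D image stacks with physical voxel sizes.

The raw observable of the pipeline is a 3-channel fluorescence z-stack:
a DNA counterstain, a FISH probe channel and a lamin immunostain channel,
with anisotropic voxels (the z step is typically coarser than xy).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

#: Canonical channel roles, in storage order.
CHANNEL_ROLES = ("dna", "probe", "lamin")


@dataclass
class ImageStack:
    """A multi-channel 3D voxel grid.

    Parameters
    ----------
    data
        Array of shape ``(C, Z, Y, X)`` with non-negative counts.
    channel_roles
        Role name per channel, e.g. ``("dna", "probe", "lamin")``.
    voxel_size_zyx
        Physical voxel size in micrometres per axis, ``(z, y, x)``.
    """

    data: np.ndarray
    channel_roles: tuple[str, ...] = CHANNEL_ROLES
    voxel_size_zyx: tuple[float, float, float] = (0.3, 0.1, 0.1)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.channel_roles = tuple(self.channel_roles)
        self.voxel_size_zyx = tuple(float(v) for v in self.voxel_size_zyx)
        if self.data.ndim != 4:
            raise ValueError(f"expected (C, Z, Y, X) data, got shape {self.data.shape}")
        if len(self.channel_roles) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_roles)} channel roles for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_roles)) != len(self.channel_roles):
            raise ValueError("channel roles must be unique")
        if len(self.voxel_size_zyx) != 3 or any(v <= 0 for v in self.voxel_size_zyx):
            raise ValueError(f"voxel sizes must be three positive values, got {self.voxel_size_zyx}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.isfinite(self.data).all():
            raise ValueError("stack contains non-finite values")
        if self.data.min() < 0:
            raise ValueError("stack contains negative counts")

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[1:])

    def channel(self, role: str) -> np.ndarray:
        """Return the ``(Z, Y, X)`` volume for a channel role."""
        try:
            idx = self.channel_roles.index(role)
        except ValueError:
            raise KeyError(
                f"channel role {role!r} not in stack (have {self.channel_roles})"
            ) from None
        return self.data[idx]

    # ------------------------------------------------------------------ I/O

    def save_ome_tiff(self, path: str | Path) -> None:
        """Write the stack as OME-TIFF (ZCYX plane order, sizes in metadata)."""
        data = np.ascontiguousarray(np.moveaxis(self.data, 0, 1))  # -> (Z, C, Y, X)
        sz, sy, sx = self.voxel_size_zyx
        tifffile.imwrite(
            str(path),
            data,
            ome=True,
            metadata={
                "axes": "ZCYX",
                "Channel": {"Name": list(self.channel_roles)},
                "PhysicalSizeZ": sz,
                "PhysicalSizeY": sy,
                "PhysicalSizeX": sx,
                "PhysicalSizeZUnit": "µm",
                "PhysicalSizeYUnit": "µm",
                "PhysicalSizeXUnit": "µm",
            },
        )


def load_ome_tiff(
    path: str | Path,
    channel_roles: tuple[str, ...] | None = None,
    voxel_size_zyx: tuple[float, float, float] | None = None,
) -> ImageStack:
    """Read an OME-TIFF stack written by :meth:`ImageStack.save_ome_tiff`.

    Channel names and voxel sizes are recovered from the OME metadata when
    present; explicit arguments override the metadata.
    """
    with tifffile.TiffFile(str(path)) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        meta_roles: tuple[str, ...] | None = None
        meta_sizes: tuple[float, float, float] | None = None
        if tif.ome_metadata:
            import xml.etree.ElementTree as ET

            root = ET.fromstring(tif.ome_metadata)
            ns = {"ome": root.tag.split("}")[0].strip("{")}
            pixels = root.find(".//ome:Pixels", ns)
            if pixels is not None:
                names = [c.get("Name") for c in pixels.findall("ome:Channel", ns)]
                if names and all(names):
                    meta_roles = tuple(names)
                try:
                    meta_sizes = (
                        float(pixels.get("PhysicalSizeZ")),
                        float(pixels.get("PhysicalSizeY")),
                        float(pixels.get("PhysicalSizeX")),
                    )
                except (TypeError, ValueError):
                    meta_sizes = None

    # normalise axis order to (C, Z, Y, X)
    axes = axes.replace("S", "C")
    if set(axes) - set("CZYX"):
        raise ValueError(f"unsupported axes {axes!r} in {path}")
    for missing in set("CZYX") - set(axes):
        data = data[np.newaxis]
        axes = missing + axes
    order = [axes.index(a) for a in "CZYX"]
    data = np.transpose(data, order)

    roles = channel_roles or meta_roles or CHANNEL_ROLES[: data.shape[0]]
    sizes = voxel_size_zyx or meta_sizes or (0.3, 0.1, 0.1)
    return ImageStack(data=data, channel_roles=roles, voxel_size_zyx=sizes)
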