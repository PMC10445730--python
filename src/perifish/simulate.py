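"""Synthetic fluorescence scenes with known geometry and known spot positions.

The generator emulates the imaging situation the pipeline is built for:
densely packed, near-ellipsoidal blastoderm nuclei; a thin, punctate lamin
shell at each nucleus boundary; one or two diffraction-limited FISH probe
spots per nucleus placed at a *requested* normalized radial position;
anisotropic voxels; Poisson shot noise plus Gaussian read noise over a
uniform background.

Every scene comes with a :class:`GroundTruth` recording exact (pre-blur,
pre-noise) nucleus geometries, spot positions, normalized radial positions
(1 = centre, 0 = boundary) and exact Euclidean spot-to-surface distances,
so that each downstream stage can be tested as a parameter-recovery
problem.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import ndimage

from .geometry import fibonacci_sphere, surface_distance, uniform_directions
from .stack import CHANNEL_ROLES, ImageStack


class SceneGenerationError(RuntimeError):
    """Raised when a requested scene cannot be realised (e.g. nuclei do not fit)."""


class SceneParams(BaseModel):
    """Parameters of a synthetic scene.

    ``spots_spec`` lists the probe spots to render as
    ``(nucleus_index, r, amplitude)`` where ``r`` is the normalized radial
    position (1 = nucleus centre, 0 = boundary). The direction of each spot
    from its nucleus centre is drawn uniformly at random (seeded).
    """

    model_config = ConfigDict(extra="forbid")

    shape_zyx: tuple[int, int, int] = (16, 128, 128)
    voxel_size_zyx: tuple[float, float, float] = (0.3, 0.1, 0.1)
    n_nuclei: int = 4
    nucleus_semiaxes_um: tuple[float, float] = (1.4, 2.2)
    shell_thickness_um: float = 0.4
    spots_spec: list[tuple[int, float, float]] = Field(default_factory=list)
    psf_sigma_um: tuple[float, float, float] = (0.3, 0.1, 0.1)
    background: float = 20.0
    read_noise_sd: float = 3.0
    seed: int = 0
    #: draw one radius per nucleus instead of three distinct semi-axes
    spherical: bool = False
    # rendering parameters (counts); not part of the geometric ground truth
    dna_amplitude: float = 300.0
    lamin_dot_amplitude: float = 400.0
    lamin_dot_spacing_um: float = 0.3
    lamin_amplitude_cv: float = 0.3  # lognormal sigma of per-dot brightness
    lamin_dot_jitter: float = 0.02  # radians of angular jitter off the lattice
    max_placement_attempts: int = 500

    @model_validator(mode="after")
    def _check(self) -> "SceneParams":
        if any(s <= 0 for s in self.shape_zyx):
            raise ValueError("shape_zyx must be positive")
        if any(v <= 0 for v in self.voxel_size_zyx):
            raise ValueError("voxel_size_zyx must be positive")
        if self.n_nuclei <= 0:
            raise ValueError("n_nuclei must be positive")
        lo, hi = self.nucleus_semiaxes_um
        if not (0 < lo <= hi):
            raise ValueError("nucleus_semiaxes_um must be an increasing positive range")
        if self.shell_thickness_um <= 0:
            raise ValueError("shell_thickness_um must be positive")
        if any(s <= 0 for s in self.psf_sigma_um):
            raise ValueError("psf_sigma_um must be positive")
        if self.background < 0 or self.read_noise_sd < 0:
            raise ValueError("background and read_noise_sd must be non-negative")
        for i, (idx, r, amp) in enumerate(self.spots_spec):
            if not (0 <= idx < self.n_nuclei):
                raise ValueError(f"spots_spec[{i}] references nonexistent nucleus {idx}")
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"spots_spec[{i}] radial position {r} outside [0, 1]")
            if amp <= 0:
                raise ValueError(f"spots_spec[{i}] amplitude must be positive")
        return self


@dataclass
class GroundTruth:
    """Simulator-side truth: exact geometry before blurring and noise."""

    nucleus_centers_um: np.ndarray  # (N, 3) zyx
    nucleus_semiaxes_um: np.ndarray  # (N, 3) zyx
    spot_nucleus: np.ndarray  # (S,) int
    true_spot_positions_um: np.ndarray  # (S, 3) zyx
    true_radial_positions: np.ndarray  # (S,) in [0, 1], 1 = centre
    true_shell_distances_um: np.ndarray  # (S,) exact distance to the surface

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "nucleus": self.spot_nucleus,
                "z_um": self.true_spot_positions_um[:, 0],
                "y_um": self.true_spot_positions_um[:, 1],
                "x_um": self.true_spot_positions_um[:, 2],
                "r": self.true_radial_positions,
                "shell_distance_um": self.true_shell_distances_um,
            }
        )
        df.to_csv(path, index=False)


def apply_noise(
    clean: ImageStack, background: float, read_noise_sd: float, seed: int
) -> ImageStack:
    """Add shot and read noise to a clean stack.

    Output counts are ``Poisson(clean + background) + N(0, read_noise_sd)``,
    clipped at zero and quantized to unsigned 16-bit integers, mimicking an
    sCMOS camera.
    """
    if background < 0:
        raise ValueError("background must be non-negative")
    if read_noise_sd < 0:
        raise ValueError("read_noise_sd must be non-negative")
    data = np.asarray(clean.data, dtype=np.float64)
    if not np.isfinite(data).all():
        raise ValueError("clean stack contains non-finite values")
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(data + background).astype(np.float64)
    if read_noise_sd > 0:
        noisy += rng.normal(0.0, read_noise_sd, size=noisy.shape)
    noisy = np.clip(np.rint(noisy), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    return ImageStack(noisy, clean.channel_roles, clean.voxel_size_zyx)


def _place_nuclei(params: SceneParams, rng: np.random.Generator):
    """Sequentially place non-overlapping ellipsoids inside the volume.

    Overlap is excluded conservatively via bounding spheres separated by at
    least the shell thickness; placements are re-drawn up to
    ``max_placement_attempts`` times before giving up.
    """
    extent = np.array(params.shape_zyx) * np.array(params.voxel_size_zyx)
    lo, hi = params.nucleus_semiaxes_um
    centers, semiaxes = [], []
    for i in range(params.n_nuclei):
        for _ in range(params.max_placement_attempts):
            if params.spherical:
                ax = np.full(3, rng.uniform(lo, hi))
            else:
                ax = rng.uniform(lo, hi, size=3)
                # squash z so nuclei fit thin stacks, as in a blastoderm monolayer
                ax[0] = min(ax[0], (extent[0] - params.shell_thickness_um) / 2.2)
            margin = ax + params.shell_thickness_um
            if np.any(extent - 2 * margin <= 0):
                continue
            c = rng.uniform(margin, extent - margin)
            gap = params.shell_thickness_um
            ok = all(
                np.linalg.norm(c - cj) > ax.max() + aj.max() + gap
                for cj, aj in zip(centers, semiaxes)
            )
            if ok:
                centers.append(c)
                semiaxes.append(ax)
                break
        else:
            raise SceneGenerationError(
                f"could not place nucleus {i} without overlap after "
                f"{params.max_placement_attempts} attempts"
            )
    return np.array(centers), np.array(semiaxes)


def _voxel_centers_um(shape_zyx, voxel_size_zyx):
    """Physical coordinate of each voxel centre per axis (index * size)."""
    return [np.arange(n) * s for n, s in zip(shape_zyx, voxel_size_zyx)]


def _fill_ellipsoid(volume: np.ndarray, center, semiaxes, amplitude, coords) -> np.ndarray:
    """Fill the ellipsoid interior; returns the interior voxel mask."""
    zs, ys, xs = coords
    m2 = (
        ((zs[:, None, None] - center[0]) / semiaxes[0]) ** 2
        + ((ys[None, :, None] - center[1]) / semiaxes[1]) ** 2
        + ((xs[None, None, :] - center[2]) / semiaxes[2]) ** 2
    )
    inside = m2 <= 1.0
    volume[inside] += amplitude
    return inside


def _render_gaussian_spot(
    volume, pos_um, amplitude, sigma_um, voxel_size, radial_cutoff_um: float | None = None
) -> None:
    """Add a Gaussian spot at a sub-voxel physical position.

    With ``radial_cutoff_um`` the kernel is truncated at that Euclidean
    (physical) radius, confining the rendered support to a ball around the
    spot — used for lamin puncta so the shell support stays within the
    stated shell thickness of the nucleus surface.
    """
    shape = volume.shape
    offsets = []
    slices = []
    for ax in range(3):
        s = sigma_um[ax]
        reach = radial_cutoff_um if radial_cutoff_um is not None else 4 * s
        c = pos_um[ax] / voxel_size[ax]
        half = max(1, int(np.ceil(reach / voxel_size[ax])))
        i0, i1 = max(0, int(np.floor(c)) - half), min(shape[ax], int(np.ceil(c)) + half + 1)
        if i0 >= i1:
            return
        idx = np.arange(i0, i1)
        offsets.append(idx * voxel_size[ax] - pos_um[ax])
        slices.append(slice(i0, i1))
    dz, dy, dx = np.meshgrid(*offsets, indexing="ij")
    sz, sy, sx = sigma_um
    blob = amplitude * np.exp(-0.5 * ((dz / sz) ** 2 + (dy / sy) ** 2 + (dx / sx) ** 2))
    if radial_cutoff_um is not None:
        blob[dz**2 + dy**2 + dx**2 > radial_cutoff_um**2] = 0.0
    volume[tuple(slices)] += blob


def generate_scene(params: SceneParams) -> tuple[ImageStack, GroundTruth]:
    """Render a 3-channel scene and its exact ground truth.

    Channel content (before noise):

    * ``dna``   — uniform fill of each nucleus interior;
    * ``probe`` — one PSF-blurred Gaussian spot per ``spots_spec`` entry, at
      the position whose normalized radial coordinate equals the requested
      ``r`` along a random direction;
    * ``lamin`` — punctate dots sampled densely on each nucleus surface
      (immunostaining is punctate; the Cy5 detections are treated downstream
      as a point cloud sampling the lamina).

    The scene is noiseless (deterministic rounding of the clean render) when
    ``background == 0 and read_noise_sd == 0``; otherwise shot and read
    noise are applied via :func:`apply_noise` with a seed derived from
    ``params.seed``. Identical params give bit-identical stacks.
    """
    rng = np.random.default_rng(params.seed)
    centers, semiaxes = _place_nuclei(params, rng)
    coords = _voxel_centers_um(params.shape_zyx, params.voxel_size_zyx)
    voxel_size = np.array(params.voxel_size_zyx)
    shape = tuple(params.shape_zyx)

    dna = np.zeros(shape, dtype=np.float64)
    probe = np.zeros(shape, dtype=np.float64)
    lamin = np.zeros(shape, dtype=np.float64)

    interior = np.zeros(shape, dtype=bool)
    for c, a in zip(centers, semiaxes):
        interior |= _fill_ellipsoid(dna, c, a, params.dna_amplitude, coords)
    # the counterstain is blurred by the optics like everything else; the
    # half-maximum edge of the blurred fill stays on the nucleus surface
    dna = ndimage.gaussian_filter(dna, sigma=np.array(params.psf_sigma_um) / voxel_size)

    for c, a in zip(centers, semiaxes):
        # punctate lamin: a jittered quasi-uniform lattice of bright dots
        # centred on the nucleus surface, each rendered as a PSF-shaped blob
        # truncated at half the shell thickness so the shell support stays
        # tight around the surface
        area = 4 * np.pi * (np.prod(a) ** (2 / 3))  # sphere-equivalent area
        n_dots = max(50, int(area / params.lamin_dot_spacing_um**2))
        u = fibonacci_sphere(n_dots)
        if params.lamin_dot_jitter > 0:
            u = u + rng.normal(0.0, params.lamin_dot_jitter, u.shape)
            u /= np.linalg.norm(u, axis=1, keepdims=True)
        amps = params.lamin_dot_amplitude * rng.lognormal(0.0, params.lamin_amplitude_cv, n_dots)
        for p, amp in zip(c + u * a, amps):
            _render_gaussian_spot(
                lamin, p, amp, params.psf_sigma_um, voxel_size,
                radial_cutoff_um=params.shell_thickness_um / 2,
            )
    # the lamina sits just beneath the nuclear envelope: keep only the
    # staining inside the chromatin boundary, so the slightly-grown
    # segmentation masks can cover it entirely
    lamin[~interior] = 0.0

    spot_nucleus, spot_pos, spot_r, spot_d = [], [], [], []
    for nuc_idx, r, amp in params.spots_spec:
        c, a = centers[nuc_idx], semiaxes[nuc_idx]
        u = uniform_directions(rng, 1)[0]
        pos = c + (1.0 - r) * (a * u)  # ellipsoidal radius m = 1 - r
        _render_gaussian_spot(probe, pos, amp, params.psf_sigma_um, voxel_size)
        spot_nucleus.append(nuc_idx)
        spot_pos.append(pos)
        spot_r.append(r)
        spot_d.append(surface_distance(pos, c, a))

    clean = ImageStack(
        np.clip(np.rint(np.stack([dna, probe, lamin])), 0, np.iinfo(np.uint16).max).astype(
            np.uint16
        ),
        CHANNEL_ROLES,
        params.voxel_size_zyx,
    )
    if params.background == 0 and params.read_noise_sd == 0:
        stack = clean
    else:
        noise_seed = int(np.random.default_rng(params.seed + 1).integers(0, 2**31 - 1))
        stack = apply_noise(clean, params.background, params.read_noise_sd, noise_seed)

    truth = GroundTruth(
        nucleus_centers_um=centers,
        nucleus_semiaxes_um=semiaxes,
        spot_nucleus=np.array(spot_nucleus, dtype=int),
        true_spot_positions_um=np.array(spot_pos, dtype=float).reshape(-1, 3),
        true_radial_positions=np.array(spot_r, dtype=float),
        true_shell_distances_um=np.array(spot_d, dtype=float),
    )
    return stack, truth


def random_spots_spec(
    n_nuclei: int,
    r_mean: float,
    r_sd: float,
    amplitude: float,
    rng: np.random.Generator,
    spots_per_nucleus: int = 2,
) -> list[tuple[int, float, float]]:
    """Draw a spots_spec with radial positions ~ N(r_mean, r_sd) clipped to [0.02, 0.98].

    Emulates a condition in which a locus sits at a characteristic normalized
    distance from the periphery (e.g. lamina-tethered vs released loci).
    """
    spec = []
    for nuc in range(n_nuclei):
        for _ in range(spots_per_nucleus):
            r = float(np.clip(rng.normal(r_mean, r_sd), 0.02, 0.98))
            spec.append((nuc, r, amplitude))
    return spec
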