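import numpy as np
import pytest

from perifish import SceneParams, SegmentationParams, generate_scene, segment_nuclei


@pytest.fixture(scope="session")
def noiseless_scene():
    """Two well-separated nuclei, no noise: the workhorse for recovery tests."""
    params = SceneParams(
        shape_zyx=(16, 128, 128),
        n_nuclei=2,
        nucleus_semiaxes_um=(1.5, 2.0),
        spots_spec=[(0, 0.5, 500.0), (1, 0.25, 500.0)],
        background=0.0,
        read_noise_sd=0.0,
        seed=42,
    )
    return params, *generate_scene(params)


@pytest.fixture(scope="session")
def noisy_scene():
    """Same geometry as the noiseless scene but with realistic noise."""
    params = SceneParams(
        shape_zyx=(16, 128, 128),
        n_nuclei=2,
        nucleus_semiaxes_um=(1.5, 2.0),
        spots_spec=[(0, 0.5, 500.0), (1, 0.25, 500.0)],
        seed=42,
    )
    return params, *generate_scene(params)


@pytest.fixture(scope="session")
def segmented_noiseless(noiseless_scene):
    params, stack, truth = noiseless_scene
    return stack, truth, segment_nuclei(stack, SegmentationParams())


@pytest.fixture(scope="session")
def spherical_scene():
    """Noiseless spherical nuclei at near-isotropic sampling, for 3D
    distance recovery (the lamina is densely resolvable here)."""
    params = SceneParams(
        shape_zyx=(48, 128, 128),
        voxel_size_zyx=(0.1, 0.1, 0.1),
        psf_sigma_um=(0.12, 0.08, 0.08),
        n_nuclei=2,
        nucleus_semiaxes_um=(1.5, 1.9),
        spherical=True,
        spots_spec=[(0, 0.2, 500.0), (0, 0.5, 500.0), (0, 0.8, 500.0),
                    (1, 0.3, 500.0), (1, 0.6, 500.0), (1, 0.9, 500.0)],
        background=0.0,
        read_noise_sd=0.0,
        seed=11,
    )
    return params, *generate_scene(params)


def brute_force_median(volume: np.ndarray, size_zyx) -> np.ndarray:
    """Per-voxel sort-and-pick-middle median with edge-including reflect
    padding (numpy's "symmetric", matching scipy.ndimage's "reflect")."""
    pads = [(s // 2, s // 2) for s in size_zyx]
    padded = np.pad(volume, pads, mode="symmetric")
    out = np.empty_like(volume)
    for z in range(volume.shape[0]):
        for y in range(volume.shape[1]):
            for x in range(volume.shape[2]):
                window = padded[z : z + size_zyx[0], y : y + size_zyx[1], x : x + size_zyx[2]]
                out[z, y, x] = np.sort(window.ravel())[window.size // 2]
    return out


def brute_force_otsu(values: np.ndarray) -> float:
    """Exhaustive scan over candidate thresholds maximizing between-class
    variance; class rule is value > threshold; lowest qualifying wins."""
    values = np.asarray(values, dtype=float).ravel()
    candidates = np.unique(values)[:-1]  # highest value cannot be a threshold
    best_t, best_v = None, -np.inf
    n = values.size
    for t in candidates:
        lo = values[values <= t]
        hi = values[values > t]
        w0, w1 = lo.size / n, hi.size / n
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v + 1e-12:
            best_v, best_t = v, t
    return float(best_t)
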