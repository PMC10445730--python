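"""Ellipsoid geometry used by the scene generator and ground truth.

Nuclei are modelled as axis-aligned ellipsoids. The normalized radial
coordinate of a point follows the convention used throughout the package:
1 at the nucleus centre, 0 on the boundary.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq


def ellipsoidal_radius(point: np.ndarray, center: np.ndarray, semiaxes: np.ndarray) -> float:
    """Return ``m = ||(p - c) / a||``: 0 at the centre, 1 on the surface."""
    return float(np.linalg.norm((np.asarray(point, float) - center) / semiaxes))


def surface_distance(point, center, semiaxes) -> float:
    """Exact Euclidean distance from ``point`` to the ellipsoid surface.

    For spheres this is ``|R - |p - c||`` in closed form. For general
    axis-aligned ellipsoids the nearest surface point solves

        s_i = a_i^2 y_i / (a_i^2 + t),   sum_i (s_i / a_i)^2 = 1

    for the Lagrange multiplier ``t`` (y = p - c), found by bracketed
    root-finding. A point at the centre is at distance ``min(a)`` (the
    smallest semi-axis) from the surface.
    """
    center = np.asarray(center, float)
    semiaxes = np.asarray(semiaxes, float)
    y = np.asarray(point, float) - center
    if np.allclose(semiaxes, semiaxes[0]):
        return float(abs(semiaxes[0] - np.linalg.norm(y)))
    r = np.linalg.norm(y)
    if r == 0.0:
        return float(semiaxes.min())

    a2 = semiaxes**2

    def f(t: float) -> float:
        return float(np.sum((semiaxes * y / (a2 + t)) ** 2) - 1.0)

    # t ranges over (-min(a_i^2 with y_i != 0), inf); f is strictly decreasing.
    active = np.abs(y) > 1e-300
    t_lo = -float(a2[active].min()) + 1e-12
    if f(t_lo) <= 0:
        # nearly degenerate (point on a symmetry axis); fall back to dense
        # sampling of the surface along the meridian through the point.
        return _surface_distance_sampled(y, semiaxes)
    t_hi = max(r * semiaxes.max(), a2.max())
    while f(t_hi) > 0:
        t_hi *= 2.0
    t = brentq(f, t_lo, t_hi, xtol=1e-14, rtol=1e-15)
    s = a2 * y / (a2 + t)
    return float(np.linalg.norm(s - y))


def _surface_distance_sampled(y: np.ndarray, semiaxes: np.ndarray, n: int = 20000) -> float:
    rng = np.random.default_rng(0)
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    pts = u * semiaxes
    return float(np.min(np.linalg.norm(pts - y, axis=1)))


def uniform_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    """Draw ``n`` unit vectors uniformly on the sphere, shape (n, 3)."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v


def fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit vectors on the sphere (Fibonacci lattice), (n, 3).

    Unlike random directions, the lattice has no large empty holes, so a
    point cloud built on it covers the surface with bounded gaps.
    """
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.cos(phi), np.sin(phi) * np.sin(theta), np.sin(phi) * np.cos(theta)]
    )
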