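"""Planar polygon primitives shared by the mechanics, imaging and synthdata modules.

Polygons are (n, 2) float arrays of vertices in physical units (µm),
ordered either way; closed rings are accepted (the closing vertex is
dropped).  Signed quantities follow the shoelace convention; public
functions return magnitudes.
"""

from __future__ import annotations

import numpy as np


def as_polygon(vertices) -> np.ndarray:
    """Validate and normalise a vertex list to an open (n, 2) array."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise ValueError("polygon needs an (n>=3, 2) vertex array")
    if np.allclose(v[0], v[-1]) and v.shape[0] > 3:
        v = v[:-1]
    return v


def signed_area(vertices) -> float:
    """Shoelace signed area; positive for counter-clockwise order."""
    v = as_polygon(vertices)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_area(vertices) -> float:
    return abs(signed_area(vertices))


def polygon_perimeter(vertices) -> float:
    v = as_polygon(vertices)
    d = np.diff(np.vstack([v, v[:1]]), axis=0)
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


def polygon_centroid(vertices) -> np.ndarray:
    """Area centroid (not the vertex mean)."""
    v = as_polygon(vertices)
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    if a == 0.0:
        raise ValueError("degenerate polygon (zero area)")
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


def polygon_second_moments(vertices) -> tuple[float, float, float]:
    """Central second moments (mu_xx, mu_yy, mu_xy) of the polygon interior.

    Exact Green's-theorem formulas, normalised by area (per-unit-area
    moments, i.e. the covariance of a uniform density over the polygon).
    """
    v = as_polygon(vertices)
    c = polygon_centroid(v)
    x, y = v[:, 0] - c[0], v[:, 1] - c[1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    ixx = np.sum(cross * (x * x + x * xn + xn * xn)) / 12.0
    iyy = np.sum(cross * (y * y + y * yn + yn * yn)) / 12.0
    ixy = np.sum(cross * (x * yn + 2 * x * y + 2 * xn * yn + xn * y)) / 24.0
    return float(ixx / a), float(iyy / a), float(ixy / a)


def star_polygon(
    center: tuple[float, float],
    mean_radius: float,
    n_vertices: int = 64,
    harmonics: dict[int, tuple[float, float]] | None = None,
    rotation: float = 0.0,
) -> np.ndarray:
    """Star-convex polygon with radial cosine harmonics.

    ``harmonics`` maps mode k -> (amplitude, phase); the radius is
    r(t) = mean_radius * (1 + sum_k a_k cos(k t + phi_k)).
    """
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    r = np.ones_like(t)
    for k, (amp, phase) in (harmonics or {}).items():
        r = r + amp * np.cos(k * t + phase)
    if np.any(r <= 0):
        raise ValueError("harmonic amplitudes collapse the radius")
    r = mean_radius * r
    ang = t + rotation
    return np.column_stack([center[0] + r * np.cos(ang), center[1] + r * np.sin(ang)])


def scale_to_area(vertices, target_area: float) -> np.ndarray:
    """Isotropically rescale a polygon about its centroid to a target area."""
    if target_area <= 0:
        raise ValueError("target area must be positive")
    v = as_polygon(vertices)
    c = polygon_centroid(v)
    s = np.sqrt(target_area / polygon_area(v))
    return c + (v - c) * s
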