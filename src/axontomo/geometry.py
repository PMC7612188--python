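"""Paths, local frames and Euler-angle conventions.

Coordinates are physical, in nanometres, right-handed (x, y, z).  Volumes are
stored in (z, y, x) voxel order with the centre of voxel (0, 0, 0) at the
origin.  Orientations are intrinsic Z-X-Z Euler triplets (phi, theta, psi) in
degrees; the rotation matrix R maps box-frame vectors into the tomogram frame,
and the box z-axis maps onto the local filament tangent.  The in-plane (spin)
angle about the filament axis is psi.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def euler_to_matrix(phi: float, theta: float, psi: float) -> np.ndarray:
    """Rotation matrix for intrinsic Z-X-Z Euler angles in degrees."""
    return Rotation.from_euler("ZXZ", [phi, theta, psi], degrees=True).as_matrix()


def matrix_to_euler(R: np.ndarray) -> tuple[float, float, float]:
    phi, theta, psi = Rotation.from_matrix(R).as_euler("ZXZ", degrees=True)
    return float(phi), float(theta), float(psi)


def wrap_angle(a):
    """Wrap degrees into (-180, 180]."""
    a = np.asarray(a, dtype=float)
    out = -((-a + 180.0) % 360.0 - 180.0)
    return out if out.ndim else float(out)


def path_arclength(points: np.ndarray) -> np.ndarray:
    """Cumulative arclength (nm) along a polyline, starting at 0."""
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_path(points: np.ndarray, arclengths: np.ndarray) -> np.ndarray:
    """Positions at given arclengths by linear interpolation along the polyline."""
    points = np.asarray(points, dtype=float)
    s = path_arclength(points)
    out = np.empty((len(arclengths), 3))
    for k in range(3):
        out[:, k] = np.interp(arclengths, s, points[:, k])
    return out


def path_tangents(samples: np.ndarray) -> np.ndarray:
    """Unit tangents by central differences (one-sided at the ends)."""
    samples = np.asarray(samples, dtype=float)
    t = np.gradient(samples, axis=0)
    n = np.linalg.norm(t, axis=1, keepdims=True)
    if np.any(n < 1e-12):
        raise ValueError("degenerate path: repeated points give zero tangents")
    return t / n


def parallel_transport_frames(tangents: np.ndarray) -> np.ndarray:
    """Rotation matrices whose z-columns follow the tangents smoothly.

    The first frame picks an arbitrary normal; subsequent frames are obtained
    by the minimal rotation taking one tangent to the next, which avoids the
    frame flips a naive Frenet construction produces on near-straight paths.
    """
    tangents = np.asarray(tangents, dtype=float)
    n = len(tangents)
    frames = np.empty((n, 3, 3))
    t0 = tangents[0]
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, t0)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    x = ref - np.dot(ref, t0) * t0
    x /= np.linalg.norm(x)
    y = np.cross(t0, x)
    frames[0] = np.column_stack([x, y, t0])
    for i in range(1, n):
        a, b = tangents[i - 1], tangents[i]
        v = np.cross(a, b)
        s = np.linalg.norm(v)
        c = float(np.dot(a, b))
        if s < 1e-12:
            R = np.eye(3) if c > 0 else -np.eye(3)
        else:
            vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
            R = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
        x = R @ frames[i - 1][:, 0]
        x -= np.dot(x, b) * b
        x /= np.linalg.norm(x)
        y = np.cross(b, x)
        frames[i] = np.column_stack([x, y, b])
    return frames


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()


def fibonacci_sphere(n: int) -> np.ndarray:
    """Roughly uniform unit directions (n, 3) via the golden-spiral lattice."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
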