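"""Rotation algebra for particle orientations.

Orientations are ZYZ intrinsic Euler triplets (phi, theta, psi) in degrees,
composed as ``R = Rz(phi) @ Ry(theta) @ Rz(psi)`` — the rot/tilt/psi
composition used by RELION particle tables. Only *relative* rotations between
neighbouring particles enter the downstream statistics, so any consistent
convention would leave those invariant; this one is pinned for round-trip
determinism.

The hemisphere map sends a rotated reference vector (the image of (0, 0, 1)
under a relative rotation) to a planar disc by stereographic projection:
vectors with z > 0 to the northern map, z <= 0 to the southern map. The north
pole of the map is zero relative rotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HemispherePoint",
    "euler_to_matrix",
    "eulers_to_matrices",
    "matrix_to_euler",
    "relative_rotation",
    "rotated_pole",
    "stereographic_project",
    "random_eulers",
    "validate_rotation",
]

_GIMBAL_EPS = 1e-7


@dataclass(frozen=True)
class HemispherePoint:
    """Planar image of a unit vector under two-sided stereographic projection."""

    u: float
    v: float
    hemisphere: str  # "north" | "south"

    def __post_init__(self) -> None:
        if self.u**2 + self.v**2 > 1.0 + 1e-9:
            raise ValueError("hemisphere point escapes the closed unit disc")


def _rz(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _ry(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def euler_to_matrix(euler: tuple[float, float, float]) -> np.ndarray:
    """ZYZ intrinsic Euler triplet (degrees) -> rotation matrix.

    ``R = Rz(phi) @ Ry(theta) @ Rz(psi)``; total on finite input.
    """
    phi, theta, psi = (float(a) for a in euler)
    if not all(np.isfinite([phi, theta, psi])):
        raise ValueError(f"non-finite Euler angles {euler!r}")
    return _rz(phi) @ _ry(theta) @ _rz(psi)


def eulers_to_matrices(eulers: np.ndarray) -> np.ndarray:
    """Vectorised euler_to_matrix: (n, 3) degrees -> (n, 3, 3)."""
    e = np.radians(np.asarray(eulers, dtype=float))
    cph, sph = np.cos(e[:, 0]), np.sin(e[:, 0])
    cth, sth = np.cos(e[:, 1]), np.sin(e[:, 1])
    cps, sps = np.cos(e[:, 2]), np.sin(e[:, 2])
    R = np.empty((len(e), 3, 3))
    R[:, 0, 0] = cph * cth * cps - sph * sps
    R[:, 0, 1] = -cph * cth * sps - sph * cps
    R[:, 0, 2] = cph * sth
    R[:, 1, 0] = sph * cth * cps + cph * sps
    R[:, 1, 1] = -sph * cth * sps + cph * cps
    R[:, 1, 2] = sph * sth
    R[:, 2, 0] = -sth * cps
    R[:, 2, 1] = sth * sps
    R[:, 2, 2] = cth
    return R


def validate_rotation(R: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError(f"rotation matrix must be 3x3, got {R.shape}")
    if not np.allclose(R.T @ R, np.eye(3), atol=tol) or abs(np.linalg.det(R) - 1.0) > tol:
        raise ValueError("matrix is not a proper rotation (orthonormal, det +1)")
    return R


def matrix_to_euler(R: np.ndarray) -> tuple[tuple[float, float, float], bool]:
    """Rotation matrix -> ZYZ Euler triplet (degrees) and a gimbal flag.

    At theta ~ 0 or 180 only phi+psi (resp. phi-psi) is determined; the
    convention psi = 0 breaks the tie and the flag is set True.
    """
    R = validate_rotation(R)
    cth = np.clip(R[2, 2], -1.0, 1.0)
    theta = np.degrees(np.arccos(cth))
    sth = np.sqrt(max(0.0, 1.0 - cth * cth))
    if sth > _GIMBAL_EPS:
        phi = np.degrees(np.arctan2(R[1, 2], R[0, 2]))
        psi = np.degrees(np.arctan2(R[2, 1], -R[2, 0]))
        return (float(phi), float(theta), float(psi)), False
    if cth > 0:  # theta ~ 0: R = Rz(phi + psi)
        phi = np.degrees(np.arctan2(R[1, 0], R[0, 0]))
        return (float(phi), 0.0, 0.0), True
    # theta ~ 180: R = Rz(phi - psi) @ diag(-1, 1, -1)
    phi = np.degrees(np.arctan2(-R[1, 0], -R[0, 0]))
    return (float(phi), 180.0, 0.0), True


def relative_rotation(
    neighbor: tuple[float, float, float], reference: tuple[float, float, float]
) -> np.ndarray:
    """Rotation of the neighbour expressed in the reference particle's frame.

    Returns ``R(reference)^-1 @ R(neighbor)``; the identity when the two
    orientations coincide.
    """
    return euler_to_matrix(reference).T @ euler_to_matrix(neighbor)


def rotated_pole(R: np.ndarray) -> np.ndarray:
    """Image of the reference vector (0, 0, 1) under a rotation (unit 3-vector)."""
    return np.asarray(R, dtype=float)[:, 2].copy()


def stereographic_project(v: np.ndarray) -> HemispherePoint:
    """Two-sided stereographic projection of a unit vector into the unit disc.

    z > 0 routes to the northern map (u, v) = (x, y)/(1 + z); z <= 0 to the
    southern map (x, y)/(1 - z). Both maps send their hemisphere into the
    closed unit disc; (0, 0, 1) lands at the origin of the northern map.
    """
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if abs(n - 1.0) > 1e-6:
        raise ValueError(f"expected a unit vector, |v| = {n}")
    x, y, z = v / n
    if z > 0:
        return HemispherePoint(x / (1.0 + z), y / (1.0 + z), "north")
    return HemispherePoint(x / (1.0 - z), y / (1.0 - z), "south")


def random_eulers(n: int, rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform random orientations as (n, 3) ZYZ Euler degrees.

    phi, psi ~ U[-180, 180); cos(theta) ~ U[-1, 1] gives the uniform measure
    on SO(3) in the ZYZ chart.
    """
    phi = rng.uniform(-180.0, 180.0, n)
    psi = rng.uniform(-180.0, 180.0, n)
    theta = np.degrees(np.arccos(rng.uniform(-1.0, 1.0, n)))
    return np.column_stack([phi, theta, psi])
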