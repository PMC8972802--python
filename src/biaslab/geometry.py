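"""Poses, Euler-angle conventions and rotation-group utilities.

Angles follow the ZYZ intrinsic convention used by RELION-style STAR files:
a pose (rot, tilt, psi) in degrees corresponds to the rotation matrix
``A = Rz(rot) @ Ry(tilt) @ Rz(psi)``, and a projection image at that pose is
the line integral of the volume along the rotated z axis (the third column
of ``A``).  In-plane shifts are in pixels, applied after rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.transform import Rotation


@dataclass(frozen=True)
class Pose:
    """Orientation (three ZYZ Euler angles, degrees) plus in-plane shift (pixels)."""

    rot: float = 0.0
    tilt: float = 0.0
    psi: float = 0.0
    shift_x: float = 0.0
    shift_y: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.tilt <= 180.0:
            raise ValueError(f"tilt must be in [0, 180], got {self.tilt}")

    def matrix(self) -> np.ndarray:
        return euler_to_matrix(self.rot, self.tilt, self.psi)

    def with_shift(self, shift_x: float, shift_y: float) -> "Pose":
        return replace(self, shift_x=shift_x, shift_y=shift_y)


def euler_to_matrix(rot: float, tilt: float, psi: float) -> np.ndarray:
    """Rotation matrix A = Rz(rot) Ry(tilt) Rz(psi) (intrinsic ZYZ, degrees)."""
    return Rotation.from_euler("ZYZ", [rot, tilt, psi], degrees=True).as_matrix()


def matrix_to_euler(a: np.ndarray) -> tuple[float, float, float]:
    rot, tilt, psi = Rotation.from_matrix(a).as_euler("ZYZ", degrees=True)
    if tilt < 0:  # fold into the tilt in [0, 180] branch
        rot, tilt, psi = rot + 180.0, -tilt, psi + 180.0
    rot = ((rot + 180.0) % 360.0) - 180.0
    psi = ((psi + 180.0) % 360.0) - 180.0
    return float(rot), float(tilt), float(psi)


def angular_distance(p1: Pose, p2: Pose) -> float:
    """Geodesic distance on SO(3) between two poses, in degrees.

    arccos((trace(R1 R2^T) - 1) / 2), ignoring in-plane shifts.
    """
    r = p1.matrix() @ p2.matrix().T
    c = (np.trace(r) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def fibonacci_directions(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the sphere (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = np.pi * (1.0 + 5.0**0.5) * i
    s = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)


def direction_to_euler(d: np.ndarray) -> tuple[float, float]:
    """(rot, tilt) such that the viewing axis A(rot, tilt, 0) @ ez equals d."""
    d = np.asarray(d, dtype=float)
    d = d / np.linalg.norm(d)
    tilt = float(np.degrees(np.arccos(np.clip(d[2], -1.0, 1.0))))
    rot = float(np.degrees(np.arctan2(d[1], d[0]))) if tilt > 1e-9 else 0.0
    return rot, tilt


def mean_pose(poses: list[Pose]) -> Pose:
    """Chordal (quaternion) mean orientation with averaged shifts."""
    rots = Rotation.from_matrix(np.stack([p.matrix() for p in poses]))
    rot, tilt, psi = matrix_to_euler(rots.mean().as_matrix())
    sx = float(np.mean([p.shift_x for p in poses]))
    sy = float(np.mean([p.shift_y for p in poses]))
    return Pose(rot, tilt, psi, sx, sy)
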