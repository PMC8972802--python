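"""The cubic density-map container used throughout the package."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Volume:
    """A real-valued cubic 3-D density grid.

    data is indexed [z, y, x]; the real-space origin is the voxel at index
    ``box // 2`` along every axis. voxel_size is in Å per voxel.
    """

    data: np.ndarray
    voxel_size: float = 1.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or len(set(self.data.shape)) != 1:
            raise ValueError("volume must be a cubic 3-D grid")
        if self.box < 16 or self.box % 2 != 0:
            raise ValueError(f"box must be even and >= 16, got {self.box}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def box(self) -> int:
        return self.data.shape[0]

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.voxel_size)

    def __add__(self, other: "Volume") -> "Volume":
        self._check_match(other)
        return Volume(self.data + other.data, self.voxel_size)

    def __sub__(self, other: "Volume") -> "Volume":
        self._check_match(other)
        return Volume(self.data - other.data, self.voxel_size)

    def __mul__(self, scalar: float) -> "Volume":
        return Volume(self.data * scalar, self.voxel_size)

    __rmul__ = __mul__

    def _check_match(self, other: "Volume") -> None:
        if other.box != self.box:
            raise ValueError(f"box mismatch: {self.box} vs {other.box}")
        if not np.isclose(other.voxel_size, self.voxel_size):
            raise ValueError("voxel size mismatch")


def radial_coordinates(box: int) -> np.ndarray:
    """Voxel distance from the centered origin, shape (box, box, box)."""
    q = np.arange(box) - box // 2
    qz, qy, qx = np.meshgrid(q, q, q, indexing="ij")
    return np.sqrt(qx**2 + qy**2 + qz**2)
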