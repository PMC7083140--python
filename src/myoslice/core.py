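"""Core containers shared across the imaging and simulation modules."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelStack", "DegenerateInputError", "InvalidSpecError"]


class InvalidSpecError(ValueError):
    """A generator or analysis specification is internally inconsistent."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but carries no usable signal (e.g. constant image)."""


@dataclass
class VoxelStack:
    """Calibrated 3D intensity volume.

    Axes are ordered z-y-x (plane, row, column), 0-based. ``voxel_size_um``
    is (dz, dy, dx) in micrometres. Intensities are non-negative and finite;
    confocal counts after attenuation correction may be float.
    """

    intensities: np.ndarray
    voxel_size_um: tuple[float, float, float]
    channel_label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise InvalidSpecError("stack must be 3D (z, y, x)")
        if not np.all(np.isfinite(self.intensities)):
            raise InvalidSpecError("stack intensities must be finite")
        if self.intensities.size and self.intensities.min() < 0:
            raise InvalidSpecError("stack intensities must be >= 0")
        vs = tuple(float(v) for v in self.voxel_size_um)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise InvalidSpecError("voxel_size_um must be three positive values")
        self.voxel_size_um = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def z_depths_um(self) -> np.ndarray:
        """Depth of each plane below the stack surface, in micrometres."""
        return np.arange(self.shape[0]) * self.voxel_size_um[0]

    def copy_with(self, intensities: np.ndarray) -> "VoxelStack":
        return VoxelStack(
            intensities=intensities,
            voxel_size_um=self.voxel_size_um,
            channel_label=self.channel_label,
            metadata=dict(self.metadata),
        )
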