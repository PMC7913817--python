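"""In-memory CT volume container and tissue label conventions.

Axis convention (fixed, right-handed): array axes are ordered
``(sagittal, coronal, axial)`` with 0-based voxel indices.  Axis 0 (x) runs
left-to-right, axis 1 (y) runs anterior-to-posterior, axis 2 (z) runs
cranial-to-caudal.  The physical position of voxel ``(i, j, k)`` is
``(i*sx, j*sy, k*sz)`` millimetres, i.e. voxel centres sit on the spacing
grid with the centre of voxel 0 at the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Any

import numpy as np


class Tissue(IntEnum):
    """Ground-truth voxel labels (mutually exclusive)."""

    BACKGROUND = 0
    TRABECULAR = 1
    CORTICAL = 2
    ENDPLATE = 3
    PLEXUS = 4
    SAT = 5
    VAT = 6
    MUSCLE = 7
    ORGAN = 8
    PHANTOM_PHASE_1 = 9
    PHANTOM_PHASE_2 = 10
    CUTIS = 11


#: Anatomical order of the thirteen measured vertebral levels.
LEVELS: tuple[str, ...] = (
    "Th5", "Th6", "Th7", "Th8", "Th9", "Th10",
    "Th11", "Th12", "L1", "L2", "L3", "L4", "L5",
)


@dataclass
class ScanVolume:
    """A 3-D CT volume in Hounsfield units with voxel spacing and metadata.

    Parameters
    ----------
    data:
        float32 HU array, axes ``(sagittal, coronal, axial)``.
    spacing:
        voxel spacing ``(sx, sy, sz)`` in mm.
    meta:
        scan metadata: per-level vertebral geometry (centres in mm, heights,
        radii), the L4/5 disc plane position, and generator provenance.
        Synthetic scans always carry this; it stands in for the manual
        level identification a radiologist performs on clinical CT.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("ScanVolume.data must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centres along one axis."""
        return np.arange(self.shape[axis]) * self.spacing[axis]
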