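"""In-memory containers for 3-D image volumes and lung-ROI masks.

Every stage of the pipeline consumes a :class:`Volume3D` — a scalar
intensity grid with physical voxel spacing in millimetres — and, for
quantification, a congruent binary :class:`LungMask` delimiting the lung
region of interest (heart and attached great vessels excluded by
construction of the mask).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

Triple = Tuple[float, float, float]

#: Echo times (ms) of the two ultrashort-echo-time MRI readouts.
TE_SHORT_MS = 0.324
TE_LONG_MS = 1.0


def _default_affine(voxel_mm: Triple) -> np.ndarray:
    """Affine mapping 0-based voxel indices to world mm (voxel centres)."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_mm
    return aff


@dataclass
class Volume3D:
    """A 3-D grid of scalar intensities with physical spacing.

    Parameters
    ----------
    data
        3-D array of finite scalar intensities.
    voxel_mm
        Voxel edge lengths along each array axis, in mm. All positive.
    modality
        One of ``"MRI"``, ``"PET"``, ``"CT"``.
    echo_time_ms
        Echo time for MRI volumes (0.324 ms short / 1.0 ms long);
        ``None`` for other modalities.
    affine
        4x4 matrix mapping 0-based voxel indices to world coordinates in
        mm.  Defaults to a diagonal scaling by ``voxel_mm``.
    """

    data: np.ndarray
    voxel_mm: Triple
    modality: str = "MRI"
    echo_time_ms: Optional[float] = None
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D requires a 3-D grid, got ndim={self.data.ndim}")
        self.voxel_mm = tuple(float(v) for v in self.voxel_mm)  # type: ignore[assignment]
        if len(self.voxel_mm) != 3 or any(v <= 0 for v in self.voxel_mm):
            raise ValueError(f"voxel_mm must be 3 positive reals, got {self.voxel_mm}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume3D intensities must be finite")
        if self.affine is None:
            self.affine = _default_affine(self.voxel_mm)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_mm))

    def extent_mm(self) -> Triple:
        """Physical field-of-view edge lengths (mm) along each axis."""
        return tuple(n * v for n, v in zip(self.data.shape, self.voxel_mm))  # type: ignore[return-value]


@dataclass
class LungMask:
    """Binary lung-ROI grid congruent with a companion :class:`Volume3D`."""

    mask: np.ndarray
    voxel_mm: Triple

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("LungMask requires a 3-D grid")
        self.voxel_mm = tuple(float(v) for v in self.voxel_mm)  # type: ignore[assignment]
        if any(v <= 0 for v in self.voxel_mm):
            raise ValueError("voxel_mm components must be positive")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_mm))

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3

    def check_congruent(self, vol: Volume3D) -> None:
        if self.mask.shape != vol.data.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} incongruent with volume {vol.data.shape}"
            )
        if not np.allclose(self.voxel_mm, vol.voxel_mm):
            raise ValueError(
                f"mask spacing {self.voxel_mm} differs from volume {vol.voxel_mm}"
            )
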