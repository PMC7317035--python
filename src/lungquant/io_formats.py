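"""NIfTI volume I/O, isotropic resampling and per-scan metadata tables.

NIfTI-1 is the interchange format: world coordinates in mm, 0-based voxel
indices, affine mapping voxel centres.  Cross-modality work (MRI vs PET)
happens on isotropically resampled grids; the default target of 0.4 mm
matches the reconstructed PET grid so PET is never up-interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import List, Optional, Union

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import LungMask, Volume3D

#: Default isotropic grid spacing (mm) for cross-modality analysis.
DEFAULT_ISO_MM = 0.4

SCANMETA_COLUMNS = [
    "animal_id",
    "group",
    "day",
    "dose_MBq",
    "t_injection_iso8601",
    "t_scan_iso8601",
]


# ---------------------------------------------------------------------------
# Volumes


def read_volume(
    path: Union[str, Path],
    modality: str = "MRI",
    echo_time_ms: Optional[float] = None,
) -> Volume3D:
    """Read a single-volume NIfTI file into a :class:`Volume3D`.

    Raises
    ------
    ValueError
        If the file holds a non-3-D image or lacks voxel spacing.
    IOError
        If the file is missing or unreadable (truncated files raise rather
        than yielding a partial volume).
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata())
    except FileNotFoundError:
        raise
    except Exception as exc:  # nibabel raises various per-format errors
        raise IOError(f"could not read NIfTI volume {path}: {exc}") from exc
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"{path}: missing or invalid voxel spacing {zooms}")
    return Volume3D(
        data=data,
        voxel_mm=tuple(float(z) for z in zooms),
        modality=modality,
        echo_time_ms=echo_time_ms,
        affine=np.asarray(img.affine),
    )


def write_volume(vol: Volume3D, path: Union[str, Path]) -> None:
    """Write a :class:`Volume3D` as NIfTI-1; round-trips grid, spacing, affine."""
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), vol.affine)
    img.header.set_zooms(vol.voxel_mm)
    nib.save(img, str(path))


def read_mask(path: Union[str, Path]) -> LungMask:
    vol = read_volume(path, modality="MASK")
    return LungMask(mask=vol.data > 0.5, voxel_mm=vol.voxel_mm)


def write_mask(mask: LungMask, path: Union[str, Path]) -> None:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = mask.voxel_mm
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), aff)
    img.header.set_zooms(mask.voxel_mm)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Resampling


def _resample_grid(
    data: np.ndarray, voxel_mm, target_mm: float, order: int
) -> np.ndarray:
    if target_mm <= 0:
        raise ValueError(f"target spacing must be positive, got {target_mm}")
    zoom = [v / target_mm for v in voxel_mm]
    # grid_mode=True treats samples as cell centres so world extent is kept;
    # output shape per axis is round(n * old_mm / target_mm).  Edge
    # replication ("nearest") keeps constant volumes constant instead of
    # blending zeros into boundary voxels.
    return ndimage.zoom(
        data.astype(float), zoom, order=order, mode="nearest", grid_mode=True
    )


def resample_isotropic(
    vol: Volume3D, target_mm: float = DEFAULT_ISO_MM, order: str = "trilinear"
) -> Volume3D:
    """Resample a volume onto an isotropic grid of ``target_mm`` spacing.

    ``order`` is ``"trilinear"`` for image volumes or ``"nearest"`` for
    label-like data.  World extent is preserved to within one voxel.
    """
    if target_mm <= 0:
        raise ValueError(f"target spacing must be positive, got {target_mm}")
    orders = {"nearest": 0, "trilinear": 1}
    if order not in orders:
        raise ValueError(f"order must be one of {sorted(orders)}, got {order!r}")
    data = _resample_grid(vol.data, vol.voxel_mm, target_mm, orders[order])
    return Volume3D(
        data=data,
        voxel_mm=(target_mm,) * 3,
        modality=vol.modality,
        echo_time_ms=vol.echo_time_ms,
    )


def resample_mask_isotropic(mask: LungMask, target_mm: float = DEFAULT_ISO_MM) -> LungMask:
    """Nearest-neighbour resample of a binary mask; output stays binary."""
    if target_mm <= 0:
        raise ValueError(f"target spacing must be positive, got {target_mm}")
    data = _resample_grid(mask.mask.astype(float), mask.voxel_mm, target_mm, 0)
    return LungMask(mask=data > 0.5, voxel_mm=(target_mm,) * 3)


# ---------------------------------------------------------------------------
# Scan metadata


@dataclass
class ScanMeta:
    """Per-scan acquisition record: who, when, and the injected tracer dose."""

    animal_id: str
    group: str
    day: int
    dose_MBq: float
    t_injection: datetime
    t_scan: datetime
    notes: str = ""

    def __post_init__(self) -> None:
        if self.t_scan < self.t_injection:
            raise ValueError(
                f"{self.animal_id}: scan time {self.t_scan} precedes injection "
                f"{self.t_injection}"
            )
        if self.dose_MBq is not None and self.dose_MBq <= 0:
            raise ValueError(f"{self.animal_id}: dose must be positive, got {self.dose_MBq}")


def read_scan_meta(path: Union[str, Path]) -> List[ScanMeta]:
    df = pd.read_csv(path)
    missing = [c for c in SCANMETA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"scan metadata CSV missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(
            ScanMeta(
                animal_id=str(row["animal_id"]),
                group=str(row["group"]),
                day=int(row["day"]),
                dose_MBq=float(row["dose_MBq"]),
                t_injection=datetime.fromisoformat(str(row["t_injection_iso8601"])),
                t_scan=datetime.fromisoformat(str(row["t_scan_iso8601"])),
            )
        )
    return out


def write_scan_meta(records: List[ScanMeta], path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in records],
            "group": [r.group for r in records],
            "day": [r.day for r in records],
            "dose_MBq": [r.dose_MBq for r in records],
            "t_injection_iso8601": [r.t_injection.isoformat() for r in records],
            "t_scan_iso8601": [r.t_scan.isoformat() for r in records],
        }
    )
    df.to_csv(path, index=False)
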