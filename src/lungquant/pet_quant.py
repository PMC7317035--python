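"""FDG-PET quantification: decay correction, rigid MI registration, uptake.

The uptake read-out is a dimensionless dose fraction, not an SUV: total
in-ROI activity (MBq) divided by the injected dose decay-corrected to the
scan time, and additionally per mm³ of ROI.  ¹⁸F half-life is fixed at
109.77 min.  PET is rigidly registered onto the (isotropically resampled)
MRI frame by maximising mutual information of the joint intensity
histogram with a derivative-free optimiser capped at 200 iterations, the
MRI always serving as the fixed reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional, Tuple

import numpy as np
import SimpleITK as sitk

from .volume import LungMask, Volume3D

#: Physical half-life of fluorine-18, minutes.
F18_HALF_LIFE_MIN = 109.77


# ---------------------------------------------------------------------------
# Dose decay correction


@dataclass
class TracerDose:
    """Injected tracer dose and the clock times needed to decay-correct it.

    Either supply ``t_injection``/``t_reference`` as datetimes, or
    construct with :meth:`from_elapsed` giving the elapsed minutes
    directly.
    """

    injected_MBq: float
    t_injection: Optional[datetime] = None
    t_reference: Optional[datetime] = None
    half_life_min: float = F18_HALF_LIFE_MIN
    _elapsed_min: Optional[float] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.injected_MBq <= 0:
            raise ValueError(f"injected dose must be positive, got {self.injected_MBq}")
        if self.half_life_min <= 0:
            raise ValueError(f"half-life must be positive, got {self.half_life_min}")
        if self.elapsed_min < 0:
            raise ValueError(
                f"reference time precedes injection (elapsed {self.elapsed_min} min)"
            )

    @classmethod
    def from_elapsed(
        cls,
        injected_MBq: float,
        elapsed_min: float,
        half_life_min: float = F18_HALF_LIFE_MIN,
    ) -> "TracerDose":
        return cls(
            injected_MBq=injected_MBq,
            half_life_min=half_life_min,
            _elapsed_min=float(elapsed_min),
        )

    @property
    def elapsed_min(self) -> float:
        if self._elapsed_min is not None:
            return self._elapsed_min
        if self.t_injection is None or self.t_reference is None:
            raise ValueError("need t_injection and t_reference (or elapsed minutes)")
        return (self.t_reference - self.t_injection).total_seconds() / 60.0


def decay_correct(dose: TracerDose) -> float:
    """Dose remaining at the reference time: ``A0 * 2^(-dt / T_half)``, MBq."""
    return dose.injected_MBq * 2.0 ** (-dose.elapsed_min / dose.half_life_min)


# ---------------------------------------------------------------------------
# Rigid transform plumbing (SimpleITK physical space; note that converting a
# numpy grid to a SimpleITK image reverses axis order, so transform
# components are indexed (x, y, z) = array axes (2, 1, 0))


@dataclass
class RigidTransform:
    """6-parameter rigid motion: Euler rotations (deg) and translation (mm)."""

    rotations_deg: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    translations_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def to_sitk(self) -> sitk.Euler3DTransform:
        t = sitk.Euler3DTransform()
        t.SetCenter([float(c) for c in self.center])
        t.SetRotation(*[math.radians(a) for a in self.rotations_deg])
        t.SetTranslation([float(v) for v in self.translations_mm])
        return t

    @classmethod
    def from_sitk(cls, t: sitk.Euler3DTransform) -> "RigidTransform":
        return cls(
            rotations_deg=tuple(
                math.degrees(a) for a in (t.GetAngleX(), t.GetAngleY(), t.GetAngleZ())
            ),
            translations_mm=tuple(t.GetTranslation()),
            center=tuple(t.GetCenter()),
        )

    def inverse(self) -> "RigidTransform":
        inv = self.to_sitk().GetInverse()
        return RigidTransform.from_sitk(sitk.Euler3DTransform(inv.Downcast()))

    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix acting on physical points."""
        t = self.to_sitk()
        m = np.eye(4)
        m[:3, :3] = np.asarray(t.GetMatrix()).reshape(3, 3)
        c = np.asarray(t.GetCenter())
        off = np.asarray(t.GetTranslation()) + c - m[:3, :3] @ c
        m[:3, 3] = off
        return m

    def translation_voxels(self, vol: Volume3D) -> Tuple[float, float, float]:
        """Translation expressed in voxels per array axis of ``vol``."""
        tz, ty, tx = self.translations_mm[2], self.translations_mm[1], self.translations_mm[0]
        return (
            tz / vol.voxel_mm[0],
            ty / vol.voxel_mm[1],
            tx / vol.voxel_mm[2],
        )

    def as_dict(self) -> dict:
        return {
            "rotations_deg": list(self.rotations_deg),
            "translations_mm": list(self.translations_mm),
            "center_mm": list(self.center),
        }


def _to_sitk_image(vol: Volume3D) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.astype(np.float64)))
    img.SetSpacing(tuple(reversed(vol.voxel_mm)))
    return img


def _from_sitk_image(img: sitk.Image, template: Volume3D) -> Volume3D:
    data = sitk.GetArrayFromImage(img)
    return Volume3D(
        data=data,
        voxel_mm=tuple(reversed(img.GetSpacing())),
        modality=template.modality,
        echo_time_ms=template.echo_time_ms,
    )


def apply_rigid(vol: Volume3D, transform: RigidTransform, order: str = "trilinear") -> Volume3D:
    """Resample ``vol`` through ``transform`` onto its own grid.

    Follows the resampling convention: the output at grid point x holds the
    input interpolated at transform(x).
    """
    interp = {"trilinear": sitk.sitkLinear, "nearest": sitk.sitkNearestNeighbor}[order]
    img = _to_sitk_image(vol)
    out = sitk.Resample(img, img, transform.to_sitk(), interp, 0.0)
    return _from_sitk_image(out, vol)


# ---------------------------------------------------------------------------
# Mutual information and registration


def mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    """MI (nats) of the joint histogram of two equally-shaped arrays.

    Intensities are min-max scaled into ``bins`` bins.  Used as a direct
    metric probe; the registration itself optimises the equivalent Mattes
    formulation.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("arrays must have identical size")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("no information: constant image")
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def register_rigid_mi(
    moving: Volume3D,
    fixed: Volume3D,
    max_iterations: int = 200,
    mi_bins: int = 32,
) -> RigidTransform:
    """Rigid mutual-information registration of ``moving`` onto ``fixed``.

    The MRI reference is the fixed image; PET (or CT) moves.  The metric is
    Mattes mutual information on ``mi_bins`` histogram bins over all voxels
    (deterministic — no random sampling); the optimiser is Powell's
    derivative-free method capped at ``max_iterations`` iterations.  The
    returned transform maps fixed-image physical points into the moving
    image, ready for resampling the moving image onto the fixed grid.
    """
    for name, vol in (("moving", moving), ("fixed", fixed)):
        if np.ptp(vol.data) == 0:
            raise ValueError(f"no information: {name} image is constant")
    f_img = _to_sitk_image(fixed)
    m_img = _to_sitk_image(moving)

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=mi_bins)
    reg.SetMetricSamplingStrategy(reg.NONE)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsPowell(
        numberOfIterations=max_iterations,
        maximumLineIterations=25,
        stepLength=1.0,
        stepTolerance=1e-4,
        valueTolerance=1e-6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    init = sitk.CenteredTransformInitializer(
        f_img, m_img, sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY,
    )
    reg.SetInitialTransform(init, inPlace=False)
    final = reg.Execute(f_img, m_img)
    t = final.Downcast()
    if isinstance(t, sitk.CompositeTransform):  # registration wraps the result
        t = t.GetNthTransform(t.GetNumberOfTransforms() - 1).Downcast()
    return RigidTransform.from_sitk(sitk.Euler3DTransform(t))


def resample_to_fixed(
    moving: Volume3D, fixed: Volume3D, transform: RigidTransform, order: str = "trilinear"
) -> Volume3D:
    """Resample ``moving`` onto the grid of ``fixed`` through ``transform``."""
    interp = {"trilinear": sitk.sitkLinear, "nearest": sitk.sitkNearestNeighbor}[order]
    out = sitk.Resample(
        _to_sitk_image(moving), _to_sitk_image(fixed), transform.to_sitk(), interp, 0.0
    )
    return _from_sitk_image(out, moving)


# ---------------------------------------------------------------------------
# Fractional uptake


@dataclass
class UptakeResult:
    """Dose-fraction uptake inside the lung ROI."""

    fractional_uptake_total: float
    fractional_uptake_per_mm3: float
    roi_volume_mm3: float
    registration: Optional[RigidTransform] = None

    def to_dict(self) -> dict:
        return {
            "fractional_uptake_total": self.fractional_uptake_total,
            "fractional_uptake_per_mm3": self.fractional_uptake_per_mm3,
            "roi_volume_mm3": self.roi_volume_mm3,
            "registration": self.registration.as_dict() if self.registration else None,
        }


def fractional_uptake(
    pet: Volume3D,
    mask: LungMask,
    dose: TracerDose,
    calibration: float = 1.0,
    registration: Optional[RigidTransform] = None,
) -> UptakeResult:
    """In-ROI activity divided by the decay-corrected injected dose.

    ``calibration`` converts PET voxel values into MBq per voxel (scanner
    dependent; synthetic phantoms use 1).  The PET volume must already sit
    on the mask grid (register and resample first).
    """
    mask.check_congruent(pet)
    if mask.n_voxels == 0:
        raise ValueError("empty lung mask")
    corrected = decay_correct(dose)
    if corrected <= 0:
        raise ValueError("decay-corrected dose is zero")
    total_activity = float(pet.data[mask.mask].sum()) * calibration
    frac_total = total_activity / corrected
    roi_vol = mask.volume_mm3
    return UptakeResult(
        fractional_uptake_total=frac_total,
        fractional_uptake_per_mm3=frac_total / roi_vol,
        roi_volume_mm3=roi_vol,
        registration=registration,
    )
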