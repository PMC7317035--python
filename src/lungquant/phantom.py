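"""Synthetic dual-echo MR + PET lung phantoms and longitudinal cohorts.

The study design this generator emulates: rats imaged at days 0, 3, 7, 14,
21 and 28 after an intratracheal insult.  In-lung MR intensities follow a
two-component mixture — a dominant low-signal parenchyma mode and a
high-signal lesion mode — which is exactly the histogram structure the
threshold algorithm exploits.  PET activity is spatially coupled to the
lesion.  Cohorts carry three arms: saline controls whose lung volume grows
slowly with animal growth, "low responders" whose inflammatory volume bump
resolves toward control by the final day, and "high responders" whose lung
volume keeps rising.

Everything is seeded and bit-reproducible: the same spec and seed give
identical volumes voxel for voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .cohort import AnimalTimecourse, DayRecord
from .volume import LungMask, TE_LONG_MS, TE_SHORT_MS, Volume3D

import pandas as pd


# ---------------------------------------------------------------------------
# Specs


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of a single dual-echo MR + PET phantom.

    Intensities are arbitrary units (magnitude images, truncated at zero).
    ``pet_noise`` is the proportionality constant of a Gaussian noise model
    with variance proportional to the local mean — a desk-scale proxy for
    Poisson counting noise.
    """

    grid_shape: Tuple[int, int, int] = (64, 64, 64)
    voxel_mm: Tuple[float, float, float] = (0.4, 0.4, 0.4)
    lung_fraction: float = 0.3
    lesion_fraction: float = 0.1
    mu_low: float = 100.0
    mu_high: float = 300.0
    sigma_low: float = 20.0
    sigma_high: float = 20.0
    pet_background: float = 1.0
    pet_lesion_gain: float = 4.0
    pet_noise: float = 0.01
    fibrosis_contrast: float = 0.0  # extra short-echo lesion contrast, off by default
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) < 4 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 ints >= 4, got {self.grid_shape}")
        if any(v <= 0 for v in self.voxel_mm):
            raise ValueError(f"voxel_mm must be positive, got {self.voxel_mm}")
        if not 0 < self.lung_fraction < 1:
            raise ValueError(f"lung_fraction must lie in (0,1), got {self.lung_fraction}")
        # the lung is one ellipsoid inscribed in the grid: max fraction pi/6
        if self.lung_fraction >= np.pi / 6:
            raise ValueError(
                f"lung_fraction {self.lung_fraction} exceeds the inscribed-ellipsoid "
                f"maximum {np.pi / 6:.3f}"
            )
        if not 0 <= self.lesion_fraction < 1:
            raise ValueError(
                f"lesion_fraction must lie in [0,1); got {self.lesion_fraction} "
                f"(achievable maximum is the whole lung, fraction < 1)"
            )
        if self.mu_high <= self.mu_low:
            raise ValueError(f"mu_high ({self.mu_high}) must exceed mu_low ({self.mu_low})")
        if self.sigma_low <= 0 or self.sigma_high <= 0:
            raise ValueError("component standard deviations must be positive")
        if self.pet_background < 0 or self.pet_lesion_gain < 0 or self.pet_noise < 0:
            raise ValueError("PET parameters must be nonnegative")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_mm))

    @property
    def grid_volume_mm3(self) -> float:
        return float(np.prod(self.grid_shape)) * self.voxel_volume_mm3


@dataclass(frozen=True)
class CohortSpec:
    """Design of a longitudinal three-arm cohort.

    Lung-volume trajectories, relative to each arm's baseline:

    * control: ``1 + growth_rate * day`` (slow linear animal growth);
    * both challenged arms share an inflammation bump of relative amplitude
      ``bump_amplitude`` peaking at ``inflammation_peak_day``;
    * the low arm holds the bump until day 14 then decays so its final-day
      volume is ``low_final_gain`` times baseline (near control growth);
    * the high arm keeps rising to ``high_final_gain`` times baseline.

    ``noise_cv`` is multiplicative per-observation biological + measurement
    scatter (coefficient of variation).
    """

    n_control: int = 4
    n_low: int = 4
    n_high: int = 4
    days: Tuple[int, ...] = (0, 3, 7, 14, 21, 28)
    growth_rate: float = 0.05 / 28.0
    inflammation_peak_day: int = 7
    bump_amplitude: float = 0.15
    high_final_gain: float = 1.3
    low_final_gain: float = 1.05
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 1:
            raise ValueError("n_control must be >= 1 (control arm anchors the design)")
        if self.n_low < 0 or self.n_high < 0:
            raise ValueError("arm sizes must be nonnegative")
        days = tuple(int(d) for d in self.days)
        if 0 not in days:
            raise ValueError("days must contain the baseline day 0")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError(f"days must be strictly increasing, got {days}")
        if not self.high_final_gain > self.low_final_gain >= 1.0:
            raise ValueError(
                "need high_final_gain > low_final_gain >= 1, got "
                f"{self.high_final_gain} vs {self.low_final_gain}"
            )
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")


@dataclass
class PhantomTruth:
    """Ground truth of a generated phantom, for recovery tests."""

    lesion_mask: np.ndarray
    true_lesion_volume_mm3: float
    true_lung_volume_mm3: float
    component_params: Dict[str, float]


# ---------------------------------------------------------------------------
# Single phantom


def _ellipsoid_lung(spec: PhantomSpec) -> np.ndarray:
    """Boolean lung mask: one ellipsoid inscribed in the grid.

    Semi-axes are proportional to the grid half-extents, scaled so the
    analytic ellipsoid volume equals ``lung_fraction`` of the grid.
    """
    scale = (6.0 * spec.lung_fraction / np.pi) ** (1.0 / 3.0)
    semi = [scale * n / 2.0 for n in spec.grid_shape]
    centre = [(n - 1) / 2.0 for n in spec.grid_shape]
    grids = np.ogrid[tuple(slice(0, n) for n in spec.grid_shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centre, semi))
    return r2 <= 1.0


def _lesion_mask(spec: PhantomSpec, lung: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Lesion as the level set of a min-of-ellipsoids potential inside the lung.

    1–5 random ellipsoidal blobs seed the potential; taking exactly the
    ``n_target`` lowest-potential in-lung voxels makes the realised lesion
    volume match the requested fraction to one voxel.
    """
    n_lung = int(lung.sum())
    n_target = int(round(spec.lesion_fraction * n_lung))
    if n_target == 0:
        return np.zeros_like(lung)
    if n_target > n_lung:  # unreachable for lesion_fraction < 1; guard anyway
        raise ValueError(
            f"lesion does not fit inside lung: requested {n_target} voxels, "
            f"achievable maximum {n_lung}"
        )
    n_blobs = int(rng.integers(1, 6))
    centre = np.array([(n - 1) / 2.0 for n in spec.grid_shape])
    scale = (6.0 * spec.lung_fraction / np.pi) ** (1.0 / 3.0)
    lung_semi = np.array([scale * n / 2.0 for n in spec.grid_shape])
    grids = np.ogrid[tuple(slice(0, n) for n in spec.grid_shape)]

    potential = np.full(spec.grid_shape, np.inf)
    for _ in range(n_blobs):
        # blob centres well inside the lung (<= 60% of the normalised radius)
        while True:
            u = rng.uniform(-0.6, 0.6, size=3)
            if (u ** 2).sum() <= 0.36:
                break
        c = centre + u * lung_semi
        radii = rng.uniform(0.15, 0.35, size=3) * lung_semi
        phi = sum(((g - ci) / ri) ** 2 for g, ci, ri in zip(grids, c, radii))
        potential = np.minimum(potential, phi)

    potential = np.where(lung, potential, np.inf)
    flat = np.argsort(potential, axis=None, kind="stable")[:n_target]
    lesion = np.zeros(spec.grid_shape, dtype=bool)
    lesion.ravel()[flat] = True
    return lesion


def make_lung_phantom(
    spec: PhantomSpec,
) -> Tuple[Volume3D, Volume3D, Volume3D, LungMask, PhantomTruth]:
    """Generate (short-echo MR, long-echo MR, PET, lung mask, ground truth).

    In-lung MR intensities are a two-component Gaussian mixture truncated at
    zero; PET is ``pet_background`` plus ``pet_lesion_gain`` inside the
    lesion, with variance-proportional-to-mean Gaussian noise.
    """
    rng = np.random.default_rng(spec.seed)
    lung = _ellipsoid_lung(spec)
    lesion = _lesion_mask(spec, lung, rng)

    def mr_volume(echo_ms: float, lesion_mu: float) -> Volume3D:
        data = rng.normal(0.1 * spec.mu_low, spec.sigma_low, size=spec.grid_shape)
        paren = lung & ~lesion
        data[paren] = rng.normal(spec.mu_low, spec.sigma_low, size=int(paren.sum()))
        if lesion.any():
            data[lesion] = rng.normal(lesion_mu, spec.sigma_high, size=int(lesion.sum()))
        np.clip(data, 0.0, None, out=data)
        return Volume3D(data, spec.voxel_mm, modality="MRI", echo_time_ms=echo_ms)

    vol_long = mr_volume(TE_LONG_MS, spec.mu_high)
    vol_short = mr_volume(TE_SHORT_MS, spec.mu_high * (1.0 + spec.fibrosis_contrast))

    pet_mean = np.full(spec.grid_shape, spec.pet_background, dtype=float)
    pet_mean[lesion] += spec.pet_lesion_gain
    pet = pet_mean + rng.normal(0.0, 1.0, size=spec.grid_shape) * np.sqrt(
        spec.pet_noise * pet_mean
    )
    np.clip(pet, 0.0, None, out=pet)
    vol_pet = Volume3D(pet, spec.voxel_mm, modality="PET")

    mask = LungMask(mask=lung, voxel_mm=spec.voxel_mm)
    truth = PhantomTruth(
        lesion_mask=lesion,
        true_lesion_volume_mm3=float(lesion.sum()) * spec.voxel_volume_mm3,
        true_lung_volume_mm3=float(lung.sum()) * spec.voxel_volume_mm3,
        component_params={
            "mu_low": spec.mu_low,
            "mu_high": spec.mu_high,
            "sigma_low": spec.sigma_low,
            "sigma_high": spec.sigma_high,
            "pet_background": spec.pet_background,
            "pet_lesion_gain": spec.pet_lesion_gain,
            "lesion_fraction": spec.lesion_fraction,
            "lung_fraction": spec.lung_fraction,
        },
    )
    return vol_short, vol_long, vol_pet, mask, truth


# ---------------------------------------------------------------------------
# Longitudinal cohort


def _bump_shape(arm: str, cspec: CohortSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear inflammation-bump shape (knot days, shape values).

    Shape 0 at baseline, 1 at the inflammation peak; then the low arm holds
    until day 14 and decays to its final-gain residual while the high arm
    keeps rising.
    """
    p = cspec.inflammation_peak_day
    final = cspec.days[-1]
    base_final = 1.0 + cspec.growth_rate * final
    a = cspec.bump_amplitude
    if arm == "control":
        return np.array([0.0, final]), np.array([0.0, 0.0])
    if arm == "low":
        resid = max(0.0, (cspec.low_final_gain - base_final) / a)
        hold = min(14.0, final)
        return np.array([0.0, p, hold, final]), np.array([0.0, 1.0, 1.0, resid])
    if arm == "high":
        final_shape = (cspec.high_final_gain - base_final) / a
        return np.array([0.0, p, final]), np.array([0.0, 1.0, final_shape])
    raise ValueError(f"unknown arm {arm!r}")


def _relative_volume(arm: str, day: float, cspec: CohortSpec) -> float:
    knots, shape = _bump_shape(arm, cspec)
    return 1.0 + cspec.growth_rate * day + cspec.bump_amplitude * float(
        np.interp(day, knots, shape)
    )


def _lesion_fraction(arm: str, day: float, cspec: CohortSpec, pspec: PhantomSpec) -> float:
    knots, shape = _bump_shape(arm, cspec)
    frac = pspec.lesion_fraction * float(np.interp(day, knots, shape))
    return float(np.clip(frac, 0.0, 0.95))


@dataclass
class SyntheticAnimal:
    """One simulated animal: its designed time course plus per-day phantom specs.

    ``timecourse`` carries the designed quantities (lung volume, lesion
    volumes per echo, fractional uptake) directly from the generative model;
    ``day_specs`` lets callers materialise full image volumes for any day via
    :func:`make_lung_phantom` to run the imaging pipeline end to end.
    """

    animal_id: str
    true_arm: str  # generative label: control / low / high
    timecourse: AnimalTimecourse
    day_specs: Dict[int, PhantomSpec] = field(default_factory=dict)

    def realize(self, day: int):
        return make_lung_phantom(self.day_specs[day])


def make_cohort(cspec: CohortSpec, pspec: PhantomSpec) -> List[SyntheticAnimal]:
    """Generate a longitudinal cohort of designed animal time courses.

    Designed per-day quantities: lung volume follows the arm trajectory with
    multiplicative ``noise_cv`` scatter; lesion volume is the designed lesion
    fraction of the lung; fractional uptake is the PET mixture mean over the
    lung (background plus lesion gain) scaled by lung volume, mirroring how
    total in-ROI activity scales in the imaging pipeline.
    """
    rng = np.random.default_rng(cspec.seed)
    v0 = pspec.lung_fraction * pspec.grid_volume_mm3
    arms = (
        [("control", i) for i in range(cspec.n_control)]
        + [("low", i) for i in range(cspec.n_low)]
        + [("high", i) for i in range(cspec.n_high)]
    )
    uptake_scale = 1.0e-6  # arbitrary activity-per-mm3 to fraction-of-dose scale

    cohort: List[SyntheticAnimal] = []
    for arm, i in arms:
        animal_id = f"{arm[0].upper()}{i + 1:02d}"
        exposure = "saline" if arm == "control" else "bleomycin"
        records: Dict[int, DayRecord] = {}
        day_specs: Dict[int, PhantomSpec] = {}
        for day in cspec.days:
            rel = _relative_volume(arm, day, cspec)
            lf = _lesion_fraction(arm, day, cspec, pspec)

            def jitter() -> float:
                if cspec.noise_cv == 0:
                    return 1.0
                return max(0.05, 1.0 + cspec.noise_cv * rng.standard_normal())

            lung_vol = v0 * rel * jitter()
            lesion_vol = lf * lung_vol
            lesion_noisy = lesion_vol * jitter()
            uptake = (
                pspec.pet_background * lung_vol + pspec.pet_lesion_gain * lesion_vol
            ) * uptake_scale * jitter()
            records[int(day)] = DayRecord(
                lung_volume_mm3=float(lung_vol),
                high_signal_volume_long_mm3=float(lesion_noisy),
                high_signal_volume_short_mm3=float(lesion_noisy),
                fractional_uptake_total=float(uptake),
            )
            day_specs[int(day)] = replace(
                pspec,
                lesion_fraction=lf,
                lung_fraction=min(0.5, pspec.lung_fraction * rel),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        cohort.append(
            SyntheticAnimal(
                animal_id=animal_id,
                true_arm=arm,
                timecourse=AnimalTimecourse(
                    animal_id=animal_id, arm=exposure, records=records
                ),
                day_specs=day_specs,
            )
        )
    return cohort


# ---------------------------------------------------------------------------
# qPCR tables


def make_qpcr_table(
    genes: Sequence[str],
    ref_genes: Sequence[str],
    groups: Sequence[str] = ("control", "bleomycin"),
    effects: Optional[Dict[str, Dict[str, object]]] = None,
    days: Sequence[int] = (3, 7, 14, 21, 28),
    n_per_group: int = 4,
    noise_sd: float = 0.3,
    base_ct: Optional[Dict[str, float]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthesise a wide-format Ct table (sample metadata + one column per gene).

    ``effects[gene][group]`` is a log2 fold change (scalar, or ``{day: lfc}``
    for time-varying targets) relative to the first group, which acts as the
    control.  A +e log2 effect lowers the gene's Ct by e cycles.  Reference
    genes have group- and day-independent expected Ct.
    """
    genes = list(genes)
    ref_genes = list(ref_genes)
    if len(ref_genes) < 1:
        raise ValueError("at least one reference gene is required")
    missing = set(ref_genes) - set(genes)
    if missing:
        raise ValueError(f"reference genes not in gene list: {sorted(missing)}")
    effects = effects or {}
    bad = set(effects) & set(ref_genes)
    if bad:
        raise ValueError(f"effects given for reference genes: {sorted(bad)}")
    if base_ct is None:
        base_ct = {g: 18.0 + 10.0 * (i / max(1, len(genes) - 1)) for i, g in enumerate(genes)}

    rng = np.random.default_rng(seed)
    control_group = groups[0]

    def lfc(gene: str, group: str, day: int) -> float:
        if group == control_group or gene not in effects:
            return 0.0
        spec = effects[gene].get(group, 0.0)
        if isinstance(spec, dict):
            return float(spec.get(day, 0.0))
        return float(spec)

    rows = []
    for day in days:
        for group in groups:
            for i in range(n_per_group):
                row: Dict[str, object] = {
                    "sample_id": f"{group[:4]}_d{day}_{i + 1}",
                    "group": group,
                    "day": int(day),
                }
                for g in genes:
                    ct = base_ct[g] - lfc(g, group, day)
                    if noise_sd > 0:
                        ct += rng.normal(0.0, noise_sd)
                    row[g] = ct
                rows.append(row)
    return pd.DataFrame(rows)
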