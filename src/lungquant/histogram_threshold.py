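"""Automatic "high-signal" lesion thresholding from the lung-ROI histogram.

The lesion biomarker is derived without manual intensity choices: the in-ROI
intensity histogram is built and lightly smoothed; the first (lowest
intensity) substantial peak is taken as the normal-parenchyma mode; on the
right slope of that peak the point of sharpest decline is located; the
straight line tangent to the slope at that point is extended to its x-axis
intercept; and every ROI voxel brighter than that intercept counts as
"high-signal" lesion volume.  Raw intensities are used throughout — no
in-view normalisation — because only the threshold location matters, not
the absolute signal scale.

Numeric conventions (the acquisition software the procedure descends from
does not pin these down; they are configurable here):

* 256 bins over [0, 99.5th in-ROI percentile], overflow clipped into the
  last bin;
* smoothing: centred moving average, 5 bins, nearest-edge padding;
* "first peak": lowest-intensity local maximum of the smoothed counts with
  prominence >= 5% of the global maximum; boundary bin 0 is admitted;
* "sharpest decline": most negative central-difference derivative between
  the peak and the next local minimum, ties broken toward the peak;
* membership is strict: intensity > threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .volume import LungMask, Volume3D


@dataclass(frozen=True)
class HistogramParams:
    """Tunable knobs of the histogram-threshold chain."""

    n_bins: int = 256
    upper_percentile: float = 99.5  # robust top of the binning range
    smooth_window: int = 5  # centred moving-average width (bins)
    prominence_frac: float = 0.05  # min peak prominence vs global max

    def __post_init__(self) -> None:
        if self.n_bins < 16:
            raise ValueError(f"n_bins must be >= 16, got {self.n_bins}")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be a positive odd integer")
        if not 0 < self.upper_percentile <= 100:
            raise ValueError("upper_percentile must lie in (0, 100]")
        if not 0 <= self.prominence_frac < 1:
            raise ValueError("prominence_frac must lie in [0, 1)")


@dataclass
class IntensityHistogram:
    """Binned in-ROI intensity counts plus their smoothed version.

    Bins are half-open ``[e_i, e_{i+1})`` except the last, which is closed
    so that clipped overflow lands inside it.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    smoothed_counts: np.ndarray
    source: str = ""
    n_voxels: int = 0

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass
class ThresholdResult:
    """Threshold provenance and the resulting high-signal volumetry."""

    peak_bin_center: float
    decline_bin_center: float
    tangent_slope: float  # counts per intensity unit, < 0
    tangent_value: float  # smoothed count at the decline point
    threshold: float
    high_signal_voxels: int
    high_signal_volume_mm3: float
    total_roi_volume_mm3: float
    source: str = ""

    @property
    def low_signal_volume_mm3(self) -> float:
        return self.total_roi_volume_mm3 - self.high_signal_volume_mm3

    def to_dict(self) -> dict:
        return {
            "source": self.source,
            "peak_bin_center": self.peak_bin_center,
            "decline_bin_center": self.decline_bin_center,
            "tangent_slope": self.tangent_slope,
            "tangent_value": self.tangent_value,
            "threshold": self.threshold,
            "high_signal_voxels": self.high_signal_voxels,
            "high_signal_volume_mm3": self.high_signal_volume_mm3,
            "total_roi_volume_mm3": self.total_roi_volume_mm3,
        }


# ---------------------------------------------------------------------------
# Histogram construction


def smooth_counts(counts: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with nearest-edge padding."""
    return ndimage.uniform_filter1d(counts.astype(float), size=window, mode="nearest")


def histogram_from_values(
    values: np.ndarray,
    params: HistogramParams = HistogramParams(),
    source: str = "",
    bin_edges: Optional[np.ndarray] = None,
) -> IntensityHistogram:
    """Bin a 1-D array of intensities into an :class:`IntensityHistogram`.

    With default ``bin_edges=None`` the bins span [0, robust maximum] where
    the robust maximum is the configured upper percentile; values beyond the
    range are clipped into the extreme bins so every value is counted once.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("cannot build a histogram from zero voxels")
    if bin_edges is None:
        hi = float(np.percentile(values, params.upper_percentile))
        if hi <= 0:
            hi = max(float(values.max()), np.finfo(float).tiny)
        bin_edges = np.linspace(0.0, hi, params.n_bins + 1)
    else:
        bin_edges = np.asarray(bin_edges, dtype=float)
    clipped = np.clip(values, bin_edges[0], bin_edges[-1])
    counts, _ = np.histogram(clipped, bins=bin_edges)
    return IntensityHistogram(
        bin_edges=bin_edges,
        counts=counts,
        smoothed_counts=smooth_counts(counts, params.smooth_window),
        source=source,
        n_voxels=int(values.size),
    )


def build_histogram(
    vol: Volume3D,
    mask: LungMask,
    params: HistogramParams = HistogramParams(),
) -> IntensityHistogram:
    """Histogram of the in-ROI voxel intensities of ``vol``."""
    mask.check_congruent(vol)
    if mask.n_voxels == 0:
        raise ValueError("empty lung mask: no ROI voxels to histogram")
    source = (
        f"{vol.modality}"
        + (f" TE={vol.echo_time_ms}ms" if vol.echo_time_ms is not None else "")
    )
    return histogram_from_values(vol.data[mask.mask], params, source=source)


# ---------------------------------------------------------------------------
# Peak / decline / tangent chain


def _local_maxima(s: np.ndarray) -> np.ndarray:
    """Indices of local maxima, boundary bins admitted; plateaus yield their
    first bin.  A flat array has no maxima.

    A maximal run of equal values ``s[a..b]`` is a local maximum when the
    terrain falls away on every side that exists: ``a == 0`` or
    ``s[a-1] < s[a]``, and ``b == n-1`` or ``s[b+1] < s[a]``.  The run
    spanning the whole array (a flat histogram) is never a maximum.
    """
    n = len(s)
    out = []
    a = 0
    while a < n:
        b = a
        while b + 1 < n and s[b + 1] == s[a]:
            b += 1
        if not (a == 0 and b == n - 1):
            rises_left = a == 0 or s[a - 1] < s[a]
            falls_right = b == n - 1 or s[b + 1] < s[a]
            if rises_left and falls_right:
                out.append(a)
        a = b + 1
    return np.asarray(out, dtype=int)


def _prominence(s: np.ndarray, i: int) -> float:
    """Topographic prominence of the maximum at ``i``.

    Walk outward on each side until terrain higher than ``s[i]`` or the
    array boundary; the prominence is the drop from the peak to the higher
    of the per-side lowest points passed.  A side that does not exist (the
    peak sits at the boundary) imposes no base, so a boundary peak keeps
    the prominence of its one slope.
    """
    bases = []
    low = None
    j = i - 1
    while j >= 0 and s[j] <= s[i]:
        low = s[j] if low is None else min(low, s[j])
        j -= 1
    if low is not None:
        bases.append(low)
    low = None
    j = i + 1
    while j < len(s) and s[j] <= s[i]:
        low = s[j] if low is None else min(low, s[j])
        j += 1
    if low is not None:
        bases.append(low)
    if not bases:
        return 0.0
    return float(s[i] - max(bases))


def find_first_peak(h: IntensityHistogram, prominence_frac: float = 0.05) -> int:
    """Lowest-intensity qualifying local maximum of the smoothed counts.

    This is the normal-parenchyma mode: the ROI excludes airspace-free
    structures, so the first substantial maximum is the low-signal lung
    tissue, never the lesion mode further right.
    """
    s = h.smoothed_counts
    maxima = _local_maxima(s)
    if maxima.size == 0:
        raise ValueError("degenerate histogram: no local maximum")
    floor = prominence_frac * float(np.max(s))
    for i in maxima:
        if _prominence(s, int(i)) >= floor:
            return int(i)
    raise ValueError("degenerate histogram: no peak with sufficient prominence")


def _central_diff(s: np.ndarray) -> np.ndarray:
    """Central-difference derivative in counts per bin (one-sided at edges)."""
    return np.gradient(s.astype(float))


def find_sharpest_decline(
    h: IntensityHistogram, peak: int, prominence_frac: float = 0.05
) -> int:
    """Bin of steepest descent on the right slope of the peak.

    Searches from the peak to the first subsequent local minimum (or the
    last bin) and returns the bin with the most negative central-difference
    derivative; ties go to the bin closest to the peak.  Counting noise puts
    shallow dips all along the slope, so a bounding minimum must be
    substantial: it qualifies only with topographic prominence (of the
    negated counts) at least ``prominence_frac`` of the global maximum —
    the mirror image of the rule peaks must pass.
    """
    s = h.smoothed_counts
    n = len(s)
    if not 0 <= peak < n - 1:
        raise ValueError(f"peak index {peak} leaves no right slope")
    # first substantial local minimum strictly right of the peak
    floor = prominence_frac * float(np.max(s))
    stop = n - 1
    for j in _local_maxima(-s):
        if j > peak and _prominence(-s, int(j)) >= floor:
            stop = int(j)
            break
    d = _central_diff(s)
    window = np.arange(peak + 1, stop + 1)
    if window.size == 0:
        raise ValueError("no declining slope right of the peak")
    j = int(window[np.argmin(d[window])])
    if d[j] >= 0:
        raise ValueError("no declining slope right of the peak")
    return j


def tangent_threshold(h: IntensityHistogram, decline: int) -> float:
    """x-intercept of the line tangent to the smoothed histogram at ``decline``.

    With the smoothed count ``v`` and the central-difference slope ``s``
    (counts per intensity unit) at the decline bin centre ``x0``, the
    tangent ``y = v + s (x - x0)`` crosses zero at ``x0 - v/s``.
    """
    sm = h.smoothed_counts
    slope = float(_central_diff(sm)[decline]) / h.bin_width
    if slope >= 0:
        raise ValueError(f"tangent slope must be negative, got {slope}")
    v = float(sm[decline])
    if v < 0:
        raise ValueError("smoothed count at the decline point must be nonnegative")
    x0 = float(h.bin_centers[decline])
    return x0 - v / slope


def compute_threshold(
    h: IntensityHistogram, params: HistogramParams = HistogramParams()
) -> Tuple[int, int, float]:
    """Run peak -> decline -> tangent and return (peak, decline, threshold)."""
    peak = find_first_peak(h, params.prominence_frac)
    decline = find_sharpest_decline(h, peak, params.prominence_frac)
    return peak, decline, tangent_threshold(h, decline)


# ---------------------------------------------------------------------------
# Volumetry


def high_signal_volume(
    vol: Volume3D,
    mask: LungMask,
    threshold: float,
    provenance: Optional[dict] = None,
    return_mask: bool = False,
):
    """Count in-ROI voxels strictly brighter than ``threshold``.

    Returns a :class:`ThresholdResult`; with ``return_mask=True`` also
    returns the binary high-signal mask (the cyan-overlay analogue of the
    lesion rendering).
    """
    mask.check_congruent(vol)
    if not np.isfinite(threshold):
        raise ValueError(f"threshold must be finite, got {threshold}")
    prov = provenance or {}
    in_roi = vol.data[mask.mask]
    n_high = int(np.count_nonzero(in_roi > threshold))
    vx = mask.voxel_volume_mm3
    result = ThresholdResult(
        peak_bin_center=float(prov.get("peak_bin_center", np.nan)),
        decline_bin_center=float(prov.get("decline_bin_center", np.nan)),
        tangent_slope=float(prov.get("tangent_slope", np.nan)),
        tangent_value=float(prov.get("tangent_value", np.nan)),
        threshold=float(threshold),
        high_signal_voxels=n_high,
        high_signal_volume_mm3=n_high * vx,
        total_roi_volume_mm3=mask.volume_mm3,
        source=str(prov.get("source", "")),
    )
    if return_mask:
        high = np.zeros_like(mask.mask)
        high[mask.mask] = vol.data[mask.mask] > threshold
        return result, LungMask(mask=high, voxel_mm=mask.voxel_mm)
    return result


def analyze_volume(
    vol: Volume3D,
    mask: LungMask,
    params: HistogramParams = HistogramParams(),
) -> ThresholdResult:
    """Full chain for one echo: histogram -> threshold -> high-signal volume."""
    h = build_histogram(vol, mask, params)
    peak, decline, thr = compute_threshold(h, params)
    sm = h.smoothed_counts
    prov = {
        "peak_bin_center": h.bin_centers[peak],
        "decline_bin_center": h.bin_centers[decline],
        "tangent_slope": float(_central_diff(sm)[decline]) / h.bin_width,
        "tangent_value": float(sm[decline]),
        "source": h.source,
    }
    return high_signal_volume(vol, mask, thr, provenance=prov)


@dataclass
class ScanQuantification:
    """Per-echo threshold results plus the total lung volume of one scan."""

    short_echo: ThresholdResult
    long_echo: ThresholdResult
    total_lung_volume_mm3: float


def quantify_scan(
    short_echo: Volume3D,
    long_echo: Volume3D,
    mask: LungMask,
    params: HistogramParams = HistogramParams(),
) -> ScanQuantification:
    """Run the threshold chain independently per echo and report lung volume."""
    results = {}
    for label, vol in (("short", short_echo), ("long", long_echo)):
        try:
            results[label] = analyze_volume(vol, mask, params)
        except ValueError as exc:
            raise ValueError(f"{label}-echo analysis failed: {exc}") from exc
    return ScanQuantification(
        short_echo=results["short"],
        long_echo=results["long"],
        total_lung_volume_mm3=mask.volume_mm3,
    )
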