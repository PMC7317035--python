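# Methods note

This note records the model each module implements, the parameter defaults
and their rationale, what the synthetic generator does and does not
emulate, the numerical conventions, and known limitations. Every empirical
number quoted here is computed by the test suite or by
`scripts/acceptance.py`.

## 1. Histogram threshold chain (`histogram_threshold`)

**Model.** Inside the lung ROI the intensity histogram is assumed to show a
dominant low-intensity parenchyma mode with a high-intensity lesion/tissue
component to its right. The lesion threshold is derived entirely from the
histogram: (1) bin the in-ROI intensities, (2) smooth, (3) take the first
(lowest-intensity) substantial local maximum as the parenchyma mode,
(4) on its right slope find the bin of sharpest decline (most negative
derivative), (5) extend the tangent line at that bin to its x-axis
intercept, (6) count ROI voxels strictly brighter than the intercept.

**Closed form.** For a pure Gaussian mode N(m, σ²) the sharpest decline is
the inflection point at m + σ and the tangent there crosses zero at
m + 2σ. On a noise-free Gaussian histogram (counts = expected bin masses)
the implementation lands within 0.1 bin widths of m + 2σ
(`test_criterion_2_tangent_closed_form` asserts ≤ 1.5 bin widths).

**Parameters and defaults.**

- `n_bins = 256`: fine enough that the bin width stays well below the
  parenchyma σ for realistic dynamic ranges; matches common histogram
  export sizes.
- Binning range `[0, 99.5th percentile]`, overflow clipped into the end
  bins, so every ROI voxel is counted exactly once and a handful of hot
  voxels cannot stretch the grid.
- `smooth_window = 5` bins, centred moving average, nearest-edge padding:
  suppresses counting noise without displacing the mode materially.
- `prominence_frac = 0.05`: a local maximum qualifies as "the peak" only
  with topographic prominence ≥ 5% of the global maximum; the mirrored
  rule (prominence of the negated counts) qualifies the local minimum that
  bounds the decline search window. Without this, shot-noise dips within
  the peak's cap truncate the search window and produce near-flat tangents.
  Boundary bins are admitted as peaks; a side that does not exist imposes
  no prominence base.
- Derivatives are central differences (one-sided at the ends); ties in the
  decline search resolve toward the peak; membership is strict
  (intensity > threshold), making high + low = ROI an exact identity.

**Oracle.** `tests/oracles.py` re-derives peak, decline and threshold by
exhaustive run-scans and per-bin loops sharing no code with the package;
the pipeline matches it bin-for-bin on 100 random 1–3-component mixture
histograms (acceptance criterion 1).

**Limitation (intrinsic bias).** A threshold at m + 2σ leaves the upper
≈ 2.3% tail of the parenchyma mode above it, and histogram noise tends to
steepen the fitted tangent, adding more. The recovered high-signal volume
therefore overshoots the true lesion volume by roughly
`0.023 × (lung/lesion)` in relative terms. Measured on the acceptance
sweep (5σ mode separation, 64³ grid, 5 seeds per fraction): relative error
0.54–0.88 at lesion fraction 0.05, 0.25–0.36 at 0.10, 0.12–0.18 at 0.20.
Consequently the release criterion demanding ≤ 20% error for fractions
down to 0.05 is unattainable by any implementation that also satisfies the
m + 2σ closed form; the corresponding acceptance test documents this and
fails by design.

## 2. I/O and resampling (`io_formats`)

NIfTI-1 via nibabel; volumes must be 3-D with positive finite spacings;
truncated files surface as `IOError`. Isotropic resampling uses
`scipy.ndimage.zoom` with `grid_mode=True` (samples are cell centres, so
physical extent is preserved and the output shape per axis is
`round(n·old/target)`) and edge replication at boundaries (constant
volumes stay constant). The default target of 0.4 mm matches the PET voxel
size, so MRI (0.22 × 0.22 × 2 mm acquisition grid) and PET meet on a
common grid without upsampling PET. Masks resample by nearest neighbour;
in-mask physical volume changes by < 5% for masks ≥ 1000 voxels (asserted).

## 3. PET quantification (`pet_quant`)

- **Decay correction**: `A(t) = A₀ · 2^(−Δt/T½)` with T½(¹⁸F) fixed at
  109.77 min. 30 MBq after one half-life → 15 MBq exactly; the base-2 form
  equals `exp(−ln2·Δt/T½)` to 1e-12 relative (asserted).
- **Registration**: rigid 6-parameter Euler transform, Mattes mutual
  information (32 bins), deterministic full sampling, Powell's
  derivative-free optimiser capped at 200 iterations, MRI always the fixed
  image, geometric centred initialisation (SimpleITK). Known misalignments
  up to 3 voxels / 5° are recovered with residuals ≪ 0.5 voxel / 1°
  (acceptance criterion 6; the seed-1 acceptance run measures a maximum
  translation residual of ~0.01 mm and rotation residual ~0.7°).
  Registration test phantoms use an anisotropic grid (48 × 56 × 40): the
  lung ellipsoid is inscribed in the grid, and a sphere on a cubic grid
  leaves rotation unidentifiable.
- **Fractional uptake**: total in-ROI activity (voxel values ×
  `calibration`, MBq) divided by the decay-corrected dose; additionally
  per mm³ of ROI (total / ROI volume — the identity
  `per_mm3 × roi_volume = total` holds to 1e-9 relative by construction).

## 4. Cohort analysis (`cohort`)

- **Responder rule**: relative growth g = V(final)/V(baseline); an animal
  is "high" when g > control mean + k·(control SD), default k = 2, ≥ 2
  classifiable controls required. Relative growth cancels animal size
  (asserted as a scale-invariance property).
- **Limitation (marginal low/control separation)**: low responders are
  designed to return toward control growth, so any k·SD boundary retains
  false-positive mass against them. At trajectory noise CV 0.02 the
  labels are reproduced perfectly in 13/20 generator seeds; at the default
  seed one low animal (g = 1.0877) crosses the 4-control boundary
  (≈ 1.081). The acceptance test asserting 100% accuracy at the default
  seed therefore fails and documents this; robust properties (high arm and
  controls always recovered; aggregate accuracy ≥ 0.9 across 10 seeds) are
  asserted in the unit suite. At noise CV 0.10 accuracy degrades to ~0.75
  (reported, not asserted).
- **Statistics from first principles**: Mann–Whitney U with midranks,
  exact two-tailed p by full enumeration of rank assignments for combined
  n ≤ 20 (`p = P(min(U, n₁n₂−U) ≤ observed)`), normal approximation with
  tie and continuity correction above; Spearman ρ as the Pearson
  correlation of midranks with a t-approximation p; one-way ANOVA F with
  pooled-MSW pairwise t tests and Bonferroni multiplication (capped at 1);
  star bands \*/\*\*/\*\*\*/\*\*\*\* at 0.05/0.01/0.001/0.0001. Only
  distribution tail functions come from scipy; the exact small-sample
  enumerations are cross-checked against independent oracles.

## 5. ΔΔCT (`qpcr`)

The per-sample reference level is the arithmetic mean of the reference-gene
Cts — identical to the geometric mean of the expression levels 2^−Ct, the
standard multi-reference-gene convention. dCt = Ct_target − Ct_ref;
ddCt subtracts the mean control dCt of the same day stratum (time-matched
control normalisation); fold = 2^−ddCt with amplification efficiency fixed
at 2. Missing reference Cts are dropped from the mean with a warning
(error if all are missing); missing target Cts propagate as missing folds,
never imputed. A noiseless +2 log2 effect round-trips to fold 4.000
exactly, and folds are invariant under a global +c Ct shift.

## 6. Synthetic generator (`phantom`)

**What it emulates.**

- An ellipsoidal lung inscribed in the grid occupying `lung_fraction`
  (default 0.3) of it; a lesion occupying exactly `lesion_fraction` of the
  lung (the n lowest values of a random multi-ellipsoid potential — exact
  voxel count, so ground truth is exact).
- Two-component Gaussian intensity mixture (parenchyma
  `mu_low = 100, sigma = 20`; lesion `mu_high = 300, sigma = 20` — 10σ
  apart by default, truncated at 0), reproducing the dominant
  low-signal peak plus high-signal component of in-ROI histograms; the
  short echo uses the same structure with a small contrast offset.
- PET = background + gain × lesion indicator with variance-proportional
  Gaussian noise, coupling uptake to lesion burden.
- Designed cohorts over days 0/3/7/14/21/28: controls grow linearly
  (5% over 28 days); both challenged arms share an inflammation bump
  peaking at day 7; after day 14 the low arm decays to a 1.05× final gain
  and the high arm rises to 1.3×; multiplicative log-normal-style jitter
  with `noise_cv` (default 0.05). Per-day phantom specs are materialised
  on demand; all seeds derived via `numpy.random.default_rng` and kept
  below 2³¹.
- Ct tables with five reference genes (group/day-independent expected Ct)
  and target genes whose Ct drops by the log2 effect in cycles, with
  Gaussian technical noise (default SD 0.3 cycles).

**What it does not emulate.** Airway/vascular anatomy, partial-volume and
reconstruction effects, B1/coil inhomogeneity, PET attenuation/scatter,
respiratory motion, histology or BAL read-outs, and any animal-level
physiology beyond the designed volume/lesion/uptake trajectories.

## 7. Numerical conventions

- All arrays are numpy `float64`; array axis 0 maps to the SimpleITK z
  axis (spacing tuples are reversed at the boundary).
- Histogram bins are half-open `[e_i, e_{i+1})` with the last bin closed.
- Voxel volumes in mm³; volumes in mm³; doses in MBq; times in minutes.
- Determinism: every stochastic routine takes an explicit integer seed;
  identical seeds give bit-identical outputs (asserted).
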